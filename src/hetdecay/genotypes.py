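"""Core genotype containers.

A :class:`GenotypeTable` holds diploid genotype calls at biallelic SNPs for a
set of individuals, with per-site metadata (contig, position, allele pair and,
when known, the ancestral allele inferred from an outgroup).  Genotypes are
encoded as ``0`` (hom-ref), ``1`` (het), ``2`` (hom-alt) and ``-1`` (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
_NUCS = frozenset("ACGT")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP site."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele not in _NUCS or self.alt_allele not in _NUCS:
            raise ValueError(
                f"alleles must be single nucleotides, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.ancestral_allele is not None and self.ancestral_allele not in _NUCS:
            raise ValueError(
                f"ancestral allele must be A/C/G/T or None, got "
                f"{self.ancestral_allele!r}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.position)


@dataclass(frozen=True)
class SampleMeta:
    """Per-specimen metadata: location, collection year, optional group."""

    sample_id: str
    longitude: float
    latitude: float
    year: int
    group: str | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")


def validate_years(meta: Iterable[SampleMeta], window: tuple[int, int] = (1800, 2100)) -> None:
    """Raise if any collection year falls outside a plausible window."""
    lo, hi = window
    bad = [m.sample_id for m in meta if not lo <= m.year <= hi]
    if bad:
        raise ValueError(f"collection years outside [{lo}, {hi}] for samples: {bad}")


@dataclass(frozen=True)
class HetRecord:
    """Per-individual heterozygosity: het calls over genotyped positions."""

    sample_id: str
    n_het: int
    n_genotyped: int

    def __post_init__(self) -> None:
        if self.n_genotyped <= 0:
            raise ValueError(f"{self.sample_id}: n_genotyped must be positive")
        if not 0 <= self.n_het <= self.n_genotyped:
            raise ValueError(f"{self.sample_id}: n_het must lie in [0, n_genotyped]")

    @property
    def heterozygosity(self) -> float:
        return self.n_het / self.n_genotyped


class GenotypeTable:
    """Individuals x biallelic-SNP genotype matrix.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, one per matrix row.
    sites : sequence of SiteRecord
        Site metadata, one per matrix column; (contig, position) unique.
    genotypes : ndarray of shape (n_samples, n_sites)
        Integer codes 0/1/2 with -1 for missing.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        sites: Sequence[SiteRecord],
        genotypes: np.ndarray,
    ) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(sample_ids), len(sites)):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"({len(sample_ids)}, {len(sites)})"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique")
        keys = [s.key for s in sites]
        if len(set(keys)) != len(keys):
            raise ValueError("(contig, position) pairs must be unique")
        valid = np.isin(genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.sample_ids = list(sample_ids)
        self.sites = list(sites)
        self.genotypes = genotypes

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_sites)

    def site_call_rates(self) -> np.ndarray:
        """Fraction of non-missing genotypes per site."""
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.genotypes != MISSING).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.genotypes != MISSING).mean(axis=1)

    def take_sites(self, index: np.ndarray | Sequence[int]) -> "GenotypeTable":
        index = np.asarray(index, dtype=int)
        return GenotypeTable(
            self.sample_ids,
            [self.sites[i] for i in index],
            self.genotypes[:, index],
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeTable":
        index = np.asarray(index, dtype=int)
        return GenotypeTable(
            [self.sample_ids[i] for i in index],
            self.sites,
            self.genotypes[index, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.sites == other.sites
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:
        return f"GenotypeTable(n_samples={self.n_samples}, n_sites={self.n_sites})"


@dataclass
class QCStage:
    name: str
    n_sites_before: int
    n_sites_after: int
    n_samples_before: int
    n_samples_after: int
    params: Mapping[str, object] = field(default_factory=dict)


@dataclass
class QCReport:
    """Ordered per-stage bookkeeping of the cleaning chain."""

    stages: list[QCStage] = field(default_factory=list)

    def add(self, stage: QCStage) -> None:
        if self.stages:
            prev = self.stages[-1]
            if (
                stage.n_sites_before != prev.n_sites_after
                or stage.n_samples_before != prev.n_samples_after
            ):
                raise ValueError("QC stage counts are not chained consistently")
        if stage.n_sites_after > stage.n_sites_before:
            raise ValueError("site count increased within a QC stage")
        if stage.n_samples_after > stage.n_samples_before:
            raise ValueError("sample count increased within a QC stage")
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "n_sites_before": s.n_sites_before,
                    "n_sites_after": s.n_sites_after,
                    "n_samples_before": s.n_samples_before,
                    "n_samples_after": s.n_samples_after,
                    "params": dict(s.params),
                }
                for s in self.stages
            ]
        )
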