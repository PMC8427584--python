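"""Genotype cleaning chain for museum-specimen SNP data.

Dried museum skins accumulate postmortem cytosine deamination, which surfaces
as spurious C->T (and complementary G->A) transition calls.  The cleaning
chain applied here, in order: per-site call-rate filter, removal of candidate
damage transitions using an outgroup ancestral-allele call, thinning to one
site per contig, per-individual call-rate filter, and a minor-allele-frequency
filter.  Each stage is a projection (a subset of rows/columns), so the chain
is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import MISSING, GenotypeTable, HetRecord, QCReport, QCStage

logger = logging.getLogger(__name__)

#: transition pairs produced by deamination: ancestral -> derived
_DAMAGE = {("C", "T"), ("G", "A")}


def _check_rate(min_rate: float) -> float:
    min_rate = float(min_rate)
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError(f"rate threshold must be in [0, 1], got {min_rate}")
    return min_rate


def site_call_rate_filter(table: GenotypeTable, min_rate: float) -> GenotypeTable:
    """Keep sites whose fraction of non-missing genotypes is >= ``min_rate``."""
    min_rate = _check_rate(min_rate)
    keep = np.flatnonzero(table.site_call_rates() >= min_rate)
    return table.take_sites(keep)


def damage_site_indices(table: GenotypeTable) -> np.ndarray:
    """Indices of sites matching the deamination signature.

    A site is flagged when its allele pair is {C,T} with ancestral C, or
    {G,A} with ancestral G — i.e. the derived allele is the deamination
    product, regardless of which allele is labelled ref in the VCF.
    """
    flagged = []
    for j, s in enumerate(table.sites):
        anc = s.ancestral_allele
        if anc is None:
            continue
        pair = {s.ref_allele, s.alt_allele}
        if anc in pair:
            derived = (pair - {anc}).pop()
            if (anc, derived) in _DAMAGE:
                flagged.append(j)
    return np.asarray(flagged, dtype=int)


def damage_site_filter(table: GenotypeTable) -> GenotypeTable:
    """Remove candidate postmortem-damage transitions (C->T / G->A).

    Sites with an unknown ancestral allele cannot be classified and are
    retained (counted as unfilterable by :func:`run_qc_chain`).
    """
    drop = set(damage_site_indices(table).tolist())
    keep = [j for j in range(table.n_sites) if j not in drop]
    n_unknown = sum(1 for s in table.sites if s.ancestral_allele is None)
    if n_unknown:
        logger.info("damage filter: %d sites lack an ancestral call (retained)", n_unknown)
    return table.take_sites(keep)


def thin_one_per_contig(
    table: GenotypeTable, strategy: str = "first", seed: int | None = None
) -> GenotypeTable:
    """Keep exactly one site per contig.

    ``strategy="first"`` keeps the lowest position on each contig
    (deterministic); ``strategy="random"`` picks uniformly and requires a
    seed for reproducibility.
    """
    if strategy not in ("first", "random"):
        raise ValueError(f"strategy must be 'first' or 'random', got {strategy!r}")
    if strategy == "random" and seed is None:
        raise ValueError("strategy='random' requires a seed")
    by_contig: dict[str, list[int]] = {}
    for j, s in enumerate(table.sites):
        by_contig.setdefault(s.contig, []).append(j)
    rng = np.random.default_rng(seed)
    keep = []
    for contig, idx in by_contig.items():
        if strategy == "first":
            keep.append(min(idx, key=lambda j: table.sites[j].position))
        else:
            keep.append(idx[rng.integers(len(idx))])
    keep.sort()
    return table.take_sites(keep)


def individual_call_rate_filter(table: GenotypeTable, min_rate: float) -> GenotypeTable:
    """Keep samples whose fraction of non-missing genotypes is >= ``min_rate``."""
    min_rate = _check_rate(min_rate)
    keep = np.flatnonzero(table.sample_call_rates() >= min_rate)
    if keep.size == 0:
        raise ValueError("individual call-rate filter removed every sample")
    return table.take_samples(keep)


def allele_frequencies(table: GenotypeTable) -> np.ndarray:
    """Alt-allele frequency per site from non-missing diploid genotypes.

    Sites with no genotyped individuals get frequency NaN.
    """
    g = table.genotypes
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0).astype(float)
    n_alleles = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


def maf_filter(table: GenotypeTable, min_maf: float) -> GenotypeTable:
    """Keep sites with minor-allele frequency strictly greater than ``min_maf``."""
    min_maf = float(min_maf)
    if not 0.0 <= min_maf < 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5), got {min_maf}")
    f = allele_frequencies(table)
    maf = np.minimum(f, 1.0 - f)
    keep = np.flatnonzero(np.nan_to_num(maf, nan=0.0) > min_maf)
    return table.take_sites(keep)


@dataclass
class QCConfig:
    """Thresholds and options for the full cleaning chain.

    ``rate_semantics="call_rate"`` reads the 20%/40% thresholds as minimum
    genotyping (call) rates; ``"missingness"`` reads them as maximum missing
    fractions, i.e. a call-rate floor of ``1 - threshold``.
    """

    min_site_rate: float = 0.2
    min_ind_rate: float = 0.4
    min_maf: float = 0.01
    thin_strategy: str = "first"
    seed: int | None = None
    rate_semantics: str = "call_rate"
    thin: bool = True

    def __post_init__(self) -> None:
        if self.rate_semantics not in ("call_rate", "missingness"):
            raise ValueError(
                f"rate_semantics must be 'call_rate' or 'missingness', "
                f"got {self.rate_semantics!r}"
            )

    def effective_site_rate(self) -> float:
        if self.rate_semantics == "missingness":
            return 1.0 - self.min_site_rate
        return self.min_site_rate

    def effective_ind_rate(self) -> float:
        if self.rate_semantics == "missingness":
            return 1.0 - self.min_ind_rate
        return self.min_ind_rate


def run_qc_chain(
    table: GenotypeTable, config: QCConfig | None = None
) -> tuple[GenotypeTable, QCReport]:
    """Apply the ordered cleaning chain and record per-stage counts.

    Order: site call rate -> damage removal -> one site per contig ->
    individual call rate -> MAF.
    """
    config = config or QCConfig()
    report = QCReport()

    def _record(name: str, before: GenotypeTable, after: GenotypeTable, **params: object) -> None:
        report.add(
            QCStage(
                name=name,
                n_sites_before=before.n_sites,
                n_sites_after=after.n_sites,
                n_samples_before=before.n_samples,
                n_samples_after=after.n_samples,
                params=params,
            )
        )

    t0 = table
    t1 = site_call_rate_filter(t0, config.effective_site_rate())
    _record("site_call_rate", t0, t1, min_rate=config.effective_site_rate(),
            rate_semantics=config.rate_semantics)

    n_unfilterable = sum(1 for s in t1.sites if s.ancestral_allele is None)
    t2 = damage_site_filter(t1)
    _record("damage_transitions", t1, t2, n_unfilterable=n_unfilterable)

    if config.thin:
        t3 = thin_one_per_contig(t2, config.thin_strategy, config.seed)
        _record("thin_one_per_contig", t2, t3, strategy=config.thin_strategy)
    else:
        t3 = t2
        _record("thin_one_per_contig", t2, t3, strategy="skipped")

    t4 = individual_call_rate_filter(t3, config.effective_ind_rate())
    _record("individual_call_rate", t3, t4, min_rate=config.effective_ind_rate(),
            rate_semantics=config.rate_semantics)

    t5 = maf_filter(t4, config.min_maf)
    _record("maf", t4, t5, min_maf=config.min_maf)

    return t5, report


def compute_heterozygosity(
    table: GenotypeTable,
    callable_totals: Mapping[str, int] | None = None,
) -> list[HetRecord]:
    """Per-individual heterozygosity records.

    The numerator is the count of het calls per sample.  The denominator is
    the number of non-missing genotyped sites in the table, unless
    ``callable_totals`` provides a per-sample total of callable base pairs —
    the convention that yields per-base-pair heterozygosities on the order of
    1e-4 when invariant assembled positions are included.
    """
    g = table.genotypes
    n_het = (g == 1).sum(axis=1)
    n_called = (g != MISSING).sum(axis=1)
    records = []
    for i, sid in enumerate(table.sample_ids):
        if callable_totals is not None and sid in callable_totals:
            denom = int(callable_totals[sid])
        else:
            denom = int(n_called[i])
        if denom <= 0:
            raise ValueError(f"sample {sid!r} has zero genotyped positions")
        records.append(HetRecord(sample_id=sid, n_het=int(n_het[i]), n_genotyped=denom))
    return records


class QCPipeline(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`run_qc_chain`.

    ``transform`` maps a :class:`GenotypeTable` to its cleaned version; the
    per-stage report from the last transform is stored on ``report_``.
    """

    def __init__(
        self,
        min_site_rate: float = 0.2,
        min_ind_rate: float = 0.4,
        min_maf: float = 0.01,
        thin_strategy: str = "first",
        seed: int | None = None,
        rate_semantics: str = "call_rate",
        thin: bool = True,
    ) -> None:
        self.min_site_rate = min_site_rate
        self.min_ind_rate = min_ind_rate
        self.min_maf = min_maf
        self.thin_strategy = thin_strategy
        self.seed = seed
        self.rate_semantics = rate_semantics
        self.thin = thin

    def _config(self) -> QCConfig:
        return QCConfig(
            min_site_rate=self.min_site_rate,
            min_ind_rate=self.min_ind_rate,
            min_maf=self.min_maf,
            thin_strategy=self.thin_strategy,
            seed=self.seed,
            rate_semantics=self.rate_semantics,
            thin=self.thin,
        )

    def fit(self, X: GenotypeTable, y: object = None) -> "QCPipeline":
        self.n_sites_in_ = X.n_sites
        return self

    def transform(self, X: GenotypeTable) -> GenotypeTable:
        cleaned, report = run_qc_chain(X, self._config())
        self.report_ = report
        return cleaned
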