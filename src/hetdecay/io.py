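"""Readers and writers for genotype tables, metadata and results.

Supported inputs: uncompressed or bgzipped VCF (biallelic SNPs; ancestral
allele from an ``AA`` INFO field or a sidecar TSV), a plain genotype TSV
(rows = samples, columns = ``contig:position:ref:alt``, cells 0/1/2/NA), and
a metadata TSV with columns ``sample_id longitude latitude year [group]``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    GenotypeTable,
    HetRecord,
    QCReport,
    SampleMeta,
    SiteRecord,
    validate_years,
)

logger = logging.getLogger(__name__)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "longitude", "latitude", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path} missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    records = []
    for row in df.itertuples(index=False):
        group = getattr(row, "group", None)
        if group is not None and (pd.isna(group) or group == ""):
            group = None
        records.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                longitude=float(row.longitude),
                latitude=float(row.latitude),
                year=int(row.year),
                group=None if group is None else str(group),
            )
        )
    validate_years(records)
    return records


def read_ancestral_tsv(path: str | Path) -> dict[tuple[str, int], str]:
    """Read a sidecar TSV ``contig  position  ancestral``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "position", "ancestral"],
                     dtype={"contig": str, "ancestral": str}, comment="#")
    return {
        (str(r.contig), int(r.position)): str(r.ancestral).upper()
        for r in df.itertuples(index=False)
        if str(r.ancestral).upper() in "ACGT" and len(str(r.ancestral)) == 1
    }


def read_vcf(
    path: str | Path,
    ancestral: Mapping[tuple[str, int], str] | None = None,
) -> GenotypeTable:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeTable`.

    Multi-allelic or non-SNP records are skipped with a warning.  The
    ancestral allele is taken from the ``AA`` INFO key, overridden by the
    ``ancestral`` mapping when given.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    sites: list[SiteRecord] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if ref not in "ACGT" or alt not in "ACGT":
            n_skipped += 1
            continue
        aa = None
        if ancestral is not None:
            aa = ancestral.get((var.CHROM, var.POS))
        if aa is None:
            raw = var.INFO.get("AA")
            if raw is not None:
                raw = str(raw).upper()
                if raw in "ACGT" and len(raw) == 1:
                    aa = raw
        sites.append(
            SiteRecord(
                contig=var.CHROM,
                position=var.POS,
                ref_allele=ref,
                alt_allele=alt,
                ancestral_allele=aa,
            )
        )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        row = np.full(len(sample_ids), MISSING, dtype=np.int8)
        row[gt == 0] = 0
        row[gt == 1] = 1
        row[gt == 3] = 2
        rows.append(row)
    if n_skipped:
        logger.warning("%s: skipped %d non-biallelic-SNP records", path, n_skipped)
    geno = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeTable(sample_ids, sites, geno)


def _parse_site_column(name: str) -> SiteRecord:
    parts = name.split(":")
    if len(parts) != 4:
        raise ValueError(
            f"genotype TSV column {name!r} is not of the form contig:position:ref:alt"
        )
    contig, pos, ref, alt = parts
    return SiteRecord(contig=contig, position=int(pos), ref_allele=ref.upper(),
                      alt_allele=alt.upper())


def read_genotype_tsv(
    path: str | Path,
    ancestral: Mapping[tuple[str, int], str] | None = None,
) -> GenotypeTable:
    """Read a genotype TSV (rows=samples, columns=``contig:pos:ref:alt``)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    sites = []
    for name in df.columns:
        rec = _parse_site_column(str(name))
        if ancestral is not None and rec.key in ancestral:
            rec = SiteRecord(rec.contig, rec.position, rec.ref_allele,
                             rec.alt_allele, ancestral[rec.key])
        sites.append(rec)
    geno = df.to_numpy(dtype=float)
    out = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeTable([str(s) for s in df.index], sites, out)


def read_genotype_table(
    genotype_path: str | Path,
    metadata_path: str | Path,
    ancestral_path: str | Path | None = None,
) -> tuple[GenotypeTable, list[SampleMeta]]:
    """Read genotypes (VCF or TSV, by extension) plus sample metadata.

    Every genotyped sample must appear in the metadata; missing ids raise a
    ValueError naming them.
    """
    genotype_path = Path(genotype_path)
    if not genotype_path.exists():
        raise FileNotFoundError(genotype_path)
    ancestral = read_ancestral_tsv(ancestral_path) if ancestral_path else None
    suffixes = "".join(genotype_path.suffixes).lower()
    if ".vcf" in suffixes:
        table = read_vcf(genotype_path, ancestral)
    else:
        table = read_genotype_tsv(genotype_path, ancestral)
    meta = read_metadata(metadata_path)
    by_id = {m.sample_id: m for m in meta}
    absent = [sid for sid in table.sample_ids if sid not in by_id]
    if absent:
        raise ValueError(f"samples missing from metadata: {absent}")
    meta_ordered = [by_id[sid] for sid in table.sample_ids]
    return table, meta_ordered


def write_genotype_tsv(table: GenotypeTable, path: str | Path) -> None:
    cols = [f"{s.contig}:{s.position}:{s.ref_allele}:{s.alt_allele}" for s in table.sites]
    df = pd.DataFrame(
        np.where(table.genotypes == MISSING, np.nan, table.genotypes),
        index=table.sample_ids,
        columns=cols,
    )
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def write_ancestral_tsv(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in table.sites:
            if s.ancestral_allele is not None:
                fh.write(f"{s.contig}\t{s.position}\t{s.ancestral_allele}\n")


def write_het_tsv(records: Iterable[HetRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "n_het": r.n_het,
                "n_genotyped": r.n_genotyped,
                "heterozygosity": r.heterozygosity,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_het_tsv(path: str | Path) -> list[HetRecord]:
    """Read a heterozygosity TSV with count columns (n_het, n_genotyped)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "n_het", "n_genotyped"} - set(df.columns)
    if missing:
        raise ValueError(
            f"heterozygosity file {path} lacks count columns {sorted(missing)}"
        )
    return [
        HetRecord(sample_id=str(r.sample_id), n_het=int(r.n_het),
                  n_genotyped=int(r.n_genotyped))
        for r in df.itertuples(index=False)
    ]


def read_het_values(path: str | Path) -> tuple[list[str], "np.ndarray"]:
    """Read per-sample heterozygosity values from a TSV.

    Accepts either a count table (n_het, n_genotyped) or a plain table with
    a ``heterozygosity`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    ids = [str(s) for s in df["sample_id"]]
    if {"n_het", "n_genotyped"} <= set(df.columns):
        values = df["n_het"].to_numpy(float) / df["n_genotyped"].to_numpy(float)
    elif "heterozygosity" in df.columns:
        values = df["heterozygosity"].to_numpy(float)
    else:
        raise ValueError(
            f"{path}: need n_het/n_genotyped or a heterozygosity column"
        )
    return ids, values


def write_metadata_tsv(meta: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "longitude": m.longitude,
                "latitude": m.latitude,
                "year": m.year,
                "group": m.group if m.group is not None else "",
            }
            for m in meta
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_qc_report(report: QCReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)
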