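"""Pairwise differentiation and isolation by distance.

Pairwise FST between a-priori groups uses the Weir & Cockerham (1984)
estimator, combining loci as the ratio of summed variance components.
Isolation by distance is tested with a Mantel permutation test between the
linearised FST matrix (F/(1-F)) and geographic distance between group
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeTable, SampleMeta
from .geo import geo_distance_matrix

__all__ = [
    "FstMatrix",
    "MantelResult",
    "weir_cockerham_fst",
    "pairwise_fst",
    "linearize_fst",
    "group_distance_matrix",
    "mantel_test",
]


@dataclass
class FstMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("FST matrix shape must match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("FST matrix must be symmetric")
        self.values = v


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None


def _group_counts(
    table: GenotypeTable, groups: Mapping[str, str]
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Per-(group, locus) sample sizes, alt-allele frequencies and observed
    het frequencies, with missing genotypes excluded per locus."""
    labels = sorted(set(groups.values()))
    g = table.genotypes
    n_called = np.zeros((len(labels), table.n_sites))
    freq = np.zeros_like(n_called)
    het = np.zeros_like(n_called)
    for k, lab in enumerate(labels):
        rows = [i for i, s in enumerate(table.sample_ids) if groups.get(s) == lab]
        if len(rows) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        sub = g[rows]
        called = sub != MISSING
        nk = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(nk > 0, np.where(called, sub, 0).sum(axis=0) / (2.0 * nk), np.nan)
            het[k] = np.where(nk > 0, (sub == 1).sum(axis=0) / nk, np.nan)
        n_called[k] = nk
    return labels, n_called, freq, het


def weir_cockerham_fst(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> float:
    """Multi-locus Weir-Cockerham (1984) theta for r populations.

    Parameters are per-(population, locus) arrays: diploid sample sizes
    ``n``, alt-allele frequencies ``p`` and observed heterozygote
    frequencies ``h``.  Loci where fewer than two populations have at least
    two genotyped diploids are dropped.  Returns the ratio of summed
    variance components sum(a) / sum(a + b + c).
    """
    n = np.asarray(n, dtype=float)
    r = n.shape[0]
    ok = (n >= 2).sum(axis=0) == r
    n, p, h = n[:, ok], p[:, ok], h[:, ok]
    if n.shape[1] == 0:
        raise ValueError("no locus has >= 2 genotyped diploids in every population")

    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)

    inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
    a = nbar / nc * (s2 - inner / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0

    denom = (a + b + c).sum()
    if denom == 0:
        return 0.0
    return float(a.sum() / denom)


def pairwise_fst(table: GenotypeTable, groups: Mapping[str, str]) -> FstMatrix:
    """Pairwise Weir-Cockerham FST between every pair of groups."""
    labels, n, p, h = _group_counts(table, groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    k = len(labels)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            idx = [i, j]
            theta = weir_cockerham_fst(n[idx], p[idx], h[idx])
            out[i, j] = out[j, i] = theta
    return FstMatrix(labels=labels, values=out)


def linearize_fst(fst: FstMatrix | np.ndarray) -> np.ndarray:
    """Elementwise F/(1-F); undefined (error) at F = 1, negatives passed
    through.  Strictly increasing on (-1, 1)."""
    v = fst.values if isinstance(fst, FstMatrix) else np.asarray(fst, dtype=float)
    if np.any(v >= 1.0):
        raise ValueError("linearization undefined for FST >= 1")
    return v / (1.0 - v)


def group_distance_matrix(
    meta: Sequence[SampleMeta],
    groups: Mapping[str, str],
    metric: str = "euclidean_degrees",
) -> tuple[list[str], np.ndarray]:
    """Distances between group centroids (mean member lon/lat)."""
    labels = sorted(set(groups.values()))
    centroids = []
    for lab in labels:
        pts = np.array(
            [[m.longitude, m.latitude] for m in meta if groups.get(m.sample_id) == lab]
        )
        if pts.size == 0:
            raise ValueError(f"group {lab!r} has no samples with coordinates")
        centroids.append(pts.mean(axis=0))
    D = geo_distance_matrix(np.array(centroids), metric=metric)
    return labels, D


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_test(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """One-tailed (upper) Mantel permutation test.

    r is the Pearson correlation of the upper triangles; the null
    distribution permutes rows and columns of ``B`` jointly; the p-value is
    (1 + #{r_perm >= r_obs}) / (1 + n_perm), so p >= 1/(n_perm + 1).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A and B must be square matrices of the same shape")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValueError("A and B must be symmetric")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = A.shape[0]
    a = _upper(A)
    if np.std(a) == 0 or np.std(_upper(B)) == 0:
        raise ValueError("zero variance in a distance matrix upper triangle")

    a_c = a - a.mean()
    a_norm = np.sqrt((a_c**2).sum())

    def corr_with(b_vec: np.ndarray) -> float:
        b_c = b_vec - b_vec.mean()
        return float((a_c @ b_c) / (a_norm * np.sqrt((b_c**2).sum())))

    r_obs = corr_with(_upper(B))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += corr_with(_upper(B[np.ix_(perm, perm)])) >= r_obs
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed)
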