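import numpy as np
import pytest

from hetdecay import GenotypeTable, SampleMeta, SiteRecord


def make_sites(n, contig_of=None, ancestral=True):
    """n generic non-damage sites (A/C with ancestral A)."""
    sites = []
    for j in range(n):
        contig = contig_of(j) if contig_of else f"c{j}"
        sites.append(
            SiteRecord(
                contig=contig,
                position=j + 1 if contig_of else 1,
                ref_allele="A",
                alt_allele="C",
                ancestral_allele="A" if ancestral else None,
            )
        )
    return sites


def make_table(genotypes, contig_of=None, ancestral=True, sites=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = genotypes.shape
    ids = [f"s{i}" for i in range(n_samples)]
    if sites is None:
        sites = make_sites(n_sites, contig_of=contig_of, ancestral=ancestral)
    return GenotypeTable(ids, sites, genotypes)


@pytest.fixture
def small_meta():
    return [
        SampleMeta("s0", -105.0, 40.0, 1902),
        SampleMeta("s1", -106.0, 41.0, 1950),
        SampleMeta("s2", -104.0, 39.0, 2009),
    ]


def random_decay_data(rng, n=5):
    """A small valid scaled dataset for likelihood tests."""
    from hetdecay import DecayData

    coords = np.column_stack(
        [rng.uniform(-110, -100, n), rng.uniform(35, 45, n)]
    )
    diff = coords[:, None, :] - coords[None, :, :]
    D = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(D, 0.0)
    return DecayData(
        sample_ids=[f"s{i}" for i in range(n)],
        H=rng.uniform(0.1, 1.0, n),
        T=rng.uniform(0.0, 1.0, n),
        coords=coords,
        D=D / D.max(),
    )
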