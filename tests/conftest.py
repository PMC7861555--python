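import numpy as np
import pandas as pd
import pytest

from polygrowth import mixedassoc, synthio


@pytest.fixture(scope="session")
def base_sim():
    """A small two-region study reused by read-only tests."""
    return synthio.SimConfig(
        n_per_region=(40, 40), n_snps=1200, fst_target=0.1, n_causal=30,
        h2=0.7, seed=11,
    )


@pytest.fixture(scope="session")
def geno(base_sim):
    return synthio.simulate_genotypes(base_sim)


@pytest.fixture(scope="session")
def kinship(geno):
    return mixedassoc.compute_kinship(geno)


def nei_fst_oracle(counts1, n1, counts2, n2, components=False):
    """Hand-coded Nei & Chesser per-locus Fst from alt-allele counts.

    ``counts`` are alt-allele counts among ``n`` haploid-equivalent lines
    (fully homozygous; no heterozygotes).  Returns the unclamped
    (Ht - Hs) / Ht, or the (Hs, Ht) pair when ``components``.
    """
    p1, p2 = counts1 / n1, counts2 / n2
    n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
    homozygosity = ((p1**2 + (1 - p1) ** 2) + (p2**2 + (1 - p2) ** 2)) / 2.0
    hs = n_harm / (n_harm - 1.0) * (1.0 - homozygosity)
    pbar = (p1 + p2) / 2.0
    ht = 1.0 - (pbar**2 + (1 - pbar) ** 2) + hs / (2.0 * n_harm)
    if components:
        return hs, ht
    return (ht - hs) / ht if ht > 0 else 0.0


def anova_h2_oracle(pheno: pd.DataFrame) -> float:
    """Method-of-moments H2 from a balanced one-way replicate table."""
    wide = pheno.pivot_table(index="line_id", columns="replicate", values="value")
    r = wide.shape[1]
    msb = wide.mean(axis=1).var(ddof=1) * r
    msw = wide.var(axis=1, ddof=1).mean()
    vg = max((msb - msw) / r, 0.0)
    return vg / (vg + msw)
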