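"""Population differentiation: per-SNP and per-gene Fst, random-set tests,
loss-of-function burden, and regional trait contrasts.

Fst follows the Nei (1987) / Nei & Chesser (1983) gene-diversity estimator
with sample-size correction (the hierfstat ``basic.stats`` family):
per-locus Hs and Ht are corrected with the harmonic mean sample size and
the observed heterozygosity, and Fst = (Ht - Hs) / Ht with negative values
clamped to zero.  Lines are treated as haploid-equivalent: a homozygous
call contributes 0 or 1 to the allele frequency and a heterozygous call
0.5.  Gene-level values aggregate SNPs by ratio of sums,
sum(Ht - Hs) / sum(Ht).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from string import ascii_lowercase

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import MISSING, GenotypeMatrix, check_regions


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def _locus_components(
    G: GenotypeMatrix, pop_masks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (Hs, Ht) with Nei & Chesser sample-size correction.

    Returns NaN components where a population has no non-missing call.
    """
    npop = len(pop_masks)
    m = G.n_markers
    p = np.empty((npop, m))
    ho = np.empty((npop, m))
    n_eff = np.empty((npop, m))
    for k, mask in enumerate(pop_masks):
        codes = G.codes[mask].astype(float)
        valid = codes != MISSING
        codes[~valid] = np.nan
        cnt = valid.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p[k] = np.nansum(codes, axis=0) / (2.0 * cnt)
            ho[k] = np.nansum(codes == 1, axis=0) / cnt
        p[k, cnt == 0] = np.nan
        n_eff[k] = cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        n_harm = npop / np.sum(1.0 / n_eff, axis=0)
    mho = ho.mean(axis=0)
    homozygosity = (p**2 + (1.0 - p) ** 2).mean(axis=0)
    hs = n_harm / (n_harm - 1.0) * (1.0 - homozygosity - mho / (2.0 * n_harm))
    pbar = p.mean(axis=0)
    ht = (
        1.0 - (pbar**2 + (1.0 - pbar) ** 2)
        + hs / (n_harm * npop)
        - mho / (2.0 * n_harm * npop)
    )
    return hs, ht


def _pop_masks(G: GenotypeMatrix, pops: tuple[str, str]) -> list[np.ndarray]:
    if G.regions is None:
        raise ValueError("genotype matrix carries no region labels")
    masks = [np.asarray(G.regions) == p for p in pops]
    for pop, mask in zip(pops, masks):
        if mask.sum() < 2:
            raise ValueError(f"region {pop!r} has fewer than 2 lines")
    return masks


def per_snp_fst(G: GenotypeMatrix, pops: tuple[str, str]) -> pd.DataFrame:
    """Nei-style Fst per SNP between two regions (negatives set to zero).

    Markers monomorphic in both regions get Fst 0; markers fully missing
    in one region get NaN.
    """
    hs, ht = _locus_components(G, _pop_masks(G, pops))
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, 0.0)
    fst = np.where(np.isnan(hs) | np.isnan(ht), np.nan, np.maximum(fst, 0.0))
    out = G.marker_frame()
    out["fst"] = fst
    out.attrs["populations"] = tuple(pops)
    return out


def per_gene_fst(
    G: GenotypeMatrix, pops: tuple[str, str], genes: pd.DataFrame
) -> pd.DataFrame:
    """Ratio-of-sums Fst per gene interval: sum(Ht - Hs) / sum(Ht).

    ``genes`` needs columns gene_id, chrom, start, end (1-based inclusive).
    Genes without SNPs get NaN; a gene on a chromosome absent from the
    marker map raises.
    """
    hs, ht = _locus_components(G, _pop_masks(G, pops))
    known_chroms = set(np.asarray(G.chrom, dtype=str))
    records = []
    for g in genes.itertuples():
        if str(g.chrom) not in known_chroms:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom} not in marker map")
        inside = (
            (np.asarray(G.chrom, dtype=str) == str(g.chrom))
            & (G.pos >= g.start)
            & (G.pos <= g.end)
        )
        inside &= ~(np.isnan(hs) | np.isnan(ht))
        if not inside.any():
            records.append((g.gene_id, np.nan, 0))
            continue
        num = np.sum(ht[inside] - hs[inside])
        den = np.sum(ht[inside])
        fst = max(num / den, 0.0) if den > 0 else 0.0
        records.append((g.gene_id, fst, int(inside.sum())))
    out = pd.DataFrame(records, columns=["gene_id", "fst", "n_snps"])
    out.attrs["populations"] = tuple(pops)
    return out


def fst_set_test(
    fst: pd.DataFrame,
    hit_ids: np.ndarray,
    n_resamples: int = 10_000,
    seed: int = 0,
    percentile: float = 95.0,
) -> dict:
    """Is a marker set more differentiated than random sets of equal size?

    Returns the two-sided Kolmogorov-Smirnov p of the hit-set Fst
    distribution against the genome-wide one, and the resampling p: the
    fraction of ``n_resamples`` random equal-size marker sets whose 95th
    Fst percentile reaches the hit set's (with a +1 correction so p is
    never 0).
    """
    if n_resamples <= 0:
        raise ValueError("n_resamples must be positive")
    hit_ids = np.asarray(hit_ids)
    if hit_ids.size == 0:
        raise ValueError("empty hit set")
    genome = fst.dropna(subset=["fst"])
    hit = genome[genome["marker_id"].isin(hit_ids)]["fst"].to_numpy()
    if hit.size == 0:
        raise ValueError("hit set does not intersect the genome-wide table")
    allv = genome["fst"].to_numpy()
    ks = stats.ks_2samp(hit, allv)
    obs = np.percentile(hit, percentile)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, allv.size, size=(n_resamples, hit.size))
    rand_perc = np.percentile(allv[draws], percentile, axis=1)
    exceed = int(np.sum(rand_perc >= obs))
    return {
        "ks_p": float(ks.pvalue),
        "ks_stat": float(ks.statistic),
        "observed_percentile": float(obs),
        "exceedance_p": (1 + exceed) / (n_resamples + 1),
        "n_hits": int(hit.size),
    }


# ---------------------------------------------------------------------------
# LOF burden and regional contrasts
# ---------------------------------------------------------------------------

def lof_burden_test(
    lof: pd.DataFrame, phenotype: pd.Series
) -> tuple[pd.Series, float, float]:
    """Per-line LOF burden and its Spearman correlation with a phenotype.

    ``lof`` is genes x genotypes in {0,1}; burden is the per-genotype
    column sum.  Lines are matched on identifiers.
    """
    burden = lof.sum(axis=0)
    shared = burden.index.intersection(phenotype.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 lines shared between burden and phenotype")
    b = burden[shared].astype(float)
    if b.nunique() <= 1:
        raise ValueError("burden has zero variance")
    rho, p = stats.spearmanr(b, phenotype[shared])
    return burden, float(rho), float(p)


@dataclass
class RegionComparison:
    group_means: pd.Series
    contrasts: pd.DataFrame          # pair, estimate, p_adj (Tukey single-step)
    letters: dict[str, str]          # compact letter display


def _letter_display(groups: list[str], sig_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display."""
    sets: list[set] = [set(groups)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                sets.extend([s - {a}, s - {b}])
        # absorb subsets
        sets = [s for s in sets if s and not any(s < t for t in sets)]
    sets.sort(key=lambda s: sorted(s))
    letters = {g: "" for g in groups}
    for letter, s in zip(ascii_lowercase, sets):
        for g in sorted(s):
            letters[g] += letter
    return letters


def region_compare(
    means: pd.DataFrame,
    value_col: str = "mean",
    region_col: str = "region",
    alpha: float = 0.05,
) -> RegionComparison:
    """Regional group means with Tukey-adjusted all-pairwise contrasts.

    Fits the one-way model value ~ region and performs every pairwise
    comparison with single-step (Tukey HSD) family-wise adjustment,
    summarized as a compact letter display.  Regions with a single
    genotype are excluded with a warning.
    """
    df = means[[value_col, region_col]].dropna().copy()
    counts = df[region_col].value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding regions with < 2 genotypes: {singletons}")
        df = df[~df[region_col].isin(singletons)]
    check_regions(df[region_col], min_per_region=2)
    tuk = pairwise_tukeyhsd(
        df[value_col].to_numpy(), df[region_col].to_numpy(), alpha=alpha
    )
    table = pd.DataFrame(
        tuk.summary().data[1:], columns=tuk.summary().data[0]
    )
    contrasts = pd.DataFrame(
        {
            "group1": table["group1"],
            "group2": table["group2"],
            "estimate": table["meandiff"].astype(float),
            "p_adj": table["p-adj"].astype(float),
            "reject": table["reject"].astype(bool),
        }
    )
    sig = {
        frozenset((r.group1, r.group2))
        for r in contrasts.itertuples()
        if r.reject
    }
    groups = sorted(df[region_col].unique())
    return RegionComparison(
        group_means=df.groupby(region_col)[value_col].mean(),
        contrasts=contrasts,
        letters=_letter_display(groups, sig),
    )


def write_fst_tsv(fst: pd.DataFrame, path: str) -> None:
    fst.to_csv(path, sep="\t", index=False)
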