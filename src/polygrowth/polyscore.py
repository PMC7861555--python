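"""Polygenic scores and the Qx over-dispersion test.

Marginally associated SNPs (p below an index threshold) are reduced to
quasi-independent index SNPs by greedy LD clumping (plink-style: ascending
p, physical window, r2 cutoff); their effect sizes alpha_l and allele
frequencies p_l yield a polygenic score per unit (a genotype treated as
its own population, or a region),

    Z = 2 * sum_l alpha_l * p_l .

Under neutral drift the centered vector of scores across m units is
multivariate normal with covariance 2 * V_A * F, where
V_A = 4 * sum_l alpha_l^2 * eps_l * (1 - eps_l) (eps_l the across-unit
mean frequency) and F the drift covariance derived from kinship.  The Qx
statistic is the associated Mahalanobis norm and is chi-square with m - 1
degrees of freedom when the trait drifts neutrally; an empirical null
re-draws frequency-matched random marker sets carrying the same effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix
from .mixedassoc import mixed_gwas


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------

def ld_r2(G: GenotypeMatrix, focal: int, others: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of genotype codes, pairwise-complete."""
    x = G.codes[:, focal].astype(float)
    x[x == MISSING] = np.nan
    out = np.empty(others.size)
    Y = G.codes[:, others].astype(float)
    Y[Y == MISSING] = np.nan
    for i in range(others.size):
        y = Y[:, i]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            out[i] = 0.0
        else:
            out[i] = np.corrcoef(x[ok], y[ok])[0, 1] ** 2
    return out


@dataclass
class ClumpSet:
    index: pd.DataFrame                  # marker_id, chrom, pos, p, beta
    members: dict[str, list[str]]        # index marker -> clumped markers

    @property
    def n_index(self) -> int:
        return len(self.index)


def ld_clump(
    assoc: pd.DataFrame,
    G: GenotypeMatrix,
    p_index: float = 1e-4,
    window: float = 1_000_000,
    p_secondary: float = 0.01,
    r2: float = 0.5,
) -> ClumpSet:
    """Greedy plink-style clumping of an association table.

    Markers with p < ``p_index`` seed clumps in ascending p order (ties
    broken by position then marker id); every unassigned marker with
    p < ``p_secondary`` within ``window``/2 of the index and in LD
    (r2 >= ``r2``) joins the clump and is removed from further
    consideration.  The returned index SNPs are mutually unclumped.
    """
    marker_pos = {m: i for i, m in enumerate(G.marker_ids)}
    tab = assoc.dropna(subset=["p"]).copy()
    tab = tab[tab["marker_id"].isin(marker_pos)]
    tab = tab.sort_values(["p", "chrom", "pos", "marker_id"]).reset_index(drop=True)
    assigned: set[str] = set()
    index_rows = []
    members: dict[str, list[str]] = {}
    cand = tab[tab["p"] < p_secondary]
    for row in tab[tab["p"] < p_index].itertuples():
        if row.marker_id in assigned:
            continue
        assigned.add(row.marker_id)
        index_rows.append(row)
        near = cand[
            (cand["chrom"] == row.chrom)
            & (np.abs(cand["pos"] - row.pos) <= window / 2)
            & ~cand["marker_id"].isin(assigned)
        ]
        clumped: list[str] = []
        if len(near):
            jidx = np.array([marker_pos[m] for m in near["marker_id"]])
            r2v = ld_r2(G, marker_pos[row.marker_id], jidx)
            for m, v in zip(near["marker_id"], r2v):
                if v >= r2:
                    assigned.add(m)
                    clumped.append(m)
        members[row.marker_id] = clumped
    cols = ["marker_id", "chrom", "pos", "p"] + (
        ["beta"] if "beta" in assoc.columns else []
    )
    index = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in index_rows],
                         columns=cols)
    return ClumpSet(index=index, members=members)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def unit_frequencies(G: GenotypeMatrix, markers: np.ndarray,
                     by_region: bool = False) -> pd.DataFrame:
    """Allele frequencies per unit (line, or region when ``by_region``).

    For a single selfing genotype the frequency is dosage/2 in {0, 0.5, 1}
    (missing calls mean-imputed).
    """
    idx = {m: i for i, m in enumerate(G.marker_ids)}
    cols = np.array([idx[m] for m in markers])
    freq = G.dosage_imputed()[:, cols] / 2.0
    df = pd.DataFrame(freq, index=G.line_ids, columns=markers)
    if by_region:
        if G.regions is None:
            raise ValueError("no region labels on the genotype matrix")
        df = df.groupby(pd.Series(G.regions, index=G.line_ids)).mean()
    return df


def polygenic_score(freqs: pd.DataFrame, effects: np.ndarray) -> pd.Series:
    """Z = 2 * sum_l alpha_l * p_l per unit (row of ``freqs``)."""
    f = freqs.to_numpy(dtype=float)
    if f.min() < 0 or f.max() > 1:
        raise ValueError("allele frequencies must lie in [0, 1]")
    effects = np.asarray(effects, dtype=float)
    z = 2.0 * f @ effects
    return pd.Series(z, index=freqs.index, name="score")


# ---------------------------------------------------------------------------
# Qx
# ---------------------------------------------------------------------------

@dataclass
class QxResult:
    qx: float
    df: int
    p_chi2: float
    n_markers: int
    p_empirical: float | None = None
    null_qx: np.ndarray | None = None


def drift_covariance(
    G: GenotypeMatrix,
    by_region: bool = False,
    selfing: bool = False,
    max_markers: int | None = 20_000,
    seed: int = 0,
) -> np.ndarray:
    """Among-unit drift covariance F estimated from genome-wide markers.

    F is half the standardized allele covariance,
    F_ij = mean_l (p_il - eps_l)(p_jl - eps_l) / (eps_l (1 - eps_l)) / 2,
    the scaling under which Cov(Z) = 2 * V_A * F holds for polygenic
    scores (a single inbred line has F_ii = 1/2).  Identity-by-state
    kinship cannot be used here: its baseline between unrelated lines is
    sum(p^2 + q^2)/m, not zero, so it does not measure allele covariance.
    Units are lines, or regions when ``by_region``.  ``selfing=True``
    doubles the scaling (variance inflation for selfing family units).
    """
    freqs = G.dosage_imputed() / 2.0
    if by_region:
        if G.regions is None:
            raise ValueError("no region labels on the genotype matrix")
        df = pd.DataFrame(freqs).groupby(np.asarray(G.regions)).mean()
        freqs = df.to_numpy()
    if max_markers is not None and freqs.shape[1] > max_markers:
        cols = np.random.default_rng(seed).choice(
            freqs.shape[1], max_markers, replace=False
        )
        freqs = freqs[:, cols]
    eps = freqs.mean(axis=0)
    keep = (eps > 0) & (eps < 1)
    s = (freqs[:, keep] - eps[keep]) / np.sqrt(eps[keep] * (1 - eps[keep]))
    F = (s @ s.T) / keep.sum() / 2.0
    return 2.0 * F if selfing else F


def _qx_statistic(freqs: np.ndarray, effects: np.ndarray, F: np.ndarray) -> float:
    m = freqs.shape[0]
    z = 2.0 * freqs @ effects
    zc = z - z.mean()
    eps = freqs.mean(axis=0)
    va = 4.0 * np.sum(effects**2 * eps * (1.0 - eps))
    if va <= 0:
        raise ValueError("zero additive variance (all loci fixed or effects 0)")
    C = np.eye(m) - np.ones((m, m)) / m
    Fc = C @ F @ C
    return float(zc @ np.linalg.pinv(2.0 * va * Fc, hermitian=True) @ zc)


def qx_test(
    freqs: pd.DataFrame,
    effects: np.ndarray,
    F: np.ndarray,
    null_freq_pool: pd.DataFrame | None = None,
    n_null: int = 1000,
    seed: int = 0,
    frequency_matched: bool = True,
) -> QxResult:
    """Over-dispersion test of polygenic scores across units.

    ``freqs`` holds the associated loci (units x loci), ``effects`` their
    aligned effect sizes and ``F`` the among-unit drift covariance.  When
    ``null_freq_pool`` (units x candidate loci) is given, ``n_null``
    random marker sets of equal size — drawn from the same mean-frequency
    decile as each associated locus when ``frequency_matched`` — carry the
    observed effects through the same statistic to give an empirical p.
    """
    if freqs.shape[0] < 2:
        raise ValueError("Qx needs >= 2 units")
    fmat = freqs.to_numpy(dtype=float)
    effects = np.asarray(effects, dtype=float)
    qx = _qx_statistic(fmat, effects, F)
    dof = fmat.shape[0] - 1
    result = QxResult(
        qx=qx, df=dof, p_chi2=float(stats.chi2.sf(qx, dof)),
        n_markers=fmat.shape[1],
    )
    if null_freq_pool is not None and n_null > 0:
        pool = null_freq_pool.to_numpy(dtype=float)
        rng = np.random.default_rng(seed)
        eps_pool = pool.mean(axis=0)
        maf_pool = np.minimum(eps_pool, 1 - eps_pool)
        eps_obs = fmat.mean(axis=0)
        maf_obs = np.minimum(eps_obs, 1 - eps_obs)
        edges = np.quantile(maf_pool, np.linspace(0, 1, 11))
        pool_bins = np.clip(np.searchsorted(edges, maf_pool, side="right") - 1, 0, 9)
        obs_bins = np.clip(np.searchsorted(edges, maf_obs, side="right") - 1, 0, 9)
        bin_members = [np.where(pool_bins == b)[0] for b in range(10)]
        null_qx = np.empty(n_null)
        for s in range(n_null):
            if frequency_matched:
                cols = np.array([
                    rng.choice(bin_members[b]) if bin_members[b].size
                    else rng.integers(pool.shape[1])
                    for b in obs_bins
                ])
            else:
                cols = rng.choice(pool.shape[1], size=fmat.shape[1], replace=False)
            null_qx[s] = _qx_statistic(pool[:, cols], effects, F)
        result.null_qx = null_qx
        result.p_empirical = (1 + int(np.sum(null_qx >= qx))) / (n_null + 1)
    return result


# ---------------------------------------------------------------------------
# validation schemes
# ---------------------------------------------------------------------------

def _gwas_scores(
    pheno: pd.Series,
    G: GenotypeMatrix,
    K: np.ndarray,
    score_lines: np.ndarray,
    p_index: float,
    clump: bool = True,
) -> tuple[pd.Series | None, pd.DataFrame]:
    assoc = mixed_gwas(pheno.to_numpy(), G, K)
    if clump:
        cs = ld_clump(assoc, G, p_index=p_index)
        hits = cs.index
    else:
        hits = assoc[assoc["p"] < p_index]
    if hits.empty:
        return None, hits
    sub = G.take_lines(np.where(np.isin(G.line_ids, score_lines))[0])
    freqs = unit_frequencies(sub, hits["marker_id"].to_numpy())
    return polygenic_score(freqs, hits["beta"].to_numpy()), hits


def validate_scores(
    pheno: pd.DataFrame,
    G: GenotypeMatrix,
    K: np.ndarray,
    scheme: str = "replicate_cv",
    p_index: float = 1e-4,
    n_random: int = 1000,
    seed: int = 0,
) -> dict:
    """Validate GWAS-derived polygenic scores against held-out phenotypes.

    ``pheno`` is long-format (line_id, replicate, value) aligned with
    ``G.line_ids``.  Schemes:

    * ``holdout80`` — GWAS on 80% of genotypes, score the remaining 20%,
      Spearman rho against their observed means;
    * ``replicate_cv`` — GWAS on the mean of two replicates, score all
      lines, rho against the third replicate;
    * ``random_sets`` — rho of the associated-set score compared to the
      empirical rho distribution of ``n_random`` equal-size random marker
      sets (median, 95th percentile, max, exceedance fraction).
    """
    rng = np.random.default_rng(seed)
    wide = pheno.pivot_table(index="line_id", columns="replicate", values="value")
    wide = wide.loc[[l for l in G.line_ids if l in wide.index]]
    means = wide.mean(axis=1)

    if scheme == "holdout80":
        lines = means.index.to_numpy()
        perm = rng.permutation(lines.size)
        cut = int(round(0.8 * lines.size))
        train, test = lines[perm[:cut]], lines[perm[cut:]]
        tr_idx = np.where(np.isin(G.line_ids, train))[0]
        Gtr = G.take_lines(tr_idx)
        Ktr = K[np.ix_(tr_idx, tr_idx)]
        scores, hits = _gwas_scores(means[Gtr.line_ids], Gtr, Ktr, test, p_index)
        if scores is None:
            return {"scheme": scheme, "rho": np.nan, "p": np.nan, "n_snps": 0}
        rho, p = stats.spearmanr(scores[test], means[test])
        return {"scheme": scheme, "rho": float(rho), "p": float(p),
                "n_snps": len(hits)}

    if scheme == "replicate_cv":
        if wide.shape[1] < 3:
            raise ValueError("replicate_cv needs >= 3 replicates")
        reps = list(wide.columns)
        train_mean = wide[reps[:2]].mean(axis=1)
        held = wide[reps[2]]
        scores, hits = _gwas_scores(
            train_mean[G.line_ids], G, K, G.line_ids, p_index
        )
        if scores is None:
            return {"scheme": scheme, "rho": np.nan, "p": np.nan, "n_snps": 0}
        ok = held.dropna().index
        rho, p = stats.spearmanr(scores[ok], held[ok])
        return {"scheme": scheme, "rho": float(rho), "p": float(p),
                "n_snps": len(hits)}

    if scheme == "random_sets":
        assoc = mixed_gwas(means[G.line_ids].to_numpy(), G, K)
        cs = ld_clump(assoc, G, p_index=p_index)
        hits = cs.index
        if hits.empty:
            return {"scheme": scheme, "rho_associated": np.nan, "n_snps": 0}
        freqs = unit_frequencies(G, hits["marker_id"].to_numpy())
        z = polygenic_score(freqs, hits["beta"].to_numpy())
        rho_assoc, _ = stats.spearmanr(z[means.index], means)
        beta_all = pd.Series(assoc["beta"].to_numpy(),
                             index=assoc["marker_id"]).dropna()
        rhos = np.empty(n_random)
        for s in range(n_random):
            pick = rng.choice(beta_all.index.to_numpy(), size=len(hits),
                              replace=False)
            fr = unit_frequencies(G, pick)
            zr = polygenic_score(fr, beta_all[pick].to_numpy())
            rhos[s], _ = stats.spearmanr(zr[means.index], means)
        return {
            "scheme": scheme,
            "rho_associated": float(rho_assoc),
            "rho_random_median": float(np.median(rhos)),
            "rho_random_95": float(np.percentile(rhos, 95)),
            "rho_random_max": float(rhos.max()),
            "exceedance": float(np.mean(rhos >= rho_assoc)),
            "n_snps": len(hits),
        }

    raise ValueError(f"unknown validation scheme {scheme!r}")
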