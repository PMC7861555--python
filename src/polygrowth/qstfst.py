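"""Qst estimation and Qst-vs-Fst comparison.

Qst = VarB / (VarB + VarW), where VarB is the genetic variance between
regions and VarW the genotypic variance within regions.  Both components
are REML estimates of a one-way random-effects model on genotypic means
(region as random intercept, residual = genotype-within-region), so for
selfing lines they are broad-sense components.  Significance is assessed
two ways: a permutation null that randomizes region labels and compares
qst - fst95 (the 95th percentile of the genome-wide SNP Fst distribution),
and a parametric neutral null that draws genotypic values from a
multivariate normal with covariance Vg * K (kinship), propagating neutral
drift into an expected Qst distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar


@dataclass
class QstResult:
    trait: str
    qst: float
    var_b: float
    var_w: float
    fst_percentile_attained: float | None = None
    p_perm: float | None = None
    p_mvn: float | None = None


def _group_stats(values: np.ndarray, regions: np.ndarray):
    labels, inv = np.unique(regions, return_inverse=True)
    k = labels.size
    n_j = np.bincount(inv).astype(float)
    sums = np.bincount(inv, weights=values)
    means = sums / n_j
    ssw = float(np.sum((values - means[inv]) ** 2))
    return labels, n_j, means, ssw


def _reml_oneway(values: np.ndarray, regions: np.ndarray):
    """REML variance components (varB, varW) of y = mu + region + error.

    Profiled over the ratio lambda = varB/varW: given lambda the residual
    variance has the closed form (Q + SSW) / (N - 1), leaving a
    one-dimensional search.
    """
    values = np.asarray(values, dtype=float)
    _, n_j, means, ssw = _group_stats(values, np.asarray(regions))
    k, N = n_j.size, values.size
    if k < 2:
        raise ValueError("need >= 2 regions")
    if np.var(values) == 0:
        raise ValueError("all values identical; variance components undefined")

    def neg2ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = lam + 1.0 / n_j
        mu = np.sum(means / w) / np.sum(1.0 / w)
        q = np.sum((means - mu) ** 2 / w)
        var_w = (q + ssw) / (N - 1)
        return (
            (N - 1) * np.log(var_w)
            + (q + ssw) / var_w
            + np.sum(np.log(w))
            + np.log(np.sum(1.0 / w))
        )

    grid = np.linspace(np.log(1e-9), np.log(1e9), 80)
    vals = [neg2ll(g) for g in grid]
    best = grid[int(np.argmin(vals))]
    res = minimize_scalar(neg2ll, bounds=(best - 1.5, best + 1.5), method="bounded")
    log_lam = float(res.x) if res.fun <= min(vals) else float(best)
    lam = np.exp(log_lam)
    w = lam + 1.0 / n_j
    mu = np.sum(means / w) / np.sum(1.0 / w)
    q = np.sum((means - mu) ** 2 / w)
    var_w = (q + ssw) / (N - 1)
    var_b = lam * var_w
    if lam < 2e-9:          # boundary: no detectable between-region variance
        var_b = 0.0
    return float(var_b), float(var_w)


def estimate_qst(
    means: pd.DataFrame,
    value_col: str = "mean",
    region_col: str = "region",
    trait: str = "",
) -> QstResult:
    """REML Qst of one trait from genotypic means with region labels."""
    df = means[[value_col, region_col]].dropna()
    counts = df[region_col].value_counts()
    if (counts < 3).any() or counts.size < 2:
        raise ValueError("need >= 2 regions with >= 3 genotypes each")
    var_b, var_w = _reml_oneway(df[value_col].to_numpy(), df[region_col].to_numpy())
    total = var_b + var_w
    if total <= 0:
        raise ValueError("zero total variance")
    return QstResult(trait=trait, qst=var_b / total, var_b=var_b, var_w=var_w)


def qst_permutation(
    means: pd.DataFrame,
    fst95: float,
    value_col: str = "mean",
    region_col: str = "region",
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for the statistic qst - fst95.

    Region labels are shuffled across genotypes; p is the add-one-corrected
    fraction of permutations whose statistic reaches the observed one.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    obs = estimate_qst(means, value_col, region_col).qst - fst95
    values = means[value_col].to_numpy(dtype=float)
    regions = means[region_col].to_numpy()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(regions)
        var_b, var_w = _reml_oneway(values, perm)
        if var_b / (var_b + var_w) - fst95 >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def qst_mvn_null(
    K: np.ndarray,
    regions: np.ndarray,
    vg: float,
    n_sims: int = 10_000,
    seed: int = 0,
    observed_qst: float | None = None,
    additive_x2: bool = False,
) -> dict:
    """Neutral Qst distribution from multivariate-normal drift on kinship.

    Each simulation draws genotypic values ~ MVN(0, Vg * K) (Vg doubled if
    ``additive_x2``, the additive-framework scaling) and re-estimates Qst,
    yielding the distribution expected if the trait drifted neutrally along
    the relatedness structure.  Returns the simulated distribution, its
    90/95/99 percentiles and, when ``observed_qst`` is given, the fraction
    of simulated values at or above it.
    """
    if n_sims <= 0:
        raise ValueError("n_sims must be positive")
    regions = np.asarray(regions)
    K = np.asarray(K, dtype=float)
    if K.shape[0] != regions.size:
        raise ValueError("kinship and region labels disagree in length")
    scale = 2.0 * vg if additive_x2 else vg
    cov = scale * K + np.eye(K.shape[0]) * (1e-8 * scale)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov += np.eye(K.shape[0]) * (1e-4 * scale)
        L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_sims)
    for s in range(n_sims):
        y = L @ rng.standard_normal(K.shape[0])
        var_b, var_w = _reml_oneway(y, regions)
        sims[s] = var_b / (var_b + var_w)
    out = {
        "distribution": sims,
        "percentiles": {
            q: float(np.percentile(sims, q)) for q in (90, 95, 99)
        },
    }
    if observed_qst is not None:
        out["p"] = float(np.mean(sims >= observed_qst))
    return out


def qst_vs_fst(qst: float, fst: pd.DataFrame | np.ndarray) -> dict:
    """Empirical percentile of the genome-wide Fst distribution at ``qst``."""
    values = fst["fst"].to_numpy() if isinstance(fst, pd.DataFrame) else np.asarray(fst)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty Fst distribution")
    perc = float(stats.percentileofscore(values, qst, kind="weak"))
    return {
        "percentile": perc,
        "exceeds_95th": bool(qst > np.percentile(values, 95)),
        "fst95": float(np.percentile(values, 95)),
    }
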