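"""Mixed-model association machinery (EMMA / EMMAX style).

The model is y = X b + u + e with u ~ N(0, sg2 * K) and e ~ N(0, se2 * I),
where K is an identity-by-state kinship matrix over inbred lines.  The
variance ratio delta = se2 / sg2 is estimated by REML through the spectral
decomposition of the kinship (a one-dimensional profile likelihood).  Per
marker, the EMMAX approximation reuses the null-model variance components
and performs generalized least squares after rotating phenotype and
genotypes into the eigenbasis; exact EMMA (re-estimating delta per marker)
is available for small problems.

Pseudo-heritability sg2 / (sg2 + se2) quantifies how much phenotypic
variance the relatedness structure explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .containers import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filtering and kinship
# ---------------------------------------------------------------------------

def filter_markers(
    G: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.05
) -> GenotypeMatrix:
    """Keep markers with MAF >= ``maf_min`` and missingness <= ``max_missing``.

    Both boundaries are inclusive (a marker at exactly 5% MAF and 5%
    missing data is retained); MAF is computed on non-missing calls.
    """
    keep = (G.maf() >= maf_min) & (G.missing_fraction() <= max_missing)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"all {G.n_markers} markers removed by the MAF/missingness filter"
        )
    log.info("filter_markers: kept %d of %d markers (%d removed)",
             int(keep.sum()), G.n_markers, n_dropped)
    return G.take_markers(np.where(keep)[0])


def compute_kinship(G: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state kinship: mean over markers of 1 - |g_i - g_j| / 2.

    Averaged over pairwise-complete markers.  Symmetric with unit diagonal;
    entries lie in [0, 1].  Raises if a pair of lines shares no non-missing
    marker.
    """
    if G.n_lines < 2:
        raise ValueError("kinship needs >= 2 lines")
    codes = G.codes.astype(float)
    valid = codes != MISSING
    codes[~valid] = 0.0
    n = G.n_lines
    K = np.empty((n, n))
    counts = valid.astype(float) @ valid.T.astype(float)
    if (counts == 0).any():
        raise ValueError("a pair of lines shares no non-missing markers")
    for i in range(n):
        diff = np.abs(codes[i] - codes)            # (n, m)
        diff[~(valid[i] & valid)] = 0.0
        sharing = counts[i] - (diff.sum(axis=1) / 2.0)
        K[i] = sharing / counts[i]
    return (K + K.T) / 2.0


def _stabilize(K: np.ndarray) -> np.ndarray:
    """Jitter the diagonal by 1e-6 if the smallest eigenvalue is < 1e-8."""
    w = np.linalg.eigvalsh(K)
    if w.min() < 1e-8:
        K = K + np.eye(K.shape[0]) * 1e-6
        if np.linalg.eigvalsh(K).min() < -1e-8:
            raise ValueError("kinship matrix not positive semi-definite")
    return K


# ---------------------------------------------------------------------------
# REML variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float                 # se2 / sg2
    reml_loglik: float

    @property
    def pseudo_h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else 0.0


def _reml_profile(eigvals: np.ndarray, eta2: np.ndarray):
    """Restricted log-likelihood of delta given the projected spectrum."""
    nq = eigvals.size

    def loglik(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = eigvals + d
        s = np.sum(eta2 / denom)
        return 0.5 * (
            nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(s))
            - np.sum(np.log(denom))
        )

    return loglik


def reml_null(
    y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None
) -> VarianceComponents:
    """REML estimates of (sg2, se2) for y = X b + u + e, u ~ N(0, sg2 K).

    One-dimensional grid-plus-Brent search over log(delta) on the spectrum
    of the kinship projected off the fixed-effect space.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    K = _stabilize(np.asarray(K, dtype=float))
    q = np.linalg.matrix_rank(X)
    # orthonormal basis of the complement of col(X)
    u_x, _, _ = np.linalg.svd(X, full_matrices=True)
    basis = u_x[:, q:]                       # n x (n - q)
    Kp = basis.T @ K @ basis
    eigvals, vecs = np.linalg.eigh(Kp)
    eigvals = np.maximum(eigvals, 0.0)
    eta = vecs.T @ (basis.T @ y)
    eta2 = eta**2
    loglik = _reml_profile(eigvals, eta2)
    grid = np.linspace(np.log(1e-5), np.log(1e5), 100)
    vals = np.array([loglik(g) for g in grid])
    best = grid[int(np.argmax(vals))]
    res = minimize_scalar(
        lambda g: -loglik(g), bracket=None,
        bounds=(best - 1.0, best + 1.0), method="bounded",
    )
    log_delta = float(res.x) if -res.fun >= vals.max() else float(best)
    delta = float(np.exp(log_delta))
    nq = n - q
    sg2 = float(np.sum(eta2 / (eigvals + delta)) / nq)
    return VarianceComponents(
        sigma_g2=sg2, sigma_e2=delta * sg2, delta=delta,
        reml_loglik=float(loglik(log_delta)),
    )


# ---------------------------------------------------------------------------
# association scans
# ---------------------------------------------------------------------------

def _rotate(K: np.ndarray, delta: float):
    """Whitening transform for V = sg2 (K + delta I)."""
    s, U = np.linalg.eigh(_stabilize(K))
    w = 1.0 / np.sqrt(np.maximum(s, 0.0) + delta)
    return (U * w).T            # D^{-1/2} U'


def mixed_gwas(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    method: str = "emmax",
) -> pd.DataFrame:
    """Per-marker mixed-model association scan.

    ``method="emmax"`` (default) fixes delta at its null-model REML value
    and runs a vectorized generalized least squares per marker;
    ``method="emma"`` re-estimates delta for every marker (exact, slow).
    P-values are from the t distribution with n - rank(X) - 1 df; missing
    genotypes are mean-imputed per marker (the kinship never is).  The
    result carries the Bonferroni threshold 0.05 / n_markers in
    ``df.attrs["bonferroni"]``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    ones = np.ones((n, 1))
    X = ones if covariates is None else np.column_stack([ones, covariates])
    dosage = G.dosage_imputed()
    var = dosage.var(axis=0)
    testable = var > 0
    if (~testable).any():
        log.info("mixed_gwas: skipping %d zero-variance markers",
                 int((~testable).sum()))

    if method == "emma":
        rows = _emma_exact(y, dosage, K, X, testable)
    elif method == "emmax":
        vc = reml_null(y, K, X)
        R = _rotate(K, vc.delta)
        yr = R @ y
        Xr = R @ X
        Gr = R @ dosage
        # Frisch-Waugh: residualize on rotated covariates
        Q, _ = np.linalg.qr(Xr)
        yr_r = yr - Q @ (Q.T @ yr)
        Gr_r = Gr - Q @ (Q.T @ Gr)
        gtg = np.einsum("ij,ij->j", Gr_r, Gr_r)
        gty = Gr_r.T @ yr_r
        dof = n - X.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gty / gtg
            rss = (yr_r @ yr_r) - beta * gty
            sigma2 = rss / dof
            se = np.sqrt(sigma2 / gtg)
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        rows = pd.DataFrame({"beta": beta, "se": se, "t": tstat, "p": p})
        rows.loc[~testable, ["beta", "se", "t", "p"]] = np.nan
    else:
        raise ValueError(f"unknown method {method!r}")

    out = pd.concat([G.marker_frame(), rows], axis=1)
    out["maf"] = G.maf()
    out = out[testable].reset_index(drop=True)
    out["p"] = out["p"].clip(lower=np.finfo(float).tiny, upper=1.0)
    out.attrs["bonferroni"] = 0.05 / max(len(out), 1)
    if method == "emmax":
        out.attrs["pseudo_h2"] = vc.pseudo_h2
        out.attrs["variance_components"] = vc
    return out


def _emma_exact(y, dosage, K, X, testable) -> pd.DataFrame:
    n = y.size
    beta = np.full(dosage.shape[1], np.nan)
    se = np.full_like(beta, np.nan)
    tstat = np.full_like(beta, np.nan)
    p = np.full_like(beta, np.nan)
    dof = n - X.shape[1] - 1
    for j in np.where(testable)[0]:
        Xj = np.column_stack([X, dosage[:, j]])
        vc = reml_null(y, K, Xj)
        R = _rotate(K, vc.delta)
        yr, Xjr = R @ y, R @ Xj
        XtX = Xjr.T @ Xjr
        coef = np.linalg.solve(XtX, Xjr.T @ yr)
        resid = yr - Xjr @ coef
        s2 = (resid @ resid) / dof
        cov = s2 * np.linalg.inv(XtX)
        beta[j] = coef[-1]
        se[j] = np.sqrt(cov[-1, -1])
        tstat[j] = beta[j] / se[j]
        p[j] = 2.0 * stats.t.sf(abs(tstat[j]), dof)
    return pd.DataFrame({"beta": beta, "se": se, "t": tstat, "p": p})


def lof_gwas(
    y: np.ndarray,
    lof: pd.DataFrame,
    K: np.ndarray,
    maf_min: float = 0.05,
    method: str = "emmax",
) -> pd.DataFrame:
    """Mixed-model scan over binary gene LOF states (genes x genotypes).

    The same machinery as the SNP scan with 0/1 coding; genes whose LOF
    frequency (folded) is below ``maf_min`` or with zero variance are
    skipped.
    """
    states = lof.to_numpy(dtype=np.int8)
    if not np.isin(states, (0, 1)).all():
        raise ValueError("LOF matrix entries must be 0/1")
    freq = states.mean(axis=1)
    keep = np.minimum(freq, 1 - freq) >= maf_min
    if not keep.any():
        raise ValueError("no gene passes the LOF frequency filter")
    sub = states[keep]
    G = GenotypeMatrix(
        codes=sub.T * 2,                       # reuse the 0/2 dosage pathway
        chrom=np.zeros(keep.sum(), dtype=int),
        pos=np.arange(1, keep.sum() + 1),
        line_ids=np.asarray(lof.columns),
        marker_ids=np.asarray(lof.index[keep]),
    )
    out = mixed_gwas(y, G, K, method=method)
    out = out.rename(columns={"marker_id": "gene"}).drop(columns=["chrom", "pos"])
    out["beta"] = out["beta"] * 2.0            # per-LOF-state effect
    out["se"] = out["se"] * 2.0
    freq_map = pd.Series(freq[keep], index=lof.index[keep])
    out["lof_freq"] = out["gene"].map(freq_map).to_numpy()
    return out


def kinship_corrected_correlation(
    x: np.ndarray, y: np.ndarray, K: np.ndarray
) -> tuple[float, float]:
    """Pearson r with a mixed-model p-value that corrects for relatedness.

    The reported correlation is the plain Pearson coefficient; its p-value
    comes from the Wald test on the slope of y = a + b x + u + e with
    u ~ N(0, sg2 K), which absorbs trait covariance induced by population
    structure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    X = np.column_stack([np.ones(n), x])
    vc = reml_null(y, K, X)
    R = _rotate(K, vc.delta)
    yr, Xr = R @ y, R @ X
    XtX = Xr.T @ Xr
    coef = np.linalg.solve(XtX, Xr.T @ yr)
    resid = yr - Xr @ coef
    dof = n - 2
    s2 = (resid @ resid) / dof
    se = np.sqrt(s2 * np.linalg.inv(XtX)[1, 1])
    tstat = coef[1] / se
    p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return r, p
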