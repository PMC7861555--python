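"""Growth-curve fitting and quantitative-genetic summaries of growth.

Rosette diameter over time is modeled per plant as a three-parameter
logistic, d(t) = FS / (1 + exp(-slope * (t - t50))):

* FS   -- final size, the upper asymptote (cm);
* slope -- the positive rate constant of the linear growth phase (1/day);
* t50  -- the inflection point, the day at which half of FS is reached.

Plant-level parameters are then combined into design-corrected genotypic
means (accession + block + tray/(row + col) linear model, estimated
marginal means with nuisance factors averaged out), genotype-by-environment
plasticity residuals (LL means regressed on HL means), and broad-sense
heritability (genotype as random effect, block fixed, REML).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy.optimize import least_squares

from .containers import DiameterSeries, GrowthParameters
from .synthio import logistic_curve

PARAMS = ("fs", "slope", "t50")


# ---------------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------------

def _residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    fs, slope, t50 = theta
    return logistic_curve(t, fs, slope, t50) - y


def _jacobian(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    fs, slope, t50 = theta
    e = np.exp(-slope * (t - t50))
    li = 1.0 / (1.0 + e)
    j = np.empty((t.size, 3))
    j[:, 0] = li
    j[:, 1] = fs * e * (t - t50) * li**2
    j[:, 2] = -fs * e * slope * li**2
    return j


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    fs0 = float(y.max())
    if fs0 <= 0:
        fs0 = 1.0
    above = t[y >= fs0 / 2.0]
    t50_0 = float(above[0]) if above.size else float(np.median(t))
    grad = np.diff(y) / np.diff(t)
    slope0 = 4.0 * max(float(grad.max()) if grad.size else 0.1, 1e-3) / fs0
    return np.array([fs0, slope0, t50_0])


def fit_logistic(
    series: DiameterSeries, seed: int = 0, n_restarts: int = 5
) -> GrowthParameters:
    """Least-squares fit of the three-parameter logistic to one plant.

    Levenberg-Marquardt with an analytic Jacobian, started from a
    data-driven guess (FS = max diameter, t50 = first day past half of it,
    slope from the steepest observed gradient) and, on failure, from
    ``n_restarts`` deterministically jittered starts.  A fit is flagged as
    failed (``converged=False``) when the optimizer does not converge or
    the solution is not a positive, bounded increasing curve; such records
    are excluded downstream.
    """
    t, y = series.days, series.diameters
    if len(np.unique(t)) < 4:
        raise ValueError("fitting needs >= 4 distinct time points")
    if y.max() <= 0:      # plant never emerged; no growth curve to fit
        return GrowthParameters(np.nan, np.nan, np.nan, np.nan,
                                t.size, False)
    x0 = _initial_guess(t, y)
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.6, 1.4, size=3)
        try:
            res = least_squares(
                _residuals, start, jac=_jacobian, args=(t, y), method="lm",
                max_nfev=2000,
            )
        except Exception:
            continue
        fs, slope, t50 = res.x
        ok = (
            res.success
            and slope > 0
            and t50 > 0
            and 0.5 * y.max() < fs < 10.0 * max(y.max(), 1e-6)
        )
        sse = float(2.0 * res.cost)
        if ok and (best is None or sse < best[1]):
            best = (res.x, sse)
    if best is None:
        return GrowthParameters(
            fs=np.nan, slope=np.nan, t50=np.nan, sse=np.nan,
            n_points=t.size, converged=False,
        )
    (fs, slope, t50), sse = best
    return GrowthParameters(
        fs=float(fs), slope=float(slope), t50=float(t50),
        sse=sse, n_points=t.size, converged=True,
    )


def fit_all(
    series: list[DiameterSeries], seed: int = 0, min_timepoints: int = 4
) -> pd.DataFrame:
    """Fit every plant; returns one row per plant with design covariates.

    Plants with fewer than ``min_timepoints`` non-missing observations or
    failed fits are kept with ``converged=False`` so callers can log and
    drop them.
    """
    rows = []
    for s in series:
        keep = ~np.isnan(s.diameters)
        meta = {
            "plant_id": s.plant_id, "genotype": s.genotype_id,
            "regime": s.regime, "block": s.block, "tray": s.tray,
            "row": s.row, "col": s.col,
        }
        if keep.sum() < min_timepoints:
            fit = GrowthParameters(np.nan, np.nan, np.nan, np.nan,
                                   int(keep.sum()), False)
        else:
            sub = DiameterSeries(
                s.plant_id, s.genotype_id, s.regime, s.block, s.tray,
                s.row, s.col, s.days[keep], s.diameters[keep],
            )
            fit = fit_logistic(sub, seed=seed)
        rows.append({**meta, **asdict(fit)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design-corrected genotypic means
# ---------------------------------------------------------------------------

def genotypic_means(
    fits: pd.DataFrame,
    parameter: str = "fs",
    nuisance: str = "C(block) + C(tray) + C(tray):C(row) + C(tray):C(col)",
) -> pd.DataFrame:
    """Estimated marginal genotype means of one growth parameter.

    Fits ``parameter ~ genotype + block + tray + tray:row + tray:col`` by
    ordinary least squares and reports, per genotype, the model prediction
    averaged over every observed design cell, which removes block, tray
    and within-tray position effects.  Genotypes without a single
    successful fit are dropped with a warning.
    """
    data = fits.loc[fits.get("converged", True) & fits[parameter].notna()].copy()
    dropped = set(fits["genotype"]) - set(data["genotype"])
    if dropped:
        warnings.warn(f"dropping genotypes with no successful fit: {sorted(dropped)}")
    if data.empty:
        raise ValueError("no successful fits to average")
    formula = f"{parameter} ~ C(genotype)"
    # collapse nuisance terms whose factor is constant (degenerate designs)
    kept_terms = []
    for term in [t.strip() for t in nuisance.split("+")]:
        factors = [f[2:-1] for f in term.split(":")]
        if all(data[f].nunique() > 1 for f in factors):
            kept_terms.append(term)
    if kept_terms:
        formula += " + " + " + ".join(kept_terms)
    model = smf.ols(formula, data=data)
    fit = model.fit()
    design_info = model.data.design_info
    grid = data[["block", "tray", "row", "col"]]
    records = []
    for geno, _ in data.groupby("genotype"):
        counter = grid.copy()
        counter["genotype"] = geno
        (X,) = build_design_matrices([design_info], counter)
        a = np.asarray(X).mean(axis=0)
        mean = float(a @ fit.params)
        se = float(np.sqrt(a @ fit.cov_params() @ a))
        records.append({"genotype": geno, "parameter": parameter,
                        "mean": mean, "se": se})
    return pd.DataFrame(records)


def genotypic_means_all(
    fits: pd.DataFrame, parameters: tuple[str, ...] = PARAMS, **kwargs
) -> pd.DataFrame:
    """Genotype x parameter table of adjusted means (wide on parameter)."""
    pieces = [genotypic_means(fits, p, **kwargs) for p in parameters]
    long = pd.concat(pieces, ignore_index=True)
    return long.pivot(index="genotype", columns="parameter", values="mean")[
        list(parameters)
    ]


# ---------------------------------------------------------------------------
# plasticity and heritability
# ---------------------------------------------------------------------------

def gxe_residuals(
    means_hl: pd.DataFrame, means_ll: pd.DataFrame, parameter: str = "fs"
) -> pd.DataFrame:
    """Plasticity of each genotype: residual of its LL mean regressed on HL.

    The OLS line captures the population-average light response; a
    genotype's residual is its deviation from that response (positive =
    expands more than average under low light).
    """
    hl = means_hl.loc[means_hl["parameter"] == parameter].set_index("genotype")["mean"]
    ll = means_ll.loc[means_ll["parameter"] == parameter].set_index("genotype")["mean"]
    shared = hl.index.intersection(ll.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 genotypes present in both regimes")
    x, y = hl[shared].to_numpy(), ll[shared].to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.DataFrame(
        {"genotype": shared, "parameter": parameter, "gxe_residual": resid}
    )


def broad_sense_h2(
    fits: pd.DataFrame, parameter: str = "fs"
) -> float:
    """Broad-sense heritability H2 = Vg / (Vg + Ve) of one growth parameter.

    REML fit of ``parameter ~ block`` with genotype as random intercept;
    Vg is the genotype variance component and Ve the residual.  Clipped to
    [0, 1].
    """
    data = fits.loc[fits.get("converged", True) & fits[parameter].notna()].copy()
    if data[parameter].nunique() <= 1:
        raise ValueError("phenotype is constant; H2 undefined")
    counts = data.groupby("genotype").size()
    if (counts >= 2).sum() < 10:
        raise ValueError("need >= 2 replicates for >= 10 genotypes")
    # degenerate limit: replicates identical within genotype
    within = data.groupby("genotype")[parameter].var(ddof=1).mean()
    total = data[parameter].var(ddof=1)
    if within is not None and total > 0 and within / total < 1e-12:
        return 1.0
    formula = f"{parameter} ~ C(block)" if data["block"].nunique() > 1 else f"{parameter} ~ 1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["genotype"])
        res = model.fit(reml=True)
    vg = float(np.asarray(res.cov_re)[0, 0])
    ve = float(res.scale)
    return float(np.clip(vg / (vg + ve), 0.0, 1.0))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_phenotype_csv(path: str) -> list[DiameterSeries]:
    """Read the wide per-plant layout written by the synthetic generator.

    Columns: plant_id (optional), genotype, regime (optional, default HL),
    block, tray, row, col, then ``diam<day>`` measurement columns.
    """
    df = pd.read_csv(path)
    diam_cols = [c for c in df.columns if c.startswith("diam")]
    if not diam_cols:
        raise ValueError(f"{path}: no diam<day> columns found")
    days = np.array([float(c[4:]) for c in diam_cols])
    order = np.argsort(days)
    days, diam_cols = days[order], [diam_cols[i] for i in order]
    out = []
    for i, r in df.iterrows():
        vals = r[diam_cols].to_numpy(dtype=float)
        keep = ~np.isnan(vals)
        out.append(
            DiameterSeries(
                plant_id=str(r.get("plant_id", f"plant{i}")),
                genotype_id=str(r["genotype"]),
                regime=str(r.get("regime", "HL")),
                block=int(r["block"]), tray=int(r["tray"]),
                row=int(r["row"]), col=int(r["col"]),
                days=days[keep], diameters=vals[keep],
            )
        )
    return out


def write_means_csv(means: pd.DataFrame, path: str) -> None:
    means.to_csv(path, index=False)
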