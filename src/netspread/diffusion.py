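"""Linear diffusion of seeded pathology and the bidirectional regression fit.

Pathology seeded at one region spreads along the structural connectome as
``x(t) = exp(-c L t) x0`` for a rate constant ``c`` and a directional
Laplacian ``L``.  Observed regional pathology (log10 of the across-animal
mean percent area occupied) is regressed, per timepoint, on the log10 of the
anterograde and retrograde diffusion predictions:

    y(t) = b0(t) + b_a(t) * log10(x_a(t)) + b_r(t) * log10(x_r(t)) + eps(t)

The rate constants ``(c_a, c_r)`` are global across timepoints and chosen to
minimize the pooled sum of squared residuals; the regression weights are
refit per timepoint by ordinary least squares.  Regions whose predicted mass
falls at or below a small floor are excluded before taking logs, as are
regions with zero observed pathology at that timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .connectome import Connectome, SeedVector, build_laplacians, seed_vector

__all__ = [
    "DiffusionParams",
    "FittedModel",
    "PathologySummary",
    "FitConfig",
    "PropagatorCache",
    "propagate",
    "predict_log",
    "fit_model",
    "model_fit_statistic",
    "predict_alternate_seed_maps",
    "summarize_pathology",
]

MODES = ("bidirectional", "anterograde", "retrograde", "euclidean")

# which log-predictors each mode regresses on
_MODE_DIRECTIONS = {
    "bidirectional": ("antero", "retro"),
    "anterograde": ("antero",),
    "retrograde": ("retro",),
    # the surrogate network is symmetric, so the two Laplacians coincide;
    # a single rate constant and single predictor are used
    "euclidean": ("retro",),
}


@dataclass
class DiffusionParams:
    """Global rate constants (per month) and per-timepoint regression weights."""

    c_a: float
    c_r: float
    coeffs: dict[float, tuple[float, float, float]] = field(default_factory=dict)
    # coeffs[t] = (b0, b_a, b_r); unused directions carry b fixed at 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c_a) and self.c_a >= 0):
            raise ValueError(f"c_a must be finite and >= 0, got {self.c_a}")
        if not (np.isfinite(self.c_r) and self.c_r >= 0):
            raise ValueError(f"c_r must be finite and >= 0, got {self.c_r}")


@dataclass
class TimepointFit:
    """Per-timepoint regression outcome on the included-region mask."""

    mask: np.ndarray  # bool over regions; True = included in regression
    y: np.ndarray  # observed log10 pathology (NaN outside mask)
    yhat: np.ndarray  # predicted log10 pathology (NaN outside mask)
    residuals: np.ndarray  # y - yhat (NaN outside mask)
    r: float  # Pearson r over the mask; NaN if undefined


@dataclass
class FittedModel:
    params: DiffusionParams
    mode: str
    seed_region: str
    region_ids: list[str]
    anatomical_ids: list[str]
    hemisphere: list[str] | None
    timepoints: list[float]
    fits: dict[float, TimepointFit]
    sse: float

    def residual_frame(self) -> pd.DataFrame:
        """Residuals as a region x timepoint DataFrame (NaN where excluded)."""
        data = {t: self.fits[t].residuals for t in self.timepoints}
        return pd.DataFrame(data, index=self.region_ids)


@dataclass
class PathologySummary:
    """Region x timepoint means of percent area occupied, one measure."""

    region_ids: list[str]
    timepoints: list[float]
    values: np.ndarray  # shape (n_regions, n_timepoints), mean across mice
    measure: str = "total"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), len(self.timepoints)):
            raise ValueError("values shape does not match regions x timepoints")
        if np.any(self.values < 0):
            raise ValueError("pathology values must be >= 0")
        tp = np.asarray(self.timepoints, dtype=float)
        if np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        self.timepoints = [float(t) for t in tp]


@dataclass
class FitConfig:
    """Optimizer settings for the rate-constant search.

    A log-spaced grid over ``(c_a, c_r)`` is scanned first; optionally a
    derivative-free Nelder-Mead refinement is started from the best grid
    cell.  Deterministic given the configuration.
    """

    grid_size: int = 20
    c_bounds: tuple[float, float] = (1e-3, 1e2)
    refine: bool = True
    floor: float = 1e-12
    refine_maxiter: int = 200

    def grid(self) -> np.ndarray:
        lo, hi = self.c_bounds
        return np.logspace(np.log10(lo), np.log10(hi), self.grid_size)


class PropagatorCache:
    """Memoized matrix exponentials ``exp(-c L t)`` for one connectome.

    The propagator does not depend on the seed, so one cached matrix serves
    every seed region (a seed's prediction is just a column).  Sharing a
    cache across alternate-seed refits and cross-validation iterations is
    what makes those loops affordable.
    """

    def __init__(self, conn: Connectome):
        self.conn = conn
        L_a, L_r = build_laplacians(conn)
        self.L = {"antero": L_a, "retro": L_r}
        self._mats: dict[tuple[str, float, float], np.ndarray] = {}

    def matrix(self, direction: str, c: float, t: float) -> np.ndarray:
        key = (direction, float(c), float(t))
        mat = self._mats.get(key)
        if mat is None:
            mat = _expm_propagator(self.L[direction], c, t)
            self._mats[key] = mat
        return mat

    def column(self, direction: str, c: float, t: float, seed_idx: int) -> np.ndarray:
        return self.matrix(direction, c, t)[:, seed_idx]


def _expm_propagator(L: np.ndarray, c: float, t: float) -> np.ndarray:
    P = expm(-float(c) * float(t) * L)
    if not np.all(np.isfinite(P)):
        raise FloatingPointError(
            f"matrix exponential overflowed (c*t = {c * t:.3g}); "
            "check rate constant and time units"
        )
    # clip the tiny negative round-off that expm can produce
    np.clip(P, 0.0, None, out=P)
    return P


def propagate(L: np.ndarray, c: float, t: float, x0: SeedVector | np.ndarray) -> np.ndarray:
    """Diffuse ``x0`` for ``t`` months at rate ``c`` on Laplacian ``L``.

    Returns ``x(t) = exp(-c L t) x0``.  Total mass is conserved; entries are
    clipped at zero (round-off below -1e-12 would indicate a defect and is
    not clipped silently by the propagator check).
    """
    if c < 0:
        raise ValueError(f"rate constant must be >= 0, got {c}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    x0v = x0.x0 if isinstance(x0, SeedVector) else np.asarray(x0, dtype=float)
    return _expm_propagator(np.asarray(L, dtype=float), c, t) @ x0v


def predict_log(
    x_a: np.ndarray | None,
    x_r: np.ndarray | None,
    b0: float,
    b_a: float,
    b_r: float,
    floor: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-linear prediction from diffusion predictors.

    Regions where a used predictor is at or below ``floor`` are masked out
    (the log would be undefined or dominated by numerical noise).  Returns
    ``(yhat, mask)`` with ``yhat`` NaN outside the mask.  A predictor passed
    as ``None`` is unused and its weight must be zero.
    """
    if floor <= 0:
        raise ValueError(f"floor must be > 0, got {floor}")
    used = [v for v in (x_a, x_r) if v is not None]
    if not used:
        raise ValueError("at least one predictor required")
    n = len(used[0])
    if any(len(v) != n for v in used):
        raise ValueError("predictor length mismatch")
    mask = np.ones(n, dtype=bool)
    for v in used:
        mask &= np.asarray(v) > floor
    yhat = np.full(n, np.nan)
    val = np.full(mask.sum(), float(b0))
    if x_a is not None:
        val = val + b_a * np.log10(np.asarray(x_a)[mask])
    if x_r is not None:
        val = val + b_r * np.log10(np.asarray(x_r)[mask])
    yhat[mask] = val
    return yhat, mask


def model_fit_statistic(
    yhat: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Sample Pearson correlation between prediction and observation.

    Returns NaN (the undefined flag) when either vector has zero variance on
    the mask or fewer than 3 regions are included.
    """
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if mask is None:
        mask = np.isfinite(yhat) & np.isfinite(y)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(yhat) & np.isfinite(y)
    if mask.sum() < 3:
        return float("nan")
    a = yhat[mask]
    b = y[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def summarize_pathology(
    df: pd.DataFrame,
    conn: Connectome,
    measure: str = "total",
    hemisphere_match: bool | None = None,
) -> PathologySummary:
    """Collapse a long pathology table to region x timepoint means.

    Expects columns ``mouse_id, mpi, region_id, hemisphere, measure,
    pct_area``.  If the connectome carries hemisphere tags (and
    ``hemisphere_match`` is not False), rows are matched to connectome nodes
    on (anatomical label, hemisphere); otherwise on ``region_id`` alone,
    averaging across hemispheres.  Rows naming regions absent from the
    connectome are dropped with a warning.
    """
    import warnings

    sub = df[df["measure"] == measure].copy()
    if sub.empty:
        raise ValueError(f"no rows with measure {measure!r}")
    if hemisphere_match is None:
        hemisphere_match = conn.hemisphere is not None and any(
            h != "none" for h in conn.hemisphere
        )
    if hemisphere_match:
        node_of = {
            (b, h): r
            for r, b, h in zip(conn.region_ids, conn.anatomical_ids, conn.hemisphere)
        }
        keys = list(zip(sub["region_id"], sub["hemisphere"]))
        sub["node"] = [node_of.get(k) for k in keys]
    else:
        known = set(conn.region_ids)
        sub["node"] = [r if r in known else None for r in sub["region_id"]]
    dropped = sub["node"].isna()
    if dropped.any():
        missing = sorted(set(sub.loc[dropped, "region_id"]))
        warnings.warn(
            f"dropping {int(dropped.sum())} pathology rows for regions not in the "
            f"connectome: {missing[:10]}{'...' if len(missing) > 10 else ''}",
            stacklevel=2,
        )
        sub = sub[~dropped]
    means = sub.groupby(["node", "mpi"])["pct_area"].mean()
    timepoints = sorted(sub["mpi"].unique())
    values = np.zeros((conn.n, len(timepoints)))
    for j, t in enumerate(timepoints):
        for i, r in enumerate(conn.region_ids):
            values[i, j] = means.get((r, t), 0.0)
    return PathologySummary(
        region_ids=list(conn.region_ids),
        timepoints=[float(t) for t in timepoints],
        values=values,
        measure=measure,
    )


def _mode_rates(mode: str, c_a: float, c_r: float) -> dict[str, float]:
    dirs = _MODE_DIRECTIONS[mode]
    rates = {}
    if "antero" in dirs:
        rates["antero"] = c_a
    if "retro" in dirs:
        rates["retro"] = c_r
    return rates


def _timepoint_ols(
    y_log: np.ndarray,
    obs_mask: np.ndarray,
    predictors: dict[str, np.ndarray],
    floor: float,
) -> tuple[tuple[float, float, float], TimepointFit] | None:
    """OLS of observed log pathology on log predictors at one timepoint.

    Returns None when fewer included regions than regression parameters.
    """
    n = len(y_log)
    mask = obs_mask.copy()
    for v in predictors.values():
        mask &= v > floor
    k = 1 + len(predictors)
    m = int(mask.sum())
    if m < k:
        return None
    X = np.ones((m, k))
    order = []
    for j, (d, v) in enumerate(predictors.items(), start=1):
        X[:, j] = np.log10(v[mask])
        order.append(d)
    yv = y_log[mask]
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    yhat_m = X @ beta
    b0 = float(beta[0])
    b_a = float(beta[order.index("antero") + 1]) if "antero" in order else 0.0
    b_r = float(beta[order.index("retro") + 1]) if "retro" in order else 0.0
    y_full = np.full(n, np.nan)
    yhat_full = np.full(n, np.nan)
    y_full[mask] = yv
    yhat_full[mask] = yhat_m
    resid = y_full - yhat_full
    r = model_fit_statistic(yhat_full, y_full)
    fit = TimepointFit(mask=mask, y=y_full, yhat=yhat_full, residuals=resid, r=r)
    return (b0, b_a, b_r), fit


def _evaluate(
    summary: PathologySummary,
    cache: PropagatorCache,
    seed_idx: int,
    mode: str,
    c_a: float,
    c_r: float,
    floor: float,
    include: np.ndarray,
) -> tuple[float, dict[float, tuple[float, float, float]], dict[float, TimepointFit]]:
    """Pooled SSE plus per-timepoint OLS coefficients at fixed rates."""
    sse = 0.0
    coeffs: dict[float, tuple[float, float, float]] = {}
    fits: dict[float, TimepointFit] = {}
    rates = _mode_rates(mode, c_a, c_r)
    for j, t in enumerate(summary.timepoints):
        col = summary.values[:, j]
        obs_mask = (col > 0) & include
        if obs_mask.sum() < 3:
            continue
        with np.errstate(divide="ignore"):
            y_log = np.where(col > 0, np.log10(np.where(col > 0, col, 1.0)), np.nan)
        predictors = {
            d: cache.column(d, c, t, seed_idx) for d, c in rates.items()
        }
        out = _timepoint_ols(y_log, obs_mask, predictors, floor)
        if out is None:
            continue
        beta, fit = out
        coeffs[t] = beta
        fits[t] = fit
        sse += float(np.nansum(fit.residuals**2))
    return sse, coeffs, fits


def fit_model(
    pathology: PathologySummary,
    conn: Connectome,
    seed: SeedVector | str,
    mode: str = "bidirectional",
    config: FitConfig | None = None,
    cache: PropagatorCache | None = None,
    include_regions: np.ndarray | None = None,
) -> FittedModel:
    """Fit the diffusion regression model to summarized pathology.

    Global rate constants are found by a log-spaced grid search over
    ``(c_a, c_r)`` (1-D for single-direction modes) minimizing the pooled
    SSE across timepoints, optionally refined by Nelder-Mead in log10 rate
    space.  Per-timepoint intercept and direction weights come from OLS on
    regions with nonzero observed pathology and predictors above the floor.

    ``include_regions`` restricts the regression to a boolean subset of
    regions (used by cross-validation); predictions can still be evaluated
    on the complement afterwards.  ``mode="euclidean"`` expects ``conn`` to
    be the distance surrogate network.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    config = config or FitConfig()
    if cache is None:
        cache = PropagatorCache(conn)
    if isinstance(seed, str):
        seed = seed_vector(conn, seed)
    seed_idx = int(np.argmax(seed.x0))
    include = (
        np.ones(conn.n, dtype=bool)
        if include_regions is None
        else np.asarray(include_regions, dtype=bool)
    )
    n_nonzero_tp = sum(
        ((pathology.values[:, j] > 0) & include).sum() >= 3
        for j in range(len(pathology.timepoints))
    )
    if len(pathology.timepoints) < 2 or n_nonzero_tp < 2:
        raise ValueError(
            "need at least 2 timepoints with >= 3 regions of nonzero pathology"
        )

    dirs = _MODE_DIRECTIONS[mode]
    grid = config.grid()

    def objective(ca: float, cr: float) -> float:
        sse, coeffs, _ = _evaluate(
            pathology, cache, seed_idx, mode, ca, cr, config.floor, include
        )
        if not coeffs:
            return np.inf
        return sse

    best = (np.inf, grid[0], grid[0])
    if len(dirs) == 2:
        for ca in grid:
            for cr in grid:
                s = objective(ca, cr)
                if s < best[0]:
                    best = (s, ca, cr)
    else:
        for c in grid:
            s = objective(c, c)
            if s < best[0]:
                best = (s, c, c)
    if not np.isfinite(best[0]):
        raise ValueError(
            "model could not be fit: fewer included regions than parameters "
            "at every timepoint for every candidate rate"
        )

    _, ca, cr = best
    if config.refine:
        lo, hi = np.log10(config.c_bounds[0]), np.log10(config.c_bounds[1])

        def clipped(v: np.ndarray) -> np.ndarray:
            return 10 ** np.clip(v, lo, hi)

        if len(dirs) == 2:
            fun = lambda v: objective(*clipped(v))
            x0 = np.log10([ca, cr])
        else:
            fun = lambda v: objective(clipped(v)[0], clipped(v)[0])
            x0 = np.log10([ca])
        res = minimize(
            fun,
            x0,
            method="Nelder-Mead",
            options={"maxiter": config.refine_maxiter, "xatol": 1e-4, "fatol": 1e-12},
        )
        if np.isfinite(res.fun) and res.fun <= best[0]:
            v = clipped(np.atleast_1d(res.x))
            ca, cr = (v[0], v[1]) if len(dirs) == 2 else (v[0], v[0])

    sse, coeffs, fits = _evaluate(
        pathology, cache, seed_idx, mode, ca, cr, config.floor, include
    )
    c_a = ca if "antero" in dirs else 0.0
    c_r = cr if "retro" in dirs else 0.0
    params = DiffusionParams(c_a=c_a, c_r=c_r, coeffs=coeffs)
    return FittedModel(
        params=params,
        mode=mode,
        seed_region=seed.seed_region,
        region_ids=list(conn.region_ids),
        anatomical_ids=conn.anatomical_ids,
        hemisphere=list(conn.hemisphere) if conn.hemisphere is not None else None,
        timepoints=sorted(coeffs),
        fits=fits,
        sse=sse,
    )


def predict_map(
    cache: PropagatorCache,
    params: DiffusionParams,
    mode: str,
    seed_idx: int,
    t: float,
    floor: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted log pathology map at one timepoint for fixed parameters."""
    b0, b_a, b_r = params.coeffs[t]
    rates = _mode_rates(mode, params.c_a, params.c_r)
    x_a = cache.column("antero", rates["antero"], t, seed_idx) if "antero" in rates else None
    x_r = cache.column("retro", rates["retro"], t, seed_idx) if "retro" in rates else None
    return predict_log(x_a, x_r, b0, b_a, b_r, floor=floor)


def predict_alternate_seed_maps(
    fitted: FittedModel,
    conn: Connectome,
    seeds: list[str],
    floor: float = 1e-12,
    cache: PropagatorCache | None = None,
) -> dict[str, dict[float, np.ndarray]]:
    """Predicted maps for alternate seed sites with parameters held fixed.

    The fitted rate constants and per-timepoint weights are kept constant;
    only the seed vector changes.  Returns ``{seed: {t: yhat}}`` with NaN at
    masked regions.
    """
    if cache is None:
        cache = PropagatorCache(conn)
    out: dict[str, dict[float, np.ndarray]] = {}
    for s in seeds:
        idx = conn.index(s)
        out[s] = {}
        for t in fitted.timepoints:
            yhat, _ = predict_map(cache, fitted.params, fitted.mode, idx, t, floor)
            out[s][t] = yhat
    return out
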