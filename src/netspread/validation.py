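"""Seed-specificity null test and cross-validated model comparison.

Two complementary checks of the diffusion model:

* the *alternate-seed* test refits the full model with the seed moved to
  randomly chosen other regions and asks how often a wrong seed explains the
  data as well as the experimental one;
* *cross-validation* repeatedly splits the regions into train/test halves,
  fits each candidate spread model (Euclidean surrogate, anterograde-only,
  retrograde-only, bidirectional) on the training half, and scores the
  Pearson correlation of its predictions on the held-out half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import ranksums

from .connectome import Connectome, euclidean_surrogate, seed_vector
from .diffusion import (
    FitConfig,
    FittedModel,
    PathologySummary,
    PropagatorCache,
    fit_model,
    model_fit_statistic,
    predict_map,
)

__all__ = ["SeedNullResult", "CrossvalResult", "alternate_seed_test", "crossval_compare"]


@dataclass
class SeedNullResult:
    """Outcome of the alternate-seed specificity test."""

    actual_seed: str
    alternate_seeds: list[str]
    timepoints: list[float]
    r_actual: dict[float, float]
    r_alternate: dict[float, np.ndarray]  # length n_alt per timepoint
    p: dict[float, float]  # add-one permutation p, never exactly 0
    p_raw: dict[float, float]  # raw proportion as reported in the source data

    @property
    def n_alt(self) -> int:
        return len(self.alternate_seeds)


@dataclass
class CrossvalResult:
    """Held-out fit distributions per model type and their pairwise tests."""

    modes: list[str]
    timepoints: list[float]
    n_iter: int
    heldout_r: dict[str, dict[float, np.ndarray]]  # mode -> t -> length n_iter
    comparisons: dict[tuple[str, str], dict[float, dict]] = field(default_factory=dict)
    # comparisons[(m1, m2)][t] = {"median_diff": float, "p": float | None}
    unstable_modes: list[str] = field(default_factory=list)


def alternate_seed_test(
    pathology: PathologySummary,
    conn: Connectome,
    actual_seed: str,
    mode: str = "bidirectional",
    n_alt: int = 500,
    rng_seed: int | None = None,
    config: FitConfig | None = None,
    replace: bool = False,
    cache: PropagatorCache | None = None,
) -> SeedNullResult:
    """Refit the model with randomly drawn alternate seed regions.

    For each alternate seed the seed vector is redefined and the model fully
    refit (same optimizer settings), yielding a null distribution of fits
    per timepoint.  ``p(t) = (1 + #{r_alt(t) >= r_actual(t)}) / (1 + n_alt)``
    (add-one convention, never exactly 0); the raw proportion is stored
    alongside.  The actual seed is never among the alternates.
    """
    if n_alt < 1:
        raise ValueError(f"n_alt must be >= 1, got {n_alt}")
    candidates = [r for r in conn.region_ids if r != actual_seed]
    if n_alt > len(candidates) and not replace:
        raise ValueError(
            f"n_alt={n_alt} exceeds the {len(candidates)} candidate regions; "
            "enable replace=True to sample with replacement"
        )
    rng = np.random.default_rng(rng_seed)
    # draw in lexicographic candidate order so the stream is label-stable
    order = sorted(candidates)
    chosen = list(rng.choice(order, size=n_alt, replace=replace))

    if cache is None:
        cache = PropagatorCache(conn)
    config = config or FitConfig()

    actual_fit = fit_model(pathology, conn, actual_seed, mode, config, cache)
    timepoints = list(actual_fit.timepoints)
    r_actual = {t: actual_fit.fits[t].r for t in timepoints}

    # fit each distinct alternate seed once (sampling with replacement can
    # repeat seeds; the refit is deterministic given the config)
    r_by_seed: dict[str, dict[float, float]] = {}
    for s in dict.fromkeys(chosen):
        try:
            f = fit_model(pathology, conn, s, mode, config, cache)
            r_by_seed[s] = {t: f.fits[t].r if t in f.fits else np.nan
                            for t in timepoints}
        except ValueError:
            r_by_seed[s] = {t: np.nan for t in timepoints}
    r_alt: dict[float, list[float]] = {
        t: [r_by_seed[s][t] for s in chosen] for t in timepoints
    }

    p: dict[float, float] = {}
    p_raw: dict[float, float] = {}
    r_alt_arr: dict[float, np.ndarray] = {}
    for t in timepoints:
        arr = np.asarray(r_alt[t], dtype=float)
        r_alt_arr[t] = arr
        n_ge = int(np.sum(arr >= r_actual[t]))  # NaN compares False
        p[t] = (1 + n_ge) / (1 + n_alt)
        p_raw[t] = n_ge / n_alt
    return SeedNullResult(
        actual_seed=actual_seed,
        alternate_seeds=chosen,
        timepoints=timepoints,
        r_actual=r_actual,
        r_alternate=r_alt_arr,
        p=p,
        p_raw=p_raw,
    )


def _heldout_r(
    fitted: FittedModel,
    pathology: PathologySummary,
    cache: PropagatorCache,
    seed_idx: int,
    test_mask: np.ndarray,
    floor: float,
) -> dict[float, float]:
    """Pearson r of train-fitted predictions on held-out regions."""
    out = {}
    for j, t in enumerate(pathology.timepoints):
        if t not in fitted.params.coeffs:
            out[t] = np.nan
            continue
        col = pathology.values[:, j]
        obs = (col > 0) & test_mask
        yhat, pred_mask = predict_map(cache, fitted.params, fitted.mode, seed_idx, t, floor)
        m = obs & pred_mask
        with np.errstate(divide="ignore"):
            y = np.where(col > 0, np.log10(np.where(col > 0, col, 1.0)), np.nan)
        out[t] = model_fit_statistic(yhat, y, m)
    return out


def crossval_compare(
    pathology: PathologySummary,
    conn: Connectome,
    seed_region: str,
    coords: np.ndarray | None = None,
    modes: tuple[str, ...] = ("euclidean", "anterograde", "retrograde", "bidirectional"),
    n_iter: int = 500,
    split_fraction: float = 0.5,
    rng_seed: int | None = None,
    config: FitConfig | None = None,
) -> CrossvalResult:
    """Compare spread models by repeated train/test splits over regions.

    Per iteration, regions are randomly partitioned; parameters are
    estimated on the training half and each model is scored by the Pearson
    correlation of its predictions with the held-out half.  The per-mode
    held-out distributions are compared pairwise per timepoint with a
    two-sided Wilcoxon rank-sum test.  With ``n_iter=1`` the distributions
    have a single entry and comparisons are reported as undefined (p=None).
    A mode that fails to fit on more than half of the iterations is flagged
    unstable rather than silently dropped.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    config = config or FitConfig()
    rng = np.random.default_rng(rng_seed)

    caches: dict[str, PropagatorCache] = {}
    conns: dict[str, Connectome] = {}
    main_cache = PropagatorCache(conn)
    for m in modes:
        if m == "euclidean":
            c = coords if coords is not None else conn.coords
            if c is None:
                raise ValueError("euclidean mode requires region centroids")
            surro = euclidean_surrogate(c, region_ids=list(conn.region_ids))
            conns[m] = surro
            caches[m] = PropagatorCache(surro)
        else:
            conns[m] = conn
            caches[m] = main_cache

    seed_idx = conn.index(seed_region)
    n = conn.n
    # permutation stream anchored to lexicographic region order, so the
    # held-out distributions do not depend on input file row order
    lex = np.argsort(np.asarray(conn.region_ids))
    n_train = max(int(round(split_fraction * n)), 1)

    timepoints = list(pathology.timepoints)
    held: dict[str, dict[float, list[float]]] = {
        m: {t: [] for t in timepoints} for m in modes
    }
    failures = {m: 0 for m in modes}

    for _ in range(n_iter):
        perm = lex[rng.permutation(n)]
        train = np.zeros(n, dtype=bool)
        train[perm[:n_train]] = True
        test = ~train
        for m in modes:
            try:
                fitted = fit_model(
                    pathology, conns[m], seed_region, m, config, caches[m],
                    include_regions=train,
                )
                rs = _heldout_r(
                    fitted, pathology, caches[m], seed_idx, test, config.floor
                )
            except ValueError:
                failures[m] += 1
                rs = {t: np.nan for t in timepoints}
            for t in timepoints:
                held[m][t].append(rs.get(t, np.nan))

    heldout_r = {
        m: {t: np.asarray(held[m][t], dtype=float) for t in timepoints} for m in modes
    }
    unstable = [m for m in modes if failures[m] > n_iter / 2]

    comparisons: dict[tuple[str, str], dict[float, dict]] = {}
    for m1, m2 in combinations(modes, 2):
        comparisons[(m1, m2)] = {}
        for t in timepoints:
            a = heldout_r[m1][t]
            b = heldout_r[m2][t]
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            if n_iter < 2 or len(a) < 2 or len(b) < 2:
                comparisons[(m1, m2)][t] = {"median_diff": np.nan, "p": None}
                continue
            stat = ranksums(a, b)
            comparisons[(m1, m2)][t] = {
                "median_diff": float(np.median(a) - np.median(b)),
                "p": float(stat.pvalue),
            }
    return CrossvalResult(
        modes=list(modes),
        timepoints=timepoints,
        n_iter=n_iter,
        heldout_r=heldout_r,
        comparisons=comparisons,
        unstable_modes=unstable,
    )
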