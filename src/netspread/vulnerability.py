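"""Residual-based regional vulnerability and pathology timing summaries.

The diffusion regression's residuals measure how much more (positive) or
less (negative) pathology a region carries than its connectivity predicts.
Averaging residuals over the late timepoints — where the model is reliable —
gives a composite per-region vulnerability score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import FittedModel, PathologySummary, model_fit_statistic

__all__ = [
    "VulnerabilityMap",
    "composite_vulnerability",
    "residual_correlation_matrix",
    "peak_timepoint",
]

DEFAULT_VULN_MPI = (1.0, 3.0, 6.0, 9.0)


@dataclass
class VulnerabilityMap:
    """Composite per-region vulnerability (mean residual, log10 units).

    ``count`` records how many timepoint-by-hemisphere residuals contributed
    to each score; regions excluded from the model at every included
    timepoint carry no score (absent from the map).
    """

    region_ids: list[str]
    score: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.count = np.asarray(self.count, dtype=int)
        if np.any(self.count < 1):
            raise ValueError("scores defined only where count >= 1")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("scores must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.region_ids, name="vulnerability")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": self.region_ids, "score": self.score, "n_contributing": self.count}
        )


def _match_timepoints(available: list[float], wanted) -> list[float]:
    out = []
    for t in available:
        if any(np.isclose(t, w) for w in wanted):
            out.append(t)
    return out


def composite_vulnerability(
    fitted: FittedModel,
    include_mpi=DEFAULT_VULN_MPI,
    pool_hemispheres: bool = True,
) -> VulnerabilityMap:
    """Average model residuals over the included timepoints per region.

    Early timepoints are excluded by default because model performance there
    is weak and residual patterns differ from the later, stable ones.  When
    the connectome is hemispheric and ``pool_hemispheres`` is on, the ipsi
    and contra instances of an anatomical region are averaged into a single
    score; only defined residuals contribute (no imputation — imputing zeros
    would bias the score toward resilience).
    """
    tps = _match_timepoints(fitted.timepoints, include_mpi)
    if not tps:
        raise ValueError(
            f"include_mpi {tuple(include_mpi)} is disjoint from fitted "
            f"timepoints {tuple(fitted.timepoints)}"
        )
    labels = (
        fitted.anatomical_ids
        if pool_hemispheres
        else list(fitted.region_ids)
    )
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for t in tps:
        resid = fitted.fits[t].residuals
        for lab, v in zip(labels, resid):
            if np.isfinite(v):
                sums[lab] = sums.get(lab, 0.0) + float(v)
                counts[lab] = counts.get(lab, 0) + 1
    # preserve first-appearance order of labels
    seen = []
    for lab in labels:
        if lab in counts and lab not in seen:
            seen.append(lab)
    score = np.array([sums[lab] / counts[lab] for lab in seen])
    count = np.array([counts[lab] for lab in seen])
    return VulnerabilityMap(region_ids=seen, score=score, count=count)


def residual_correlation_matrix(fitted: FittedModel) -> pd.DataFrame:
    """Pairwise Pearson correlations between residual vectors.

    One block per timepoint (split further by hemisphere when the connectome
    is hemispheric). Correlations are computed on regions where both vectors
    are defined; cells with fewer than 3 shared regions are NaN. Diagonal is
    exactly 1.
    """
    blocks: dict[str, np.ndarray] = {}
    hemispheric = fitted.hemisphere is not None and any(
        h != "none" for h in fitted.hemisphere
    )
    for t in fitted.timepoints:
        resid = fitted.fits[t].residuals
        if hemispheric:
            hemi = np.asarray(fitted.hemisphere)
            for h in ("ipsi", "contra"):
                sel = hemi == h
                if sel.any():
                    blocks[f"{t:g}_{h}"] = resid[sel]
        else:
            blocks[f"{t:g}"] = resid
    names = list(blocks)
    if len(names) < 2:
        raise ValueError("need at least 2 residual vectors")
    k = len(names)
    M = np.full((k, k), np.nan)
    for i in range(k):
        M[i, i] = 1.0
        for j in range(i + 1, k):
            a, b = blocks[names[i]], blocks[names[j]]
            if len(a) != len(b):
                continue
            shared = np.isfinite(a) & np.isfinite(b)
            if shared.sum() < 3:
                continue
            M[i, j] = M[j, i] = model_fit_statistic(a, b, shared)
    if not any(
        np.isfinite(M[i, j]) for i in range(k) for j in range(i + 1, k)
    ):
        raise ValueError("no residual vector pair shares >= 3 regions")
    return pd.DataFrame(M, index=names, columns=names)


def peak_timepoint(pathology: PathologySummary) -> pd.Series:
    """Timepoint of maximal mean pathology per region.

    Ties break to the earliest timepoint; all-zero series are flagged
    ``"none"``.  Returns an object-dtype Series indexed by region.
    """
    if len(pathology.timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    tp = np.asarray(pathology.timepoints)
    out = []
    for i, r in enumerate(pathology.region_ids):
        row = pathology.values[i]
        if np.all(row == 0):
            out.append("none")
        else:
            out.append(float(tp[int(np.argmax(row))]))  # argmax takes first max
    return pd.Series(out, index=pathology.region_ids, name="peak_mpi", dtype=object)
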