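"""Segment/gene quality control and gene-vulnerability association.

Mirrors the standard processing of a spatial-profiling expression dataset:
segments are dropped when any sequencing metric falls below threshold,
genes are dropped when rarely detected above the negative-probe limit of
quantification (LOQ) or flagged as Grubbs outliers; surviving expression is
normalized per gene by a scaled sigmoid and a rank inverse-normal
transform, then correlated with regional vulnerability (Pearson, BH-FDR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SEGMENT_QC_THRESHOLDS",
    "qc_segments",
    "grubbs_test",
    "qc_genes",
    "sigmoid_scale",
    "rank_inverse_normal",
    "gene_vulnerability_correlation",
    "kinase_filter",
]

# metric -> minimum acceptable value; evaluated in this order, first failure
# recorded as the removal reason
SEGMENT_QC_THRESHOLDS = {
    "trimmed_pct": 80.0,
    "stitched_pct": 80.0,
    "aligned_pct": 75.0,
    "saturation_pct": 50.0,
    "pct_genes_above_loq": 3.0,
}

_REASON = {
    "trimmed_pct": "trimmed",
    "stitched_pct": "stitched",
    "aligned_pct": "aligned",
    "saturation_pct": "saturation",
    "pct_genes_above_loq": "loq",
}


def qc_segments(
    metrics: pd.DataFrame, thresholds: dict[str, float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a segment metrics table into kept and removed segments.

    A segment is removed if any metric falls strictly below its threshold;
    the removed table carries the first failing metric (in the fixed order
    trimmed, stitched, aligned, saturation, loq) as ``reason``.
    """
    thresholds = {**SEGMENT_QC_THRESHOLDS, **(thresholds or {})}
    missing = [c for c in SEGMENT_QC_THRESHOLDS if c not in metrics.columns]
    if missing:
        raise ValueError(f"missing metric columns: {missing}")
    for c in SEGMENT_QC_THRESHOLDS:
        col = metrics[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)) or np.any(col < 0) or np.any(col > 100):
            raise ValueError(f"metric {c!r} must be finite and within [0, 100]")
    reasons = []
    for _, row in metrics.iterrows():
        reason = None
        for c in SEGMENT_QC_THRESHOLDS:
            if row[c] < thresholds[c]:
                reason = _REASON[c]
                break
        reasons.append(reason)
    reasons = pd.Series(reasons, index=metrics.index)
    removed = metrics[reasons.notna()].copy()
    removed["reason"] = reasons[reasons.notna()]
    kept = metrics[reasons.isna()].copy()
    return kept, removed


@dataclass
class GrubbsResult:
    outlier_index: int | None
    G: float
    G_critical: float
    degenerate: bool = False


def grubbs_test(values: np.ndarray, alpha: float = 0.01) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    ``G = max |x_i - mean| / sd`` (sample sd); the critical value is
    ``((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2))`` with ``t`` the upper
    ``alpha/(2n)`` quantile of Student's t at ``n-2`` degrees of freedom.
    An outlier is reported iff ``G > G_critical``.  Constant input returns
    no outlier with the degenerate flag set.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"Grubbs test needs n >= 3, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    sd = x.std(ddof=1)
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
    if sd == 0:
        return GrubbsResult(None, 0.0, g_crit, degenerate=True)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    G = float(dev[idx] / sd)
    return GrubbsResult(idx if G > g_crit else None, G, g_crit)


def _geometric_stats(x: np.ndarray) -> tuple[float, float]:
    """Geometric mean and geometric SD (multiplicative), zeros floored at 1."""
    logs = np.log(np.maximum(x, 1.0))
    return float(np.exp(logs.mean())), float(np.exp(logs.std(ddof=1)))


def qc_genes(
    counts: pd.DataFrame,
    neg_probe_rows: list[str],
    alpha: float = 0.01,
    min_detect_frac: float = 0.01,
    keep_genes: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Gene-level QC against the negative-probe limit of quantification.

    Per segment, ``LOQ = geomean(neg probes) * geoSD(neg probes)^2``; a gene
    is detected in a segment when its count exceeds that segment's LOQ.
    Genes detected in fewer than ``min_detect_frac`` of segments are
    removed (genes named in ``keep_genes`` are exempt from every rule,
    supporting a-priori targets retained regardless of QC performance), as
    are single-pass Grubbs outliers: *global* (across genes, on
    per-gene pooled log2 geometric means) and *local* (within a gene,
    across its per-segment log2 values).  Returns the kept gene list and a
    ledger naming the rule that removed each gene.
    """
    if not neg_probe_rows:
        raise ValueError("need at least one negative-probe row")
    vals = counts.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative counts")
    neg = counts.loc[neg_probe_rows].to_numpy(dtype=float)
    genes = [g for g in counts.index if g not in set(neg_probe_rows)]
    gmat = counts.loc[genes].to_numpy(dtype=float)
    n_seg = counts.shape[1]

    loq = np.empty(n_seg)
    for j in range(n_seg):
        gm, gsd = _geometric_stats(neg[:, j])
        loq[j] = gm * gsd**2

    protected = set(keep_genes or ())
    removed: list[tuple[str, str]] = []
    detected = gmat > loq[None, :]
    frac = detected.mean(axis=1)
    survivors = []
    for g, f in zip(genes, frac):
        if f < min_detect_frac and g not in protected:
            removed.append((g, "LOQ"))
        else:
            survivors.append(g)

    if len(survivors) >= 3:
        pooled = np.log2(counts.loc[survivors].to_numpy(dtype=float).mean(axis=1) + 1)
        res = grubbs_test(pooled, alpha=alpha)
        if res.outlier_index is not None:
            g = survivors[res.outlier_index]
            if g not in protected:
                removed.append((g, "global_grubbs"))
                survivors = [x for x in survivors if x != g]
    kept = []
    for g in survivors:
        row = np.log2(counts.loc[g].to_numpy(dtype=float) + 1)
        if len(row) >= 3 and g not in protected:
            res = grubbs_test(row, alpha=alpha)
            if res.outlier_index is not None and not res.degenerate:
                removed.append((g, "local_grubbs"))
                continue
        kept.append(g)
    ledger = pd.DataFrame(removed, columns=["gene", "reason"])
    return kept, ledger


def sigmoid_scale(x: np.ndarray) -> np.ndarray:
    """Scaled sigmoidal normalization onto [0, 1].

    z-scores are passed through the logistic function and min-max rescaled;
    strictly order-preserving.  Constant input returns all 0.5.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    sd = x.std()
    if sd == 0:
        return np.full(len(x), 0.5)
    z = (x - x.mean()) / sd
    s = 1.0 / (1.0 + np.exp(-z))
    return (s - s.min()) / (s.max() - s.min())


def rank_inverse_normal(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank inverse-normal (Blom) transform.

    ``z_i = Phi^{-1}((rank_i - 3/8) / (n + 1/4))`` with average ranks for
    ties.  An all-tied vector maps to all zeros.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    if np.all(x == x[0]):
        return np.zeros(n)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))


def _pearson_with_p(G: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of matrix G against vector v, with two-sided p."""
    n = G.shape[1]
    Gc = G - G.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    gnorm = np.sqrt((Gc**2).sum(axis=1))
    vnorm = np.sqrt((vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Gc @ vc) / (gnorm * vnorm)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    return r, p


def gene_vulnerability_correlation(
    atlas: pd.DataFrame,
    vulnerability: pd.Series,
    skip_sigmoid: bool = False,
) -> pd.DataFrame:
    """Correlate each gene's regional expression with vulnerability.

    ``atlas`` is gene x region; regions are intersected with the
    vulnerability map (requiring at least 4 shared regions).  Per gene the
    expression vector is sigmoid-scaled then rank inverse-normal
    transformed; vulnerability is rank inverse-normal transformed; the
    association is the Pearson correlation with its two-sided p, and q is
    the Benjamini-Hochberg FDR across genes.  Genes constant across regions
    are returned with NaN statistics and excluded from the FDR.

    The rank transform makes the sigmoid order-irrelevant; it is applied
    anyway for fidelity to the stated pipeline, and ``skip_sigmoid`` offers
    the equivalent fast path.
    """
    if atlas.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if atlas.columns.duplicated().any():
        raise ValueError("duplicate region ids")
    shared = [r for r in atlas.columns if r in set(vulnerability.index)]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} regions shared; need >= 4")
    X = atlas[shared].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite expression values")
    v = rank_inverse_normal(vulnerability[shared].to_numpy(dtype=float))
    n = len(shared)

    constant = np.all(X == X[:, [0]], axis=1)
    T = np.empty_like(X)
    for i in range(X.shape[0]):
        if constant[i]:
            continue
        g = X[i] if skip_sigmoid else sigmoid_scale(X[i])
        T[i] = rank_inverse_normal(g)
    r = np.full(X.shape[0], np.nan)
    p = np.full(X.shape[0], np.nan)
    ok = ~constant
    if ok.any():
        r[ok], p[ok] = _pearson_with_p(T[ok], v)
    q = np.full(X.shape[0], np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": atlas.index,
            "r": r,
            "p": p,
            "q": q,
            "n": n,
            "constant": constant,
        }
    ).set_index("gene")


def kinase_filter(
    assoc: pd.DataFrame,
    kinase_list: list[str],
    de_gene_list: list[str],
    q_threshold: float = 0.05,
    direction: str = "positive",
) -> list[str]:
    """Kinases significantly associated with vulnerability and differentially
    expressed in inclusion-bearing neurons.

    Keeps genes present in ``kinase_list`` with ``q < q_threshold`` and a
    correlation of the requested sign, intersected with ``de_gene_list``;
    returned ordered by descending r.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    kin = [g for g in kinase_list if g in assoc.index]
    de = set(de_gene_list)
    rows = assoc.loc[kin]
    sig = rows["q"] < q_threshold
    sign = rows["r"] > 0 if direction == "positive" else rows["r"] < 0
    hits = rows[sig & sign & rows.index.isin(de)]
    return list(hits.sort_values("r", ascending=False).index)
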