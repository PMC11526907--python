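"""Preranked gene-set enrichment (weighted Kolmogorov-Smirnov running sum).

Genes are sorted by a score (here, the Pearson correlation of expression
with regional vulnerability).  For a gene set, a running sum increments by
the set genes' |score|^w share at hits and decrements uniformly at misses;
the enrichment score ES is the extremum of that walk.  Significance comes
from gene-label permutation: random same-size sets define the null, p and
the normalized ES are computed per sign, and the FDR follows the standard
preranked convention (same-sign null exceedance rate over observed
exceedance rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GeneSetResult", "enrichment_score", "preranked_gsea"]


@dataclass
class GeneSetResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str]


def enrichment_score(
    sorted_genes: list[str],
    sorted_scores: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> tuple[float, list[str]]:
    """ES and leading-edge genes for one set on a score-sorted gene list.

    ``sorted_genes``/``sorted_scores`` must be in descending score order.
    Hits advance the running sum by ``|score|^weight`` normalized over the
    set; misses retreat by ``1/(N - k)``.  ES is the running-sum value of
    largest magnitude (ties break to the positive side).
    """
    n = len(sorted_genes)
    hit = np.fromiter((g in gene_set for g in sorted_genes), dtype=bool, count=n)
    k = int(hit.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    w = np.abs(np.asarray(sorted_scores, dtype=float)) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all set genes have score 0: fall back to unweighted steps
        hit_w = hit.astype(float)
        total = float(k)
    step_hit = hit_w / total
    step_miss = np.where(hit, 0.0, 1.0 / (n - k))
    running = np.cumsum(step_hit - step_miss)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        lead = [g for g, h in zip(sorted_genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        es = float(running[i_min])
        lead = [g for g, h in zip(sorted_genes[i_min:], hit[i_min:]) if h]
    return es, lead


def _es_only(hit: np.ndarray, w: np.ndarray, n: int) -> float:
    """ES for a boolean hit vector (permutation inner loop)."""
    k = int(hit.sum())
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = hit.astype(float)
        total = float(k)
    running = np.cumsum(hit_w / total - np.where(hit, 0.0, 1.0 / (n - k)))
    hi = running.max()
    lo = running.min()
    return float(hi) if hi >= -lo else float(lo)


def preranked_gsea(
    ranking: dict[str, float],
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    rng_seed: int | None = None,
) -> list[GeneSetResult]:
    """Preranked enrichment of gene sets in a score-ranked gene list.

    Sets are intersected with the ranked universe; sets smaller than
    ``min_size`` after intersection are skipped (empty intersections with a
    warning).  The null is gene-label permutation: ``n_perm`` random sets of
    matching size.  Per set, ``NES = ES / mean(|null ES| of matching
    sign)``, ``p`` is the add-one same-sign exceedance, and FDR follows the
    standard preranked convention.  Deterministic given ``rng_seed``.
    """
    import warnings

    genes = list(ranking)
    scores = np.asarray([ranking[g] for g in genes], dtype=float)
    order = np.argsort(-scores, kind="stable")
    sorted_genes = [genes[i] for i in order]
    sorted_scores = scores[order]
    n = len(sorted_genes)
    universe = set(sorted_genes)
    w = np.abs(sorted_scores) ** weight
    rng = np.random.default_rng(rng_seed)

    kept: list[tuple[str, set[str]]] = []
    for name, members in gene_sets.items():
        inter = members & universe
        if not inter:
            warnings.warn(f"gene set {name!r} has empty intersection; skipped",
                          stacklevel=2)
            continue
        if len(inter) < min_size or len(inter) >= n:
            continue
        kept.append((name, inter))

    # one permutation null per distinct set size
    sizes = sorted({len(m) for _, m in kept})
    null_by_size: dict[int, np.ndarray] = {}
    for k in sizes:
        null = np.empty(n_perm)
        for b in range(n_perm):
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size=k, replace=False)] = True
            null[b] = _es_only(hit, w, n)
        null_by_size[k] = null

    obs = []
    for name, members in kept:
        es, lead = enrichment_score(sorted_genes, sorted_scores, members, weight)
        obs.append((name, members, es, lead))

    def _nes(es: float, null: np.ndarray) -> float:
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.abs(same).mean() if len(same) else np.abs(null).mean()
        return es / denom if denom > 0 else np.nan

    results = []
    all_obs_nes = []
    all_null_nes = []
    for name, members, es, lead in obs:
        null = null_by_size[len(members)]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        n_same = len(same)
        if n_same:
            exceed = int(np.sum(np.abs(same) >= abs(es)))
            p = (1 + exceed) / (1 + n_same)
        else:
            p = 1.0 / (1 + n_perm)
        nes = _nes(es, null)
        all_obs_nes.append(nes)
        all_null_nes.append(np.array([_nes(e, null) for e in null]))
        results.append(GeneSetResult(name, len(members), es, nes, p, np.nan, lead))

    # FDR: same-sign null NES exceedance rate over observed exceedance rate
    if results:
        obs_nes = np.asarray(all_obs_nes)
        null_nes = np.concatenate(all_null_nes)
        for res, nes in zip(results, obs_nes):
            if not np.isfinite(nes):
                res.fdr = np.nan
                continue
            same_null = null_nes[null_nes >= 0] if nes >= 0 else null_nes[null_nes < 0]
            same_obs = obs_nes[obs_nes >= 0] if nes >= 0 else obs_nes[obs_nes < 0]
            num = np.mean(np.abs(same_null) >= abs(nes)) if len(same_null) else 0.0
            den = np.mean(np.abs(same_obs) >= abs(nes)) if len(same_obs) else 1.0
            res.fdr = float(min(1.0, num / den)) if den > 0 else 1.0
    return results
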