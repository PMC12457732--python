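"""Model evaluation: rank-based AUC, max-TSS threshold selection, filtering.

Replicates are evaluated on their held-out 30% test partition. AUC is the
Mann-Whitney probability that a presence outscores a background point (ties
count one half). The binarization threshold maximizes sensitivity +
specificity over all observed scores (the max-TSS / Youden criterion); TSS =
sensitivity + specificity - 1. Only replicates with AUC >= 0.75 and
TSS >= 0.7 enter the ensemble.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def auc(scores_presence, scores_background) -> float:
    """Rank-based (Mann-Whitney) AUC; ties scored 0.5."""
    a = np.asarray(scores_presence, dtype=np.float64)
    b = np.asarray(scores_background, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def select_threshold_tss(scores_presence, scores_background) -> tuple[float, float, float, float]:
    """Pick the score threshold maximizing sensitivity + specificity.

    Every unique observed score is a candidate; a point is predicted present
    iff its score >= threshold. Ties among maxima break toward the smallest
    threshold. Returns (threshold, tss, sensitivity, specificity).
    """
    a = np.asarray(scores_presence, dtype=np.float64)
    b = np.asarray(scores_background, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = np.unique(np.concatenate([a, b]))  # sorted ascending
    # sens(t) = P(a >= t), spec(t) = P(b < t); vectorized via searchsorted on sorted arrays
    a_sorted, b_sorted = np.sort(a), np.sort(b)
    sens = (a.size - np.searchsorted(a_sorted, thresholds, side="left")) / a.size
    spec = np.searchsorted(b_sorted, thresholds, side="left") / b.size
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (smallest t) maximum
    return float(thresholds[best]), float(tss[best]), float(sens[best]), float(spec[best])


def filter_replicates(replicates: list, auc_min: float = 0.75, tss_min: float = 0.7) -> list:
    """Keep replicates with auc >= auc_min and tss >= tss_min (both inclusive)."""
    retained = [r for r in replicates if r.auc >= auc_min and r.tss >= tss_min]
    if not retained:
        raise RuntimeError(
            f"no replicate passed AUC >= {auc_min} and TSS >= {tss_min}; ensemble impossible")
    return retained


def retention_by_algorithm(replicates: list, retained: list) -> dict[str, tuple[int, int]]:
    """Per-algorithm (n_retained, n_total) counts."""
    out: dict[str, list[int]] = {}
    kept = {id(r) for r in retained}
    for r in replicates:
        alg = r.spec.algorithm
        cur = out.setdefault(alg, [0, 0])
        cur[1] += 1
        if id(r) in kept:
            cur[0] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}
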