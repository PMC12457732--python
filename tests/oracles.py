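"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written the slow, obviously-correct way and must stay
independent of the code paths it checks.
"""

import numpy as np
from scipy import integrate


def auc_pair_counting(pres, back) -> float:
    """AUC by exhaustive pair comparison; ties count one half."""
    wins = 0.0
    for a in pres:
        for b in back:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pres) * len(back))


def tss_threshold_scan(pres, back):
    """Best (threshold, tss) by scanning every observed score, smallest-t ties."""
    pres = list(pres)
    back = list(back)
    best_t, best_tss = None, -np.inf
    for t in sorted(set(pres) | set(back)):
        tp = sum(1 for a in pres if a >= t)
        tn = sum(1 for b in back if b < t)
        tss = tp / len(pres) + tn / len(back) - 1.0
        if tss > best_tss:
            best_t, best_tss = t, tss
    return best_t, best_tss


def spearman_rank_pearson(x, y) -> float:
    """Spearman rho as Pearson correlation of mid-ranks."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def spherical_cell_area_quad(lon_w, lon_e, lat_s, lat_n, radius) -> float:
    """Cell area by numerical integration of the surface element R^2 cos(phi)."""
    inner, _ = integrate.quad(lambda phi: np.cos(phi),
                              np.deg2rad(lat_s), np.deg2rad(lat_n))
    return radius**2 * np.deg2rad(lon_e - lon_w) * inner


def sd_two_pass(values) -> float:
    """Sample SD, explicit two-pass formula."""
    values = [v for v in values if not np.isnan(v)]
    n = len(values)
    if n < 2:
        return float("nan")
    mean = sum(values) / n
    return float(np.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)))
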