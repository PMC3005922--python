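"""Reference-threshold calibration and intra/inter distance validation.

Given distances between pairs of compounds known to share a binding mode
(or scaffold) — "intra" pairs — and pairs known not to — "inter" pairs —
the reference threshold is the distance cut t* that maximizes
discrimination accuracy: the fraction of intra pairs falling strictly
below t plus inter pairs falling at or above t, over all pairs. The same
pair populations feed a pooled-variance two-sample t-test, the check that
intra-cluster distances are significantly smaller than inter-cluster ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ThresholdResult:
    """Maximum-discrimination threshold and the accuracy it achieves."""

    t_star: float
    accuracy: float
    n_intra: int
    n_inter: int


@dataclass
class TTestResult:
    """Two-sample pooled-variance t-test summary for intra vs inter distances."""

    mean_intra: float
    mean_inter: float
    std_intra: float
    std_inter: float
    t_stat: float
    p_value: float
    alpha: float
    reject: bool


def _as_array(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} distances must be a non-empty 1-d sequence")
    return arr


def discrimination_accuracy(t: float, intra, inter) -> float:
    """(# intra < t + # inter >= t) / (n_intra + n_inter)."""
    intra = _as_array("intra", intra)
    inter = _as_array("inter", inter)
    hits = int(np.sum(intra < t)) + int(np.sum(inter >= t))
    return hits / (intra.size + inter.size)


def threshold_candidates(intra, inter) -> np.ndarray:
    """Candidate cuts: midpoints between consecutive pooled unique distances,
    plus the two extremes (the minimum itself, and just past the maximum)."""
    pooled = np.unique(np.concatenate([_as_array("intra", intra),
                                       _as_array("inter", inter)]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    return np.concatenate([[pooled[0]], mids, [pooled[-1] + 1.0]])


def reference_threshold(intra, inter) -> ThresholdResult:
    """Sweep every candidate cut and return the smallest maximizer."""
    intra = _as_array("intra", intra)
    inter = _as_array("inter", inter)
    best_t = None
    best_acc = -1.0
    for t in threshold_candidates(intra, inter):
        acc = discrimination_accuracy(float(t), intra, inter)
        if acc > best_acc:
            best_acc = acc
            best_t = float(t)
    return ThresholdResult(
        t_star=best_t,
        accuracy=best_acc,
        n_intra=int(intra.size),
        n_inter=int(inter.size),
    )


def intra_inter_ttest(intra, inter, alpha: float = 0.01) -> TTestResult:
    """Pooled-variance two-sided two-sample t-test on distance populations.

    Degenerate case: zero pooled variance with equal means gives t = 0,
    p = 1 (no evidence of separation).
    """
    intra = _as_array("intra", intra)
    inter = _as_array("inter", inter)
    if intra.size < 2 or inter.size < 2:
        raise ValueError("each sample needs at least 2 distances")
    s1 = float(np.std(intra, ddof=1))
    s2 = float(np.std(inter, ddof=1))
    m1 = float(np.mean(intra))
    m2 = float(np.mean(inter))
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = float(np.sign(m1 - m2)) * np.inf
            p = 0.0
    else:
        res = stats.ttest_ind(intra, inter, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return TTestResult(
        mean_intra=m1,
        mean_inter=m2,
        std_intra=s1,
        std_inter=s2,
        t_stat=t_stat,
        p_value=p,
        alpha=alpha,
        reject=bool(p < alpha),
    )
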