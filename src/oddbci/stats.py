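"""Behavioral metrics and statistical machinery.

Behavioral summaries follow signal-detection conventions: the hit rate is
the fraction of odd (target) sounds answered within the 2 s response
window, the false-positive rate the fraction of standards answered, and
d' = z(hit) - z(fp) with 1/(2n) edge clipping. Responses later than 2 s are
"late" and excluded from RT averages.

Group statistics use a paired sign-flip permutation test on per-subject
condition-difference maps with Benjamini-Hochberg FDR control at
alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .preprocess import EpochSet


@dataclass
class BehaviorSummary:
    n_odd: int
    n_standard: int
    n_hit: int
    n_miss: int
    n_late: int
    n_fp: int
    hit_rate: float
    miss_rate: float
    late_rate: float
    fp_rate: float
    d_prime: float
    mean_rt_ms: float


@dataclass
class StatMap:
    """Point-wise p-values with an FDR-adjusted significance mask."""

    p: np.ndarray
    mask: np.ndarray
    n_perm: int
    alpha: float = 0.05
    observed: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def d_prime(hit_rate: float, fp_rate: float, n_odd: int, n_std: int) -> float:
    """Sensitivity d' = z(hit) - z(fp), rates clipped to [1/(2n), 1-1/(2n)]."""
    if n_odd <= 0 or n_std <= 0:
        raise ValueError("trial counts must be positive")
    if not (0 <= hit_rate <= 1 and 0 <= fp_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    h = np.clip(hit_rate, 1 / (2 * n_odd), 1 - 1 / (2 * n_odd))
    f = np.clip(fp_rate, 1 / (2 * n_std), 1 - 1 / (2 * n_std))
    return float(sstats.norm.ppf(h) - sstats.norm.ppf(f))


def summarize_behavior(trials: pd.DataFrame) -> BehaviorSummary:
    """Rates, d' and mean RT from a trial table (one row per stimulus)."""
    odd = trials[trials["stimulus"] == "odd"]
    std = trials[trials["stimulus"] == "standard"]
    if len(odd) == 0:
        raise ValueError("no odd trials")
    n_hit = int((odd["outcome"] == "hit").sum())
    n_miss = int((odd["outcome"] == "miss").sum())
    n_late = int((odd["outcome"] == "late").sum())
    n_fp = int((std["outcome"] == "fp").sum())
    n_odd, n_std = len(odd), len(std)
    hit_rate = n_hit / n_odd
    fp_rate = n_fp / n_std if n_std else 0.0
    rts = odd.loc[odd["outcome"] == "hit", "rt_ms"]
    return BehaviorSummary(
        n_odd=n_odd, n_standard=n_std, n_hit=n_hit, n_miss=n_miss,
        n_late=n_late, n_fp=n_fp, hit_rate=hit_rate, miss_rate=n_miss / n_odd,
        late_rate=n_late / n_odd, fp_rate=fp_rate,
        d_prime=d_prime(hit_rate, fp_rate, n_odd, max(n_std, 1)),
        mean_rt_ms=float(rts.mean()) if len(rts) else float("nan"))


def match_responses(stim_onsets: np.ndarray, stim_classes: np.ndarray,
                    press_times: np.ndarray,
                    window_s: float = 2.0) -> pd.DataFrame:
    """Reconstruct a trial table from raw event streams.

    A press within ``(0, window_s]`` of the most recent odd sound is that
    sound's response (first press wins); any press not matching an odd
    window is a false positive attributed to the most recent standard.
    """
    stim_onsets = np.asarray(stim_onsets, float)
    order = np.argsort(stim_onsets, kind="stable")
    onsets, classes = stim_onsets[order], np.asarray(stim_classes, object)[order]
    outcome = np.where(classes == "odd", "miss", "none").astype(object)
    rt = np.full(len(onsets), np.nan)
    for t in np.sort(np.asarray(press_times, float)):
        prev = np.searchsorted(onsets, t, side="right") - 1
        # most recent odd sound with the press inside its window
        cand = [i for i in range(prev, -1, -1)
                if t - onsets[i] <= window_s and classes[i] == "odd"]
        hit = next((i for i in cand if outcome[i] == "miss"), None)
        if hit is not None and 0 < t - onsets[hit]:
            outcome[hit] = "hit"
            rt[hit] = (t - onsets[hit]) * 1000.0
        elif prev >= 0 and classes[prev] == "standard" and outcome[prev] == "none":
            outcome[prev] = "fp"
            rt[prev] = (t - onsets[prev]) * 1000.0
    return pd.DataFrame({"onset_s": onsets, "stimulus": classes,
                         "outcome": outcome, "rt_ms": rt})


# ---------------------------------------------------------------------------
# trial balancing
# ---------------------------------------------------------------------------

def balance_trial_counts(epochs: EpochSet,
                         rng: Optional[np.random.Generator] = None,
                         conditions: Optional[list] = None) -> EpochSet:
    """Randomly subsample every condition to the minimum condition count."""
    rng = np.random.default_rng(rng)
    conds = conditions or sorted(set(epochs.labels.tolist()))
    idx = {c: np.flatnonzero(epochs.labels == c) for c in conds}
    if any(len(v) == 0 for v in idx.values()):
        raise ValueError("a condition has no trials")
    n_min = min(len(v) for v in idx.values())
    keep = np.sort(np.concatenate(
        [rng.choice(v, size=n_min, replace=False) for v in idx.values()]))
    return epochs.select(keep)


# ---------------------------------------------------------------------------
# permutation testing and FDR
# ---------------------------------------------------------------------------

def fdr_correct(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up mask at level ``alpha``."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(p.shape)


def pointwise_permutation_test(a: np.ndarray, b: np.ndarray,
                               n_perm: int = 2000,
                               rng: Optional[np.random.Generator] = None,
                               alpha: float = 0.05) -> StatMap:
    """Paired sign-flip permutation test on per-subject condition maps.

    ``a`` and ``b`` are (n_subjects, ...) arrays of per-subject condition
    means. The statistic is the across-subject mean difference at each
    point; the null is generated by independent random sign flips of each
    subject's difference map; p-values use the add-one estimator and are
    two-sided. The returned mask is BH-FDR corrected at ``alpha``.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("condition maps must have identical shapes")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values")
    rng = np.random.default_rng(rng)
    d = (a - b).reshape(a.shape[0], -1)
    n_subj = d.shape[0]
    obs = d.mean(axis=0)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    perm = (flips @ d) / n_subj
    exceed = (np.abs(perm) >= np.abs(obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    mask = fdr_correct(p, alpha)
    shape = a.shape[1:]
    return StatMap(p.reshape(shape), mask.reshape(shape), n_perm, alpha,
                   obs.reshape(shape))


def paired_t_test(x, y) -> tuple:
    """Two-sided paired t-test; returns ``(t, df, p)``.

    Zero-variance differences are undefined and reported as NaN.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of >= 2 subjects")
    d = x - y
    df = len(d) - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, df, 1.0
        return float("nan"), df, float("nan")
    t, p = sstats.ttest_rel(x, y)
    return float(t), df, float(p)
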