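"""Condition-wise ERP, spectral and time-frequency features.

ERP measurements follow the oddball conventions used throughout this
package: N1 is the most negative sample in a montage-specific search window
(50-150 ms for the scalp montage, 120-220 ms for the ear grid, whose
auditory N1 peaks later), P300 is the mean amplitude over 300-500 ms
post-stimulus. PSDs use Welch's method with 250 ms Hamming segments and no
overlap. ERSPs use Morlet wavelets at 40 frequencies in [3, 40] Hz with
c(f) = 3 * (f / 3)^0.8 cycles, evaluated on a 250-point grid over
[-442, 938] ms and expressed in dB against a common (condition-pooled)
pre-stimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .preprocess import EpochSet

#: channel pools whose mean waveform is measured, per montage
DEFAULT_POOLS = {
    "ear_grid16": {"left": ["L2", "L3"], "right": ["R2", "R3"]},
    "scalp8": {"Cz": ["Cz"], "Pz": ["Pz"]},
}

#: N1 search windows (ms) per montage
N1_WINDOWS_MS = {"scalp8": (50.0, 150.0), "ear_grid16": (120.0, 220.0)}

P300_WINDOW_MS = (300.0, 500.0)


@dataclass
class ERPResult:
    """Grand-average ERP of one condition with scalar measurements."""

    waveform: np.ndarray            # channels x samples, uV
    times: np.ndarray               # seconds
    ch_names: list
    n_trials: int
    pooled: Dict[str, np.ndarray] = field(default_factory=dict)
    n1: Dict[str, tuple] = field(default_factory=dict)      # pool -> (uV, ms)
    p300: Dict[str, float] = field(default_factory=dict)    # pool -> uV


@dataclass
class PSDResult:
    freqs: np.ndarray               # Hz
    power: np.ndarray               # channels x freqs, uV^2/Hz
    ch_names: list
    n_trials: int

    def db(self) -> np.ndarray:
        return 10.0 * np.log10(np.maximum(self.power, 1e-20))


@dataclass
class ERSPResult:
    freqs: np.ndarray               # 40 frequencies, Hz
    times: np.ndarray               # 250 points, seconds
    db: np.ndarray                  # channels x freqs x times
    ch_names: list
    n_trials: int


# ---------------------------------------------------------------------------
# ERP
# ---------------------------------------------------------------------------

def average_erp(epochs: EpochSet, pooling: Optional[Dict[str, list]] = None,
                montage: Optional[str] = None) -> Dict[str, ERPResult]:
    """Per-condition trial-average ERP with pooled-channel measurements."""
    results = {}
    n1_win = N1_WINDOWS_MS.get(montage, (50.0, 150.0))
    for cond in sorted(set(epochs.labels.tolist())):
        sel = epochs.labels == cond
        if not sel.any():
            continue
        wave = epochs.data[sel].mean(axis=0)
        res = ERPResult(wave, epochs.times, list(epochs.ch_names),
                        int(sel.sum()))
        for name, chans in (pooling or {}).items():
            rows = [epochs.ch_names.index(c) for c in chans]
            pooled = wave[rows].mean(axis=0)
            res.pooled[name] = pooled
            res.n1[name] = measure_n1(pooled, epochs.times, n1_win)
            res.p300[name] = measure_p300(pooled, epochs.times)
        results[str(cond)] = res
    return results


def measure_n1(waveform: np.ndarray, times: np.ndarray,
               search_ms: tuple = (50.0, 150.0)) -> tuple:
    """Most negative sample in the search window -> (amplitude uV, latency ms).

    Ties go to the earliest latency (argmin returns the first minimum).
    """
    t_ms = times * 1000.0
    mask = (t_ms >= search_ms[0] - 1e-9) & (t_ms <= search_ms[1] + 1e-9)
    if not mask.any():
        raise ValueError("N1 search window outside the epoch")
    seg = waveform[mask]
    k = int(np.argmin(seg))
    return float(seg[k]), float(t_ms[mask][k])


def measure_p300(waveform: np.ndarray, times: np.ndarray,
                 window_ms: tuple = P300_WINDOW_MS) -> float:
    """Mean amplitude over the 300-500 ms post-stimulus window."""
    t_ms = times * 1000.0
    if t_ms[-1] < window_ms[1] - 1e-9:
        raise ValueError("epoch does not cover the P300 window")
    mask = (t_ms >= window_ms[0] - 1e-9) & (t_ms <= window_ms[1] + 1e-9)
    return float(waveform[mask].mean())


# ---------------------------------------------------------------------------
# Welch PSD and band power
# ---------------------------------------------------------------------------

def welch_psd(epochs: EpochSet, segment_s: float = 0.25
              ) -> Dict[str, PSDResult]:
    """Per-condition Welch PSD: non-overlapping Hamming segments of
    ``floor(segment_s * rate)`` samples, averaged over segments and trials."""
    nperseg = int(np.floor(segment_s * epochs.rate))
    if epochs.data.shape[2] < nperseg:
        raise ValueError("epoch shorter than one Welch segment")
    results = {}
    for cond in sorted(set(epochs.labels.tolist())):
        sel = epochs.labels == cond
        f, pxx = sps.welch(epochs.data[sel], fs=epochs.rate, window="hamming",
                           nperseg=nperseg, noverlap=0, axis=2)
        results[str(cond)] = PSDResult(f, pxx.mean(axis=0),
                                       list(epochs.ch_names), int(sel.sum()))
    return results


def band_power(psd: PSDResult, band: tuple) -> np.ndarray:
    """Mean power (uV^2/Hz) per channel over grid frequencies in ``band``.

    A grid frequency belongs to the band when its resolution bin overlaps
    the interval, so narrow bands (e.g. the 7-8 Hz alpha window on a
    ~4 Hz Welch grid) still map to their nearest bin.
    """
    if band[0] > psd.freqs[-1] or band[1] < psd.freqs[0]:
        raise ValueError(f"band {band} does not overlap the frequency grid")
    mask = (psd.freqs >= band[0] - 1e-9) & (psd.freqs <= band[1] + 1e-9)
    if not mask.any():
        df = np.median(np.diff(psd.freqs))
        mask = (psd.freqs + df / 2 > band[0]) & (psd.freqs - df / 2 < band[1])
    if not mask.any():
        raise ValueError(f"band {band} does not overlap the frequency grid")
    return psd.power[:, mask].mean(axis=1)


def center_psd_across_conditions(psds: Dict[str, PSDResult]
                                 ) -> Dict[str, np.ndarray]:
    """Subject-level display normalization: each condition's dB spectrum
    minus the across-condition mean dB spectrum."""
    db = {c: p.db() for c, p in psds.items()}
    mean = np.mean(list(db.values()), axis=0)
    return {c: v - mean for c, v in db.items()}


# ---------------------------------------------------------------------------
# ERSP
# ---------------------------------------------------------------------------

ERSP_FREQS = np.linspace(3.0, 40.0, 40)
ERSP_TIMES = np.linspace(-0.442, 0.938, 250)


def wavelet_cycles(freqs: np.ndarray, base_cycles: float = 3.0,
                   expansion: float = 0.8) -> np.ndarray:
    """Cycles per frequency: ``base_cycles * (f / f_min)^expansion``."""
    return base_cycles * (freqs / freqs[0]) ** expansion


def ersp(epochs: EpochSet, freqs: Optional[np.ndarray] = None,
         times: Optional[np.ndarray] = None,
         expansion: float = 0.8) -> Dict[str, ERSPResult]:
    """Per-condition event-related spectral perturbation.

    Morlet-wavelet power is averaged over trials, interpolated onto the
    output time grid, and converted to dB against a common baseline: the
    mean pre-stimulus power pooled over all conditions, per channel and
    frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = ERSP_FREQS if freqs is None else np.asarray(freqs)
    times = ERSP_TIMES if times is None else np.asarray(times)
    n_cycles = wavelet_cycles(freqs, expansion=expansion)
    t_in = epochs.times

    mean_power = {}
    counts = {}
    for cond in sorted(set(epochs.labels.tolist())):
        sel = epochs.labels == cond
        power = tfr_array_morlet(epochs.data[sel], sfreq=epochs.rate,
                                 freqs=freqs, n_cycles=n_cycles,
                                 output="avg_power", zero_mean=True,
                                 verbose="error")
        # interpolate onto the requested time grid
        out = np.empty((power.shape[0], len(freqs), len(times)))
        for c in range(power.shape[0]):
            for fi in range(len(freqs)):
                out[c, fi] = np.interp(times, t_in, power[c, fi])
        mean_power[str(cond)] = out
        counts[str(cond)] = int(sel.sum())

    pre = times < 0.0
    baseline = np.mean([p[:, :, pre].mean(axis=2) for p in mean_power.values()],
                       axis=0)  # channels x freqs, pooled over conditions
    results = {}
    for cond, p in mean_power.items():
        db = 10.0 * np.log10(np.maximum(p, 1e-30)
                             / np.maximum(baseline[:, :, None], 1e-30))
        results[cond] = ERSPResult(freqs.copy(), times.copy(), db,
                                   list(epochs.ch_names), counts[cond])
    return results
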