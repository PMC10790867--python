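"""Cleaning and epoching of continuous oddball EEG.

Pipeline order (enforced by :func:`preprocess_recording`): resample to
250 Hz -> zero-phase band-pass FIR (Hamming, order 414) -> bad-channel
repair -> artifact subspace reconstruction (ASR) -> ear-grid bipolar
re-referencing (ear montage only) -> epoching with baseline correction.

ASR here is the sliding-window covariance-eigendecomposition variant:
component variances of each 0.5 s window are compared against the
directional variance of a low-artifact calibration segment; components
beyond ``burst_sd`` standard deviations are reconstructed from the retained
subspace, and windows are recombined with a Hann cross-fade. A recording
whose flagged-window fraction exceeds ``max_repaired_fraction`` is marked
unusable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .synthetic import ContinuousRecording, MONTAGES

logger = logging.getLogger("oddbci")


@dataclass
class FilterSpec:
    """Band-pass FIR design: Hamming window, linear phase."""

    low_hz: float = 1.0
    high_hz: float = 20.0
    order: int = 414
    window: str = "hamming"
    transition_hz: float = 1.0

    def validate(self, rate: float) -> None:
        if not (0 < self.low_hz < self.high_hz < rate / 2):
            raise ValueError(
                f"need 0 < low < high < Nyquist, got [{self.low_hz}, "
                f"{self.high_hz}] at {rate} Hz")
        if self.order % 2:
            raise ValueError("order must be even (integer group delay)")

    def taps(self, rate: float) -> np.ndarray:
        self.validate(rate)
        return sps.firwin(self.order + 1, [self.low_hz, self.high_hz],
                          window=self.window, pass_zero=False, fs=rate)


ERP_BAND = FilterSpec(1.0, 20.0)
SPECTRAL_BAND = FilterSpec(1.0, 40.0)


@dataclass
class ASRParams:
    """clean_rawdata-style hyperparameters."""

    flatline_s: float = 5.0
    channel_correlation: float = 0.85
    line_noise_sd: float = 4.0
    burst_sd: float = 10.0
    max_repaired_fraction: float = 0.45
    window_s: float = 0.5
    calibration_s: float = 60.0

    def __post_init__(self):
        for v in (self.flatline_s, self.channel_correlation, self.line_noise_sd,
                  self.burst_sd, self.window_s):
            if v <= 0:
                raise ValueError("ASR parameters must be positive")
        if not 0 < self.max_repaired_fraction <= 1:
            raise ValueError("max_repaired_fraction must be in (0, 1]")


@dataclass
class EpochSet:
    """Trials x channels x samples, cut around events.

    The epoch window is half-open ``[start, end)`` in seconds relative to the
    event, so ``n_samples = round((end - start) * rate)`` and the onset
    sample is included.
    """

    data: np.ndarray
    rate: float
    window: tuple
    labels: np.ndarray          # condition per trial
    ch_names: list
    baseline: Optional[tuple] = None
    n_dropped: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        expected = int(round((self.window[1] - self.window[0]) * self.rate))
        if self.data.ndim != 3 or self.data.shape[2] != expected:
            raise ValueError("epoch sample count does not match window")
        if self.baseline is not None:
            if not (self.window[0] - 1e-9 <= self.baseline[0]
                    and self.baseline[1] <= self.window[1] + 1e-9):
                raise ValueError("baseline window must lie inside epoch window")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) / self.rate

    def select(self, idx) -> "EpochSet":
        return EpochSet(self.data[idx], self.rate, self.window,
                        self.labels[idx], list(self.ch_names), self.baseline,
                        self.n_dropped)

    def pick_channels(self, names: Sequence[str]) -> "EpochSet":
        order = [self.ch_names.index(n) for n in names]
        return EpochSet(self.data[:, order], self.rate, self.window,
                        self.labels, list(names), self.baseline, self.n_dropped)


# ---------------------------------------------------------------------------
# resampling and filtering
# ---------------------------------------------------------------------------

def resample(recording: ContinuousRecording, target_rate: float
             ) -> ContinuousRecording:
    """Polyphase anti-aliased resampling; event times stay in seconds."""
    if target_rate > recording.rate:
        raise ValueError("upsampling is not supported")
    if target_rate == recording.rate:
        return recording.copy()
    frac = Fraction(target_rate / recording.rate).limit_denominator(1000)
    data = sps.resample_poly(recording.data, frac.numerator, frac.denominator,
                             axis=1)
    out = recording.copy()
    out.data = data
    out.rate = float(target_rate)
    return out


def filter_data(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR along the last axis at effective zero phase.

    The signal is reflection-padded, convolved, and shifted back by the
    group delay (order/2 samples), so component latencies are preserved and
    the output has the input's length.
    """
    order = len(taps) - 1
    pad = order
    x = np.atleast_2d(data)
    xp = np.pad(x, [(0, 0), (pad, pad)], mode="reflect")
    y = sps.fftconvolve(xp, taps[None, :], mode="full", axes=1)
    # full conv of length N+2p+order; aligned output starts at pad + order/2
    start = pad + order // 2
    y = y[:, start:start + x.shape[1]]
    return y if data.ndim == 2 else y[0]


def bandpass_filter(recording: ContinuousRecording, spec: FilterSpec
                    ) -> ContinuousRecording:
    taps = spec.taps(recording.rate)
    out = recording.copy()
    out.data = filter_data(recording.data, taps)
    return out


# ---------------------------------------------------------------------------
# bad-channel detection and repair
# ---------------------------------------------------------------------------

# approximate unit-sphere 10-20 positions for the scalp montage
_SCALP_XYZ = {
    "Cz": (0.0, 0.0, 1.0), "Fz": (0.0, 0.719, 0.695),
    "Pz": (0.0, -0.719, 0.695), "C3": (-0.719, 0.0, 0.695),
    "C4": (0.719, 0.0, 0.695), "Fpz": (0.0, 0.951, 0.309),
    "Fp1": (-0.294, 0.905, 0.309), "Fp2": (0.294, 0.905, 0.309),
}


def _longest_flat_run(x: np.ndarray, tol: float = 1e-9) -> int:
    flat = np.abs(np.diff(x)) < tol
    if not flat.any():
        return 0
    # lengths of runs of True
    edges = np.diff(np.concatenate([[0], flat.view(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max()) + 1


def find_bad_channels(recording: ContinuousRecording, params: ASRParams
                      ) -> list:
    """Channels that are flat, decorrelated from all neighbours, or
    dominated by high-frequency noise (robust z > line_noise_sd)."""
    x = recording.data
    n_ch = x.shape[0]
    fs = recording.rate
    bad = set()

    flat_n = int(params.flatline_s * fs)
    for i in range(n_ch):
        if _longest_flat_run(x[i]) >= flat_n:
            bad.add(i)

    # windowed correlation: a channel is bad when its best correlation with
    # any other channel stays below the threshold in > 40% of 1 s windows
    # (whole-recording correlation would be poisoned by transient artifacts)
    good = [i for i in range(n_ch) if i not in bad]
    win = int(fs)
    n_win = x.shape[1] // win
    if len(good) >= 2 and n_win >= 1:
        xs = x[good, : n_win * win].reshape(len(good), n_win, win)
        low = np.zeros(len(good))
        for w in range(n_win):
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(xs[:, w])
            np.fill_diagonal(corr, np.nan)
            maxcorr = np.nanmax(np.abs(corr), axis=1)
            low += (maxcorr < params.channel_correlation) | ~np.isfinite(maxcorr)
        for k, i in enumerate(good):
            if low[k] / n_win > 0.4:
                bad.add(i)

    # high-frequency "noisiness": HF-to-LF amplitude ratio, robust z-score
    sos = sps.butter(4, min(45.0, fs / 2 * 0.9), btype="lowpass", fs=fs,
                     output="sos")
    lf = sps.sosfiltfilt(sos, x, axis=1)
    hf = x - lf
    ratio = hf.std(axis=1) / np.maximum(lf.std(axis=1), 1e-12)
    med = np.median(ratio)
    mad = np.median(np.abs(ratio - med)) * 1.4826
    if mad > 0:
        z = (ratio - med) / mad
        # absolute floor: HF content must be a material share of the signal,
        # otherwise band-passed data with near-identical tiny ratios would
        # produce spurious robust-z outliers
        bad.update(np.flatnonzero((z > params.line_noise_sd)
                                  & (ratio > 0.1)).tolist())

    return sorted(bad)


def _interpolate_channel(recording: ContinuousRecording, idx: int,
                         good: list) -> np.ndarray:
    labels = recording.labels
    if recording.montage == "scalp8":
        p0 = np.array(_SCALP_XYZ[labels[idx]])
        w, acc = 0.0, np.zeros(recording.n_samples)
        for j in good:
            d = np.linalg.norm(np.array(_SCALP_XYZ[labels[j]]) - p0)
            wj = 1.0 / max(d, 1e-6) ** 2
            acc += wj * recording.data[j]
            w += wj
        return acc / w
    # ear grid: mean of adjacent same-grid electrodes
    side, num = labels[idx][0], int(labels[idx][1:])
    neigh = [f"{side}{num - 1}", f"{side}{num + 1}"]
    rows = [labels.index(n) for n in neigh
            if n in labels and labels.index(n) in good]
    if not rows:  # fall back to the grid average
        rows = [j for j in good if labels[j][0] == side]
    return recording.data[rows].mean(axis=0)


def repair_bad_channels(recording: ContinuousRecording, params: ASRParams
                        ) -> tuple:
    """Flag and interpolate bad channels; returns ``(recording, flagged)``."""
    if recording.n_channels < 3:
        raise ValueError("need at least 3 channels")
    bad = find_bad_channels(recording, params)
    if len(bad) > recording.n_channels / 2:
        raise RuntimeError(
            f"{len(bad)}/{recording.n_channels} channels flagged bad "
            f"({[recording.labels[i] for i in bad]}); recording unusable")
    out = recording.copy()
    good = [i for i in range(recording.n_channels) if i not in bad]
    for i in bad:
        out.data[i] = _interpolate_channel(recording, i, good)
    flagged = [recording.labels[i] for i in bad]
    if flagged:
        logger.info("repaired channels: %s", flagged)
    return out, flagged


# ---------------------------------------------------------------------------
# artifact subspace reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ASRResult:
    recording: ContinuousRecording
    repaired_fraction: float
    usable: bool


def _auto_calibration(data: np.ndarray, fs: float, seconds: float) -> np.ndarray:
    """Pick the quietest 1 s windows (multichannel RMS z-score) as calibration."""
    win = int(fs)
    n_win = data.shape[1] // win
    if n_win < 1:
        raise ValueError("recording shorter than one calibration window")
    segs = data[:, : n_win * win].reshape(data.shape[0], n_win, win)
    rms = np.sqrt((segs ** 2).mean(axis=(0, 2)))
    order = np.argsort(rms)
    keep = order[: max(1, min(n_win, int(np.ceil(seconds))))]
    return np.concatenate([segs[:, k, :] for k in np.sort(keep)], axis=1)


def asr_clean(recording: ContinuousRecording, params: ASRParams,
              calibration: Optional[ContinuousRecording] = None) -> ASRResult:
    """Sliding-window artifact subspace reconstruction.

    ``calibration`` may be another recording containing low-artifact signal;
    by default the quietest stretches of the input itself are used. Requires
    at least 30 s of calibration data.
    """
    fs = recording.rate
    x = recording.data
    n_ch, n_samp = x.shape
    win = int(round(params.window_s * fs))
    if calibration is not None:
        calib = calibration.data
    else:
        calib = _auto_calibration(x, fs, params.calibration_s)
    if calib.shape[1] < win:
        raise ValueError("calibration shorter than one ASR window")
    if calib.shape[1] < 30 * fs:
        warnings.warn("less than 30 s of calibration data for ASR")
    calib = calib - calib.mean(axis=1, keepdims=True)
    c0 = calib @ calib.T / calib.shape[1]
    evals, evecs = np.linalg.eigh(c0)
    evals = np.maximum(evals, 1e-12)
    m = evecs @ np.diag(np.sqrt(evals)) @ evecs.T  # sqrtm(C0)

    # per-component amplitude statistics over calibration windows: the
    # rejection threshold along a direction v is
    #   sum_j ((mu_j + burst_sd * sig_j) * (V0^T v)_j)^2
    # with mu/sig robust location/scale of the windowed component RMS
    y = evecs.T @ calib
    n_cw = y.shape[1] // win
    if n_cw < 2:
        raise ValueError("calibration shorter than two ASR windows")
    yw = y[:, : n_cw * win].reshape(y.shape[0], n_cw, win)
    comp_rms = np.sqrt((yw ** 2).mean(axis=2))
    mu = np.median(comp_rms, axis=1)
    sig = np.maximum(np.median(np.abs(comp_rms - mu[:, None]), axis=1) * 1.4826,
                     0.05 * mu)  # guard zero-MAD degeneracy
    t_amp = mu + params.burst_sd * sig  # amplitude threshold per component
    # interpolated channels make the data rank-deficient; degenerate
    # directions carry no artifact information and must never flag
    var_floor = 1e-6 * evals.max()

    hop = win // 2
    starts = list(range(0, max(n_samp - win, 0) + 1, hop))
    if not starts:
        raise ValueError("recording shorter than one ASR window")
    if starts[-1] + win < n_samp:
        starts.append(n_samp - win)
    taper = sps.windows.hann(win, sym=False) + 1e-3
    out = np.zeros_like(x)
    weight = np.zeros(n_samp)
    n_flagged = 0
    for s in starts:
        seg = x[:, s:s + win]
        seg0 = seg - seg.mean(axis=1, keepdims=True)
        cw = seg0 @ seg0.T / win
        lam, v = np.linalg.eigh(cw)
        # threshold for each window component from calibration statistics
        proj = evecs.T @ v                      # components x directions
        thresh = ((t_amp[:, None] * proj) ** 2).sum(axis=0)
        flagged = (lam > np.maximum(thresh, var_floor)) & (lam > var_floor)
        if flagged.any():
            n_flagged += 1
            vtm = v.T @ m
            vtm[flagged] = 0.0
            r = m @ np.linalg.pinv(vtm) @ v.T
            seg = r @ seg
        out[:, s:s + win] += seg * taper
        weight[s:s + win] += taper
    out /= np.maximum(weight, 1e-12)

    frac = n_flagged / len(starts)
    rec = recording.copy()
    rec.data = out
    usable = frac <= params.max_repaired_fraction
    if not usable:
        logger.warning("ASR repaired %.1f%% of windows (> %.0f%%): unusable",
                       100 * frac, 100 * params.max_repaired_fraction)
    return ASRResult(rec, frac, usable)


# ---------------------------------------------------------------------------
# re-referencing and epoching
# ---------------------------------------------------------------------------

EAR_ANALYSIS = [f"L{i}" for i in range(1, 5)] + [f"R{i}" for i in range(1, 5)]
SCALP_ANALYSIS = ["Fz", "Cz", "Pz", "C3", "C4"]  # frontopolars excluded


def rereference_ear_grid(recording: ContinuousRecording) -> ContinuousRecording:
    """Vertical bipolar derivation for the ear grid.

    L1-L4 become L_i - mean(L6, L7); R1-R4 become R_i - mean(R6, R7). The
    reference channels are retained unmodified; the re-referenced channels
    are marked as analysis channels.
    """
    if recording.montage != "ear_grid16":
        raise ValueError("re-referencing applies to the ear_grid16 montage")
    labels = recording.labels
    for ref in ("L6", "L7", "R6", "R7"):
        if ref not in labels:
            raise ValueError(f"missing reference channel {ref}")
    out = recording.copy()
    for side in "LR":
        ref = recording.data[[labels.index(f"{side}6"),
                              labels.index(f"{side}7")]].mean(axis=0)
        for i in range(1, 5):
            out.data[labels.index(f"{side}{i}")] -= ref
    out.analysis_labels = list(EAR_ANALYSIS)
    return out


def extract_epochs(recording: ContinuousRecording,
                   onsets_s: np.ndarray,
                   window: tuple = (-0.2, 1.0),
                   baseline: Optional[tuple] = (-0.2, 0.0),
                   labels: Optional[np.ndarray] = None) -> EpochSet:
    """Cut epochs ``[start, end)`` seconds around each onset.

    Onsets whose window exceeds the record bounds are dropped (count is
    reported on the result). Baseline correction subtracts the per-channel
    mean over the baseline window from each epoch.
    """
    fs = recording.rate
    i_start = int(round(window[0] * fs))
    n_samp = int(round((window[1] - window[0]) * fs))
    onsets_s = np.asarray(onsets_s, dtype=float)
    if labels is None:
        labels = np.array(["trial"] * len(onsets_s), dtype=object)
    labels = np.asarray(labels, dtype=object)

    epochs, kept = [], []
    for k, t in enumerate(onsets_s):
        i0 = int(round(t * fs)) + i_start
        if i0 < 0 or i0 + n_samp > recording.n_samples:
            continue
        epochs.append(recording.data[:, i0:i0 + n_samp])
        kept.append(k)
    n_dropped = len(onsets_s) - len(kept)
    if n_dropped:
        logger.info("dropped %d events outside record bounds", n_dropped)
    if not epochs:
        raise ValueError("no events survive epoching")
    data = np.stack(epochs)
    if baseline is not None:
        t = window[0] + np.arange(n_samp) / fs
        mask = (t >= baseline[0] - 1e-9) & (t < baseline[1] - 1e-9)
        data = data - data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(data, fs, tuple(window), labels[kept],
                    list(recording.labels), baseline, n_dropped)


def preprocess_recording(recording: ContinuousRecording,
                         band: str = "erp",
                         asr_params: Optional[ASRParams] = None,
                         target_rate: float = 250.0,
                         reject_epochs: bool = False) -> tuple:
    """Full cleaning chain; returns ``(recording, ASRResult, flagged)``.

    ``band`` selects the [1, 20] Hz ERP or [1, 40] Hz spectral filter. The
    epoch-level rejection heuristic (peak-to-peak / kurtosis) is applied
    later, at epoching time, only when ``reject_epochs`` is set.
    """
    params = asr_params or ASRParams()
    spec = {"erp": ERP_BAND, "spectral": SPECTRAL_BAND}[band]
    logger.info("preprocess: resample %g -> %g Hz", recording.rate, target_rate)
    rec = resample(recording, target_rate)
    logger.info("preprocess: band-pass [%g, %g] Hz", spec.low_hz, spec.high_hz)
    rec = bandpass_filter(rec, spec)
    rec, flagged = repair_bad_channels(rec, params)
    asr = asr_clean(rec, params)
    rec = asr.recording
    if rec.montage == "ear_grid16":
        rec = rereference_ear_grid(rec)
    else:
        rec.analysis_labels = [l for l in SCALP_ANALYSIS if l in rec.labels]
    return rec, asr, flagged


def reject_bad_epochs(epochs: EpochSet, ptp_uv: float = 100.0,
                      kurtosis_z: float = 5.0) -> EpochSet:
    """Statistical epoch rejection: drop epochs whose peak-to-peak amplitude
    exceeds ``ptp_uv`` or whose sample kurtosis is a > ``kurtosis_z`` outlier
    across epochs. Disabled by default in the pipeline."""
    from scipy.stats import kurtosis
    ptp = np.ptp(epochs.data, axis=2).max(axis=1)
    kur = kurtosis(epochs.data, axis=2).max(axis=1)
    med, mad = np.median(kur), np.median(np.abs(kur - np.median(kur))) * 1.4826
    z = (kur - med) / max(mad, 1e-12)
    keep = (ptp <= ptp_uv) & (z <= kurtosis_z)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("epoch rejection dropped %d epochs", dropped)
    out = epochs.select(np.flatnonzero(keep))
    out.n_dropped += dropped
    return out
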