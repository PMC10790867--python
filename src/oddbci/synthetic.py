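"""Synthetic oddball EEG: stimulus schedules, behavior, and continuous recordings.

Generates auditory-oddball sessions with the statistical structure the
downstream analyses assume: a 75/25 standard/odd stimulus stream with
jittered ISI, hit/miss/late behavioral outcomes, and multichannel EEG built
from spatially mixed 1/f background, band-limited rhythms with
condition-dependent power modulation, condition-dependent N1/P300 templates,
and blink/muscle/flatline artifacts.

Two montage families are supported: a 16-channel around-the-ear grid
(labels L1-L8, R1-R8; analysis derivations are vertical bipolars against
the mean of the 6th and 7th electrode of each grid) and an 8-channel scalp
set (Fpz, Fp1, Fp2, Fz, Cz, Pz, C3, C4).

All randomness flows through a single ``numpy.random.Generator``; fixing the
seed fixes schedule, behavior and signal bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

MONTAGES = {
    "ear_grid16": [f"L{i}" for i in range(1, 9)] + [f"R{i}" for i in range(1, 9)],
    "scalp8": ["Fpz", "Fp1", "Fp2", "Fz", "Cz", "Pz", "C3", "C4"],
}

#: frequency bands (Hz) whose power is modulated per condition
BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (7.0, 8.0),
    "beta": (25.0, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass
class ERPTemplate:
    """Evoked-response template for one channel and condition.

    The N1 is a negative Gaussian bump (SD 20 ms) at ``n1_latency_ms``;
    the P300 is a raised-cosine bump spanning 300-500 ms post-stimulus whose
    *mean* over that window equals ``p300_mean_uv``.
    """

    n1_amp_uv: float = 0.0
    n1_latency_ms: float = 100.0
    p300_mean_uv: float = 0.0


def _scalp_templates() -> dict:
    # Cz / Pz carry the reference hit/miss values; neighbours scaled down.
    def spread(cz, pz, others=0.7, frontal=0.3):
        out = {"Cz": cz, "Pz": pz}
        for lab in ("Fz", "C3", "C4"):
            out[lab] = ERPTemplate(cz.n1_amp_uv * others, cz.n1_latency_ms,
                                   cz.p300_mean_uv * others)
        for lab in ("Fpz", "Fp1", "Fp2"):
            out[lab] = ERPTemplate(cz.n1_amp_uv * frontal, cz.n1_latency_ms,
                                   cz.p300_mean_uv * frontal)
        return out

    return {
        "hit": spread(ERPTemplate(-2.00, 106.0, 1.12), ERPTemplate(-1.69, 104.0, 1.47)),
        "miss": spread(ERPTemplate(-2.93, 109.0, -1.78), ERPTemplate(-2.72, 113.0, -1.06)),
        "standard": spread(ERPTemplate(-1.60, 106.0, 0.0), ERPTemplate(-1.35, 104.0, 0.0)),
    }


def _ear_templates() -> dict:
    # Upper-row electrodes L1-L4 / R1-R4 carry the template; the lower rows
    # (including the L6/L7, R6/R7 reference pairs) carry none, so the
    # vertical bipolar derivation recovers the template unchanged.
    def spread(left, right):
        out = {}
        for i in range(1, 5):
            out[f"L{i}"] = left
            out[f"R{i}"] = right
        return out

    return {
        "hit": spread(ERPTemplate(-1.51, 171.0, 1.14), ERPTemplate(-1.04, 174.0, 1.57)),
        "miss": spread(ERPTemplate(-0.71, 196.0, -0.26), ERPTemplate(-1.95, 191.5, 0.36)),
        "standard": spread(ERPTemplate(-1.20, 171.0, 0.0), ERPTemplate(-0.85, 174.0, 0.0)),
    }


def default_templates(montage: str) -> dict:
    """Per-condition, per-channel ERP templates for a montage."""
    if montage == "scalp8":
        return _scalp_templates()
    if montage == "ear_grid16":
        return _ear_templates()
    raise ValueError(f"unknown montage id: {montage!r}")


#: per-condition band-power gain (dB) applied over the trial's state window.
#: Misses carry the higher beta/gamma power, an alpha increase (attentional
#: disengagement), and reduced theta; hits show the opposite theta/alpha
#: pattern. Gains are attentional-state differences, so they span the whole
#: trial (including the pre-stimulus second), not just the response window.
DEFAULT_BAND_GAINS_DB = {
    "hit": {"theta": 1.5, "alpha": -1.0, "beta": 0.0, "gamma": 0.0},
    "miss": {"theta": -1.5, "alpha": 2.0, "beta": 1.1, "gamma": 1.5},
    "standard": {"theta": 0.0, "alpha": 0.0, "beta": 0.0, "gamma": 0.0},
}

#: baseline RMS (uV) of each ongoing band-limited rhythm
DEFAULT_BAND_RMS_UV = {"theta": 3.0, "alpha": 6.0, "beta": 2.0, "gamma": 1.5}

#: spatial weighting of the state gains, per condition: the miss-state alpha
#: increase is posterior-focal and its theta suppression frontal-midline,
#: while the hit-state engagement changes are spatially diffuse. The
#: per-channel gain is ``gain_db * weight``, so the two states differ in
#: spatial pattern, not just magnitude. Ear-grid channels see the scalp
#: topography only weakly, so they use uniform weights.
DEFAULT_BAND_TOPOGRAPHY = {
    "scalp8": {
        "hit": {
            "theta": {"Fpz": 0.8, "Fp1": 0.8, "Fp2": 0.8, "Fz": 1.0,
                      "Cz": 1.0, "Pz": 0.9, "C3": 0.9, "C4": 0.9},
            "alpha": {"Fpz": 0.8, "Fp1": 0.8, "Fp2": 0.8, "Fz": 0.8,
                      "Cz": 0.8, "Pz": 0.8, "C3": 0.8, "C4": 0.8},
        },
        "miss": {
            "theta": {"Fpz": 0.5, "Fp1": 0.5, "Fp2": 0.5, "Fz": 1.4,
                      "Cz": 1.1, "Pz": 0.7, "C3": 0.7, "C4": 0.7},
            "alpha": {"Fpz": 0.2, "Fp1": 0.2, "Fp2": 0.2, "Fz": 0.5,
                      "Cz": 1.0, "Pz": 1.6, "C3": 0.8, "C4": 0.8},
        },
    },
    "ear_grid16": {},
}


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults emulate the study conditions.

    Amplitudes in microvolts, times in the stated units. ``seed`` is unused
    when an explicit ``numpy.random.Generator`` is passed to the operations.
    """

    montage: str = "scalp8"
    rate: float = 500.0
    base_isi: float = 1.5
    jitter_max: float = 2.0
    p_odd: float = 0.25
    miss_prob: float = 0.347
    fp_prob: float = 0.010
    late_prob: float = 0.005
    rt_mean_ms: float = 789.0
    rt_sd_ms: float = 100.0
    response_window_ms: float = 2000.0
    background_rms_uv: float = 10.0
    one_over_f_exponent: float = 1.0
    common_mode_gain: float = 4.0
    nonstationarity_db: float = 1.5    # SD of slow background amplitude drift
    nonstationarity_tau_s: float = 10.0
    band_rms_uv: dict = field(default_factory=lambda: dict(DEFAULT_BAND_RMS_UV))
    band_gains_db: dict = field(default_factory=lambda: {
        c: dict(g) for c, g in DEFAULT_BAND_GAINS_DB.items()})
    erp_templates: Optional[dict] = None   # condition -> channel -> ERPTemplate
    band_topography: Optional[dict] = None  # condition -> band -> ch -> weight
    modulation_window_s: tuple = (-1.0, 1.5)   # state window around onset
    blink_rate_per_min: float = 2.0
    blink_amp_uv: float = 100.0
    muscle_rate_per_min: float = 1.0
    muscle_burst_sd: float = 10.0
    flatline_prob: float = 0.0
    flatline_duration_s: float = 6.0
    seed: Optional[int] = None

    def __post_init__(self):
        self.modulation_window_s = tuple(self.modulation_window_s)
        for p in (self.p_odd, self.miss_prob, self.fp_prob, self.late_prob,
                  self.flatline_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.background_rms_uv < 0:
            raise ValueError("background RMS must be >= 0")
        if self.montage not in MONTAGES:
            raise ValueError(f"unknown montage id: {self.montage!r}")
        if self.erp_templates is None:
            self.erp_templates = default_templates(self.montage)
        if self.band_topography is None:
            self.band_topography = {
                cond: {b: dict(w) for b, w in per.items()}
                for cond, per in DEFAULT_BAND_TOPOGRAPHY[self.montage].items()}

    @property
    def channel_labels(self) -> list:
        return list(MONTAGES[self.montage])

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class StimulusSchedule:
    """Onsets (s) and classes ('standard'/'odd') of an oddball stream."""

    onsets: np.ndarray
    classes: np.ndarray
    base_isi: float = 1.5
    jitter_max: float = 2.0
    p_odd: float = 0.25

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if len(self.onsets) != len(self.classes):
            raise ValueError("onsets and classes length mismatch")
        d = np.diff(self.onsets)
        if len(d) and (np.any(d < self.base_isi - 1e-9)
                       or np.any(d > self.base_isi + self.jitter_max + 1e-9)):
            raise ValueError("inter-stimulus gaps outside [isi, isi+jitter]")

    def __len__(self):
        return len(self.onsets)


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording in microvolts.

    ``events`` is a DataFrame with columns ``onset_s`` and ``marker``
    ('standard' / 'odd' / 'response'). ``artifacts`` carries ground-truth
    artifact intervals as (start_s, end_s, kind, channel_indices) tuples when
    the recording came from the generator.
    """

    rate: float
    labels: list
    data: np.ndarray
    events: pd.DataFrame
    montage: str
    artifacts: list = field(default_factory=list)
    analysis_labels: Optional[list] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be channels x samples matching labels")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN")
        dur = self.n_samples / self.rate
        if len(self.events) and (self.events["onset_s"].min() < 0
                                 or self.events["onset_s"].max() > dur):
            raise ValueError("events outside record duration")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(self.rate, list(self.labels), self.data.copy(),
                                   self.events.copy(), self.montage,
                                   list(self.artifacts),
                                   None if self.analysis_labels is None
                                   else list(self.analysis_labels))


# ---------------------------------------------------------------------------
# stimulus schedule and behavior
# ---------------------------------------------------------------------------

def generate_stimulus_schedule(n_stimuli: int, config: SimulationConfig,
                               rng: Optional[np.random.Generator] = None
                               ) -> StimulusSchedule:
    """Draw an oddball stimulus stream.

    Gaps are ``base_isi + U(0, jitter_max)`` seconds; classes are independent
    Bernoulli(``p_odd``) draws.
    """
    if n_stimuli < 0:
        raise ValueError("n_stimuli must be >= 0")
    rng = config.rng() if rng is None else rng
    gaps = config.base_isi + rng.uniform(0.0, config.jitter_max, size=n_stimuli)
    onsets = np.cumsum(gaps)
    classes = np.where(rng.random(n_stimuli) < config.p_odd, "odd", "standard")
    return StimulusSchedule(onsets, classes.astype(object),
                            config.base_isi, config.jitter_max, config.p_odd)


def simulate_behavior(schedule: StimulusSchedule, config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate button-press behavior for a schedule.

    Returns a trial table (one row per stimulus) with columns ``onset_s``,
    ``stimulus``, ``outcome`` ('hit'/'miss'/'late' for odds, 'fp'/'none' for
    standards) and ``rt_ms`` (NaN when no response). Hits draw their RT from
    a normal(rt_mean, rt_sd) truncated to (0, response_window]; late
    responses fall beyond the window.
    """
    rng = config.rng() if rng is None else rng
    n = len(schedule)
    outcome = np.empty(n, dtype=object)
    rt = np.full(n, np.nan)
    w = config.response_window_ms
    for i in range(n):
        if schedule.classes[i] == "odd":
            u = rng.random()
            if u < config.late_prob:
                outcome[i] = "late"
                rt[i] = w + rng.exponential(200.0)
            elif u < config.late_prob + config.miss_prob:
                outcome[i] = "miss"
            else:
                outcome[i] = "hit"
                while True:  # truncated normal on (0, w]
                    r = rng.normal(config.rt_mean_ms, config.rt_sd_ms)
                    if 0.0 < r <= w:
                        rt[i] = r
                        break
        else:
            if rng.random() < config.fp_prob:
                outcome[i] = "fp"
                rt[i] = rng.uniform(0.0, w)
            else:
                outcome[i] = "none"
    return pd.DataFrame({"onset_s": schedule.onsets,
                         "stimulus": schedule.classes,
                         "outcome": outcome, "rt_ms": rt})


def condition_of(trials: pd.DataFrame) -> np.ndarray:
    """Per-stimulus condition label: 'hit' / 'miss' / 'standard' (late odd
    trials are labelled 'late' and are excluded from condition contrasts)."""
    cond = np.where(trials["stimulus"].to_numpy() == "standard", "standard",
                    trials["outcome"].to_numpy())
    return cond.astype(object)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def one_over_f_noise(n_samples: int, rate: float, exponent: float,
                     rng: np.random.Generator, n_sources: int = 1) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise, one row per source."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_sources, len(freqs)))
            + 1j * rng.standard_normal((n_sources, len(freqs)))) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _band_noise(n_samples: int, rate: float, band: tuple,
                rng: np.random.Generator, n_sources: int) -> np.ndarray:
    """Unit-RMS noise band-limited to ``band`` (FFT brick-wall)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = (rng.standard_normal((n_sources, len(freqs)))
            + 1j * rng.standard_normal((n_sources, len(freqs)))) * mask
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _slow_drift(n_samples: int, rate: float, sd_db: float, tau_s: float,
                rng: np.random.Generator) -> np.ndarray:
    """Lognormal amplitude envelope: Gaussian log-gain smoothed over tau."""
    n_slow = max(int(np.ceil(n_samples / (rate * tau_s))) + 2, 4)
    g = rng.standard_normal(n_slow)
    t_slow = np.arange(n_slow) * tau_s
    t = np.arange(n_samples) / rate
    log_gain = np.interp(t, t_slow, g) * sd_db
    return 10.0 ** (log_gain / 20.0)


def _random_orthonormal(n: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def _erp_waveform(template: ERPTemplate, rate: float, duration_s: float = 0.6
                  ) -> np.ndarray:
    """Sampled template starting at stimulus onset."""
    t = np.arange(int(round(duration_s * rate))) / rate
    lat = template.n1_latency_ms / 1000.0
    wave = template.n1_amp_uv * np.exp(-0.5 * ((t - lat) / 0.020) ** 2)
    in_p3 = (t >= 0.300) & (t <= 0.500)
    # raised cosine with mean p300_mean over [300, 500] ms
    wave[in_p3] += (2.0 * template.p300_mean_uv
                    * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[in_p3] - 0.300) / 0.200)))
    return wave


def synthesize_recording(schedule: StimulusSchedule, trials: pd.DataFrame,
                         config: SimulationConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> ContinuousRecording:
    """Render the continuous EEG for a schedule + trial table.

    Signal model per channel: spatially mixed 1/f background, four ongoing
    band-limited rhythms whose amplitude is scaled by the per-condition gain
    during the post-stimulus second of every trial, the condition's ERP
    template, and (if the configured rates are positive) injected artifacts.
    Stimulus and response events are embedded in the event stream.
    """
    rng = config.rng() if rng is None else rng
    if config.rate < 250:
        raise ValueError("sampling rate must be >= 250 Hz")
    labels = config.channel_labels
    n_ch = len(labels)
    duration = (schedule.onsets[-1] + 3.0) if len(schedule) else 10.0
    n_samp = int(round(duration * config.rate))

    mix = _random_orthonormal(n_ch, rng)
    data = np.zeros((n_ch, n_samp))
    if config.background_rms_uv > 0:
        src = one_over_f_noise(n_samp, config.rate, config.one_over_f_exponent,
                               rng, n_ch)
        bg = config.background_rms_uv * (mix @ src)
        if config.common_mode_gain > 0:
            # shared reference-derived component: makes neighbouring channels
            # realistically correlated; cancels under bipolar re-referencing
            common = one_over_f_noise(n_samp, config.rate,
                                      config.one_over_f_exponent, rng, 1)[0]
            bg += config.common_mode_gain * config.background_rms_uv * common
        if config.nonstationarity_db > 0:
            # slow lognormal amplitude drift: EEG background power is not
            # stationary over the tens-of-seconds scale
            bg *= _slow_drift(n_samp, config.rate, config.nonstationarity_db,
                              config.nonstationarity_tau_s, rng)
        data += bg

    cond = condition_of(trials)
    # ongoing rhythms with per-trial gain envelopes
    for band, (lo, hi) in BANDS.items():
        rms = config.band_rms_uv.get(band, 0.0)
        if rms <= 0:
            continue
        comp = rms * (_random_orthonormal(n_ch, rng)
                      @ _band_noise(n_samp, config.rate, (lo, hi), rng, n_ch))
        env_db = np.zeros((n_ch, n_samp))  # per-channel state gain in dB
        ramp = int(round(0.05 * config.rate))
        for onset, c in zip(schedule.onsets, cond):
            gain_db = config.band_gains_db.get(str(c), {}).get(band, 0.0)
            if gain_db == 0.0:
                continue
            topo = config.band_topography.get(str(c), {}).get(band, {})
            w = np.array([topo.get(lab, 1.0) for lab in labels])
            i0 = max(int(round((onset + config.modulation_window_s[0])
                               * config.rate)), 0)
            i1 = min(int(round((onset + config.modulation_window_s[1])
                               * config.rate)), n_samp)
            if i0 >= n_samp or i1 <= i0:
                continue
            g = gain_db * w[:, None]
            env_db[:, i0:i1] = g
            # linear dB ramps to avoid spectral splatter at the edges
            up = np.linspace(0.0, 1.0, ramp)[None, :] * g
            if i0 >= ramp:
                env_db[:, i0 - ramp:i0] = up
            if i1 + ramp <= n_samp:
                env_db[:, i1:i1 + ramp] = up[:, ::-1]
        data += comp * 10.0 ** (env_db / 20.0)

    # event-locked templates
    templates = config.erp_templates
    for onset, c in zip(schedule.onsets, cond):
        per_chan = templates.get(str(c))
        if per_chan is None:
            continue
        i0 = int(round(onset * config.rate))
        for ci, lab in enumerate(labels):
            tpl = per_chan.get(lab)
            if tpl is None:
                continue
            wave = _erp_waveform(tpl, config.rate)
            i1 = min(i0 + len(wave), n_samp)
            data[ci, i0:i1] += wave[: i1 - i0]

    ev = [{"onset_s": o, "marker": str(c)}
          for o, c in zip(schedule.onsets, schedule.classes)]
    resp = trials[np.isfinite(trials["rt_ms"].to_numpy())]
    for _, row in resp.iterrows():
        t = row["onset_s"] + row["rt_ms"] / 1000.0
        if t <= duration:
            ev.append({"onset_s": t, "marker": "response"})
    events = pd.DataFrame(ev, columns=["onset_s", "marker"])
    events = events.sort_values("onset_s", kind="stable").reset_index(drop=True)

    rec = ContinuousRecording(config.rate, labels, data, events, config.montage)
    if (config.blink_rate_per_min > 0 or config.muscle_rate_per_min > 0
            or config.flatline_prob > 0):
        rec, _ = inject_artifacts(rec, config, rng)
    return rec


# blink spatial weights, front-loaded on the scalp montage
_BLINK_WEIGHTS = {
    "scalp8": {"Fpz": 1.0, "Fp1": 1.0, "Fp2": 1.0, "Fz": 0.5, "Cz": 0.25,
               "Pz": 0.1, "C3": 0.15, "C4": 0.15},
    "ear_grid16": {lab: (0.3 if lab[1] in "1234" else 0.2)
                   for lab in MONTAGES["ear_grid16"]},
}


def inject_artifacts(recording: ContinuousRecording, config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None
                     ) -> tuple:
    """Add blink transients, muscle bursts and optional flatlines.

    Returns ``(recording, intervals)`` where each interval is
    ``(start_s, end_s, kind, channel_indices)`` ground truth. With all rates
    zero the signal is returned unchanged (same values, new object).
    """
    for rate_ in (config.blink_rate_per_min, config.muscle_rate_per_min):
        if rate_ < 0:
            raise ValueError("artifact rates must be >= 0")
    rng = config.rng() if rng is None else rng
    rec = recording.copy()
    fs = rec.rate
    n = rec.n_samples
    dur_min = rec.duration / 60.0
    intervals = []

    n_blinks = rng.poisson(config.blink_rate_per_min * dur_min)
    weights = _BLINK_WEIGHTS[rec.montage]
    w = np.array([weights.get(lab, 0.1) for lab in rec.labels])
    blen = int(round(0.3 * fs))
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(blen) / blen))
    for t0 in np.sort(rng.uniform(0, rec.duration - 0.5, n_blinks)):
        i0 = int(round(t0 * fs))
        seg = slice(i0, min(i0 + blen, n))
        rec.data[:, seg] += config.blink_amp_uv * np.outer(w, bump[: seg.stop - i0])
        intervals.append((t0, t0 + blen / fs, "blink", tuple(range(rec.n_channels))))

    n_bursts = rng.poisson(config.muscle_rate_per_min * dur_min)
    # "k x SD" bursts are relative to the recording's actual channel scale
    base_sd = float(np.median(rec.data.std(axis=1))) or 1.0
    sos = sps.butter(4, 20.0, btype="highpass", fs=fs, output="sos")
    for t0 in np.sort(rng.uniform(0, rec.duration - 2.0, n_bursts)):
        blen_s = rng.uniform(0.5, 1.5)
        i0, i1 = int(round(t0 * fs)), int(round((t0 + blen_s) * fs))
        i1 = min(i1, n)
        chans = rng.choice(rec.n_channels, size=rng.integers(1, 5), replace=False)
        noise = sps.sosfilt(sos, rng.standard_normal((len(chans), i1 - i0)), axis=1)
        noise *= (config.muscle_burst_sd * base_sd
                  / np.maximum(noise.std(axis=1, keepdims=True), 1e-12))
        taper = sps.windows.tukey(i1 - i0, 0.25)
        rec.data[chans, i0:i1] += noise * taper
        intervals.append((t0, i1 / fs, "muscle", tuple(int(c) for c in chans)))

    if rng.random() < config.flatline_prob and rec.duration > config.flatline_duration_s + 1:
        ch = int(rng.integers(rec.n_channels))
        t0 = rng.uniform(0, rec.duration - config.flatline_duration_s - 0.5)
        i0 = int(round(t0 * fs))
        i1 = i0 + int(round(config.flatline_duration_s * fs))
        rec.data[ch, i0:i1] = 0.0
        intervals.append((t0, i1 / fs, "flatline", (ch,)))

    rec.artifacts = list(recording.artifacts) + intervals
    return rec, intervals


def simulate_session(config: SimulationConfig, n_stimuli: int = 565,
                     rng: Optional[np.random.Generator] = None):
    """Convenience wrapper: schedule -> behavior -> recording.

    Returns ``(recording, trials)`` for one synthetic participant.
    """
    rng = config.rng() if rng is None else rng
    schedule = generate_stimulus_schedule(n_stimuli, config, rng)
    trials = simulate_behavior(schedule, config, rng)
    rec = synthesize_recording(schedule, trials, config, rng)
    return rec, trials
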