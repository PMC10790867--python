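"""Readers and writers: EDF recordings, TSV event/trial tables, JSON configs.

Recordings are stored as plain EDF (16-bit, physical units microvolts) with
the event stream in a tab-separated sidecar (columns ``onset_s``,
``marker`` and, for trial tables, ``outcome`` and ``rt_ms``). The EDF
writer/reader here is deliberately minimal: one-second data records,
per-channel physical scaling, and the true sample count stashed in the
reserved header field so round-trips preserve length exactly.
"""

from __future__ import annotations

import dataclasses
import json
import struct
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic import (ContinuousRecording, ERPTemplate, MONTAGES,
                        SimulationConfig)

_HDR = 256
_SIG_HDR = 256


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:n]
    return b + b" " * (n - len(b))


def write_recording(recording: ContinuousRecording, path) -> Path:
    """Write a recording to EDF; events go to ``<stem>.events.tsv``."""
    path = Path(path)
    fs = recording.rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_ch, n_samp = recording.data.shape
    n_rec = int(np.ceil(n_samp / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, :n_samp] = recording.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad(f"Startdate X X X X montage={recording.montage}", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(_HDR + _SIG_HDR * n_ch), 8))
        f.write(_pad(f"NSAMP={n_samp}", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(n_ch), 4))
        for lab in recording.labels:
            f.write(_pad(lab, 16))
        for _ in recording.labels:
            f.write(_pad("", 80))
        for _ in recording.labels:
            f.write(_pad("uV", 8))
        for v in pmin:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for v in pmax:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        f.write(_pad(str(dmin), 8) * n_ch)
        f.write(_pad(str(dmax), 8) * n_ch)
        for _ in recording.labels:
            f.write(_pad("", 80))
        f.write(_pad(str(spr), 8) * n_ch)
        f.write(_pad("", 32) * n_ch)
        for r in range(n_rec):
            f.write(digital[:, r * spr:(r + 1) * spr].tobytes())

    write_events(recording.events, events_path(path))
    return path


def events_path(edf_path) -> Path:
    p = Path(edf_path)
    return p.with_name(p.stem + ".events.tsv")


def read_recording(path, events: Optional[pd.DataFrame] = None
                   ) -> ContinuousRecording:
    """Read an EDF recording (events from the sidecar file if present)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HDR:
        raise ValueError(f"truncated EDF header: file ends at byte {len(raw)}")

    def fld(off, n):
        return raw[off:off + n].decode("ascii", errors="replace").strip()

    try:
        hdr_bytes = int(fld(184, 8))
        n_rec = int(fld(236, 8))
        rec_dur = float(fld(244, 8))
        n_ch = int(fld(252, 4))
    except ValueError as e:
        raise ValueError(f"malformed EDF header: {e}") from None
    if len(raw) < hdr_bytes:
        raise ValueError(f"truncated EDF header: file ends at byte {len(raw)}")
    reserved = fld(192, 44)
    n_true = int(reserved.split("=", 1)[1]) if reserved.startswith("NSAMP=") else None

    off = _HDR
    labels = [fld(off + 16 * i, 16) for i in range(n_ch)]
    off += n_ch * (16 + 80)
    units = [fld(off + 8 * i, 8) for i in range(n_ch)]
    off += n_ch * 8
    pmin = np.array([float(fld(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    pmax = np.array([float(fld(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    dmin = np.array([float(fld(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    dmax = np.array([float(fld(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * (8 + 80)
    spr = [int(fld(off + 8 * i, 8)) for i in range(n_ch)]
    if any(u not in ("uV", "µV", "") for u in units):
        raise ValueError(f"unexpected physical units {set(units)}; expected uV")
    if len(set(spr)) != 1:
        raise ValueError("heterogeneous per-signal rates are not supported")
    spr = spr[0]
    fs = spr / rec_dur

    expected = hdr_bytes + n_rec * n_ch * spr * 2
    if len(raw) < expected:
        raise ValueError(
            f"truncated EDF data: expected {expected} bytes, file ends at "
            f"byte {len(raw)}")
    flat = np.frombuffer(raw[hdr_bytes:expected], dtype="<i2")
    data = (flat.reshape(n_rec, n_ch, spr).transpose(1, 0, 2)
            .reshape(n_ch, n_rec * spr).astype(float))
    scale = (pmax - pmin) / (dmax - dmin)
    data = (data - dmin[:, None]) * scale[:, None] + pmin[:, None]
    if n_true is not None:
        data = data[:, :n_true]

    if events is None:
        ep = events_path(path)
        events = read_events(ep) if ep.exists() else pd.DataFrame(
            columns=["onset_s", "marker"])
    montage = next((m for m, labs in MONTAGES.items() if labels == labs),
                   "custom")
    hdr_montage = [t for t in fld(88, 80).split() if t.startswith("montage=")]
    if hdr_montage:
        montage = hdr_montage[0].split("=", 1)[1]
    return ContinuousRecording(fs, labels, data, events, montage)


# ---------------------------------------------------------------------------
# event / trial tables
# ---------------------------------------------------------------------------

def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = [c for c in ("onset_s", "marker", "stimulus", "outcome", "rt_ms")
            if c in events.columns]
    events.to_csv(path, sep="\t", index=False, columns=cols,
                  float_format="%.6f")
    return path


def read_events(path) -> pd.DataFrame:
    """Read a TSV event stream or trial table; onsets are seconds."""
    df = pd.read_csv(path, sep="\t")
    if "onset_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'onset_s'")
    if not ("marker" in df.columns or "stimulus" in df.columns):
        raise ValueError(f"{path}: missing required column 'marker'")
    if len(df) and not df["onset_s"].is_monotonic_increasing:
        warnings.warn(f"{path}: onsets out of order; sorting")
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    tpl = d.get("erp_templates")
    if tpl is not None:
        d["erp_templates"] = {
            cond: {ch: (ERPTemplate(**v) if isinstance(v, dict) else v)
                   for ch, v in per.items()}
            for cond, per in tpl.items()}
    return SimulationConfig(**d)


def save_config(cfg, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config_to_dict(cfg), indent=2, sort_keys=True))
    return path


def load_simulation_config(path) -> SimulationConfig:
    return simulation_config_from_dict(json.loads(Path(path).read_text()))
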