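"""End-to-end orchestration: simulate -> preprocess -> features -> stats -> classify.

The pipeline emulates a cohort of synthetic participants performing the
auditory oddball task, runs each recording through the cleaning chain, and
produces a machine-readable report: behavioral summary (miss/FP rates, d',
RT), N1/P300 measurement tables, band-power contrasts, group-level
permutation statistics, and per-subject cross-validated classification
accuracies for the MDM and tangent-space classifiers.

One global seed fixes every stage; per-subject generators are spawned from
it, so the report is bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import features as feat
from . import preprocess as prep
from . import riemann, stats
from .synthetic import (BANDS, SimulationConfig, condition_of,
                        simulate_session)

logger = logging.getLogger("oddbci")


@dataclass
class PipelineConfig:
    """Global configuration; defaults mirror the study conditions."""

    montage: str = "scalp8"
    n_subjects: int = 9
    n_stimuli: int = 565
    simulation: Optional[SimulationConfig] = None
    asr: prep.ASRParams = field(default_factory=prep.ASRParams)
    erp_window: tuple = (-0.2, 1.0)
    erp_baseline: tuple = (-0.2, 0.0)
    spectral_window: tuple = (-1.0, 1.5)
    n_perm: int = 2000
    alpha: float = 0.05
    folds: int = 5
    classifiers: tuple = ("mdm", "tsc")
    balance: str = "tomek"
    prototype_augment: bool = True
    include_ersp: bool = False
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        self.erp_window = tuple(self.erp_window)
        self.erp_baseline = tuple(self.erp_baseline)
        self.spectral_window = tuple(self.spectral_window)
        self.classifiers = tuple(self.classifiers)
        if self.simulation is None:
            self.simulation = SimulationConfig(montage=self.montage)
        elif self.simulation.montage != self.montage:
            raise ValueError("simulation montage disagrees with pipeline montage")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def analyze_subject(recording, trials, config: PipelineConfig,
                    rng: np.random.Generator) -> dict:
    """Run one subject through cleaning, ERP/spectral features and CV."""
    out = {"behavior": dataclasses.asdict(stats.summarize_behavior(trials))}
    cond = condition_of(trials)
    stim = trials["onset_s"].to_numpy()
    pools = feat.DEFAULT_POOLS[config.montage]

    # --- ERP band: ERPs + classification -----------------------------------
    rec, asr, flagged = prep.preprocess_recording(
        recording, band="erp", asr_params=config.asr)
    out["asr"] = {"repaired_fraction": asr.repaired_fraction,
                  "usable": asr.usable, "repaired_channels": flagged}
    if not asr.usable:
        out["excluded"] = True
        return out
    keep = np.isin(cond, ["hit", "miss"])
    epochs = prep.extract_epochs(rec, stim[keep], config.erp_window,
                                 config.erp_baseline, cond[keep])
    erps = feat.average_erp(epochs, pools, montage=config.montage)
    out["erp"] = {c: {"n_trials": r.n_trials,
                      "n1": {p: {"amp_uv": v[0], "lat_ms": v[1]}
                             for p, v in r.n1.items()},
                      "p300_uv": dict(r.p300)}
                  for c, r in erps.items()}
    out["erp_pooled_waveforms"] = {
        c: {p: w for p, w in r.pooled.items()} for c, r in erps.items()}
    out["erp_times"] = epochs.times

    chans = rec.analysis_labels
    out["cv"] = {}
    cv_seed = int(rng.integers(2 ** 31))  # same folds for every classifier
    for clf in config.classifiers:
        cv = riemann.crossvalidate_epochs(
            epochs.pick_channels(chans), classifier=clf, folds=config.folds,
            seed=cv_seed, balance=config.balance,
            prototype_augment=config.prototype_augment)
        out["cv"][clf] = {
            "classes": cv.classes,
            "fold_balanced": cv.fold_balanced,
            "fold_class_recall": cv.fold_class_recall,
            "balanced_accuracy": cv.balanced_accuracy,
            "balanced_sem": cv.balanced_sem}

    # --- spectral band: PSD band powers (balanced trial counts) ------------
    rec_s, asr_s, _ = prep.preprocess_recording(
        recording, band="spectral", asr_params=config.asr)
    eps_s = prep.extract_epochs(rec_s, stim[keep], config.spectral_window,
                                baseline=None, labels=cond[keep])
    eps_s = stats.balance_trial_counts(eps_s, rng)
    psds = feat.welch_psd(eps_s)
    bp = {}
    psd_pooled = {}
    for c, p in psds.items():
        rows = {name: [p.ch_names.index(ch) for ch in chs]
                for name, chs in pools.items()}
        bp[c] = {band: {name: float(feat.band_power(p, BANDS[band])[r].mean())
                        for name, r in rows.items()}
                 for band in BANDS}
        psd_pooled[c] = {name: p.db()[r].mean(axis=0) for name, r in rows.items()}
    out["band_power"] = bp
    out["psd_freqs"] = psds[next(iter(psds))].freqs
    out["psd_pooled_db"] = psd_pooled

    if config.include_ersp:
        pool_chans = sorted({ch for chs in pools.values() for ch in chs})
        ersps = feat.ersp(eps_s.pick_channels(pool_chans))
        out["ersp"] = {c: {"freqs": r.freqs, "times": r.times, "db": r.db,
                           "ch_names": r.ch_names}
                       for c, r in ersps.items()}
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate the cohort, analyze every subject, add group statistics."""
    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.spawn(config.n_subjects + 1)
    group_rng = np.random.default_rng(subject_seeds[-1])

    subjects = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        logger.info("pipeline: subject %d/%d", i + 1, config.n_subjects)
        rec, trials = simulate_session(config.simulation, config.n_stimuli, rng)
        res = analyze_subject(rec, trials, config, rng)
        res["subject"] = i
        subjects.append(res)

    usable = [s for s in subjects if not s.get("excluded")]
    report = {"config": _jsonify_config(config), "subjects": subjects,
              "n_excluded": len(subjects) - len(usable)}

    beh = np.array([[s["behavior"]["miss_rate"], s["behavior"]["fp_rate"],
                     s["behavior"]["d_prime"], s["behavior"]["mean_rt_ms"]]
                    for s in subjects])
    report["group"] = {"behavior": {
        "miss_rate": _mean_sem(beh[:, 0]), "fp_rate": _mean_sem(beh[:, 1]),
        "d_prime": _mean_sem(beh[:, 2]), "mean_rt_ms": _mean_sem(beh[:, 3])}}

    if len(usable) >= 2:
        # group ERP contrast on the first pooled derivation
        pools = feat.DEFAULT_POOLS[config.montage]
        pool0 = next(iter(pools))
        a = np.stack([np.asarray(s["erp_pooled_waveforms"]["hit"][pool0])
                      for s in usable])
        b = np.stack([np.asarray(s["erp_pooled_waveforms"]["miss"][pool0])
                      for s in usable])
        sm = stats.pointwise_permutation_test(
            a, b, n_perm=config.n_perm, rng=group_rng, alpha=config.alpha)
        report["group"]["erp_stat"] = {
            "pool": pool0, "n_perm": sm.n_perm, "alpha": sm.alpha,
            "n_significant": int(sm.mask.sum()), "min_p": float(sm.p.min()),
            "p": sm.p, "mask": sm.mask.astype(int)}

        cvsum = {}
        for clf in config.classifiers:
            acc = np.array([s["cv"][clf]["balanced_accuracy"] for s in usable])
            cvsum[clf] = _mean_sem(acc)
        report["group"]["cv"] = cvsum
        if set(("mdm", "tsc")) <= set(config.classifiers):
            t, df, p = stats.paired_t_test(
                [s["cv"]["tsc"]["balanced_accuracy"] for s in usable],
                [s["cv"]["mdm"]["balanced_accuracy"] for s in usable])
            report["group"]["tsc_vs_mdm"] = {"t": t, "df": df, "p": p}

    report = _jsonify(report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_report(report, out / "report.json")
    return report


def _mean_sem(x) -> dict:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    sem = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return {"mean": float(x.mean()), "sem": sem, "n": int(len(x))}


def _jsonify_config(config: PipelineConfig) -> dict:
    return _jsonify(dataclasses.asdict(config))


def save_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return path
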