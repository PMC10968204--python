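"""End-to-end orchestration: simulate → ingest → decompose → features →
label → stats → models, plus the two-device validation path.

``run_pipeline`` executes the full chain for a multi-subject synthetic
study (or user-supplied logs), writing the feature table, the class-summary
and correlation tables, the model-comparison grid and per-target Shapley
attribution CSVs into a report directory together with a JSON run log
(config, config hash, seeds, stage order, versions).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import microeda
from microeda.decompose import CvxEdaParams, cvxeda_decompose
from microeda.features import EDA_FEATURES, build_feature_table, FeatureTable
from microeda.ingest import (
    ENV_COLUMNS,
    EDASignal,
    RawRecording,
    butter_lowpass,
    moving_average,
    normalize,
    raw_to_eda,
    resample,
)
from microeda.labeling import label_reports
from microeda.models import model_grid, forward_models, reverse_models
from microeda.simulate import EffectModel, SessionDesign, generate_session
from microeda.spectral import SpectralConfig
from microeda.stats import correlation_matrix, feature_class_summary, spearman

SUBJECTIVE = ["difficulty", "stress", "dominance", "arousal", "valence"]


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    n_subjects: int = 5
    n_windows: int = 8
    window_s: float = 900.0
    seed: int = 0
    eda_rate: float = 10.0
    decompose_rate: float = 4.0
    analysis_rate: float = 2.0
    lowpass_cutoff: float = 1.5
    lowpass_order: int = 32
    labeling_rule: str = "strict"
    nsscr_min_amplitude: float = 0.01
    cvxeda: dict = field(default_factory=dict)
    effect: dict = field(default_factory=dict)
    run_models: bool = True
    rf_n_estimators: int = 200
    split_repeats: int = 5
    attribution_instances: int = 40
    attribution_background: int = 16

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def process_recording(rec: RawRecording, config: RunConfig):
    """Raw volts → conductance → 4 Hz low-passed signal → decomposition →
    2 Hz tonic/phasic components. Returns (decomposition, tonic2, phasic2)."""
    eda = raw_to_eda(rec)
    eda4 = resample(eda, config.decompose_rate)
    filt = butter_lowpass(eda4, config.lowpass_cutoff, config.lowpass_order)
    decomp = cvxeda_decompose(filt, CvxEdaParams(**config.cvxeda))
    tonic2 = resample(EDASignal(values=decomp.tonic, rate=decomp.rate),
                      config.analysis_rate).values
    phasic2 = resample(EDASignal(values=decomp.phasic, rate=decomp.rate),
                       config.analysis_rate).values
    return decomp, tonic2, phasic2


def run_pipeline(config: RunConfig | None = None, out_dir=None,
                 sessions: list | None = None) -> dict:
    """Run the full analysis and write report artifacts.

    ``sessions`` may carry pre-built :class:`~microeda.simulate.SessionData`
    objects (e.g. from real logs); otherwise ``config.n_subjects`` synthetic
    sessions are generated. Returns a dict of in-memory results and, when
    ``out_dir`` is given, writes CSV/JSON artifacts there.
    """
    config = config or RunConfig()
    t0 = time.time()
    log = {"config": config.to_dict(), "config_hash": config.config_hash(),
           "version": microeda.__version__, "stages": []}

    if sessions is None:
        sessions = []
        for i in range(config.n_subjects):
            subject_seed = config.seed * 1000 + i
            design = SessionDesign(n_windows=config.n_windows,
                                   window_s=config.window_s, seed=subject_seed)
            sessions.append(generate_session(
                design, EffectModel(**config.effect), seed=subject_seed,
                eda_rate=config.eda_rate, subject_id=f"S{i}"))
        log["stages"].append("simulate")

    spectral_cfg = SpectralConfig(analysis_rate=config.analysis_rate)
    per_sample_frames, per_window_frames = [], []
    for sess in sessions:
        rec = sess.recording
        _, tonic2, phasic2 = process_recording(rec, config)
        labels = label_reports(sess.reports, rule=config.labeling_rule)
        label_cols = labels[["window", "label"] + SUBJECTIVE]
        ft = build_feature_table(
            tonic2, phasic2, sess.environment, rate=config.analysis_rate,
            subject=rec.subject_id, window_s=config.window_s,
            nsscr_min_amplitude=config.nsscr_min_amplitude,
            spectral_cfg=spectral_cfg, labels=label_cols)
        per_sample_frames.append(ft.per_sample)
        per_window_frames.append(ft.per_window)
    table = FeatureTable(per_sample=pd.concat(per_sample_frames, ignore_index=True),
                         per_window=pd.concat(per_window_frames, ignore_index=True))
    log["stages"] += ["ingest", "decompose", "features", "label"]

    pw = table.per_window
    results: dict = {"feature_table": table, "log": log}

    # statistics stage: class summary + the three correlation grids
    results["class_summary"] = feature_class_summary(pw)
    results["corr_subjective"] = correlation_matrix(pw, SUBJECTIVE)
    high = pw[pw["label"] == "high"]
    env_cols = [c for c in ENV_COLUMNS if c in pw.columns]
    results["corr_env_eda"] = correlation_matrix(
        high if len(high) >= 4 else pw, env_cols,
        [f for f in EDA_FEATURES if f in pw.columns])
    results["corr_env_subjective"] = correlation_matrix(
        high if len(high) >= 4 else pw, env_cols, SUBJECTIVE)
    log["stages"].append("stats")

    if config.run_models:
        targets = [f for f in EDA_FEATURES if f in pw.columns]
        results["model_grid"] = model_grid(
            pw, targets, env_cols, seed=config.seed,
            n_repeats=config.split_repeats,
            rf_params={"n_estimators": config.rf_n_estimators})
        from microeda.models import ModelSpec
        rf = ModelSpec(family="random_forest",
                       hyperparameters={"n_estimators": config.rf_n_estimators},
                       seed=config.seed)
        results["forward"] = forward_models(
            pw, spec=rf, seed=config.seed, n_repeats=config.split_repeats,
            max_instances=config.attribution_instances)
        results["reverse"] = reverse_models(
            pw, spec=rf, seed=config.seed, n_repeats=config.split_repeats,
            max_instances=config.attribution_instances)
        log["stages"].append("models")

    log["elapsed_s"] = round(time.time() - t0, 2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.per_sample.to_csv(out / "features_2hz.csv", index=False)
        table.per_window.to_csv(out / "features_windows.csv", index=False)
        results["class_summary"].to_csv(out / "class_summary.csv")
        results["corr_subjective"].to_csv(out / "corr_subjective.csv")
        results["corr_env_eda"].to_csv(out / "corr_env_eda.csv")
        results["corr_env_subjective"].to_csv(out / "corr_env_subjective.csv")
        if config.run_models:
            results["model_grid"].to_csv(out / "model_grid.csv")
            for direction in ("forward", "reverse"):
                for tgt, d in results[direction].items():
                    if d["attribution"] is not None:
                        d["attribution"].to_frame().to_csv(
                            out / f"attribution_{direction}_{tgt}.csv",
                            index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2)
    return results


def validate_devices(rec_a: RawRecording, rec_b: RawRecording, *,
                     rate: float = 4.0, components: bool = True,
                     smoothing_s: float = 2.0,
                     params: CvxEdaParams | None = None) -> dict:
    """Two-device congruence: Spearman ρ of the preprocessed traces.

    Both streams are converted to conductance, resampled to 4 Hz, low-pass
    filtered (1.5 Hz, order 32, zero phase), min-max normalized and
    smoothed with a moving average; with ``components=True`` both are also
    decomposed and tonic/phasic correlations reported.
    """
    def prep(rec):
        eda = raw_to_eda(rec)
        eda = resample(eda, rate)
        eda = butter_lowpass(eda)
        eda = normalize(eda)
        return moving_average(eda, smoothing_s)

    a, b = prep(rec_a), prep(rec_b)
    n = min(len(a), len(b))
    out = {"rho_raw": spearman(a.values[:n], b.values[:n])}
    if components:
        da = cvxeda_decompose(a.evolve(a.values[:n], "trim"), params)
        db = cvxeda_decompose(b.evolve(b.values[:n], "trim"), params)
        out["rho_tonic"] = spearman(da.tonic, db.tonic)
        out["rho_phasic"] = spearman(da.phasic, db.phasic)
    return out
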