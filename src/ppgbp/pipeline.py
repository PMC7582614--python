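"""End-to-end orchestration: simulate -> preprocess -> segment -> features ->
select -> train -> predict -> evaluate.

``run_pipeline`` wires the stages together on a synthetic record, writes
every intermediate artifact as CSV into an output directory, and returns the
final agreement report.  All randomness derives from the single seed in the
config (the generator uses it directly; the regressor uses seed + 1), so a
rerun with an identical config reproduces every artifact byte for byte.
A manifest records all defaults in effect and per-stage counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, fiducials, preprocess, regressor, selection
from .io import cycles_table, dump_manifest, write_report, write_waveform
from .synthetic import SynthConfig, generate_record

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    high_cut_hz: float = 8.0
    low_cut_hz: float = 0.0
    criteria: fiducials.AbnormalCycleCriteria = field(
        default_factory=fiducials.AbnormalCycleCriteria
    )
    gamma: selection.GammaConfig = field(default_factory=selection.GammaConfig)
    n_select: int = 32
    force_include: tuple[str, ...] = ()
    force_exclude: tuple[str, ...] = ()
    regressor: regressor.RegressorConfig = field(
        default_factory=regressor.RegressorConfig
    )
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed governs every stochastic stage
        self.synth = dataclasses.replace(self.synth, seed=self.seed)
        self.regressor = dataclasses.replace(self.regressor, seed=self.seed + 1)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, output_dir) -> evaluation.EvalReport:
    """Run the full synthetic pipeline and write all artifacts to disk.

    Artifacts: ``waveform.csv``, ``ground_truth.csv``, ``cycles.csv``,
    ``features.csv``, ``gamma_report.csv``, ``predictions.csv``,
    ``report.csv``/``report.txt`` and ``manifest.yaml``.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    with _stage("simulate"):
        record, truth = generate_record(config.synth)
        write_waveform(record, out / "waveform.csv")
        truth.to_csv(out / "ground_truth.csv", index=False)
        counts["generated_cycles"] = len(truth)

    with _stage("preprocess"):
        pre = preprocess.preprocess_record(
            record, high_cut_hz=config.high_cut_hz, low_cut_hz=config.low_cut_hz
        )

    with _stage("segment"):
        segments, info = fiducials.segment_record(
            pre, criteria=config.criteria, record_id=record.record_id
        )
        cycles_table(segments).to_csv(out / "cycles.csv", index=False)
        counts.update(info)
        if len(segments) < 10:
            raise ValueError(
                f"only {len(segments)} usable cycles; record too short or too noisy"
            )

    with _stage("extract-features"):
        matrix = features.compute_feature_matrix(segments)
        matrix.to_csv(out / "features.csv", index=False, float_format="%.10g")
        labels = matrix[["sbp_mmHg", "dbp_mmHg"]]
        feats = matrix[list(features.FEATURE_NAMES)]
        # features that never produced a finite value cannot be candidates
        candidates = feats.columns[np.isfinite(feats).mean() > 0.5]
        complete = feats[candidates].dropna().index
        counts["dropped_incomplete_cycles"] = len(feats) - len(complete)
        feats = feats.loc[complete, candidates]
        labels = labels.loc[complete]

    with _stage("select-features"):
        std = features.standardize(feats)
        gamma = selection.gamma_report(std.values, config.gamma)
        n_select = min(config.n_select, int(np.isfinite(gamma).sum()))
        report = selection.rank_and_select(
            gamma,
            n_lowest=n_select,
            force_include=config.force_include,
            force_exclude=config.force_exclude,
        )
        report.to_csv(out / "gamma_report.csv", index_label="feature")
        selected = sorted(report.index[report["selected"]])
        counts["selected_features"] = len(selected)

    with _stage("train"):
        reg_cfg = dataclasses.replace(config.regressor, input_dim=len(selected))
        x = std.values[selected].to_numpy()
        y = labels.to_numpy()
        (x_tr, y_tr), (x_te, y_te), (x_va, y_va) = regressor.split_dataset(
            x, y, reg_cfg.split_fractions, seed=reg_cfg.seed
        )
        model = regressor.train(reg_cfg, x_tr, y_tr, x_va, y_va)
        model.history.to_csv(out / "training_history.csv", index=False)

    with _stage("predict"):
        pred = regressor.predict(model, x_te)
        pd.DataFrame(
            {
                "truth_sbp": y_te[:, 0],
                "truth_dbp": y_te[:, 1],
                "est_sbp": pred[:, 0],
                "est_dbp": pred[:, 1],
            }
        ).to_csv(out / "predictions.csv", index=False, float_format="%.10g")

    with _stage("evaluate"):
        report_eval = evaluation.evaluate(
            y_te[:, 0], y_te[:, 1], pred[:, 0], pred[:, 1]
        )
        write_report(report_eval, out / "report.csv", out / "report.txt")

    manifest = {
        "seed": config.seed,
        "synth": dataclasses.asdict(config.synth),
        "high_cut_hz": config.high_cut_hz,
        "low_cut_hz": config.low_cut_hz,
        "criteria": dataclasses.asdict(config.criteria),
        "gamma": dataclasses.asdict(config.gamma),
        "n_select": config.n_select,
        "regressor": dataclasses.asdict(config.regressor),
        "counts": counts,
        "selected_features": selected,
    }
    # YAML-safe scalars only
    manifest["synth"]["bp_map"] = {
        k: list(v) if isinstance(v, tuple) else v
        for k, v in dataclasses.asdict(config.synth)["bp_map"].items()
    }
    dump_manifest(_listify(manifest), out / "manifest.yaml")
    return report_eval


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
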