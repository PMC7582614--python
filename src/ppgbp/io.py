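"""Readers and writers for waveforms, cycle tables, and configuration.

Waveform files are plain delimited text (comma or whitespace), one sample
per row:

* one column: PPG amplitude only (a sampling rate must be supplied);
* two columns: time in seconds, PPG (rate inferred from time deltas);
* three columns: time, PPG, ABP in mmHg.

A first row that does not parse as numbers is treated as a header.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import WaveformRecord

__all__ = [
    "read_waveform",
    "write_waveform",
    "cycles_table",
    "write_report",
    "report_to_frame",
    "load_yaml_config",
    "dump_manifest",
]

_SPLIT = re.compile(r"[,\s;]+")


def read_waveform(
    path, sampling_rate_hz: float | None = None, record_id: str | None = None
) -> WaveformRecord:
    """Parse a delimited-text waveform file into a WaveformRecord.

    The sampling rate is inferred from the time column when present and
    consistent; a ``sampling_rate_hz`` argument overrides inference and is
    required for single-column files.  Malformed rows raise a ValueError
    naming the line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in _SPLIT.split(line) if f]
            try:
                values = [float(f) for f in fields]
            except ValueError:
                if not rows and lineno <= 2:
                    continue  # header row
                raise ValueError(
                    f"{path.name}: non-numeric value on line {lineno}"
                ) from None
            if width is None:
                width = len(values)
                if width not in (1, 2, 3):
                    raise ValueError(
                        f"{path.name}: expected 1-3 columns, got {width} "
                        f"on line {lineno}"
                    )
            elif len(values) != width:
                raise ValueError(
                    f"{path.name}: ragged row on line {lineno} "
                    f"({len(values)} fields, expected {width})"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    data = np.asarray(rows)

    if width == 1:
        if sampling_rate_hz is None:
            raise ValueError(
                f"{path.name}: single-column file needs an explicit sampling rate"
            )
        ppg, abp = data[:, 0], None
        fs = sampling_rate_hz
    else:
        times, ppg = data[:, 0], data[:, 1]
        abp = data[:, 2] if width == 3 else None
        if sampling_rate_hz is not None:
            fs = sampling_rate_hz
        else:
            deltas = np.diff(times)
            if len(deltas) == 0 or np.any(deltas <= 0):
                raise ValueError(f"{path.name}: time column is not increasing")
            fs = 1.0 / float(np.median(deltas))
    return WaveformRecord(
        samples=ppg,
        sampling_rate_hz=fs,
        abp_samples=abp,
        record_id=record_id or path.stem,
    )


def write_waveform(record: WaveformRecord, path) -> None:
    """Write (time_s, ppg[, abp_mmHg]) as CSV with a header row."""
    cols = {"time_s": record.times_s, "ppg": record.samples}
    if record.abp_samples is not None:
        cols["abp_mmHg"] = record.abp_samples
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")


def cycles_table(segments) -> pd.DataFrame:
    """Per-cycle summary: fiducial indices (record coordinates) and labels."""
    rows = []
    for i, seg in enumerate(segments):
        f = seg.fiducials.shifted(seg.start_idx)
        rows.append(
            {
                "record_id": seg.record_id,
                "cycle_index": i,
                "onset_idx": f.onset_idx,
                "max_slope_idx": f.max_slope_idx,
                "systolic_peak_idx": f.systolic_peak_idx,
                "dicrotic_notch_idx": (
                    -1 if f.dicrotic_notch_idx is None else f.dicrotic_notch_idx
                ),
                "min_slope_idx": f.min_slope_idx,
                "offset_idx": f.offset_idx,
                "duration_s": seg.duration_s,
                "sbp_mmHg": seg.sbp_mmHg,
                "dbp_mmHg": seg.dbp_mmHg,
            }
        )
    return pd.DataFrame(rows)


def report_to_frame(report) -> pd.DataFrame:
    """EvalReport -> two-row DataFrame (SBP, DBP) of all metrics."""
    rows = []
    for name in ("sbp", "dbp"):
        d = dataclasses.asdict(getattr(report, name))
        d["target"] = name.upper()
        rows.append(d)
    frame = pd.DataFrame(rows)
    return frame[["target"] + [c for c in frame.columns if c != "target"]]


def write_report(report, csv_path, text_path=None) -> None:
    frame = report_to_frame(report)
    frame.to_csv(csv_path, index=False)
    if text_path is not None:
        lines = [f"paired records: n = {report.n}", ""]
        for _, row in frame.iterrows():
            lines += [
                f"{row['target']}:",
                f"  RMSE {row['rmse_mmHg']:.3f} mmHg, MAE {row['mae_mmHg']:.3f} mmHg",
                f"  mean error {row['mean_error_mmHg']:.3f} mmHg, "
                f"SD {row['sd_error_mmHg']:.3f} mmHg "
                f"-> AAMI {'pass' if row['aami_pass'] else 'FAIL'}",
                f"  |err| <= 5/10/15 mmHg: {row['cum_pct_5']:.2f}% / "
                f"{row['cum_pct_10']:.2f}% / {row['cum_pct_15']:.2f}% "
                f"-> BHS grade {row['bhs_grade']}",
                f"  Pearson r {row['pearson_r']:.4f}, "
                f"LOA ({row['loa_low_mmHg']:.2f}, {row['loa_high_mmHg']:.2f}) mmHg",
                "",
            ]
        Path(text_path).write_text("\n".join(lines))


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def dump_manifest(manifest: dict, path) -> None:
    """Write the run manifest (every default in effect) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False, default_flow_style=False)
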