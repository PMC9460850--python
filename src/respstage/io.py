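"""Plain-text readers and writers for every pipeline artifact.

All formats are delimited text with a mandatory header line; lines starting
with ``#`` are comments (used to stamp the producing config hash).  Stages
are spelled by their enum tokens (AWAKE/N1/N2/N3/REM).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import Centroid, CentroidSet
from .errors import InvalidParameterError
from .evaluate import ClassificationReport, SweepResult
from .processing import FeatureVector
from .scaling import ScalingConfig
from .stages import SleepStage
from .trace import RespirationTrace


def _write_csv(path, frame: pd.DataFrame, header_comments: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def write_trace(path, trace: RespirationTrace,
                header_comments: Iterable[str] = ()) -> None:
    frame = pd.DataFrame({"time_s": trace.times(), "voltage_V": trace.samples})
    _write_csv(path, frame, header_comments)


def read_trace(path) -> RespirationTrace:
    frame = pd.read_csv(path, comment="#")
    for col in ("time_s", "voltage_V"):
        if col not in frame.columns:
            raise InvalidParameterError(f"{path}: missing required column {col!r}")
    t = frame["time_s"].to_numpy(float)
    if len(t) < 2:
        raise InvalidParameterError(f"{path}: need at least 2 samples to infer dt")
    dt = float(np.median(np.diff(t)))
    return RespirationTrace(frame["voltage_V"].to_numpy(float), dt,
                            start_time=float(t[0]))


def write_hypnogram(path, hypnogram: Sequence[tuple[float, float, SleepStage]],
                    header_comments: Iterable[str] = ()) -> None:
    frame = pd.DataFrame(
        [{"start_s": s, "duration_s": d, "stage": st.name} for s, d, st in hypnogram])
    _write_csv(path, frame, header_comments)


def read_hypnogram(path) -> list[tuple[float, float, SleepStage]]:
    """Parse a (start_s, duration_s, stage) file; errors name the line."""
    records = []
    header = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header[:3] != ["start_s", "duration_s", "stage"]:
                    raise InvalidParameterError(
                        f"{path}, line {lineno}: expected header "
                        f"'start_s,duration_s,stage', got {line!r}")
                continue
            parts = [c.strip() for c in line.split(",")]
            if len(parts) < 3:
                raise InvalidParameterError(
                    f"{path}, line {lineno}: expected 3 columns, got {line!r}")
            try:
                start, dur = float(parts[0]), float(parts[1])
            except ValueError:
                raise InvalidParameterError(
                    f"{path}, line {lineno}: non-numeric start/duration in {line!r}"
                ) from None
            try:
                stage = SleepStage.from_name(parts[2])
            except KeyError as exc:
                raise InvalidParameterError(f"{path}, line {lineno}: {exc}") from None
            records.append((start, dur, stage))
    if header is None:
        raise InvalidParameterError(f"{path}: empty hypnogram file (header required)")
    return records


def write_features(path, features: Sequence[FeatureVector],
                   window_starts: Sequence[float] | None = None,
                   header_comments: Iterable[str] = ()) -> None:
    if window_starts is None:
        window_starts = [30.0 * i for i in range(len(features))]
    frame = pd.DataFrame(
        [{"window_start_s": s, "rate_bpm": f.rate_bpm, "voltage_V": f.voltage,
          "stage": f.stage_label.name if f.stage_label is not None else ""}
         for s, f in zip(window_starts, features)])
    _write_csv(path, frame, header_comments)


def read_features(path) -> list[FeatureVector]:
    frame = pd.read_csv(path, comment="#", keep_default_na=False)
    out = []
    for _, row in frame.iterrows():
        stage = str(row.get("stage", "")).strip()
        label = SleepStage.from_name(stage) if stage else None
        out.append(FeatureVector(float(row["rate_bpm"]), float(row["voltage_V"]),
                                 label))
    return out


def write_model(path, cset: CentroidSet,
                header_comments: Iterable[str] = ()) -> None:
    """Serialize a centroid set (k, centroids, scaling, fit metadata) to YAML."""
    doc = {
        "k": cset.k,
        "centroids": [
            {"i": c.index_i, "x": c.x, "y": c.y,
             "stage": c.stage.name if c.stage is not None else None}
            for c in cset.centroids],
        "scaling": (None if cset.scaling is None else
                    {"weight_W": cset.scaling.weight_W,
                     "voltage_reference": cset.scaling.voltage_reference}),
        "metadata": {k: v for k, v in cset.metadata.items() if k != "history"},
    }
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_model(path) -> CentroidSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    centroids = [
        Centroid(index_i=int(c["i"]), x=float(c["x"]), y=float(c["y"]),
                 stage=None if c.get("stage") is None
                 else SleepStage.from_name(c["stage"]))
        for c in doc["centroids"]]
    scaling = None
    if doc.get("scaling"):
        scaling = ScalingConfig(weight_W=float(doc["scaling"]["weight_W"]),
                                voltage_reference=float(
                                    doc["scaling"]["voltage_reference"]))
    return CentroidSet(centroids, scaling=scaling,
                       metadata=doc.get("metadata") or {})


def write_report(path, report: ClassificationReport,
                 header_comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        report.to_frame().to_csv(fh)
        fh.write("\n")
        acc = pd.DataFrame(
            [{"stage": s.name, "accuracy": a}
             for s, a in report.per_stage_accuracy.items()]
            + [{"stage": "AVERAGED", "accuracy": report.averaged_accuracy}])
        acc.to_csv(fh, index=False)


def write_sweep(path, sweep: SweepResult,
                header_comments: Iterable[str] = ()) -> None:
    _write_csv(path, sweep.to_frame(), header_comments)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
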