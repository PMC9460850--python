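"""End-to-end pipeline: simulate -> extract -> fit -> classify -> evaluate.

:class:`PipelineConfig` gathers every tunable with defaults reproducing the
reference pipeline: 30-s windows at dt = 0.017 s, the 0.1-0.5 Hz band,
weight W = 0.1, k = 5 clusters, and a stratified benchmark with 40 training
and 40 test windows per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import yaml

from . import io as rio
from .errors import InvalidParameterError
from .evaluate import fit_and_classify, weight_sweep
from .processing import extract_features
from .stages import STAGE_ORDER, SleepStage
from .synth import default_stage_models, synth_session, StageSignalModel
from .trace import AcquisitionModel, SleepSession

import numpy as np


@dataclass
class PipelineConfig:
    """Every design-decision setting of the pipeline, serializable to YAML."""

    # simulator
    dt: float = 0.017
    epoch_length: float = 30.0
    dc_offset: float = 1.2
    noise_sd: float = 0.05
    train_windows_per_stage: int = 40
    test_windows_per_stage: int = 40
    stage_overrides: dict = field(default_factory=dict)
    # processing
    window_length: float = 30.0
    band: tuple[float, float] = (0.1, 0.5)
    grid_hz: float = 0.002
    peak_summary: str = "mean"
    # scaling / classifier
    weight_W: float = 0.1
    k: int = 5
    n_init: int = 10
    mode: str = "supervised"      # or "kmeans"
    # evaluation
    sweep_weights: tuple[float, ...] = (1.0, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["sweep_weights"] = list(self.sweep_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "sweep_weights" in d:
            d["sweep_weights"] = tuple(d["sweep_weights"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_models(self) -> dict[SleepStage, StageSignalModel]:
        models = default_stage_models()
        for name, overrides in self.stage_overrides.items():
            stage = SleepStage.from_name(name)
            models[stage] = dataclasses.replace(models[stage], **overrides)
        return models

    def acquisition(self) -> AcquisitionModel:
        return AcquisitionModel(dc_offset=self.dc_offset, noise_sd=self.noise_sd)


def stratified_hypnogram(windows_per_stage: int, epoch_length: float,
                         seed: int) -> list[tuple[SleepStage, float]]:
    """Equal epochs per stage in a seeded shuffled order."""
    entries = [(stage, epoch_length)
               for stage in STAGE_ORDER for _ in range(windows_per_stage)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    return [entries[i] for i in order]


def simulate_benchmark_session(config: PipelineConfig, windows_per_stage: int,
                               seed: int) -> SleepSession:
    hyp = stratified_hypnogram(windows_per_stage, config.epoch_length, seed)
    return synth_session(hyp, models=config.stage_models(),
                         acq=config.acquisition(), dt=config.dt, seed=seed)


def run_all(config: PipelineConfig | None = None, seed: int = 0,
            outdir=None) -> dict:
    """Full seeded benchmark; optionally writes all artifacts to ``outdir``.

    Returns a dict with the train/test sessions and features, the fitted
    centroid set, and the :class:`ClassificationReport`.
    """
    config = config or PipelineConfig()
    train_session = simulate_benchmark_session(
        config, config.train_windows_per_stage, seed)
    test_session = simulate_benchmark_session(
        config, config.test_windows_per_stage, seed + 10007)
    kwargs = dict(window_length=config.window_length, band=config.band,
                  grid_hz=config.grid_hz, peak_summary=config.peak_summary)
    train_features = extract_features(train_session, **kwargs)
    test_features = extract_features(test_session, **kwargs)
    report, cset = fit_and_classify(
        train_features, test_features, weight_W=config.weight_W, k=config.k,
        seed=seed, n_init=config.n_init, mode=config.mode)
    result = {
        "config": config, "seed": seed,
        "train_session": train_session, "test_session": test_session,
        "train_features": train_features, "test_features": test_features,
        "centroids": cset, "report": report,
    }
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def run_sweep(config: PipelineConfig | None = None, seed: int = 0):
    """The weight-value sweep on the same seeded benchmark."""
    config = config or PipelineConfig()
    result = run_all(config, seed)
    sweep = weight_sweep(result["train_features"], result["test_features"],
                         config.sweep_weights, k=config.k, seed=seed,
                         n_init=config.n_init, mode=config.mode)
    return sweep, result


def write_artifacts(result: dict, outdir) -> None:
    """Write every pipeline artifact with the producing config hash stamped."""
    config: PipelineConfig = result["config"]
    out = rio.ensure_dir(outdir)
    comments = [f"config_hash: {config.config_hash()}", f"seed: {result['seed']}"]
    for split in ("train", "test"):
        session: SleepSession = result[f"{split}_session"]
        rio.write_trace(out / f"{split}_trace.csv", session.concatenated(),
                        comments)
        rio.write_hypnogram(out / f"{split}_hypnogram.csv", session.hypnogram,
                            comments)
        starts = [s for s, _, _ in session.hypnogram]
        rio.write_features(out / f"{split}_features.csv",
                           result[f"{split}_features"], starts, comments)
    rio.write_model(out / "model.yaml", result["centroids"], comments)
    rio.write_report(out / "report.csv", result["report"], comments)
    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"seed": result["seed"],
                        "config_hash": config.config_hash()}, fh)
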