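"""End-to-end orchestration: simulate -> segment -> label -> train -> evaluate.

A single configuration document drives the whole run; every stage writes
its artifacts to disk and the manifest records the resolved config, the
artifact paths and their checksums, so deterministic stages reproduce
bit-identical outputs from the same manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import evaluate
from .labels import group_labels, individual_label, individual_label_values
from .models import ModelSpec
from .records import save_shards
from .segmentation import SampleSet, SegmentationConfig, build_sample_set
from .streams import read_recording, write_recording
from .synth import ParticipantProfile, SimConfig, simulate_session
from .training import TrainConfig, holdout_train

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_config"]


@dataclass
class PipelineConfig:
    """One document for the whole pipeline.

    Exactly one data source: either ``simulation`` (a list of per-session
    simulator settings) or ``recording_paths``.
    """

    simulation: list[dict] | None = None
    recording_paths: list[str] | None = None
    segmentation: dict = field(default_factory=dict)
    labelling_scheme: str = "individual"
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "runs/run0"
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise OSError(f"cannot parse config {path!r}: {exc}") from exc
        return PipelineConfig(**doc)


@dataclass
class RunManifest:
    config: dict
    artifacts: dict[str, str] = field(default_factory=dict)  # name -> path
    checksums: dict[str, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)


def validate_config(config: PipelineConfig) -> list[str]:
    """Check every stage invariant; returns problem messages (empty = valid)."""
    problems: list[str] = []
    has_sim = bool(config.simulation)
    has_rec = bool(config.recording_paths)
    if has_sim == has_rec:
        problems.append(
            "data source: exactly one of simulation or recording_paths is required"
        )
    wl = config.segmentation.get("window_length", 8.0)
    if not wl > 0:
        problems.append("segmentation.window_length must be > 0")
    if config.labelling_scheme not in ("individual", "group"):
        problems.append("labelling_scheme must be 'individual' or 'group'")
    hf = config.training.get("holdout_fraction", 0.10)
    if not 0.0 < hf < 1.0:
        problems.append("training.holdout_fraction must lie in (0, 1)")
    lr = config.training.get("lr_max", 0.01)
    if not lr > 0:
        problems.append("training.lr_max must be > 0")
    ep = config.training.get("epochs_per_fold", 25)
    if ep < 1:
        problems.append("training.epochs_per_fold must be >= 1")
    try:
        ModelSpec(**config.model)
    except (TypeError, ValueError) as exc:
        problems.append(f"model: {exc}")
    if has_sim:
        for i, sim in enumerate(config.simulation):
            try:
                _sim_config(sim, config.seed, i)
            except (TypeError, ValueError) as exc:
                problems.append(f"simulation[{i}]: {exc}")
    return problems


def _sim_config(doc: dict, global_seed: int, index: int) -> SimConfig:
    doc = dict(doc)
    profile = ParticipantProfile(**doc.pop("profile", {}))
    doc.setdefault("seed", global_seed + 101 * index)
    doc.setdefault("participant_id", f"sim{index:02d}")
    if "puzzle_difficulties" in doc:
        doc["puzzle_difficulties"] = tuple(doc["puzzle_difficulties"])
        doc.setdefault("n_puzzles", len(doc["puzzle_difficulties"]))
    return SimConfig(profile=profile, **doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, artifact: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {artifact!r}: {cause}")
        self.stage = stage
        self.artifact = artifact


def run_pipeline(config: PipelineConfig):
    """Execute all stages in order; returns ``(RunManifest, EvalReport)``."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config),
        versions={"fuseload": __version__, "numpy": np.__version__},
    )

    # stage 1: data source -------------------------------------------------
    recordings = []
    truths = []
    if config.simulation:
        for i, sim_doc in enumerate(config.simulation):
            cfg = _sim_config(sim_doc, config.seed, i)
            rec, truth = simulate_session(cfg)
            p = out / f"recording_{i:02d}.h5"
            try:
                write_recording(rec, p)
            except OSError as exc:
                raise StageError("simulate", str(p), exc) from exc
            manifest.artifacts[f"recording_{i}"] = str(p)
            manifest.checksums[f"recording_{i}"] = _sha256(p)
            recordings.append(read_recording(p))
            truths.append(truth)
            logger.info("simulated session %d: %d markers", i, len(rec.markers))
    else:
        for i, rp in enumerate(config.recording_paths):
            try:
                recordings.append(read_recording(rp))
            except OSError as exc:
                raise StageError("ingest", str(rp), exc) from exc
            manifest.artifacts[f"recording_{i}"] = str(rp)

    # stage 2: labels ------------------------------------------------------
    if config.simulation:
        if config.labelling_scheme == "individual":
            ratings_per_session = [
                {pid: individual_label(r) for pid, r in t.ratings.items()}
                for t in truths
            ]
            label_values = individual_label_values()
        else:
            all_pids = sorted({pid for t in truths for pid in t.ratings})
            means = np.array(
                [np.mean([t.ratings[pid] for t in truths if pid in t.ratings])
                 for pid in all_pids]
            )
            glabels = group_labels(means)
            ratings_per_session = [
                {pid: glabels[all_pids.index(pid)] for pid in t.ratings}
                for t in truths
            ]
            label_values = np.sort(glabels)
    else:
        raise NotImplementedError(
            "real-recording runs need a ratings CSV; use the library API"
        )

    # stage 3: segmentation ------------------------------------------------
    seg_cfg = SegmentationConfig(**config.segmentation)
    sets = []
    for rec, ratings in zip(recordings, ratings_per_session):
        sets.append(
            build_sample_set(rec, ratings, seg_cfg,
                             labelling_scheme=config.labelling_scheme)
        )
    sample_set = SampleSet.concat(sets)
    shard_dir = out / "shards"
    save_shards(sample_set, shard_dir)
    manifest.artifacts["shards"] = str(shard_dir)
    logger.info("segmented %d samples", len(sample_set))

    # stage 4: training ----------------------------------------------------
    spec = ModelSpec(**config.model)
    train_cfg = TrainConfig(**{**config.training, "seed": config.seed})
    try:
        _, _, preds, yte = holdout_train(spec, sample_set, train_cfg)
    except Exception as exc:
        raise StageError("train", "holdout", exc) from exc

    # stage 5: evaluation --------------------------------------------------
    report = evaluate(preds, yte, label_values)
    report_path = out / "eval_report.json"
    report_path.write_text(
        json.dumps(
            {
                "mean_abs_error": report.mean_abs_error,
                "low": report.low,
                "within_1_level": report.within_1_level,
                "within_1_5_levels": report.within_1_5_levels,
                "accuracy": report.accuracy,
                "off_by_one_accuracy": report.off_by_one_accuracy,
                "error_mean": report.error_mean,
                "error_sd": report.error_sd,
            },
            indent=2,
        )
    )
    manifest.artifacts["eval_report"] = str(report_path)
    manifest.checksums["eval_report"] = _sha256(report_path)
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest, report
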