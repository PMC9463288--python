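"""Configuration, serialization, structured logging and the end-to-end pipeline.

Stage order: simulate -> exclude -> segment -> features -> tables -> RANOVA
-> distance maps -> top-distance selection -> classification. Every artifact
is written under one output directory together with a manifest recording the
configuration, seeds, package version and artifact hashes, so each numeric
artifact is reproducible from the manifest alone.

Recordings serialize as one directory per participant/exercise/file holding
per-stream columnar CSV tables (timestamp + channels) plus a JSON metadata
sidecar; all tabular artifacts are CSV with headers, summaries are JSON.
Logging is structured (JSON lines) with per-stage timings and record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import LEARNER_FAMILIES, evaluate_roster, report, select_top_distance
from .distance import build_maps
from .emg_features import DEFAULT_BAND
from .motion_features import DEFAULT_POC_HYSTERESIS_M
from .ranova import neglog10_summary, ranova_table
from .segment import GestureParams, segment_recording
from .synth import (
    BODY_PARTS,
    CohortConfig,
    ConfigError,
    MultimodalRecording,
    RecordingMeta,
    default_excluded_ids,
    exclude_participants,
    simulate_cohort,
)
from .table import build_feature_tables, impute_group_means, normalize_minmax

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "save_recordings",
    "load_recordings",
    "save_table",
    "load_table",
    "get_logger",
]


@dataclass
class PipelineConfig:
    """Schema-validated configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    gesture: GestureParams = field(default_factory=GestureParams)
    emg_band: tuple[float, float] = DEFAULT_BAND
    per_sample_averaging: bool = True
    signed_f_range: bool = True
    poc_hysteresis_m: float = DEFAULT_POC_HYSTERESIS_M
    include_imu: bool = True
    distance_algorithms: tuple[str, ...] = ("euclidean", "mahalanobis")
    distance_normalized: bool = False
    benjamini_hochberg: bool = False
    roster: tuple[str, ...] = LEARNER_FAMILIES
    folds: int = 5
    selection_fraction: float = 0.15
    group_by_participant: bool = False
    seed: int = 0
    excluded_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        if isinstance(self.gesture, dict):
            self.gesture = GestureParams(**self.gesture)
        bad = set(self.roster) - set(LEARNER_FAMILIES)
        if bad:
            raise ConfigError(f"unknown learner families: {sorted(bad)}")
        if not 0 < self.selection_fraction <= 1:
            raise ConfigError("selection_fraction must lie in (0, 1]")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        for alg in self.distance_algorithms:
            if alg not in ("euclidean", "mahalanobis"):
                raise ConfigError(f"unknown distance algorithm {alg!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# structured logging

class _JsonlFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        entry = {
            "ts": round(record.created, 3),
            "level": record.levelname,
            "msg": record.getMessage(),
        }
        entry.update(getattr(record, "fields", {}))
        return json.dumps(entry)


def get_logger(log_path: Path | None = None) -> logging.Logger:
    logger = logging.getLogger("endoeval")
    logger.setLevel(logging.INFO)
    for h in [h for h in logger.handlers if isinstance(h, logging.FileHandler)]:
        h.close()
        logger.removeHandler(h)
    if log_path is not None:
        handler = logging.FileHandler(log_path)
        handler.setFormatter(_JsonlFormatter())
        logger.addHandler(handler)
    return logger


def _log_stage(logger: logging.Logger, stage: str, t0: float, **fields) -> None:
    logger.info(stage, extra={"fields": {"stage": stage, "elapsed_s": round(time.time() - t0, 3), **fields}})


# --------------------------------------------------------------------------
# recording / table serialization

def _rec_dir(root: Path, meta: RecordingMeta) -> Path:
    return root / meta.participant / f"ex{meta.exercise}" / f"file{meta.file_index}"


def save_recordings(recordings: list[MultimodalRecording], root: str | Path) -> Path:
    """Write per-stream CSV tables + JSON sidecars, and a cohort manifest."""
    root = Path(root)
    index = []
    for rec in recordings:
        d = _rec_dir(root, rec.meta)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"timestamp": rec.semg_t, **{f"ch{i+1}": rec.semg[i] for i in range(8)}}
        ).to_csv(d / "semg.csv", index=False)
        pd.DataFrame(
            {
                "timestamp": rec.orientation_t,
                "roll": rec.orientation[0],
                "pitch": rec.orientation[1],
                "yaw": rec.orientation[2],
            }
        ).to_csv(d / "orientation.csv", index=False)
        skel = {"timestamp": rec.skeleton_t}
        for p, part in enumerate(BODY_PARTS):
            for a, ax in enumerate("xyz"):
                skel[f"{part}_{ax}"] = rec.skeleton[p, a]
        pd.DataFrame(skel).to_csv(d / "skeleton.csv", index=False)
        meta = asdict(rec.meta) | {"attempt_truth": rec.attempt_truth}
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
        index.append(str(d.relative_to(root)))
    (root / "manifest.json").write_text(json.dumps({"recordings": index}, indent=1))
    return root


def load_recordings(root: str | Path) -> list[MultimodalRecording]:
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    out = []
    for rel in manifest["recordings"]:
        d = root / rel
        meta_d = json.loads((d / "meta.json").read_text())
        truth = [tuple(x) for x in meta_d.pop("attempt_truth", [])]
        meta = RecordingMeta(**meta_d)
        semg = pd.read_csv(d / "semg.csv")
        ori = pd.read_csv(d / "orientation.csv")
        skel = pd.read_csv(d / "skeleton.csv")
        skel_arr = np.stack(
            [
                np.stack([skel[f"{part}_{ax}"].to_numpy() for ax in "xyz"])
                for part in BODY_PARTS
            ]
        )
        out.append(
            MultimodalRecording(
                semg=semg[[f"ch{i+1}" for i in range(8)]].to_numpy().T,
                semg_t=semg["timestamp"].to_numpy(),
                orientation=ori[["roll", "pitch", "yaw"]].to_numpy().T,
                orientation_t=ori["timestamp"].to_numpy(),
                skeleton=skel_arr,
                skeleton_t=skel["timestamp"].to_numpy(),
                meta=meta,
                attempt_truth=truth,
            )
        )
    return out


def save_table(tbl: pd.DataFrame, path: str | Path) -> None:
    """Feature table as CSV plus a JSON column dictionary (round-trippable)."""
    path = Path(path)
    tbl.to_csv(path, index=False)
    coldict = {"columns": list(tbl.columns)}
    path.with_suffix(".columns.json").write_text(json.dumps(coldict, indent=1))


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# the pipeline

def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path = "endoeval_out",
    write_recordings: bool = False,
) -> Path:
    """Run every stage end-to-end and write all artifacts under ``out_dir``.

    Raw stream serialization is optional (``write_recordings``) — streams are
    bulky and fully reproducible from the manifest's cohort configuration.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = get_logger(out / "pipeline_log.jsonl")

    t0 = time.time()
    cohort = simulate_cohort(cfg.cohort)
    _log_stage(logger, "simulate", t0, n_recordings=len(cohort))

    t0 = time.time()
    excluded = (
        cfg.excluded_ids
        if cfg.excluded_ids is not None
        else default_excluded_ids(cfg.cohort)
    )
    kept, n_removed = exclude_participants(cohort, list(excluded))
    _log_stage(logger, "exclude", t0, excluded_ids=list(excluded), removed_datasets=n_removed)
    if write_recordings:
        save_recordings(kept, out / "recordings")

    t0 = time.time()
    tables = build_feature_tables(
        kept,
        cfg.gesture,
        band=cfg.emg_band,
        per_sample=cfg.per_sample_averaging,
        signed_f_range=cfg.signed_f_range,
        poc_hysteresis=cfg.poc_hysteresis_m,
        include_imu=cfg.include_imu,
    )
    seg_index = []
    for ex, tbl in tables.items():
        tbl = impute_group_means(tbl)
        tables[ex] = tbl
        save_table(tbl, out / f"features_ex{ex}.csv")
        seg_index.append({"exercise": ex, "attempts": len(tbl)})
    _log_stage(logger, "features", t0, tables={str(k): len(v) for k, v in tables.items()})

    t0 = time.time()
    for ex, tbl in tables.items():
        rt = ranova_table(tbl)
        if cfg.benjamini_hochberg:
            from scipy.stats import false_discovery_control

            for col in ("p_time", "p_time_endo"):
                rt[col + "_bh"] = false_discovery_control(rt[col])
        rt.to_csv(out / f"ranova_ex{ex}.csv", index=False)
        (out / f"ranova_boxplot_ex{ex}.json").write_text(
            json.dumps(neglog10_summary(rt), indent=1)
        )
    _log_stage(logger, "ranova", t0)

    t0 = time.time()
    maps = {}
    for ex, tbl in tables.items():
        for alg in cfg.distance_algorithms:
            dmap = build_maps(tbl, alg, normalized=cfg.distance_normalized)
            maps[(ex, alg)] = dmap
            dmap.full.to_csv(out / f"distance_{alg}_full_ex{ex}.csv")
            dmap.reduced.to_csv(out / f"distance_{alg}_reduced_ex{ex}.csv")
            (out / f"distance_{alg}_order_ex{ex}.json").write_text(
                json.dumps(
                    {
                        "rows_desc": list(dmap.reduced.index),
                        "cols_desc": list(dmap.reduced.columns),
                    },
                    indent=1,
                )
            )
    _log_stage(logger, "distances", t0, n_maps=len(maps))

    t0 = time.time()
    per_ex = {}
    selections = {}
    for ex, tbl in tables.items():
        sel_map = maps.get((ex, "euclidean")) or next(
            m for (e, _), m in maps.items() if e == ex
        )
        selected = select_top_distance(sel_map, cfg.selection_fraction)
        selections[ex] = selected
        norm = normalize_minmax(tbl)
        per_ex[ex] = evaluate_roster(
            norm,
            features_top=selected,
            roster=cfg.roster,
            folds=cfg.folds,
            seed=cfg.seed,
            group_by_participant=cfg.group_by_participant,
        )
    rep = report(per_ex, folds=cfg.folds, seed=cfg.seed)
    rep.accuracies.to_csv(out / "classification_report.csv")
    (out / "selected_features.json").write_text(json.dumps(selections, indent=1))
    _log_stage(logger, "classify", t0, best=rep.best.to_dict().__str__())

    artifacts = sorted(p.name for p in out.iterdir() if p.suffix in (".csv", ".json"))
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "cohort_seed": cfg.cohort.seed,
        "segment_index": seg_index,
        "artifact_hashes": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
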