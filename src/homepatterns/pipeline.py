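"""End-to-end orchestration: simulate -> features -> separability -> embed
-> cluster -> validate, as one reproducible, logged, manifest-checked run.

A run is a pure function of its :class:`RunConfig`: the master seed is
fanned out deterministically per stage, every artifact is written under the
run directory together with a config snapshot, and a manifest records a
content hash for each artifact so that byte-identical reproduction can be
verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import clustering, features, reduction, separability, similarity
from .events import EventStream, write_events
from .simulate import SimulationSpec, simulate_cohorts

log = logging.getLogger("homepatterns")

ALL_STAGES = ("simulate", "features", "separability", "embed", "cluster",
              "validate")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    out_dir: str = "run"
    seed: int = 0
    n_op: int = 5
    n_ci: int = 5
    n_days: int = 78
    effect_size: float = 1.0
    sweep_sizes: tuple[int, ...] = (78, 57, 36, 22)
    train_fraction: float = 0.7
    rho_threshold: float = 0.85
    kaiser_cutoff: float = 1.0
    analyses: tuple[str, ...] = tuple(similarity.ANALYSIS_SUBSETS)
    stages: tuple[str, ...] = ALL_STAGES

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed below 2^31."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("sweep_sizes", "analyses", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path)


def run_pipeline(config: RunConfig,
                 streams: list[EventStream] | None = None,
                 cohorts: Mapping[str, str] | None = None) -> Path:
    """Execute the configured stages; returns the run directory.

    Without pre-loaded ``streams``/``cohorts`` the simulate stage must be
    enabled (it provides them).  Re-running with an identical config yields
    byte-identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    artifacts: list[Path] = [out / "config.yaml"]
    stages = set(config.stages)

    if "simulate" in stages:
        log.info("simulate: %d OP + %d CI participants, %d days",
                 config.n_op, config.n_ci, config.n_days)
        spec = SimulationSpec(n_op=config.n_op, n_ci=config.n_ci,
                              n_days=config.n_days,
                              seed=config.stage_seed("simulate"),
                              effect_size=config.effect_size)
        streams, label_frame = simulate_cohorts(spec)
        cohorts = dict(zip(label_frame["user_id"], label_frame["cohort"]))
        data_dir = out / "data"
        data_dir.mkdir(exist_ok=True)
        for stream in streams:
            write_events([stream], data_dir / f"{stream.user_id}.csv")
            artifacts.append(data_dir / f"{stream.user_id}.csv")
        label_frame.to_csv(data_dir / "labels.csv", index=False)
        artifacts.append(data_dir / "labels.csv")
    if streams is None or cohorts is None:
        raise ValueError("streams and cohorts required when simulate is skipped")

    day_frames: dict[str, pd.DataFrame] = {}
    split = None
    if stages & {"features", "separability", "embed", "cluster", "validate"}:
        log.info("features: extracting day-level vectors for %d streams",
                 len(streams))
        for stream in streams:
            day_frames[stream.user_id] = features.day_feature_frame(stream)
        shared_days = sorted(set.intersection(
            *(set(f.index) for f in day_frames.values())))
        split = features.split_days(shared_days, config.train_fraction,
                                    config.stage_seed("split"))
        if "features" in stages:
            feat_dir = out / "features"
            feat_dir.mkdir(exist_ok=True)
            for user_id, frame in day_frames.items():
                _write_csv(frame, feat_dir / f"{user_id}_days.csv")
                artifacts.append(feat_dir / f"{user_id}_days.csv")
            split.to_json(feat_dir / "day_split.json")
            artifacts.append(feat_dir / "day_split.json")
            log.info("features: %d shared days -> %d train / %d test",
                     len(shared_days), len(split.train_days),
                     len(split.test_days))

    train_frames = {u: f.loc[f.index.isin(set(split.train_days))]
                    for u, f in day_frames.items()} if split else {}

    if "separability" in stages:
        log.info("separability: size sweep %s", config.sweep_sizes)
        sweep = separability.size_sweep(day_frames, config.sweep_sizes,
                                        config.stage_seed("separability"))
        payload = {str(size): res.to_dict() for size, res in sweep.items()}
        path = out / "separability.json"
        path.write_text(json.dumps(payload, indent=2))
        artifacts.append(path)

    if "embed" in stages:
        matrix = features.aggregate_participants(train_frames, "full84")
        reduced, dropped = reduction.pearson_filter(matrix,
                                                    config.rho_threshold)
        pca = reduction.pca_kaiser(reduced, config.kaiser_cutoff)
        coords, stress = reduction.sammon_map(pca.scores,
                                              seed=config.stage_seed("embed"))
        log.info("embed: %d -> %d features -> %d components, stress %.3g",
                 matrix.shape[1], reduced.shape[1], pca.n_retained, stress)
        (out / "dropped_features.txt").write_text("\n".join(dropped) + "\n")
        pd.DataFrame({"eigenvalue": pca.eigenvalues}).to_csv(
            out / "eigenvalues.csv", index_label="component")
        coords.to_csv(out / "sammon_coords.csv", index_label="user_id")
        ed = similarity.ed_matrix(coords)
        similarity.simi_matrix(ed).to_csv(out / "simi_matrix.csv")
        artifacts += [out / "dropped_features.txt", out / "eigenvalues.csv",
                      out / "sammon_coords.csv", out / "simi_matrix.csv"]

    if stages & {"cluster", "validate"}:
        analysis_config = similarity.AnalysisConfig(
            rho_threshold=config.rho_threshold,
            kaiser_cutoff=config.kaiser_cutoff,
            seed=config.stage_seed("cluster"))
        reports = similarity.run_room_analyses(train_frames, cohorts,
                                               analysis_config,
                                               tags=config.analyses)
        if "cluster" in stages:
            # validity indices of the night-time clustering
            matrix = features.aggregate_participants(train_frames, "night12")
            reduced, _ = reduction.pearson_filter(matrix, config.rho_threshold)
            pca = reduction.pca_kaiser(reduced, config.kaiser_cutoff)
            km = clustering.kmeans_fit(pca.scores,
                                       seed=analysis_config.seed)
            scores = {
                "dunn": clustering.dunn_index(pca.scores,
                                              km.train_assignments),
                "silhouette": clustering.silhouette_mean(
                    pca.scores, km.train_assignments),
            }
            (out / "cluster_validity.json").write_text(
                json.dumps(scores, indent=2))
            artifacts.append(out / "cluster_validity.json")
            log.info("cluster: dunn %.3f silhouette %.3f",
                     scores["dunn"], scores["silhouette"])
        if "validate" in stages:
            similarity.write_reports(reports, out / "validation.json")
            table = similarity.reports_to_table(reports)
            (out / "validation_table.txt").write_text(
                table.to_string(index=False) + "\n")
            artifacts += [out / "validation.json",
                          out / "validation_table.txt"]
            log.info("validate: \n%s", table.to_string(index=False))

    manifest = {
        str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in artifacts
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
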