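"""Similarity analysis on the 2-D map and validation against clinical cohorts.

The Sammon map's pairwise Euclidean distances are rescaled to a
dissimilarity matrix Simi in [0, 1] — 0 the closest pair of participants,
1 the farthest — using the off-diagonal minimum and maximum.

For validation, each 2-group clustering is compared against the care
provider's OP (older persons) / CI (cognitively impaired) cohort labels.
The cluster-to-cohort mapping is not identified by the clustering itself,
so of the two possible mappings the one maximizing accuracy is taken, and
the confusion matrix (rows = true cohort OP/CI, columns = matched cluster)
yields accuracy, sensitivity (OP recall), specificity (CI recall) and
per-cluster precision.  Recall and precision conventions are both reported
because published practice varies between them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import clustering, features, reduction

COHORTS = ("OP", "CI")

#: analysis tag -> participant-level feature subset
ANALYSIS_SUBSETS = {
    "night": "night12",
    "full24": "full84",
    "bedroom": "bedroom28",
    "bathroom": "bathroom28",
    "lounge": "lounge28",
}


def ed_matrix(points: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Euclidean distances between 2-D map points."""
    ids = points.index if isinstance(points, pd.DataFrame) else None
    A = np.asarray(points, dtype=float)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 points")
    D = cdist(A, A)
    if ids is None:
        ids = pd.RangeIndex(A.shape[0])
    return pd.DataFrame(D, index=ids, columns=ids)


def simi_matrix(ed: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescaling of the off-diagonal distances to [0, 1].

    Simi_ij = (ED_ij - min) / (max - min) over off-diagonal entries, so the
    closest pair maps to 0 and the farthest to 1; the diagonal stays 0.  A
    degenerate matrix (max = min) maps every off-diagonal entry to 0.
    """
    D = ed.to_numpy(dtype=float)
    off = ~np.eye(D.shape[0], dtype=bool)
    lo, hi = D[off].min(), D[off].max()
    if hi > lo:
        S = (D - lo) / (hi - lo)
    else:
        S = np.zeros_like(D)
    S[~off] = 0.0
    S[off] = np.clip(S[off], 0.0, 1.0)
    return pd.DataFrame(S, index=ed.index, columns=ed.columns)


def match_clusters(cluster_labels: Mapping[str, int],
                   cohort_labels: Mapping[str, str]) -> np.ndarray:
    """2x2 confusion (rows = OP, CI; cols = matched clusters) at best accuracy.

    Cluster ids are anonymous, so both cluster->cohort mappings are tried
    and the one with the higher accuracy kept; the resulting accuracy is
    therefore always >= 0.5.
    """
    users = list(cohort_labels)
    missing = [u for u in users if u not in cluster_labels]
    if missing or len(cluster_labels) != len(users):
        raise ValueError(f"label sets differ (missing {missing})")
    best_conf, best_acc = None, -1.0
    for mapping in ((0, 1), (1, 0)):
        conf = np.zeros((2, 2), dtype=int)
        for u in users:
            row = COHORTS.index(cohort_labels[u])
            col = mapping[int(cluster_labels[u])]
            conf[row, col] += 1
        acc = np.trace(conf) / conf.sum()
        if acc > best_acc:
            best_conf, best_acc = conf, acc
    return best_conf


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class ValidationReport:
    """Cohort-recovery metrics of one analysis (full precision retained)."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: float              # OP recall
    specificity: float              # CI recall
    precision_op_cluster: float
    precision_ci_cluster: float
    analysis_tag: str = ""
    method: str = ""

    def rounded(self) -> dict:
        """Display form: metrics rounded half-up to 2 decimals."""
        return {
            "analysis": self.analysis_tag, "method": self.method,
            "confusion": self.confusion.tolist(),
            "accuracy": _round2(self.accuracy),
            "sensitivity": _round2(self.sensitivity),
            "specificity": _round2(self.specificity),
            "precision_op_cluster": _round2(self.precision_op_cluster),
            "precision_ci_cluster": _round2(self.precision_ci_cluster),
        }


def cohort_metrics(confusion: np.ndarray, analysis_tag: str = "",
                   method: str = "") -> ValidationReport:
    """Accuracy / sensitivity / specificity / per-cluster precision of a 2x2."""
    conf = np.asarray(confusion)
    if conf.shape != (2, 2) or (conf < 0).any():
        raise ValueError("confusion must be a 2x2 nonnegative count matrix")
    n = conf.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num, den):
        return float(num / den) if den > 0 else 0.0

    return ValidationReport(
        confusion=conf,
        accuracy=float(np.trace(conf) / n),
        sensitivity=_ratio(conf[0, 0], conf[0].sum()),
        specificity=_ratio(conf[1, 1], conf[1].sum()),
        precision_op_cluster=_ratio(conf[0, 0], conf[:, 0].sum()),
        precision_ci_cluster=_ratio(conf[1, 1], conf[:, 1].sum()),
        analysis_tag=analysis_tag, method=method,
    )


@dataclass
class AnalysisConfig:
    """Knobs of the reduce -> cluster -> validate chain."""

    rho_threshold: float = 0.85
    kaiser_cutoff: float = 1.0
    kmeans_restarts: int = 10
    som_epochs: int = 500
    seed: int = 0


def analyse_subset(day_frames: Mapping[str, pd.DataFrame],
                   cohorts: Mapping[str, str], tag: str,
                   config: AnalysisConfig | None = None,
                   ) -> dict[str, ValidationReport]:
    """Run aggregation, reduction, KM and SOM clustering, and validation
    for one feature subset; returns one report per clustering method."""
    config = config or AnalysisConfig()
    matrix = features.aggregate_participants(day_frames, ANALYSIS_SUBSETS[tag])
    reduced, _dropped = reduction.pearson_filter(matrix, config.rho_threshold)
    pca = reduction.pca_kaiser(reduced, config.kaiser_cutoff)
    X = pca.scores
    km = clustering.kmeans_fit(X, k=2, restarts=config.kmeans_restarts,
                               seed=config.seed)
    som = clustering.som_fit(X, grid=(1, 2), epochs=config.som_epochs,
                             seed=config.seed)
    reports = {}
    for model in (km, som):
        labels = dict(zip(X.index, model.train_assignments))
        conf = match_clusters(labels, cohorts)
        reports[model.method] = cohort_metrics(conf, tag, model.method)
    return reports


def run_room_analyses(day_frames: Mapping[str, pd.DataFrame],
                      cohorts: Mapping[str, str],
                      config: AnalysisConfig | None = None,
                      tags: Sequence[str] = tuple(ANALYSIS_SUBSETS),
                      ) -> dict[str, dict[str, ValidationReport]]:
    """The full battery: night, full-24 h and per-room block analyses."""
    return {tag: analyse_subset(day_frames, cohorts, tag, config)
            for tag in tags}


def reports_to_table(reports: Mapping[str, Mapping[str, ValidationReport]],
                     ) -> pd.DataFrame:
    """Rendered validation table (one row per analysis x method, 2-dp metrics)."""
    rows = [rep.rounded() for by_method in reports.values()
            for rep in by_method.values()]
    return pd.DataFrame(rows).drop(columns=["confusion"])


def write_reports(reports: Mapping[str, Mapping[str, ValidationReport]],
                  path: str | Path) -> None:
    payload = {tag: {m: rep.rounded() for m, rep in by_method.items()}
               for tag, by_method in reports.items()}
    Path(path).write_text(json.dumps(payload, indent=2))
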