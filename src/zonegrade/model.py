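"""Model / Results objects tying the pipeline together.

:class:`ZonalGradeGroupModel` is built from a per-lesion feature table for
one prostatic zone group (peripheral zone, or transitional zone + anterior
fibromuscular stroma). Its :meth:`~ZonalGradeGroupModel.fit` runs the
semi-exhaustive subset search for each one-vs-rest Grade-Group task and
returns a :class:`ZonalGradeGroupResults` carrying the ranked subsets,
cross-validated AUCs and operating-point metrics, with ``summary()``,
``predict()`` and CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import (TASKS, BinaryTask, apply_normalization,
                         fit_normalization, knn_score_matrix, ovr_assign)
from .features import FEATURE_NAMES, extract_features
from .io_preprocess import ROIFragment
from .search import SearchConfig, SubsetResult, run_zone_analysis

__all__ = [
    "feature_table",
    "ZonalGradeGroupModel",
    "ZonalGradeGroupResults",
    "RANKED_CSV_HEADER",
]

META_COLUMNS = ["patient_id", "lesion_id", "zone", "gg"]
RANKED_CSV_HEADER = ["rank", "subset_indices", "subset_names", "mean_auc",
                     "fold1_auc", "fold2_auc", "fold3_auc", "accuracy",
                     "sensitivity", "specificity"]


def feature_table(records, fragments, G: int = 128) -> pd.DataFrame:
    """Extract the 38-feature panel for each lesion into a tidy table.

    Columns: patient_id, lesion_id, zone, gg, then the 38 canonical
    feature names.
    """
    rows = []
    for rec, frag in zip(records, fragments):
        fv = extract_features(frag, G=G)
        rows.append([rec.patient_id, rec.lesion_id, rec.zone, rec.gg,
                     *fv.values])
    return pd.DataFrame(rows, columns=META_COLUMNS + list(FEATURE_NAMES))


class ZonalGradeGroupModel:
    """Grade-Group grading model for one prostatic zone group.

    Parameters
    ----------
    features : pandas.DataFrame
        One row per lesion with the meta columns ``patient_id, lesion_id,
        zone, gg`` followed by the 38 feature columns.
    zone_group : {"PZ", "TZAFS"}
        Which zone the table belongs to; "TZAFS" covers TZ and AFS lesions,
        which are graded together.
    config : SearchConfig
        Subset-size range, folds, seed and KNN settings.
    """

    def __init__(self, features: pd.DataFrame, zone_group: str = "PZ",
                 config: SearchConfig | None = None,
                 tasks: tuple[BinaryTask, ...] = TASKS):
        missing = [c for c in META_COLUMNS + list(FEATURE_NAMES)
                   if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing[:4]}...")
        if zone_group not in ("PZ", "TZAFS"):
            raise ValueError("zone_group must be 'PZ' or 'TZAFS'")
        zones = ("PZ",) if zone_group == "PZ" else ("TZ", "AFS")
        self.data = features[features["zone"].isin(zones)].reset_index(drop=True)
        if len(self.data) == 0:
            raise ValueError(f"no lesions for zone group {zone_group}")
        self.zone_group = zone_group
        self.config = config or SearchConfig()
        self.tasks = tasks
        self.X = self.data[list(FEATURE_NAMES)].to_numpy(dtype=float)
        self.gg = self.data["gg"].to_numpy(dtype=int)

    @classmethod
    def from_cohort(cls, cohort, zone_group: str = "PZ",
                    config: SearchConfig | None = None,
                    G: int = 128) -> "ZonalGradeGroupModel":
        """Build directly from a cohort of lesion records + ROI fragments."""
        table = feature_table(cohort.records, cohort.fragments, G=G)
        return cls(table, zone_group=zone_group, config=config)

    def fit(self, feature_pool: tuple[int, ...] | None = None
            ) -> "ZonalGradeGroupResults":
        """Run the per-task semi-exhaustive search and return results."""
        ranked = run_zone_analysis(self.X, self.gg, self.config,
                                   tasks=self.tasks, feature_pool=feature_pool)
        return ZonalGradeGroupResults(model=self, ranked=ranked)


@dataclass
class ZonalGradeGroupResults:
    """Fitted results: ranked subsets per task and trained predictors."""

    model: ZonalGradeGroupModel
    ranked: dict[str, list[SubsetResult]]

    @property
    def best(self) -> dict[str, SubsetResult]:
        """Top-ranked subset per task."""
        return {name: res[0] for name, res in self.ranked.items()}

    def task_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-task KNN probability scores for query rows (n, n_tasks).

        Each task's predictor uses its best subset, with normalization and
        neighbors from the full training cohort of this zone.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(self.model.tasks)))
        for t, task in enumerate(self.model.tasks):
            best = self.ranked[task.name][0]
            cols = np.asarray(best.subset) - 1
            params = fit_normalization(self.model.X[:, cols])
            tr = apply_normalization(self.model.X[:, cols], params)
            te = apply_normalization(X[:, cols], params)
            y = task.labels(self.model.gg)
            out[:, t] = knn_score_matrix(tr, y, te, self.model.config.knn)
        return out

    def predict(self, X: np.ndarray) -> list[str]:
        """One-vs-rest task label per query row (highest score wins)."""
        scores = self.task_scores(X)
        return [ovr_assign(row, self.model.tasks).name for row in scores]

    def predict_fragment(self, frag: ROIFragment, G: int = 128) -> str:
        fv = extract_features(frag, G=G)
        return self.predict(fv.values[None, :])[0]

    def summary(self) -> pd.DataFrame:
        """Best subset and CV metrics per one-vs-rest task."""
        rows = []
        for task in self.model.tasks:
            b = self.ranked[task.name][0]
            names = ", ".join(FEATURE_NAMES[i - 1] for i in b.subset)
            rows.append([task.name, self.model.zone_group,
                         " ".join(map(str, b.subset)), names,
                         round(b.mean_auc, 4), round(b.accuracy, 4),
                         round(b.sensitivity, 4), round(b.specificity, 4)])
        return pd.DataFrame(rows, columns=[
            "task", "zone", "subset", "subset_names", "mean_auc", "accuracy",
            "sensitivity", "specificity"])

    def ranked_frame(self, task: str) -> pd.DataFrame:
        """Ranked-subset table for one task in the canonical CSV layout."""
        rows = []
        for rank, r in enumerate(self.ranked[task], start=1):
            names = ";".join(FEATURE_NAMES[i - 1] for i in r.subset)
            aucs = list(r.fold_aucs) + [np.nan] * (3 - len(r.fold_aucs))
            rows.append([rank, " ".join(map(str, r.subset)), names,
                         r.mean_auc, *aucs[:3], r.accuracy, r.sensitivity,
                         r.specificity])
        return pd.DataFrame(rows, columns=RANKED_CSV_HEADER)

    def to_csv(self, out_dir: str | Path) -> list[Path]:
        """Write one ranked CSV per task; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for task in self.ranked:
            p = out_dir / f"ranked_{self.model.zone_group}_{task}.csv"
            self.ranked_frame(task).to_csv(p, index=False, float_format="%.12g")
            paths.append(p)
        return paths
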