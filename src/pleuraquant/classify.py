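"""Random-forest classification protocol for effusion complexity.

Five independent binary tasks are trained over the combined complexity +
radiomic feature table: simple-vs-complex plus one model per complexity
feature (hyperdense fluid, pleural thickening, gas, loculation). The
protocol for each task:

1. random 1:1 downsampling of the majority class (training data only),
2. preliminary forest to rank features by impurity importance; features at
   or above the median importance are kept (ties at the cutoff kept),
3. leave-one-out cross-validated grid search over forest regularizers,
4. final fit; test-time positivity requires probability strictly > 0.5.

A light model/results surface (:class:`EffusionClassifier` /
:class:`ClassifierResults`) wraps the protocol; the free functions expose
the individual steps.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import CaseTable, LABEL_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "ModelBundle",
    "PredictionRecord",
    "EffusionClassifier",
    "ClassifierResults",
    "downsample_balanced",
    "select_features_by_importance",
    "tune_loo",
    "train_all",
    "predict",
    "prepare_features",
    "DEFAULT_GRID",
]

TASKS = ("simple_vs_complex", "hyperdense_fluid", "pleural_thickening",
         "gas", "loculation")
TASK_LABEL = {
    "simple_vs_complex": "complex",
    "hyperdense_fluid": "hyperdense_fluid",
    "pleural_thickening": "pleural_thickening",
    "gas": "gas",
    "loculation": "loculation",
}

#: leave-one-out tuning grid; tree count fixed at 100 (accuracy plateaus
#: there at these sample sizes and the grid stays tractable on one CPU)
DEFAULT_GRID = tuple(
    {"n_estimators": 100, "max_depth": d, "min_samples_leaf": leaf}
    for d in (None, 8)
    for leaf in (1, 5)
)

DECISION_THRESHOLD = 0.5


def _seed_stream(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def prepare_features(table: CaseTable, aggregate: str = "max") -> pd.DataFrame:
    """Per-case numeric feature matrix with missing-value handling.

    Rows are aggregated over sides by ``max`` (classification is per
    patient); missing values are imputed with 0 and flagged in a
    ``<name>_missing`` indicator so "undefined" never masquerades as an
    observed zero.
    """
    df = table.df.copy()
    feats = table.feature_columns
    keep = ["case_id"] + feats + [c for c in LABEL_COLUMNS if c in df.columns]
    df = df[keep]
    if aggregate == "max":
        df = df.groupby("case_id", sort=True).max(numeric_only=True).reset_index()
    elif aggregate != "none":
        raise ValueError(f"unknown aggregation {aggregate!r}")
    for c in feats:
        miss = df[c].isna()
        if miss.any():
            df[f"{c}_missing"] = miss.astype(int)
            df[c] = df[c].fillna(0.0)
        else:
            df[f"{c}_missing"] = 0
    return df


def downsample_balanced(df: pd.DataFrame, label: str, seed: int) -> pd.DataFrame:
    """Randomly subsample the majority class to a 1:1 ratio (no replacement)."""
    counts = df[label].value_counts()
    if len(counts) < 2 or (counts == 0).any():
        raise ValueError(f"label {label!r} needs both classes to downsample")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for value, group in df.groupby(label, sort=True):
        if len(group) > n_min:
            idx = rng.choice(group.index.to_numpy(), size=n_min, replace=False)
            parts.append(df.loc[np.sort(idx)])
        else:
            parts.append(group)
    return pd.concat(parts).sort_index().reset_index(drop=True)


def select_features_by_importance(
    df: pd.DataFrame,
    label: str,
    feature_cols: list[str],
    percentile: float = 50.0,
    seed: int = 0,
    n_estimators: int = 100,
) -> list[str]:
    """Keep features at or above the given percentile of forest importance.

    A preliminary forest is fitted on the balanced table; features whose
    mean-impurity-decrease importance reaches the percentile cutoff are
    kept, ties at the cutoff included.
    """
    if len(feature_cols) < 1:
        raise ValueError("need at least one feature")
    if len(feature_cols) == 1:
        return list(feature_cols)
    X = df[feature_cols].to_numpy(dtype=float)
    y = df[label].to_numpy(dtype=int)
    if np.ptp(X, axis=0).max() == 0:
        warnings.warn("all features constant; importances are all zero")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    return keep_at_percentile(feature_cols, forest.feature_importances_,
                              percentile)


def keep_at_percentile(names, importances, percentile: float = 50.0):
    """Names whose importance reaches the percentile cutoff (ties kept)."""
    cutoff = np.percentile(np.asarray(importances, dtype=float), percentile)
    return [c for c, v in zip(names, importances) if v >= cutoff]


def tune_loo(
    df: pd.DataFrame,
    label: str,
    feature_cols: list[str],
    grid: tuple[dict, ...] = DEFAULT_GRID,
    seed: int = 0,
) -> dict:
    """Leave-one-out grid search; returns the best hyperparameters.

    Scored by LOO accuracy; ties broken toward fewer trees, then shallower
    depth, then larger leaf (the most regularized candidate).
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    n = len(df)
    if n < 5:
        raise ValueError(f"need >= 5 rows for leave-one-out tuning, got {n}")
    X = df[feature_cols].to_numpy(dtype=float)
    y = df[label].to_numpy(dtype=int)

    def sort_key(item):
        acc, params = item
        depth = params["max_depth"]
        return (
            -acc,
            params["n_estimators"],
            float("inf") if depth is None else depth,
            -params["min_samples_leaf"],
        )

    scored = []
    for params in grid:
        correct = 0
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
            clf.fit(X[tr], y[tr])
            correct += int(clf.predict(X[i: i + 1])[0] == y[i])
        scored.append((correct / n, dict(params)))
    scored.sort(key=sort_key)
    return scored[0][1]


@dataclass
class ModelBundle:
    """Everything needed to replay predictions for the 5 tasks exactly."""

    models: dict = field(default_factory=dict)  # task -> fitted forest
    selected: dict = field(default_factory=dict)  # task -> feature names
    params: dict = field(default_factory=dict)  # task -> tuned params
    seed: int = 0
    threshold: float = DECISION_THRESHOLD
    skipped: dict = field(default_factory=dict)  # task -> reason

    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "seed": self.seed,
            "threshold": self.threshold,
            "selected": self.selected,
            "params": self.params,
            "skipped": self.skipped,
            "tasks": list(self.models),
        }
        (out_dir / "bundle.json").write_text(json.dumps(meta, indent=1))
        for task, model in self.models.items():
            joblib.dump(model, out_dir / f"{task}.joblib")
        return out_dir

    @classmethod
    def load(cls, out_dir) -> "ModelBundle":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "bundle.json").read_text())
        models = {
            task: joblib.load(out_dir / f"{task}.joblib")
            for task in meta["tasks"]
        }
        return cls(
            models=models, selected=meta["selected"], params=meta["params"],
            seed=meta["seed"], threshold=meta["threshold"],
            skipped=meta["skipped"],
        )


@dataclass
class PredictionRecord:
    case_id: str
    probabilities: dict  # task -> positive-class probability
    calls: dict  # task -> binary call (probability strictly > 0.5)


def train_all(
    table: CaseTable,
    seed: int = 0,
    grid: tuple[dict, ...] = DEFAULT_GRID,
    tasks: tuple[str, ...] = TASKS,
) -> ModelBundle:
    """Run the full 5-task protocol on a training table."""
    df = prepare_features(table)
    feature_cols = [
        c for c in df.columns
        if c not in ("case_id",) and c not in LABEL_COLUMNS
    ]
    bundle = ModelBundle(seed=seed)
    seeds = _seed_stream(seed, 3 * len(tasks))
    for k, task in enumerate(tasks):
        label = TASK_LABEL[task]
        if label not in df.columns or df[label].nunique() < 2:
            reason = f"label {label!r} has a single class; model skipped"
            logger.warning(reason)
            bundle.skipped[task] = reason
            continue
        s_down, s_sel, s_fit = seeds[3 * k: 3 * k + 3]
        balanced = downsample_balanced(df, label, seed=s_down)
        selected = select_features_by_importance(
            balanced, label, feature_cols, percentile=50.0, seed=s_sel
        )
        params = tune_loo(balanced, label, selected, grid=grid, seed=s_fit)
        model = RandomForestClassifier(random_state=s_fit, n_jobs=1, **params)
        model.fit(
            balanced[selected].to_numpy(dtype=float),
            balanced[label].to_numpy(dtype=int),
        )
        bundle.models[task] = model
        bundle.selected[task] = list(selected)
        bundle.params[task] = dict(params)
    return bundle


def predict(bundle: ModelBundle, table: CaseTable) -> list[PredictionRecord]:
    """Predict all tasks for a table; call positive iff probability > 0.5."""
    df = prepare_features(table)
    records = []
    if df.empty:
        return records
    for _, row in df.iterrows():
        probs, calls = {}, {}
        for task, model in bundle.models.items():
            cols = bundle.selected[task]
            missing = [c for c in cols if c not in df.columns]
            x = np.array(
                [[0.0 if c in missing else float(row[c]) for c in cols]]
            )
            if missing:
                logger.warning("features %s absent at prediction; imputed 0",
                               missing)
            pos = list(model.classes_).index(1)
            p = float(model.predict_proba(x)[0][pos])
            probs[task] = p
            calls[task] = int(p > bundle.threshold)
        records.append(
            PredictionRecord(case_id=str(row["case_id"]),
                             probabilities=probs, calls=calls)
        )
    return records


class EffusionClassifier:
    """Model object over a training :class:`CaseTable`.

    ``EffusionClassifier(table).fit(seed=7)`` runs the full protocol and
    returns a :class:`ClassifierResults`.
    """

    def __init__(self, table: CaseTable, tasks: tuple[str, ...] = TASKS,
                 grid: tuple[dict, ...] = DEFAULT_GRID):
        self.table = table
        self.tasks = tasks
        self.grid = grid

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "EffusionClassifier":
        return cls(CaseTable(df), **kwargs)

    def fit(self, seed: int = 0) -> "ClassifierResults":
        bundle = train_all(self.table, seed=seed, grid=self.grid,
                           tasks=self.tasks)
        return ClassifierResults(self, bundle)


class ClassifierResults:
    """Fitted protocol: bundle access, prediction, and a summary table."""

    def __init__(self, model: EffusionClassifier, bundle: ModelBundle):
        self.model = model
        self.bundle = bundle

    def predict(self, table: CaseTable) -> list[PredictionRecord]:
        return predict(self.bundle, table)

    def predict_frame(self, table: CaseTable) -> pd.DataFrame:
        recs = self.predict(table)
        rows = []
        for r in recs:
            row = {"case_id": r.case_id}
            for task in self.bundle.models:
                row[f"p_{task}"] = r.probabilities[task]
                row[f"call_{task}"] = r.calls[task]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Effusion classification protocol", "=" * 34]
        for task in self.model.tasks:
            if task in self.bundle.skipped:
                lines.append(f"{task}: SKIPPED ({self.bundle.skipped[task]})")
                continue
            sel = self.bundle.selected[task]
            p = self.bundle.params[task]
            lines.append(
                f"{task}: {len(sel)} features "
                f"(depth={p['max_depth']}, leaf={p['min_samples_leaf']}, "
                f"trees={p['n_estimators']})"
            )
            lines.append("   " + ", ".join(sel[:6]) + (" ..." if len(sel) > 6 else ""))
        lines.append(f"decision threshold: > {self.bundle.threshold}")
        return "\n".join(lines)
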