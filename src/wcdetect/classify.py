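"""Semi-supervised target classification.

The classification stage mirrors how a small set of operator-reviewed slice
labels is stretched across a whole survey:

1. labels are *extended* within multi-ping objects (slices sharing an object
   very likely share a class);
2. features are normalized with a Yeo-Johnson power transform followed by
   standardization — raw coordinates are exempt;
3. a distance-weighted kNN *pseudo-labeller* trained on the labelled rows
   assigns provisional labels to every unlabelled row;
4. the pseudo-labelled table is stratified-split 70:30 and a gradient
   boosting classifier is grid-searched (5-fold CV) on the training part,
   with the six raw-coordinate columns removed so the model can transfer to
   other sites;
5. the fitted bundle (normalizer + schema + pseudo-labeller spec + ensemble)
   is saved and applied to unseen surveys after recomputing the survey-local
   features (flattened coordinates and the k-means Cluster code).

Classification reports follow the standard per-class precision / recall /
F1 / support layout with accuracy, macro and weighted averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import classification_report, confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import PowerTransformer

from .metrics import COORDINATE_COLUMNS, TABLE2_COLUMNS, cluster_feature, flatten_coords

__all__ = [
    "CLASSES",
    "DEFAULT_GRID",
    "FeatureNormalizer",
    "ModelBundle",
    "SchemaError",
    "normalize_features",
    "extend_labels",
    "mutual_info_scores",
    "pseudo_label",
    "stratified_split",
    "train_ensemble",
    "evaluate",
    "predict_unseen",
    "report_frame",
]

logger = logging.getLogger(__name__)

CLASSES = ["FISH", "GAS", "NOISE", "PLATFORM"]

#: brute-force grid for the gradient boosting classifier
DEFAULT_GRID = {
    "learning_rate": [0.05, 0.1],
    "n_estimators": [100, 300],
    "max_depth": [2, 3],
}

#: columns never passed through the power transform (raw locations and the
#: categorical cluster code)
UNTRANSFORMED = set(COORDINATE_COLUMNS) | {"x", "y", "Cluster"}


class SchemaError(ValueError):
    """Feature table does not match the fitted feature schema."""


class FeatureNormalizer:
    """Yeo-Johnson + standardization for every non-coordinate feature.

    Coordinate columns (and the categorical Cluster code) pass through
    bit-exact; constant columns are left as-is with a warning.
    """

    def __init__(self) -> None:
        self.transformed_: list[str] = []
        self.constant_: list[str] = []
        self.pt_: Optional[PowerTransformer] = None

    def fit(self, table: pd.DataFrame) -> "FeatureNormalizer":
        candidates = [c for c in TABLE2_COLUMNS if c not in UNTRANSFORMED]
        self.constant_ = [c for c in candidates if table[c].nunique() <= 1]
        if self.constant_:
            warnings.warn(
                f"constant features left untransformed: {self.constant_}",
                stacklevel=2,
            )
        self.transformed_ = [c for c in candidates if c not in self.constant_]
        self.pt_ = PowerTransformer(method="yeo-johnson", standardize=True)
        self.pt_.fit(table[self.transformed_].to_numpy(dtype=float))
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[self.transformed_] = self.pt_.transform(
            table[self.transformed_].to_numpy(dtype=float)
        )
        return out


def normalize_features(
    table: pd.DataFrame, normalizer: Optional[FeatureNormalizer] = None
) -> tuple[pd.DataFrame, FeatureNormalizer]:
    """Normalize the feature columns; fit a normalizer if none is given."""
    if normalizer is None:
        normalizer = FeatureNormalizer().fit(table)
    return normalizer.transform(table), normalizer


def extend_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Propagate operator labels to unlabelled slices of the same object.

    Conflicting labels inside one object are resolved by majority; exact
    ties leave the object's unlabelled rows unlabelled (logged).  The
    labelled fraction never decreases and existing labels are never altered.
    """
    out = table.copy()
    for oid, group in table.groupby("object_id"):
        if oid < 0:
            continue
        lab = group["label"][group["label"] != ""]
        if lab.empty:
            continue
        counts = lab.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            logger.warning("object %s has tied labels %s; left unresolved", oid, dict(counts))
            continue
        majority = counts.index[0]
        sel = (out["object_id"] == oid) & (out["label"] == "")
        out.loc[sel, "label"] = majority
    return out


def mutual_info_scores(table: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Mutual information between each feature and the label (report only)."""
    lab = table[table["label"] != ""]
    if lab["label"].nunique() < 2:
        raise ValueError("need labelled rows from at least two classes")
    X = lab[TABLE2_COLUMNS].to_numpy(dtype=float)
    discrete = [TABLE2_COLUMNS.index("Cluster")]
    mi = mutual_info_classif(
        X, lab["label"], discrete_features=discrete, random_state=seed
    )
    return pd.Series(mi, index=TABLE2_COLUMNS).sort_values(ascending=False)


def report_frame(y_true, y_pred) -> pd.DataFrame:
    """Per-class precision/recall/F1/support with accuracy and averages."""
    rep = classification_report(
        y_true, y_pred, output_dict=True, zero_division=0
    )
    rows = {}
    for key in sorted(k for k in rep if k not in ("accuracy", "macro avg", "weighted avg")):
        rows[key] = rep[key]
    n = int(sum(r["support"] for r in rows.values()))
    rows["accuracy"] = {
        "precision": np.nan, "recall": np.nan, "f1-score": rep["accuracy"], "support": n,
    }
    rows["macro avg"] = rep["macro avg"]
    rows["weighted avg"] = rep["weighted avg"]
    df = pd.DataFrame(rows).T
    df.columns = ["Precision", "Recall", "F1-Score", "Support"]
    df["Support"] = df["Support"].astype(int)
    return df


def pseudo_label(
    table: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    holdout: float = 0.3,
    min_confidence: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """kNN pseudo-labelling of the unlabelled rows.

    A distance-weighted Euclidean kNN is fitted on the labelled rows; its
    quality is reported on a stratified hold-out fraction of those rows,
    then it is refitted on all labelled rows and every unlabelled row
    receives a pseudo-label (optionally only above ``min_confidence``).
    The kNN works on the coordinate-free feature space: raw locations would
    propagate labels by position rather than by shape and behaviour.
    Existing labels are never altered.  Returns (table with a
    ``pseudo_label`` column, report frame, confusion matrix).
    """
    features = [c for c in TABLE2_COLUMNS if c not in COORDINATE_COLUMNS]
    out = table.copy()
    lab = out[out["label"] != ""]
    if len(lab) == 0:
        raise ValueError("no labelled rows")
    X_lab = lab[features].to_numpy(dtype=float)
    y_lab = lab["label"].to_numpy()

    if holdout > 0 and lab["label"].value_counts().min() >= 2:
        Xtr, Xte, ytr, yte = train_test_split(
            X_lab, y_lab, test_size=holdout, stratify=y_lab, random_state=seed
        )
        knn = KNeighborsClassifier(n_neighbors=min(k, len(Xtr)), weights="distance")
        knn.fit(Xtr, ytr)
        ypred = knn.predict(Xte)
        report = report_frame(yte, ypred)
        cm = confusion_matrix(yte, ypred, labels=sorted(np.unique(y_lab)))
    else:
        report = pd.DataFrame()
        cm = np.zeros((0, 0), dtype=int)

    knn = KNeighborsClassifier(n_neighbors=min(k, len(X_lab)), weights="distance")
    knn.fit(X_lab, y_lab)
    unl = out["label"] == ""
    out["pseudo_label"] = out["label"]
    if unl.any():
        X_unl = out.loc[unl, features].to_numpy(dtype=float)
        pred = knn.predict(X_unl)
        if min_confidence > 0:
            conf = knn.predict_proba(X_unl).max(axis=1)
            pred = np.where(conf >= min_confidence, pred, "")
        out.loc[unl, "pseudo_label"] = pred
    return out, report, cm


def stratified_split(
    table: pd.DataFrame,
    test_fraction: float = 0.3,
    seed: int = 0,
    label_column: str = "pseudo_label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive 70:30 split preserving class proportions."""
    y = table[label_column]
    if y.value_counts().min() < 2:
        raise ValueError("every class needs at least 2 rows to stratify")
    train, test = train_test_split(
        table, test_size=test_fraction, stratify=y, random_state=seed
    )
    return train, test


@dataclass
class ModelBundle:
    """Fitted normalization, schema, pseudo-labeller spec and ensemble."""

    normalizer: FeatureNormalizer
    feature_schema: list[str]
    excluded_features: list[str]
    knn_spec: dict
    classifier: GradientBoostingClassifier
    metadata: dict = dc_field(default_factory=dict)

    @property
    def model_features(self) -> list[str]:
        return [c for c in self.feature_schema if c not in self.excluded_features]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def _validate_schema(table: pd.DataFrame, schema: Sequence[str]) -> None:
    missing = [c for c in schema if c not in table.columns]
    extra = [
        c for c in table.columns
        if c in TABLE2_COLUMNS and c not in schema
    ]
    if missing or extra:
        raise SchemaError(f"schema mismatch: missing={missing} extra={extra}")


def train_ensemble(
    train: pd.DataFrame,
    normalizer: FeatureNormalizer,
    grid: Optional[dict] = None,
    seed: int = 0,
    cv: int = 5,
    label_column: str = "pseudo_label",
    knn_spec: Optional[dict] = None,
) -> ModelBundle:
    """Grid-searched gradient boosting on the coordinate-free feature space.

    Exhaustive grid search with stratified ``cv``-fold cross-validation on
    the training table; ties in mean CV accuracy are broken toward fewer
    trees, then shallower depth, then lower learning rate.  The winning
    model is refitted on the full training set and packaged with the
    normalization parameters and feature schema.
    """
    grid = grid or DEFAULT_GRID
    y = train[label_column].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain at least two classes")
    features = [c for c in TABLE2_COLUMNS if c not in COORDINATE_COLUMNS]
    X = train[features].to_numpy(dtype=float)

    n_splits = min(cv, int(pd.Series(y).value_counts().min()))
    search = GridSearchCV(
        GradientBoostingClassifier(random_state=seed),
        grid,
        cv=StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed),
        scoring="accuracy",
        refit=False,
    )
    search.fit(X, y)
    res = pd.DataFrame(search.cv_results_)
    res = res.sort_values(
        by=["mean_test_score", "param_n_estimators", "param_max_depth", "param_learning_rate"],
        ascending=[False, True, True, True],
        kind="stable",
    )
    best = res.iloc[0]["params"]
    clf = GradientBoostingClassifier(random_state=seed, **best)
    clf.fit(X, y)
    return ModelBundle(
        normalizer=normalizer,
        feature_schema=list(TABLE2_COLUMNS),
        excluded_features=list(COORDINATE_COLUMNS),
        knn_spec=knn_spec or {"k": 5, "metric": "euclidean", "weights": "distance"},
        classifier=clf,
        metadata={
            "seed": seed,
            "split_ratio": "70:30",
            "grid": grid,
            "best_params": dict(best),
            "cv_accuracy": float(res.iloc[0]["mean_test_score"]),
            "n_train": int(len(train)),
        },
    )


def evaluate(
    bundle: ModelBundle, test: pd.DataFrame, label_column: str = "pseudo_label"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classification report + confusion matrix on a held-out table."""
    _validate_schema(test, bundle.feature_schema)
    X = test[bundle.model_features].to_numpy(dtype=float)
    y = test[label_column].to_numpy()
    pred = bundle.classifier.predict(X)
    labels = sorted(np.unique(np.concatenate([y, pred])))
    return report_frame(y, pred), confusion_matrix(y, pred, labels=labels)


def predict_unseen(
    bundle: ModelBundle,
    table: pd.DataFrame,
    seed: Optional[int] = None,
    recompute_survey_features: bool = True,
    return_proba: bool = False,
):
    """Classify a (raw) unseen-survey feature table with a saved bundle.

    The table must carry the trained schema (order-insensitive).  The
    survey-local features — flattened coordinates about the new survey's own
    centroid and the k-means Cluster code — are recomputed per survey (the
    bundle transfers the model, not the site geometry), then the stored
    normalization is applied and the coordinate-free ensemble predicts one
    label per slice.
    """
    _validate_schema(table, bundle.feature_schema)
    out = table.copy()
    if recompute_survey_features:
        centroid = (
            float(out["Geometric center latitude"].mean()),
            float(out["Geometric center longitude"].mean()),
        )
        x, y = flatten_coords(
            out["Geometric center latitude"].to_numpy(),
            out["Geometric center longitude"].to_numpy(),
            centroid,
        )
        out["x"], out["y"] = x, y
        out["Cluster"] = cluster_feature(
            out, k=4, seed=seed if seed is not None else bundle.metadata.get("seed", 0)
        )
    normed = bundle.normalizer.transform(out)
    X = normed[bundle.model_features].to_numpy(dtype=float)
    pred = bundle.classifier.predict(X)
    if return_proba:
        return pred, bundle.classifier.predict_proba(X)
    return pred
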