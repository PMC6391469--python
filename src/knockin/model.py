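"""Random-Forest modelling of HDR knock-in efficiency.

The central object is :class:`HdrEfficiencyModel`, a statsmodels-style model
specification built from a feature matrix (or directly from curated samples
via :meth:`HdrEfficiencyModel.from_samples`).  ``fit()`` returns an
:class:`HdrEfficiencyResults` carrying the fitted forest, out-of-bag (OOB)
error estimates, feature importances and a ``summary()`` table; stratified
cross-validation, prediction and plotting hang off the results object.

Two OOB conventions are computed side by side:

* ``oob_error`` — ensemble-vote OOB misclassification: each sample is
  predicted by majority vote of the trees that did not see it, and the
  error is the fraction misclassified (0.5 ~ random chance for balanced
  classes).  This is the headline number.
* ``oob_error_per_tree`` — the mean over trees of each tree's error on its
  own out-of-bag samples.

Module-level functions expose the evaluation protocol pieces (stratified
5-fold cross-validation, ROC AUC, confusion matrices, the efficiency
improvement statistic, mutation-to-cut distance regression, the model-family
comparison and the centre-outward arm-region sweep) for use without the
class wrapper.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (  # per-tree bootstrap bookkeeping
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from . import features as feat
from .dataset import Sample, labels_array

DEFAULT_N_TREES = 1000
DEFAULT_SEED = 42


# ---------------------------------------------------------------------------
# metric primitives


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (equals the Mann-Whitney rank statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC is undefined with a single class present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def confusion_accuracy(
    predictions: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, float]:
    """2x2 confusion matrix (rows = actual low/high, cols = predicted) and accuracy."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths"
        )
    matrix = _sk_confusion(truth, predictions, labels=[0, 1])
    accuracy = float(np.trace(matrix) / matrix.sum())
    return matrix, accuracy


def improvement_statistic(
    efficiencies: np.ndarray, predicted_high_mask: np.ndarray
) -> float:
    """Percent gain in mean efficiency from model-guided target selection.

    Compares the mean efficiency of the selected (predicted high) targets
    with the mean over all targets: 100 * (mean_selected - mean_all) / mean_all.
    """
    efficiencies = np.asarray(efficiencies, dtype=float)
    mask = np.asarray(predicted_high_mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("the selection mask must pick at least one sample")
    overall = efficiencies.mean()
    if overall == 0:
        raise ValueError("mean efficiency of all targets is zero")
    return float(100.0 * (efficiencies[mask].mean() - overall) / overall)


def distance_regression(
    samples: Sequence[Sample], *, signed: bool = False
) -> tuple[float, float, float]:
    """OLS of HDR efficiency on mutation-to-cut distance: (slope, intercept, R²).

    Uses the absolute distance by default, pooling both sides of the cut;
    ``signed=True`` fits the raw signed distance instead.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a distance regression")
    d = np.array([s.distance for s in samples], dtype=float)
    if not signed:
        d = np.abs(d)
    if np.allclose(d, d[0]):
        raise ValueError("distance has zero variance; regression is undefined")
    y = np.array([s.hdr_eff for s in samples])
    if np.allclose(y, y[0]):
        # constant response: zero slope, R² = 0 (linregress yields NaN here)
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(d, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# forest training


def _per_tree_oob_error(forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray) -> float:
    """Mean over trees of each tree's error on its own out-of-bag samples."""
    n = len(y)
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    errs = []
    for tree in forest.estimators_:
        oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if len(oob_idx) == 0:
            continue
        pred = tree.predict(X[oob_idx])
        errs.append(float(np.mean(pred != y[oob_idx])))
    return float(np.mean(errs)) if errs else float("nan")


@dataclass
class FittedForest:
    """A trained forest with both OOB conventions and named importances."""

    scheme: str
    n_trees: int
    seed: int
    oob_error: float
    oob_error_per_tree: float
    feature_importances: pd.Series
    estimator: RandomForestClassifier = field(repr=False)
    feature_names: tuple[str, ...] = field(repr=False, default=())

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def predict_proba_high(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        idx = list(self.estimator.classes_).index(1)
        return proba[:, idx]


def train_forest(
    X,
    y,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = DEFAULT_SEED,
    *,
    scheme: str = "custom",
    max_features: Union[str, int, float, None] = "sqrt",
) -> FittedForest:
    """Train a Random Forest classifier and estimate its OOB error.

    Square-root feature subsampling and unlimited depth by default; fully
    deterministic under a fixed seed.
    """
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else tuple(
        f"x{i}" for i in range(np.asarray(X).shape[1])
    )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(y) < 10:
        raise ValueError(f"need at least 10 samples to train, got {len(y)}")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    importances = pd.Series(forest.feature_importances_, index=list(names))
    return FittedForest(
        scheme=scheme,
        n_trees=n_trees,
        seed=seed,
        oob_error=float(1.0 - forest.oob_score_),
        oob_error_per_tree=_per_tree_oob_error(forest, X, y),
        feature_importances=importances,
        estimator=forest,
        feature_names=names,
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldMetrics:
    fold: int
    oob_error: float
    roc_auc: float
    precision: float
    recall: float
    correct: int
    n_test: int


@dataclass
class ModelReport:
    """Cross-validated evaluation of one feature scheme.

    Headline metrics are unweighted means over folds; ``correct`` is the
    total number of held-out samples classified correctly across all folds
    (out of ``n``).  ``oob_error`` is the fold-averaged OOB of the five
    training forests; ``oob_error_full`` is the OOB of a forest trained on
    the whole dataset.
    """

    scheme: str
    n_features: int
    n: int
    oob_error: float
    oob_error_full: float
    roc_auc: float
    precision: float
    recall: float
    correct: int
    per_fold: list[FoldMetrics] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_features": self.n_features,
            "oob_error": self.oob_error,
            "oob_error_full": self.oob_error_full,
            "roc_auc": self.roc_auc,
            "precision": self.precision,
            "recall": self.recall,
            "correct": f"{self.correct}/{self.n}",
        }


def make_folds(y, k: int = 5, seed: int = DEFAULT_SEED) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold assignments, reusable across schemes for paired comparison."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def cross_validate(
    X,
    y,
    k: int = 5,
    seed: int = DEFAULT_SEED,
    *,
    n_trees: int = DEFAULT_N_TREES,
    scheme: str = "custom",
    folds: Optional[list[tuple[np.ndarray, np.ndarray]]] = None,
) -> ModelReport:
    """Stratified k-fold evaluation reporting OOB, ROC AUC, precision,
    recall and the total correct count over held-out samples."""
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds is None:
        folds = make_folds(y, k=k, seed=seed)
    per_fold: list[FoldMetrics] = []
    correct_total = 0
    for i, (tr, te) in enumerate(folds):
        fitted = train_forest(Xa[tr], y[tr], n_trees=n_trees, seed=seed, scheme=scheme)
        scores = fitted.predict_proba_high(Xa[te])
        pred = fitted.predict(Xa[te])
        n_correct = int(np.sum(pred == y[te]))
        correct_total += n_correct
        per_fold.append(
            FoldMetrics(
                fold=i,
                oob_error=fitted.oob_error,
                roc_auc=roc_auc(scores, y[te]) if len(np.unique(y[te])) > 1 else float("nan"),
                precision=float(precision_score(y[te], pred, zero_division=0)),
                recall=float(recall_score(y[te], pred, zero_division=0)),
                correct=n_correct,
                n_test=len(te),
            )
        )
    full = train_forest(Xa, y, n_trees=n_trees, seed=seed, scheme=scheme)

    def fold_mean(attr: str) -> float:
        vals = [getattr(f, attr) for f in per_fold]
        return float(np.nanmean(vals))

    return ModelReport(
        scheme=scheme,
        n_features=Xa.shape[1],
        n=len(y),
        oob_error=fold_mean("oob_error"),
        oob_error_full=full.oob_error,
        roc_auc=fold_mean("roc_auc"),
        precision=fold_mean("precision"),
        recall=fold_mean("recall"),
        correct=correct_total,
        per_fold=per_fold,
    )


# ---------------------------------------------------------------------------
# feature-matrix construction from curated samples


def build_feature_matrix(
    samples: Sequence[Sample],
    scheme: str,
    *,
    k: Optional[int] = None,
    include_di: bool = True,
) -> pd.DataFrame:
    """Encode every sample under one scheme into a (n_samples, p) DataFrame."""
    rows = [
        feat.encode_sample(
            s.guide, (s.ssodn, s.center_index), scheme, k=k, include_di=include_di
        )
        for s in samples
    ]
    names = rows[0].names
    for fv in rows[1:]:
        if fv.names != names:
            raise ValueError("inconsistent feature name order across samples")
    return pd.DataFrame(
        [fv.values for fv in rows],
        columns=list(names),
        index=[s.target_id for s in samples],
    )


def run_model_family(
    samples: Sequence[Sample],
    schemes: Sequence[str],
    *,
    k: int = 5,
    seed: int = DEFAULT_SEED,
    n_trees: int = DEFAULT_N_TREES,
    include_di: bool = True,
) -> list[ModelReport]:
    """Evaluate several feature schemes with identical fold assignments."""
    y = labels_array(samples)
    folds = make_folds(y, k=k, seed=seed)
    reports = []
    for scheme in schemes:
        X = build_feature_matrix(samples, scheme, include_di=include_di)
        reports.append(
            cross_validate(
                X, y, k=k, seed=seed, n_trees=n_trees, scheme=scheme, folds=folds
            )
        )
    return reports


def reports_to_frame(reports: Sequence[ModelReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports]).set_index("scheme")


# ---------------------------------------------------------------------------
# centre-outward arm-region sweep


@dataclass
class SweepResult:
    """OOB error of forests trained on donor regions of increasing length.

    Regions start at the edited centre base and extend outward into one arm
    (k = region length in bases).
    """

    side: str
    points: list[tuple[int, float]]

    @property
    def ks(self) -> np.ndarray:
        return np.array([k for k, _ in self.points])

    @property
    def oob_errors(self) -> np.ndarray:
        return np.array([e for _, e in self.points])

    def spearman(self) -> tuple[float, float]:
        """Spearman rho (and p-value) of OOB error against region length."""
        rho, p = stats.spearmanr(self.ks, self.oob_errors)
        return float(rho), float(p)

    def plot(self, ax=None):
        """OOB error against region length (one line per sweep)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ks, self.oob_errors, marker="o", label=f"{self.side} arm")
        ax.set_xlabel("region length from centre (bases)")
        ax.set_ylabel("OOB error")
        ax.legend()
        return ax


def region_sweep_run(
    samples: Sequence[Sample],
    side: str,
    k_min: int = 5,
    k_max: Optional[int] = None,
    *,
    step: int = 1,
    seed: int = DEFAULT_SEED,
    n_trees: int = DEFAULT_N_TREES,
    include_di: bool = True,
) -> SweepResult:
    """Train one forest per centre-outward region length and record its OOB.

    ``k_max`` defaults to the shortest arm on that side across the dataset.
    """
    y = labels_array(samples)
    arm_lengths = [s.arm3 if side == "3prime" else s.arm5_len for s in samples]
    side_max = min(arm_lengths)
    if side_max < k_min:
        raise ValueError(
            f"shortest {side} arm ({side_max} nt) is below the minimum region "
            f"length k_min={k_min}"
        )
    if k_max is None:
        k_max = side_max
    if k_max > side_max:
        raise ValueError(f"k_max={k_max} exceeds the shortest {side} arm ({side_max} nt)")
    scheme = "O2" if side == "3prime" else "O3"
    points = []
    for k in range(k_min, k_max + 1, step):
        X = build_feature_matrix(samples, scheme, k=k, include_di=include_di)
        fitted = train_forest(X, y, n_trees=n_trees, seed=seed, scheme=f"{scheme}[k={k}]")
        points.append((k, fitted.oob_error))
    return SweepResult(side=side, points=points)


# ---------------------------------------------------------------------------
# statsmodels-style façade


class HdrEfficiencyModel:
    """Random-Forest model of high/low HDR efficiency from sequence features.

    Parameters
    ----------
    X : DataFrame or array, shape (n_samples, n_features)
        Feature matrix (one of the composition encodings, or any numeric
        features).
    y : array of {0, 1}
        1 = high-efficiency target (above the dataset median), 0 = low.
    scheme : str
        Name of the encoding used, recorded in reports and manifests.
    n_trees, seed, max_features :
        Forest hyperparameters (defaults: 1000 trees, sqrt feature
        subsampling, seed 42).
    """

    def __init__(
        self,
        X,
        y,
        scheme: str = "custom",
        n_trees: int = DEFAULT_N_TREES,
        seed: int = DEFAULT_SEED,
        max_features: Union[str, int, float, None] = "sqrt",
    ):
        self.X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        self.y = np.asarray(y)
        self.scheme = scheme
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[Sample],
        scheme: str = "M1",
        *,
        k: Optional[int] = None,
        include_di: bool = True,
        **kwargs,
    ) -> "HdrEfficiencyModel":
        """Build the model from curated, labelled samples under one encoding."""
        X = build_feature_matrix(samples, scheme, k=k, include_di=include_di)
        return cls(X, labels_array(samples), scheme=scheme, **kwargs)

    def fit(self) -> "HdrEfficiencyResults":
        fitted = train_forest(
            self.X,
            self.y,
            n_trees=self.n_trees,
            seed=self.seed,
            scheme=self.scheme,
            max_features=self.max_features,
        )
        return HdrEfficiencyResults(self, fitted)

    def cross_validate(self, k: int = 5, seed: Optional[int] = None) -> ModelReport:
        return cross_validate(
            self.X,
            self.y,
            k=k,
            seed=self.seed if seed is None else seed,
            n_trees=self.n_trees,
            scheme=self.scheme,
        )


class HdrEfficiencyResults:
    """Fit results: OOB estimates, importances, prediction and summary."""

    def __init__(self, model: HdrEfficiencyModel, fitted: FittedForest):
        self.model = model
        self._fitted = fitted

    @property
    def oob_error(self) -> float:
        return self._fitted.oob_error

    @property
    def oob_error_per_tree(self) -> float:
        return self._fitted.oob_error_per_tree

    @property
    def feature_importances(self) -> pd.Series:
        return self._fitted.feature_importances

    @property
    def estimator(self) -> RandomForestClassifier:
        return self._fitted.estimator

    def predict(self, X) -> np.ndarray:
        return self._fitted.predict(X)

    def predict_proba_high(self, X) -> np.ndarray:
        return self._fitted.predict_proba_high(X)

    def roc_points(self, X, y) -> pd.DataFrame:
        """ROC curve points (FPR, TPR, threshold) on an evaluation set."""
        fpr, tpr, thr = roc_curve(np.asarray(y), self.predict_proba_high(X))
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    def manifest(self) -> dict:
        """Reproducibility manifest: scheme, hyperparameters, feature order."""
        return {
            "scheme": self.model.scheme,
            "n_trees": self.model.n_trees,
            "seed": self.model.seed,
            "max_features": str(self.model.max_features),
            "feature_names": list(self._fitted.feature_names),
            "n_samples": int(len(self.model.y)),
            "oob_error": self.oob_error,
            "oob_error_per_tree": self.oob_error_per_tree,
        }

    def summary(self, top_features: int = 10) -> str:
        """Human-readable fit summary."""
        lines = [
            "HDR efficiency Random-Forest results",
            "=" * 44,
            f"scheme:             {self.model.scheme}",
            f"samples:            {len(self.model.y)} "
            f"({int(self.model.y.sum())} high / {int((1 - self.model.y).sum())} low)",
            f"features:           {self.model.X.shape[1]}",
            f"trees:              {self.model.n_trees}",
            f"seed:               {self.model.seed}",
            f"OOB error (vote):   {self.oob_error:.3f}",
            f"OOB error (tree):   {self.oob_error_per_tree:.3f}",
            "-" * 44,
            f"top {top_features} feature importances:",
        ]
        top = self.feature_importances.sort_values(ascending=False).head(top_features)
        lines += [f"  {name:<24s} {value:.4f}" for name, value in top.items()]
        return "\n".join(lines)


def save_model(results: HdrEfficiencyResults, path) -> None:
    """Persist a fitted model with its manifest (joblib + embedded JSON)."""
    import joblib

    joblib.dump({"manifest": results.manifest(), "results": results}, path)


def load_model(path, expect_scheme: Optional[str] = None) -> HdrEfficiencyResults:
    """Load a persisted model; refuses a scheme mismatch."""
    import joblib

    payload = joblib.load(path)
    manifest = payload["manifest"]
    if expect_scheme is not None and manifest["scheme"] != expect_scheme:
        raise ValueError(
            f"model file was trained with scheme {manifest['scheme']!r}, "
            f"expected {expect_scheme!r}"
        )
    return payload["results"]
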