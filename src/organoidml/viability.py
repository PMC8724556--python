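"""Linear live/dead organoid classifier with greedy feature selection.

The classifier mirrors the assay's supervised design: organoids from
untreated wells and from a staurosporine-killed positive control are
labeled live/dead, features are standardized, an automated forward
selection picks the discriminative subset by cross-validated accuracy, and
a ridge-regularized linear discriminant is fit on the survivors.  The
signed distance of a sample from the decision boundary, in pooled
within-class standard-deviation units of the training projection, is
reported as the *goodness* (a signal-to-noise ratio); goodness > 0 means
live, and a sample exactly on the boundary is called dead (conservative
for viability claims).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .errors import TrainingError, ValidationError

LIVE = "live"
DEAD = "dead"


def _as_frame(X, feature_names: Sequence[str] | None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=np.float64)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_names))


class ViabilityClassifier(BaseEstimator, ClassifierMixin):
    """Live/dead linear classifier with automated feature selection.

    Parameters
    ----------
    max_features : int
        Upper bound on the number of selected features.
    cv_folds : int
        Stratified cross-validation folds used during selection (reduced
        with a warning when a class has fewer examples than folds).
    cv_repeats : int
        Repetitions of the fold split (different shuffles) averaged into
        each candidate's CV accuracy; damps fold noise so chance-level
        fluctuations do not grow the model.
    min_improvement : float
        Minimum CV-accuracy gain (fraction, default 0.005 = 0.5 percentage
        points) required to add a feature; ties and insufficient gains stop
        the search, so smaller models win.  Chance-level data can therefore
        end with an empty selection, giving a constant (majority-class)
        model.
    shrinkage_grid : tuple of float
        Ridge shrinkage values for the final linear discriminant, chosen by
        the same cross-validation.
    random_state : int
        Seeds every CV split (default 17).

    Attributes (after fit)
    ----------------------
    selected_features_ : list of str, in selection order
    coef_, intercept_ : weights and bias on standardized selected features
    mean_, scale_ : per-selected-feature standardization from training data
    goodness_scale_ : pooled within-class sd of the training projection
    shrinkage_ : chosen shrinkage value
    selection_report_ : DataFrame of the greedy search (feature, cv accuracy)
    ranked_features_ : selected features ordered by |coefficient| (relevance)
    """

    def __init__(
        self,
        max_features: int = 12,
        cv_folds: int = 5,
        cv_repeats: int = 5,
        min_improvement: float = 0.005,
        shrinkage_grid: tuple[float, ...] = (0.0, 1e-3, 1e-2, 1e-1),
        random_state: int = 17,
    ):
        self.max_features = max_features
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.min_improvement = min_improvement
        self.shrinkage_grid = shrinkage_grid
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _lda(shrinkage: float) -> LinearDiscriminantAnalysis:
        return LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=None if shrinkage == 0.0 else shrinkage
        )

    def _cv_accuracy(self, Xs, y, cols, splits, shrinkage=0.0) -> float:
        acc = []
        sub = Xs[:, cols]
        for train_idx, test_idx in splits:
            clf = self._lda(shrinkage)
            clf.fit(sub[train_idx], y[train_idx])
            acc.append(float(np.mean(clf.predict(sub[test_idx]) == y[test_idx])))
        return float(np.mean(acc))

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        import warnings

        frame = _as_frame(X, feature_names)
        y = np.asarray(y, dtype=object)
        if frame.isna().any().any() or not np.all(np.isfinite(frame.to_numpy())):
            raise ValidationError("feature matrix contains non-finite values")
        labels, counts = np.unique(y, return_counts=True)
        if set(labels) != {LIVE, DEAD}:
            raise TrainingError(f"need both 'live' and 'dead' labels, got {list(labels)}")
        if counts.min() < 2:
            raise TrainingError("need at least 2 examples per class")

        names = list(frame.columns)
        Xraw = frame.to_numpy(dtype=np.float64)
        mean = Xraw.mean(axis=0)
        sd = Xraw.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xs = (Xraw - mean) / sd

        n_folds = min(self.cv_folds, int(counts.min()))
        if n_folds < self.cv_folds:
            warnings.warn(f"reducing CV folds from {self.cv_folds} to {n_folds}")

        def make_splits(step: int) -> list:
            # fresh folds every greedy step: the winner's-curse inflation of
            # the previous step's best score does not carry into the next
            # comparison, so chance-level data stops the search early
            splits = []
            for rep in range(self.cv_repeats):
                skf = StratifiedKFold(
                    n_splits=n_folds,
                    shuffle=True,
                    random_state=self.random_state + 1000 * step + rep,
                )
                splits.extend(skf.split(Xs, y))
            return splits

        baseline = float(counts.max() / counts.sum())  # majority-class accuracy
        selected: list[int] = []
        best_acc = baseline
        report_rows = []
        while len(selected) < min(self.max_features, len(names)):
            splits = make_splits(len(selected))
            candidates = [j for j in range(len(names)) if j not in selected]
            scores = [self._cv_accuracy(Xs, y, selected + [j], splits) for j in candidates]
            order = int(np.argmax(scores))  # ties -> first in panel order
            cand, cand_acc = candidates[order], scores[order]
            if cand_acc < best_acc + self.min_improvement:
                break
            selected.append(cand)
            best_acc = cand_acc
            report_rows.append({"feature": names[cand], "cv_accuracy": cand_acc})
        splits = make_splits(len(selected))

        self.classes_ = np.asarray([DEAD, LIVE], dtype=object)
        if selected:
            shrink_scores = [
                self._cv_accuracy(Xs, y, selected, splits, shrinkage=s)
                for s in self.shrinkage_grid
            ]
            self.shrinkage_ = float(self.shrinkage_grid[int(np.argmax(shrink_scores))])
            final = self._lda(self.shrinkage_)
            final.fit(Xs[:, selected], y)
            # classes_ sorted alphabetically: ['dead', 'live'] -> decision > 0 is live
            self.classes_ = final.classes_
            self.coef_ = final.coef_[0].astype(np.float64)
            self.intercept_ = float(final.intercept_[0])
        else:
            # chance-level data: constant majority-class model
            self.shrinkage_ = 0.0
            self.coef_ = np.zeros(0)
            n_live = int((y == LIVE).sum())
            n_dead = int((y == DEAD).sum())
            self.intercept_ = float(np.log(n_live / n_dead)) if n_live != n_dead else 0.0
        self.selected_features_ = [names[j] for j in selected]
        self.mean_ = mean[selected]
        self.scale_ = sd[selected]

        raw_margin = Xs[:, selected] @ self.coef_ + self.intercept_
        pooled = []
        for lab in self.classes_:
            m = raw_margin[y == lab]
            pooled.append(((m - m.mean()) ** 2).sum())
        denom = max(len(y) - 2, 1)
        scale = float(np.sqrt(sum(pooled) / denom))
        self.goodness_scale_ = scale if scale > 0 else 1.0
        self.selection_report_ = pd.DataFrame(report_rows, columns=["feature", "cv_accuracy"])
        order_rel = np.argsort(-np.abs(self.coef_), kind="stable")
        self.ranked_features_ = [self.selected_features_[j] for j in order_rel]
        self.cv_accuracy_ = best_acc
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        return self

    def _standardized(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.selected_features_ if f not in X.columns]
            if missing:
                raise ValidationError(f"input is missing selected features: {missing}")
            sub = X[self.selected_features_].to_numpy(dtype=np.float64)
        elif isinstance(X, dict):
            missing = [f for f in self.selected_features_ if f not in X]
            if missing:
                raise ValidationError(f"input is missing selected features: {missing}")
            sub = np.asarray([[X[f] for f in self.selected_features_]], dtype=np.float64)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=np.float64))
            if X.shape[1] == len(self.selected_features_):
                sub = X
            elif X.shape[1] == self.n_features_in_:
                idx = [list(self.feature_names_in_).index(f) for f in self.selected_features_]
                sub = X[:, idx]
            else:
                raise ValidationError(
                    f"expected {len(self.selected_features_)} (selected) or "
                    f"{self.n_features_in_} (full panel) columns, got {X.shape[1]}"
                )
        return (sub - self.mean_) / self.scale_

    def decision_function(self, X) -> np.ndarray:
        """Goodness: signed margin in pooled within-class sd units (> 0 = live)."""
        Z = self._standardized(X)
        return (Z @ self.coef_ + self.intercept_) / self.goodness_scale_

    def predict(self, X) -> np.ndarray:
        g = self.decision_function(X)
        return np.where(g > 0, LIVE, DEAD).astype(object)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "coef_")
        payload = {
            "features": self.selected_features_,
            "weights": [float(w) for w in self.coef_],
            "bias": self.intercept_,
            "standardize": {
                "mean": [float(m) for m in self.mean_],
                "sd": [float(s) for s in self.scale_],
            },
            "goodness_scale": self.goodness_scale_,
            "shrinkage": self.shrinkage_,
            "seed": self.random_state,
            "training_summary": {
                "cv_accuracy": self.cv_accuracy_,
                "ranked_features": self.ranked_features_,
                "selection": self.selection_report_.to_dict(orient="records"),
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ViabilityClassifier":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        model = cls(random_state=int(d.get("seed", 17)))
        model.selected_features_ = list(d["features"])
        model.coef_ = np.asarray(d["weights"], dtype=np.float64)
        model.intercept_ = float(d["bias"])
        model.mean_ = np.asarray(d["standardize"]["mean"], dtype=np.float64)
        model.scale_ = np.asarray(d["standardize"]["sd"], dtype=np.float64)
        model.goodness_scale_ = float(d["goodness_scale"])
        model.shrinkage_ = float(d.get("shrinkage", 0.0))
        model.classes_ = np.asarray([DEAD, LIVE], dtype=object)
        summary = d.get("training_summary", {})
        model.cv_accuracy_ = float(summary.get("cv_accuracy", float("nan")))
        model.ranked_features_ = list(summary.get("ranked_features", model.selected_features_))
        model.selection_report_ = pd.DataFrame(
            summary.get("selection", []), columns=["feature", "cv_accuracy"]
        )
        model.feature_names_in_ = np.asarray(model.selected_features_, dtype=object)
        model.n_features_in_ = len(model.selected_features_)
        return model


def train_classifier(
    examples: pd.DataFrame,
    label_column: str = "label",
    feature_columns: Sequence[str] | None = None,
    max_features: int = 12,
    cv_folds: int = 5,
    seed: int = 17,
) -> tuple[ViabilityClassifier, pd.DataFrame]:
    """Functional wrapper: fit from a labeled feature table.

    Returns the fitted model and its selection report (features in the
    order they were added, with cross-validated accuracy).
    """
    if feature_columns is None:
        from .features import FEATURE_PANEL

        feature_columns = [c for c in FEATURE_PANEL if c in examples.columns]
        if not feature_columns:
            feature_columns = [
                c for c in examples.columns
                if c != label_column and pd.api.types.is_numeric_dtype(examples[c])
            ]
    model = ViabilityClassifier(max_features=max_features, cv_folds=cv_folds, random_state=seed)
    model.fit(examples[list(feature_columns)], examples[label_column].to_numpy())
    return model, model.selection_report_


def classify(model: ViabilityClassifier, vector) -> tuple[str, float]:
    """Classify one feature vector; returns (label, goodness)."""
    g = float(model.decision_function(vector)[0])
    return (LIVE if g > 0 else DEAD), g
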