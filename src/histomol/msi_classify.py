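"""Pixel-wise PLS-DA classification of tumor MSI spectra.

A partial least squares regression on one-hot class indicators scores every
pixel for each tumor subtype (ccRCC, RO, ChRCC).  Validation is
leave-one-patient-out: all pixels of one patient are held out, a model is
trained on the remaining patients, and the held-out pixels are scored —
patient-level pixel grouping is mandatory, random pixel folds would leak a
patient's spectra into its own training set.

A patient-level diagnosis takes the median pixel score per class; the
class with the highest median wins, and any other class whose median lies
within 10% of the winning median (the margin rule) is reported as
indistinguishable from the winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression

from .msi_preprocess import FeatureMatrix

__all__ = [
    "CLASS_ORDER",
    "PLSDAClassifier",
    "PatientCall",
    "PixelCVResult",
    "fit_plsda",
    "choose_n_components",
    "loo_patient_cv",
    "patient_call",
    "rank_features",
    "pca_scores",
]

CLASS_ORDER = ("ccRCC", "RO", "ChRCC")


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA: PLS2 regression on one-hot labels used as a classifier.

    X and the indicator matrix are mean-centered (no variance scaling);
    components come from the standard iterative PLS2 algorithm.  Prediction
    yields one continuous score per class; ``predict`` takes the argmax.

    Attributes
    ----------
    classes_ : class order of the score columns.
    coef_ : (features x classes) regression coefficients on centered data.
    x_scores_ : training component scores (pixels x components).
    """

    def __init__(self, n_components: int = 5,
                 class_order: Sequence[str] | None = None):
        self.n_components = n_components
        self.class_order = class_order

    def fit(self, X, y):
        X = _values(X)
        y = np.asarray(y)
        present = list(pd.unique(y))
        if len(present) < 2:
            raise ValueError("PLS-DA needs at least two classes")
        if self.class_order is not None:
            order = [c for c in self.class_order if c in present]
            missing = set(present) - set(order)
            if missing:
                raise ValueError(f"labels {missing} absent from class_order")
        else:
            order = [c for c in CLASS_ORDER if c in present] or sorted(present)
        limit = min(X.shape[0] - 1, X.shape[1])
        if not 1 <= self.n_components <= limit:
            raise ValueError(
                f"n_components={self.n_components} outside [1, {limit}] "
                f"for a {X.shape[0]} x {X.shape[1]} training matrix")
        Y = np.column_stack([(y == c).astype(float) for c in order])
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        self._pls.fit(X, Y)
        self.classes_ = np.asarray(order)
        self.coef_ = self._pls.coef_.T  # features x classes
        self.x_scores_ = self._pls.x_scores_
        self.x_mean_ = self._pls._x_mean
        self.y_mean_ = self._pls._y_mean
        return self

    def predict_scores(self, X) -> np.ndarray:
        """Continuous per-class scores (pixels x classes)."""
        return self._pls.predict(_values(X))

    def predict(self, X) -> np.ndarray:
        scores = self.predict_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


def _values(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


def fit_plsda(X, labels, n_components: int = 5,
              class_order: Sequence[str] | None = None) -> PLSDAClassifier:
    """Fit a :class:`PLSDAClassifier` (functional form)."""
    return PLSDAClassifier(n_components, class_order).fit(X, labels)


# ---------------------------------------------------------------------------
# Patient-level call


@dataclass
class PatientCall:
    """Median-score diagnosis for one patient with the margin rule applied."""

    patient_id: str
    median_scores: dict[str, float]
    winner: str
    ambiguous_with: set[str] = field(default_factory=set)
    margin_fraction: float = 0.10
    unclassifiable: bool = False

    @property
    def label(self) -> str:
        """Human-readable call, e.g. ``"RO"`` or ``"RO/ChRCC"``."""
        if self.unclassifiable:
            return "unclassifiable"
        parts = [self.winner] + sorted(self.ambiguous_with,
                                       key=lambda c: -self.median_scores[c])
        return "/".join(parts)


def patient_call(pixel_scores: np.ndarray, class_order: Sequence[str],
                 margin_fraction: float = 0.10,
                 patient_id: str = "") -> PatientCall:
    """Median class scores over a patient's pixels -> winner + ambiguity set.

    The winner is the class with the highest median score; every other class
    whose median lies within ``margin_fraction`` x |winner median| of the
    winner joins the ambiguity set (score differences that small are
    considered indistinguishable).  A non-positive winning median admits no
    meaningful margin and is flagged unclassifiable.
    """
    scores = np.atleast_2d(np.asarray(pixel_scores, dtype=np.float64))
    if scores.shape[0] == 0:
        raise ValueError("patient_call needs at least one pixel")
    if not 0 < margin_fraction < 1:
        raise ValueError("margin_fraction must be in (0, 1)")
    if scores.shape[1] != len(class_order):
        raise ValueError("score columns must match class_order")
    medians = {c: float(np.median(scores[:, j])) for j, c in enumerate(class_order)}
    winner = max(class_order, key=lambda c: medians[c])
    if medians[winner] <= 0:
        return PatientCall(patient_id, medians, winner, set(),
                           margin_fraction, unclassifiable=True)
    cut = margin_fraction * abs(medians[winner])
    ambiguous = {c for c in class_order
                 if c != winner and medians[winner] - medians[c] < cut}
    return PatientCall(patient_id, medians, winner, ambiguous, margin_fraction)


# ---------------------------------------------------------------------------
# Leave-one-patient-out cross-validation


@dataclass
class PixelCVResult:
    """Held-out pixel scores for every patient under LOPO CV."""

    class_order: tuple[str, ...]
    pixels: pd.DataFrame  # patient_id, true_class + one score column per class

    @property
    def predicted(self) -> np.ndarray:
        scores = self.pixels[list(self.class_order)].to_numpy()
        return np.asarray(self.class_order)[np.argmax(scores, axis=1)]

    def pixel_accuracy(self, per_class: bool = True):
        pred = self.predicted
        true = self.pixels["true_class"].to_numpy()
        if not per_class:
            return float(np.mean(pred == true))
        return {c: float(np.mean(pred[true == c] == c))
                for c in self.class_order if np.any(true == c)}

    def save_score_maps(self, patient_id: str, path) -> None:
        """Render one patient's per-class pixel score maps side by side.

        Statistics always use the unsmoothed scores; this rendering is
        purely presentational.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        grp = self.pixels[self.pixels["patient_id"] == patient_id]
        if grp.empty:
            raise KeyError(f"no pixels for patient {patient_id!r}")
        xs, ys = grp["x"].to_numpy(), grp["y"].to_numpy()
        fig, axes = plt.subplots(1, len(self.class_order),
                                 figsize=(3 * len(self.class_order), 3))
        for ax, cls in zip(np.atleast_1d(axes), self.class_order):
            grid = np.full((ys.max(), xs.max()), np.nan)
            grid[ys - 1, xs - 1] = grp[cls].to_numpy()
            im = ax.imshow(grid, origin="lower", cmap="viridis",
                           interpolation="none")
            med = float(np.median(grp[cls]))
            ax.set_title(f"{cls} (median {med:.2f})")
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.suptitle(patient_id)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)

    def patient_calls(self, margin_fraction: float = 0.10) -> dict[str, PatientCall]:
        calls = {}
        for pid, grp in self.pixels.groupby("patient_id", sort=False):
            calls[pid] = patient_call(grp[list(self.class_order)].to_numpy(),
                                      self.class_order, margin_fraction, pid)
        return calls


def loo_patient_cv(X, labels, patient_ids, n_components: int = 5,
                   class_order: Sequence[str] | None = None,
                   coords: Sequence[tuple[int, int]] | None = None,
                   ) -> PixelCVResult:
    """Leave-one-patient-out CV: each patient's pixels scored by a model
    trained on all other patients.

    Every training fold must retain at least two patients per class; a fold
    losing an entire class raises an error naming the class.
    """
    X = _values(X)
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    patients = list(pd.unique(patient_ids))
    if len(patients) < 3:
        raise ValueError("leave-one-patient-out CV needs at least 3 patients")
    patient_class = {p: labels[patient_ids == p][0] for p in patients}
    order = [c for c in (class_order or CLASS_ORDER)
             if c in set(patient_class.values())]

    frames = []
    for held in patients:
        train = patient_ids != held
        train_classes = pd.Series([patient_class[p] for p in patients if p != held])
        counts = train_classes.value_counts()
        for c in order:
            if counts.get(c, 0) == 0:
                raise ValueError(
                    f"holding out {held} removes every patient of class {c!r}")
            if counts.get(c, 0) < 2:
                raise ValueError(
                    f"training fold without {held} keeps <2 patients of class {c!r}")
        model = PLSDAClassifier(n_components, order).fit(X[train], labels[train])
        test = ~train
        scores = model.predict_scores(X[test])
        frame = pd.DataFrame(scores, columns=list(model.classes_))
        frame.insert(0, "true_class", labels[test])
        frame.insert(0, "patient_id", held)
        if coords is not None:
            test_idx = np.flatnonzero(test)
            frame["x"] = [coords[i][0] for i in test_idx]
            frame["y"] = [coords[i][1] for i in test_idx]
        frames.append(frame)
    return PixelCVResult(tuple(order), pd.concat(frames, ignore_index=True))


def choose_n_components(X, labels, patient_ids, max_components: int = 34,
                        class_order: Sequence[str] | None = None,
                        ) -> tuple[int, np.ndarray]:
    """Scan 1..max_components by LOPO CV; return (best count, accuracy curve).

    The optimum maximizes mean per-pixel accuracy; ties go to the smallest
    component count.  The scan is capped at the largest count every training
    fold can support.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    X = _values(X)
    patient_ids = np.asarray(patient_ids)
    if len(pd.unique(patient_ids)) < 3:
        raise ValueError("need at least 3 patients")
    fold_sizes = [np.sum(patient_ids != p) for p in pd.unique(patient_ids)]
    cap = min(min(fold_sizes) - 1, X.shape[1], max_components)
    accuracies = np.zeros(cap)
    for c in range(1, cap + 1):
        res = loo_patient_cv(X, labels, patient_ids, n_components=c,
                             class_order=class_order)
        accuracies[c - 1] = res.pixel_accuracy(per_class=False)
    best = int(np.argmax(accuracies)) + 1  # argmax takes the first = smallest
    return best, accuracies


# ---------------------------------------------------------------------------
# Interpretation helpers


def rank_features(model: PLSDAClassifier) -> dict[str, pd.DataFrame]:
    """Features ranked by signed PLS coefficient, per class, descending.

    A positive coefficient marks presence / higher abundance of that m/z in
    the class; the sort is stable so zero-coefficient features keep their
    axis order.
    """
    out = {}
    for j, cls in enumerate(model.classes_):
        coef = model.coef_[:, j]
        order = np.argsort(-coef, kind="stable")
        out[str(cls)] = pd.DataFrame({
            "feature_index": order,
            "coefficient": coef[order],
        })
    return out


def pca_scores(X, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA scores and explained-variance ratios."""
    from sklearn.decomposition import PCA

    X = _values(X)
    if X.shape[0] <= n_components:
        raise ValueError("need more rows than components")
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix has no principal components")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
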