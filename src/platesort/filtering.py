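"""Removal of non-organism records: hard TOF/EXT cutoffs and a trained
bubble classifier.

The instrument cannot tell organisms from air bubbles or precipitate, so
two cleaning steps are offered.  First, inclusive minimum/maximum cutoffs
on object size (TOF) and optical density (EXT) exclude records outside the
plausible range of the organism.  Second, a support-vector classifier can
be trained per device from a two-plate protocol — one plate of pure
organisms (bubble trap engaged), one plate of pure bubbles (trap
disengaged) — and then used to score every object with a bubble
probability.  Bubbles separate from organisms mainly on optical density
per unit length, so the EXT/TOF ratio is included among the default
features.

Both steps are exposed as scikit-learn style estimators
(:class:`CutoffFilter`, :class:`BubbleClassifier`) plus thin functional
wrappers (:func:`apply_cutoffs`, :func:`train_bubble_classifier`,
:func:`classify_bubbles`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (
    FeatureMissingError,
    InsufficientTrainingDataError,
    InvalidCutoffError,
)
from .io_copas import RawPlate

DEFAULT_FEATURES = ("tof", "ext", "green", "yellow", "red", "ext_tof_ratio")


@dataclass(frozen=True)
class CutoffSpec:
    """Inclusive bounds on TOF and EXT; ``None`` means unbounded."""

    tof_min: float | None = None
    tof_max: float | None = None
    ext_min: float | None = None
    ext_max: float | None = None

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.tof_min, self.tof_max, "tof"),
            (self.ext_min, self.ext_max, "ext"),
        ):
            if lo is not None and lo < 0:
                raise InvalidCutoffError(f"{name}_min must be nonnegative")
            if lo is not None and hi is not None and lo > hi:
                raise InvalidCutoffError(f"inverted {name} bounds: {lo} > {hi}")

    def mask(self, data: pd.DataFrame) -> pd.Series:
        """Boolean keep-mask: True where the record survives the cutoffs."""
        keep = pd.Series(True, index=data.index)
        if self.tof_min is not None:
            keep &= data["tof"] >= self.tof_min
        if self.tof_max is not None:
            keep &= data["tof"] <= self.tof_max
        if self.ext_min is not None:
            keep &= data["ext"] >= self.ext_min
        if self.ext_max is not None:
            keep &= data["ext"] <= self.ext_max
        return keep


class CutoffFilter(BaseEstimator, TransformerMixin):
    """Stateless transformer applying inclusive TOF/EXT cutoffs to a plate."""

    def __init__(
        self,
        tof_min: float | None = None,
        tof_max: float | None = None,
        ext_min: float | None = None,
        ext_max: float | None = None,
    ):
        self.tof_min = tof_min
        self.tof_max = tof_max
        self.ext_min = ext_min
        self.ext_max = ext_max

    def fit(self, X: RawPlate, y=None) -> "CutoffFilter":
        self.spec_ = CutoffSpec(self.tof_min, self.tof_max, self.ext_min, self.ext_max)
        return self

    def transform(self, X: RawPlate) -> RawPlate:
        plate, self.removed_count_ = apply_cutoffs(
            X, CutoffSpec(self.tof_min, self.tof_max, self.ext_min, self.ext_max)
        )
        return plate


def apply_cutoffs(plate: RawPlate, cutoffs: CutoffSpec) -> tuple[RawPlate, int]:
    """Keep exactly the observations inside the cutoff box, order preserved.

    Returns the filtered plate and the number of removed records.
    Comparisons are inclusive at both bounds; records with NaN in a bounded
    channel fail that comparison and are removed.
    """
    keep = cutoffs.mask(plate.data)
    out = plate.with_data(plate.data[keep])
    return out, int(len(plate.data) - len(out.data))


def _feature_frame(data: pd.DataFrame, features: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    for f in features:
        if f == "ext_tof_ratio":
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = data["ext"].to_numpy(float) / data["tof"].to_numpy(float)
            ratio[~np.isfinite(ratio)] = np.nan
            cols[f] = ratio
        elif f in data.columns:
            cols[f] = data[f].to_numpy(float)
        else:
            raise FeatureMissingError(f"feature {f!r} not present in plate")
        if np.all(np.isnan(cols[f])):
            raise FeatureMissingError(f"feature {f!r} is entirely missing")
    return pd.DataFrame(cols, index=data.index)


class BubbleClassifier(BaseEstimator):
    """Two-class bubble-vs-organism classifier trained per device.

    An RBF support-vector machine on standardized features (training-set
    center and spread), following the two-plate training protocol: label
    every record of the pure-organism plate 0 and every record of the
    pure-bubble plate 1.  Decision scores are mapped to [0, 1] by Platt
    scaling — a logistic link fitted to cross-validated decision scores —
    so ``predict_proba`` returns a calibrated bubble probability; an
    object is *flagged* when that probability is strictly greater than
    ``threshold``.

    Parameters
    ----------
    features : ordered feature names; ``ext_tof_ratio`` is computed on the
        fly as EXT/TOF (optical density per unit length).
    threshold : bubble-probability cutoff for drop mode, default 0.5.
    random_state : seed for the held-out split and the SVM's internal
        probability calibration.

    Fitted attributes (trailing underscore) include ``holdout_accuracy_``,
    the accuracy on a stratified 20% held-out split — an honest estimate of
    how separable the two training plates are on the chosen features.
    """

    def __init__(
        self,
        features: tuple[str, ...] = DEFAULT_FEATURES,
        threshold: float = 0.5,
        C: float = 1.0,
        gamma: str | float = "scale",
        random_state: int = 0,
    ):
        self.features = features
        self.threshold = threshold
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def _resolve_features(self, data: pd.DataFrame) -> tuple[str, ...]:
        # with the default feature set, fluorescence channels that are
        # entirely absent are dropped (not every instrument records them);
        # an explicitly requested feature must exist
        defaults = tuple(self.features) == DEFAULT_FEATURES
        resolved = []
        for f in self.features:
            if f == "ext_tof_ratio":
                resolved.append(f)
                continue
            if f not in data.columns:
                raise FeatureMissingError(f"feature {f!r} not present in plate")
            if data[f].isna().all():
                if defaults and f in ("green", "yellow", "red"):
                    continue
                raise FeatureMissingError(f"feature {f!r} is entirely missing")
            resolved.append(f)
        if not resolved:
            raise FeatureMissingError("no usable features")
        return tuple(resolved)

    def fit(self, object_plate: RawPlate, bubble_plate: RawPlate) -> "BubbleClassifier":
        if len(object_plate) == 0 or len(bubble_plate) == 0:
            raise InsufficientTrainingDataError(
                "both training plates must contain records "
                f"(objects: {len(object_plate)}, bubbles: {len(bubble_plate)})"
            )
        feats = self._resolve_features(object_plate.data)
        Xo = _feature_frame(object_plate.data, feats)
        Xb = _feature_frame(bubble_plate.data, feats)
        X = pd.concat([Xo, Xb], ignore_index=True).to_numpy(float)
        y = np.concatenate([np.zeros(len(Xo), int), np.ones(len(Xb), int)])
        finite = np.isfinite(X).all(axis=1)
        X, y = X[finite], y[finite]
        if np.unique(y).size < 2:
            raise InsufficientTrainingDataError("one class vanished after NaN removal")
        if np.allclose(X.std(axis=0), 0):
            warnings.warn("training features have zero variance", stacklevel=2)

        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=0.2, stratify=y, random_state=self.random_state
        )
        scaler = StandardScaler().fit(X_tr)
        Z_tr = scaler.transform(X_tr)
        svm = SVC(C=self.C, gamma=self.gamma, kernel="rbf")
        svm.fit(Z_tr, y_tr)
        # Platt scaling: logistic link on cross-validated decision scores,
        # so the calibration data are out-of-fold for the SVM
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=self.random_state)
        scores = cross_val_predict(
            SVC(C=self.C, gamma=self.gamma, kernel="rbf"),
            Z_tr,
            y_tr,
            cv=cv,
            method="decision_function",
        )
        link = LogisticRegression(C=1e6).fit(scores.reshape(-1, 1), y_tr)

        self.feature_names_ = feats
        self.scaling_center_ = scaler.mean_.copy()
        self.scaling_spread_ = scaler.scale_.copy()
        self.support_vectors_ = svm.support_vectors_.copy()
        self.dual_coef_ = svm.dual_coef_[0].copy()
        self.intercept_ = float(svm.intercept_[0])
        self.gamma_value_ = float(svm._gamma)
        self.platt_a_ = float(link.coef_[0, 0])
        self.platt_b_ = float(link.intercept_[0])

        p_te = self._proba_from_raw(X_te)
        self.holdout_accuracy_ = float(((p_te > 0.5).astype(int) == y_te).mean())
        self.holdout_size_ = int(len(y_te))
        return self

    def _decision_function(self, Z: np.ndarray) -> np.ndarray:
        K = rbf_kernel(Z, self.support_vectors_, gamma=self.gamma_value_)
        return K @ self.dual_coef_ + self.intercept_

    def _proba_from_raw(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.scaling_center_) / self.scaling_spread_
        return expit(self.platt_a_ * self._decision_function(Z) + self.platt_b_)

    def predict_proba(self, plate: RawPlate) -> np.ndarray:
        """Bubble probability in [0, 1] for every observation (NaN features -> NaN)."""
        X = _feature_frame(plate.data, self.feature_names_).to_numpy(float)
        out = np.full(len(X), np.nan)
        finite = np.isfinite(X).all(axis=1)
        if finite.any():
            out[finite] = self._proba_from_raw(X[finite])
        return out

    def predict(self, plate: RawPlate) -> np.ndarray:
        """True where an observation is flagged as a bubble (prob > threshold)."""
        p = self.predict_proba(plate)
        return np.asarray(p > self.threshold)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize to a single self-describing JSON file."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "support_vectors_")
        state = {
            "format": "platesort-bubble-classifier-v1",
            "features": list(self.feature_names_),
            "threshold": self.threshold,
            "C": self.C,
            "gamma": self.gamma if isinstance(self.gamma, str) else float(self.gamma),
            "random_state": self.random_state,
            "holdout_accuracy": self.holdout_accuracy_,
            "holdout_size": self.holdout_size_,
            "scaling": {
                "center": self.scaling_center_.tolist(),
                "spread": self.scaling_spread_.tolist(),
            },
            "svm": {
                "support_vectors": self.support_vectors_.tolist(),
                "dual_coef": self.dual_coef_.tolist(),
                "intercept": self.intercept_,
                "gamma_value": self.gamma_value_,
            },
            "platt": {"a": self.platt_a_, "b": self.platt_b_},
        }
        Path(path).write_text(json.dumps(state, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "BubbleClassifier":
        state = json.loads(Path(path).read_text())
        if state.get("format") != "platesort-bubble-classifier-v1":
            raise ValueError(f"{path}: not a saved bubble classifier")
        clf = cls(
            features=tuple(state["features"]),
            threshold=state["threshold"],
            C=state["C"],
            gamma=state["gamma"],
            random_state=state["random_state"],
        )
        clf.feature_names_ = tuple(state["features"])
        clf.holdout_accuracy_ = state["holdout_accuracy"]
        clf.holdout_size_ = state["holdout_size"]
        clf.scaling_center_ = np.asarray(state["scaling"]["center"], float)
        clf.scaling_spread_ = np.asarray(state["scaling"]["spread"], float)
        clf.support_vectors_ = np.asarray(state["svm"]["support_vectors"], float)
        clf.dual_coef_ = np.asarray(state["svm"]["dual_coef"], float)
        clf.intercept_ = float(state["svm"]["intercept"])
        clf.gamma_value_ = float(state["svm"]["gamma_value"])
        clf.platt_a_ = float(state["platt"]["a"])
        clf.platt_b_ = float(state["platt"]["b"])
        return clf


def train_bubble_classifier(
    object_plate: RawPlate,
    bubble_plate: RawPlate,
    features: tuple[str, ...] | None = None,
    threshold: float = 0.5,
    random_state: int = 0,
) -> BubbleClassifier:
    """Train a :class:`BubbleClassifier` on the two-plate protocol."""
    clf = BubbleClassifier(
        features=tuple(features) if features else DEFAULT_FEATURES,
        threshold=threshold,
        random_state=random_state,
    )
    return clf.fit(object_plate, bubble_plate)


def classify_bubbles(
    plate: RawPlate, clf: BubbleClassifier, mode: str = "annotate"
) -> tuple[RawPlate, int]:
    """Score a plate with a trained classifier.

    ``annotate`` fills ``is_bubble_prob`` for every observation and removes
    nothing; ``drop`` additionally removes observations whose probability
    strictly exceeds the classifier threshold.  Returns the plate and the
    flagged count.
    """
    if mode not in ("annotate", "drop"):
        raise ValueError(f"mode must be 'annotate' or 'drop', got {mode!r}")
    probs = clf.predict_proba(plate)
    data = plate.data.copy()
    data["is_bubble_prob"] = probs
    flagged = np.asarray(probs > clf.threshold)
    if mode == "drop":
        out = plate.with_data(data[~flagged])
    else:
        out = plate.with_data(data)
    return out, int(flagged.sum())
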