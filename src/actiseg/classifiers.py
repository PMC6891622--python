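"""Single-cycle / segment classifiers and sliding-window baselines.

Every classifier maps a 6 x L signal segment to one of C + 1 classes
(C target motion states plus "None") behind a uniform contract:
``fit(segments, labels)``, ``predict_one(segment) -> label``,
``predict_proba_one(segment) -> distribution``.

Two families are provided:

* a convolutional classifier with additive shortcut connections,
  operating on cycles linearly resampled to a fixed 6 x 128 input;
* classical estimators (1-NN, Gaussian naive Bayes, random forest,
  RBF-kernel SVM with grid-searched hyperparameters) on a 41-value
  handcrafted feature vector: per channel the mean, energy (sum of
  squares), variance, interquartile range and the summed level-1 and
  level-2 wavelet detail coefficients, plus the Pearson correlation of
  each adjacent channel pair.

Sliding-window baselines (a set of window lengths, or one fixed
length) turn any such classifier into a detector for comparison with
the anchor-based method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pywt
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import _nn
from .anchors import ScoredDetection, iou, nms
from .io import IntervalAnnotation, SensorSequence, resample_to_length

NONE_LABEL = "None"
N_FEATURES = 41

CLASSICAL_KINDS = ("knn", "nb", "rf", "svm")


# ---------------------------------------------------------------------------
# handcrafted features


def extract_features(segment: np.ndarray, wavelet: str = "db4") -> np.ndarray:
    """41 handcrafted statistics of a 6 x L segment.

    Per channel: mean, energy, variance, interquartile range, summed
    level-1 and level-2 wavelet detail coefficients (36 values), then
    the Pearson correlation of the 5 adjacent channel pairs.
    Zero-variance pairs get correlation 0.
    """
    segment = np.asarray(segment, float)
    if segment.ndim != 2 or segment.shape[0] != 6:
        raise ValueError("segment must be 6 x L")
    if segment.shape[1] < 4:
        raise ValueError("segment must have at least 4 samples")
    feats: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # short-signal DWT levels
        for row in segment:
            q75, q25 = np.percentile(row, [75, 25])
            coeffs = pywt.wavedec(row, wavelet, level=2)
            _, cd2, cd1 = coeffs
            feats.extend([row.mean(), float(np.sum(row ** 2)), row.var(),
                          q75 - q25, float(cd1.sum()), float(cd2.sum())])
    for i in range(5):
        a, b = segment[i], segment[i + 1]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            feats.append(0.0)
        else:
            feats.append(float(np.corrcoef(a, b)[0, 1]))
    return np.array(feats)


# ---------------------------------------------------------------------------
# uniform classifier contract


class CycleClassifier(BaseEstimator):
    """Common surface of all segment classifiers."""

    classes_: list[str]

    def fit(self, segments, labels):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict_proba_one(self, segment) -> np.ndarray:
        raise NotImplementedError

    def predict_proba(self, segments) -> np.ndarray:
        return np.vstack([self.predict_proba_one(s) for s in segments])

    def predict_one(self, segment) -> str:
        dist = self.predict_proba_one(segment)
        return self.classes_[int(np.argmax(dist))]

    def predict(self, segments) -> list[str]:
        return [self.predict_one(s) for s in segments]

    @staticmethod
    def _ordered_classes(labels) -> list[str]:
        # deterministic order, "None" always last when present
        classes = sorted(set(labels) - {NONE_LABEL})
        if NONE_LABEL in set(labels):
            classes.append(NONE_LABEL)
        return classes


class ClassicalCycleClassifier(CycleClassifier):
    """Handcrafted features + a scikit-learn estimator.

    ``kind`` is one of knn (1-nearest-neighbour), nb (Gaussian naive
    Bayes), rf (random forest) or svm (RBF kernel; penalty C and kernel
    width searched on a grid with stratified cross-validation).
    Segments may also be precomputed 41-value feature vectors.
    """

    def __init__(self, kind: str = "svm", knn_k: int = 1,
                 n_trees: int = 200, wavelet: str = "db4",
                 svm_C_grid: tuple = (0.1, 1.0, 10.0, 100.0),
                 svm_gamma_grid: tuple = (0.01, 0.1, 1.0),
                 random_state: int = 0):
        self.kind = kind
        self.knn_k = knn_k
        self.n_trees = n_trees
        self.wavelet = wavelet
        self.svm_C_grid = svm_C_grid
        self.svm_gamma_grid = svm_gamma_grid
        self.random_state = random_state

    def _featurize(self, segment) -> np.ndarray:
        segment = np.asarray(segment, float)
        if segment.ndim == 1:  # already a feature vector
            return segment
        return extract_features(segment, self.wavelet)

    def _make_estimator(self, n_samples: int):
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k)
        if self.kind == "nb":
            return GaussianNB()
        if self.kind == "rf":
            return RandomForestClassifier(n_estimators=self.n_trees,
                                          random_state=self.random_state)
        if self.kind == "svm":
            return SVC(kernel="rbf", probability=True,
                       random_state=self.random_state)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def fit(self, segments, labels):
        labels = list(labels)
        if len(set(labels)) < 2:
            raise ValueError("need at least 2 classes to fit")
        X = np.vstack([self._featurize(s) for s in segments])
        est = self._make_estimator(len(labels))
        if self.kind == "svm":
            cv = StratifiedKFold(3, shuffle=True,
                                 random_state=self.random_state)
            search = GridSearchCV(
                SVC(kernel="rbf", random_state=self.random_state),
                {"C": list(self.svm_C_grid),
                 "gamma": list(self.svm_gamma_grid)},
                cv=cv, n_jobs=1)
            scaler = StandardScaler().fit(X)
            search.fit(scaler.transform(X), labels)
            est = SVC(kernel="rbf", probability=True,
                      random_state=self.random_state, **search.best_params_)
            self.best_params_ = search.best_params_
        self.pipeline_ = Pipeline([("scale", StandardScaler()), ("clf", est)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)  # SVC(probability)
            self.pipeline_.fit(X, labels)
        order = list(self.pipeline_.classes_)
        self.classes_ = self._ordered_classes(labels)
        self._perm = [order.index(c) for c in self.classes_]
        return self

    def predict_proba(self, segments) -> np.ndarray:
        if not hasattr(self, "pipeline_"):
            raise NotFittedError("classifier is not fitted")
        X = np.vstack([self._featurize(s) for s in segments])
        return self.pipeline_.predict_proba(X)[:, self._perm]

    def predict_proba_one(self, segment) -> np.ndarray:
        return self.predict_proba([segment])[0]


class CNNCycleClassifier(CycleClassifier):
    """Convolutional cycle classifier with shortcut connections.

    Inputs are resampled to a fixed 6 x ``input_len`` (128 samples =
    2.56 s at 50 Hz) by per-channel linear interpolation, then pass
    through three strided convolution blocks, each followed by an
    additive-shortcut residual pair, a global average pool and a
    softmax head.  The final layer is zero-initialised, so the loss
    before training is exactly log(C + 1).
    """

    def __init__(self, input_len: int = 128, epochs: int = 30,
                 lr: float = 1e-3, batch_size: int = 32,
                 random_state: int = 0):
        self.input_len = input_len
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.random_state = random_state

    def _build(self, n_classes: int, rng: np.random.Generator) -> None:
        self.net_ = _nn.Sequential(
            _nn.Conv2d(6, 16, (1, 7), stride_w=2, pad_w=3, rng=rng),
            _nn.ReLU(),
            _nn.ResidualBlock(16, rng),
            _nn.Conv2d(16, 24, (1, 5), stride_w=2, pad_w=2, rng=rng),
            _nn.ReLU(),
            _nn.ResidualBlock(24, rng),
            _nn.Conv2d(24, 32, (1, 3), stride_w=2, pad_w=1, rng=rng),
            _nn.ReLU(),
            _nn.ResidualBlock(32, rng),
        )
        self.fc_ = _nn.Linear(32, n_classes, rng=rng)
        self.fc_.W[...] = 0.0

    def _as_input(self, segment) -> np.ndarray:
        segment = np.asarray(segment, float)
        if segment.shape[1] != self.input_len:
            segment = resample_to_length(segment, self.input_len)
        return segment

    def _forward(self, batch: np.ndarray):
        """batch (B, 6, input_len) -> logits (B, n_classes)."""
        feats = self.net_.forward(batch[:, :, None, :])   # (B, 32, 1, w)
        self._gap_width = feats.shape[3]
        pooled = feats.mean(axis=(2, 3))                  # (B, 32)
        return self.fc_.forward(pooled)

    def _backward(self, g_logits: np.ndarray) -> None:
        g_pooled = self.fc_.backward(g_logits)
        B = g_pooled.shape[0]
        g_feats = np.broadcast_to(
            g_pooled[:, :, None, None] / self._gap_width,
            (B, g_pooled.shape[1], 1, self._gap_width)).copy()
        self.net_.backward(g_feats)

    def fit(self, segments, labels):
        labels = list(labels)
        if len(set(labels)) < 2:
            raise ValueError("need at least 2 classes to fit")
        rng = np.random.default_rng(self.random_state)
        self.classes_ = self._ordered_classes(labels)
        self._build(len(self.classes_), rng)
        X = np.stack([self._as_input(s) for s in segments])
        y = np.array([self.classes_.index(l) for l in labels])
        onehot = np.eye(len(self.classes_))[y]
        opt = _nn.Adam(self.net_.parameters() + self.fc_.parameters(),
                       lr=self.lr)
        n = len(X)
        order = np.arange(n)
        self.loss_trace_ = []
        for _epoch in range(self.epochs):
            rng.shuffle(order)
            losses = []
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                self.net_.zero_grad()
                self.fc_.zero_grad()
                logits = self._forward(X[idx])
                loss, g = _nn.softmax_cross_entropy(logits, onehot[idx])
                self._backward(g)
                opt.step()
                losses.append(loss)
            self.loss_trace_.append(float(np.mean(losses)))
        return self

    def predict_proba_one(self, segment) -> np.ndarray:
        if not hasattr(self, "fc_"):
            raise NotFittedError("classifier is not fitted")
        logits = self._forward(self._as_input(segment)[None])
        return _nn.softmax(logits, axis=1)[0]

    def predict_proba(self, segments) -> np.ndarray:
        if not hasattr(self, "fc_"):
            raise NotFittedError("classifier is not fitted")
        X = np.stack([self._as_input(s) for s in segments])
        return _nn.softmax(self._forward(X), axis=1)


def fit_cnn(segments, labels, config: dict | None = None,
            seed: int = 0) -> CNNCycleClassifier:
    return CNNCycleClassifier(random_state=seed, **(config or {})).fit(
        segments, labels)


def fit_classical(kind: str, segments_or_features, labels,
                  random_state: int = 0, **kwargs) -> ClassicalCycleClassifier:
    if kind not in CLASSICAL_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return ClassicalCycleClassifier(kind=kind, random_state=random_state,
                                    **kwargs).fit(segments_or_features, labels)


def make_classifier(kind: str, random_state: int = 0,
                    **kwargs) -> CycleClassifier:
    """Factory over all five kinds: cnn plus the four classical ones."""
    if kind == "cnn":
        return CNNCycleClassifier(random_state=random_state, **kwargs)
    if kind in CLASSICAL_KINDS:
        return ClassicalCycleClassifier(kind=kind, random_state=random_state,
                                        **kwargs)
    raise ValueError(f"unknown classifier kind {kind!r}")


# ---------------------------------------------------------------------------
# sliding-window baselines


@dataclass
class SlidingWindowSpec:
    """Window lengths (samples) and fractional overlap of a baseline."""

    lengths: tuple[int, ...] = (30, 40, 50)
    overlap: float = 0.4

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths):
            raise ValueError("window lengths must be positive")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")

    def stride(self, length: int) -> int:
        return max(1, int(round(length * (1 - self.overlap))))


def window_starts(T: int, length: int, stride: int) -> list[int]:
    if T < length:
        return []
    return list(range(0, T - length + 1, stride))


def sliding_window_baseline(seq: SensorSequence, spec: SlidingWindowSpec,
                            classifiers) -> list[ScoredDetection]:
    """Classify every window of every configured length; windows whose
    best class is not "None" become detections scored by that class
    probability, then NMS (0.3) merges across lengths.

    ``classifiers`` is a single fitted classifier or a dict
    ``{length: classifier}`` (one specially trained per length).
    """
    dets: list[ScoredDetection] = []
    T = seq.n_samples
    for length in spec.lengths:
        clf = classifiers[length] if isinstance(classifiers, dict) \
            else classifiers
        starts = window_starts(T, length, spec.stride(length))
        if not starts:
            continue
        dists = clf.predict_proba([seq.data[:, s:s + length] for s in starts])
        for s, dist in zip(starts, dists):
            k = int(np.argmax(dist))
            label = clf.classes_[k]
            if label == NONE_LABEL:
                continue
            dets.append(ScoredDetection(
                IntervalAnnotation(s, s + length, label),
                score=float(dist[k])))
    return nms(dets, 0.3)


def _window_label_assw(start: int, end: int,
                       anns: list[IntervalAnnotation]) -> str:
    best, best_iou = NONE_LABEL, 0.5
    for a in anns:
        v = iou(start, end, a.start, a.end)
        if v > best_iou:
            best, best_iou = a.label, v
    return best


def _window_label_flsw(start: int, end: int,
                       anns: list[IntervalAnnotation]) -> str:
    # FLSW matching rule: the entire real interval lies inside the window
    contained = [a for a in anns if start <= a.start and a.end <= end]
    if not contained:
        return NONE_LABEL
    return max(contained, key=lambda a: a.length).label


def train_sliding_baseline(records, spec: SlidingWindowSpec,
                           mode: str = "assw", kind: str = "svm",
                           max_none_ratio: float = 2.0,
                           random_state: int = 0):
    """Train baseline classifiers from annotated records.

    ``mode='assw'`` trains one classifier per window length with
    IOU > 0.5 window labeling; ``mode='flsw'`` uses a single length and
    labels a window by the real interval it fully contains.  "None"
    windows are subsampled to at most ``max_none_ratio`` times the
    positive count to keep training sets manageable.
    Returns ``{length: classifier}``.
    """
    if mode not in ("assw", "flsw"):
        raise ValueError("mode must be 'assw' or 'flsw'")
    labeler = _window_label_assw if mode == "assw" else _window_label_flsw
    rng = np.random.default_rng(random_state)
    out = {}
    for length in spec.lengths:
        segs, labels = [], []
        for seq, anns in records:
            for s in window_starts(seq.n_samples, length, spec.stride(length)):
                segs.append(seq.data[:, s:s + length])
                labels.append(labeler(s, s + length, anns))
        pos_idx = [i for i, l in enumerate(labels) if l != NONE_LABEL]
        none_idx = [i for i, l in enumerate(labels) if l == NONE_LABEL]
        cap = int(max_none_ratio * max(len(pos_idx), 1))
        if len(none_idx) > cap:
            none_idx = list(rng.choice(none_idx, size=cap, replace=False))
        keep = sorted(pos_idx + none_idx)
        clf = make_classifier(kind, random_state=random_state)
        clf.fit([segs[i] for i in keep], [labels[i] for i in keep])
        out[length] = clf
    return out
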