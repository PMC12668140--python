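"""Vigilance-state classification from multimodal windowed features.

Pipeline: pooled EEG spectrogram windows → rank-6 non-negative matrix
factorization (NMF) → per-window 8-vector (6 NMF loadings + EMG RMS + accel
RMS) → standardization (training statistics only) → small feedforward
network (one hidden layer of 32 units) → per-window Wake/NREM/REM labels →
15-window persistence filter to eliminate transient state flickers.

Validation is leave-one-subject-out: the NMF basis, standardization
parameters, class balancing, and network weights are all fit on the training
subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.neural_network import MLPClassifier

from .sigproc import Spectrogram
from .synthio import N_STATES, STATE_NAMES

N_NMF = 6
N_FEATURES = 8


@dataclass
class NMFModel:
    """Nonnegative spectral basis (k × frequencies) plus fit metadata."""

    basis: np.ndarray               # (k, n_freqs), >= 0
    frequencies: np.ndarray
    variance_captured: float        # 1 - ||X - WH||^2 / ||X - mean||^2

    def __post_init__(self) -> None:
        if (self.basis < 0).any():
            raise ValueError("NMF basis must be nonnegative")
        if not 0.0 <= self.variance_captured <= 1.0:
            raise ValueError("variance_captured must lie in [0, 1]")


@dataclass
class Hypnogram:
    """Per-window vigilance labels with provenance."""

    labels: np.ndarray              # int codes {0: WAKE, 1: NREM, 2: REM}
    window_centers: np.ndarray      # s
    provenance: str = "raw"         # raw | persistence-filtered | manual

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if not np.isin(self.labels, np.arange(N_STATES)).all():
            raise ValueError("labels must be 3-state codes")

    @property
    def n_windows(self) -> int:
        return self.labels.size

    def state_names(self) -> list[str]:
        return [STATE_NAMES[s] for s in self.labels]


@dataclass
class FeatureMatrix:
    """Per-window 8-dimensional feature vectors aligned to a window grid."""

    features: np.ndarray            # (windows, 8)
    window_centers: np.ndarray
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        if self.features.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features")
        if self.features.shape[0] != self.window_centers.size:
            raise ValueError("rows must align to window grid")


@dataclass
class CVReport:
    """Leave-one-subject-out cross-validation summary."""

    fold_accuracies: list[float]
    overall_accuracy: float
    confusion: np.ndarray           # (3, 3) counts, rows = true state
    subjects: list[str] = field(default_factory=list)


def fit_nmf(spectrograms: list[Spectrogram] | Spectrogram, k: int = N_NMF,
            seed: int = 0, max_iter: int = 400) -> NMFModel:
    """Fit a rank-``k`` NMF to pooled spectrogram rows.

    Variance captured is defined against the mean-centered total:
    1 − ||X − WH||² / ||X − X̄||² (the factorization itself is computed on
    the raw nonnegative X).
    """
    specs = [spectrograms] if isinstance(spectrograms, Spectrogram) else list(spectrograms)
    x = np.vstack([s.power for s in specs])
    if (x < 0).any():
        raise ValueError("spectrogram power must be nonnegative")
    freqs = specs[0].frequencies
    for s in specs[1:]:
        if not np.array_equal(s.frequencies, freqs):
            raise ValueError("spectrogram frequency grids must match")
    model = NMF(n_components=k, init="nndsvda", random_state=seed,
                max_iter=max_iter, tol=1e-5)
    w = model.fit_transform(x)
    h = model.components_
    resid = np.linalg.norm(x - w @ h) ** 2
    total = np.linalg.norm(x - x.mean(axis=0)) ** 2
    # constant rows: nothing to explain beyond the mean -> fully captured
    if total <= 1e-12 * np.linalg.norm(x) ** 2:
        var = 1.0
    else:
        var = 1.0 - resid / total
    return NMFModel(basis=h, frequencies=freqs,
                    variance_captured=float(np.clip(var, 0.0, 1.0)))


def transform_nmf(model: NMFModel, spec: Spectrogram) -> np.ndarray:
    """Project spectrogram windows onto the basis by nonnegative least squares."""
    if not np.array_equal(model.frequencies, spec.frequencies):
        raise ValueError("frequency grid mismatch with NMF basis")
    ht = model.basis.T
    out = np.empty((spec.power.shape[0], model.basis.shape[0]))
    for i, row in enumerate(spec.power):
        out[i], _ = nnls(ht, row)
    return out


def assemble_features(loadings: np.ndarray, emg_rms: np.ndarray,
                      accel_rms: np.ndarray, window_centers: np.ndarray,
                      subject_id: str = "s0") -> FeatureMatrix:
    """Concatenate NMF loadings with EMG and accelerometer RMS (8 columns)."""
    n = loadings.shape[0]
    if not (emg_rms.size == n == accel_rms.size == window_centers.size):
        raise ValueError("inputs must share the window grid")
    feats = np.column_stack([loadings, emg_rms, accel_rms])
    return FeatureMatrix(features=feats, window_centers=np.asarray(window_centers),
                         subject_id=subject_id)


@dataclass
class Standardizer:
    """Per-feature z-scoring with parameters frozen from training data."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        return cls(mean=x.mean(axis=0), sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


def balance_classes(x: np.ndarray, y: np.ndarray,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Downsample every class to the rarest class's count (without replacement)."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = np.concatenate([
        rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
        for c in classes
    ])
    keep.sort()
    return x[keep], y[keep]


def train_classifier(features: np.ndarray, labels: np.ndarray, seed: int = 0,
                     hidden: int = 32, max_iter: int = 500) -> MLPClassifier:
    """Train the feedforward network (one hidden layer of 32 units).

    Fitted with L-BFGS, which is fast and reliable for feature vectors this
    small and avoids the stochastic-solver sensitivity to feature scaling
    and validation-split luck. Deterministic for a fixed seed (weight
    initialization only).
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    if present.size < N_STATES:
        missing = [STATE_NAMES[s] for s in range(N_STATES) if s not in present]
        raise ValueError(f"training data lacks class(es): {missing}")
    clf = MLPClassifier(hidden_layer_sizes=(hidden,), activation="relu",
                        solver="lbfgs", max_iter=max_iter, random_state=seed)
    clf.fit(features, labels)
    return clf


def persistence_filter(h: Hypnogram, min_run: int = 15) -> Hypnogram:
    """Suppress state runs shorter than ``min_run`` windows.

    Scanning left to right, any maximal run shorter than ``min_run`` is
    merged into the preceding surviving state; leading short runs are merged
    into the first surviving state that follows. If no run reaches
    ``min_run``, the longest run's label wins everywhere. Idempotent and
    never introduces labels absent from the input.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    y = h.labels.copy()
    n = y.size
    # run-length encode
    bounds = np.flatnonzero(np.diff(y)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [n]])
    runs = [(y[s], s, e) for s, e in zip(starts, ends)]

    out = np.empty(n, dtype=np.intp)
    current: int | None = None
    pending_start = 0
    for label, s, e in runs:
        if e - s >= min_run:
            if current is None:
                out[:s] = label          # leading short runs -> first survivor
            current = int(label)
            out[s:e] = label
            pending_start = e
        else:
            if current is not None:
                out[s:e] = current
            # else deferred until the first surviving run
            pending_start = e
    if current is None:
        lengths = [e - s for _, s, e in runs]
        label = runs[int(np.argmax(lengths))][0]
        out[:] = label
    return Hypnogram(labels=out, window_centers=h.window_centers,
                     provenance="persistence-filtered")


def loso_cv(sessions: list[tuple[list[Spectrogram] | Spectrogram, np.ndarray,
                                 np.ndarray, Hypnogram, str]] | None = None,
            *, feature_sessions: list[tuple[FeatureMatrix, Hypnogram]] | None = None,
            seed: int = 0, min_run: int = 15,
            spectrograms: list[Spectrogram] | None = None,
            emg_rms: list[np.ndarray] | None = None,
            accel_rms: list[np.ndarray] | None = None,
            labels: list[Hypnogram] | None = None,
            subject_ids: list[str] | None = None) -> CVReport:
    """Leave-one-subject-out cross-validation of the staging pipeline.

    For every held-out subject: fit the NMF basis on the pooled training
    spectrograms, assemble and standardize features with training statistics,
    class-balance by downsampling, train the network, predict the held-out
    subject's windows, and apply the persistence filter before scoring.
    Nothing derived from the held-out subject enters training.

    Sessions are given either as raw per-subject inputs
    (``spectrograms``, ``emg_rms``, ``accel_rms``, ``labels``) or via the
    positional ``sessions`` list of (spectrogram, emg_rms, accel_rms,
    hypnogram, subject_id) tuples.
    """
    if sessions is not None:
        spectrograms = [s[0] for s in sessions]
        emg_rms = [s[1] for s in sessions]
        accel_rms = [s[2] for s in sessions]
        labels = [s[3] for s in sessions]
        subject_ids = [s[4] for s in sessions]
    if spectrograms is None or labels is None:
        raise ValueError("provide sessions or per-subject arrays")
    n_sub = len(spectrograms)
    if n_sub < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(n_sub)]

    fold_acc: list[float] = []
    confusion = np.zeros((N_STATES, N_STATES), dtype=int)
    n_correct = 0
    n_total = 0
    for held in range(n_sub):
        train_idx = [i for i in range(n_sub) if i != held]
        nmf = fit_nmf([spectrograms[i] for i in train_idx], seed=seed)

        def feats_for(i: int) -> np.ndarray:
            ld = transform_nmf(nmf, spectrograms[i])
            return np.column_stack([ld, emg_rms[i], accel_rms[i]])

        x_train = np.vstack([feats_for(i) for i in train_idx])
        y_train = np.concatenate([labels[i].labels for i in train_idx])
        std = Standardizer.fit(x_train)
        x_bal, y_bal = balance_classes(std.transform(x_train), y_train,
                                       seed=seed + held)
        clf = train_classifier(x_bal, y_bal, seed=seed)

        x_test = std.transform(feats_for(held))
        y_pred = clf.predict(x_test)
        pred_h = persistence_filter(
            Hypnogram(labels=y_pred, window_centers=labels[held].window_centers),
            min_run=min_run)
        y_true = labels[held].labels
        ok = int((pred_h.labels == y_true).sum())
        fold_acc.append(ok / y_true.size)
        n_correct += ok
        n_total += y_true.size
        for t, p in zip(y_true, pred_h.labels):
            confusion[t, p] += 1
    return CVReport(fold_accuracies=fold_acc,
                    overall_accuracy=n_correct / n_total,
                    confusion=confusion, subjects=list(subject_ids))
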