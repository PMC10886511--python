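"""Classification of RA vs SA neurotactile events from TFIs, and the ITI /
accuracy ANOVAs.

The classifier follows the transfer-learning recipe used on the platform:
generic early convolutional layers are kept fixed and only the final layers
are trained on the task.  Here the fixed part is a compact two-stage bank
of seeded random convolutional filters with ReLU and max-pooling (random
convolutional features are well-established generic image descriptors),
and the trainable head is a logistic regression fitted by minibatch SGD.
Training runs for a fixed number of epochs; the reported accuracy is the
mean of the final 10 validation evaluations (one per epoch).

Everything is deterministic under a fixed seed; no weight downloads are
required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

__all__ = ["ClassifierConfig", "ClassificationResult", "ITIStats", "TFIClassifier",
           "train_and_validate", "compare_iti_anova", "compare_accuracy_anova",
           "augment_images"]


@dataclass(frozen=True)
class ClassifierConfig:
    input_size: int = 227
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 1e-3
    val_fraction: float = 0.3          # 70 % train / 30 % validation
    augment: bool = True
    n_augment: int = 2                 # augmented copies added per training image
    max_translation: int = 30          # px, horizontal and vertical
    report_last: int = 10              # evaluations averaged into the headline accuracy
    #: repeated-run aggregation: >1 averages the headline accuracy over this
    #: many independent split+training runs (sd then spans run means)
    n_runs: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")


@dataclass(frozen=True)
class ClassificationResult:
    accuracy_mean: float               # %, mean of the final validation evaluations
    accuracy_sd: float                 # %, sd over those evaluations
    per_epoch: tuple                   # validation accuracy (fraction) per epoch
    n_train: int
    n_val: int
    classes: tuple
    seed: int


@dataclass(frozen=True)
class ITIStats:
    f_stat: float
    p_value: float
    significant: bool
    alpha: float
    group_means: tuple
    group_ns: tuple


def _to_array(images) -> np.ndarray:
    if len(images) == 0:
        raise ValueError("empty image set")
    if hasattr(images[0], "pixels"):
        images = [im.pixels for im in images]
    X = np.asarray(images)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError("expected a stack of (H, W, 3) images")
    return X


def _translate(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape[:2]
    xs0, xs1 = max(0, dx), min(w, w + dx)
    ys0, ys1 = max(0, dy), min(h, h + dy)
    out[ys0:ys1, xs0:xs1] = img[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def augment_images(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                   n_copies: int, max_translation: int):
    """Random left-right flips plus random translations up to the limit.

    Returns the originals with ``n_copies`` augmented variants appended.
    """
    outs, labs = [X], [y]
    for _ in range(n_copies):
        batch = np.empty_like(X)
        for i, img in enumerate(X):
            im = img[:, ::-1] if rng.random() < 0.5 else img
            dx, dy = rng.integers(-max_translation, max_translation + 1, size=2)
            batch[i] = _translate(im, int(dx), int(dy))
        outs.append(batch)
        labs.append(y)
    return np.concatenate(outs), np.concatenate(labs)


class TFIClassifier(BaseEstimator, ClassifierMixin):
    """Fixed convolutional feature bank + SGD-trained logistic head.

    Parameters mirror :class:`ClassifierConfig`; the estimator is
    sklearn-compatible (``fit`` / ``predict`` / ``score``) and deterministic
    under ``random_state``.
    """

    def __init__(self, epochs=10, batch_size=16, learning_rate=1e-3,
                 n_filters1=8, n_filters2=16, kernel=5, pool=2, downsample=4,
                 random_state=0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_filters1 = n_filters1
        self.n_filters2 = n_filters2
        self.kernel = kernel
        self.pool = pool
        self.downsample = downsample
        self.random_state = random_state

    # -- fixed feature pathway -------------------------------------------
    def _filters(self):
        rng = np.random.default_rng(self.random_state)
        k = self.kernel
        f1 = rng.standard_normal((self.n_filters1, k, k, 3)).astype(np.float32)
        f1 -= f1.mean(axis=(1, 2, 3), keepdims=True)
        f2 = rng.standard_normal((self.n_filters2, k, k, self.n_filters1)).astype(np.float32)
        f2 -= f2.mean(axis=(1, 2, 3), keepdims=True)
        return f1, f2

    @staticmethod
    def _conv(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
        # x: (H, W, Cin), filt: (Cout, k, k, Cin) -> (H-k+1, W-k+1, Cout)
        k = filt.shape[1]
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
        # win: (H', W', Cin, k, k)
        return np.tensordot(win, filt, axes=([2, 3, 4], [3, 1, 2]))

    @staticmethod
    def _pool(x: np.ndarray, p: int) -> np.ndarray:
        h, w, c = x.shape
        h2, w2 = h // p, w // p
        x = x[: h2 * p, : w2 * p]
        return x.reshape(h2, p, w2, p, c).max(axis=(1, 3))

    def _features_one(self, img: np.ndarray, f1, f2) -> np.ndarray:
        x = img.astype(np.float32) / 255.0
        d = self.downsample
        h, w = (x.shape[0] // d) * d, (x.shape[1] // d) * d
        x = x[:h, :w].reshape(h // d, d, w // d, d, 3).mean(axis=(1, 3))
        x = np.maximum(self._conv(x, f1), 0.0)
        x = self._pool(x, self.pool)
        x = np.maximum(self._conv(x, f2), 0.0)
        x = self._pool(x, self.pool)
        return x.ravel()

    def transform(self, X) -> np.ndarray:
        """Fixed-pathway features for a stack of images."""
        X = _to_array(X)
        f1, f2 = self._filters()
        return np.stack([self._features_one(im, f1, f2) for im in X])

    # -- trainable head ---------------------------------------------------
    def fit(self, X, y, validation=None):
        """Train the head; ``validation=(Xv, yv)`` tracks per-epoch accuracy
        in ``validation_accuracy_``."""
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data must contain at least two classes")
        F = self.transform(X)
        self.mean_ = F.mean(axis=0)
        self.std_ = F.std(axis=0) + 1e-8
        F = (F - self.mean_) / self.std_
        rng = np.random.default_rng(self.random_state)
        self.head_ = SGDClassifier(
            loss="log_loss", learning_rate="constant", eta0=self.learning_rate,
            alpha=1e-4, random_state=int(self.random_state) % (2**31),
        )
        Fv = yv = None
        if validation is not None:
            Xv, yv = validation
            Fv = (self.transform(Xv) - self.mean_) / self.std_
        acc = []
        n = F.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                sel = order[lo : lo + self.batch_size]
                self.head_.partial_fit(F[sel], y[sel], classes=self.classes_)
            if Fv is not None:
                acc.append(float((self.head_.predict(Fv) == yv).mean()))
        self.validation_accuracy_ = tuple(acc)
        return self

    def predict(self, X):
        check_is_fitted(self, "head_")
        F = (self.transform(X) - self.mean_) / self.std_
        return self.head_.predict(F)


def _fit_head(F_train, y_train, F_val, y_val, config, run_seed):
    """Minibatch-SGD logistic head on precomputed features; returns the
    per-epoch validation accuracies."""
    mean = F_train.mean(axis=0)
    std = F_train.std(axis=0) + 1e-8
    Ftr = (F_train - mean) / std
    Fv = (F_val - mean) / std
    classes = np.unique(y_train)
    head = SGDClassifier(loss="log_loss", learning_rate="constant",
                         eta0=config.learning_rate, alpha=1e-4,
                         random_state=int(run_seed) % (2**31))
    rng = np.random.default_rng(run_seed)
    acc = []
    n = Ftr.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            sel = order[lo : lo + config.batch_size]
            head.partial_fit(Ftr[sel], y_train[sel], classes=classes)
        acc.append(float((head.predict(Fv) == y_val).mean()))
    return acc


def train_and_validate(images, labels, config: ClassifierConfig = ClassifierConfig()) -> ClassificationResult:
    """The full per-session classification protocol.

    Stratified 70/30 train/validation split, augmentation (random
    vertical-axis flips, translations up to 30 px) applied to the training
    portion only, 10 training epochs, and the headline accuracy taken as
    the mean over the final 10 validation evaluations.  With
    ``n_runs > 1`` the whole split/train/validate cycle repeats with fresh
    splits and the headline accuracy averages the runs (the reported sd
    then spans run means).  The fixed convolutional features are extracted
    once and shared across runs.
    """
    X = _to_array(images)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes of TFIs")
    proto = TFIClassifier(epochs=config.epochs, batch_size=config.batch_size,
                          learning_rate=config.learning_rate,
                          random_state=config.seed)
    F0 = proto.transform(X)
    F_aug = None
    if config.augment and config.n_augment > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        Xa, _ = augment_images(X, y, rng, config.n_augment, config.max_translation)
        F_aug = proto.transform(Xa[len(X):])  # copies only, originals excluded

    idx = np.arange(len(y))
    run_means, per_epoch, n_train = [], None, 0
    n_val = 0
    for r in range(max(1, config.n_runs)):
        tr, val = train_test_split(idx, test_size=config.val_fraction,
                                   stratify=y, random_state=config.seed + r)
        Ftr, ytr = F0[tr], y[tr]
        if F_aug is not None:
            copies = np.concatenate(
                [F_aug[k * len(y) + tr] for k in range(config.n_augment)])
            Ftr = np.concatenate([Ftr, copies])
            ytr = np.concatenate([ytr] + [y[tr]] * config.n_augment)
        evals = _fit_head(Ftr, ytr, F0[val], y[val], config,
                          np.random.SeedSequence([config.seed, 2, r]).generate_state(1)[0])
        run_means.append(float(np.mean(evals[-config.report_last:])))
        per_epoch = tuple(evals)
        n_train, n_val = len(ytr), len(val)
    run_means = np.asarray(run_means)
    if run_means.size > 1:
        sd = float(run_means.std(ddof=1) * 100.0)
    else:
        last = np.asarray(per_epoch[-config.report_last:])
        sd = float(last.std(ddof=1) * 100.0) if last.size > 1 else 0.0
    return ClassificationResult(
        accuracy_mean=float(run_means.mean() * 100.0),
        accuracy_sd=sd,
        per_epoch=per_epoch,
        n_train=n_train, n_val=n_val,
        classes=tuple(np.unique(y).tolist()), seed=config.seed,
    )


def compare_iti_anova(ra_itis, sa_itis, alpha: float = 0.05) -> ITIStats:
    """Unbalanced one-way ANOVA between RA and SA inter-tap intervals.

    A fixed-effects F-test tolerating unequal group sizes; significance is
    flagged at the given level (default 0.05).
    """
    ra = np.asarray(ra_itis, dtype=float)
    sa = np.asarray(sa_itis, dtype=float)
    if ra.size < 2 or sa.size < 2:
        raise ValueError("each ITI group needs at least two samples")
    pooled = np.concatenate([ra, sa])
    if np.allclose(pooled, pooled[0]):
        raise ZeroDivisionError("zero total variance: the F statistic is undefined")
    f, p = stats.f_oneway(ra, sa)
    return ITIStats(
        f_stat=float(f), p_value=float(p), significant=bool(p < alpha), alpha=alpha,
        group_means=(float(ra.mean()), float(sa.mean())),
        group_ns=(int(ra.size), int(sa.size)),
    )


def compare_accuracy_anova(accuracies_by_mode: dict) -> tuple[float, float]:
    """One-way ANOVA of classification accuracies across embodiment modes.

    ``accuracies_by_mode`` maps a mode label to its replicate accuracies
    (at least two modes with at least two replicates each).  Returns
    ``(F, p)``.
    """
    groups = [np.asarray(v, dtype=float) for v in accuracies_by_mode.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 modes with >= 2 replicate accuracies each")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        raise ZeroDivisionError("zero total variance: the F statistic is undefined")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
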