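"""Single-trial decoding with calibrated RBF support vector machines.

Each trial's channels x samples matrix is flattened channel-major into a
feature vector; features are standardized per *channel* (mean and SD pooled
over all training trials and time points of that channel, N-1 denominator);
an RBF-kernel SVC wrapped in sigmoid (Platt) calibration — with internal
5-fold cross-validation on the training data only — provides calibrated
class probabilities.  Accuracy is estimated with a stratified tenfold
cross-validation for balanced tasks, or ten Monte Carlo resamplings (each
subsampling every class without replacement to the smallest class size,
then a stratified 90/10 split) for unbalanced ones.

Chance level is established empirically by a fold-matched random decoder
(uniform labels over the task's M classes) and a one-sided Wilcoxon
signed-rank test of "real median accuracy > random median accuracy",
Bonferroni-corrected for the number of subjects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats as sps
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .preprocessing import EpochSet
from .stimulus_design import DecodingTask

N_FOLDS = 10
CALIBRATION_FOLDS = 5


# ---------------------------------------------------------------------------
# Feature matrix and z-scoring
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Trials x (channels*samples) features with the index bijection."""

    X: np.ndarray
    n_channels: int
    n_samples: int
    labels: np.ndarray  # (n_trials,) class labels (strings)
    ch_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.shape[1] != self.n_channels * self.n_samples:
            raise ValueError("feature count must equal channels * samples")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("label count must match trials")

    def feature_index(self, feature: int) -> tuple[int, int]:
        """(channel, sample) of a flat feature index (channel-major)."""
        return divmod(feature, self.n_samples)

    def flat_index(self, channel: int, sample: int) -> int:
        return channel * self.n_samples + sample

    def as_epochs_array(self) -> np.ndarray:
        return self.X.reshape(-1, self.n_channels, self.n_samples)

    def select(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[idx], self.n_channels, self.n_samples,
                             self.labels[idx], self.ch_names)


def vectorize(epochs: EpochSet, labels: np.ndarray | None = None) -> FeatureMatrix:
    """Flatten each trial channel-major: all samples of channel 0 first."""
    n, c, s = epochs.data.shape
    if labels is None:
        labels = epochs.stimulus_ids
    return FeatureMatrix(
        X=epochs.data.reshape(n, c * s),
        n_channels=c,
        n_samples=s,
        labels=labels,
        ch_names=list(epochs.ch_names),
    )


def task_labels(task: DecodingTask, stimulus_ids: np.ndarray) -> np.ndarray:
    """Per-trial class labels under a task; excluded trials get ''."""
    out = np.array([task.assign(sid) or "" for sid in stimulus_ids], dtype=object)
    return out


def task_features(epochs: EpochSet, task: DecodingTask) -> FeatureMatrix:
    """Vectorize only the trials that belong to one of the task's classes."""
    labels = task_labels(task, epochs.stimulus_ids)
    mask = labels != ""
    fm = vectorize(epochs, labels)
    return fm.select(np.flatnonzero(mask))


@dataclass
class ZScoreParams:
    """Per-channel standardization moments, fitted on training data only."""

    mu: np.ndarray  # (n_channels,)
    sigma: np.ndarray  # (n_channels,)
    n_channels: int
    n_samples: int
    fitted_on: str = "train"


def zscore_fit(train: FeatureMatrix, fitted_on: str = "train") -> ZScoreParams:
    """Per-channel mean/SD pooled over training trials and time points.

    SD uses the (N_trials * N_samples - 1) denominator.
    """
    data = train.as_epochs_array()  # (n, c, s)
    pooled = data.transpose(1, 0, 2).reshape(train.n_channels, -1)
    mu = pooled.mean(axis=1)
    sigma = pooled.std(axis=1, ddof=1)
    bad = np.flatnonzero(sigma <= 0)
    if bad.size:
        names = ([train.ch_names[i] for i in bad] if train.ch_names
                 else bad.tolist())
        raise ValueError(f"zero variance in channel(s) {names}")
    return ZScoreParams(mu=mu, sigma=sigma, n_channels=train.n_channels,
                        n_samples=train.n_samples, fitted_on=fitted_on)


def zscore_apply(params: ZScoreParams, fm: FeatureMatrix) -> FeatureMatrix:
    if (fm.n_channels, fm.n_samples) != (params.n_channels, params.n_samples):
        raise ValueError("feature geometry does not match fitted parameters")
    data = fm.as_epochs_array()
    out = (data - params.mu[None, :, None]) / params.sigma[None, :, None]
    return FeatureMatrix(out.reshape(fm.X.shape), fm.n_channels, fm.n_samples,
                         fm.labels, fm.ch_names)


# ---------------------------------------------------------------------------
# Calibrated decoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoderSettings:
    C: float = 1.0
    gamma: float | str = "scale"
    calibration_folds: int = CALIBRATION_FOLDS
    calibration_method: str = "sigmoid"


@dataclass
class TrainedDecoder:
    """Calibrated RBF-SVM with recorded class order.

    ``ovr_machines`` holds one plain binary RBF SVC per class (one-vs-rest,
    or a single machine for binary problems), fitted on the same training
    data; the sensitivity-mapping module differentiates these directly.
    """

    model: CalibratedClassifierCV
    classes: np.ndarray
    settings: DecoderSettings
    ovr_machines: list[tuple[str, SVC]] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)

    def state_hash(self) -> str:
        """Hash of the fitted state (support vectors, dual coefs, calibrators)."""
        h = hashlib.sha256()
        for cal in self.model.calibrated_classifiers_:
            est = cal.estimator
            h.update(np.ascontiguousarray(est.support_vectors_).tobytes())
            h.update(np.ascontiguousarray(est.dual_coef_).tobytes())
            h.update(np.ascontiguousarray(est.intercept_).tobytes())
            for c in cal.calibrators:
                h.update(np.float64(c.a_).tobytes())
                h.update(np.float64(c.b_).tobytes())
        return h.hexdigest()


def fit_calibrated_decoder(
    train: FeatureMatrix, settings: DecoderSettings | None = None
) -> TrainedDecoder:
    """Fit the calibrated RBF SVC on a training set.

    Calibration (Platt sigmoid scaling) uses internal stratified
    cross-validation on the training set only.
    """
    settings = settings if settings is not None else DecoderSettings()
    y = train.labels.astype(str)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    base = SVC(kernel="rbf", C=settings.C, gamma=settings.gamma)
    model = CalibratedClassifierCV(
        base, method=settings.calibration_method, cv=settings.calibration_folds
    )
    model.fit(train.X, y)

    ovr: list[tuple[str, SVC]] = []
    if len(classes) == 2:
        svc = SVC(kernel="rbf", C=settings.C, gamma=settings.gamma)
        svc.fit(train.X, y)
        ovr.append((str(classes[1]), svc))
    else:
        for c in classes:
            svc = SVC(kernel="rbf", C=settings.C, gamma=settings.gamma)
            svc.fit(train.X, (y == c).astype(int))
            ovr.append((str(c), svc))
    return TrainedDecoder(model=model, classes=model.classes_, settings=settings,
                          ovr_machines=ovr)


# ---------------------------------------------------------------------------
# Cross-validated accuracy
# ---------------------------------------------------------------------------

@dataclass
class ProbMatrix:
    """Calibrated test-set probabilities of one fold."""

    P: np.ndarray  # (n_test, M)
    true_labels: np.ndarray
    classes: np.ndarray
    fold: int

    def __post_init__(self) -> None:
        if np.any(self.P < 0) or not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must lie on the simplex")


@dataclass
class FoldAccuracies:
    task: str
    subject: str
    accuracies: np.ndarray  # (n_folds,)
    scheme: Literal["tenfold", "monte-carlo-resample", "random"]
    seed: int
    fold_test_sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())


@dataclass
class DecodingRun:
    """Cross-validated decoding output: accuracies plus per-fold probabilities."""

    accuracies: FoldAccuracies
    prob_matrices: list[ProbMatrix]
    fold_true_labels: list[np.ndarray]
    classes: np.ndarray


def _is_balanced(labels: np.ndarray, ratio: float = 1.5) -> bool:
    _, counts = np.unique(labels, return_counts=True)
    return counts.max() <= ratio * counts.min()


def _fit_and_score(
    train: FeatureMatrix, test: FeatureMatrix, settings: DecoderSettings, fold: int
) -> tuple[float, ProbMatrix]:
    params = zscore_fit(train)
    train_z = zscore_apply(params, train)
    test_z = zscore_apply(params, test)
    decoder = fit_calibrated_decoder(train_z, settings)
    pred = decoder.predict(test_z.X)
    acc = float(np.mean(pred == test_z.labels.astype(str)))
    probs = ProbMatrix(
        P=decoder.predict_proba(test_z.X),
        true_labels=test_z.labels.astype(str),
        classes=decoder.classes,
        fold=fold,
    )
    return acc, probs


def crossval_decode(
    features: FeatureMatrix,
    task_name: str = "",
    scheme: Literal["auto", "tenfold", "monte-carlo-resample"] = "auto",
    seed: int = 0,
    settings: DecoderSettings | None = None,
    subject: str = "sim",
    n_folds: int = N_FOLDS,
) -> DecodingRun:
    """Estimate decoding accuracy over ten folds or ten resamplings.

    Standardization and calibration are refitted inside every training fold;
    the test fold never influences any fitted parameter.
    """
    settings = settings if settings is not None else DecoderSettings()
    y = features.labels.astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"class(es) with fewer than {n_folds} trials: "
            f"{dict(zip(classes[counts < n_folds], counts[counts < n_folds]))}"
        )
    if scheme == "auto":
        scheme = "tenfold" if _is_balanced(y) else "monte-carlo-resample"

    accs, probs, trues, sizes = [], [], [], []
    if scheme == "tenfold":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(skf.split(features.X, y)):
            acc, pm = _fit_and_score(features.select(tr), features.select(te),
                                     settings, fold)
            accs.append(acc)
            probs.append(pm)
            trues.append(y[te])
            sizes.append(len(te))
    elif scheme == "monte-carlo-resample":
        rng = np.random.default_rng(seed)
        n_min = counts.min()
        for fold in range(n_folds):
            chosen = np.concatenate([
                rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
                for c in classes
            ])
            sub = features.select(chosen)
            tr, te = train_test_split(
                np.arange(len(chosen)), test_size=0.1,
                stratify=sub.labels.astype(str),
                random_state=int(rng.integers(2**31 - 1)),
            )
            acc, pm = _fit_and_score(sub.select(tr), sub.select(te), settings, fold)
            accs.append(acc)
            probs.append(pm)
            trues.append(sub.labels.astype(str)[te])
            sizes.append(len(te))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    fold_accs = FoldAccuracies(
        task=task_name, subject=subject, accuracies=np.array(accs),
        scheme=scheme, seed=seed, fold_test_sizes=sizes,
    )
    return DecodingRun(accuracies=fold_accs, prob_matrices=probs,
                       fold_true_labels=trues, classes=classes)


def random_decoder(
    fold_true_labels: list[np.ndarray],
    classes: np.ndarray,
    seed: int = 0,
    task_name: str = "",
    subject: str = "sim",
) -> FoldAccuracies:
    """Fold-matched chance decoder: uniform labels over the M classes."""
    rng = np.random.default_rng(seed)
    accs = []
    for true in fold_true_labels:
        pred = rng.choice(classes, size=len(true))
        accs.append(float(np.mean(pred == np.asarray(true))))
    return FoldAccuracies(
        task=task_name, subject=subject, accuracies=np.array(accs),
        scheme="random", seed=seed, fold_test_sizes=[len(t) for t in fold_true_labels],
    )


# ---------------------------------------------------------------------------
# Chance-level statistics
# ---------------------------------------------------------------------------

@dataclass
class ChanceComparison:
    p_value: float
    p_corrected: float
    statistic: float
    degenerate: bool
    shapiro_p_real: float
    shapiro_p_random: float


def compare_to_chance(
    real: FoldAccuracies, random: FoldAccuracies, n_subjects: int = 1
) -> ChanceComparison:
    """One-sided paired Wilcoxon of real vs fold-matched random accuracies.

    Bonferroni multiplies the p-value by the number of subjects (capped at
    1).  Shapiro-Wilk normality of each accuracy set is reported, not used
    as a gate.  If every paired difference is zero the signed-rank statistic
    is undefined; that case is flagged and p is 1.
    """
    a, b = real.accuracies, random.accuracies
    if len(a) != len(b):
        raise ValueError("fold counts differ between real and random decoders")
    diffs = a - b
    degenerate = bool(np.all(diffs == 0))
    if degenerate:
        p, stat = 1.0, 0.0
    else:
        try:
            res = sps.wilcoxon(a, b, alternative="greater", zero_method="wilcox",
                               method="exact")
        except ValueError:
            res = sps.wilcoxon(a, b, alternative="greater", zero_method="wilcox",
                               method="auto")
        p, stat = float(res.pvalue), float(res.statistic)

    def _shapiro(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # constant: trivially non-Gaussian
        return float(sps.shapiro(x).pvalue)

    return ChanceComparison(
        p_value=p,
        p_corrected=min(1.0, p * n_subjects),
        statistic=stat,
        degenerate=degenerate,
        shapiro_p_real=_shapiro(a),
        shapiro_p_random=_shapiro(b),
    )
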