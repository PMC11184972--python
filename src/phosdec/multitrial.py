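"""Multi-trial inference: aggregating calibrated probabilities over trials.

A single EEG trial carries little information, but a percept can be probed
repeatedly.  Given calibrated per-trial class probabilities ``p_{i,k}``
(trial i, class k) for N presentations of the same stimulus class, the
aggregated probability of class k is

    p_k = prod_i (p_{i,k} / p_{i,M})^(1/N)  /  sum_j prod_i (p_{i,j} / p_{i,M})^(1/N)

i.e. a normalized geometric mean of the per-trial probabilities (the
reference-class ratios cancel after normalization; the identity is kept as
a tested invariant).  Evaluation is in log space after epsilon-clipping.

Accuracy-vs-N curves slide an overlapping window of N same-class trials
(stride 1) over each fold's class-shuffled test set and score the argmax of
the aggregate; N=1 reproduces single-trial accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decoding import DecodingRun, ProbMatrix

EPS = 1e-12
DEFAULT_N_RANGE = tuple(range(1, 16))


@dataclass
class AggregatedProb:
    p: np.ndarray  # (M,)
    n_trials: int
    window_trials: list[int] = field(default_factory=list)


def _clip_rows(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("probabilities must be finite")
    P = np.clip(P, EPS, None)
    return P / P.sum(axis=1, keepdims=True)


def aggregate_probabilities(P: np.ndarray, window_trials: list[int] | None = None) -> AggregatedProb:
    """Aggregate one window of per-trial probability rows.

    Implements the reference-class ratio form literally, in log space: with
    r_{i,j} = log p_{i,j} - log p_{i,M}, the aggregate is
    softmax(mean_i r_{i,.}).
    """
    P = _clip_rows(np.atleast_2d(P))
    n, m = P.shape
    logp = np.log(P)
    log_ratio = logp - logp[:, -1][:, None]  # reference class: last (index M)
    s = log_ratio.mean(axis=0)
    s -= s.max()  # numerical guard before exponentiation
    w = np.exp(s)
    return AggregatedProb(p=w / w.sum(), n_trials=n,
                          window_trials=list(window_trials or range(n)))


def geometric_mean_aggregate(P: np.ndarray) -> np.ndarray:
    """Normalized geometric mean of probability rows (reference-free form)."""
    P = _clip_rows(np.atleast_2d(P))
    s = np.log(P).mean(axis=0)
    s -= s.max()
    w = np.exp(s)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Accuracy-vs-N curves
# ---------------------------------------------------------------------------

@dataclass
class AccuracyCurve:
    task: str
    subject: str
    n_values: list[int]
    #: (n_folds, len(n_values)) per-fold accuracy; NaN where no class had
    #: enough trials
    per_fold: np.ndarray
    skipped: list[tuple[int, int, str]] = field(default_factory=list)  # (fold, N, class)

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.per_fold, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fi in range(self.per_fold.shape[0]):
            for ni, n in enumerate(self.n_values):
                rows.append(dict(task=self.task, subject=self.subject, fold=fi,
                                 n_trials=n, accuracy=self.per_fold[fi, ni]))
        return pd.DataFrame(rows)


def _fold_windows(
    pm: ProbMatrix, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Aggregate predictions for all same-class windows of size n in a fold.

    Returns (predicted labels, true labels, classes skipped for lack of
    trials).  Trials are shuffled within class; windows overlap (stride 1).
    """
    preds, trues, skipped = [], [], []
    log_clipped = np.log(_clip_rows(pm.P))
    ref = log_clipped - log_clipped[:, -1][:, None]
    for c in np.unique(pm.true_labels):
        idx = np.flatnonzero(pm.true_labels == c)
        if len(idx) < n:
            skipped.append(str(c))
            continue
        idx = rng.permutation(idx)
        r = ref[idx]  # (n_c, M)
        csum = np.vstack([np.zeros(r.shape[1]), np.cumsum(r, axis=0)])
        window_means = (csum[n:] - csum[:-n]) / n  # (n_c - n + 1, M)
        win_pred = pm.classes[np.argmax(window_means, axis=1)]
        preds.append(win_pred)
        trues.append(np.full(len(win_pred), c, dtype=object))
    if not preds:
        return np.array([]), np.array([]), skipped
    return np.concatenate(preds), np.concatenate(trues), skipped


def multitrial_accuracy(
    run: DecodingRun,
    n_range: tuple[int, ...] = DEFAULT_N_RANGE,
    seed: int = 0,
    task: str = "",
    subject: str = "sim",
) -> AccuracyCurve:
    """Accuracy-vs-N curve over a decoding run's folds.

    Window argmax with N=1 equals the single-trial argmax, so the first
    entry reproduces single-trial accuracy.
    """
    n_values = sorted(n_range)
    per_fold = np.full((len(run.prob_matrices), len(n_values)), np.nan)
    skipped: list[tuple[int, int, str]] = []
    for fi, pm in enumerate(run.prob_matrices):
        rng = np.random.default_rng(seed + 1000 * fi)
        for ni, n in enumerate(n_values):
            preds, trues, skip = _fold_windows(pm, n, rng)
            for c in skip:
                skipped.append((fi, n, c))
            if len(preds):
                per_fold[fi, ni] = float(np.mean(preds == trues))
    return AccuracyCurve(task=task, subject=subject, n_values=n_values,
                         per_fold=per_fold, skipped=skipped)


# ---------------------------------------------------------------------------
# Delta-vs-single regression and confusion matrices
# ---------------------------------------------------------------------------

@dataclass
class DeltaRegression:
    slope: float
    intercept: float
    slope_p: float
    r_value: float
    n_points: int


def accuracy_delta_regression(
    single_acc: np.ndarray, delta: np.ndarray
) -> DeltaRegression:
    """OLS of (multi - single) accuracy deltas on single-trial accuracy.

    Two-sided t-test p-value for a zero slope.
    """
    x = np.asarray(single_acc, dtype=float)
    y = np.asarray(delta, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("single-trial accuracies are constant; slope undefined")
    res = sps.linregress(x, y)
    return DeltaRegression(slope=float(res.slope), intercept=float(res.intercept),
                           slope_p=float(res.pvalue), r_value=float(res.rvalue),
                           n_points=len(x))


def delta_regression_from_curve(curve: AccuracyCurve, n_multi: int = 15) -> DeltaRegression:
    """Regression of per-fold (N=n_multi minus N=1) deltas on N=1 accuracy."""
    i1 = curve.n_values.index(1)
    im = curve.n_values.index(n_multi)
    x = curve.per_fold[:, i1]
    y = curve.per_fold[:, im] - curve.per_fold[:, i1]
    ok = ~np.isnan(x) & ~np.isnan(y)
    return accuracy_delta_regression(x[ok], y[ok])


def confusion_matrices(
    run: DecodingRun, n: int = 1, seed: int = 0
) -> np.ndarray:
    """Row-normalized confusion matrices at window size n, fold-averaged.

    Entry (true, predicted) is the fraction of windows of the true class
    assigned to the predicted class; rows of classes absent from a fold are
    excluded from that fold's normalization.
    """
    classes = run.classes
    m = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    mats = []
    for fi, pm in enumerate(run.prob_matrices):
        rng = np.random.default_rng(seed + 1000 * fi)
        preds, trues, _ = _fold_windows(pm, n, rng)
        if not len(preds):
            continue
        mat = np.zeros((m, m))
        for t, p in zip(trues, preds):
            mat[index[t], index[p]] += 1
        rowsum = mat.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        mats.append(mat / rowsum)
    if not mats:
        raise ValueError(f"no fold produced windows at N={n}")
    return np.mean(mats, axis=0)
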