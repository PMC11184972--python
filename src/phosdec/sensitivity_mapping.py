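"""Sensitivity maps of RBF-SVM decoders: which features drive decisions.

For an RBF kernel machine with decision function

    f(x) = sum_i a_i exp(-gamma * ||x - x_i||^2) + b

(a_i the signed dual coefficients, x_i the support vectors), the partial
derivative with respect to feature j is

    df/dx_j = sum_i a_i * (-2*gamma) * (x_j - x_{ij}) * exp(-gamma * ||x - x_i||^2).

The sensitivity of feature j is the mean over a set of data points of the
squared derivative; reshaped to channels x samples it yields a spatial map
(mean over time per channel) and a temporal map (mean over channels per
sample).  Multi-class decoders average the maps of their one-vs-rest
machines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from .decoding import FeatureMatrix, TrainedDecoder


@dataclass
class SensitivityMap:
    """Non-negative per-feature importance with its channels x samples view."""

    values: np.ndarray  # (n_features,)
    n_channels: int
    n_samples: int
    ch_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_channels * self.n_samples,):
            raise ValueError("map length must equal channels * samples")
        if np.any(self.values < 0):
            raise ValueError("sensitivity values must be non-negative")

    @property
    def grid(self) -> np.ndarray:
        """Channels x samples view (channel-major feature order)."""
        return self.values.reshape(self.n_channels, self.n_samples)


def _check_rbf(svc: SVC) -> float:
    if svc.kernel != "rbf":
        raise ValueError(f"sensitivity mapping requires an RBF kernel, got {svc.kernel!r}")
    return float(svc._gamma)


def decision_gradient(svc: SVC, x: np.ndarray) -> np.ndarray:
    """Analytic gradient of a binary RBF SVC's decision function at x."""
    gamma = _check_rbf(svc)
    x = np.asarray(x, dtype=float).reshape(1, -1)
    sv = svc.support_vectors_
    if x.shape[1] != sv.shape[1]:
        raise ValueError("query dimension does not match the fitted machine")
    alpha = svc.dual_coef_.ravel()  # a_i = alpha_i * y_i
    k = rbf_kernel(x, sv, gamma=gamma).ravel()  # (n_sv,)
    weights = alpha * k
    return -2.0 * gamma * (x.ravel() * weights.sum() - weights @ sv)


def _machine_sensitivity(svc: SVC, X: np.ndarray) -> np.ndarray:
    """Mean squared decision gradient over the rows of X, per feature."""
    gamma = _check_rbf(svc)
    sv = svc.support_vectors_
    alpha = svc.dual_coef_.ravel()
    k = rbf_kernel(X, sv, gamma=gamma)  # (n, n_sv)
    w = k * alpha[None, :]
    grads = -2.0 * gamma * (X * w.sum(axis=1, keepdims=True) - w @ sv)
    return np.mean(grads**2, axis=0)


def sensitivity_map(decoder: TrainedDecoder, data: FeatureMatrix) -> SensitivityMap:
    """Sensitivity map of a trained decoder over a data set.

    Uses the decoder's plain one-vs-rest RBF machines (one for binary
    problems); multi-class maps are the average over classes.
    """
    if data.X.shape[0] == 0:
        raise ValueError("empty data")
    if not decoder.ovr_machines:
        raise ValueError("decoder carries no kernel machines for differentiation")
    maps = [_machine_sensitivity(svc, data.X) for _, svc in decoder.ovr_machines]
    return SensitivityMap(
        values=np.mean(maps, axis=0),
        n_channels=data.n_channels,
        n_samples=data.n_samples,
        ch_names=data.ch_names,
    )


def reduce_map(smap: SensitivityMap) -> tuple[np.ndarray, np.ndarray]:
    """(spatial, temporal) reductions: mean over samples, mean over channels."""
    grid = smap.grid
    return grid.mean(axis=1), grid.mean(axis=0)
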