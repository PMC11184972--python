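"""Class-wise ERP averaging and cluster-based permutation statistics.

The cluster test asks, per channel, whether the single-trial responses of
two or more stimulus classes differ anywhere along the epoch while
controlling the family-wise error over time points.  Recipe: a pointwise
one-way F statistic across classes is thresholded at the F quantile for
``cluster_alpha``; suprathreshold samples form contiguous clusters whose
mass is the summed F; the null distribution is the maximum cluster mass
under random relabelings of the trials, and each observed cluster gets
``p = (1 + #{null >= mass}) / (1 + n_permutations)``.

Channels are tested independently (no spatial clustering), mirroring a
per-channel ERP figure with significance bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocessing import EpochSet


@dataclass
class ERP:
    """Average evoked response of one stimulus class."""

    data: np.ndarray  # (n_channels, n_samples), uV
    class_label: str
    n_trials: int
    ch_names: list[str]
    fs: float
    tmin: float
    subject: str = "sim"


def compute_erp(epochs: EpochSet, class_members: set[str], label: str = "") -> ERP:
    """Mean across the class's trials, per channel and sample."""
    mask = np.isin(epochs.stimulus_ids, sorted(class_members))
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"class {label!r} has no trials in the epoch set")
    return ERP(
        data=epochs.data[mask].mean(axis=0),
        class_label=label,
        n_trials=n,
        ch_names=list(epochs.ch_names),
        fs=epochs.fs,
        tmin=epochs.tmin,
        subject=epochs.subject,
    )


def select_posterior_channels(ch_names: list[str]) -> tuple[list[str], list[str]]:
    """Occipital/parietal channels: names containing an 'O' or a 'P'.

    The rule is literal, case-insensitive substring matching; frontopolar
    names such as 'Fp1' match the 'P' rule and are returned separately as
    flagged ambiguities so callers can exclude them.
    """
    selected = [n for n in ch_names if "o" in n.lower() or "p" in n.lower()]
    flagged = [n for n in selected if n.lower().startswith("fp")]
    if not selected:
        warnings.warn("no posterior channels matched; returning all channels")
        return list(ch_names), []
    return selected, flagged


# ---------------------------------------------------------------------------
# Cluster machinery
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start: int  # sample index, inclusive
    stop: int  # exclusive
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    channel: str
    clusters: list[Cluster]
    n_permutations: int
    cluster_alpha: float
    f_threshold: float

    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _f_statistic(groups: list[np.ndarray]) -> np.ndarray:
    """Pointwise one-way F across groups; each group is (n_i, n_samples)."""
    all_data = np.concatenate(groups, axis=0)
    n_total = all_data.shape[0]
    m = len(groups)
    grand = all_data.mean(axis=0)
    ssb = np.zeros(all_data.shape[1])
    ssw = np.zeros(all_data.shape[1])
    for g in groups:
        mean_g = g.mean(axis=0)
        ssb += g.shape[0] * (mean_g - grand) ** 2
        ssw += ((g - mean_g) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (m - 1)) / (ssw / (n_total - m))
    return np.nan_to_num(f, nan=0.0, posinf=0.0)


def _clusters_from_mask(mask: np.ndarray, values: np.ndarray) -> list[tuple[int, int, float]]:
    """Contiguous True runs as (start, stop, mass) with mass = sum(values)."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return [(int(a), int(b), float(csum[b] - csum[a])) for a, b in zip(starts, stops)]


def _max_cluster_masses(f_matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Per-row maximum cluster mass of a (n_rows, n_samples) F array."""
    p, t = f_matrix.shape
    mask = np.concatenate([f_matrix > threshold, np.zeros((p, 1), bool)], axis=1).ravel()
    vals = np.concatenate([f_matrix, np.zeros((p, 1))], axis=1).ravel()
    padded = np.concatenate([[False], mask])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    masses = csum[stops] - csum[starts]
    out = np.zeros(p)
    np.maximum.at(out, starts // (t + 1), masses)
    return out


def _permuted_f(data: np.ndarray, sizes: np.ndarray, n_permutations: int,
                rng: np.random.Generator) -> np.ndarray:
    """F statistics for random relabelings: (n_permutations, n_samples).

    Vectorized over permutations: per group, a boolean membership matrix is
    multiplied against the data and its square to get group sums.
    """
    n, t = data.shape
    m = len(sizes)
    labels = np.zeros(n, dtype=np.int64)
    edges = np.cumsum(sizes)
    for g in range(1, m):
        labels[edges[g - 1]:edges[g]] = g
    perms = rng.permuted(np.tile(labels, (n_permutations, 1)), axis=1)

    data_sq = data**2
    total_sum = data.sum(axis=0)
    total_sumsq = data_sq.sum(axis=0)
    grand_mean = total_sum / n

    ssb = np.zeros((n_permutations, t))
    ssw_part = np.zeros((n_permutations, t))
    for g in range(m):
        member = (perms == g).astype(data.dtype)  # (P, n)
        s_g = member @ data
        ss_g = member @ data_sq
        n_g = sizes[g]
        ssb += n_g * (s_g / n_g - grand_mean) ** 2
        ssw_part += ss_g - s_g**2 / n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (m - 1)) / (ssw_part / (n - m))
    return np.nan_to_num(f, nan=0.0, posinf=0.0)


def cluster_permutation_test(
    groups: list[np.ndarray],
    channel: str = "",
    n_permutations: int = 1024,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test for one channel.

    ``groups`` holds one (n_trials_i, n_samples) array per class.
    """
    if len(groups) < 2:
        raise ValueError("need at least two classes")
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    sizes = np.array([g.shape[0] for g in groups])
    if np.any(sizes < 2):
        raise ValueError("each class needs at least two trials")
    n, m = int(sizes.sum()), len(groups)
    if n <= m:
        raise ValueError("fewer trials than classes")

    f_threshold = float(sps.f.ppf(1.0 - cluster_alpha, m - 1, n - m))
    f_obs = _f_statistic(groups)
    observed = _clusters_from_mask(f_obs > f_threshold, f_obs)

    rng = np.random.default_rng(seed)
    data = np.concatenate(groups, axis=0)
    f_perm = _permuted_f(data, sizes, n_permutations, rng)
    null_max = _max_cluster_masses(f_perm, f_threshold)

    clusters = [
        Cluster(
            start=a,
            stop=b,
            mass=mass,
            p_value=float((1 + np.sum(null_max >= mass)) / (1 + n_permutations)),
        )
        for a, b, mass in observed
    ]
    return ClusterResult(
        channel=channel,
        clusters=clusters,
        n_permutations=n_permutations,
        cluster_alpha=cluster_alpha,
        f_threshold=f_threshold,
    )


def significance_bands(
    result: ClusterResult, levels: tuple[float, ...] = (0.05, 0.01, 0.001)
) -> dict[int, float]:
    """Map sample index -> strictest significance level met by its cluster."""
    if list(levels) != sorted(levels, reverse=True):
        raise ValueError("levels must be sorted descending")
    bands: dict[int, float] = {}
    for cluster in result.clusters:
        met = [lv for lv in levels if cluster.p_value < lv]
        if not met:
            continue
        strictest = min(met)
        for t in range(cluster.start, cluster.stop):
            bands[t] = min(bands.get(t, 1.0), strictest)
    return bands


# ---------------------------------------------------------------------------
# Task-level analysis
# ---------------------------------------------------------------------------

def erp_cluster_analysis(
    epochs: EpochSet,
    task,
    channels: list[str] | None = None,
    n_permutations: int = 1024,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the per-channel cluster test for every channel of a task.

    Returns a tidy table (channel, cluster start/end in s, mass, p).
    ``channels`` defaults to the posterior ('O'/'P') selection.
    """
    if channels is None:
        channels, _ = select_posterior_channels(epochs.ch_names)
    rows = []
    for k, ch in enumerate(channels):
        ci = epochs.ch_names.index(ch)
        groups = []
        for label, members in task.classes.items():
            mask = np.isin(epochs.stimulus_ids, sorted(members))
            if mask.sum() >= 2:
                groups.append(epochs.data[mask, ci, :])
        if len(groups) < 2:
            continue
        res = cluster_permutation_test(
            groups, channel=ch, n_permutations=n_permutations,
            cluster_alpha=cluster_alpha, seed=seed + k,
        )
        for c in res.clusters:
            rows.append(
                dict(
                    channel=ch,
                    t_start=epochs.tmin + c.start / epochs.fs,
                    t_stop=epochs.tmin + c.stop / epochs.fs,
                    mass=c.mass,
                    p_value=c.p_value,
                )
            )
    return pd.DataFrame(rows, columns=["channel", "t_start", "t_stop", "mass", "p_value"])
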