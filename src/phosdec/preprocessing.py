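"""Preprocessing chain: channel rejection, bandpass filtering, epoching.

The chain is deliberately minimal, matching a real-time use case:

1. drop channels with electrode impedance above 100 kOhm;
2. zero-phase Hamming-window FIR bandpass (0.5-30 Hz) on the continuous
   recording of each session;
3. cut epochs from -0.3 to 0.75 s around each stimulus onset
   (``floor(1.05*fs)`` samples starting ``floor(0.3*fs)`` samples before
   the onset sample);
4. subtract the (-0.3, -0.1) s baseline mean per trial and channel;
5. reject channels whose trial-averaged RMS (aRMS) falls outside the Tukey
   fences ``[q1 - 1.5*IQR, q3 + 1.5*IQR]`` computed across channels.

Sample indexing is 0-based with epoch sample 0 at exactly -0.3 s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import mne
import numpy as np
from scipy.signal import fftconvolve, freqz

from .stimulus_design import EventSchedule, ScheduledEvent
from .synthetic_data import ContinuousRecording, IMPEDANCE_THRESHOLD_KOHM

mne.set_log_level("ERROR")


# ---------------------------------------------------------------------------
# Impedance-based rejection
# ---------------------------------------------------------------------------

def reject_high_impedance(
    recording: ContinuousRecording, threshold_kohm: float = IMPEDANCE_THRESHOLD_KOHM
) -> tuple[ContinuousRecording, list[str]]:
    """Remove channels whose impedance exceeds the threshold.

    Returns the reduced recording and the names of the removed channels.
    """
    imp = recording.layout.impedances
    if imp is None:
        raise ValueError("recording layout carries no impedances")
    keep = imp <= threshold_kohm
    removed = [n for n, k in zip(recording.layout.names, keep) if not k]
    if not np.any(keep):
        raise ValueError("impedance rejection removed every channel")
    out = ContinuousRecording(
        data=recording.data[keep],
        fs=recording.fs,
        layout=recording.layout.subset(keep),
        start_time=recording.start_time,
    )
    return out, removed


# ---------------------------------------------------------------------------
# FIR bandpass
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FIRFilterSpec:
    """Hamming-window FIR bandpass with its derived half-amplitude cutoffs."""

    l_freq: float
    h_freq: float
    fs: float
    l_trans_bandwidth: float
    h_trans_bandwidth: float
    taps: np.ndarray

    @property
    def half_amplitude_cutoffs(self) -> tuple[float, float]:
        """(-6 dB) cutoffs in the middle of each transition band, Hz."""
        return (
            self.l_freq - self.l_trans_bandwidth / 2.0,
            self.h_freq + self.h_trans_bandwidth / 2.0,
        )

    def response(self, freqs: np.ndarray) -> np.ndarray:
        """Magnitude response of the taps at the given frequencies."""
        _, h = freqz(self.taps, worN=np.asarray(freqs, dtype=float), fs=self.fs)
        return np.abs(h)

    def measured_half_amplitude_cutoffs(self, resolution: int = 2**18) -> tuple[float, float]:
        """-6 dB points measured from the realized taps, by interpolation."""
        w, h = freqz(self.taps, worN=resolution, fs=self.fs)
        mag = np.abs(h)
        above = mag > 0.5
        crossings = np.flatnonzero(np.diff(above))
        cuts = []
        for i in crossings:
            # linear interpolation between the two samples around 0.5
            f = w[i] + (0.5 - mag[i]) * (w[i + 1] - w[i]) / (mag[i + 1] - mag[i])
            cuts.append(float(f))
        if len(cuts) < 2:
            raise RuntimeError("could not locate both half-amplitude crossings")
        return (cuts[0], cuts[-1])


def transition_bandwidths(l_freq: float, h_freq: float, fs: float) -> tuple[float, float]:
    """Default transition bandwidths of the window-method design.

    lower = min(max(0.25*l_freq, 2 Hz), l_freq);
    upper = min(max(0.25*h_freq, 2 Hz), fs/2 - h_freq).
    """
    lower = min(max(0.25 * l_freq, 2.0), l_freq)
    upper = min(max(0.25 * h_freq, 2.0), fs / 2.0 - h_freq)
    return lower, upper


def design_bandpass(l_freq: float = 0.5, h_freq: float = 30.0, fs: float = 1000.0) -> FIRFilterSpec:
    """Design the zero-phase Hamming-window FIR bandpass.

    With the defaults (0.5-30 Hz at 1 kHz) the half-amplitude cutoffs are
    0.25 and 33.75 Hz.
    """
    if not (0 < l_freq < h_freq < fs / 2.0):
        raise ValueError(f"invalid band ({l_freq}, {h_freq}) Hz at fs={fs}")
    lower, upper = transition_bandwidths(l_freq, h_freq, fs)
    taps = mne.filter.create_filter(
        None,
        fs,
        l_freq=l_freq,
        h_freq=h_freq,
        l_trans_bandwidth=lower,
        h_trans_bandwidth=upper,
        fir_window="hamming",
        fir_design="firwin",
        phase="zero",
        verbose="ERROR",
    )
    return FIRFilterSpec(
        l_freq=l_freq,
        h_freq=h_freq,
        fs=fs,
        l_trans_bandwidth=lower,
        h_trans_bandwidth=upper,
        taps=np.asarray(taps),
    )


def apply_filter(recording: ContinuousRecording, spec: FIRFilterSpec) -> ContinuousRecording:
    """Apply the FIR bandpass with zero net group delay.

    The symmetric odd-length taps are applied in a single pass and the
    linear-phase delay is compensated, so the output is aligned with the
    input.  Edges are padded with the edge value to limit transients.
    """
    if recording.fs != spec.fs:
        raise ValueError("filter was designed for a different sampling rate")
    n_taps = len(spec.taps)
    if recording.n_samples <= n_taps:
        raise ValueError(
            f"recording ({recording.n_samples} samples) shorter than filter ({n_taps} taps)"
        )
    pad = n_taps // 2
    padded = np.pad(recording.data, ((0, 0), (pad, pad)), mode="edge")
    filtered = fftconvolve(padded, spec.taps[None, :], mode="same", axes=1)
    filtered = filtered[:, pad:-pad]
    return ContinuousRecording(
        data=filtered, fs=recording.fs, layout=recording.layout,
        start_time=recording.start_time,
    )


# ---------------------------------------------------------------------------
# Epoching and baseline correction
# ---------------------------------------------------------------------------

EPOCH_TMIN_S = -0.3
EPOCH_TMAX_S = 0.75
BASELINE_WINDOW_S = (-0.3, -0.1)


@dataclass
class EpochSet:
    """Baseline-correctable trials x channels x samples, with labels."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), uV
    fs: float
    ch_names: list[str]
    stimulus_ids: np.ndarray  # (n_trials,) of str
    tmin: float = EPOCH_TMIN_S
    sessions: np.ndarray | None = None
    subject: str = "sim"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match channel names")
        if self.data.shape[0] != len(self.stimulus_ids):
            raise ValueError("trial axis does not match stimulus ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epochs contain non-finite samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.fs

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            ch_names=list(self.ch_names),
            stimulus_ids=self.stimulus_ids[mask],
            tmin=self.tmin,
            sessions=None if self.sessions is None else self.sessions[mask],
            subject=self.subject,
        )

    def select_channels(self, names: list[str]) -> "EpochSet":
        idx = [self.ch_names.index(n) for n in names]
        return EpochSet(
            data=self.data[:, idx, :],
            fs=self.fs,
            ch_names=list(names),
            stimulus_ids=self.stimulus_ids,
            tmin=self.tmin,
            sessions=self.sessions,
            subject=self.subject,
        )

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        np.save(stem.with_suffix(".npy"), self.data)
        meta = dict(
            fs=self.fs,
            ch_names=self.ch_names,
            stimulus_ids=self.stimulus_ids.tolist(),
            tmin=self.tmin,
            sessions=None if self.sessions is None else self.sessions.tolist(),
            subject=self.subject,
        )
        with open(stem.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, stem: str | Path) -> "EpochSet":
        stem = Path(stem)
        data = np.load(stem.with_suffix(".npy"))
        with open(stem.with_suffix(".json")) as fh:
            meta = json.load(fh)
        return cls(
            data=data,
            fs=meta["fs"],
            ch_names=meta["ch_names"],
            stimulus_ids=np.array(meta["stimulus_ids"]),
            tmin=meta["tmin"],
            sessions=None if meta["sessions"] is None else np.array(meta["sessions"]),
            subject=meta["subject"],
        )


def epoch_n_samples(fs: float) -> int:
    """floor(1.05 * fs) samples per epoch."""
    return int(np.floor(1.05 * fs))


def extract_epochs(
    recording: ContinuousRecording,
    events: list[ScheduledEvent] | EventSchedule,
    session: int | None = None,
    subject: str = "sim",
) -> EpochSet:
    """Cut (-0.3, 0.75) s epochs around stimulus onsets.

    An epoch for onset time ``T`` covers samples
    ``floor(T*fs) - floor(0.3*fs)`` through the following
    ``floor(1.05*fs) - 1``.  Events whose windows fall outside the
    recording are dropped with a warning.
    """
    if isinstance(events, EventSchedule):
        sessions = events.sessions
        if session is None:
            if len(sessions) != 1:
                raise ValueError("schedule covers several sessions; pass session=")
            session = sessions[0]
        events = events.session_events(session)
    fs = recording.fs
    n_samp = epoch_n_samples(fs)
    pre = int(np.floor(0.3 * fs))
    data, ids, sess = [], [], []
    n_dropped = 0
    for ev in events:
        start = int(np.floor(ev.onset * fs)) - pre
        stop = start + n_samp
        if start < 0 or stop > recording.n_samples:
            n_dropped += 1
            continue
        data.append(recording.data[:, start:stop])
        ids.append(ev.stimulus_id)
        sess.append(ev.session)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} truncated epochs at recording edges")
    if not data:
        raise ValueError("no epochs could be extracted")
    return EpochSet(
        data=np.stack(data),
        fs=fs,
        ch_names=list(recording.layout.names),
        stimulus_ids=np.array(ids),
        sessions=np.array(sess),
        subject=subject,
    )


def concatenate_epochs(parts: list[EpochSet]) -> EpochSet:
    """Pool epochs from several sessions (identical channels and fs)."""
    first = parts[0]
    for p in parts[1:]:
        if p.ch_names != first.ch_names or p.fs != first.fs:
            raise ValueError("epoch sets differ in channels or sampling rate")
    return EpochSet(
        data=np.concatenate([p.data for p in parts]),
        fs=first.fs,
        ch_names=list(first.ch_names),
        stimulus_ids=np.concatenate([p.stimulus_ids for p in parts]),
        tmin=first.tmin,
        sessions=(
            None
            if any(p.sessions is None for p in parts)
            else np.concatenate([p.sessions for p in parts])
        ),
        subject=first.subject,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial/channel's (-0.3, -0.1) s baseline mean."""
    if abs(epochs.tmin - EPOCH_TMIN_S) > 1e-9:
        raise ValueError("epoch window must start at -0.3 s")
    n_base = int(np.floor(0.2 * epochs.fs))
    baseline = epochs.data[:, :, :n_base].mean(axis=2, keepdims=True)
    return EpochSet(
        data=epochs.data - baseline,
        fs=epochs.fs,
        ch_names=list(epochs.ch_names),
        stimulus_ids=epochs.stimulus_ids,
        tmin=epochs.tmin,
        sessions=epochs.sessions,
        subject=epochs.subject,
    )


# ---------------------------------------------------------------------------
# aRMS channel rejection
# ---------------------------------------------------------------------------

@dataclass
class ChannelStats:
    """Per-channel trial-averaged RMS and its Tukey fences."""

    ch_names: list[str]
    arms: np.ndarray
    q1: float
    q3: float
    quartile_method: str = "linear"

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def fences(self) -> tuple[float, float]:
        return (self.q1 - 1.5 * self.iqr, self.q3 + 1.5 * self.iqr)


def compute_arms(epochs: EpochSet, quartile_method: str = "linear") -> ChannelStats:
    """Average over trials of the per-trial RMS over time, per channel.

    ``quartile_method`` selects the quartile convention for the fences:
    numpy's ``linear`` interpolation (default) or Tukey ``hinges``
    (``midpoint``).
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    rms = np.sqrt(np.mean(epochs.data**2, axis=2))  # (trials, channels)
    arms = rms.mean(axis=0)
    method = {"linear": "linear", "hinges": "midpoint"}[quartile_method]
    q1, q3 = np.quantile(arms, [0.25, 0.75], method=method)
    return ChannelStats(
        ch_names=list(epochs.ch_names),
        arms=arms,
        q1=float(q1),
        q3=float(q3),
        quartile_method=quartile_method,
    )


def reject_outlier_channels(stats: ChannelStats) -> tuple[np.ndarray, list[str]]:
    """Mask of channels to keep, plus the names of rejected outliers.

    A channel is rejected iff its aRMS lies strictly outside
    ``[q1 - 1.5*IQR, q3 + 1.5*IQR]``.
    """
    if len(stats.arms) < 4:
        raise ValueError("need at least 4 channels for quartile fences")
    low, high = stats.fences
    keep = (stats.arms >= low) & (stats.arms <= high)
    if not np.any(keep):
        raise ValueError("aRMS rejection removed every channel")
    removed = [n for n, k in zip(stats.ch_names, keep) if not k]
    return keep, removed


def apply_channel_mask(epochs: EpochSet, keep: np.ndarray) -> EpochSet:
    names = [n for n, k in zip(epochs.ch_names, keep) if k]
    return epochs.select_channels(names)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class PreprocessReport:
    removed_impedance: list[str] = field(default_factory=list)
    removed_arms: list[str] = field(default_factory=list)
    n_epochs: int = 0
    filter_cutoffs: tuple[float, float] | None = None


def preprocess_sessions(
    recordings: dict[int, ContinuousRecording],
    schedule: EventSchedule,
    l_freq: float = 0.5,
    h_freq: float = 30.0,
    subject: str = "sim",
) -> tuple[EpochSet, PreprocessReport]:
    """Run the full chain on one subject's per-session recordings.

    Impedance rejection and filtering are per session; epochs from all
    sessions are pooled before the aRMS rejection (the aRMS statistic is
    indexed by channel and subject only).
    """
    report = PreprocessReport()
    parts = []
    for session, rec in sorted(recordings.items()):
        if rec.layout.impedances is not None:
            rec, removed = reject_high_impedance(rec)
            report.removed_impedance = sorted(set(report.removed_impedance) | set(removed))
        spec = design_bandpass(l_freq, h_freq, rec.fs)
        report.filter_cutoffs = spec.half_amplitude_cutoffs
        rec = apply_filter(rec, spec)
        parts.append(extract_epochs(rec, schedule, session=session, subject=subject))
    epochs = concatenate_epochs(parts)
    epochs = baseline_correct(epochs)
    stats = compute_arms(epochs)
    keep, removed = reject_outlier_channels(stats)
    report.removed_arms = removed
    epochs = apply_channel_mask(epochs, keep)
    report.n_epochs = epochs.n_trials
    return epochs, report
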