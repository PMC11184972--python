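"""End-to-end synthetic studies at desk scale.

The full experimental design (128 channels at 1 kHz, 3000 presentations of
60 stimuli) is expensive to simulate repeatedly, so the canned studies here
run a scaled version — fewer channels, lower sampling rate, fewer trials —
while exercising every stage: schedule, synthesis, impedance rejection,
filtering, epoching, baseline, aRMS rejection, decoding, chance statistics,
and multi-trial aggregation.  The scaled defaults are 32 channels at
250 Hz with 300 trials for a binary task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .decoding import (
    ChanceComparison,
    DecoderSettings,
    DecodingRun,
    FoldAccuracies,
    compare_to_chance,
    crossval_decode,
    random_decoder,
    task_features,
)
from .multitrial import AccuracyCurve, multitrial_accuracy
from .preprocessing import EpochSet, PreprocessReport, preprocess_sessions
from .stimulus_design import (
    DecodingTask,
    EventSchedule,
    ScheduledEvent,
    StimulusRegistry,
    build_stimulus_registry,
    build_task_registry,
)
from .synthetic_data import (
    ErpEffectParams,
    NoiseParams,
    make_channel_layout,
    simulate_impedances,
    synthesize_recording,
)


@dataclass(frozen=True)
class ScaledStudyConfig:
    """Problem sizes and physics of a scaled synthetic study."""

    n_channels: int = 32
    fs: float = 250.0
    n_trials: int = 300
    n_bad_channels: int = 2
    effect_scale: float = 1.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    erp: ErpEffectParams = field(default_factory=ErpEffectParams)
    settings: DecoderSettings = field(default_factory=DecoderSettings)
    lead_in: float = 2.0

    def effect(self) -> ErpEffectParams:
        return self.erp.scaled(self.effect_scale)


def make_custom_schedule(
    stimulus_ids_per_class: dict[str, list[str]],
    n_trials: int,
    seed: int = 0,
    lead_in: float = 2.0,
) -> EventSchedule:
    """Single-session schedule with trials split evenly across classes.

    Within a class, presentations cycle through the class's stimuli so each
    stimulus is shown a near-equal number of times.
    """
    rng = np.random.default_rng(seed)
    classes = sorted(stimulus_ids_per_class)
    per_class = n_trials // len(classes)
    ids: list[str] = []
    for c in classes:
        members = sorted(stimulus_ids_per_class[c])
        reps = [members[i % len(members)] for i in range(per_class)]
        ids.extend(reps)
    rng.shuffle(ids)
    gaps = 0.75 + rng.uniform(1.0, 1.25, size=len(ids) - 1)
    onsets = lead_in + np.concatenate([[0.0], np.cumsum(gaps)])
    events = [
        ScheduledEvent(onset=float(t), stimulus_id=s, session=0, subsession=0)
        for t, s in zip(onsets, ids)
    ]
    return EventSchedule(events=events)


@dataclass
class StudyResult:
    task: DecodingTask
    epochs: EpochSet
    report: PreprocessReport
    run: DecodingRun
    random: FoldAccuracies
    chance: ChanceComparison
    curve: AccuracyCurve

    @property
    def single_trial_accuracy(self) -> float:
        return self.run.accuracies.mean

    @property
    def chance_level(self) -> float:
        return 1.0 / self.task.M


def simulate_task_epochs(
    task: DecodingTask,
    registry: StimulusRegistry,
    config: ScaledStudyConfig,
    seed: int,
    subject: str = "sim",
) -> tuple[EpochSet, PreprocessReport]:
    """Simulate and preprocess one subject's epochs for one task."""
    layout = make_channel_layout(config.n_channels)
    layout = simulate_impedances(layout, n_bad=config.n_bad_channels, seed=seed)
    schedule = make_custom_schedule(
        {label: sorted(members) for label, members in task.classes.items()},
        n_trials=config.n_trials,
        seed=seed,
        lead_in=config.lead_in,
    )
    recording = synthesize_recording(
        schedule, registry, layout, erp=config.effect(), noise=config.noise,
        seed=seed + 1, fs=config.fs,
    )
    return preprocess_sessions({0: recording}, schedule, subject=subject)


def run_task_study(
    task_name: str = "left_vs_right",
    seed: int = 0,
    config: ScaledStudyConfig | None = None,
    n_multitrial_max: int = 15,
    subject: str = "sim",
    n_subjects_for_correction: int = 1,
) -> StudyResult:
    """Scaled end-to-end study of one decoding task on synthetic data."""
    config = config if config is not None else ScaledStudyConfig()
    registry = build_stimulus_registry()
    tasks = {t.name: t for t in build_task_registry(registry)}
    task = tasks[task_name]

    epochs, report = simulate_task_epochs(task, registry, config, seed, subject)
    features = task_features(epochs, task)
    run = crossval_decode(
        features, task_name=task.name, scheme="tenfold", seed=seed + 2,
        settings=config.settings, subject=subject,
    )
    rand = random_decoder(run.fold_true_labels, run.classes, seed=seed + 3,
                          task_name=task.name, subject=subject)
    chance = compare_to_chance(run.accuracies, rand,
                               n_subjects=n_subjects_for_correction)
    curve = multitrial_accuracy(
        run, n_range=tuple(range(1, n_multitrial_max + 1)), seed=seed + 4,
        task=task.name, subject=subject,
    )
    return StudyResult(task=task, epochs=epochs, report=report, run=run,
                       random=rand, chance=chance, curve=curve)
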