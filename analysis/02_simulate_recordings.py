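"""Simulate a scaled synthetic acquisition and persist it to disk.

One session of continuous EEG (32 channels at 250 Hz by default) covering
every stimulus of the left-vs-right task, written as FIF plus events TSV
and channel-metadata JSON under scratch/ (binary data stay out of
results/).
"""

import argparse
from pathlib import Path

from phosdec.pipeline import ScaledStudyConfig, make_custom_schedule
from phosdec.stimulus_design import build_stimulus_registry, build_task_registry
from phosdec.synthetic_data import (
    make_channel_layout,
    simulate_impedances,
    synthesize_recording,
    write_recording,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--task", default="left_vs_right")
    ap.add_argument("--n-trials", type=int, default=300)
    ap.add_argument("--out", type=Path, default=Path("scratch/recordings"))
    args = ap.parse_args()

    cfg = ScaledStudyConfig(n_trials=args.n_trials)
    registry = build_stimulus_registry()
    task = {t.name: t for t in build_task_registry(registry)}[args.task]
    layout = simulate_impedances(make_channel_layout(cfg.n_channels),
                                 n_bad=cfg.n_bad_channels, seed=args.seed)
    schedule = make_custom_schedule(
        {k: sorted(v) for k, v in task.classes.items()},
        n_trials=cfg.n_trials, seed=args.seed,
    )
    recording = synthesize_recording(
        schedule, registry, layout, erp=cfg.effect(), noise=cfg.noise,
        seed=args.seed + 1, fs=cfg.fs,
    )
    paths = write_recording(recording, schedule.to_frame(), args.out / "session0")
    print(f"simulated {recording.duration:.0f} s of {layout.n_channels}-channel "
          f"EEG at {cfg.fs:.0f} Hz for task {task.name!r}")
    for kind, path in paths.items():
        print(f"  {kind}: {path}")


if __name__ == "__main__":
    main()
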