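"""Build the stimulus registry, the ten decoding tasks, and the schedule.

Writes the 60-stimulus registry and the class tables to results/design/,
plus a seed-randomized two-session presentation schedule (2 x 1500 events,
25 repetitions per stimulus per session).
"""

import argparse
from pathlib import Path

from phosdec.stimulus_design import (
    build_stimulus_registry,
    build_task_registry,
    generate_schedule,
    tasks_to_yaml,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/design"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    registry = build_stimulus_registry()
    registry.to_frame().to_csv(args.out / "stimuli.tsv", sep="\t", index=False)
    registry.to_yaml(args.out / "stimuli.yaml")

    tasks = build_task_registry(registry)
    tasks_to_yaml(tasks, args.out / "tasks.yaml")

    schedule = generate_schedule(registry, seed=args.seed)
    schedule.to_tsv(args.out / "schedule.tsv")

    print(f"registry: {len(registry)} stimuli")
    for t in tasks:
        sizes = {k: len(v) for k, v in t.classes.items()}
        print(f"task {t.name}: M={t.M} balanced={t.balanced} sizes={sizes}")
    df = schedule.to_frame()
    print(f"schedule: {len(df)} presentations, "
          f"{df.stimulus_id.value_counts().iloc[0]} per stimulus")


if __name__ == "__main__":
    main()
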