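"""Feature-importance maps of the trained RBF decoders.

Fits a calibrated decoder on the full (z-scored) training data of a task
and computes the mean-squared-gradient sensitivity map, reduced to a
spatial (per-channel) and temporal (per-sample) importance profile;
written as TSV tables to results/sensitivity/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from phosdec.decoding import fit_calibrated_decoder, task_features, zscore_apply, zscore_fit
from phosdec.pipeline import ScaledStudyConfig, simulate_task_epochs
from phosdec.sensitivity_mapping import reduce_map, sensitivity_map
from phosdec.stimulus_design import build_stimulus_registry, build_task_registry


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--tasks", nargs="+", default=["left_vs_right", "superior_vs_inferior"])
    ap.add_argument("--out", type=Path, default=Path("results/sensitivity"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    registry = build_stimulus_registry()
    tasks = {t.name: t for t in build_task_registry(registry)}
    cfg = ScaledStudyConfig()

    for name in args.tasks:
        epochs, _ = simulate_task_epochs(tasks[name], registry, cfg, seed=args.seed)
        fm = task_features(epochs, tasks[name])
        fm_z = zscore_apply(zscore_fit(fm), fm)
        decoder = fit_calibrated_decoder(fm_z)
        smap = sensitivity_map(decoder, fm_z)
        spatial, temporal = reduce_map(smap)

        grid = pd.DataFrame(smap.grid, index=fm.ch_names)
        grid.to_csv(args.out / f"{name}_map.tsv", sep="\t")
        pd.DataFrame(dict(channel=fm.ch_names, importance=spatial)).to_csv(
            args.out / f"{name}_spatial.tsv", sep="\t", index=False)
        times = epochs.tmin + np.arange(epochs.n_samples) / epochs.fs
        pd.DataFrame(dict(time_s=times, importance=temporal)).to_csv(
            args.out / f"{name}_temporal.tsv", sep="\t", index=False)

        top = [fm.ch_names[i] for i in np.argsort(spatial)[::-1][:5]]
        peak_t = times[int(np.argmax(temporal))]
        print(f"{name}: top-5 channels {top}; temporal peak at {peak_t:.3f} s")


if __name__ == "__main__":
    main()
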