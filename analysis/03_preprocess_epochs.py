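"""Preprocess the simulated recording into baseline-corrected epochs.

Reads the FIF + sidecars written by 02_simulate_recordings.py, runs the
chain (impedance rejection, 0.5-30 Hz zero-phase FIR, epoching, baseline,
aRMS channel rejection), saves epochs to scratch/ and the rejection report
to results/preprocessing/.
"""

import argparse
import json
from pathlib import Path

from phosdec.preprocessing import preprocess_sessions
from phosdec.stimulus_design import EventSchedule
from phosdec.synthetic_data import read_recording


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--recordings", type=Path, default=Path("scratch/recordings"))
    ap.add_argument("--epochs-out", type=Path, default=Path("scratch/epochs/session0"))
    ap.add_argument("--report-out", type=Path, default=Path("results/preprocessing"))
    args = ap.parse_args()

    recording, _ = read_recording(args.recordings / "session0")
    schedule = EventSchedule.from_tsv(args.recordings / "session0_events.tsv")
    epochs, report = preprocess_sessions({0: recording}, schedule)
    epochs.save(args.epochs_out)

    args.report_out.mkdir(parents=True, exist_ok=True)
    with open(args.report_out / "report.json", "w") as fh:
        json.dump(
            dict(
                removed_impedance=report.removed_impedance,
                removed_arms=report.removed_arms,
                n_epochs=report.n_epochs,
                filter_half_amplitude_cutoffs_hz=report.filter_cutoffs,
                n_channels_kept=epochs.n_channels,
                n_samples_per_epoch=epochs.n_samples,
            ),
            fh, indent=2,
        )
    print(f"kept {report.n_epochs} epochs x {epochs.n_channels} channels "
          f"x {epochs.n_samples} samples")
    print(f"impedance-rejected: {report.removed_impedance}")
    print(f"aRMS-rejected: {report.removed_arms}")
    print(f"filter half-amplitude cutoffs: {report.filter_cutoffs} Hz")


if __name__ == "__main__":
    main()
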