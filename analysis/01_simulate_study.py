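#!/usr/bin/env python
"""Generate the synthetic crossover study and export example data files.

Builds the default seeded dataset - 18 athletes x 3 conditioning protocols
(ESG/RBG/SQG) x 6 side-kick trials of 15-channel sEMG at 2000 Hz, plus three
vertical jumps at 6/8/10 min post intervention - and writes one subject's
raw files (trial CSV, cycle-event JSON, MVC CSV) together with the full
flight-time table, so every downstream script can also be exercised from
files rather than in-memory objects.
"""

from pathlib import Path

from kicksyn.interface import (jumps_frame, write_events_json,
                               write_jumps_csv, write_mvc_csv,
                               write_trial_csv)
from kicksyn.synthgen import GeneratorConfig, generate_study

OUT = Path("results/data")
SEED = 42


def main() -> None:
    config = GeneratorConfig(seed=SEED)
    dataset = generate_study(config)
    OUT.mkdir(parents=True, exist_ok=True)

    subject = dataset.subjects[0]
    session = subject.sessions["ESG"]
    trial = session.trials[0]
    write_trial_csv(OUT / f"{subject.subject_id}_ESG_trial1.csv", trial)
    write_events_json(OUT / f"{subject.subject_id}_ESG_trial1_events.json",
                      trial.events_s)
    write_mvc_csv(OUT / f"{subject.subject_id}_ESG_mvc.csv", session.mvc)
    jumps = jumps_frame(dataset)
    write_jumps_csv(OUT / "jumps.csv", jumps)

    n_trials = sum(len(s.sessions[p].trials) for s in dataset.subjects
                   for p in s.sessions)
    print(f"dataset: {len(dataset.subjects)} subjects x "
          f"{len(subject.sessions)} protocols x "
          f"{len(session.trials)} trials = {n_trials} EMG trials")
    print(f"trial shape: {trial.emg.shape[0]} channels x "
          f"{trial.emg.shape[1]} samples @ {trial.sampling_rate:.0f} Hz")
    print(f"ground truth: {dataset.ground_truth.n_synergies} synergies, "
          f"protocol weight boosts x{1 + config.effect_magnitude:.2f} "
          "(ESG: GM/RF/RFR, RBG: VL/GMed)")
    print(f"jump rows written: {len(jumps)} -> {OUT/'jumps.csv'}")


if __name__ == "__main__":
    main()
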