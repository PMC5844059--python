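#!/usr/bin/env python
"""Enumerate the experimental design and write its condition/session tables.

Prints the structural counts (52 conditions = 4 auditory + 8 visual + 40
audiovisual; 16 AV location combinations per reliability; 352 stimulus
trials per session) and writes the condition list plus one example
audiovisual session plan under results/design/.
"""

from pathlib import Path

from ventriloquist import design

OUT = Path(__file__).resolve().parents[1] / "results" / "design"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    conds = design.enumerate_mle_conditions()
    frame = design.conditions_to_frame(conds)
    frame.to_csv(OUT / "mle_conditions.csv", index=False)
    n_av = (frame.modality == "AV").sum()
    print(f"cue-combination condition set: {len(frame)} conditions "
          f"({(frame.modality == 'A').sum()} auditory, "
          f"{(frame.modality == 'V').sum()} visual, {n_av} audiovisual)")

    combos = design.enumerate_full_av_combinations()
    n_high = sum(1 for c, _ in combos if c.visual_reliability == "high")
    n_mle = sum(m for c, m in combos if c.visual_reliability == "high")
    print(f"full audiovisual grid: {n_high} location combinations per "
          f"reliability, {n_mle} in the congruent/±6° subset")

    plan = design.build_session_plan(design.av_session_conditions("auditory"),
                                     trials_per_condition=11, seed=1,
                                     session_id=0, report="auditory")
    design.plans_to_frame([plan]).to_csv(OUT / "example_av_session.csv", index=False)
    print(f"example AV session: {plan.n_stimulus_trials} stimulus trials "
          f"+ {plan.n_null_events} null events -> {OUT / 'example_av_session.csv'}")


if __name__ == "__main__":
    main()
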