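#!/usr/bin/env python
"""EMG processing of the simulated recordings.

Computes MVC-normalized, delay-shifted linear envelopes for the baseline
and retention EMG written by 01_simulate_gait.py, reports the measured
gastrocnemius-to-soleus activation ratio of each trial, and applies the
adaptive feedback-target rule to the achieved reduction. Writes envelope
CSVs and results/emg_summary.json.
"""

import json
from pathlib import Path

from coordsim import io as cio
from coordsim.emg import FeedbackState, activation_ratio, update_feedback_target
from coordsim.pipeline import envelopes_on_grid, process_emg

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ratios = {}
    for preset in ("baseline", "retention"):
        raw, fs = cio.read_emg_csv(DATA / f"{preset}_emg.csv")
        mvc, _ = cio.read_emg_csv(DATA / f"{preset}_mvc.csv")
        trial = cio.read_trial_csv(DATA / f"{preset}_trial.csv")
        delayed = process_emg(raw, mvc, fs)
        cio.write_emg_csv(delayed.channels, fs, OUT / f"{preset}_envelopes.csv")
        grid = envelopes_on_grid(delayed.channels, fs, trial, 1.1)
        ratios[preset] = activation_ratio(
            grid["gasmed"], grid["soleus"], trial.stance_mask
        )
        print(f"{preset}: activation ratio {ratios[preset]:.3f}")

    achieved = 1.0 - ratios["retention"] / ratios["baseline"]
    state = FeedbackState(baseline_ratio=ratios["baseline"],
                          baseline_gastroc=0.0)
    state = update_feedback_target(state, achieved)
    print(f"achieved reduction {100 * achieved:.1f}% -> next feedback "
          f"target {100 * state.current_target_reduction:.1f}%")

    (OUT / "emg_summary.json").write_text(json.dumps({
        "ratio_baseline": ratios["baseline"],
        "ratio_retention": ratios["retention"],
        "achieved_reduction": achieved,
        "next_target_reduction": state.current_target_reduction,
    }, indent=2))


if __name__ == "__main__":
    main()
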