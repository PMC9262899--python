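#!/usr/bin/env python
"""Generate the synthetic gait dataset used by the downstream analyses.

Writes one normative (baseline) and one retention-preset gait cycle, with
raw EMG and MVC recordings, to results/data/. The retention preset scales
the gastrocnemius ground truth down and the soleus up so that the
ground-truth activation ratio falls by exactly 25%.
"""

from pathlib import Path

from coordsim import io as cio
from coordsim.model import default_fixture
from coordsim.synth import TrialConfig, generate_emg, generate_trial, retention_config

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = default_fixture()
    for preset, cfg in (
        ("baseline", TrialConfig()),
        ("retention", retention_config()),
    ):
        trial, truth = generate_trial(model, cfg, seed=SEED)
        raw, mvc = generate_emg(truth)
        cio.write_trial_csv(trial, OUT / f"{preset}_trial.csv")
        cio.write_emg_csv(raw, 2000.0, OUT / f"{preset}_emg.csv")
        cio.write_emg_csv(mvc, 2000.0, OUT / f"{preset}_mvc.csv")
        print(
            f"{preset}: {len(trial.t)} frames, "
            f"{int(trial.stance_mask.sum())} stance, "
            f"bodyweight {trial.bodyweight:.0f} N -> {OUT}"
        )


if __name__ == "__main__":
    main()
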