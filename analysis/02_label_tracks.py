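#!/usr/bin/env python
"""Label the GPS cohort with the speed/tortuosity rules and score recovery.

The cohort is regenerated in memory from the shared seed (the generator is
bit-reproducible), labelled fix-by-fix, and compared against the latent
states.  Finding: with the default behavioural separation the kinematic
rules recover the true states at ~97-98% of defined fixes.
"""

import json
from pathlib import Path

import pandas as pd

from shearwater.labelling import LABELS, label_track
from shearwater.pipeline import PipelineConfig, stage_seed
from shearwater.synthetic import simulate_foraging_cohort

SEED = 20070615
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = PipelineConfig(seed=SEED)
    trips = simulate_foraging_cohort(cfg.sim, stage_seed(SEED, "trips"))
    rows = []
    for t in trips:
        lab = label_track(t.track, cfg.thresholds)
        defined = lab["label"].isin(LABELS)
        sub = pd.DataFrame(
            {"true": t.true_states[defined.to_numpy()], "rule": lab.loc[defined, "label"]}
        )
        rows.append(sub)
    allrows = pd.concat(rows, ignore_index=True)
    confusion = pd.crosstab(allrows["true"], allrows["rule"])
    accuracy = float((allrows["true"] == allrows["rule"]).mean())
    (ROOT / "results").mkdir(exist_ok=True)
    confusion.to_csv(ROOT / "results" / "02_rule_confusion.csv")
    summary = {
        "n_trips": len(trips),
        "n_defined_fixes": int(len(allrows)),
        "state_recovery_accuracy": accuracy,
    }
    (ROOT / "results" / "02_labelling_summary.json").write_text(json.dumps(summary, indent=1))
    print(confusion)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
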