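"""Synthetic two-observer visual rating and inter-rater agreement.

Two simulated readers rate each patient's pair of images
(early_better / same / delayed_better) from the perceived dAI plus
perception noise; agreement is scored with Cohen's kappa.  Writes
results/ratings.csv and results/kappa.json.
"""

import json
from pathlib import Path

import pandas as pd

from fdgasym.asymmetry_stats import (
    ai_records_from_suvmeans,
    cohen_kappa,
    ratings_contingency,
    simulate_observers,
)
from fdgasym.config import load_config

SEED = 1

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    obs_cfg = load_config(None).observers
    df = pd.read_csv(RESULTS / "suvmeans.csv")
    records = ai_records_from_suvmeans(df)
    pairs = simulate_observers(records, obs_cfg.noise_sd, obs_cfg.same_threshold, seed=SEED + 777)
    pd.DataFrame(
        [dict(patient_id=p.patient_id, obs1=p.obs1, obs2=p.obs2) for p in pairs]
    ).to_csv(RESULTS / "ratings.csv", index=False)

    table = ratings_contingency(pairs)
    res = cohen_kappa(table)
    (RESULTS / "kappa.json").write_text(
        json.dumps(
            {"kappa": res.kappa, "p_observed": res.p_observed, "p_expected": res.p_expected,
             "band": res.band, "contingency": table.tolist()},
            indent=2,
        )
    )
    for i, row in enumerate(("early_better", "same", "delayed_better")):
        print(f"  {row:>14}: {table[i].tolist()}")
    print(f"kappa = {res.kappa:.3f} ({res.band}); observed agreement {res.p_observed:.2f}")


if __name__ == "__main__":
    main()
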