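#!/usr/bin/env python
"""Extract the 13 daily movement-behaviour features.

Regenerates the default cohort (same seed as 01_simulate_cohort.py), applies
the wear-time validity rule and weekday/weekend-weighted averaging, and
writes one 13-feature row per included participant.  Prints the per-archetype
feature means — the planted profile structure the clustering stage should
recover.
"""

import argparse
from pathlib import Path

import pandas as pd

from moveprofiles import cohort, features

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = cohort.CohortConfig(n_participants=1000, seed=seed)
    days, truth = cohort.simulate_cohort(cfg)
    feats = features.extract_features(days)
    feats.to_csv(RESULTS / "features.csv")
    n_excluded = len(days) - len(feats)
    print(f"included {len(feats)} / {len(days)} participants "
          f"({n_excluded} failed the 2-weekday/2-weekend-day validity rule)")
    print(f"participants with a feature missing on all valid days: "
          f"{int(feats['any_feature_missing'].sum())}")

    order = ["active", "active_sitters", "light_movers", "prolonged_sitters", "most_sedentary"]
    by_arch = (
        feats.join(truth[["true_archetype"]])
        .groupby("true_archetype")[features.FEATURE_COLUMNS]
        .mean()
        .loc[order]
    )
    with pd.option_context("display.width", 200, "display.max_columns", 20):
        print("\nper-archetype feature means (planted structure):")
        print(by_arch.T.round(1).to_string())
    print(f"\nwrote {RESULTS / 'features.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
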