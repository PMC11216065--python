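#!/usr/bin/env python
"""Estimate profile-mortality associations.

Joins the recovered profile assignments with the survival table and fits the
three sequentially adjusted age-as-timescale Cox models (sociodemographic;
+lifestyle; +health-related), runs the proportional-hazards and interaction
diagnostics, rotates the reference profile, and repeats the fully adjusted
model after excluding deaths in the first two years of follow-up.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from moveprofiles import association

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    truth = pd.read_csv(RESULTS / "cohort_truth.csv", index_col="participant_id")
    assignments = pd.read_csv(RESULTS / "assignments.csv", index_col="participant_id")
    records = truth.join(assignments, how="inner")
    ref = "active" if "active" in set(records["profile"]) else records["profile"].iloc[0]

    tables = []
    for level in (1, 2, 3):
        res = association.cox_fit(records, model_level=level, reference=ref)
        t = res.hr.copy()
        t.insert(0, "model", level)
        tables.append(t)
        print(f"model {level} (n={res.n}, events={res.n_events}):")
        print(
            t.apply(
                lambda r: f"  {r.name:<18} HR {r['HR']:.2f} ({r['lo']:.2f} to {r['hi']:.2f})"
                if pd.notna(r["lo"]) else f"  {r.name:<18} 1.00 (reference)",
                axis=1,
            ).str.cat(sep="\n")
        )
    pd.concat(tables).to_csv(RESULTS / "association.csv", index_label="profile")

    res3 = association.cox_fit(records, model_level=3, reference=ref)
    global_p, _ = association.schoenfeld_test(res3)
    inter = association.interaction_tests(records, reference=ref)
    sens, n_early = association.sensitivity_exclude_early(records, 2.0, reference=ref)
    rotation = association.reference_rotation(records, model_level=3)
    rotation.to_csv(RESULTS / "rotation.csv")

    print(f"\nproportional hazards (global Schoenfeld) p = {global_p:.2f}")
    print("interaction p-values: "
          + ", ".join(f"{k}={v:.2f}" for k, v in inter.items()))
    print(f"sensitivity: excluded {n_early} deaths within 2 y of entry; fully "
          f"adjusted HRs -> "
          + ", ".join(f"{p}={h:.2f}" for p, h in sens.hr["HR"].items() if p != ref))
    (RESULTS / "association_diagnostics.json").write_text(
        json.dumps(
            {
                "reference": ref,
                "schoenfeld_global_p": global_p,
                "interaction_p": inter.to_dict(),
                "n_early_deaths_excluded": n_early,
                "sensitivity_hr": sens.hr["HR"].to_dict(),
                "tie_method": "efron",
                "interaction_test": "likelihood-ratio",
            },
            indent=2,
        )
    )
    print(f"wrote association.csv, rotation.csv, association_diagnostics.json under {RESULTS}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
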