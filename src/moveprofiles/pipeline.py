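"""End-to-end orchestration: simulate -> extract -> profile -> associate.

A run is driven by a :class:`RunConfig` (loadable from YAML), writes its
artifacts (CSV tables, diagnostics JSON, a profile figure) into a run
directory, and records a manifest with the seed, parameters and SHA-256 of
every artifact so a run is fully reproducible from its directory.

The single user-facing seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``: stage order is simulate,
profiling, so editing one stage's options never shifts another stage's
stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, cohort, features, profiling


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    cohort: cohort.CohortConfig = field(default_factory=cohort.CohortConfig)
    cutpoints: tuple[float, float] = (40.0, 100.0)
    bin_width: float = 25.0
    k_range: tuple[int, int] = (2, 8)
    k_override: int | None = None
    n_init: int = profiling.DEFAULT_N_INIT
    gap_B: int = profiling.DEFAULT_B
    reference_profile: str = "active"
    model_levels: tuple[int, ...] = (1, 2, 3)
    sensitivity_window_years: float = 2.0
    write_epochs: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ccfg = raw.pop("cohort", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if ccfg:
            arch = ccfg.pop("archetypes", None)
            cfg.cohort = cohort.CohortConfig(**ccfg)
            if arch is not None:
                cfg.cohort.archetypes = [cohort.ArchetypeSpec(**a) for a in arch]
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(epochs: pd.DataFrame, survival: pd.DataFrame | None = None) -> dict:
    """Schema/consistency report for epoch and survival tables."""
    errors: list[str] = []
    need = {
        "participant_id", "date", "day_type", "epoch_index",
        "epoch_start_clock_time", "accel_mg", "wear_flag",
    }
    missing = need - set(epochs.columns)
    if missing:
        errors.append(f"epoch table missing columns: {sorted(missing)}")
    else:
        bad_types = set(epochs["day_type"].unique()) - {"weekday", "weekend"}
        if bad_types:
            errors.append(f"unknown day_type labels: {sorted(bad_types)}")
        acc = pd.to_numeric(epochs["accel_mg"], errors="coerce")
        if acc.isna().any() or (acc < 0).any():
            errors.append("accel_mg must be numeric, finite and >= 0 (unit: mg)")
        for (pid, date), g in epochs.groupby(["participant_id", "date"]):
            idx = g["epoch_index"].to_numpy()
            if not np.all(np.diff(idx) == 1):
                errors.append(f"non-monotone epoch_index for participant {pid} day {date}")
                break
    report = {
        "n_rows": int(len(epochs)),
        "n_participants": int(epochs["participant_id"].nunique()) if "participant_id" in epochs else 0,
        "errors": errors,
    }
    if survival is not None:
        sneed = {"participant_id", "entry_age_years", "event_age_years", "event_flag"}
        smiss = sneed - set(survival.columns)
        if smiss:
            errors.append(f"survival table missing columns: {sorted(smiss)}")
        elif (survival["event_age_years"] <= survival["entry_age_years"]).any():
            errors.append("event_age_years must exceed entry_age_years")
        report["n_survival_rows"] = int(len(survival))
    report["ok"] = not errors
    return report


def run_all(config: RunConfig) -> Path:
    """Run every stage and return the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sim_seed, prof_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))

    ccfg = dataclasses.replace(config.cohort, seed=sim_seed)
    days, truth = cohort.simulate_cohort(ccfg)
    truth.to_csv(out / "truth.csv")
    if config.write_epochs:
        cohort.epochs_to_frame(days).to_csv(out / "epochs.csv", index=False)

    feats = features.extract_features(days)
    feats.to_csv(out / "features.csv")

    usable = feats.loc[~feats["any_feature_missing"]]
    model, params, diag, summary, assignments = profiling.profile_cohort(
        usable,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        k_override=config.k_override,
        n_init=config.n_init,
        B=config.gap_B,
        seed=prof_seed,
    )
    assignments.to_csv(out / "assignments.csv")
    summary.mean_z.assign(profile=summary.names, size=summary.sizes).to_csv(
        out / "centroids.csv", index=False
    )
    diagnostics = {
        "seed": config.seed,
        "candidate_k": diag.candidate_k,
        "wss": {str(k): v for k, v in diag.wss.items()},
        "gap": {str(k): v for k, v in diag.gap.items()},
        "gap_se": {str(k): v for k, v in diag.gap_se.items()},
        "elbow_k": diag.elbow_k,
        "gap_k": diag.gap_k,
        "chosen_k": diag.chosen_k,
        "k_used": model.k,
    }
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    profiling.plot_profile_means(summary, out / "profile_means.png")

    records = truth.join(assignments, how="inner")
    ref = config.reference_profile
    if ref not in set(assignments["profile"]):
        ref = summary.names[int(np.argmax(summary.mean_z.iloc[:, 0]))]
    tables = []
    for level in config.model_levels:
        res = association.cox_fit(records, model_level=level, reference=ref)
        t = res.hr.copy()
        t.insert(0, "model", level)
        tables.append(t)
    pd.concat(tables).to_csv(out / "association.csv", index_label="profile")
    rotation = association.reference_rotation(records, model_level=max(config.model_levels))
    rotation.to_csv(out / "rotation.csv")
    res3 = association.cox_fit(records, model_level=max(config.model_levels), reference=ref)
    global_p, _ = association.schoenfeld_test(res3)
    sens, n_early = association.sensitivity_exclude_early(
        records, config.sensitivity_window_years, model_level=max(config.model_levels), reference=ref
    )
    assoc_diag = {
        "reference": ref,
        "schoenfeld_global_p": global_p,
        "n_early_deaths_excluded": n_early,
        "sensitivity_hr": sens.hr["HR"].to_dict(),
        "interaction_p": association.interaction_tests(records, reference=ref).to_dict(),
        "tie_method": "efron",
        "interaction_test": "likelihood-ratio",
    }
    (out / "association_diagnostics.json").write_text(json.dumps(assoc_diag, indent=2))

    manifest = {
        "seed": config.seed,
        "stage_seeds": {"simulate": sim_seed, "profiling": prof_seed},
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix in {".csv", ".json"}
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
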