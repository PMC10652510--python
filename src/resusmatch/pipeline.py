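"""End-to-end orchestration: simulate/load -> filter -> impute -> fit-ps ->
match -> analyze, per rhythm stratum, with deterministic artifacts.

Every stage writes its intermediate artifact into the report directory plus
a manifest (config hash, seeds, stage row counts in study-flow style), so
each stage can be re-run from its inputs. Outputs are deterministic given
the config and seeds: running the same config twice produces byte-identical
artifacts. Progress logging goes to stderr, not into the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, bench, impute, matching, propensity, registry, simulate
from .registry import Cohort

BALANCE_COVARIATES = [
    "sex", "age", "witnessed", "bystander_cpr", "initial_rhythm",
    "bystander_aed", "physician_staffed", "shock_by_paramedic",
    "advanced_airway", "prehosp_adrenaline_n", "prehosp_rosc",
    "call_to_hospital_min", "rhythm_on_arrival", "volume_category",
]


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    out_dir: str = "report"
    #: path to an input cohort CSV; when None, a cohort is simulated
    cohort_path: str | None = None
    simulate: simulate.SimulationConfig = field(
        default_factory=lambda: simulate.default_config(n=2000, seed=0))
    #: which strata to analyse ("both" runs every non-empty stratum)
    stratum: str = "both"
    caliper_k: float = 0.2
    horizon: int = registry.HORIZON
    match_seed: int = 0
    impute_enabled: bool = True
    impute_seed: int = 0
    impute_max_iter: int = 10
    impute_n_estimators: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulate"})
        if sim_raw:
            sim = simulate.default_config(
                n=sim_raw.get("n", 2000), seed=sim_raw.get("seed", 0),
                beta_treat=sim_raw.get("beta_treat", 0.0))
            if sim_raw.get("bias_scenario"):
                sim = simulate.bias_scenario(sim)
            if "rhythm_probs" in sim_raw:
                sim.covariates.rhythm_probs = tuple(sim_raw["rhythm_probs"])
            cfg.simulate = sim
        return cfg


def _log(msg: str) -> None:
    print(f"[resusmatch] {msg}", file=sys.stderr)


def _config_hash(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # the hash identifies the analysis, not its location
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config),
                      "seeds": {"simulate": config.simulate.seed,
                                "match": config.match_seed,
                                "impute": config.impute_seed},
                      "caliper_k": config.caliper_k,
                      "horizon": config.horizon,
                      "flow": {}, "strata": {}}

    if config.cohort_path is not None:
        _log(f"reading cohort from {config.cohort_path}")
        cohort = registry.read_cohort(config.cohort_path)
    else:
        _log(f"simulating cohort (n={config.simulate.n}, seed={config.simulate.seed})")
        cohort, truth = simulate.simulate_cohort(config.simulate)
        truth.table.to_csv(out / "truth.csv", index=False)
    registry.write_cohort(cohort, out / "cohort.csv")
    manifest["flow"]["n_input"] = len(cohort)

    eligible, flow = registry.apply_exclusion_criteria(cohort)
    flow.to_csv(out / "flow.csv", index=False)
    manifest["flow"]["n_eligible"] = len(eligible)
    manifest["flow"]["exclusions"] = dict(zip(flow["reason"], map(int, flow["n_excluded"])))
    _log(f"eligible {len(eligible)} / {len(cohort)}")

    if config.impute_enabled and eligible.records[list(registry.MASKABLE_FIELDS)].isna().any().any():
        _log("imputing missing covariates")
        res = impute.impute_missing(eligible, seed=config.impute_seed,
                                    max_iter=config.impute_max_iter,
                                    n_estimators=config.impute_n_estimators)
        eligible = res.cohort
        manifest["imputation"] = {"iterations": res.iterations_run,
                                  "converged": res.converged}
    registry.write_cohort(eligible, out / "eligible.csv")

    volume = registry.derive_hospital_volume(registry.ecpr_counts(eligible))
    shock, nonshock = registry.stratify_by_rhythm(eligible)
    strata = {"shockable": shock, "non_shockable": nonshock}
    if config.stratum != "both":
        strata = {config.stratum: strata[config.stratum]}

    for name, sub in strata.items():
        n_treated = int(sub.timelines["ecpr_minute"].notna().sum())
        if len(sub) == 0 or n_treated == 0:
            manifest["strata"][name] = {"n": len(sub), "n_treated": n_treated,
                                        "skipped": "no patients or no ECPR events"}
            continue
        _log(f"stratum {name}: n={len(sub)}, treated={n_treated}")
        sdir = out / name
        sdir.mkdir(exist_ok=True)
        rows = propensity.build_person_minute_table(sub, volume=volume)
        fit = propensity.fit_td_finegray(rows)
        (sdir / "psfit.json").write_text(fit.to_json())
        scores = propensity.score_lookup(rows, fit)
        risk_sets = matching.build_risk_sets(sub.timelines)
        matched = matching.sequential_match(
            risk_sets, scores, caliper_k=config.caliper_k,
            score_sd=fit.score_sd, seed=config.match_seed, stratum=name)
        pairs = matched.to_frame()
        pairs.to_csv(sdir / "pairs.csv", index=False)
        if config.caliper_k == 0 and len(matched.unmatched_treated):
            _log(f"warning: caliper 0 left {len(matched.unmatched_treated)} "
                 "treated unmatched (only exact score ties can match)")

        vol_series = registry.attach_volume_category(sub, volume)
        extra = pd.DataFrame({"id": sub.records["id"], "volume_category": vol_series})
        if matched.pairs:
            arm_t, arm_c = analysis.matched_arm_frames(matched, sub, extra=extra)
            bal = analysis.balance_table(arm_t, arm_c, BALANCE_COVARIATES,
                                         cohort_label="matched")
            bal.to_csv(sdir / "balance_matched.csv", index=False)
        treated_mask = sub.timelines["ecpr_minute"].notna().to_numpy()
        rdf_full = sub.records.join(extra.set_index("id")["volume_category"],
                                    on="id")
        bal0 = analysis.balance_table(rdf_full[treated_mask], rdf_full[~treated_mask],
                                      BALANCE_COVARIATES, cohort_label="original")
        bal0.to_csv(sdir / "balance_original.csv", index=False)

        effects = {}
        outcomes = {}
        for oc in ("survival_30d", "cpc_1_2"):
            outcomes[oc] = analysis.outcome_proportions(matched, sub.timelines, oc)
            yt, yc = analysis.pair_outcomes(matched, sub.timelines, oc)
            try:
                est = analysis.conditional_logit_1to1(yt, yc, outcome=oc)
                effects[oc] = {
                    "n_pairs": est.n_pairs, "n10": est.n10, "n01": est.n01,
                    "odds_ratio": est.odds_ratio, "ci_low": est.ci_low,
                    "ci_high": est.ci_high, "boundary": est.boundary}
            except ValueError as exc:
                effects[oc] = {"error": str(exc)}
        (sdir / "outcomes.json").write_text(json.dumps(outcomes, indent=2))
        (sdir / "effects.json").write_text(json.dumps(effects, indent=2))

        manifest["strata"][name] = {
            "n": len(sub), "n_treated": n_treated,
            "n_pairs": len(matched.pairs),
            "n_unmatched_treated": len(matched.unmatched_treated),
            "match_summary": matching.match_summary(matched, sub.timelines),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log(f"report written to {out}")
    return out
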