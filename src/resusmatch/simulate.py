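"""Seeded generator of registry-like cardiac-arrest cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not resuscitation physiology:

* baseline / pre-hospital covariates with marginals chosen to resemble a
  national OHCA registry population arriving in arrest;
* a discrete-minute competing-events process over minutes 0..119 after
  hospital arrival: at every minute a patient still in arrest may start ECPR,
  achieve ROSC, or have resuscitation terminated (death); exactly one
  terminal event can occur per minute, drawn from a categorical distribution
  whose cell probabilities are inverse-logit linear in covariates, elapsed
  time, in-hospital interventions and (optionally) a latent refractoriness
  variable; survivors of the loop are administratively censored at 120;
* in-hospital intervention onsets (defibrillation, intubation, adrenaline)
  drawn minute-by-minute before the terminal draw;
* binary 30-day survival and favourable-neurological-outcome (CPC 1-2)
  endpoints generated from a logistic model with a configurable true
  conditional treatment log-odds effect ``beta_treat``. Both potential
  outcomes are drawn from one shared uniform per patient, so ``beta_treat=0``
  makes the potential outcomes identical patient-wise and raising
  ``beta_treat`` is monotone.

Treatment timing in the default configuration depends on observed prognostic
covariates (and on elapsed time), which creates the resuscitation-time /
treatment-timing confounding the matching design must remove.
:func:`bias_scenario` additionally routes an *unobserved* latent variable
into both treatment hazard and outcome, making the naive ever-vs-never
comparison biased under the null.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registry
from .errors import ConfigError
from .registry import Cohort, HORIZON

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class CovariateParams:
    """Marginals for the baseline covariates (registry-like defaults)."""

    p_male: float = 0.80
    age_mean: float = 62.0
    age_sd: float = 15.0
    p_witnessed: float = 0.72
    p_bystander_cpr: float = 0.52
    p_bystander_aed: float = 0.06
    p_physician_staffed: float = 0.20
    #: P(initial rhythm) over (VF_VT, PEA, asystole)
    rhythm_probs: tuple[float, float, float] = (1.0, 0.0, 0.0)
    p_shock_by_paramedic_shockable: float = 0.97
    p_shock_by_paramedic_nonshockable: float = 0.06
    #: P(advanced airway) over (intubation, SGA, none)
    airway_probs: tuple[float, float, float] = (0.10, 0.48, 0.42)
    #: P(number of pre-hospital adrenaline doses 0..5, top-coded)
    adrenaline_probs: tuple[float, ...] = (0.62, 0.12, 0.10, 0.08, 0.04, 0.04)
    p_prehosp_rosc: float = 0.08
    call_to_hospital_log_mean: float = 3.47  # median ~32 min
    call_to_hospital_log_sd: float = 0.30
    n_hospitals: int = 12
    #: per-reason rates of deliberately ineligible records (exercise the
    #: study-flow filter); all zero gives an eligible-by-construction cohort
    ineligible_rates: dict = field(default_factory=lambda: {
        "no_resuscitation_attempt": 0.01,
        "age_lt_18": 0.005,
        "external_cause": 0.01,
        "no_arrest_on_ems_contact": 0.01,
        "rosc_before_arrival": 0.02,
    })


@dataclass
class HazardParams:
    """Per-minute discrete cause-specific hazards, inverse-logit linear.

    Feature names: const, age_z ((age-65)/15), male, witnessed,
    bystander_cpr, prehosp_rosc, shockable, t (minutes), latent, and the
    current in-hospital indicators defib, intubation, adrenaline.
    """

    rosc: dict = field(default_factory=lambda: {
        "const": -4.4, "age_z": -0.30, "witnessed": 0.25, "bystander_cpr": 0.20,
        "prehosp_rosc": 0.90, "shockable": 0.30, "t": -0.010,
        "defib": 0.15, "adrenaline": 0.10, "latent": 0.0,
    })
    death: dict = field(default_factory=lambda: {
        "const": -5.3, "age_z": 0.35, "t": 0.020, "shockable": -0.30, "latent": 0.0,
    })
    ecpr: dict = field(default_factory=lambda: {
        "const": -5.9, "age_z": -0.35, "witnessed": 0.30, "shockable": 0.40,
        "intubation": 0.20, "latent": 0.0,
    })
    #: clinical window for starting ECPR: hazard is 0 before ``ecpr_ramp_start``
    #: and decays exponentially after ``ecpr_decay_start`` (escalation is
    #: decided early; beyond ~40 min crews rarely cannulate)
    ecpr_ramp_start: int = 6
    ecpr_decay_start: int = 35
    ecpr_decay_rate: float = 0.25
    latent_sd: float = 0.0


@dataclass
class InterventionParams:
    """Per-minute onset hazards for in-hospital interventions."""

    defib: float = 0.05          # only drawn while rhythm course is shockable
    intubation: float = 0.10
    adrenaline_first: float = 0.12
    adrenaline_redose: float = 0.25


@dataclass
class OutcomeParams:
    """Logistic 30-day outcome model.

    ``beta_treat`` is the true conditional log-odds effect of ECPR on 30-day
    survival — the recovery target for the estimator bench. ``decay_per_min``
    optionally shrinks the benefit linearly with the treatment minute
    (off by default).
    """

    beta_treat: float = 0.0
    survival: dict = field(default_factory=lambda: {
        "const": -2.0, "age_z": -0.35, "witnessed": 0.30, "prehosp_rosc": 0.80,
        "shockable": 0.40, "latent": 0.0,
    })
    cpc_given_survival: dict = field(default_factory=lambda: {
        "const": -0.5, "age_z": -0.40, "latent": 0.0,
    })
    beta_treat_cpc: float = 0.0
    decay_per_min: float = 0.0


@dataclass
class MissingnessSpec:
    """Missingness mechanism for covariate fields.

    MCAR: independent Bernoulli per field at the given rate. MAR: the
    per-row masking probability is modulated by always-observed drivers
    (age and witnessed status), rescaled so the marginal rate is preserved.
    Event times, dispositions and outcomes are never masked.
    """

    mechanism: str = "MCAR"
    rates: dict = field(default_factory=dict)  # field -> rate in [0,1]


@dataclass
class SimulationConfig:
    n: int = 1000
    seed: int = 0
    covariates: CovariateParams = field(default_factory=CovariateParams)
    hazards: HazardParams = field(default_factory=HazardParams)
    interventions: InterventionParams = field(default_factory=InterventionParams)
    outcomes: OutcomeParams = field(default_factory=OutcomeParams)
    missingness: MissingnessSpec | None = None


@dataclass
class GroundTruth:
    """Per-patient potential outcomes and the true effect used to draw them."""

    beta_treat: float
    table: pd.DataFrame  # id, y0, y1, latent, p0, p1


def default_config(n: int = 1000, seed: int = 0, beta_treat: float = 0.0) -> SimulationConfig:
    """Shockable-rhythm cohort with prognosis-dependent treatment timing."""
    cfg = SimulationConfig(n=n, seed=seed)
    cfg.outcomes.beta_treat = beta_treat
    return cfg


def unconfounded_config(n: int = 1000, seed: int = 0,
                        beta_treat: float = 0.0) -> SimulationConfig:
    """Treatment hazard independent of prognosis (covariates and latent);
    used for clean null / coverage checks."""
    cfg = default_config(n=n, seed=seed, beta_treat=beta_treat)
    # intercept keeps the treated fraction near the default configuration's
    cfg.hazards.ecpr = {"const": -5.2}
    return cfg


def bias_scenario(config: SimulationConfig | None = None,
                  latent_strength: float = 1.0) -> SimulationConfig:
    """Preset embodying resuscitation-time confounding by an unobserved
    latent refractoriness variable.

    Higher latent values lower the ROSC hazard and raise the ECPR hazard
    (clinicians escalate on refractory patients) while also lowering 30-day
    survival; with ``beta_treat = 0`` the naive ever-vs-never comparison is
    biased under the null. ``latent_strength = 0`` reduces to the base config.
    """
    cfg = dataclasses.replace(config) if config is not None else default_config()
    cfg = _deepcopy_config(cfg)
    cfg.hazards.latent_sd = 1.0 if latent_strength else 0.0
    cfg.hazards.rosc["latent"] = -0.8 * latent_strength
    cfg.hazards.ecpr["latent"] = 0.6 * latent_strength
    cfg.outcomes.survival["latent"] = -0.8 * latent_strength
    cfg.outcomes.beta_treat = 0.0
    return cfg


def _deepcopy_config(cfg: SimulationConfig) -> SimulationConfig:
    import copy

    return copy.deepcopy(cfg)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_RHYTHMS = np.array(["VF_VT", "PEA", "asystole"])
_AIRWAYS = np.array(["intubation", "SGA", "none"])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lin(coefs: dict, feats: dict, n: int) -> np.ndarray:
    out = np.zeros(n)
    for name, c in coefs.items():
        if c == 0.0:
            continue
        if name == "const":
            out += c
        else:
            out += c * feats[name]
    return out


def _check_hazard_coefs(hp: HazardParams) -> None:
    known = {"const", "age_z", "male", "witnessed", "bystander_cpr", "prehosp_rosc",
             "shockable", "t", "latent", "defib", "intubation", "adrenaline"}
    for cause in ("rosc", "death", "ecpr"):
        bad = set(getattr(hp, cause)) - known
        if bad:
            raise ConfigError(f"unknown hazard feature(s) {sorted(bad)} for {cause}")


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a full synthetic cohort plus its ground truth.

    Fully reproducible from ``config.seed``: identical config + seed give a
    byte-identical cohort.
    """
    _check_hazard_coefs(config.hazards)
    rng = np.random.default_rng(config.seed)
    n = config.n
    cv, hp, ip, op = (config.covariates, config.hazards,
                      config.interventions, config.outcomes)

    ids = np.array([f"p{i:06d}" for i in range(n)])

    # ---- covariates --------------------------------------------------------
    male = rng.random(n) < cv.p_male
    age = np.clip(np.round(rng.normal(cv.age_mean, cv.age_sd, n)), 18, 100).astype(int)
    witnessed = rng.random(n) < cv.p_witnessed
    bcpr = rng.random(n) < cv.p_bystander_cpr
    baed = rng.random(n) < cv.p_bystander_aed
    phys = rng.random(n) < cv.p_physician_staffed
    rp = np.asarray(cv.rhythm_probs, float)
    rhythm = _RHYTHMS[rng.choice(3, size=n, p=rp / rp.sum())]
    shockable = rhythm == "VF_VT"
    p_shock = np.where(shockable, cv.p_shock_by_paramedic_shockable,
                       cv.p_shock_by_paramedic_nonshockable)
    shock_medic = rng.random(n) < p_shock
    ap = np.asarray(cv.airway_probs, float)
    airway = _AIRWAYS[rng.choice(3, size=n, p=ap / ap.sum())]
    adp = np.asarray(cv.adrenaline_probs, float)
    adren_n = rng.choice(len(adp), size=n, p=adp / adp.sum())
    prosc = rng.random(n) < cv.p_prehosp_rosc
    call_hosp = np.clip(np.round(np.exp(rng.normal(
        cv.call_to_hospital_log_mean, cv.call_to_hospital_log_sd, n))), 5, 180).astype(int)
    # skewed hospital sizes: a few large ECPR centres, many small ones
    hw = 0.7 ** np.arange(cv.n_hospitals)
    hosp_idx = rng.choice(cv.n_hospitals, size=n, p=hw / hw.sum())
    hospital = np.array([f"h{j:02d}" for j in range(cv.n_hospitals)])[hosp_idx]
    # rhythm on hospital arrival: crude progression from the initial rhythm
    u = rng.random(n)
    arr_rhythm = np.where(
        shockable, np.where(u < 0.55, "VF_VT", np.where(u < 0.80, "PEA", "asystole")),
        np.where(rhythm == "PEA", np.where(u < 0.55, "PEA", np.where(u < 0.60, "VF_VT", "asystole")),
                 np.where(u < 0.80, "asystole", "PEA")))

    latent = rng.normal(0.0, 1.0, n) if hp.latent_sd > 0 else np.zeros(n)
    latent = latent * (hp.latent_sd if hp.latent_sd > 0 else 1.0)

    feats = {
        "age_z": (age - 65.0) / 15.0,
        "male": male.astype(float),
        "witnessed": witnessed.astype(float),
        "bystander_cpr": bcpr.astype(float),
        "prehosp_rosc": prosc.astype(float),
        "shockable": shockable.astype(float),
        "latent": latent,
    }

    # static parts of the hazard linear predictors (time & TD terms added per minute)
    static = {}
    for cause in ("rosc", "death", "ecpr"):
        coefs = {k: v for k, v in getattr(hp, cause).items()
                 if k not in ("t", "defib", "intubation", "adrenaline")}
        static[cause] = _lin(coefs, feats, n)

    # ---- minute loop -------------------------------------------------------
    in_arrest = np.ones(n, bool)
    disposition = np.array(["censored"] * n, dtype=object)
    disp_minute = np.full(n, HORIZON)
    defib_on = np.full(n, -1)       # first in-hospital defib minute, -1 = never
    intub_on = np.full(n, -1)
    adren_first = np.full(n, -1)
    defib_events: list[tuple[int, np.ndarray]] = []
    adren_events: list[tuple[int, np.ndarray]] = []

    t_coef = {c: getattr(hp, c).get("t", 0.0) for c in ("rosc", "death", "ecpr")}
    z_coef = {c: {z: getattr(hp, c).get(z, 0.0) for z in ("defib", "intubation", "adrenaline")}
              for c in ("rosc", "death", "ecpr")}

    for t in range(HORIZON):
        alive = np.flatnonzero(in_arrest)
        if alive.size == 0:
            break
        # intervention onsets during minute t (drawn before the terminal draw,
        # so an intervention and a terminal event may share a minute)
        shockable_now = np.isin(arr_rhythm[alive], ("VF_VT",)) | shockable[alive]
        d_draw = rng.random(alive.size) < ip.defib
        d_hit = alive[d_draw & shockable_now]
        if d_hit.size:
            defib_events.append((t, d_hit))
            defib_on[d_hit[defib_on[d_hit] < 0]] = t
        i_draw = rng.random(alive.size) < ip.intubation
        i_hit = alive[i_draw & (intub_on[alive] < 0)]
        if i_hit.size:
            intub_on[i_hit] = t
        p_adren = np.where(adren_first[alive] < 0, ip.adrenaline_first, ip.adrenaline_redose)
        a_draw = rng.random(alive.size) < p_adren
        a_hit = alive[a_draw]
        if a_hit.size:
            adren_events.append((t, a_hit))
            adren_first[a_hit[adren_first[a_hit] < 0]] = t

        # cause-specific hazards this minute
        z = {"defib": (defib_on[alive] >= 0).astype(float),
             "intubation": (intub_on[alive] >= 0).astype(float),
             "adrenaline": (adren_first[alive] >= 0).astype(float)}
        h = {}
        for cause in ("rosc", "death", "ecpr"):
            lp = static[cause][alive] + t_coef[cause] * t
            for zname, c in z_coef[cause].items():
                if c:
                    lp = lp + c * z[zname]
            h[cause] = _sigmoid(lp)
        if t < hp.ecpr_ramp_start:
            h["ecpr"] = np.zeros(alive.size)
        elif t > hp.ecpr_decay_start:
            h["ecpr"] = h["ecpr"] * np.exp(-hp.ecpr_decay_rate * (t - hp.ecpr_decay_start))

        total = h["ecpr"] + h["rosc"] + h["death"]
        if np.any(total > 1.0):
            raise ConfigError("per-minute cause-specific hazards sum above 1")
        u = rng.random(alive.size)
        pick_ecpr = u < h["ecpr"]
        pick_rosc = ~pick_ecpr & (u < h["ecpr"] + h["rosc"])
        pick_death = ~pick_ecpr & ~pick_rosc & (u < total)
        for name, mask in (("ECPR", pick_ecpr), ("ROSC", pick_rosc), ("death", pick_death)):
            hit = alive[mask]
            if hit.size:
                disposition[hit] = name
                disp_minute[hit] = t
                in_arrest[hit] = False

    ecpr_minute = np.where(disposition == "ECPR", disp_minute, -1)
    treated = disposition == "ECPR"

    # ---- 30-day outcomes ---------------------------------------------------
    base = _lin(op.survival, feats, n)
    eff = op.beta_treat - op.decay_per_min * np.where(treated, disp_minute, 0)
    p0 = _sigmoid(base)
    p1 = _sigmoid(base + eff)
    u_out = rng.random(n)
    y0 = u_out < p0
    y1 = u_out < p1
    survival = np.where(treated, y1, y0)
    # favourable neurological outcome only among 30-day survivors
    lp_cpc = _lin(op.cpc_given_survival, feats, n) + op.beta_treat_cpc * treated
    cpc = survival & (rng.random(n) < _sigmoid(lp_cpc))

    # ---- deliberately ineligible records ----------------------------------
    resus = np.ones(n, bool)
    cause = np.array(["medical"] * n, dtype=object)
    ems_arrest = np.ones(n, bool)
    rosc_before = np.zeros(n, bool)
    rates = cv.ineligible_rates or {}
    if rates.get("no_resuscitation_attempt", 0):
        resus[rng.random(n) < rates["no_resuscitation_attempt"]] = False
    if rates.get("age_lt_18", 0):
        young = rng.random(n) < rates["age_lt_18"]
        age = np.where(young, rng.integers(16, 18, n), age)
    if rates.get("external_cause", 0):
        cause[rng.random(n) < rates["external_cause"]] = "external"
    if rates.get("no_arrest_on_ems_contact", 0):
        ems_arrest[rng.random(n) < rates["no_arrest_on_ems_contact"]] = False
    if rates.get("rosc_before_arrival", 0):
        rosc_before[rng.random(n) < rates["rosc_before_arrival"]] = True

    # ---- assemble ----------------------------------------------------------
    defib_lists: list[list[int]] = [[] for _ in range(n)]
    for t, hit in defib_events:
        for i in hit:
            defib_lists[i].append(t)
    adren_lists: list[list[int]] = [[] for _ in range(n)]
    for t, hit in adren_events:
        for i in hit:
            adren_lists[i].append(t)

    rdf = registry._typed_frame([
        dict(id=ids[i], sex="male" if male[i] else "female", age=int(age[i]),
             witnessed=bool(witnessed[i]), bystander_cpr=bool(bcpr[i]),
             initial_rhythm=rhythm[i], bystander_aed=bool(baed[i]),
             physician_staffed=bool(phys[i]), shock_by_paramedic=bool(shock_medic[i]),
             advanced_airway=airway[i], prehosp_adrenaline_n=int(adren_n[i]),
             prehosp_rosc=bool(prosc[i]), call_to_hospital_min=int(call_hosp[i]),
             rhythm_on_arrival=arr_rhythm[i], hospital_id=hospital[i],
             arrest_cause=cause[i], resuscitation_attempted=bool(resus[i]),
             arrest_on_ems_contact=bool(ems_arrest[i]),
             rosc_before_arrival_sustained=bool(rosc_before[i]))
        for i in range(n)], registry.RECORD_COLUMNS)
    tdf = registry._typed_frame([
        dict(id=ids[i],
             defib_minutes=tuple(m for m in defib_lists[i] if m <= disp_minute[i]),
             intubation_minute=int(intub_on[i]) if 0 <= intub_on[i] <= disp_minute[i] else None,
             adrenaline_minutes=tuple(m for m in adren_lists[i] if m <= disp_minute[i]),
             ecpr_minute=int(ecpr_minute[i]) if ecpr_minute[i] >= 0 else None,
             disposition=disposition[i], disposition_minute=int(disp_minute[i]),
             survival_30d=bool(survival[i]), cpc_1_2=bool(cpc[i]))
        for i in range(n)], registry.TIMELINE_COLUMNS)

    stratum = "mixed"
    if cv.rhythm_probs[1] == 0 and cv.rhythm_probs[2] == 0:
        stratum = "shockable"
    elif cv.rhythm_probs[0] == 0:
        stratum = "non_shockable"
    cohort = Cohort(rdf, tdf, stratum=stratum)

    truth = GroundTruth(
        beta_treat=op.beta_treat,
        table=pd.DataFrame({"id": ids, "y0": y0, "y1": y1, "latent": latent,
                            "p0": p0, "p1": p1}))
    out = cohort
    if config.missingness is not None:
        out = inject_missingness(cohort, config.missingness, seed=config.seed + 1)
    return out, truth


# ---------------------------------------------------------------------------
# Missingness injection
# ---------------------------------------------------------------------------

_MAR_DRIVERS = ("age", "witnessed")


def inject_missingness(cohort: Cohort, spec: MissingnessSpec, seed: int) -> Cohort:
    """Mask covariate cells per the given mechanism; returns a new cohort.

    Event times, dispositions and outcomes are never masked (records with a
    missing disposition would be excluded from the study, not imputed).
    """
    if spec.mechanism not in ("MCAR", "MAR"):
        raise ConfigError(f"unknown missingness mechanism {spec.mechanism!r}")
    for fname, rate in spec.rates.items():
        if fname not in registry.MASKABLE_FIELDS:
            raise ConfigError(f"field {fname!r} may not be masked")
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"rate for {fname!r} outside [0, 1]")
        if spec.mechanism == "MAR" and fname in _MAR_DRIVERS:
            raise ConfigError(f"MAR driver field {fname!r} cannot itself be masked")

    rng = np.random.default_rng(seed)
    rdf = cohort.records.copy()
    n = len(rdf)
    if spec.mechanism == "MAR":
        age_z = (rdf["age"].astype(float).fillna(65.0).to_numpy() - 65.0) / 15.0
        wit = rdf["witnessed"].astype("boolean").fillna(False).to_numpy(dtype=float)
        w = _sigmoid(0.8 * age_z - 0.5 * wit)
        w = w / w.mean() if n else w
    for fname, rate in spec.rates.items():
        if rate == 0.0:
            continue
        p = np.full(n, rate) if spec.mechanism == "MCAR" else np.clip(rate * w, 0.0, 1.0)
        mask = rng.random(n) < p
        col = rdf[fname]
        if str(col.dtype) in ("Int64", "boolean"):
            col = col.copy()
            col[mask] = pd.NA
        else:
            col = col.where(~mask, None)
        rdf[fname] = col
    return Cohort(rdf, cohort.timelines.copy(), stratum=cohort.stratum, validate=False)
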