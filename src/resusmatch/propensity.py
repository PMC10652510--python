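"""Time-dependent propensity model for ECPR initiation.

The propensity for starting ECPR at minute *t* after hospital arrival is
modelled on the subdistribution hazard scale: a Fine-Gray regression for the
event "ECPR initiation", treating ROSC and death (termination of
resuscitation) before ECPR as competing risks, with administrative censoring
at 120 minutes. Covariates are the time-independent baseline / pre-hospital
variables plus three time-dependent in-hospital indicators (defibrillation,
intubation, adrenaline), each switching on the minute *after* the
intervention so that an intervention during minute t cannot predict
treatment at minute t.

Because the only censoring inside the 0-120 window is administrative at a
fixed time, the Fine-Gray inverse-censoring weights are identically 1:
patients with a competing event simply remain in the subdistribution risk
sets through minute 119, with their time-dependent covariates frozen at the
last pre-event values. Tied event minutes are handled with the Breslow
approximation, and the weighted partial likelihood is maximised by Newton
iteration with step-halving.

The matching distance lives on the linear-predictor (log-hazard) scale; the
caliper standard deviation is the SD of the linear predictor over treated
patients evaluated at their treatment minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (ConvergenceError, DegenerateCovariateError, IntegrityError,
                     SeparationError)
from .registry import (HORIZON, LEVELS, NON_SHOCKABLE_RHYTHMS, SHOCKABLE_RHYTHMS,
                       Cohort, attach_volume_category, derive_hospital_volume,
                       ecpr_counts)

EVENT_NONE, EVENT_ECPR, EVENT_COMPETING, EVENT_CENSORED = 0, 1, 2, 3

#: time-dependent in-hospital indicator columns, in layout order
TD_COLUMNS = ("defib_in_hosp", "intubation_in_hosp", "adrenaline_in_hosp")


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def _dummies(series: pd.Series, name: str, levels: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Reference-coded indicators; the reference is the first level (in the
    documented dictionary order) present in the data. Levels that never vary
    are omitted."""
    present = [lv for lv in levels if (series == lv).any()]
    out = {}
    for lv in present[1:]:
        out[f"{name}_{lv}"] = (series == lv).to_numpy(dtype=float)
    return out


def baseline_design(cohort: Cohort, volume: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Time-independent covariate matrix X for the propensity model.

    Categorical fields are expanded to reference-coded indicators (reference
    = first level in the dictionary order); indicator columns that never vary
    in the stratum (e.g. initial rhythm within the shockable cohort) are
    structurally uninformative and omitted.
    """
    rdf = cohort.records
    used = ["sex", "age", "witnessed", "bystander_cpr", "initial_rhythm",
            "bystander_aed", "physician_staffed", "shock_by_paramedic",
            "advanced_airway", "prehosp_adrenaline_n", "prehosp_rosc",
            "call_to_hospital_min"]
    for col in used:
        if rdf[col].isna().any():
            raise IntegrityError(f"covariate {col!r} has missing values; impute first")
    if volume.isna().any():
        raise IntegrityError("hospital volume category missing for some patients")

    cols: dict[str, np.ndarray] = {}
    cols.update(_dummies(rdf["sex"], "sex", LEVELS["sex"]))
    cols["age"] = rdf["age"].to_numpy(dtype=float)
    for b in ("witnessed", "bystander_cpr", "bystander_aed", "physician_staffed",
              "shock_by_paramedic", "prehosp_rosc"):
        v = rdf[b].to_numpy(dtype=float)
        if v.min() != v.max():
            cols[b] = v
    cols.update(_dummies(rdf["initial_rhythm"], "initial_rhythm", LEVELS["initial_rhythm"]))
    cols.update(_dummies(rdf["advanced_airway"], "airway", LEVELS["advanced_airway"]))
    cols["prehosp_adrenaline_n"] = rdf["prehosp_adrenaline_n"].to_numpy(dtype=float)
    cols["call_to_hospital_min"] = rdf["call_to_hospital_min"].to_numpy(dtype=float)
    cols.update(_dummies(volume, "volume", LEVELS["volume_category"]))

    names = list(cols)
    X = np.column_stack([cols[c] for c in names]) if names else np.empty((len(rdf), 0))
    return X, names


def _stratum_of(cohort: Cohort) -> str:
    rhythms = set(cohort.records["initial_rhythm"].dropna())
    shock = bool(rhythms & set(SHOCKABLE_RHYTHMS))
    nonshock = bool(rhythms & set(NON_SHOCKABLE_RHYTHMS))
    if shock and nonshock:
        raise IntegrityError(
            "mixed-stratum cohort: propensity scores are fitted separately "
            "per rhythm cohort; stratify first")
    return "shockable" if shock else "non_shockable"


# ---------------------------------------------------------------------------
# Person-minute table
# ---------------------------------------------------------------------------


def build_person_minute_table(cohort: Cohort,
                              volume: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Expand a single-stratum, imputed, eligible cohort into the
    person-minute analysis table.

    One row per patient-minute: treated patients contribute rows
    t = 0..ecpr_minute (event code ECPR on the last); patients with a
    competing event (ROSC / termination) remain represented through minute
    119 with subdistribution weight 1 and time-dependent covariates frozen
    at their last pre-event values; administratively censored patients
    contribute rows t = 0..119 (censoring code on the last row).

    The returned DataFrame carries ``attrs['design_columns']`` (baseline +
    time-dependent column names) and ``attrs['stratum']``.
    """
    stratum = _stratum_of(cohort)
    tdf = cohort.timelines
    if tdf["disposition"].isna().any():
        raise IntegrityError("missing disposition; apply exclusion criteria first")
    d = tdf["disposition_minute"].to_numpy(dtype=int)
    if (d == 0).any():
        bad = tdf.loc[pd.Series(d == 0), "id"].iloc[0]
        raise IntegrityError(
            f"patient {bad!r} has disposition_minute 0; should have been excluded upstream")

    if volume is None:
        volume = derive_hospital_volume(ecpr_counts(cohort))
    vol_series = attach_volume_category(cohort, volume)
    X, xnames = baseline_design(cohort, vol_series)
    n = len(cohort)

    disp = tdf["disposition"].to_numpy(dtype=object)
    is_ecpr = disp == "ECPR"
    is_cens = disp == "censored"
    is_comp = ~is_ecpr & ~is_cens

    last = np.where(is_ecpr, d, HORIZON - 1)
    counts = last + 1
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    ridx = np.repeat(np.arange(n), counts)
    t = np.arange(counts.sum()) - np.repeat(offsets, counts)

    # first onset minute per intervention; -1 = never
    def _first(col):
        return np.array([v[0] if v else -1 for v in tdf[col]], dtype=int)

    onsets = {
        "defib_in_hosp": _first("defib_minutes"),
        "intubation_in_hosp": np.array(
            [-1 if pd.isna(v) else int(v) for v in tdf["intubation_minute"]], dtype=int),
        "adrenaline_in_hosp": _first("adrenaline_minutes"),
    }
    # indicators switch on the minute after the intervention (half-open
    # convention); for competing-event patients they are frozen at the value
    # held during the event minute
    cap = np.where(is_comp, d, HORIZON)
    teff = np.minimum(t, cap[ridx])
    zcols = {}
    for name, on in onsets.items():
        on_r = on[ridx]
        zcols[name] = ((on_r >= 0) & (teff >= on_r + 1)).astype(float)

    event = np.zeros(len(t), dtype=np.int8)
    event_row = offsets + np.where(is_ecpr, d, HORIZON - 1)
    code = np.where(is_ecpr, EVENT_ECPR, np.where(is_cens, EVENT_CENSORED, 0)).astype(np.int8)
    event[event_row] = code
    comp_row = offsets[is_comp] + d[is_comp]
    event[comp_row] = EVENT_COMPETING

    ids = np.asarray(cohort.records["id"], dtype=object)
    data = {"id": ids[ridx], "t": t, "event": event, "weight": np.ones(len(t))}
    for j, name in enumerate(xnames):
        data[name] = X[ridx, j]
    for name in TD_COLUMNS:
        data[name] = zcols[name]
    rows = pd.DataFrame(data)
    rows.attrs["design_columns"] = xnames + list(TD_COLUMNS)
    rows.attrs["stratum"] = stratum
    return rows


# ---------------------------------------------------------------------------
# Fine-Gray fit
# ---------------------------------------------------------------------------


@dataclass
class PSModelFit:
    """Fitted time-dependent subdistribution-hazard propensity model."""

    beta: pd.Series
    loglik: float
    grad_norm: float
    n_iter: int
    score_sd: float
    stratum: str

    @property
    def design_columns(self) -> list[str]:
        return list(self.beta.index)

    def to_json(self) -> str:
        return json.dumps({
            "beta": {k: float(v) for k, v in self.beta.items()},
            "loglik": self.loglik, "grad_norm": self.grad_norm,
            "n_iter": self.n_iter, "score_sd": self.score_sd,
            "stratum": self.stratum}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PSModelFit":
        d = json.loads(text)
        return cls(beta=pd.Series(d["beta"], dtype=float), loglik=d["loglik"],
                   grad_norm=d["grad_norm"], n_iter=d["n_iter"],
                   score_sd=d["score_sd"], stratum=d["stratum"])


def fit_td_finegray(rows: pd.DataFrame, tol: float = 1e-8,
                    max_iter: int = 100) -> PSModelFit:
    """Maximise the Breslow-tied weighted partial likelihood over ECPR event
    minutes by Newton iteration.

    For each event minute t the likelihood factor is
    ``exp(eta_i(t)) / sum_{j in subdistribution risk set at t} w_j exp(eta_j(t))``
    with ``eta = beta . [X, Z(t)]``. Covariates are standardised internally
    (location shifts cancel in the risk-set ratios; scales are folded back
    into the returned coefficients). ``score_sd`` is the SD of the linear
    predictor over treated patients at their treatment minutes.
    """
    cols = rows.attrs.get("design_columns")
    if cols is None:
        raise ValueError("rows table lacks attrs['design_columns']")
    ev_all = rows["event"].to_numpy()
    if not (ev_all == EVENT_ECPR).any():
        raise ValueError("no ECPR events in the person-minute table")

    X_raw = rows[list(cols)].to_numpy(dtype=float)
    sd = X_raw.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateCovariateError(
            f"degenerate covariate {cols[zero[0]]!r} (zero variance)")

    t_all = rows["t"].to_numpy()
    event_minutes = np.unique(t_all[ev_all == EVENT_ECPR])
    keep = np.isin(t_all, event_minutes)
    t = t_all[keep]
    ev = ev_all[keep]
    w = rows["weight"].to_numpy(dtype=float)[keep]
    mean = X_raw.mean(axis=0)
    Xs = (X_raw[keep] - mean) / sd

    order = np.argsort(t, kind="stable")
    t, ev, w, Xs = t[order], ev[order], w[order], Xs[order]
    starts = np.searchsorted(t, event_minutes, side="left")
    is_event = ev == EVENT_ECPR
    d_t = np.add.reduceat(is_event.astype(float), starts)
    x_events_sum = Xs[is_event].sum(axis=0)

    p = Xs.shape[1]
    beta = np.zeros(p)

    def _loglik_parts(b):
        eta = Xs @ b
        eta_max = eta.max()
        r = w * np.exp(eta - eta_max)
        S0 = np.add.reduceat(r, starts)
        ll = float(eta[is_event].sum() - (d_t * (np.log(S0) + eta_max)).sum())
        return ll, eta, r, S0

    ll, eta, r, S0 = _loglik_parts(beta)
    n_iter = 0
    grad = None
    for n_iter in range(1, max_iter + 1):
        rX = r[:, None] * Xs
        S1 = np.add.reduceat(rX, starts)            # (#minutes, p)
        mean_t = S1 / S0[:, None]
        grad = x_events_sum - (d_t[:, None] * mean_t).sum(axis=0)
        # Hessian: sum_t d_t (S2_t/S0_t - mean_t mean_t')
        H = np.zeros((p, p))
        bounds = list(starts) + [len(t)]
        for g in range(len(starts)):
            sl = slice(bounds[g], bounds[g + 1])
            S2 = Xs[sl].T @ rX[sl]
            H += d_t[g] * (S2 / S0[g] - np.outer(mean_t[g], mean_t[g]))
        gnorm = float(np.abs(grad).max())
        if gnorm < tol:
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving to keep the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, eta_new, r_new, S0_new = _loglik_parts(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, eta, r, S0 = cand, ll_new, eta_new, r_new, S0_new
        if np.abs(beta).max() > 10.0 and gnorm > 1e-3:
            raise SeparationError(
                "monotone partial likelihood: a coefficient is diverging "
                f"(|beta| > 10 after {n_iter} iterations; perfect separation)")
    else:
        raise ConvergenceError(
            f"Newton did not reach gradient tolerance {tol} in {max_iter} "
            f"iterations (last |grad| = {gnorm:.3g})")

    beta_orig = beta / sd
    series = pd.Series(beta_orig, index=list(cols))

    # score SD over treated patients at their treatment minutes
    eta_raw = X_raw[keep][order] @ beta_orig
    treated_eta = eta_raw[is_event]
    score_sd = float(np.std(treated_eta, ddof=1)) if treated_eta.size > 1 else 0.0
    if score_sd <= 0:
        raise DegenerateCovariateError(
            "score SD over treated patients is zero; caliper undefined")
    return PSModelFit(beta=series, loglik=ll, grad_norm=gnorm, n_iter=n_iter,
                      score_sd=score_sd, stratum=rows.attrs.get("stratum", "unknown"))


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def linear_predictor(fit: PSModelFit, features: Mapping[str, float]) -> float:
    """Propensity score (linear predictor) for one covariate layout
    ``[X, Z(t)]`` given as a name -> value mapping."""
    missing = [c for c in fit.design_columns if c not in features]
    extra = [c for c in features if c not in fit.design_columns]
    if missing or extra:
        raise ValueError(f"covariate layout mismatch (missing {missing}, extra {extra})")
    return float(sum(fit.beta[c] * features[c] for c in fit.design_columns))


def score_rows(rows: pd.DataFrame, fit: PSModelFit) -> np.ndarray:
    """Linear predictor for every row of a person-minute table."""
    cols = fit.design_columns
    if list(rows.attrs.get("design_columns", cols)) != cols:
        raise ValueError("person-minute table layout does not match the fit")
    return rows[cols].to_numpy(dtype=float) @ fit.beta.to_numpy()


def score_lookup(rows: pd.DataFrame, fit: PSModelFit,
                 minutes: np.ndarray | None = None) -> dict[tuple[str, int], float]:
    """(id, minute) -> score mapping for the matching step.

    Restricted to the given minutes (default: all ECPR event minutes) to keep
    the mapping small.
    """
    if minutes is None:
        minutes = np.unique(rows.loc[rows["event"] == EVENT_ECPR, "t"])
    keep = rows["t"].isin(minutes).to_numpy()
    sub = rows.loc[keep]
    scores = score_rows(sub, fit)
    return dict(zip(zip(sub["id"].tolist(), sub["t"].tolist()), scores.tolist()))
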