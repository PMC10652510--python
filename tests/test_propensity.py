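"""Person-minute table construction and the time-dependent Fine-Gray fit."""

import numpy as np
import pandas as pd
import pytest

from resusmatch import propensity, simulate
from resusmatch.errors import DegenerateCovariateError, IntegrityError
from resusmatch.propensity import (EVENT_CENSORED, EVENT_COMPETING, EVENT_ECPR,
                                   PSModelFit, build_person_minute_table,
                                   fit_td_finegray, linear_predictor, score_rows)

from conftest import make_cohort
from oracles import maximize_partial_loglik, partial_loglik_from_risk_sets


def _toy_rows(patients):
    """Hand-built person-minute table from (id, X, last_row, event_row,
    event_code) tuples with one binary covariate."""
    rows = []
    for pid, x, last, ev_at, code in patients:
        for t in range(last + 1):
            rows.append(dict(id=pid, t=t, event=code if t == ev_at else 0,
                             weight=1.0, X=float(x)))
    df = pd.DataFrame(rows)
    df.attrs["design_columns"] = ["X"]
    df.attrs["stratum"] = "shockable"
    return df


FIVE_PATIENT_TOY = [
    ("A", 1, 2, 2, EVENT_ECPR),        # ECPR at minute 2
    ("B", 0, 5, 5, EVENT_ECPR),        # ECPR at minute 5
    ("C", 1, 119, 119, EVENT_CENSORED),
    ("D", 0, 119, 1, EVENT_COMPETING),  # ROSC at 1; stays with weight 1
    ("E", 0, 119, 119, EVENT_CENSORED),
]


# ---------------------------------------------------------------------------
# Person-minute table
# ---------------------------------------------------------------------------


def _small_cohort():
    return make_cohort([
        ({}, {"disposition": "ECPR", "disposition_minute": 3, "ecpr_minute": 3}),
        ({"age": 70}, {"disposition": "ROSC", "disposition_minute": 7,
                       "survival_30d": True}),
        ({"age": 50, "witnessed": False}, {"disposition": "death",
                                           "disposition_minute": 40}),
        ({"sex": "female"}, {"adrenaline_minutes": (2,)}),
        ({"bystander_cpr": False}, {}),
    ], stratum="shockable")


def test_person_minute_rows_and_event_codes():
    rows = build_person_minute_table(_small_cohort())
    a = rows[rows["id"] == "p000"]
    assert len(a) == 4 and list(a["t"]) == [0, 1, 2, 3]
    assert a["event"].tolist() == [0, 0, 0, EVENT_ECPR]
    # competing patients stay through minute 119 with weight 1
    b = rows[rows["id"] == "p001"]
    assert len(b) == 120
    assert b.loc[b["t"] == 7, "event"].iloc[0] == EVENT_COMPETING
    assert (b["weight"] == 1.0).all()
    cens = rows[rows["id"] == "p004"]
    assert cens["event"].tolist()[-1] == EVENT_CENSORED and len(cens) == 120


def test_half_open_indicator_convention():
    """Adrenaline at minute 2 switches the indicator on from minute 3."""
    rows = build_person_minute_table(_small_cohort())
    d = rows[rows["id"] == "p003"].set_index("t")["adrenaline_in_hosp"]
    assert (d.loc[:2] == 0).all()
    assert (d.loc[3:] == 1).all()


def test_risk_set_membership_matches_brute_force():
    """Five-patient toy: subdistribution risk-set membership per event
    minute equals a direct set construction over all id x minute."""
    cohort = _small_cohort()
    rows = build_person_minute_table(cohort)
    tdf = cohort.timelines
    specs = {pid: (None if pd.isna(e) else int(e), int(d), disp)
             for pid, e, d, disp in zip(tdf["id"], tdf["ecpr_minute"],
                                        tdf["disposition_minute"], tdf["disposition"])}
    for t in sorted(rows.loc[rows["event"] == EVENT_ECPR, "t"].unique()):
        got = set(rows.loc[rows["t"] == t, "id"])
        expect = set()
        for pid, (e, d, disp) in specs.items():
            if e is not None:          # treated: present up to own event minute
                if t <= e:
                    expect.add(pid)
            elif disp in ("ROSC", "death"):
                expect.add(pid)        # competing: present at every minute
            else:
                expect.add(pid)        # censored at 120: present to 119
        assert got == expect


def test_zero_disposition_minute_rejected():
    cohort = make_cohort([({}, {"disposition": "ROSC", "disposition_minute": 0})],
                         stratum="shockable")
    with pytest.raises(IntegrityError):
        build_person_minute_table(cohort)


def test_mixed_stratum_refused():
    cohort = make_cohort([
        ({"initial_rhythm": "VF_VT"}, {"disposition": "ECPR",
                                       "disposition_minute": 5, "ecpr_minute": 5}),
        ({"initial_rhythm": "PEA"}, {}),
    ])
    with pytest.raises(IntegrityError):
        build_person_minute_table(cohort)


# ---------------------------------------------------------------------------
# Fine-Gray fit
# ---------------------------------------------------------------------------


def test_five_patient_toy_matches_grid_oracle():
    """The classic toy: beta_hat = ln(sqrt(9/2)), cross-checked against a
    direct maximisation of the enumerated partial likelihood."""
    fit = fit_td_finegray(_toy_rows(FIVE_PATIENT_TOY))
    assert fit.beta["X"] == pytest.approx(np.log(np.sqrt(9 / 2)), abs=1e-6)
    events = [
        {"x_event": np.array([1.0]), "risk_w": np.ones(5),
         "risk_x": np.array([[1.0], [0.0], [1.0], [0.0], [0.0]])},
        {"x_event": np.array([0.0]), "risk_w": np.ones(4),
         "risk_x": np.array([[0.0], [1.0], [0.0], [0.0]])},
    ]
    oracle = maximize_partial_loglik(events, p=1)
    assert fit.beta["X"] == pytest.approx(oracle[0], abs=1e-5)
    assert fit.loglik == pytest.approx(
        partial_loglik_from_risk_sets(oracle, events), abs=1e-8)


def test_reduces_to_cox_without_competing_events():
    """With no competing events (and no ties), the fit coincides with a
    time-varying Cox fit of the same long data (lifelines oracle) and with
    a direct BFGS maximisation of the enumerated Cox likelihood."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(0)
    patients = []
    ev_minutes = rng.choice(np.arange(2, 60), size=12, replace=False)
    for i in range(40):
        x = rng.normal()
        if i < 12:
            m = int(ev_minutes[i])
            patients.append((f"q{i:02d}", x, m, m, EVENT_ECPR))
        else:
            patients.append((f"q{i:02d}", x, 119, 119, EVENT_CENSORED))
    rows = _toy_rows(patients)
    fit = fit_td_finegray(rows)

    # lifelines CoxTimeVaryingFitter on (start, stop] episodes
    episodes = rows.rename(columns={"t": "start"}).copy()
    episodes["stop"] = episodes["start"] + 1
    episodes["ev"] = (episodes["event"] == EVENT_ECPR).astype(int)
    ctv = lifelines.CoxTimeVaryingFitter()
    ctv.fit(episodes[["id", "start", "stop", "ev", "X"]], id_col="id",
            event_col="ev", start_col="start", stop_col="stop")
    assert fit.beta["X"] == pytest.approx(ctv.params_["X"], abs=1e-4)

    # direct likelihood from enumerated risk sets
    events = []
    xmap = {pid: x for pid, x, *_ in patients}
    for pid, x, last, ev_at, code in patients:
        if code != EVENT_ECPR:
            continue
        risk = [xmap[q] for q, _, l, _, _ in patients
                if l >= ev_at]
        events.append({"x_event": np.array([x]), "risk_w": np.ones(len(risk)),
                       "risk_x": np.array(risk)[:, None]})
    oracle = maximize_partial_loglik(events, p=1)
    assert fit.beta["X"] == pytest.approx(oracle[0], abs=1e-5)


def test_constant_covariate_raises_degenerate_error():
    rows = _toy_rows([("A", 1, 3, 3, EVENT_ECPR), ("B", 1, 119, 119, EVENT_CENSORED)])
    with pytest.raises(DegenerateCovariateError, match="X"):
        fit_td_finegray(rows)


def test_patient_order_invariance():
    """Permuting patients leaves the coefficients unchanged to 1e-10."""
    cohort, _ = simulate.simulate_cohort(simulate.default_config(n=400, seed=17))
    from resusmatch.registry import Cohort, apply_exclusion_criteria
    eligible, _ = apply_exclusion_criteria(cohort)
    fit1 = fit_td_finegray(build_person_minute_table(eligible))
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(eligible))
    shuffled = Cohort(eligible.records.iloc[perm], eligible.timelines.iloc[perm],
                      stratum=eligible.stratum, validate=False)
    fit2 = fit_td_finegray(build_person_minute_table(shuffled))
    assert np.allclose(fit1.beta.to_numpy(), fit2.beta[fit1.beta.index].to_numpy(),
                       atol=1e-10)


def test_newton_increases_loglik_and_converges():
    cohort, _ = simulate.simulate_cohort(simulate.default_config(n=800, seed=18))
    from resusmatch.registry import apply_exclusion_criteria
    eligible, _ = apply_exclusion_criteria(cohort)
    fit = fit_td_finegray(build_person_minute_table(eligible))
    assert fit.grad_norm < 1e-8
    assert fit.score_sd > 0


def test_dropping_competing_rows_gives_cause_specific_fit():
    """Removing the post-event rows of competing patients turns the
    subdistribution fit into the cause-specific (Cox-type) fit."""
    toy = _toy_rows(FIVE_PATIENT_TOY)
    # drop D's rows after its competing event at minute 1
    reduced = toy[~((toy["id"] == "D") & (toy["t"] > 1))].copy()
    reduced.attrs.update(toy.attrs)
    fit = fit_td_finegray(reduced)
    events = [  # D is now absent from both risk sets (event at 1 < 2)
        {"x_event": np.array([1.0]), "risk_w": np.ones(4),
         "risk_x": np.array([[1.0], [0.0], [1.0], [0.0]])},
        {"x_event": np.array([0.0]), "risk_w": np.ones(3),
         "risk_x": np.array([[0.0], [1.0], [0.0]])},
    ]
    oracle = maximize_partial_loglik(events, p=1)
    assert fit.beta["X"] == pytest.approx(oracle[0], abs=1e-5)


# ---------------------------------------------------------------------------
# Linear predictor
# ---------------------------------------------------------------------------


def test_linear_predictor_properties():
    fit = fit_td_finegray(_toy_rows(FIVE_PATIENT_TOY))
    zero = PSModelFit(beta=fit.beta * 0.0, loglik=0, grad_norm=0, n_iter=0,
                      score_sd=1.0, stratum="shockable")
    assert linear_predictor(zero, {"X": 3.7}) == 0.0
    doubled = PSModelFit(beta=fit.beta * 2.0, loglik=0, grad_norm=0, n_iter=0,
                         score_sd=1.0, stratum="shockable")
    assert linear_predictor(doubled, {"X": 1.0}) == pytest.approx(
        2 * linear_predictor(fit, {"X": 1.0}))
    assert linear_predictor(fit, {"X": 1.0}) == pytest.approx(
        np.log(np.sqrt(4.5)), abs=1e-6)
    with pytest.raises(ValueError):
        linear_predictor(fit, {"Y": 1.0})


def test_fit_roundtrips_through_json():
    fit = fit_td_finegray(_toy_rows(FIVE_PATIENT_TOY))
    back = PSModelFit.from_json(fit.to_json())
    assert np.allclose(back.beta.to_numpy(), fit.beta.to_numpy())
    assert back.score_sd == pytest.approx(fit.score_sd)
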