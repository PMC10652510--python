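"""Sequential risk-set matching: risk-set construction, caliper behaviour,
replacement semantics, no-future-information, brute-force equivalence."""

import numpy as np
import pandas as pd
import pytest

from resusmatch import matching, propensity, simulate
from resusmatch.matching import (MatchedCohort, build_risk_sets, match_summary,
                                 sequential_match)
from resusmatch.registry import apply_exclusion_criteria

from conftest import make_cohort
from oracles import brute_force_match


def _tl(pid, ecpr=None, disp=120):
    return {"id": pid, "ecpr_minute": ecpr, "disposition_minute": disp}


def _frame(tls):
    return pd.DataFrame(tls).astype({"ecpr_minute": "Int64",
                                     "disposition_minute": "Int64"})


# ---------------------------------------------------------------------------
# Risk sets
# ---------------------------------------------------------------------------


def test_lone_treated_has_empty_candidate_set():
    tls = _frame([_tl("a", ecpr=4, disp=4), _tl("b", disp=3)])
    (rs,) = build_risk_sets(tls)
    assert rs.minute == 4 and rs.treated_ids == ("a",) and rs.candidate_ids == ()


def test_terminal_event_during_minute_removes_candidacy():
    """A control with ROSC at exactly minute t is not at risk at t."""
    tls = _frame([_tl("a", ecpr=5, disp=5), _tl("b", disp=5), _tl("c", disp=6)])
    (rs,) = build_risk_sets(tls)
    assert rs.candidate_ids == ("c",)


def test_treated_later_counts_as_candidate_earlier():
    tls = _frame([_tl("a", ecpr=3, disp=3), _tl("b", ecpr=9, disp=9)])
    rs3, rs9 = build_risk_sets(tls)
    assert rs3.candidate_ids == ("b",)   # b's own ECPR is in the future
    assert rs9.candidate_ids == ()


def test_risk_set_membership_equals_brute_force_enumeration():
    """Six-patient staggered toy vs direct set comprehension over id x minute."""
    tls = [_tl("a", ecpr=2, disp=2), _tl("b", disp=2), _tl("c", disp=10),
           _tl("d", ecpr=7, disp=7), _tl("e", disp=120), _tl("f", disp=7)]
    got = {rs.minute: (set(rs.treated_ids), set(rs.candidate_ids))
           for rs in build_risk_sets(_frame(tls))}
    expect = {}
    for t in range(121):
        treated = {x["id"] for x in tls if x["ecpr_minute"] == t}
        if not treated:
            continue
        cands = {x["id"] for x in tls
                 if (x["ecpr_minute"] is None or x["ecpr_minute"] > t)
                 and x["disposition_minute"] > t}
        expect[t] = (treated, cands)
    assert got == expect


# ---------------------------------------------------------------------------
# Sequential matching
# ---------------------------------------------------------------------------


def test_in_caliper_candidate_is_matched():
    tls = _frame([_tl("a", ecpr=5, disp=5), _tl("b", disp=120)])
    scores = {("a", 5): 0.0, ("b", 5): 0.02}
    m = sequential_match(build_risk_sets(tls), scores, caliper_k=0.2,
                         score_sd=1.0, seed=0)
    assert len(m.pairs) == 1
    assert m.pairs[0].control_id == "b" and m.pairs[0].distance <= m.caliper


def test_out_of_caliper_treated_is_unmatched():
    tls = _frame([_tl("a", ecpr=5, disp=5), _tl("b", disp=120)])
    scores = {("a", 5): 0.0, ("b", 5): 0.3}
    m = sequential_match(build_risk_sets(tls), scores, caliper_k=0.2,
                         score_sd=1.0, seed=0)
    assert m.pairs == [] and m.unmatched_treated == ["a"]


def test_control_reused_then_becomes_treated():
    """A control matched at t=3 and t=7 can itself be matched as treated at
    its own ECPR minute 9 (hand-enumerated replacement semantics)."""
    tls = _frame([
        _tl("t1", ecpr=3, disp=3), _tl("t2", ecpr=7, disp=7),
        _tl("c", ecpr=9, disp=9), _tl("d", disp=120),
    ])
    scores = {(p, t): 0.0 for p in ("t1", "t2", "c", "d") for t in (3, 7, 9)}
    scores[("d", 3)] = 0.5
    scores[("d", 7)] = 0.5          # d is out of caliper at 3 and 7
    m = sequential_match(build_risk_sets(tls), scores, caliper_k=0.2,
                         score_sd=1.0, seed=0)
    as_control = [p for p in m.pairs if p.control_id == "c"]
    as_treated = [p for p in m.pairs if p.treated_id == "c"]
    assert len(as_control) == 2 and {p.minute for p in as_control} == {3, 7}
    assert len(as_treated) == 1 and as_treated[0].minute == 9
    assert as_treated[0].control_id == "d"

    summ = match_summary(m, tls)
    assert summ["n_pairs"] == 3
    assert summ["n_unique_controls"] == 2          # c and d
    assert summ["n_controls_later_treated"] == 1   # only c
    assert summ["pct_controls_later_treated"] == pytest.approx(50.0)


def test_match_summary_empty_and_never_treated():
    empty = MatchedCohort()
    summ = match_summary(empty, _frame([_tl("a")]))
    assert summ["n_pairs"] == 0 and summ["pct_controls_later_treated"] == 0.0

    tls = _frame([_tl("a", ecpr=5, disp=5), _tl("b", disp=120)])
    m = sequential_match(build_risk_sets(tls), {("a", 5): 0.0, ("b", 5): 0.0},
                         score_sd=1.0, seed=0)
    summ = match_summary(m, tls)
    assert summ["pct_controls_later_treated"] == 0.0


def test_missing_score_is_reported_with_id_and_minute():
    tls = _frame([_tl("a", ecpr=5, disp=5), _tl("b", disp=120)])
    with pytest.raises(ValueError, match="5"):
        sequential_match(build_risk_sets(tls), {("a", 5): 0.0}, score_sd=1.0, seed=0)


def test_every_pair_satisfies_caliper_and_at_risk_invariants():
    """On a simulated stratum, every emitted pair obeys the caliper and the
    control's at-risk condition at the pair minute."""
    cohort, _ = simulate.simulate_cohort(simulate.default_config(n=1200, seed=23))
    eligible, _ = apply_exclusion_criteria(cohort)
    rows = propensity.build_person_minute_table(eligible)
    fit = propensity.fit_td_finegray(rows)
    scores = propensity.score_lookup(rows, fit)
    m = sequential_match(build_risk_sets(eligible.timelines), scores,
                         caliper_k=0.2, score_sd=fit.score_sd, seed=23)
    tdf = eligible.timelines.set_index("id")
    assert len(m.pairs) > 0
    for p in m.pairs:
        assert p.distance <= m.caliper + 1e-12
        ec = tdf.loc[p.control_id, "ecpr_minute"]
        assert pd.isna(ec) or int(ec) > p.minute
        assert int(tdf.loc[p.control_id, "disposition_minute"]) > p.minute
        assert int(tdf.loc[p.treated_id, "ecpr_minute"]) == p.minute
    treated_ids = [p.treated_id for p in m.pairs]
    assert len(set(treated_ids)) == len(treated_ids)


def test_no_future_information():
    """Deleting all events strictly after minute t changes no pair formed
    at minutes <= t (truncation property)."""
    cohort, _ = simulate.simulate_cohort(simulate.default_config(n=800, seed=29))
    eligible, _ = apply_exclusion_criteria(cohort)
    rows = propensity.build_person_minute_table(eligible)
    fit = propensity.fit_td_finegray(rows)
    scores = propensity.score_lookup(rows, fit)
    full = sequential_match(build_risk_sets(eligible.timelines), scores,
                            score_sd=fit.score_sd, seed=5)
    t_cut = 20
    tdf = eligible.timelines.copy()
    future = tdf["disposition_minute"].astype("Int64") > t_cut
    tdf.loc[future, "disposition_minute"] = 120
    tdf.loc[future, "ecpr_minute"] = pd.NA
    trunc_sets = [rs for rs in build_risk_sets(tdf) if rs.minute <= t_cut]
    trunc = sequential_match(trunc_sets, scores, score_sd=fit.score_sd, seed=5)
    early_full = [(p.minute, p.treated_id, p.control_id)
                  for p in full.pairs if p.minute <= t_cut]
    early_trunc = [(p.minute, p.treated_id, p.control_id) for p in trunc.pairs]
    assert sorted(early_full) == sorted(early_trunc)


def test_seeded_determinism_and_seed_sensitivity():
    cohort, _ = simulate.simulate_cohort(simulate.default_config(n=600, seed=31))
    eligible, _ = apply_exclusion_criteria(cohort)
    rows = propensity.build_person_minute_table(eligible)
    fit = propensity.fit_td_finegray(rows)
    scores = propensity.score_lookup(rows, fit)
    rsets = build_risk_sets(eligible.timelines)
    a = sequential_match(rsets, scores, score_sd=fit.score_sd, seed=1)
    b = sequential_match(rsets, scores, score_sd=fit.score_sd, seed=1)
    assert a.to_frame().equals(b.to_frame())


@pytest.mark.parametrize("instance", range(100))
def test_matches_brute_force_on_small_cohorts(instance):
    """Oracle equivalence: on random <= 20-patient cohorts the greedy
    matcher's pairs and unmatched set equal an independent brute-force
    implementation under the same seed."""
    rng = np.random.default_rng(1000 + instance)
    n = int(rng.integers(5, 21))
    tls = []
    for i in range(n):
        pid = f"x{i:02d}"
        if rng.random() < 0.4:
            m = int(rng.integers(1, 30))
            tls.append(_tl(pid, ecpr=m, disp=m))
        else:
            d = int(rng.integers(1, 121))
            tls.append(_tl(pid, disp=d if d < 120 else 120))
    frame = _frame(tls)
    minutes = sorted({x["ecpr_minute"] for x in tls if x["ecpr_minute"] is not None})
    scores = {(x["id"], t): float(np.round(rng.normal(), 3))
              for x in tls for t in minutes}
    sd = 1.0
    m = sequential_match(build_risk_sets(frame), scores, caliper_k=0.2,
                         score_sd=sd, seed=instance)
    got = sorted((p.minute, p.treated_id, p.control_id) for p in m.pairs)
    pairs, unmatched = brute_force_match(tls, scores, caliper=0.2 * sd,
                                         seed=instance)
    assert got == sorted(pairs)
    assert sorted(m.unmatched_treated) == sorted(unmatched)
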