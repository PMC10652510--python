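"""Shared fixtures: compact builders for toy cohorts."""

from __future__ import annotations

import pytest

from resusmatch.registry import Cohort, EventTimeline, PatientRecord


def make_patient(i: int, **overrides) -> PatientRecord:
    """A fully observed, eligible-by-default patient record."""
    base = dict(
        id=f"p{i:03d}", sex="male", age=60, witnessed=True, bystander_cpr=True,
        initial_rhythm="VF_VT", bystander_aed=False, physician_staffed=False,
        shock_by_paramedic=True, advanced_airway="SGA", prehosp_adrenaline_n=1,
        prehosp_rosc=False, call_to_hospital_min=30, rhythm_on_arrival="VF_VT",
        hospital_id="h1", arrest_cause="medical", resuscitation_attempted=True,
        arrest_on_ems_contact=True, rosc_before_arrival_sustained=False)
    base.update(overrides)
    return PatientRecord(**base)


def make_timeline(i: int, **overrides) -> EventTimeline:
    """Default timeline: administratively censored at 120."""
    base = dict(id=f"p{i:03d}", defib_minutes=(), intubation_minute=None,
                adrenaline_minutes=(), ecpr_minute=None, disposition="censored",
                disposition_minute=120, survival_30d=False, cpc_1_2=False)
    base.update(overrides)
    return EventTimeline(**base)


def make_cohort(specs: list[tuple[dict, dict]], stratum: str = "mixed") -> Cohort:
    """Build a cohort from (record overrides, timeline overrides) pairs."""
    recs = [make_patient(i, **r) for i, (r, _) in enumerate(specs)]
    tls = [make_timeline(i, **t) for i, (_, t) in enumerate(specs)]
    return Cohort.from_lists(recs, tls, stratum=stratum)


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture
def timeline_factory():
    return make_timeline
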