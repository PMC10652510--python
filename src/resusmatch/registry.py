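"""Registry-style cohort data model, file I/O, eligibility filtering and derived covariates.

A cohort couples one row of baseline / pre-hospital covariates per patient
(:class:`PatientRecord`) with the patient's in-hospital event timeline on a
0-120 minute clock starting at hospital arrival (:class:`EventTimeline`).
Time convention: integer minutes; an event "at minute t" occupies the
half-open interval [t, t+1); the observation horizon is fixed at 120 minutes,
at which point patients still undergoing resuscitation are administratively
censored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError

HORIZON = 120
ADRENALINE_TOP_CODE = 5

# ---------------------------------------------------------------------------
# Column dictionary
# ---------------------------------------------------------------------------

#: Level order for every categorical field. The first level is the reference
#: level wherever reference coding is needed.
LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "initial_rhythm": ("VF_VT", "PEA", "asystole"),
    "rhythm_on_arrival": ("VF_VT", "PEA", "asystole"),
    "advanced_airway": ("intubation", "SGA", "none"),
    "arrest_cause": ("medical", "external"),
    "disposition": ("ROSC", "death", "ECPR", "censored"),
    "volume_category": ("high", "middle", "low"),
}

#: kind -> how cells are parsed/serialized. "int_list" is a ";"-joined list of
#: integer minutes; missing values are empty cells.
RECORD_COLUMNS: dict[str, str] = {
    "id": "id",
    "sex": "categorical",
    "age": "int",
    "witnessed": "bool",
    "bystander_cpr": "bool",
    "initial_rhythm": "categorical",
    "bystander_aed": "bool",
    "physician_staffed": "bool",
    "shock_by_paramedic": "bool",
    "advanced_airway": "categorical",
    "prehosp_adrenaline_n": "int",
    "prehosp_rosc": "bool",
    "call_to_hospital_min": "int",
    "rhythm_on_arrival": "categorical",
    "hospital_id": "str",
    "arrest_cause": "categorical",
    "resuscitation_attempted": "bool",
    "arrest_on_ems_contact": "bool",
    "rosc_before_arrival_sustained": "bool",
}

TIMELINE_COLUMNS: dict[str, str] = {
    "id": "id",
    "defib_minutes": "int_list",
    "intubation_minute": "int",
    "adrenaline_minutes": "int_list",
    "ecpr_minute": "int",
    "disposition": "categorical",
    "disposition_minute": "int",
    "survival_30d": "bool",
    "cpc_1_2": "bool",
}

ALL_COLUMNS = {**RECORD_COLUMNS, **{k: v for k, v in TIMELINE_COLUMNS.items() if k != "id"}}

#: Covariate fields that missingness injection / imputation may touch.
#: Event times, dispositions and outcomes are never masked or imputed.
MASKABLE_FIELDS: tuple[str, ...] = (
    "sex",
    "age",
    "witnessed",
    "bystander_cpr",
    "initial_rhythm",
    "bystander_aed",
    "physician_staffed",
    "shock_by_paramedic",
    "advanced_airway",
    "prehosp_adrenaline_n",
    "prehosp_rosc",
    "call_to_hospital_min",
    "rhythm_on_arrival",
)

#: How each maskable field is treated by the imputation learners.
FIELD_IMPUTE_KIND: dict[str, str] = {
    "sex": "categorical",
    "age": "continuous",
    "witnessed": "categorical",
    "bystander_cpr": "categorical",
    "initial_rhythm": "categorical",
    "bystander_aed": "categorical",
    "physician_staffed": "categorical",
    "shock_by_paramedic": "categorical",
    "advanced_airway": "categorical",
    "prehosp_adrenaline_n": "categorical",
    "prehosp_rosc": "categorical",
    "call_to_hospital_min": "continuous",
    "rhythm_on_arrival": "categorical",
}

SHOCKABLE_RHYTHMS = ("VF_VT",)
NON_SHOCKABLE_RHYTHMS = ("PEA", "asystole")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """Baseline and pre-hospital covariates for one patient.

    ``None`` marks a missing value; only fields in :data:`MASKABLE_FIELDS`
    may legitimately be missing.
    """

    id: str
    sex: str | None = None
    age: int | None = None
    witnessed: bool | None = None
    bystander_cpr: bool | None = None
    initial_rhythm: str | None = None
    bystander_aed: bool | None = None
    physician_staffed: bool | None = None
    shock_by_paramedic: bool | None = None
    advanced_airway: str | None = None
    prehosp_adrenaline_n: int | None = None
    prehosp_rosc: bool | None = None
    call_to_hospital_min: int | None = None
    rhythm_on_arrival: str | None = None
    hospital_id: str = ""
    arrest_cause: str | None = "medical"
    resuscitation_attempted: bool | None = True
    arrest_on_ems_contact: bool | None = True
    rosc_before_arrival_sustained: bool | None = False


@dataclass
class EventTimeline:
    """In-hospital event minutes for one patient on the 0-120 clock.

    Exactly one terminal event (the final disposition in the emergency
    department): ROSC, death (termination of resuscitation), start of ECPR,
    or administrative censoring at minute 120.
    """

    id: str
    defib_minutes: tuple[int, ...] = ()
    intubation_minute: int | None = None
    adrenaline_minutes: tuple[int, ...] = ()
    ecpr_minute: int | None = None
    disposition: str | None = None
    disposition_minute: int | None = None
    survival_30d: bool = False
    cpc_1_2: bool = False


class Cohort:
    """A validated set of patient records with matching event timelines.

    Internally backed by two aligned pandas DataFrames (one row per patient,
    same id order) for vectorised work; dataclass views are built on demand.
    """

    def __init__(self, records: pd.DataFrame, timelines: pd.DataFrame,
                 stratum: str = "mixed", validate: bool = True):
        self.records = records.reset_index(drop=True)
        self.timelines = timelines.reset_index(drop=True)
        self.stratum = stratum
        if validate:
            self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_lists(cls, records: Iterable[PatientRecord],
                   timelines: Iterable[EventTimeline],
                   stratum: str = "mixed", validate: bool = True) -> "Cohort":
        rec_rows = [dataclasses.asdict(r) for r in records]
        tl_rows = [dataclasses.asdict(t) for t in timelines]
        rdf = _typed_frame(rec_rows, RECORD_COLUMNS)
        tdf = _typed_frame(tl_rows, TIMELINE_COLUMNS)
        # align timelines to record id order
        order = {pid: i for i, pid in enumerate(rdf["id"])}
        if len(tdf) and set(tdf["id"]) == set(rdf["id"]):
            tdf = tdf.iloc[np.argsort([order[p] for p in tdf["id"]])].reset_index(drop=True)
        return cls(rdf, tdf, stratum=stratum, validate=validate)

    def record_list(self) -> list[PatientRecord]:
        return [PatientRecord(**_row_kwargs(row, RECORD_COLUMNS))
                for row in self.records.to_dict("records")]

    def timeline_list(self) -> list[EventTimeline]:
        return [EventTimeline(**_row_kwargs(row, TIMELINE_COLUMNS))
                for row in self.timelines.to_dict("records")]

    def timeline_map(self) -> dict[str, EventTimeline]:
        return {t.id: t for t in self.timeline_list()}

    # -- basics --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return list(self.records["id"])

    def subset(self, mask: np.ndarray | pd.Series, stratum: str | None = None) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(self.records.loc[mask], self.timelines.loc[mask],
                      stratum=stratum or self.stratum, validate=False)

    def equals(self, other: "Cohort") -> bool:
        return (self.stratum == other.stratum
                and self.records.equals(other.records)
                and self.timelines.equals(other.timelines))

    # -- validation ----------------------------------------------------------

    def _validate(self) -> None:
        rdf, tdf = self.records, self.timelines
        if list(rdf.columns) != list(RECORD_COLUMNS):
            raise SchemaError("record frame columns do not match the column dictionary")
        if list(tdf.columns) != list(TIMELINE_COLUMNS):
            raise SchemaError("timeline frame columns do not match the column dictionary")
        if rdf["id"].duplicated().any():
            dup = rdf.loc[rdf["id"].duplicated(), "id"].iloc[0]
            raise IntegrityError(f"duplicate patient id {dup!r}")
        if list(rdf["id"]) != list(tdf["id"]):
            raise IntegrityError("record and timeline ids are not bijective / aligned")

        # categorical levels
        for col, levels in LEVELS.items():
            if col in rdf.columns:
                bad = rdf[col].dropna()[~rdf[col].dropna().isin(levels)]
            elif col in tdf.columns:
                bad = tdf[col].dropna()[~tdf[col].dropna().isin(levels)]
            else:
                continue
            if len(bad):
                raise IntegrityError(f"unknown level {bad.iloc[0]!r} in column {col!r}")

        # adrenaline top-coding
        adren = rdf["prehosp_adrenaline_n"]
        if adren.notna().any() and (adren.dropna().astype(int) > ADRENALINE_TOP_CODE).any():
            raise IntegrityError(
                f"prehosp_adrenaline_n must be top-coded at {ADRENALINE_TOP_CODE}")

        age = rdf["age"]
        if age.notna().any() and (age.dropna().astype(int) < 0).any():
            raise IntegrityError("age must be >= 0")
        cth = rdf["call_to_hospital_min"]
        if cth.notna().any() and (cth.dropna().astype(int) <= 0).any():
            raise IntegrityError("call_to_hospital_min must be > 0")

        disp = tdf["disposition"]
        dmin = tdf["disposition_minute"]
        emin = tdf["ecpr_minute"]
        has_disp = disp.notna()
        if (has_disp & dmin.isna()).any():
            raise IntegrityError("disposition present but disposition_minute missing")
        if dmin.notna().any():
            d = dmin.dropna().astype(int)
            if ((d < 0) | (d > HORIZON)).any():
                raise IntegrityError(f"disposition_minute outside [0, {HORIZON}]")

        is_ecpr = disp == "ECPR"
        ok_ecpr = emin.notna() & (emin == dmin)
        if (is_ecpr & ~ok_ecpr).any():
            bad = tdf.loc[is_ecpr & ~ok_ecpr, "id"].iloc[0]
            raise IntegrityError(
                f"patient {bad!r}: disposition ECPR requires ecpr_minute == disposition_minute")
        if (~is_ecpr & has_disp & emin.notna()).any():
            bad = tdf.loc[~is_ecpr & has_disp & emin.notna(), "id"].iloc[0]
            raise IntegrityError(f"patient {bad!r}: ecpr_minute present without ECPR disposition")

        is_cens = disp == "censored"
        if (is_cens & (dmin != HORIZON)).any():
            raise IntegrityError(f"censored disposition requires disposition_minute == {HORIZON}")
        if (has_disp & ~is_cens & (dmin == HORIZON)).any():
            raise IntegrityError(
                f"disposition_minute == {HORIZON} is reserved for administrative censoring")

        if (tdf["cpc_1_2"].fillna(False).astype(bool)
                & ~tdf["survival_30d"].fillna(False).astype(bool)).any():
            raise IntegrityError("cpc_1_2 requires survival_30d (CPC 1-2 implies alive at 30 days)")

        for col in ("defib_minutes", "adrenaline_minutes"):
            for pid, minutes, dm in zip(tdf["id"], tdf[col], dmin):
                minutes = tuple(minutes) if minutes is not None else ()
                if any(m < 0 or m > HORIZON for m in minutes):
                    raise IntegrityError(f"patient {pid!r}: {col} outside [0, {HORIZON}]")
                if list(minutes) != sorted(minutes):
                    raise IntegrityError(f"patient {pid!r}: {col} not sorted")
                if not pd.isna(dm) and minutes and minutes[-1] > int(dm):
                    raise IntegrityError(f"patient {pid!r}: {col} after final disposition")

        if self.stratum in ("shockable", "non_shockable"):
            rhythms = rdf["initial_rhythm"].dropna()
            want = SHOCKABLE_RHYTHMS if self.stratum == "shockable" else NON_SHOCKABLE_RHYTHMS
            if (~rhythms.isin(want)).any():
                raise IntegrityError(
                    f"stratum {self.stratum!r} inconsistent with initial_rhythm values")


# ---------------------------------------------------------------------------
# frame plumbing
# ---------------------------------------------------------------------------


def _typed_frame(rows: list[dict], columns: Mapping[str, str]) -> pd.DataFrame:
    if not rows:
        df = pd.DataFrame({c: [] for c in columns})
    else:
        df = pd.DataFrame(rows, columns=list(columns))
    return _coerce_types(df, columns)


def _coerce_types(df: pd.DataFrame, columns: Mapping[str, str]) -> pd.DataFrame:
    out = {}
    for col, kind in columns.items():
        s = df[col]
        if kind in ("id", "str", "categorical"):
            out[col] = s.astype("object").where(s.notna(), None)
        elif kind == "int":
            out[col] = pd.array(
                [None if pd.isna(v) else int(v) for v in s], dtype="Int64")
        elif kind == "bool":
            out[col] = pd.array(
                [None if pd.isna(v) else bool(v) for v in s], dtype="boolean")
        elif kind == "int_list":
            out[col] = pd.Series(
                [() if v is None or (isinstance(v, float) and pd.isna(v))
                 else tuple(int(x) for x in v) for v in s], dtype="object")
        else:  # pragma: no cover
            raise AssertionError(kind)
    return pd.DataFrame(out, columns=list(columns))


def _row_kwargs(row: dict, columns: Mapping[str, str]) -> dict:
    out = {}
    for col, kind in columns.items():
        v = row[col]
        if kind == "int_list":
            out[col] = tuple(v) if v is not None else ()
        elif v is None or (not isinstance(v, (tuple, list)) and pd.isna(v)):
            out[col] = None
        elif kind == "int":
            out[col] = int(v)
        elif kind == "bool":
            out[col] = bool(v)
        else:
            out[col] = v
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MISSING = ""


def _serialize_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten to one string-typed row per patient (lossless)."""
    rdf = cohort.records
    tdf = cohort.timelines.drop(columns=["id"])
    flat = pd.concat([rdf, tdf], axis=1)
    out = {}
    for col, kind in ALL_COLUMNS.items():
        s = flat[col]
        if kind == "int_list":
            out[col] = [";".join(str(m) for m in v) if v else _MISSING for v in s]
        elif kind == "bool":
            out[col] = [_MISSING if pd.isna(v) else ("true" if v else "false") for v in s]
        elif kind == "int":
            out[col] = [_MISSING if pd.isna(v) else str(int(v)) for v in s]
        else:
            out[col] = [_MISSING if v is None or pd.isna(v) else str(v) for v in s]
    return pd.DataFrame(out, columns=list(ALL_COLUMNS))


def _parse_cell(value: str, kind: str, col: str, pid: str):
    if value == _MISSING:
        return () if kind == "int_list" else None
    if kind == "int":
        try:
            f = float(value)
        except ValueError:
            raise ParseError(f"row {pid!r}, column {col!r}: {value!r} is not a number")
        if f != int(f):
            raise ParseError(f"row {pid!r}, column {col!r}: {value!r} is not an integer minute")
        return int(f)
    if kind == "bool":
        low = value.strip().lower()
        if low in ("true", "1"):
            return True
        if low in ("false", "0"):
            return False
        raise ParseError(f"row {pid!r}, column {col!r}: {value!r} is not a boolean")
    if kind == "int_list":
        try:
            return tuple(int(x) for x in value.split(";"))
        except ValueError:
            raise ParseError(f"row {pid!r}, column {col!r}: {value!r} is not a minute list")
    return value


def _deserialize_frame(flat: pd.DataFrame, stratum: str, validate: bool) -> Cohort:
    cols = list(flat.columns)
    unknown = [c for c in cols if c not in ALL_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column {unknown[0]!r}")
    missing = [c for c in ALL_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(f"missing required column {missing[0]!r}")
    flat = flat.fillna(_MISSING).astype(str)
    rec_rows, tl_rows = [], []
    for _, row in flat.iterrows():
        pid = row["id"]
        rec = {c: _parse_cell(row[c], k, c, pid) for c, k in RECORD_COLUMNS.items()}
        tl = {c: _parse_cell(row[c], k, c, pid) for c, k in TIMELINE_COLUMNS.items()
              if c != "id"}
        # Table 1 reports ">= 5" adrenaline doses as one level
        if rec["prehosp_adrenaline_n"] is not None:
            rec["prehosp_adrenaline_n"] = min(rec["prehosp_adrenaline_n"], ADRENALINE_TOP_CODE)
        tl["id"] = pid
        rec_rows.append(rec)
        tl_rows.append(tl)
    rdf = _typed_frame(rec_rows, RECORD_COLUMNS)
    tdf = _typed_frame(tl_rows, TIMELINE_COLUMNS)
    return Cohort(rdf, tdf, stratum=stratum, validate=validate)


def write_cohort(cohort: Cohort, path, format: str = "csv") -> None:
    """Serialize a cohort losslessly; inverse of :func:`read_cohort`."""
    flat = _serialize_frame(cohort)
    if format == "csv":
        flat.to_csv(path, index=False)
    elif format == "columnar":
        flat.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cohort(path, format: str = "csv", stratum: str = "mixed",
                validate: bool = True) -> Cohort:
    """Read and validate a cohort file written by :func:`write_cohort`.

    Missing values are preserved as explicit missing markers (empty cells);
    all event times are parsed as integer minutes.
    """
    if format == "csv":
        flat = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    elif format == "columnar":
        flat = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return _deserialize_frame(flat, stratum=stratum, validate=validate)


# ---------------------------------------------------------------------------
# Eligibility filtering
# ---------------------------------------------------------------------------

#: Exclusion reasons in their documented order of precedence; a record is
#: counted once, at the first criterion it fails.
EXCLUSION_REASONS = (
    "no_resuscitation_attempt",
    "age_lt_18",
    "external_cause",
    "no_arrest_on_ems_contact",
    "rosc_before_arrival",
    "hospital_without_ecpr",
    "missing_disposition",
    "zero_time_to_disposition",
)


def apply_exclusion_criteria(cohort: Cohort,
                             capable_hospitals: set[str] | None = None
                             ) -> tuple[Cohort, pd.DataFrame]:
    """Apply the study's eligibility criteria in documented order.

    Returns the eligible cohort and a per-reason exclusion-count table
    (study-flow style; a record is counted once, at the first criterion it
    fails). By default a hospital counts as ECPR-capable when any record in
    the *input* cohort has an ECPR disposition there — the input plays the
    role of the registry database. Pass ``capable_hospitals`` explicitly to
    re-filter a subset under the capability context of the original cohort.
    """
    rdf, tdf = cohort.records, cohort.timelines
    n = len(cohort)

    def _false(col):
        return rdf[col].fillna(True).astype(bool).to_numpy() == False  # noqa: E712

    fails = {}
    fails["no_resuscitation_attempt"] = _false("resuscitation_attempted")
    fails["age_lt_18"] = (rdf["age"].fillna(18).astype(int) < 18).to_numpy()
    fails["external_cause"] = (rdf["arrest_cause"] == "external").to_numpy()
    fails["no_arrest_on_ems_contact"] = _false("arrest_on_ems_contact")
    fails["rosc_before_arrival"] = (
        rdf["rosc_before_arrival_sustained"].fillna(False).astype(bool).to_numpy())
    fails["missing_disposition"] = tdf["disposition"].isna().to_numpy()
    fails["zero_time_to_disposition"] = (
        tdf["disposition_minute"].fillna(-1).astype(int) == 0).to_numpy()

    if capable_hospitals is None:
        is_ecpr = (tdf["disposition"] == "ECPR").to_numpy()
        capable_hospitals = set(rdf.loc[is_ecpr, "hospital_id"])
    fails["hospital_without_ecpr"] = (~rdf["hospital_id"].isin(capable_hospitals)).to_numpy()

    reason_idx = np.full(n, -1)
    for i, reason in enumerate(EXCLUSION_REASONS):
        mask = fails[reason] & (reason_idx == -1)
        reason_idx[mask] = i

    eligible = cohort.subset(reason_idx == -1)
    counts = [int((reason_idx == i).sum()) for i in range(len(EXCLUSION_REASONS))]
    flow = pd.DataFrame({
        "reason": list(EXCLUSION_REASONS),
        "n_excluded": counts,
    })
    flow.attrs["n_input"] = n
    flow.attrs["n_eligible"] = len(eligible)
    return eligible, flow


def stratify_by_rhythm(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition an eligible cohort into shockable (VF/pulseless VT) vs
    non-shockable (PEA, asystole) by pre-hospital initial rhythm."""
    rhythm = cohort.records["initial_rhythm"]
    if rhythm.isna().any():
        raise IntegrityError("initial_rhythm missing; impute before stratifying")
    shock = rhythm.isin(SHOCKABLE_RHYTHMS).to_numpy()
    return (cohort.subset(shock, stratum="shockable"),
            cohort.subset(~shock, stratum="non_shockable"))


# ---------------------------------------------------------------------------
# Derived covariates
# ---------------------------------------------------------------------------


def ecpr_counts(cohort: Cohort) -> dict[str, int]:
    """Number of ECPR cases per hospital (the hospital-volume measure)."""
    rdf, tdf = cohort.records, cohort.timelines
    is_ecpr = (tdf["disposition"] == "ECPR").to_numpy()
    counts = {h: 0 for h in rdf["hospital_id"].unique()}
    for h in rdf.loc[is_ecpr, "hospital_id"]:
        counts[h] += 1
    return counts


def derive_hospital_volume(counts: Mapping[str, int]) -> dict[str, str]:
    """Assign each hospital to high / middle / low ECPR-volume tertiles.

    Rank-based thresholds: the floor(n/3) smallest counts bound "low", the
    floor(2n/3) smallest bound "middle", the rest are "high"; ties at a
    boundary fall to the lower category. A single hospital is "high"
    (degenerate quantiles).
    """
    if not counts:
        raise ValueError("empty hospital count map")
    if any(c < 0 for c in counts.values()):
        raise ValueError("ECPR counts must be >= 0")
    vals = sorted(counts.values())
    n = len(vals)
    k1, k2 = n // 3, (2 * n) // 3
    q1 = vals[k1 - 1] if k1 >= 1 else None
    q2 = vals[k2 - 1] if k2 >= 1 else None
    out = {}
    for h, c in counts.items():
        if q1 is not None and c <= q1:
            out[h] = "low"
        elif q2 is not None and c <= q2:
            out[h] = "middle"
        else:
            out[h] = "high"
    return out


def attach_volume_category(cohort: Cohort, volume: Mapping[str, str]) -> pd.Series:
    """Per-patient hospital ECPR-volume category aligned to the cohort rows."""
    return cohort.records["hospital_id"].map(dict(volume)).rename("volume_category")
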