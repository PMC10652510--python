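"""Sequential 1:1 nearest-neighbour risk-set matching.

Each patient starting ECPR at minute *t* is matched, at that minute, to a
control who is still undergoing resuscitation in the emergency department
and has not received ECPR before or within the same minute. Matching is
with replacement: a matched control stays available at later minutes (and
for other treated patients within the same minute) until their own terminal
event, and may later appear as a treated patient themselves — matching
never looks at future events. The match distance is the absolute difference
of time-dependent propensity scores (linear-predictor scale), admissible
only within a caliper of ``caliper_k`` standard deviations of the score.

Boundary convention: a terminal event during minute t (ROSC, termination,
or the control's own ECPR) removes candidacy at t, read symmetrically from
"had not received ECPR before or within the same minute".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .registry import Cohort


@dataclass(frozen=True)
class RiskSet:
    """Treated patients and eligible controls for one minute."""

    minute: int
    treated_ids: tuple[str, ...]
    candidate_ids: tuple[str, ...]


@dataclass(frozen=True)
class MatchedPair:
    minute: int
    treated_id: str
    control_id: str
    treated_score: float
    control_score: float

    @property
    def distance(self) -> float:
        return abs(self.treated_score - self.control_score)


@dataclass
class MatchedCohort:
    pairs: list[MatchedPair] = field(default_factory=list)
    unmatched_treated: list[str] = field(default_factory=list)
    stratum: str = "unknown"
    caliper: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "minute": p.minute, "treated_id": p.treated_id,
            "control_id": p.control_id, "treated_score": p.treated_score,
            "control_score": p.control_score, "distance": p.distance,
        } for p in self.pairs], columns=["minute", "treated_id", "control_id",
                                         "treated_score", "control_score", "distance"])


def _timeline_frame(timelines) -> pd.DataFrame:
    if isinstance(timelines, Cohort):
        return timelines.timelines
    if isinstance(timelines, pd.DataFrame):
        return timelines
    # list of EventTimeline dataclasses
    return pd.DataFrame([{
        "id": t.id, "ecpr_minute": t.ecpr_minute,
        "disposition_minute": t.disposition_minute} for t in timelines])


def build_risk_sets(timelines) -> list[RiskSet]:
    """One risk set per minute with at least one ECPR initiation.

    A patient is a candidate control at minute t iff their ECPR (if any)
    starts strictly after t and their final disposition is strictly after t
    (still undergoing resuscitation during minute t).
    """
    tdf = _timeline_frame(timelines)
    ids = np.asarray(tdf["id"], dtype=object)
    ecpr = np.array([-1 if pd.isna(v) else int(v) for v in tdf["ecpr_minute"]])
    disp = np.array([-1 if pd.isna(v) else int(v) for v in tdf["disposition_minute"]])
    out = []
    for t in np.unique(ecpr[ecpr >= 0]):
        treated = ids[ecpr == t]
        cand = ids[((ecpr < 0) | (ecpr > t)) & (disp > t)]
        out.append(RiskSet(minute=int(t), treated_ids=tuple(treated),
                           candidate_ids=tuple(cand)))
    return out


def sequential_match(risk_sets: list[RiskSet],
                     scores: Mapping[tuple[str, int], float],
                     caliper_k: float = 0.2,
                     score_sd: float = 1.0,
                     seed: int = 0,
                     stratum: str = "unknown") -> MatchedCohort:
    """Greedy nearest-neighbour matching over minutes in increasing order.

    Within a minute, treated patients are processed in a seeded random
    order; distance ties are broken towards the smaller control id. Treated
    patients with no candidate inside the caliper are recorded as unmatched
    (and excluded from analysis downstream).
    """
    if not score_sd > 0:
        raise ValueError("score_sd must be > 0")
    caliper = caliper_k * score_sd
    rng = np.random.default_rng(seed)
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    for rs in sorted(risk_sets, key=lambda r: r.minute):
        t = rs.minute
        cand_ids = list(rs.candidate_ids)
        try:
            cand_scores = np.array([scores[(c, t)] for c in cand_ids], dtype=float)
        except KeyError as e:
            raise ValueError(f"missing score for (id, minute) = {e.args[0]}") from None
        order = rng.permutation(len(rs.treated_ids))
        for k in order:
            tid = rs.treated_ids[k]
            if (tid, t) not in scores:
                raise ValueError(f"missing score for (id, minute) = {(tid, t)}")
            ts = scores[(tid, t)]
            if not cand_ids:
                unmatched.append(tid)
                continue
            dist = np.abs(cand_scores - ts)
            dmin = dist.min()
            if dmin > caliper:
                unmatched.append(tid)
                continue
            best = min(cand_ids[j] for j in np.flatnonzero(dist == dmin))
            pairs.append(MatchedPair(minute=t, treated_id=tid, control_id=best,
                                     treated_score=float(ts),
                                     control_score=float(scores[(best, t)])))
    return MatchedCohort(pairs=pairs, unmatched_treated=unmatched,
                         stratum=stratum, caliper=float(caliper))


def match_summary(matched: MatchedCohort, timelines) -> dict:
    """Deterministic summary of a matched cohort.

    ``pct_controls_later_treated`` counts unique patients ever used as a
    control whose own ECPR started after (any of) their pair minutes — with
    candidacy requiring no ECPR before or within the pair minute, this is
    simply the unique controls with an ECPR start.
    """
    tdf = _timeline_frame(timelines)
    ecpr = {pid: (None if pd.isna(v) else int(v))
            for pid, v in zip(tdf["id"], tdf["ecpr_minute"])}
    controls = {p.control_id for p in matched.pairs}
    later = {c for c in controls if ecpr.get(c) is not None}
    dists = np.array([p.distance for p in matched.pairs], dtype=float)
    return {
        "n_pairs": len(matched.pairs),
        "n_unmatched_treated": len(matched.unmatched_treated),
        "n_unique_controls": len(controls),
        "n_controls_later_treated": len(later),
        "pct_controls_later_treated": (100.0 * len(later) / len(controls)) if controls else 0.0,
        "distance_mean": float(dists.mean()) if dists.size else 0.0,
        "distance_median": float(np.median(dists)) if dists.size else 0.0,
        "distance_max": float(dists.max()) if dists.size else 0.0,
    }
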