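"""Balance diagnostics and matched-pairs effect estimation.

Standardised mean differences (SMD) follow the usual conventions:
continuous ``(m1 - m2) / sqrt((s1^2 + s2^2)/2)`` with sample variances,
binary the same with ``p(1-p)`` variances, and multi-level categorical
variables collapse to a single non-negative Mahalanobis-type SMD over the
level proportions. ``|SMD| < 0.25`` is the acceptability bound used for
balance flags.

For 1:1 matched pairs with one binary exposure, the conditional maximum
likelihood odds ratio is the ratio of discordant-pair counts ``n10/n01``
(concordant pairs carry no information); the 95% CI is Wald on the log
scale. Pairs sharing a control (matching with replacement) are treated as
independent in the likelihood — mirroring the analysis design, with the
robustness caveat documented rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .matching import MatchedCohort
from .registry import FIELD_IMPUTE_KIND, LEVELS, Cohort

SMD_FLAG_THRESHOLD = 0.25
_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Standardised mean differences
# ---------------------------------------------------------------------------


def smd(values_g1, values_g2, kind: str = "continuous") -> float:
    """Standardised mean difference between two groups.

    ``kind``: "continuous", "binary", or "categorical" (> 2 levels; returns
    the single non-negative multivariate Mahalanobis SMD).
    """
    v1 = pd.Series(values_g1).dropna()
    v2 = pd.Series(values_g2).dropna()
    if not len(v1) or not len(v2):
        raise ValueError("each group needs at least one observation")
    if kind == "continuous":
        a = v1.astype(float).to_numpy()
        b = v2.astype(float).to_numpy()
        m1, m2 = a.mean(), b.mean()
        s2 = (a.var(ddof=1) if a.size > 1 else 0.0,
              b.var(ddof=1) if b.size > 1 else 0.0)
        pooled = (s2[0] + s2[1]) / 2.0
        if pooled == 0.0:
            if m1 == m2:
                return 0.0
            raise ValueError("zero pooled variance with unequal means (degenerate comparison)")
        return float((m1 - m2) / np.sqrt(pooled))
    if kind == "binary":
        p1 = float(v1.astype(float).mean())
        p2 = float(v2.astype(float).mean())
        pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
        if pooled == 0.0:
            if p1 == p2:
                return 0.0
            raise ValueError("zero pooled variance with unequal proportions")
        return float((p1 - p2) / np.sqrt(pooled))
    if kind == "categorical":
        levels = sorted(set(v1) | set(v2), key=str)
        if len(levels) <= 2:
            lv = levels[-1]
            return abs(smd((v1 == lv).astype(float), (v2 == lv).astype(float), "binary"))
        # drop one level; Mahalanobis distance of the proportion vectors
        use = levels[1:]
        p1 = np.array([(v1 == lv).mean() for lv in use])
        p2 = np.array([(v2 == lv).mean() for lv in use])
        k = len(use)
        S = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                if i == j:
                    S[i, j] = (p1[i] * (1 - p1[i]) + p2[i] * (1 - p2[i])) / 2.0
                else:
                    S[i, j] = -(p1[i] * p1[j] + p2[i] * p2[j]) / 2.0
        diff = p1 - p2
        try:
            x = np.linalg.solve(S, diff)
        except np.linalg.LinAlgError:
            x = np.linalg.lstsq(S, diff, rcond=None)[0]
        return float(np.sqrt(max(diff @ x, 0.0)))
    raise ValueError(f"unknown SMD kind {kind!r}")


# ---------------------------------------------------------------------------
# Balance tables
# ---------------------------------------------------------------------------


def _summary(values: pd.Series, kind: str) -> str:
    v = values.dropna()
    if not len(v):
        return "-"
    if kind == "continuous":
        q1, med, q3 = np.percentile(v.astype(float), [25, 50, 75])
        return f"{med:g} ({q1:g}, {q3:g})"
    if kind == "binary":
        x = v.astype(float)
        return f"{int(x.sum())} ({100 * x.mean():.0f}%)"
    parts = []
    for lv in sorted(set(v), key=str):
        cnt = int((v == lv).sum())
        parts.append(f"{lv}: {cnt} ({100 * cnt / len(v):.0f}%)")
    return "; ".join(parts)


def _covariate_kind(name: str) -> str:
    if name in ("age", "call_to_hospital_min"):
        return "continuous"
    if name in LEVELS and len(LEVELS[name]) > 2:
        return "categorical"
    if FIELD_IMPUTE_KIND.get(name) == "categorical" and name in LEVELS:
        return "categorical"
    if name == "prehosp_adrenaline_n":
        return "categorical"
    if name == "volume_category":
        return "categorical"
    return "binary"


def balance_table(group1: pd.DataFrame, group2: pd.DataFrame,
                  covariates: list[str],
                  labels: tuple[str, str] = ("ECPR", "control"),
                  cohort_label: str = "matched") -> pd.DataFrame:
    """Per-covariate group summaries (median [IQR] / n (%)) and SMDs.

    ``group1`` / ``group2`` are covariate frames, one row per analysis unit
    (for a matched cohort: one row per pair and arm, so reused controls are
    counted once per pair, consistent with matching with replacement).
    """
    rows = []
    for cov in covariates:
        if cov not in group1.columns or cov not in group2.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        kind = _covariate_kind(cov)
        g1, g2 = group1[cov], group2[cov]
        if kind == "binary":
            value = smd(g1.dropna().astype(float), g2.dropna().astype(float), "binary")
        else:
            value = smd(g1, g2, kind)
        rows.append({
            "covariate": cov, "kind": kind,
            f"summary_{labels[0]}": _summary(g1, kind),
            f"summary_{labels[1]}": _summary(g2, kind),
            "smd": value, "flag_imbalance": abs(value) >= SMD_FLAG_THRESHOLD,
        })
    out = pd.DataFrame(rows)
    out.attrs["cohort_label"] = cohort_label
    return out


def matched_arm_frames(matched: MatchedCohort, cohort: Cohort,
                       extra: pd.DataFrame | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair-level covariate frames (treated arm, control arm).

    Controls appear once per pair they serve in. ``extra`` columns (e.g. the
    derived hospital-volume category) are joined by patient id.
    """
    rdf = cohort.records.set_index("id")
    if extra is not None:
        rdf = rdf.join(extra.set_index("id") if "id" in extra.columns else extra)
    t_ids = [p.treated_id for p in matched.pairs]
    c_ids = [p.control_id for p in matched.pairs]
    return (rdf.loc[t_ids].reset_index(), rdf.loc[c_ids].reset_index())


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------


def outcome_proportions(matched: MatchedCohort | pd.DataFrame, timelines,
                        outcome: str = "survival_30d") -> dict:
    """Per-arm outcome counts and percentages (1 decimal), pair-level.

    The ECPR arm is the treated member of each pair, the control arm the
    control member; with-replacement duplicates count once per pair, so both
    arm sizes equal the number of pairs.
    """
    from .matching import _timeline_frame

    pairs = matched.to_frame() if isinstance(matched, MatchedCohort) else matched
    tdf = _timeline_frame(timelines)
    y = {pid: bool(v) for pid, v in zip(tdf["id"], tdf[outcome])}
    yt = np.array([y[i] for i in pairs["treated_id"]], dtype=bool)
    yc = np.array([y[i] for i in pairs["control_id"]], dtype=bool)
    n = len(pairs)
    return {
        "outcome": outcome,
        "n_pairs": n,
        "ecpr": {"n_events": int(yt.sum()),
                 "pct": round(100.0 * yt.sum() / n, 1) if n else 0.0},
        "control": {"n_events": int(yc.sum()),
                    "pct": round(100.0 * yc.sum() / n, 1) if n else 0.0},
    }


# ---------------------------------------------------------------------------
# Conditional logistic effect estimate
# ---------------------------------------------------------------------------


@dataclass
class EffectEstimate:
    """Matched-pairs conditional odds ratio with 95% CI."""

    outcome: str
    n_pairs: int
    n10: int  # treated success, control failure
    n01: int  # treated failure, control success
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or_se: float
    boundary: str | None = None  # "zero" / "infinite" when a discordant count is 0

    @property
    def log_or(self) -> float:
        return float(np.log(self.odds_ratio))


def conditional_logit_1to1(y_treated, y_control,
                           outcome: str = "survival_30d") -> EffectEstimate:
    """Conditional ML odds ratio for 1:1 pairs with one binary exposure.

    ``OR = n10 / n01`` with Wald 95% CI
    ``exp(log(OR) +/- 1.96 sqrt(1/n10 + 1/n01))``. When a discordant count
    is zero the point estimate is degenerate; a one-sided 95% profile bound
    from the conditional (binomial) likelihood is reported instead of a Wald
    interval.
    """
    yt = np.asarray(y_treated, dtype=bool)
    yc = np.asarray(y_control, dtype=bool)
    if yt.shape != yc.shape:
        raise ValueError("treated/control outcome vectors differ in length")
    n10 = int((yt & ~yc).sum())
    n01 = int((~yt & yc).sum())
    if n10 + n01 < 1:
        raise ValueError("no discordant pairs; conditional OR undefined")
    m = n10 + n01
    if n01 == 0:
        # P(all m discordant successes are treated) = p^m; profile bound on OR
        p_low = 0.05 ** (1.0 / m)
        return EffectEstimate(outcome, len(yt), n10, n01, float("inf"),
                              p_low / (1 - p_low), float("inf"), float("nan"),
                              boundary="infinite")
    if n10 == 0:
        p_high = 1 - 0.05 ** (1.0 / m)
        return EffectEstimate(outcome, len(yt), n10, n01, 0.0,
                              0.0, p_high / (1 - p_high), float("nan"),
                              boundary="zero")
    or_hat = n10 / n01
    se = float(np.sqrt(1.0 / n10 + 1.0 / n01))
    lo = float(np.exp(np.log(or_hat) - _Z95 * se))
    hi = float(np.exp(np.log(or_hat) + _Z95 * se))
    return EffectEstimate(outcome, len(yt), n10, n01, float(or_hat), lo, hi, se)


def conditional_loglik(beta: float, y_treated, y_control) -> float:
    """Full conditional log-likelihood over pairs (used as the independent
    numeric cross-check of the closed-form estimate).

    Conditioning on the pair total: concordant pairs contribute 0; a
    discordant pair contributes ``beta*1{treated success} - log(1 + e^beta)``.
    """
    yt = np.asarray(y_treated, dtype=bool)
    yc = np.asarray(y_control, dtype=bool)
    n10 = int((yt & ~yc).sum())
    n01 = int((~yt & yc).sum())
    return float(n10 * beta - (n10 + n01) * np.log1p(np.exp(beta)))


def conditional_logit_numeric(y_treated, y_control) -> float:
    """Numeric maximiser of :func:`conditional_loglik`; returns the log-OR."""
    res = optimize.minimize_scalar(
        lambda b: -conditional_loglik(b, y_treated, y_control),
        bounds=(-30.0, 30.0), method="bounded",
        options={"xatol": 1e-10})
    return float(res.x)


def pair_outcomes(matched: MatchedCohort | pd.DataFrame, timelines,
                  outcome: str = "survival_30d") -> tuple[np.ndarray, np.ndarray]:
    """Binary outcome vectors (treated, control) aligned to the pairs."""
    from .matching import _timeline_frame

    pairs = matched.to_frame() if isinstance(matched, MatchedCohort) else matched
    tdf = _timeline_frame(timelines)
    y = {pid: bool(v) for pid, v in zip(tdf["id"], tdf[outcome])}
    yt = np.array([y[i] for i in pairs["treated_id"]], dtype=bool)
    yc = np.array([y[i] for i in pairs["control_id"]], dtype=bool)
    return yt, yc


def mcnemar_table(y_treated, y_control) -> dict:
    yt = np.asarray(y_treated, dtype=bool)
    yc = np.asarray(y_control, dtype=bool)
    return {"n11": int((yt & yc).sum()), "n10": int((yt & ~yc).sum()),
            "n01": int((~yt & yc).sum()), "n00": int((~yt & ~yc).sum())}
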