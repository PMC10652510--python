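"""Independent brute-force oracles.

Everything here is written against the *definitions* (set comprehensions,
direct likelihood evaluation, scalar optimisation), deliberately sharing no
code path with the package implementation it cross-checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar


# ---------------------------------------------------------------------------
# Brute-force sequential risk-set matcher
# ---------------------------------------------------------------------------


def brute_force_match(timelines: list[dict], scores: dict, caliper: float,
                      seed: int):
    """Direct re-implementation of sequential 1:1 risk-set matching.

    ``timelines``: list of dicts with id, ecpr_minute (None allowed),
    disposition_minute. Returns (pairs, unmatched) where pairs are
    (minute, treated_id, control_id) triples. Shares the package's seeding
    convention (one generator, a permutation per event minute in increasing
    order) but derives risk sets and nearest neighbours from scratch.
    """
    ids = [t["id"] for t in timelines]
    ecpr = {t["id"]: t["ecpr_minute"] for t in timelines}
    disp = {t["id"]: t["disposition_minute"] for t in timelines}
    minutes = sorted({m for m in ecpr.values() if m is not None})
    rng = np.random.default_rng(seed)
    pairs, unmatched = [], []
    for t in minutes:
        treated = [i for i in ids if ecpr[i] == t]
        cands = [i for i in ids
                 if (ecpr[i] is None or ecpr[i] > t) and disp[i] > t]
        for k in rng.permutation(len(treated)):
            tid = treated[k]
            best, best_d = None, None
            for c in cands:
                d = abs(scores[(c, t)] - scores[(tid, t)])
                if d > caliper:
                    continue
                if best is None or d < best_d or (d == best_d and c < best):
                    best, best_d = c, d
            if best is None:
                unmatched.append(tid)
            else:
                pairs.append((t, tid, best))
    return pairs, unmatched


# ---------------------------------------------------------------------------
# Partial-likelihood oracles
# ---------------------------------------------------------------------------


def partial_loglik_from_risk_sets(beta: np.ndarray, events: list[dict]) -> float:
    """Breslow log partial likelihood evaluated directly from enumerated
    risk sets: events = [{x_event: vector, risk_x: matrix, risk_w: vector}].
    """
    beta = np.atleast_1d(beta)
    ll = 0.0
    for ev in events:
        ll += float(np.dot(ev["x_event"], beta))
        ll -= np.log(np.sum(ev["risk_w"] * np.exp(ev["risk_x"] @ beta)))
    return ll


def maximize_partial_loglik(events: list[dict], p: int) -> np.ndarray:
    res = minimize(lambda b: -partial_loglik_from_risk_sets(b, events),
                   np.zeros(p), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return np.atleast_1d(res.x)


# ---------------------------------------------------------------------------
# Conditional-likelihood oracle for matched pairs
# ---------------------------------------------------------------------------


def conditional_logit_oracle(y_treated, y_control) -> float:
    """Numeric maximiser of the pairwise conditional log-likelihood.

    Each pair's contribution is computed pair by pair from the conditioning
    argument: pairs with total 0 or 2 successes contribute a constant; a
    discordant pair contributes ``b*yt - log(1 + e^b)``.
    """
    yt = np.asarray(y_treated, dtype=int)
    yc = np.asarray(y_control, dtype=int)

    def negll(b):
        ll = 0.0
        for a, c in zip(yt, yc):
            if a + c == 1:
                ll += b * a - np.logaddexp(0.0, b)
        return -ll

    res = minimize_scalar(negll, bounds=(-25, 25), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


# ---------------------------------------------------------------------------
# Truncated geometric expectation
# ---------------------------------------------------------------------------


def truncated_geometric_mean(p: float, horizon: int) -> float:
    """E[T | T < horizon] for T ~ Geometric(p) on {0, 1, 2, ...}."""
    k = np.arange(horizon)
    pmf = p * (1 - p) ** k
    return float((k * pmf).sum() / pmf.sum())
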