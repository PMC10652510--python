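"""Iterative ensemble-of-trees imputation of missing covariates.

The algorithm is the classic iterative random-forest scheme: initialise
missing cells with the observed mean (continuous) or mode (categorical),
loop over the incomplete variables in increasing order of missingness, fit
a random-forest regressor / classifier for each on the rows where it is
observed (using all other covariates, current imputations included) and
predict its missing rows. Iterations stop the first time the normalised
change statistic increases — separately tracked for continuous
(``sum (new-old)^2 / sum new^2``) and categorical (fraction of changed
imputed cells) variables — returning the previous iteration's values, or
when ``max_iter`` is reached.

Only baseline / pre-hospital covariates are imputed; event times,
dispositions and outcomes are never touched (records with a missing
disposition are excluded from the study, not imputed). Imputation is meant
to run on the eligible cohort, after the study-flow filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .errors import ConfigError
from .registry import FIELD_IMPUTE_KIND, MASKABLE_FIELDS, Cohort


@dataclass
class ImputationResult:
    cohort: Cohort
    iterations_run: int
    converged: bool
    #: per-iteration (continuous, categorical) change statistics
    change_trace: list[tuple[float, float]]


def _encode_matrix(df: pd.DataFrame, fields: list[str]) -> np.ndarray:
    """Numeric predictor matrix: continuous as floats, categoricals one-hot."""
    cols = []
    for f in fields:
        s = df[f]
        if FIELD_IMPUTE_KIND[f] == "continuous":
            cols.append(s.astype(float).to_numpy()[:, None])
        else:
            levels = sorted({str(v) for v in s.dropna()})
            arr = np.zeros((len(df), len(levels)))
            sv = s.astype("object").astype(str)
            for j, lv in enumerate(levels):
                arr[:, j] = (sv == lv).to_numpy(dtype=float)
            cols.append(arr)
    return np.hstack(cols) if cols else np.empty((len(df), 0))


def impute_missing(cohort: Cohort, seed: int = 0, max_iter: int = 10,
                   n_estimators: int = 100, fields: list[str] | None = None,
                   ) -> ImputationResult:
    """Impute missing covariates on a cohort; observed cells are never modified.

    Deterministic given ``seed``. Raises if a field is 100% missing (nothing
    to learn from) or if no fully observed field exists.
    """
    fields = list(fields) if fields is not None else [
        f for f in MASKABLE_FIELDS if f in cohort.records.columns]
    rdf = cohort.records.copy()
    n = len(rdf)
    if n == 0:
        return ImputationResult(cohort, 0, True, [])

    miss = {f: rdf[f].isna().to_numpy() for f in fields}
    for f in fields:
        if miss[f].all():
            raise ConfigError(f"field {f!r} is 100% missing and cannot be imputed")
    if not any((~m).all() for m in miss.values()):
        raise ConfigError("imputation requires at least one fully observed field")
    incomplete = sorted((f for f in fields if miss[f].any()),
                        key=lambda f: (miss[f].mean(), f))
    if not incomplete:
        return ImputationResult(cohort, 0, True, [])

    # observed level sets / moments for initialisation
    work = rdf[fields].copy()
    kinds = {f: FIELD_IMPUTE_KIND[f] for f in fields}
    for f in fields:
        if not miss[f].any():
            continue
        obs = rdf.loc[~miss[f], f]
        if kinds[f] == "continuous":
            fill = float(obs.astype(float).mean())
            work[f] = work[f].astype(float)
            work.loc[miss[f], f] = fill
        else:
            mode = obs.mode()
            work.loc[miss[f], f] = mode.iloc[0]

    rng = np.random.default_rng(seed)
    prev_change = (np.inf, np.inf)
    trace: list[tuple[float, float]] = []
    converged = False
    iterations = 0

    for it in range(1, max_iter + 1):
        current = work.copy()
        for f in incomplete:
            m = miss[f]
            predictors = [g for g in fields if g != f]
            X = _encode_matrix(current, predictors)
            seed_f = int(rng.integers(0, 2**31 - 1))
            if kinds[f] == "continuous":
                model = RandomForestRegressor(
                    n_estimators=n_estimators, random_state=seed_f, n_jobs=1)
                y = current.loc[~m, f].astype(float).to_numpy()
                if not np.isfinite(X[~m]).all() or not np.isfinite(y).all():
                    raise ConfigError(f"non-finite learner inputs for field {f!r}")
                model.fit(X[~m], y)
                pred = model.predict(X[m])
                current.loc[m, f] = pred
            else:
                model = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=seed_f, n_jobs=1)
                y = current.loc[~m, f].astype("object").astype(str).to_numpy()
                if not np.isfinite(X[~m]).all():
                    raise ConfigError(f"non-finite learner inputs for field {f!r}")
                model.fit(X[~m], y)
                pred = model.predict(X[m])
                obs_levels = {str(v) for v in rdf.loc[~m, f]}
                assert set(pred) <= obs_levels
                current.loc[m, f] = _decode_levels(pred, rdf.loc[~m, f])

        # normalised change statistics over imputed cells
        num, den, changed, total = 0.0, 0.0, 0, 0
        for f in incomplete:
            m = miss[f]
            if kinds[f] == "continuous":
                new = current.loc[m, f].astype(float).to_numpy()
                old = work.loc[m, f].astype(float).to_numpy()
                num += float(((new - old) ** 2).sum())
                den += float((new ** 2).sum())
            else:
                new = current.loc[m, f].astype("object").to_numpy()
                old = work.loc[m, f].astype("object").to_numpy()
                changed += int((new != old).sum())
                total += int(m.sum())
        d_cont = num / den if den > 0 else 0.0
        d_cat = changed / total if total > 0 else 0.0
        trace.append((d_cont, d_cat))
        iterations = it

        cont_present = any(kinds[f] == "continuous" for f in incomplete)
        cat_present = any(kinds[f] != "continuous" for f in incomplete)
        inc_cont = d_cont > prev_change[0] if cont_present else True
        inc_cat = d_cat > prev_change[1] if cat_present else True
        if it > 1 and inc_cont and inc_cat:
            # change statistic increased: keep the previous iterate
            current = work
            converged = True
            break
        work = current
        prev_change = (d_cont, d_cat)
    else:
        current = work

    out = rdf.copy()
    for f in incomplete:
        m = miss[f]
        col = out[f]
        if kinds[f] == "continuous" and str(rdf[f].dtype) == "Int64":
            vals = np.round(current.loc[m, f].astype(float)).astype(int)
            col = col.copy()
            col[m] = vals
        else:
            col = col.copy()
            col[m] = current.loc[m, f].to_numpy()
        out[f] = col
    completed = Cohort(out, cohort.timelines.copy(), stratum=cohort.stratum,
                       validate=False)
    return ImputationResult(completed, iterations, converged, trace)


def _decode_levels(pred: np.ndarray, observed: pd.Series):
    """Map string class labels back to the observed column's value type."""
    sample = observed.iloc[0]
    if isinstance(sample, (bool, np.bool_)):
        return np.array([p == "True" for p in pred], dtype=object)
    if isinstance(sample, (int, np.integer)):
        return np.array([int(p) for p in pred], dtype=object)
    return pred.astype(object)


def mean_mode_impute(cohort: Cohort, fields: list[str] | None = None) -> Cohort:
    """Single-pass mean/mode imputation (the comparison baseline)."""
    fields = list(fields) if fields is not None else [
        f for f in MASKABLE_FIELDS if f in cohort.records.columns]
    rdf = cohort.records.copy()
    for f in fields:
        m = rdf[f].isna()
        if not m.any() or m.all():
            continue
        obs = rdf.loc[~m, f]
        col = rdf[f].copy()
        if FIELD_IMPUTE_KIND[f] == "continuous":
            fill = float(obs.astype(float).mean())
            if str(col.dtype) == "Int64":
                fill = int(round(fill))
            col[m] = fill
        else:
            col[m] = obs.mode().iloc[0]
        rdf[f] = col
    return Cohort(rdf, cohort.timelines.copy(), stratum=cohort.stratum, validate=False)
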