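"""Model evaluation: Kaplan-Meier risk-group comparison, time-dependent
ROC/AUC at fixed horizons, and multivariable Cox independence testing.

The time-dependent ROC follows the cumulative-case / dynamic-control
construction: at horizon t, cases are subjects with an event by t and
controls are subjects surviving past t. Censoring before t is handled
through Kaplan-Meier estimates of survival conditional on the marker
exceeding each cutoff (KM estimator) or through nearest-neighbour
smoothing in marker rank (NNE, span 0.25 * n^-0.20). With no censoring
before the horizon the KM construction reduces exactly to the empirical
ROC, whose trapezoidal AUC is the Mann-Whitney probability that a case
outranks a control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .containers import DAYS_PER_YEAR, ReopairError, SurvivalTable
from .coxph import ConvergenceError, cox_fit


def _km_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Product-limit survival estimate S(t) for one sample subset."""
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    s = 1.0
    i = 0
    n = len(ts)
    while i < n and ts[i] <= t:
        j = i
        d = 0
        at_risk = n - i
        while j < n and ts[j] == ts[i]:
            d += int(es[j])
            j += 1
        if d:
            s *= 1.0 - d / at_risk
        i = j
    return s


@dataclass
class TimedROC:
    """Time-dependent ROC curve at a fixed horizon."""

    horizon_years: float
    cutoffs: np.ndarray          # ascending score cutoffs ("positive" = score >= c)
    sensitivity: np.ndarray      # monotone-cleaned, for reporting
    specificity: np.ndarray      # monotone-cleaned, for reporting
    sensitivity_raw: np.ndarray
    specificity_raw: np.ndarray
    auc: float
    estimator: str               # 'KM' or 'NNE'

    def youden(self) -> pd.DataFrame:
        """Per-cutoff Youden index J = sensitivity + specificity - 1 (raw curve)."""
        return pd.DataFrame({
            "cutoff": self.cutoffs,
            "J": self.sensitivity_raw + self.specificity_raw - 1.0,
        })


def time_dependent_roc(
    scores,
    surv: SurvivalTable,
    horizon_years: float,
    estimator: str = "KM",
) -> TimedROC:
    """Cumulative-case / dynamic-control ROC at ``horizon_years``.

    ``scores`` is a per-sample Series (indexed by sample id) or an array
    aligned to the survival table. Subjects censored before the horizon
    contribute through the conditional survival estimates, not as cases or
    controls directly.
    """
    if isinstance(scores, pd.Series):
        surv = surv.subset(scores.index)
        x = scores.to_numpy(float)
    else:
        x = np.asarray(scores, float)
        if len(x) != len(surv.data):
            raise ReopairError("scores and survival table length mismatch")
    time, event = surv.times_events()
    if np.isnan(time).any():
        raise ReopairError("survival times missing; filter the cohort first")
    t = horizon_years * DAYS_PER_YEAR
    n = len(x)
    if event[time <= t].sum() == 0:
        raise ReopairError("no events before the horizon (no cases)")
    if (time > t).sum() == 0:
        raise ReopairError("no subjects surviving past the horizon (no controls)")

    cutoffs = np.unique(x)
    if estimator.upper() == "KM":
        s_all = _km_at(time, event, t)
        sens = np.empty(len(cutoffs))
        spec = np.empty(len(cutoffs))
        for i, c in enumerate(cutoffs):
            mask = x >= c
            p_c = mask.mean()
            s_c = _km_at(time[mask], event[mask], t)
            # Bayes inversion of P(T<=t | M>=c)
            sens[i] = (1.0 - s_c) * p_c / max(1.0 - s_all, 1e-300)
            spec[i] = 1.0 - s_c * p_c / max(s_all, 1e-300)
    elif estimator.upper() == "NNE":
        span = 0.25 * n ** (-0.20)
        ranks = pd.Series(x).rank(method="average").to_numpy() / n
        s_cond = np.empty(n)
        for i in range(n):
            nb = np.abs(ranks - ranks[i]) <= span
            s_cond[i] = _km_at(time[nb], event[nb], t)
        s_all = s_cond.mean()
        sens = np.empty(len(cutoffs))
        spec = np.empty(len(cutoffs))
        for i, c in enumerate(cutoffs):
            mask = x >= c
            joint = s_cond[mask].sum() / n          # P(M >= c, T > t)
            p_c = mask.mean()
            sens[i] = (p_c - joint) / max(1.0 - s_all, 1e-300)
            spec[i] = 1.0 - joint / max(s_all, 1e-300)
    else:
        raise ReopairError(f"unknown ROC estimator {estimator!r}")

    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    # integrate along the curve ordered by decreasing cutoff: (0,0) -> (1,1)
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    # isotonic cleanup for curve reporting only (raw curve feeds the AUC/Youden)
    sens_clean = np.maximum.accumulate(sens[::-1])[::-1]
    spec_clean = np.maximum.accumulate(spec)
    return TimedROC(horizon_years, cutoffs, sens_clean, spec_clean,
                    sens, spec, auc, estimator.upper())


def km_logrank(assignment: pd.Series, surv: SurvivalTable) -> dict:
    """Kaplan-Meier curves and two-sample log-rank test between risk groups.

    ``assignment`` maps sample id -> group label (e.g. 'high'/'low'). Returns
    ``{'curves': {group: DataFrame}, 'statistic', 'p'}``.
    """
    surv = surv.subset(assignment.index)
    groups = sorted(assignment.unique())
    if len(groups) < 2:
        raise ReopairError(f"need two groups for a log-rank test, got {groups}")
    if len(groups) > 2:
        raise ReopairError("km_logrank compares exactly two groups")
    time, event = surv.times_events()
    curves = {}
    masks = {}
    for g in groups:
        m = (assignment == g).to_numpy()
        masks[g] = m
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(g))
        curves[g] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(g): "survival"}
        )
    res = logrank_test(time[masks[groups[0]]], time[masks[groups[1]]],
                       event[masks[groups[0]]], event[masks[groups[1]]])
    return {"curves": curves, "statistic": float(res.test_statistic),
            "p": float(res.p_value)}


def _encode_covariates(
    surv: SurvivalTable,
    collapse_stage: bool = True,
    collapse_grade: bool = True,
) -> pd.DataFrame:
    """Encode clinical covariates for Cox fitting.

    gender: male = 1 (reference female); stage: III-IV = 1 (reference I-II);
    grade: G3-G4 = 1 (reference G1-G2); age continuous in years.
    """
    df = surv.data
    out = pd.DataFrame(index=df.index)
    if "age" in df:
        out["age"] = df["age"].astype(float)
    if "gender" in df:
        out["gender_male"] = (df["gender"].astype(str).str.lower() == "male").astype(float)
    if "stage" in df:
        s = df["stage"].astype(str).str.upper().str.replace("STAGE ", "", regex=False)
        if collapse_stage:
            out["stage_III_IV"] = s.isin(["III", "IV", "IIIA", "IIIB", "IIIC", "IVA", "IVB"]).astype(float)
        else:
            for lev in sorted(s.unique())[1:]:
                out[f"stage_{lev}"] = (s == lev).astype(float)
    if "grade" in df:
        g = df["grade"].astype(str).str.upper()
        if collapse_grade:
            out["grade_G3_G4"] = g.isin(["G3", "G4"]).astype(float)
        else:
            for lev in sorted(g.unique())[1:]:
                out[f"grade_{lev}"] = (g == lev).astype(float)
    return out


def multivariate_cox(
    risk: pd.Series,
    surv: SurvivalTable,
    risk_name: str = "risk_score",
    collapse_stage: bool = True,
    collapse_grade: bool = True,
) -> pd.DataFrame:
    """Multivariable Cox fit of survival on the risk score plus clinical covariates.

    ``risk`` is a per-sample Series (continuous score or 0/1 group
    indicator). Constant or collinear covariates are dropped with a
    warning. Returns the per-covariate hazard-ratio table (``beta``,
    ``hr``, 95% CI, ``p``).
    """
    surv = surv.subset(risk.index)
    design = _encode_covariates(surv, collapse_stage, collapse_grade)
    design.insert(0, risk_name, risk.astype(float))
    # drop constant columns, then greedily drop columns that do not raise rank
    const = [c for c in design.columns if design[c].nunique() < 2]
    if const:
        warnings.warn(f"constant covariates dropped: {const}")
        design = design.drop(columns=const)
    kept = []
    mat = np.empty((len(design), 0))
    for c in design.columns:
        cand = np.column_stack([mat, design[c].to_numpy(float)])
        centred = cand - cand.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-8) == cand.shape[1]:
            kept.append(c)
            mat = cand
        else:
            warnings.warn(f"collinear covariate dropped: {c}")
    design = design[kept]
    time, event = surv.times_events()
    if event.sum() < design.shape[1]:
        warnings.warn("fewer events than covariates; estimates may be unstable")
    fit = cox_fit(design, time, event, ties="breslow")
    return fit.summary()
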