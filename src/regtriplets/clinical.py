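"""Clinical utilities for regulatory triplets.

A triplet's prognostic score is the linear combination of its three genes'
expression weighted by multivariate Cox proportional-hazards coefficients:

    score = coef_lnc * exp_lnc + coef_imm * exp_imm + coef_ssg * exp_ssg.

Patients are stratified at the score cutoff maximizing the two-group
log-rank statistic (maximally selected rank statistic, with a minimum
group-size fraction), and triplets are screened for prognostic relevance
by requiring P < 0.05 in both a univariate Cox fit and a log-rank test.
Cox numerics are delegated to lifelines; the contract here is the score
construction, the stratification rule and the dual significance criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

from .io import ExpressionCohort


@dataclass
class TripletScoreModel:
    coef_lnc: float
    coef_imm: float
    coef_ssg: float
    scores: pd.Series  # sample -> score


@dataclass
class BreadthClass:
    labels: pd.DataFrame  # index lncRNA; columns n_cancer_types, label
    pattern_variable_pairs: set[tuple[str, str]]


def _survival_frame(cohort: ExpressionCohort) -> pd.DataFrame:
    if cohort.survival is None:
        raise ValueError("cohort has no survival metadata")
    surv = cohort.survival.dropna()
    if surv.empty:
        raise ValueError("no samples with survival metadata")
    return surv


def fit_triplet_score(
    cohort: ExpressionCohort, triplet: tuple[str, str, str], min_events: int = 20
) -> TripletScoreModel:
    """Multivariate Cox fit of (lncRNA, immune, SSG) expression; linear score."""
    lnc, imm, ssg = triplet
    surv = _survival_frame(cohort)
    if int(surv["event"].sum()) < min_events:
        raise ValueError(
            f"need >= {min_events} events, got {int(surv['event'].sum())}"
        )
    samples = list(surv.index)
    df = pd.DataFrame(
        {
            "time": surv["time"],
            "event": surv["event"],
            "lnc": cohort.values.loc[lnc, samples],
            "imm": cohort.values.loc[imm, samples],
            "ssg": cohort.values.loc[ssg, samples],
        }
    )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge for {triplet}: {err}") from err
    coef = cph.params_
    scores = (
        coef["lnc"] * cohort.values.loc[lnc]
        + coef["imm"] * cohort.values.loc[imm]
        + coef["ssg"] * cohort.values.loc[ssg]
    )
    return TripletScoreModel(
        coef_lnc=float(coef["lnc"]),
        coef_imm=float(coef["imm"]),
        coef_ssg=float(coef["ssg"]),
        scores=scores,
    )


def triplet_score(coefs: tuple[float, float, float], expressions) -> np.ndarray:
    """The linear triplet score for given coefficients and expression rows."""
    c = np.asarray(coefs, dtype=float)
    X = np.asarray(expressions, dtype=float)
    return c @ X


def optimal_cutoff_stratify(
    scores, survival: pd.DataFrame, min_group_fraction: float = 0.1
) -> tuple[float, pd.Index, pd.Index, float]:
    """Maximally selected log-rank cutoff on a per-sample score.

    Every admissible split (both groups at least ``min_group_fraction`` of
    samples, cutoffs taken between consecutive distinct scores inside the
    corresponding quantile band) is evaluated with the two-group log-rank
    statistic; the split maximizing the statistic is returned together with
    its (naive) log-rank p-value.
    """
    scores = pd.Series(scores)
    scores = scores.loc[survival.index]
    if scores.nunique() < 2:
        raise ValueError("all scores identical; no admissible cutoff")
    n = len(scores)
    min_size = max(1, int(np.ceil(min_group_fraction * n)))
    order = scores.sort_values()
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=float)

    best: tuple[float, float, float] | None = None  # (stat, cutoff, p)
    vals = order.to_numpy()
    for i in range(min_size - 1, n - min_size):
        if vals[i] == vals[i + 1]:
            continue
        cutoff = 0.5 * (vals[i] + vals[i + 1])
        high = (scores > cutoff).to_numpy()
        res = logrank_test(time[high], time[~high], event[high], event[~high])
        stat = float(res.test_statistic)
        if best is None or stat > best[0]:
            best = (stat, cutoff, float(res.p_value))
    if best is None:
        raise ValueError("no admissible cutoff under the group-size constraint")
    _, cutoff, p = best
    high_idx = scores.index[scores > cutoff]
    low_idx = scores.index[scores <= cutoff]
    return cutoff, high_idx, low_idx, p


def classify_breadth(
    lnc_cancer_types: dict[str, set],
    pair_patterns: dict[tuple[str, str], dict[str, set]] | None = None,
    common_min: int = 11,
    specific_max: int = 2,
) -> BreadthClass:
    """Breadth classification of lncRNAs across cancer types.

    A lncRNA detected in more than 10 cancer types is ``common``, in no more
    than 2 is ``specific``, otherwise ``intermediate``.  A (lncRNA, SSG)
    pair present in more than 10 cancer types with at least 2 distinct
    selected patterns across them is flagged pattern-variable.
    """
    records = []
    for lnc, cancers in lnc_cancer_types.items():
        count = len(set(cancers))
        if count >= common_min:
            label = "common"
        elif count <= specific_max:
            label = "specific"
        else:
            label = "intermediate"
        records.append({"lncRNA": lnc, "n_cancer_types": count, "label": label})
    labels = pd.DataFrame(records).set_index("lncRNA") if records else pd.DataFrame(
        columns=["n_cancer_types", "label"]
    )

    variable: set[tuple[str, str]] = set()
    if pair_patterns:
        for pair, per_cancer in pair_patterns.items():
            cancers = set(per_cancer)
            patterns = set().union(*(set(v) if not isinstance(v, str) else {v}
                                     for v in per_cancer.values()))
            if len(cancers) >= common_min and len(patterns) >= 2:
                variable.add(tuple(pair))
    return BreadthClass(labels=labels, pattern_variable_pairs=variable)


def overlap_significance(set_a, set_b, universe_size: int) -> float:
    """Hypergeometric upper-tail P(overlap >= observed)."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))


def km_table(survival: pd.DataFrame, groups: dict[str, pd.Index]) -> pd.DataFrame:
    """Kaplan-Meier event table (time, at-risk, events) per named group."""
    from lifelines import KaplanMeierFitter

    frames = []
    for name, idx in groups.items():
        sub = survival.loc[idx]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        et = kmf.event_table.reset_index().rename(
            columns={"event_at": "time", "observed": "events"}
        )
        et["group"] = name
        frames.append(et[["group", "time", "at_risk", "events"]])
    return pd.concat(frames, ignore_index=True)


def prognostic_screen(
    cohort: ExpressionCohort,
    triplets: list[tuple[str, str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dual univariate-Cox / log-rank prognostic screen of triplets.

    Each triplet is summarized by the mean of its three genes' standardized
    expression (an unfitted score, so the screen stays calibrated under the
    null); the flag requires P < alpha in both the univariate Cox fit on the
    summary and the log-rank test at its median split.
    """
    surv = _survival_frame(cohort)
    samples = list(surv.index)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=float)
    rows = []
    for triplet in triplets:
        X = cohort.values.loc[list(triplet), samples].to_numpy(dtype=float)
        Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        summary = Xz.mean(axis=0)
        df = pd.DataFrame({"time": time, "event": event, "score": summary})
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
            cox_p = float(cph.summary.loc["score", "p"])
        except ConvergenceError:
            warnings.warn(f"univariate Cox failed to converge for {triplet}")
            cox_p = float("nan")
        high = summary > np.median(summary)
        lr = logrank_test(time[high], time[~high], event[high], event[~high])
        lr_p = float(lr.p_value)
        rows.append(
            {
                "lncRNA": triplet[0],
                "immune": triplet[1],
                "SSG": triplet[2],
                "cox_p": cox_p,
                "logrank_p": lr_p,
                "prognostic": bool(cox_p < alpha and lr_p < alpha),
            }
        )
    return pd.DataFrame(rows)
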