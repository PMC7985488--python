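"""Expression-group survival analysis: No/Low/High stratification,
Kaplan-Meier curves, and covariate-adjusted Cox proportional hazards.

Samples with an undetectable canonical-isoform count (zero junction reads)
form the "No" group; the remaining samples are split at their median count
into "Low" (< median, ties included) and "High" (> median).  The
product-limit estimator is implemented here; the Cox partial-likelihood fit
(Efron ties, adjusted for sex, age and an ordered tumor-stage covariate) is
delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "ExpressionGrouping",
    "KaplanMeierCurve",
    "CoxResult",
    "stratify_expression_groups",
    "kaplan_meier",
    "kaplan_meier_by_group",
    "cox_adjusted",
    "median_survival",
]

GROUPS = ("No", "Low", "High")


@dataclass(frozen=True)
class ExpressionGrouping:
    assignments: dict[str, str]  # sample_id -> No | Low | High
    median_used: float
    n_no: int
    n_low: int
    n_high: int

    def __post_init__(self):
        if self.n_no + self.n_low + self.n_high != len(self.assignments):
            raise ValueError("group sizes do not partition the samples")


@dataclass(frozen=True)
class KaplanMeierCurve:
    group: str
    times: np.ndarray       # event times, increasing
    at_risk: np.ndarray     # number at risk just before each time
    survival: np.ndarray    # S(t) after each event time

    def __post_init__(self):
        s = np.asarray(self.survival)
        if s.size and (np.any(np.diff(s) > 1e-12) or s[0] > 1.0 + 1e-12):
            raise ValueError("survival curve must be non-increasing from <= 1")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "at_risk": self.at_risk, "survival": self.survival}
        )


@dataclass(frozen=True)
class CoxResult:
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    pvalues: dict[str, float]
    n: int
    n_events: int


def stratify_expression_groups(counts: dict[str, float]) -> ExpressionGrouping:
    """No (zero count) / Low (<= nonzero median) / High (> median) grouping."""
    values = np.array(list(counts.values()), dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero cohort; grouping undefined")
    if nonzero.size < 3:
        raise ValueError("need >= 3 nonzero samples to split at the median")
    median = float(np.median(nonzero))
    assignments = {}
    for sid, c in counts.items():
        assignments[sid] = "No" if c == 0 else ("High" if c > median else "Low")
    n = {g: sum(v == g for v in assignments.values()) for g in GROUPS}
    if n["High"] == 0:
        warnings.warn("High group is empty (all nonzero counts tie at the median)")
    return ExpressionGrouping(
        assignments=assignments, median_used=median,
        n_no=n["No"], n_low=n["Low"], n_high=n["High"],
    )


def kaplan_meier(times, events, group: str = "all") -> KaplanMeierCurve:
    """Product-limit estimator; censored samples leave the risk set silently."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events])
    out_t, out_r, out_s = [], [], []
    s = 1.0
    for t in uniq:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / n_risk
        out_t.append(t)
        out_r.append(n_risk)
        out_s.append(s)
    return KaplanMeierCurve(
        group=group,
        times=np.array(out_t),
        at_risk=np.array(out_r),
        survival=np.array(out_s),
    )


def kaplan_meier_by_group(
    grouping: ExpressionGrouping,
    times: dict[str, float],
    events: dict[str, bool],
) -> dict[str, KaplanMeierCurve]:
    curves = {}
    for g in GROUPS:
        ids = [s for s, gg in grouping.assignments.items() if gg == g]
        if not ids:
            warnings.warn(f"group {g} empty; curve omitted")
            continue
        curves[g] = kaplan_meier(
            [times[s] for s in ids], [events[s] for s in ids], group=g
        )
    return curves


def median_survival(curve: KaplanMeierCurve) -> float:
    """First time at which S(t) drops to <= 0.5 (inf if never reached)."""
    below = np.flatnonzero(curve.survival <= 0.5)
    return float(curve.times[below[0]]) if below.size else float("inf")


_SEX_CODE = {"F": 0, "M": 1}


def cox_adjusted(
    grouping: ExpressionGrouping,
    covariates: pd.DataFrame,  # index sample_id; columns sex, age, stage
    times: dict[str, float],
    events: dict[str, bool],
) -> CoxResult:
    """Cox PH fit of group indicators (vs "No") adjusted for sex, age, stage.

    Stage is encoded as an ordered integer, sex as a 0/1 indicator.  Raises
    on non-convergence or separation, naming the model.
    """
    rows = []
    for sid, g in grouping.assignments.items():
        cov = covariates.loc[sid]
        rows.append({
            "group_low": int(g == "Low"),
            "group_high": int(g == "High"),
            "sex": _SEX_CODE.get(cov["sex"], cov["sex"]),
            "age": float(cov["age"]),
            "stage": int(cov["stage"]),
            "time": float(times[sid]),
            "event": int(events[sid]),
        })
    df = pd.DataFrame(rows)
    for term in ("group_low", "group_high"):
        if df.loc[df[term] == 1, "event"].sum() == 0 and df[term].any():
            raise ValueError(f"no events in level {term}; model not identifiable")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    terms = list(summary.index)
    return CoxResult(
        hazard_ratios={t: float(summary.loc[t, "exp(coef)"]) for t in terms},
        ci_lower={t: float(summary.loc[t, "exp(coef) lower 95%"]) for t in terms},
        ci_upper={t: float(summary.loc[t, "exp(coef) upper 95%"]) for t in terms},
        pvalues={t: float(summary.loc[t, "p"]) for t in terms},
        n=len(df),
        n_events=int(df["event"].sum()),
    )
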