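"""Small-cohort survival endpoints: MST, MeST, ILS and survival curves.

MST is the arithmetic mean survival time and MeST the median; both
include censored animals at their observed time (a long-lived cured
animal contributes its full observation span, matching how preclinical
summaries are reported). The increase in lifespan (ILS) compares a
treated group's statistic to a reference group as a percent gain.
Group survival curves are Kaplan-Meier product-limit estimates, which
honour censoring and reduce to the empirical survivor function without
it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "CohortSurvival",
    "SurvivalSummary",
    "summarize",
    "ils",
    "survival_curve",
    "round_sig",
]


@dataclass(frozen=True)
class CohortSurvival:
    """Per-animal survival table: id, group label, days, event flag (1 = death)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "group", "days", "event"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("cohort table is empty")
        if (self.table["days"] <= 0).any():
            raise ValueError("survival times must be positive")

    def group(self, label: str) -> pd.DataFrame:
        sub = self.table[self.table["group"] == label]
        if len(sub) == 0:
            raise ValueError(f"no animals in group {label!r}")
        return sub


@dataclass(frozen=True)
class SurvivalSummary:
    """MST/MeST summary of one group (days, unrounded)."""

    group: str
    mst_days: float
    mest_days: float
    n: int
    n_censored: int

    def rounded(self) -> dict[str, float]:
        """Whole-day reporting precision."""
        return {
            "group": self.group,
            "mst_days": round(self.mst_days),
            "mest_days": round(self.mest_days),
            "n": self.n,
            "n_censored": self.n_censored,
        }


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (used for ILS reporting)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def summarize(cohort: CohortSurvival, group: str) -> SurvivalSummary:
    """Mean and median survival time of one group.

    Censored times enter at their observed value: the endpoint
    summarises how long the animals lived under observation, and a
    cured animal's long observation span is part of the outcome.
    """
    sub = cohort.group(group)
    days = sub["days"].to_numpy(dtype=float)
    return SurvivalSummary(
        group=group,
        mst_days=float(np.mean(days)),
        mest_days=float(np.median(days)),
        n=len(days),
        n_censored=int((sub["event"] == 0).sum()),
    )


def ils(treated: SurvivalSummary, control: SurvivalSummary) -> dict[str, float]:
    """Increase in lifespan (%) of a treated group over a control group.

    100 * (treated - control) / control, separately for the mean (MST)
    and median (MeST); reported values are rounded to 2 significant
    figures alongside the raw percentages.
    """
    if control.mst_days <= 0 or control.mest_days <= 0:
        raise ValueError("control MST and MeST must be positive")
    ils_mst = 100.0 * (treated.mst_days - control.mst_days) / control.mst_days
    ils_mest = 100.0 * (treated.mest_days - control.mest_days) / control.mest_days
    return {
        "ils_mst_pct": ils_mst,
        "ils_mest_pct": ils_mest,
        "ils_mst_pct_2sf": round_sig(ils_mst),
        "ils_mest_pct_2sf": round_sig(ils_mest),
    }


def survival_curve(cohort: CohortSurvival, group: str) -> pd.DataFrame:
    """Kaplan-Meier survival curve of one group.

    Returns a step-function table (day, fraction) starting at (0, 1);
    censored animals leave the risk set without an event, so a curve of
    all-censored animals stays flat at 1.
    """
    sub = cohort.group(group)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["days"], event_observed=sub["event"])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"day": sf.index.to_numpy(dtype=float),
         "fraction": sf.iloc[:, 0].to_numpy(dtype=float)}
    )
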