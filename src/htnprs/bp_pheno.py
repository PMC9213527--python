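"""Blood-pressure phenotyping.

Per-visit BP category follows the ACC/AHA-style definitions with an explicit
precedence HYPERTENSION > ELEVATED > NORMAL, which resolves the overlapping
printed boundaries (DBP = 80 mmHg and SBP = 120 mmHg both appear in two
definitions): DBP = 80 is hypertensive, SBP = 120 with DBP < 80 untreated is
elevated.

Two-visit longitudinal categories: hypertension at both exams; worsened
(category rank increased); improved (rank decreased, and untreated at both
exams — treated individuals are never "improved"); never hypertensive (same
non-hypertensive rank at both exams).  A treated or diagnosed first visit
followed by an untreated non-hypertensive second visit has a rank decrease
but is excluded from "improved" by the treatment rule; such records are
flagged UNCLASSIFIED rather than forced into a category.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd


class BPCategory(Enum):
    NORMAL = 0
    ELEVATED = 1
    HYPERTENSION = 2


class LongitudinalCategory(Enum):
    NEVER_HTN = "NEVER_HTN"
    IMPROVED = "IMPROVED"
    WORSENED = "WORSENED"
    HTN_BOTH = "HTN_BOTH"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class BPVisit:
    """One exam's blood-pressure measurement and treatment status."""

    sbp: float
    dbp: float
    treated: bool = False
    self_report_htn: bool = False
    age: float = 0.0
    visit_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp > 0:
            raise ValueError(f"require sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}")
        if self.age < 0:
            raise ValueError("age must be non-negative")


def bp_category(v: BPVisit) -> BPCategory:
    """Classify a visit: hypertension if SBP >= 130, DBP >= 80, diagnosed,
    or treated; else elevated if 120 <= SBP <= 129; else normal."""
    if v.sbp >= 130 or v.dbp >= 80 or v.self_report_htn or v.treated:
        return BPCategory.HYPERTENSION
    if 120 <= v.sbp <= 129:
        return BPCategory.ELEVATED
    return BPCategory.NORMAL


def is_hypertensive(v: BPVisit) -> bool:
    return bp_category(v) is BPCategory.HYPERTENSION


def longitudinal_category(v1: BPVisit, v2: BPVisit) -> LongitudinalCategory:
    """Two-visit trajectory category; v1 precedes v2."""
    c1, c2 = bp_category(v1), bp_category(v2)
    if c1 is BPCategory.HYPERTENSION and c2 is BPCategory.HYPERTENSION:
        return LongitudinalCategory.HTN_BOTH
    if c2.value > c1.value:
        return LongitudinalCategory.WORSENED
    if c2.value < c1.value:
        if not v1.treated and not v2.treated:
            return LongitudinalCategory.IMPROVED
        return LongitudinalCategory.UNCLASSIFIED
    # same rank, not both hypertensive
    return LongitudinalCategory.NEVER_HTN


def incident_cohort(
    visit_pairs: dict[str, tuple[BPVisit, BPVisit]],
    baseline_category: BPCategory,
) -> pd.DataFrame:
    """Incident-hypertension analysis cohort for one baseline category.

    Keeps samples whose baseline visit is in ``baseline_category`` (NORMAL or
    ELEVATED); the outcome is 1 iff the follow-up visit is hypertensive.
    Time between exams is carried as a covariate.
    """
    if baseline_category is BPCategory.HYPERTENSION:
        raise ValueError("incident cohorts are defined for NORMAL or ELEVATED baselines")
    rows = []
    for sid, (v1, v2) in visit_pairs.items():
        if bp_category(v1) is not baseline_category:
            continue
        rows.append(
            {
                "sample_id": sid,
                "incident_htn": int(bp_category(v2) is BPCategory.HYPERTENSION),
                "time_between_exams": v2.visit_time - v1.visit_time,
                "baseline_age": v1.age,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "incident_htn", "time_between_exams", "baseline_age"])


def categorize_frame(visits: pd.DataFrame) -> pd.DataFrame:
    """Append per-visit BP category to a long-format phenotype table.

    Expects columns sample_id, visit, sbp, dbp, treated, self_report_htn.
    """
    cats = [
        bp_category(
            BPVisit(
                sbp=row.sbp,
                dbp=row.dbp,
                treated=bool(row.treated),
                self_report_htn=bool(row.self_report_htn),
            )
        ).name
        for row in visits.itertuples(index=False)
    ]
    out = visits.copy()
    out["bp_category"] = cats
    return out


def visit_pairs_from_frame(visits: pd.DataFrame) -> dict[str, tuple[BPVisit, BPVisit]]:
    """Extract (visit 1, visit 2) BPVisit pairs per sample from a long table."""
    pairs: dict[str, tuple[BPVisit, BPVisit]] = {}
    for sid, grp in visits.groupby("sample_id", sort=False):
        grp = grp.sort_values("visit")
        if len(grp) < 2:
            continue
        v = [
            BPVisit(
                sbp=r.sbp,
                dbp=r.dbp,
                treated=bool(r.treated),
                self_report_htn=bool(r.self_report_htn),
                age=float(r.age),
                visit_time=float(r.time),
            )
            for r in grp.itertuples(index=False)
        ]
        pairs[str(sid)] = (v[0], v[1])
    return pairs
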