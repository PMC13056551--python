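"""Exposure-group assignment and timepoint-window sample selection.

Patients are partitioned by antibiotic exposure: any azithromycin day puts a
patient in the ``Azithro`` group (regardless of co-administered drugs), any
other antibiotic day without azithromycin in ``Other-Abx``, and no antibiotic
days at all in ``No-Abx``.  Patients with only partially captured antibiotic
start/stop dates are excluded.

Two single-timepoint windows are analysed, defined by cumulative days of the
group-defining exposure at sample collection:

* early: 1 +/- 1 days of exposure (0, 1 or 2 whole days);
* late:  5 +/- 1 days of exposure (4, 5 or 6 whole days).

Treated-group samples collected before any exposure are moved to the No-Abx
pool and flagged.  No-Abx comparator samples are matched on days of
hospitalization (early: day <= 40; late: day 3-40); samples qualifying for
both windows are split evenly between them (alternating over sorted sample
ids, a deterministic stand-in for an unstated rule), and the No-Abx pool is
then rarefied to 50% with a seeded uniform draw to balance group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PatientExposure",
    "GROUPS",
    "assign_exposure_group",
    "select_window_samples",
    "build_design",
    "summarize_cohort",
]

GROUPS = ("Azithro", "Other-Abx", "No-Abx")
CO_ANTIBIOTICS = (
    "vancomycin",
    "ceftriaxone",
    "cefepime",
    "piperacillin-tazobactam",
    "doxycycline",
    "meropenem",
)
MAX_HOSPITAL_DAY = 40


class IncompleteDatesError(ValueError):
    """Antibiotic start/stop dates only partially captured for a patient."""


@dataclass(frozen=True)
class PatientExposure:
    """Per-patient antibiotic exposure days and clinical covariates.

    Day sets hold whole hospital days (day 0 = admission) on which the drug
    was administered.  ``trajectory_group`` is the ordinal 1-5 severity class
    of the respiratory-illness course (5 = death within 28 days).
    """

    patient_id: str
    azithro_days: frozenset[int] = frozenset()
    other_abx_days: Mapping[str, frozenset[int]] = field(default_factory=dict)
    complete_dates: bool = True
    age_quintile: int = 3
    sex: str = "F"
    trajectory_group: int = 1
    steroids_ever: bool = False
    site_id: str = "site0"

    def __post_init__(self) -> None:
        if not 1 <= self.trajectory_group <= 5:
            raise ValueError("trajectory_group must be in 1..5")
        if not 1 <= self.age_quintile <= 5:
            raise ValueError("age_quintile must be in 1..5")
        if any(d < 0 for d in self.azithro_days):
            raise ValueError("exposure days must be non-negative")
        for days in self.other_abx_days.values():
            if any(d < 0 for d in days):
                raise ValueError("exposure days must be non-negative")

    @property
    def all_abx_days(self) -> frozenset[int]:
        days = set(self.azithro_days)
        for d in self.other_abx_days.values():
            days |= set(d)
        return frozenset(days)

    def cumulative_exposure(self, day: int, drug_days: Iterable[int]) -> int:
        """Whole days of exposure accrued by (and including) ``day``."""
        return sum(1 for d in drug_days if d <= day)


def assign_exposure_group(exposure: PatientExposure) -> str:
    """Classify one patient into Azithro / Other-Abx / No-Abx."""
    if not exposure.complete_dates:
        raise IncompleteDatesError(
            f"patient {exposure.patient_id}: partially captured antibiotic dates"
        )
    if exposure.azithro_days:
        return "Azithro"
    if any(exposure.other_abx_days.get(k) for k in exposure.other_abx_days):
        return "Other-Abx"
    return "No-Abx"


_EARLY_EXPOSURE = {0, 1, 2}
_LATE_EXPOSURE = {4, 5, 6}


def build_design(
    samples: pd.DataFrame,
    exposures: Mapping[str, PatientExposure],
    seed: int,
    rarefy_no_abx: float = 0.5,
) -> pd.DataFrame:
    """Assign every biological sample to a window (or exclude it with a reason).

    ``samples`` needs columns ``sample_id``, ``patient_id``,
    ``day_from_admission`` (negative controls should not be passed in).
    Returns one row per sample: ``group``, ``window`` (early/late/none),
    ``included``, ``reassigned_to_no_abx``, ``exclusion_reason``.
    """
    rows = []
    for s in samples.itertuples(index=False):
        day = int(s.day_from_admission)
        exp = exposures.get(s.patient_id)
        base = {
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "day_from_admission": day,
            "window": "none",
            "included": False,
            "reassigned_to_no_abx": False,
            "exclusion_reason": "",
        }
        if exp is None:
            rows.append({**base, "group": "", "exclusion_reason": "no_exposure_record"})
            continue
        try:
            group = assign_exposure_group(exp)
        except IncompleteDatesError:
            rows.append({**base, "group": "", "exclusion_reason": "incomplete_dates"})
            continue
        base["group"] = group
        if group == "Azithro":
            e = exp.cumulative_exposure(day, exp.azithro_days)
        elif group == "Other-Abx":
            e = exp.cumulative_exposure(day, exp.all_abx_days)
        else:
            e = 0
        if group != "No-Abx" and e == 0:
            # collected before the first dose: counts as an unexposed sample
            base["group"] = "No-Abx"
            base["reassigned_to_no_abx"] = True
            group = "No-Abx"
        if group == "No-Abx":
            q_early = day <= MAX_HOSPITAL_DAY
            q_late = 3 <= day <= MAX_HOSPITAL_DAY
            if not q_early and not q_late:
                base["exclusion_reason"] = "day_outside_windows"
            elif q_early and q_late:
                base["window"] = "both"  # resolved by the even split below
                base["included"] = True
            else:
                base["window"] = "early" if q_early else "late"
                base["included"] = True
        else:
            if e in _EARLY_EXPOSURE:
                base["window"] = "early"
                base["included"] = True
            elif e in _LATE_EXPOSURE:
                base["window"] = "late"
                base["included"] = True
            else:
                base["exclusion_reason"] = "exposure_outside_windows"
        rows.append(base)
    design = pd.DataFrame(rows)
    if design.empty:
        return design

    # split dual-qualifying No-Abx samples evenly: alternate over sorted ids
    dual = design.index[design["window"] == "both"].tolist()
    dual_sorted = sorted(dual, key=lambda i: design.at[i, "sample_id"])
    for pos, i in enumerate(dual_sorted):
        design.at[i, "window"] = "early" if pos % 2 == 0 else "late"

    # rarefy the No-Abx pool within each window to balance group sizes
    rng = np.random.default_rng(seed)
    for window in ("early", "late"):
        pool = design.index[
            (design["group"] == "No-Abx")
            & (design["window"] == window)
            & design["included"]
        ].to_numpy()
        pool = pool[np.argsort(design.loc[pool, "sample_id"].to_numpy())]
        n_drop = int(len(pool) * (1 - rarefy_no_abx))
        drop = rng.choice(pool, size=n_drop, replace=False)
        design.loc[drop, "included"] = False
        design.loc[drop, "window"] = "none"
        design.loc[drop, "exclusion_reason"] = "rarefied_out"
    return design


def select_window_samples(
    samples: pd.DataFrame,
    exposures: Mapping[str, PatientExposure],
    window: str,
    seed: int,
) -> pd.DataFrame:
    """Design rows for one timepoint window (``early`` or ``late``)."""
    if window not in ("early", "late"):
        raise ValueError(f"invalid window {window!r}; expected 'early' or 'late'")
    design = build_design(samples, exposures, seed=seed)
    return design[design["included"] & (design["window"] == window)].reset_index(
        drop=True
    )


def summarize_cohort(exposures: Iterable[PatientExposure]) -> pd.DataFrame:
    """Patient counts and percentages per exposure group.

    Percentages are 100 * count / total, rounded to one decimal.
    """
    counts = {g: 0 for g in GROUPS}
    excluded = 0
    for exp in exposures:
        try:
            counts[assign_exposure_group(exp)] += 1
        except IncompleteDatesError:
            excluded += 1
    total = sum(counts.values())
    out = pd.DataFrame(
        {
            "group": list(GROUPS),
            "n": [counts[g] for g in GROUPS],
        }
    )
    out["percent"] = (100.0 * out["n"] / total).round(1) if total else 0.0
    out.attrs["total"] = total
    out.attrs["excluded_incomplete_dates"] = excluded
    return out
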