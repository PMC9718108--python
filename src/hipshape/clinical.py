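"""Eligibility, exclusion, outcome-dichotomization and cohort-summary rules.

Hips are classified as symptomatic (longstanding hip/groin pain plus a
positive FADIR provocation test), "other" (the contralateral hip of a
symptomatic participant), or asymptomatic.  Hips with any radiographic
osteoarthritis (Kellgren-Lawrence grade > 0) are excluded per hip.  MRI
outcomes are dichotomized from SHOMRI subregion grades: a cartilage defect
is any grade >= 1 in any of the ten subregions; a labral tear is any grade
>= 2 (fraying, grade 1, does not count) in any of the four subregions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CARTILAGE_COLS, LABRAL_COLS, HipRecord, records_to_frame


@dataclass(frozen=True)
class OutcomeFlags:
    cartilage_defect_present: bool
    labral_tear_present: bool


def classify_symptomatic_status(
    pain_over_6mo: bool,
    fadir_positive: bool,
    participant_has_symptomatic_hip: bool,
) -> str:
    """Three-level hip status: symptomatic / other / asymptomatic.

    A hip is symptomatic when pain has lasted more than six months AND the
    FADIR test is positive.  A non-symptomatic hip of a participant who has
    at least one symptomatic hip is "other"; all remaining hips are
    asymptomatic.
    """
    if pain_over_6mo and fadir_positive:
        return "symptomatic"
    if participant_has_symptomatic_hip:
        return "other"
    return "asymptomatic"


def cartilage_defect_present(grades: Sequence[int]) -> bool:
    """True iff any of the 10 SHOMRI cartilage subregions shows grade >= 1."""
    grades = [int(g) for g in grades]
    if len(grades) != 10:
        raise ValueError(f"expected 10 cartilage grades, got {len(grades)}")
    if any(not 0 <= g <= 2 for g in grades):
        raise ValueError(f"cartilage grades must lie in 0..2, got {grades}")
    return max(grades) >= 1


def labral_tear_present(grades: Sequence[int]) -> bool:
    """True iff any of the 4 SHOMRI labral subregions shows grade >= 2."""
    grades = [int(g) for g in grades]
    if len(grades) != 4:
        raise ValueError(f"expected 4 labral grades, got {len(grades)}")
    if any(not 0 <= g <= 5 for g in grades):
        raise ValueError(f"labral grades must lie in 0..5, got {grades}")
    return max(grades) >= 2


def dichotomize(cartilage_grades, labral_grades) -> OutcomeFlags:
    return OutcomeFlags(
        cartilage_defect_present=cartilage_defect_present(cartilage_grades),
        labral_tear_present=labral_tear_present(labral_grades),
    )


def add_outcome_flags(df: pd.DataFrame) -> pd.DataFrame:
    """Append boolean outcome columns to a hip table (returns a copy)."""
    out = df.copy()
    cart = out[list(CARTILAGE_COLS)].to_numpy()
    lab = out[list(LABRAL_COLS)].to_numpy()
    out["cartilage_defect_present"] = (cart >= 1).any(axis=1)
    out["labral_tear_present"] = (lab >= 2).any(axis=1)
    return out


def exclude_kl(records):
    """Drop hips with KL grade > 0 (doubtful osteoarthritis or worse).

    Exclusion is per hip — a participant's other hip may remain in the
    cohort.  Accepts a list of :class:`HipRecord` or a hip table DataFrame;
    returns ``(retained, n_excluded)`` in the same container type.
    """
    if isinstance(records, pd.DataFrame):
        if "kl_grade" not in records.columns:
            raise ValueError("missing KL grade column")
        kl = records["kl_grade"]
        if kl.isna().any():
            raise ValueError("missing KL grade value(s)")
        keep = kl.astype(int) <= 0
        return records.loc[keep].copy(), int((~keep).sum())
    retained = [r for r in records if r.kl_grade == 0]
    return retained, len(records) - len(retained)


@dataclass
class CohortSummary:
    """Per-sex participant/hip counts, covariate quartiles and outcome rates.

    ``continuous`` maps sex -> variable -> (median, q1, q3) at participant
    level; ``counts`` maps sex -> category -> (n, percent of hips, one
    decimal).
    """

    n_participants: dict
    n_hips: dict
    continuous: dict
    counts: dict


def _pct(count: int, denom: int) -> float:
    return round(100.0 * count / denom, 1)


def cohort_summary(records) -> CohortSummary:
    """Summarise a hip table the way cohort-description tables are laid out.

    Quantiles use linear interpolation (type 7).  Continuous covariates are
    summarised per participant (first row per participant); status and
    outcome percentages use hips as the denominator.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) == 0:
        raise ValueError("cohort_summary requires a non-empty table")
    df = add_outcome_flags(df)

    n_participants: dict = {}
    n_hips: dict = {}
    continuous: dict = {}
    counts: dict = {}
    for sex, sub in df.groupby("sex"):
        participants = sub.drop_duplicates("participant_id")
        n_participants[sex] = len(participants)
        n_hips[sex] = len(sub)
        cont = {}
        for var in ("age", "height", "mass", "bmi"):
            if var in participants.columns:
                q1, med, q3 = np.percentile(
                    participants[var].to_numpy(float), [25, 50, 75]
                )
                cont[var] = (float(med), float(q1), float(q3))
        continuous[sex] = cont
        n = len(sub)
        cat = {}
        for status in ("symptomatic", "other", "asymptomatic"):
            c = int((sub["symptomatic_status"] == status).sum())
            cat[status] = (c, _pct(c, n))
        for outcome in ("cartilage_defect_present", "labral_tear_present"):
            c = int(sub[outcome].sum())
            cat[outcome] = (c, _pct(c, n))
        counts[sex] = cat
    return CohortSummary(
        n_participants=n_participants,
        n_hips=n_hips,
        continuous=continuous,
        counts=counts,
    )


def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """Flatten a :class:`CohortSummary` into a tidy long-format table."""
    rows = []
    for sex in sorted(summary.n_hips):
        rows.append({"sex": sex, "item": "n_participants",
                     "value": summary.n_participants[sex]})
        rows.append({"sex": sex, "item": "n_hips", "value": summary.n_hips[sex]})
        for var, (med, q1, q3) in summary.continuous[sex].items():
            rows.append({"sex": sex, "item": f"{var}_median", "value": med})
            rows.append({"sex": sex, "item": f"{var}_q1", "value": q1})
            rows.append({"sex": sex, "item": f"{var}_q3", "value": q3})
        for cat, (n, pct) in summary.counts[sex].items():
            rows.append({"sex": sex, "item": f"{cat}_n", "value": n})
            rows.append({"sex": sex, "item": f"{cat}_pct", "value": pct})
    return pd.DataFrame(rows, columns=["sex", "item", "value"])


__all__ = [
    "OutcomeFlags",
    "CohortSummary",
    "classify_symptomatic_status",
    "cartilage_defect_present",
    "labral_tear_present",
    "dichotomize",
    "add_outcome_flags",
    "exclude_kl",
    "cohort_summary",
    "summary_frame",
]
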