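"""Outcome arithmetic: VAS composite, change scores, effect sizes, harms.

Participants rate tinnitus loudness, annoyance, awareness and handicap on
0–100 visual analog scales (VAS); the VAS total is the mean of the four.
Questionnaire totals (THQ, TQ, THI) are carried as given. Change scores are
post − pre per participant; group effects are summarized with the
pretest-pooled standardized change difference (Morris's d for
pretest–posttest–control designs). Clinical relevance is judged against
minimal clinically important differences: TQ 5, THQ 21, THI 7 points, and
strictly more than 10 points for a VAS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutcomeRecord",
    "McidTable",
    "SESSIONS",
    "VAS_SUBSCALES",
    "vas_total",
    "change_score",
    "morris_d",
    "mcid_flag",
    "planned_dose",
    "harms_table",
    "interim_stop_check",
]

SESSIONS = ("baseline", "pre", "post", "followup")
VAS_SUBSCALES = ("vas_loudness", "vas_annoyance", "vas_awareness", "vas_handicap")
QUESTIONNAIRES = ("thq_total", "tq_total", "thi_total")


class MissingDataError(ValueError):
    """A required value is absent; outcome arithmetic never imputes."""


@dataclass(frozen=True)
class OutcomeRecord:
    """One participant's scores at one measurement session."""

    participant_id: str
    arm: str  # "treatment" | "placebo"
    session: str
    vas_loudness: float | None = None
    vas_annoyance: float | None = None
    vas_awareness: float | None = None
    vas_handicap: float | None = None
    thq_total: float | None = None
    tq_total: float | None = None
    thi_total: float | None = None
    listening_minutes: float | None = None
    harms: tuple = ()

    def __post_init__(self):
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        if self.arm not in ("treatment", "placebo"):
            raise ValueError("arm must be 'treatment' or 'placebo'")
        for name in VAS_SUBSCALES:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside the 0–100 VAS range")


@dataclass(frozen=True)
class McidTable:
    """Minimal clinically important differences, in score points."""

    tq: float = 5.0
    thq: float = 21.0
    thi: float = 7.0
    vas: float = 10.0

    def __post_init__(self):
        if min(self.tq, self.thq, self.thi, self.vas) <= 0:
            raise ValueError("all MCIDs must be positive")


def vas_total(record: OutcomeRecord) -> float:
    """Mean of the four VAS subscales; raises if any subscale is missing."""
    vals = []
    for name in VAS_SUBSCALES:
        v = getattr(record, name)
        if v is None:
            raise MissingDataError(f"{name} missing for participant "
                                   f"{record.participant_id} ({record.session})")
        vals.append(v)
    return float(np.mean(vals))


def _records_frame(records: list[OutcomeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"participant_id": r.participant_id, "arm": r.arm,
               "session": r.session}
        for name in VAS_SUBSCALES + QUESTIONNAIRES:
            row[name] = getattr(r, name)
        try:
            row["vas_total"] = vas_total(r)
        except MissingDataError:
            row["vas_total"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def change_score(records: list[OutcomeRecord], measure: str,
                 from_session: str = "pre", to_session: str = "post"):
    """Per-participant ``to − from`` changes on one measure.

    Returns ``(changes, excluded)`` where ``changes`` is a Series indexed by
    participant id (the per-protocol set with both sessions present) and
    ``excluded`` lists participants dropped for a missing session. An
    improvement (lower symptom score) is a negative change.
    """
    for s in (from_session, to_session):
        if s not in SESSIONS:
            raise ValueError(f"unknown session {s!r}")
    df = _records_frame(records)
    if measure not in df.columns:
        raise ValueError(f"unknown measure {measure!r}")
    wide = df.pivot_table(index="participant_id", columns="session",
                          values=measure, aggfunc="first")
    for s in (from_session, to_session):
        if s not in wide.columns:
            wide[s] = np.nan
    both = wide[from_session].notna() & wide[to_session].notna()
    changes = (wide.loc[both, to_session] - wide.loc[both, from_session])
    excluded = sorted(wide.index[~both])
    return changes, excluded


def morris_d(changes_t, changes_c, sd_pre_t: float, sd_pre_c: float,
             n_t: int, n_c: int) -> dict:
    """Pretest-pooled standardized difference of mean changes (Morris's d).

    d = (meanΔ_t − meanΔ_c) / SD_pre,pooled with
    SD_pre,pooled = sqrt(((n_t−1)·sd_pre_t² + (n_c−1)·sd_pre_c²)/(n_t+n_c−2)).
    The Hedges-style small-sample correction c = 1 − 3/(4(n_t+n_c−2)−1) is
    reported alongside the uncorrected value.
    """
    if n_t < 2 or n_c < 2:
        raise ValueError("need at least 2 participants per arm")
    pooled_var = (((n_t - 1) * sd_pre_t ** 2 + (n_c - 1) * sd_pre_c ** 2)
                  / (n_t + n_c - 2))
    if pooled_var <= 0:
        raise ValueError("pooled pretest SD is zero")
    d = (float(np.mean(changes_t)) - float(np.mean(changes_c))) / math.sqrt(pooled_var)
    correction = 1.0 - 3.0 / (4.0 * (n_t + n_c - 2) - 1.0)
    return {"d": d, "bias_correction": correction, "d_corrected": d * correction}


_MCID_KEY = {"tq_total": "tq", "thq_total": "thq", "thi_total": "thi"}


def mcid_flag(change: float, measure: str,
              table: McidTable | None = None) -> dict:
    """Compare |change| against the measure's MCID.

    VAS measures use a strict ``>`` rule (a change must exceed 10 points to
    count); questionnaire totals use ``≥`` their published thresholds.
    """
    table = table or McidTable()
    if measure.startswith("vas"):
        threshold, relevant = table.vas, abs(change) > table.vas
    elif measure in _MCID_KEY:
        threshold = getattr(table, _MCID_KEY[measure])
        relevant = abs(change) >= threshold
    else:
        raise ValueError(f"no MCID defined for measure {measure!r}")
    return {"clinically_relevant": bool(relevant), "threshold": threshold,
            "abs_change": abs(change)}


def planned_dose(hours_per_day: float = 2.0, days_per_week: float = 7.0,
                 weeks: float = 12.0) -> float:
    """Total planned listening hours (2 h/day over 12 weeks → 168 h)."""
    for v in (hours_per_day, days_per_week, weeks):
        if v < 0:
            raise ValueError("dose components must be non-negative")
    return hours_per_day * days_per_week * weeks


def harms_table(harm_rows: list[tuple[str, str, str]],
                respondents: int) -> pd.DataFrame:
    """Tabulate reported harms per category and arm.

    ``harm_rows`` holds (participant_id, arm, category) entries, one per
    reported harm; ``respondents`` is the number of participants who
    answered the harms questionnaire (the percentage denominator). The
    result has per-arm counts, totals, and percentages of respondents at
    one decimal; the ``any_harm`` row counts participants with ≥ 1 category.
    """
    if respondents <= 0:
        raise ValueError("respondents must be positive")
    df = pd.DataFrame(harm_rows, columns=["participant_id", "arm", "category"])
    categories = sorted(df["category"].unique()) if len(df) else []
    rows = []
    for cat in categories:
        sub = df[df["category"] == cat]
        t = sub.loc[sub["arm"] == "treatment", "participant_id"].nunique()
        c = sub.loc[sub["arm"] == "placebo", "participant_id"].nunique()
        rows.append((cat, t, c, t + c))
    t_any = df.loc[df["arm"] == "treatment", "participant_id"].nunique() if len(df) else 0
    c_any = df.loc[df["arm"] == "placebo", "participant_id"].nunique() if len(df) else 0
    rows.append(("any_harm", t_any, c_any, t_any + c_any))
    out = pd.DataFrame(rows, columns=["category", "treatment", "placebo", "total"])
    out["pct_of_respondents"] = (100.0 * out["total"] / respondents).round(1)
    return out.set_index("category")


def interim_stop_check(records: list[OutcomeRecord], measure: str = "vas_total",
                       alpha: float = 0.05) -> dict:
    """Harm-gated interim check on post−pre changes (Welch two-sample test).

    Stops only when the between-arm difference in change scores is
    significant AND the treatment arm's mean change points in the harmful
    direction (symptom scores increasing).
    """
    changes, _ = change_score(records, measure, "pre", "post")
    df = _records_frame(records)
    arm_of = df.drop_duplicates("participant_id").set_index("participant_id")["arm"]
    ch_t = changes[arm_of.reindex(changes.index) == "treatment"]
    ch_c = changes[arm_of.reindex(changes.index) == "placebo"]
    if len(ch_t) < 2 or len(ch_c) < 2:
        raise ValueError("need at least 2 complete pre/post pairs per arm")
    t_stat, p = stats.ttest_ind(ch_t, ch_c, equal_var=False)
    harmful = float(ch_t.mean()) > float(ch_c.mean())
    return {
        "stop": bool(p < alpha and harmful),
        "statistic": float(t_stat),
        "p": float(p),
        "mean_change_treatment": float(ch_t.mean()),
        "mean_change_placebo": float(ch_c.mean()),
        "n_treatment": int(len(ch_t)),
        "n_placebo": int(len(ch_c)),
    }
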