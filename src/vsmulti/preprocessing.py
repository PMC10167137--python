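"""Trial-level inclusion/exclusion rules, accuracy scoring and stimulus geometry.

A raw experiment is a tidy table with one row per stimulus presentation.
The canonical CSV schema (header names are exact) is::

    participant_id, group, gender, age, nystagmus, acuity_logmar,
    set_size, target, rt_s, correct, order

with ``group`` in {c, i}, ``gender`` in {m, f}, ``target`` in {ab, p},
``set_size`` in {4, 16, 24}, booleans coded 0/1, reaction time in seconds
and ``order`` the 1..80 presentation index (orders 1..8 are practice).

The preprocessing rules are:

* drop the eight practice presentations,
* drop test trials with reaction time strictly greater than 10 s,
* per participant x set-size x target condition keep the first eight
  correct reaction times in presentation order,
* score accuracy as correct/presented for the condition and exclude the
  condition observation when accuracy <= 50% (chance level).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

__all__ = [
    "CSV_COLUMNS",
    "ConditionSummary",
    "read_trials",
    "validate_trials",
    "drop_practice",
    "apply_rt_cutoff",
    "summarize_condition",
    "summarize_conditions",
    "build_analysis_table",
    "preprocess",
    "visual_angle",
]

CSV_COLUMNS = [
    "participant_id", "group", "gender", "age", "nystagmus", "acuity_logmar",
    "set_size", "target", "rt_s", "correct", "order",
]

N_PRACTICE = 8
RT_CUTOFF_S = 10.0
MAX_RETAINED = 8
CHANCE_ACCURACY = 0.5

GROUP_LEVELS = ("c", "i")
GENDER_LEVELS = ("f", "m")
TARGET_LEVELS = ("ab", "p")
SET_SIZES = (4, 16, 24)

COVARIATES = ["group", "gender", "age", "nystagmus", "acuity_logmar", "set_size", "target"]


@dataclass
class ConditionSummary:
    """Per participant x set-size x target retained RTs and accuracy."""

    participant_id: object
    set_size: int
    target: str
    retained_rts: list
    n_presented: int
    n_correct: int
    accuracy: float
    excluded: bool
    reason: str = ""
    empty: bool = False


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV in the canonical schema and validate it."""
    df = pd.read_csv(path)
    return validate_trials(df)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    df = df.copy()
    if df["order"].isna().any():
        raise ValueError("missing presentation order")
    bad_rt = df["rt_s"] <= 0
    if bad_rt.any():
        raise ValueError(f"{int(bad_rt.sum())} rows have non-positive reaction times")
    if not df["group"].isin(GROUP_LEVELS).all():
        raise ValueError("group must be coded c/i")
    if not df["target"].isin(TARGET_LEVELS).all():
        raise ValueError("target must be coded ab/p")
    if not df["set_size"].isin(SET_SIZES).all():
        raise ValueError(f"set_size must be one of {SET_SIZES}")
    dup = df.duplicated(subset=["participant_id", "order"])
    if dup.any():
        raise ValueError("presentation order must be unique within participant")
    df["practice"] = df["order"] <= N_PRACTICE
    return df


def _ensure_practice_column(df: pd.DataFrame) -> pd.DataFrame:
    if "practice" not in df.columns:
        if "order" not in df.columns or df["order"].isna().any():
            raise ValueError("missing presentation order")
        df = df.copy()
        df["practice"] = df["order"] <= N_PRACTICE
    return df


def drop_practice(df: pd.DataFrame) -> pd.DataFrame:
    """Remove the practice presentations (orders 1..8), preserving row order."""
    df = _ensure_practice_column(df)
    return df.loc[~df["practice"]].copy()


def apply_rt_cutoff(df: pd.DataFrame, cutoff: float = RT_CUTOFF_S) -> pd.DataFrame:
    """Remove trials with reaction time strictly greater than ``cutoff`` seconds.

    A reaction time exactly equal to the cutoff is retained.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if (df["rt_s"] <= 0).any():
        raise ValueError("non-positive reaction times")
    return df.loc[df["rt_s"] <= cutoff].copy()


def _accuracy(n_correct: int, n_presented: int, trials_to_eighth: int | None,
              rule: str) -> float:
    if rule == "proportion_correct":
        return n_correct / n_presented
    if rule == "eight_over_trials_to_eighth":
        # 8 / (number of presentations needed to reach the 8th correct
        # response); falls back to the plain proportion when fewer than
        # eight correct responses exist.
        if trials_to_eighth is None:
            return n_correct / n_presented
        return MAX_RETAINED / trials_to_eighth
    raise ValueError(f"unknown accuracy rule {rule!r}")


def summarize_condition(df: pd.DataFrame, participant_id, set_size, target,
                        cutoff: float = RT_CUTOFF_S,
                        accuracy_rule: str = "proportion_correct") -> ConditionSummary:
    """Summarise one participant x set-size x target condition.

    ``df`` must already have practice trials removed; the RT cutoff is
    applied here for RT retention only, while accuracy counts every test
    presentation of the condition.
    """
    sub = df.loc[
        (df["participant_id"] == participant_id)
        & (df["set_size"] == set_size)
        & (df["target"] == target)
    ].sort_values("order")
    n_presented = int(len(sub))
    if n_presented == 0:
        return ConditionSummary(participant_id, int(set_size), target, [], 0, 0,
                                float("nan"), excluded=False,
                                reason="no presentations", empty=True)
    correct_mask = sub["correct"].astype(bool).to_numpy()
    n_correct = int(correct_mask.sum())

    cum_correct = np.cumsum(correct_mask)
    idx_eighth = np.flatnonzero(cum_correct == MAX_RETAINED)
    trials_to_eighth = int(idx_eighth[0]) + 1 if idx_eighth.size else None

    acc = _accuracy(n_correct, n_presented, trials_to_eighth, accuracy_rule)
    retained = sub.loc[correct_mask & (sub["rt_s"] <= cutoff), "rt_s"]
    retained_rts = retained.head(MAX_RETAINED).tolist()

    excluded = acc <= CHANCE_ACCURACY
    reason = "accuracy<=50%" if excluded else ""
    return ConditionSummary(participant_id, int(set_size), target,
                            retained_rts, n_presented, n_correct, float(acc),
                            excluded=excluded, reason=reason)


def summarize_conditions(df: pd.DataFrame, cutoff: float = RT_CUTOFF_S,
                         accuracy_rule: str = "proportion_correct") -> pd.DataFrame:
    """Condition summaries for every participant x set-size x target cell.

    Returns one row per cell with participant covariates, accuracy,
    retained-RT count and median, and the exclusion flag.
    """
    df = _ensure_practice_column(df)
    test = df.loc[~df["practice"]]
    rows = []
    participants = test.drop_duplicates("participant_id").set_index("participant_id")
    for pid, psub in test.groupby("participant_id", sort=True):
        meta = participants.loc[pid]
        for set_size in SET_SIZES:
            for target in TARGET_LEVELS:
                s = summarize_condition(psub, pid, set_size, target,
                                        cutoff=cutoff, accuracy_rule=accuracy_rule)
                if s.empty:
                    continue
                rows.append({
                    "participant_id": pid,
                    "group": meta["group"],
                    "gender": meta["gender"],
                    "age": meta["age"],
                    "nystagmus": meta["nystagmus"],
                    "acuity_logmar": meta["acuity_logmar"],
                    "set_size": s.set_size,
                    "target": s.target,
                    "n_presented": s.n_presented,
                    "n_correct": s.n_correct,
                    "accuracy": s.accuracy,
                    "n_retained": len(s.retained_rts),
                    "median_rt": float(np.median(s.retained_rts)) if s.retained_rts else float("nan"),
                    "excluded": s.excluded,
                })
    return pd.DataFrame(rows)


def build_analysis_table(df: pd.DataFrame, cutoff: float = RT_CUTOFF_S,
                         accuracy_rule: str = "proportion_correct") -> pd.DataFrame:
    """Long-format table with one row per retained reaction time.

    Practice trials are dropped, the RT cutoff applied, only the first
    eight correct RTs of each condition kept, and conditions failing the
    50% accuracy rule removed entirely.
    """
    df = _ensure_practice_column(df)
    test = drop_practice(df)
    rows = []
    for (pid, set_size, target), sub in test.groupby(
            ["participant_id", "set_size", "target"], sort=True):
        s = summarize_condition(sub, pid, set_size, target, cutoff=cutoff,
                                accuracy_rule=accuracy_rule)
        if s.empty or s.excluded:
            continue
        keep = sub.sort_values("order")
        keep = keep.loc[keep["correct"].astype(bool) & (keep["rt_s"] <= cutoff)]
        rows.append(keep.head(MAX_RETAINED))
    if not rows:
        return test.iloc[0:0].copy()
    return pd.concat(rows, ignore_index=True)


def preprocess(df: pd.DataFrame, cutoff: float = RT_CUTOFF_S,
               accuracy_rule: str = "proportion_correct"):
    """Full preprocessing: returns ``(rt_table, condition_table)``.

    ``rt_table`` has one row per retained reaction time; ``condition_table``
    one row per included participant x condition observation (accuracy
    analysis table), with the <=50% rule applied to both.
    """
    df = validate_trials(df) if "practice" not in df.columns else df
    rt_table = build_analysis_table(df, cutoff=cutoff, accuracy_rule=accuracy_rule)
    cond = summarize_conditions(df, cutoff=cutoff, accuracy_rule=accuracy_rule)
    cond_included = cond.loc[~cond["excluded"]].reset_index(drop=True)
    return rt_table, cond_included


def visual_angle(extent_cm: float, distance_cm: float) -> float:
    """Visual angle in degrees subtended by ``extent_cm`` at ``distance_cm``.

    ``2 * arctan(extent / (2 * distance))``; e.g. a 0.8 cm circle viewed at
    40 cm subtends 1.15 degrees.
    """
    if not distance_cm > 0:
        raise ValueError("viewing distance must be positive")
    if extent_cm < 0:
        raise ValueError("extent must be non-negative")
    return math.degrees(2.0 * math.atan2(extent_cm, 2.0 * distance_cm))
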