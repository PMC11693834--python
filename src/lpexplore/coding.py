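"""Behavioral coding: stay/leave labels, exploratory choice events, inclusion.

Two dependent variables are derived from a session log.  A trial is a *leave*
trial when the participant plays with a different character on the next trial,
and a *stay* trial otherwise; the label sits on the trial *preceding* the
switch (the decision point), so model covariates are those available at the
moment of deciding.  The session's final trial is censored (no label).  Each
leave gives one *exploratory choice event*: which of the two alternative
characters was selected.  Inclusion requires a minimum number of trials with
each of the three characters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "label_leave_stay",
    "within_character_trial",
    "extract_choice_events",
    "apply_inclusion",
    "validate_trial_log",
]

TRIAL_LOG_COLUMNS = ("participant_id", "trial", "character_id", "predicted_loc", "actual_loc")

CHOICE_EVENT_COLUMNS = (
    "participant_id", "at_trial", "from_character", "chosen_character",
    "alternative_character", "is_first_visit_to_chosen", "alternative_visited",
)


def validate_trial_log(df: pd.DataFrame) -> None:
    """Schema check shared by synthetic and real trial logs.

    Raises ValueError naming the offending column/rows.
    """
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing required columns: {missing}")
    for col in ("predicted_loc", "actual_loc"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals > 1)]
        if len(bad):
            raise ValueError(f"column {col}: {len(bad)} rows outside [0, 1] (first at row {bad[0]})")
    for pid, g in df.groupby("participant_id", sort=False):
        t = g["trial"].to_numpy()
        if not (np.diff(t) > 0).all():
            raise ValueError(f"participant {pid}: trial indices not strictly increasing")


def label_leave_stay(characters) -> np.ndarray:
    """Per-trial labels: 1 = leave, 0 = stay, NaN = censored final trial."""
    chars = np.asarray(characters)
    if len(chars) == 0:
        raise ValueError("session must contain at least one trial")
    labels = np.full(len(chars), np.nan)
    if len(chars) > 1:
        labels[:-1] = (chars[1:] != chars[:-1]).astype(float)
    return labels


def within_character_trial(characters) -> np.ndarray:
    """1-based trial counter within each contiguous run of one character."""
    chars = np.asarray(characters)
    out = np.empty(len(chars), dtype=int)
    run = 0
    for i, c in enumerate(chars):
        run = run + 1 if i > 0 and c == chars[i - 1] else 1
        out[i] = run
    return out


def extract_choice_events(session: pd.DataFrame, characters=(1, 2, 3)) -> pd.DataFrame:
    """One row per leave decision: what was chosen over what.

    ``is_first_visit_to_chosen`` flags switches to a never-before-visited
    character (excluded from choice modelling, since expectations about it do
    not exist yet); ``alternative_visited`` flags whether the unchosen option
    had been visited.
    """
    chars = session["character_id"].to_numpy()
    pid = session["participant_id"].iloc[0]
    trials = session["trial"].to_numpy()
    char_set = set(characters)

    rows = []
    seen: set = {chars[0]} if len(chars) else set()
    for i in range(len(chars) - 1):
        cur, nxt = chars[i], chars[i + 1]
        if nxt != cur:
            (alt,) = char_set - {cur, nxt}
            rows.append({
                "participant_id": pid,
                "at_trial": trials[i],
                "from_character": cur,
                "chosen_character": nxt,
                "alternative_character": alt,
                "is_first_visit_to_chosen": nxt not in seen,
                "alternative_visited": alt in seen,
            })
        seen.add(nxt)
    return pd.DataFrame(rows, columns=list(CHOICE_EVENT_COLUMNS))


def apply_inclusion(session: pd.DataFrame, min_trials_per_character: int = 10,
                    characters=(1, 2, 3)) -> bool:
    """True iff every character accumulates at least the minimum trial count."""
    counts = session["character_id"].value_counts()
    return all(counts.get(c, 0) >= min_trials_per_character for c in characters)


def code_dataset(trials: pd.DataFrame) -> pd.DataFrame:
    """Add stay_leave and within_character_trial columns to a full trial log."""
    out = trials.copy()
    out["stay_leave"] = np.nan
    out["within_character_trial"] = 0
    for _, g in out.groupby("participant_id", sort=False):
        chars = g["character_id"].to_numpy()
        out.loc[g.index, "stay_leave"] = label_leave_stay(chars)
        out.loc[g.index, "within_character_trial"] = within_character_trial(chars)
    return out


def choice_events_dataset(trials: pd.DataFrame, characters=(1, 2, 3)) -> pd.DataFrame:
    """Choice events pooled across participants."""
    parts = [
        extract_choice_events(g, characters)
        for _, g in trials.groupby("participant_id", sort=False)
    ]
    if not parts:
        return pd.DataFrame(columns=list(CHOICE_EVENT_COLUMNS))
    return pd.concat(parts, ignore_index=True)
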