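"""Cohort construction: episode merging, note windowing, outcome labeling,
documentation-based exclusion.

Analysis unit is the admission. Registration systems split one clinical stay
into several episodes (ward transfers, brief discharges); episodes of the same
patient separated by at most 14 days are merged into one admission. The
predictor document concatenates notes from 28 days before admission start up
to 24 hours after; the outcome is positive iff at least one violent incident
(verbal or physical) falls in the window from 24 hours to 28 days after start.
Admissions with fewer than 100 words documented after the first 24 hours are
excluded as having insufficient follow-up documentation to assess the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .text import tokenize

WINDOW_BEFORE = pd.Timedelta(days=28)
WINDOW_AFTER = pd.Timedelta(hours=24)
OUTCOME_END = pd.Timedelta(days=28)
QUALIFYING_CATEGORIES = frozenset({"violence_verbal", "violence_physical"})
AUTHOR_ROLES = frozenset({"psychiatrist", "nurse"})
MIN_POST24H_WORDS = 100


def merge_episodes(episodes: pd.DataFrame, max_gap_days: int = 14) -> pd.DataFrame:
    """Merge registration episodes into admissions.

    Within each patient, consecutive episodes whose gap (next start minus
    previous end) is at most ``max_gap_days`` are merged into one admission
    spanning both; longer gaps start a new admission. Overlapping episodes
    are merged with a warning (treated as gap zero). The merged admission
    keeps the first episode's admission_id, ward and diagnosis.
    """
    required = {"admission_id", "patient_id", "start", "end"}
    missing = required - set(episodes.columns)
    if missing:
        raise ValueError(f"episodes table missing columns: {sorted(missing)}")
    gap = pd.Timedelta(days=max_gap_days)
    out_rows = []
    for _, grp in episodes.sort_values(["patient_id", "start"], kind="mergesort").groupby(
        "patient_id", sort=False
    ):
        current = None
        for row in grp.itertuples(index=False):
            if current is None:
                current = row._asdict()
                continue
            delta = row.start - current["end"]
            if delta < pd.Timedelta(0):
                warnings.warn(
                    f"overlapping episodes for patient {row.patient_id}; merging",
                    stacklevel=2,
                )
                delta = pd.Timedelta(0)
            if delta <= gap:
                current["end"] = max(current["end"], row.end)
            else:
                out_rows.append(current)
                current = row._asdict()
        if current is not None:
            out_rows.append(current)
    merged = pd.DataFrame(out_rows, columns=list(episodes.columns))
    return merged.reset_index(drop=True)


def select_note_window(admission, notes: pd.DataFrame) -> list[str]:
    """Concatenate the predictor-window notes of one admission into a token
    sequence.

    Exactly the notes with timestamp in [start - 28 d, start + 24 h] are kept,
    in chronological order. Returns an empty list when no note falls in the
    window (flagged for exclusion downstream).
    """
    start = admission["start"] if isinstance(admission, (dict, pd.Series)) else admission.start
    lo, hi = start - WINDOW_BEFORE, start + WINDOW_AFTER
    sel = notes[(notes["timestamp"] >= lo) & (notes["timestamp"] <= hi)]
    sel = sel.sort_values("timestamp", kind="mergesort")
    tokens: list[str] = []
    for text in sel["text"]:
        tokens.extend(tokenize(text))
    return tokens


def label_outcome(admission, incidents: pd.DataFrame) -> int:
    """1 iff at least one verbal/physical violence incident falls in
    (start + 24 h, start + 28 d]; all other categories never count."""
    start = admission["start"] if isinstance(admission, (dict, pd.Series)) else admission.start
    lo, hi = start + WINDOW_AFTER, start + OUTCOME_END
    if len(incidents) == 0:
        return 0
    qualifying = (
        incidents["category"].isin(QUALIFYING_CATEGORIES)
        & (incidents["timestamp"] > lo)
        & (incidents["timestamp"] <= hi)
    )
    return int(qualifying.any())


def apply_exclusions(
    labeled: pd.DataFrame, post24h_word_counts: dict[str, int] | pd.Series
) -> tuple[pd.DataFrame, int]:
    """Drop admissions with fewer than 100 words registered after the first
    24 hours of admission. Returns (retained, n_excluded)."""
    counts = pd.Series(post24h_word_counts)
    wc = labeled["admission_id"].map(counts).fillna(0).astype(int)
    keep = wc >= MIN_POST24H_WORDS
    return labeled[keep].reset_index(drop=True), int((~keep).sum())


@dataclass
class CohortResult:
    """Labeled analysis units plus bookkeeping of each filtering step."""

    labeled: pd.DataFrame           # admission_id, patient_id, outcome, word_count, length_of_stay, first_incident_day
    documents: dict[str, list[str]]  # admission_id -> predictor-window token sequence
    n_input: int
    n_excluded_words: int
    n_excluded_empty: int

    def conserved(self) -> bool:
        return self.n_input == len(self.labeled) + self.n_excluded_words + self.n_excluded_empty


def build_labeled_admissions(
    admissions: pd.DataFrame,
    notes: pd.DataFrame,
    incidents: pd.DataFrame,
    max_gap_days: int = 14,
    count_predictor_window: bool = False,
) -> CohortResult:
    """Run the full cohort pipeline: merge episodes, window notes, label
    outcomes, apply the documentation exclusion.

    ``count_predictor_window`` switches the 100-word rule to count the
    predictor-window document instead of post-24h text (the default reading is
    post-24h: too little follow-up documentation to assess the outcome).
    """
    bad_roles = set(notes["author_role"].unique()) - AUTHOR_ROLES
    if bad_roles:
        raise ValueError(f"unknown author roles: {sorted(bad_roles)}")

    merged = merge_episodes(admissions, max_gap_days=max_gap_days)
    n_input = len(merged)

    notes_by_adm = dict(tuple(notes.groupby("admission_id", sort=False)))
    inc_by_adm = dict(tuple(incidents.groupby("admission_id", sort=False)))
    empty_notes = notes.iloc[0:0]
    empty_inc = incidents.iloc[0:0]

    rows = []
    documents: dict[str, list[str]] = {}
    post24_counts: dict[str, int] = {}
    n_empty = 0
    for adm in merged.itertuples(index=False):
        a_notes = notes_by_adm.get(adm.admission_id, empty_notes)
        a_inc = inc_by_adm.get(adm.admission_id, empty_inc)
        doc = select_note_window({"start": adm.start}, a_notes)
        if not doc:
            n_empty += 1
            continue
        y = label_outcome({"start": adm.start}, a_inc)
        post = a_notes[a_notes["timestamp"] > adm.start + WINDOW_AFTER]
        post_wc = int(sum(len(tokenize(t)) for t in post["text"]))
        post24_counts[adm.admission_id] = len(doc) if count_predictor_window else post_wc

        qual = a_inc[
            a_inc["category"].isin(QUALIFYING_CATEGORIES)
            & (a_inc["timestamp"] > adm.start + WINDOW_AFTER)
            & (a_inc["timestamp"] <= adm.start + OUTCOME_END)
        ]
        first_day = (
            (qual["timestamp"].min() - adm.start) / pd.Timedelta(days=1) if len(qual) else np.nan
        )
        documents[adm.admission_id] = doc
        rows.append(
            {
                "admission_id": adm.admission_id,
                "patient_id": adm.patient_id,
                "outcome": y,
                "word_count": len(doc),
                "length_of_stay": (adm.end - adm.start) / pd.Timedelta(days=1),
                "first_incident_day": first_day,
            }
        )

    labeled = pd.DataFrame(
        rows,
        columns=[
            "admission_id",
            "patient_id",
            "outcome",
            "word_count",
            "length_of_stay",
            "first_incident_day",
        ],
    )
    retained, n_excluded = apply_exclusions(labeled, post24_counts)
    documents = {a: documents[a] for a in retained["admission_id"]}
    return CohortResult(
        labeled=retained,
        documents=documents,
        n_input=n_input,
        n_excluded_words=n_excluded,
        n_excluded_empty=n_empty,
    )
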