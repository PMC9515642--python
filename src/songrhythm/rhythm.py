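"""Inter-onset intervals, rhythm ratios, and note-length controls.

A song's rhythm is measured from the relative timing of consecutive
events rather than from absolute intervals.  For consecutive
inter-onset intervals (IOIs) ``i_n`` and ``i_(n+1)``, the rhythm ratio

    R = i_n / (i_n + i_(n+1))

lies in (0, 1); R = 0.5 marks isochrony (equal consecutive intervals).
At the note level, IOIs that span a phrase boundary are excluded: the
silence between phrases is on a different timescale from the intervals
within a phrase.  At the phrase level the same ratio is computed from
phrase onsets within a bout.

Each ratio is attributed to the note opening its first interval and to
the bigram (first note -> second note) spanning that interval; the
third note participating in the rhythm is not part of the label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import argrelmin

from .events_io import EventTable, ValidationError

#: columns of a rhythm-ratio record frame
RATIO_COLUMNS = [
    "R",
    "rhythm_length",
    "first_note",
    "second_note",
    "first_note_idx",
    "phrase_id",
    "bout_id",
    "bird_id",
]


@dataclass
class IntervalSeries:
    """Ordered inter-onset intervals with labels and grouping ids.

    ``df`` columns: ``ioi`` (s), ``first_label``, ``second_label``,
    ``first_idx`` (row index of the opening event in the source table),
    ``phrase_id``, ``bout_id``, ``bird_id``.  ``level`` is ``"note"``
    or ``"phrase"``.
    """

    df: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in ("note", "phrase"):
            raise ValueError("level must be 'note' or 'phrase'")
        if len(self.df) and (self.df["ioi"] <= 0).any():
            raise ValidationError("all inter-onset intervals must be positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def intervals(self) -> np.ndarray:
        return self.df["ioi"].to_numpy()


def compute_iois(table: EventTable, level: str = "note") -> IntervalSeries:
    """Inter-onset intervals at note or phrase level.

    Note level: one interval per consecutive note pair within a phrase
    (cross-phrase spans are ignored).  Phrase level: one interval per
    consecutive phrase-onset pair within a bout, over the entire
    recording including long silences.
    """
    if level == "note":
        if not table.has_phrases:
            raise ValidationError(
                "note-level IOIs require phrase structure; run derive_phrases"
            )
        src = table.df
        group_cols = ["bird_id", "bout_id", "phrase_id"]
    elif level == "phrase":
        src = table.phrase_table()
        src["label"] = "phrase"
        group_cols = ["bird_id", "bout_id"]
    else:
        raise ValueError("level must be 'note' or 'phrase'")

    rows = []
    for key, g in src.groupby(group_cols, sort=False):
        if len(g) < 2:
            continue
        onsets = g["onset"].to_numpy()
        labels = g["label"].to_numpy()
        idx = g.index.to_numpy()
        pid = g["phrase_id"].to_numpy() if level == "note" else np.full(len(g), -1)
        rows.append(
            pd.DataFrame(
                {
                    "ioi": np.diff(onsets),
                    "first_label": labels[:-1],
                    "second_label": labels[1:],
                    "first_idx": idx[:-1],
                    "phrase_id": pid[:-1],
                    "bout_id": g["bout_id"].to_numpy()[:-1],
                    "bird_id": g["bird_id"].to_numpy()[:-1],
                }
            )
        )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=[
                "ioi",
                "first_label",
                "second_label",
                "first_idx",
                "phrase_id",
                "bout_id",
                "bird_id",
            ]
        )
    return IntervalSeries(df, level=level)


def rhythm_ratios(series: IntervalSeries) -> pd.DataFrame:
    """Rhythm ratios R = i_n / (i_n + i_(n+1)) from consecutive IOI pairs.

    Pairs must share a phrase (note level) or a bout (phrase level), so
    a phrase with k notes yields max(k - 2, 0) ratios.  Returns a frame
    with :data:`RATIO_COLUMNS`; ``first_note``/``second_note`` label the
    bigram spanning the first interval.
    """
    df = series.df
    if series.level == "note":
        group_cols = ["bird_id", "bout_id", "phrase_id"]
    else:
        group_cols = ["bird_id", "bout_id"]
    rows = []
    for _, g in df.groupby(group_cols, sort=False):
        if len(g) < 2:
            continue
        i1 = g["ioi"].to_numpy()[:-1]
        i2 = g["ioi"].to_numpy()[1:]
        rows.append(
            pd.DataFrame(
                {
                    "R": i1 / (i1 + i2),
                    "rhythm_length": i1 + i2,
                    "first_note": g["first_label"].to_numpy()[:-1],
                    "second_note": g["second_label"].to_numpy()[:-1],
                    "first_note_idx": g["first_idx"].to_numpy()[:-1],
                    "phrase_id": g["phrase_id"].to_numpy()[:-1],
                    "bout_id": g["bout_id"].to_numpy()[:-1],
                    "bird_id": g["bird_id"].to_numpy()[:-1],
                }
            )
        )
    if rows:
        return pd.concat(rows, ignore_index=True)
    return pd.DataFrame(columns=RATIO_COLUMNS)


def bigram_labels(records: pd.DataFrame) -> pd.Series:
    """Transition label 'first->second' for each rhythm-ratio record."""
    return records["first_note"].astype(str) + "->" + records["second_note"].astype(str)


def ratio_length_density(
    records: pd.DataFrame,
    ratio_bins: int = 50,
    length_bins: int = 50,
    row_normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint density of rhythm ratio and rhythm length.

    Returns ``(grid, ratio_edges, length_edges)`` where ``grid`` has one
    row per length bin.  With ``row_normalize`` each length bin is
    normalized separately (conditional density of R given tempo);
    otherwise the grid sums to 1.
    """
    if len(records) == 0:
        raise ValueError("no rhythm-ratio records to bin")
    grid, length_edges, ratio_edges = np.histogram2d(
        records["rhythm_length"],
        records["R"],
        bins=[length_bins, ratio_bins],
        range=[
            [records["rhythm_length"].min(), records["rhythm_length"].max()],
            [0.0, 1.0],
        ],
    )
    if row_normalize:
        sums = grid.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            grid = np.where(sums > 0, grid / sums, 0.0)
    else:
        grid = grid / grid.sum()
    return grid, ratio_edges, length_edges


# ---------------------------------------------------------------------------
# note-length controls


def control_note_length(table: EventTable) -> EventTable:
    """Set every note's duration to its bird's mean duration, keeping gaps.

    Silent gaps between notes are preserved exactly and onsets are
    recomputed left to right within each phrase from the phrase's
    original onset, so any rhythm remaining after the control is carried
    by the gaps, not by note-length differences.  The mean is taken per
    bird across pooled bouts.
    """
    if not table.has_phrases:
        raise ValidationError("control_note_length requires phrase structure")
    df = table.df.copy()
    durations = df["offset"] - df["onset"]
    mean_dur = durations.groupby(df["bird_id"]).transform("mean").to_numpy()
    pieces = []
    for _, g in df.groupby(["bird_id", "bout_id", "phrase_id"], sort=False):
        onsets = g["onset"].to_numpy()
        offsets = g["offset"].to_numpy()
        gaps = onsets[1:] - offsets[:-1]
        m = mean_dur[g.index.to_numpy()]
        new_on = np.empty(len(g))
        new_on[0] = onsets[0]
        for i in range(1, len(g)):
            new_on[i] = new_on[i - 1] + m[i - 1] + gaps[i - 1]
        g = g.copy()
        g["onset"] = new_on
        g["offset"] = new_on + m
        pieces.append(g)
    return EventTable(pd.concat(pieces), has_phrases=True)


def find_length_minima(
    durations: np.ndarray | pd.Series,
    bandwidth: float | str | None = None,
    grid_size: int = 512,
) -> np.ndarray:
    """Local minima of a Gaussian KDE of note duration.

    Used to place data-driven exclusion thresholds between note-length
    modes.  Bandwidth follows Scott's rule unless overridden.  Requires
    at least 10 durations; a unimodal sample yields an empty array.
    """
    x = np.asarray(durations, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 note durations for a density estimate")
    kde = sps.gaussian_kde(x, bw_method=bandwidth)
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    (idx,) = argrelmin(dens)
    return grid[idx]


def filter_ratios_by_note_length(
    records: pd.DataFrame, table: EventTable, threshold: float
) -> pd.DataFrame:
    """Drop rhythms that include any note longer than ``threshold``.

    Each note-level ratio involves three consecutive notes (two
    intervals); a record is removed if any of the three has duration
    above the threshold, so a single long note also removes the adjacent
    ratios that share it.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(records) == 0:
        return records.copy()
    durations = (table.df["offset"] - table.df["onset"]).to_numpy()
    first = records["first_note_idx"].to_numpy().astype(int)
    long_note = durations > threshold
    keep = ~(long_note[first] | long_note[first + 1] | long_note[first + 2])
    return records.loc[keep].reset_index(drop=True)


def gap_balance(table: EventTable) -> pd.DataFrame:
    """Per-note balance of the surrounding silent gaps.

    For every note with both a preceding and a following gap inside its
    phrase, reports ``share = gap_prev / (gap_prev + gap_next)`` along
    with the note's duration and label; 0.5 means the note sits midway
    between its neighbours' offsets/onsets.  First and last notes of a
    phrase are excluded.
    """
    if not table.has_phrases:
        raise ValidationError("gap_balance requires phrase structure")
    rows = []
    for _, g in table.df.groupby(["bird_id", "bout_id", "phrase_id"], sort=False):
        if len(g) < 3:
            continue
        onsets = g["onset"].to_numpy()
        offsets = g["offset"].to_numpy()
        gaps = onsets[1:] - offsets[:-1]
        prev_gap = gaps[:-1]
        next_gap = gaps[1:]
        total = prev_gap + next_gap
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(total > 0, prev_gap / total, np.nan)
        mid = g.iloc[1:-1]
        rows.append(
            pd.DataFrame(
                {
                    "duration": (mid["offset"] - mid["onset"]).to_numpy(),
                    "gap_share": share,
                    "label": mid["label"].to_numpy(),
                    "phrase_id": mid["phrase_id"].to_numpy(),
                    "bout_id": mid["bout_id"].to_numpy(),
                    "bird_id": mid["bird_id"].to_numpy(),
                }
            )
        )
    if rows:
        return pd.concat(rows, ignore_index=True)
    return pd.DataFrame(
        columns=["duration", "gap_share", "label", "phrase_id", "bout_id", "bird_id"]
    )
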