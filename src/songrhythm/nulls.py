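"""Null models for song rhythm.

Each null answers a different question about the observed rhythm-ratio
distribution:

* ``uniform_ioi_null`` — what would the ratios look like if intervals
  were drawn i.i.d. uniformly over the observed range? (no temporal
  structure at all);
* ``shuffle_iois`` — what if the song used exactly the observed
  intervals but in random order? (interval inventory preserved,
  sequence destroyed);
* ``shuffle_notes_gaps`` — what if note durations and silent gaps were
  each shuffled independently across the bout? (both component
  inventories preserved, their pairing and order destroyed);
* ``dissociate_labels`` — what if the transition labels carried no
  information about the ratios? (both marginals preserved, association
  destroyed; consumed by the PRE bootstrap).

Every pool is bit-reproducible under a fixed seed and exactly preserves
the marginal(s) its construction states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events_io import DEFAULT_MAX_GAP, EventTable, derive_phrases
from .rhythm import IntervalSeries, compute_iois, rhythm_ratios


@dataclass
class NullPool:
    """Pooled rhythm ratios from replicated null constructions.

    ``records`` has columns ``replicate, R, rhythm_length``.
    """

    kind: str
    n_shuffles: int
    records: pd.DataFrame
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def R(self) -> np.ndarray:
        return self.records["R"].to_numpy()


def _pairs_to_frame(ratio_chunks: list[tuple[int, np.ndarray, np.ndarray]]) -> pd.DataFrame:
    if not ratio_chunks:
        return pd.DataFrame(columns=["replicate", "R", "rhythm_length"])
    return pd.DataFrame(
        {
            "replicate": np.concatenate(
                [np.full(r.size, rep) for rep, r, _ in ratio_chunks]
            ),
            "R": np.concatenate([r for _, r, _ in ratio_chunks]),
            "rhythm_length": np.concatenate([ln for _, _, ln in ratio_chunks]),
        }
    )


def _ratios_of(intervals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i1, i2 = intervals[:-1], intervals[1:]
    return i1 / (i1 + i2), i1 + i2


def shuffle_iois(
    series: IntervalSeries,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> NullPool:
    """Pool of ratios from order-shuffled inter-onset intervals.

    Each shuffle permutes the intervals *within* their original scope —
    per phrase at note level, per bout at phrase level — so the interval
    multiset and the eligibility structure (which pairs may form a
    ratio) are preserved exactly.  The pool holds per-shuffle ratio
    count x ``n_shuffles`` records.
    """
    rng = np.random.default_rng(seed)
    df = series.df
    group_cols = (
        ["bird_id", "bout_id", "phrase_id"]
        if series.level == "note"
        else ["bird_id", "bout_id"]
    )
    groups = [
        g["ioi"].to_numpy() for _, g in df.groupby(group_cols, sort=False) if len(g) >= 2
    ]
    if not groups:
        raise ValueError("no scope holds two consecutive intervals; nothing to shuffle")
    chunks = []
    for rep in range(n_shuffles):
        rs, lens = [], []
        for ivals in groups:
            perm = rng.permutation(ivals)
            r, ln = _ratios_of(perm)
            rs.append(r)
            lens.append(ln)
        chunks.append((rep, np.concatenate(rs), np.concatenate(lens)))
    return NullPool("shuffle_ioi", n_shuffles, _pairs_to_frame(chunks))


def shuffle_notes_gaps(
    table: EventTable,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
    level: str = "note",
) -> NullPool:
    """Pool of ratios from independently shuffled notes and gaps.

    Per shuffle and per bout, the note-duration multiset and the
    silent-gap multiset (all gaps between consecutive notes of the bout,
    including between-phrase silences) are each permuted independently;
    the bout is rebuilt as note, gap, note, gap, ... from the bout's
    original first onset; phrases are re-derived with ``max_gap``; and
    ratios are recomputed.  Because long silences land in new places,
    the re-derived phrase structure changes which interval pairs are
    eligible, so the pooled count generally differs from the observed
    count times ``n_shuffles``.
    """
    rng = np.random.default_rng(seed)
    df = table.df
    bouts = []
    for _, g in df.groupby(["bird_id", "bout_id"], sort=False):
        onsets = g["onset"].to_numpy()
        offsets = g["offset"].to_numpy()
        durs = offsets - onsets
        gaps = onsets[1:] - offsets[:-1]
        bouts.append((onsets[0], durs, gaps, g["bird_id"].iat[0], g["bout_id"].iat[0]))
    chunks = []
    for rep in range(n_shuffles):
        frames = []
        for start, durs, gaps, bird, bout in bouts:
            d = rng.permutation(durs)
            gp = rng.permutation(gaps)
            ons = np.empty(d.size)
            ons[0] = start
            if d.size > 1:
                ons[1:] = start + np.cumsum(d[:-1] + gp)
            frames.append(
                pd.DataFrame(
                    {
                        "onset": ons,
                        "offset": ons + d,
                        "label": "n",
                        "bout_id": bout,
                        "bird_id": bird,
                    }
                )
            )
        rebuilt = EventTable(pd.concat(frames, ignore_index=True), has_phrases=False)
        rebuilt = derive_phrases(rebuilt, max_gap=max_gap)
        rec = rhythm_ratios(compute_iois(rebuilt, level=level))
        chunks.append(
            (rep, rec["R"].to_numpy(), rec["rhythm_length"].to_numpy())
        )
    return NullPool("shuffle_note_gap", n_shuffles, _pairs_to_frame(chunks))


def uniform_ioi_null(
    series: IntervalSeries,
    n_samples_per_rep: int | None = None,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> NullPool:
    """Pool of ratios from i.i.d. uniform intervals on the observed range.

    The reference distribution for 'no rhythm at all': intervals are
    sampled uniformly on [min, max] of the observed intervals and
    consecutive pairs within each replicate form ratios.
    ``n_samples_per_rep`` defaults to the observed interval count.
    """
    ivals = series.intervals
    if ivals.size < 2:
        raise ValueError("need at least two observed intervals")
    lo, hi = float(ivals.min()), float(ivals.max())
    if lo == hi:
        raise ValueError("degenerate interval range (min == max)")
    if n_samples_per_rep is None:
        n_samples_per_rep = ivals.size
    if n_samples_per_rep < 2:
        raise ValueError("n_samples_per_rep must be >= 2")
    rng = np.random.default_rng(seed)
    chunks = []
    for rep in range(n_reps):
        draw = rng.uniform(lo, hi, size=n_samples_per_rep)
        r, ln = _ratios_of(draw)
        chunks.append((rep, r, ln))
    return NullPool("uniform", n_reps, _pairs_to_frame(chunks))


def dissociate_labels(
    records: pd.DataFrame,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
    label_cols: tuple[str, str] = ("first_note", "second_note"),
) -> list[np.ndarray]:
    """Replicate permutations of the bigram labels over ratio records.

    Returns ``n_boot`` arrays of 'first->second' labels, each a
    permutation of the observed labels: the label multiset and the ratio
    multiset are untouched while their pairing is destroyed.  Feed the
    results to :func:`songrhythm.stats.pre` to build the dissociation
    null for the observed PRE.
    """
    a, b = label_cols
    labels = (records[a].astype(str) + "->" + records[b].astype(str)).to_numpy()
    rng = np.random.default_rng(seed)
    return [rng.permutation(labels) for _ in range(n_boot)]
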