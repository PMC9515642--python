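"""Read, validate, and write labelled song-event tables.

The universal input of the pipeline is an event table: one row per
segmented note with onset/offset times in seconds, a note-type label,
and phrase/bout/bird grouping columns.  Intervals are half-open
``[onset, offset)``: a note whose onset equals the previous note's
offset touches it but does not overlap.

Tables can be read from CSV/TSV or from Praat TextGrid interval tiers
(long or short text format); phrases can be supplied explicitly or
derived from silent gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: canonical column order of the events CSV schema
COLUMNS = ["onset", "offset", "label", "phrase_id", "bout_id", "bird_id"]

#: default silent-gap threshold (s) separating phrases; singing with
#: pauses shorter than this is treated as continuous
DEFAULT_MAX_GAP = 1.0


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ValidationError(ValueError):
    """A row (or pair of rows) violates an event-table invariant."""


@dataclass(frozen=True)
class NoteEvent:
    """One segmented note: an acoustic event surrounded by silence."""

    onset: float
    offset: float
    label: str
    phrase_id: int
    bout_id: str
    bird_id: str

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class PhraseEvent:
    """A run of continuous singing; onset/offset of first/last member note."""

    onset: float
    offset: float
    phrase_id: int
    bout_id: str
    bird_id: str


@dataclass
class EventTable:
    """Ordered, validated collection of note events.

    Wraps a :class:`pandas.DataFrame` with the canonical schema
    (``onset, offset, label, phrase_id, bout_id, bird_id``), sorted by
    (bird, bout, onset).  ``has_phrases`` is False when the source had
    no phrase column; call :func:`derive_phrases` before any
    phrase-dependent computation.
    """

    df: pd.DataFrame
    has_phrases: bool = True

    def __post_init__(self) -> None:
        self.df = _canonicalize(self.df, self.has_phrases)
        _validate(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def birds(self) -> list[str]:
        return list(dict.fromkeys(self.df["bird_id"]))

    def notes(self) -> list[NoteEvent]:
        return [
            NoteEvent(r.onset, r.offset, r.label, int(r.phrase_id), r.bout_id, r.bird_id)
            for r in self.df.itertuples(index=False)
        ]

    def phrases(self) -> list[PhraseEvent]:
        """Phrase events derived by aggregating member notes."""
        if not self.has_phrases:
            raise ValidationError(
                "table has no phrase structure; call derive_phrases first"
            )
        out = []
        for (bird, bout, pid), g in self.df.groupby(
            ["bird_id", "bout_id", "phrase_id"], sort=False
        ):
            out.append(
                PhraseEvent(
                    float(g["onset"].min()),
                    float(g["offset"].max()),
                    int(pid),
                    bout,
                    bird,
                )
            )
        out.sort(key=lambda p: (p.bird_id, str(p.bout_id), p.onset))
        return out

    def phrase_table(self) -> pd.DataFrame:
        """Phrases as a DataFrame (onset, offset, phrase_id, bout_id, bird_id)."""
        ph = self.phrases()
        return pd.DataFrame(
            {
                "onset": [p.onset for p in ph],
                "offset": [p.offset for p in ph],
                "phrase_id": [p.phrase_id for p in ph],
                "bout_id": [p.bout_id for p in ph],
                "bird_id": [p.bird_id for p in ph],
            }
        )


def _canonicalize(df: pd.DataFrame, has_phrases: bool) -> pd.DataFrame:
    df = df.copy()
    for col, default in (("phrase_id", 0), ("bout_id", "bout0"), ("bird_id", "bird0")):
        if col not in df.columns:
            df[col] = default
    if not has_phrases:
        df["phrase_id"] = 0
    df["onset"] = df["onset"].astype(float)
    df["offset"] = df["offset"].astype(float)
    df["label"] = df["label"].astype(str)
    df["phrase_id"] = df["phrase_id"].astype(int)
    df = df[COLUMNS]
    df = df.sort_values(["bird_id", "bout_id", "onset"], kind="mergesort")
    return df.reset_index(drop=True)


def _validate(df: pd.DataFrame) -> None:
    if (df["onset"] < 0).any():
        bad = int(df.index[df["onset"] < 0][0])
        raise ValidationError(f"row {bad}: negative onset")
    inverted = df["offset"] <= df["onset"]
    if inverted.any():
        bad = int(df.index[inverted][0])
        raise ValidationError(
            f"row {bad}: offset {df.at[bad, 'offset']} <= onset {df.at[bad, 'onset']}"
        )
    for (bird, bout), g in df.groupby(["bird_id", "bout_id"], sort=False):
        onsets = g["onset"].to_numpy()
        offsets = g["offset"].to_numpy()
        overlap = onsets[1:] < offsets[:-1] - 1e-12
        if overlap.any():
            i = int(np.argmax(overlap))
            raise ValidationError(
                f"bird {bird} bout {bout}: notes at rows {g.index[i]} and "
                f"{g.index[i + 1]} overlap (onset {onsets[i + 1]:.6f} < "
                f"offset {offsets[i]:.6f})"
            )
        pid = g["phrase_id"].to_numpy()
        if (np.diff(pid) < 0).any():
            raise ValidationError(
                f"bird {bird} bout {bout}: phrase_id decreases along the bout"
            )


# ---------------------------------------------------------------------------
# CSV / TSV


def read_note_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> EventTable:
    """Read an events CSV/TSV into a validated :class:`EventTable`.

    Parameters
    ----------
    path
        CSV or TSV file with header.  Columns ``onset``, ``offset`` and
        ``label`` are required; ``phrase_id``, ``bout_id``, ``bird_id``
        are optional.
    dialect
        Optional mapping from canonical column names to the file's
        column names, e.g. ``{"onset": "start_s", "label": "note"}``.
    sep
        Field separator; inferred from the file extension when None
        (``.tsv`` -> tab, otherwise comma).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep)
    if dialect:
        rename = {src: dst for dst, src in dialect.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    for col in ("onset", "offset", "label"):
        if col not in raw.columns:
            raise SchemaError(
                f"missing required column {col!r}; found {list(raw.columns)}"
            )
    has_phrases = "phrase_id" in raw.columns
    return EventTable(raw, has_phrases=has_phrases)


def write_note_table(table: EventTable, path: str | Path) -> None:
    """Write the canonical events CSV (times at microsecond precision)."""
    out = table.df.copy()
    out["onset"] = out["onset"].map(lambda t: f"{t:.6f}")
    out["offset"] = out["offset"].map(lambda t: f"{t:.6f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Praat TextGrid (interval tiers, long and short text formats)

_NUM = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")
_STR = re.compile(r'"((?:[^"]|"")*)"')


def _tokenize_textgrid(text: str) -> list[str | float]:
    """Flatten a TextGrid file into its quoted-string and number tokens.

    Both the long (attribute = value) and short (bare values) dialects
    reduce to the same token stream, which is enough to recover interval
    tiers without a grammar for each layout.
    """
    tokens: list[str | float] = []
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == '"':
            m = _STR.match(text, pos)
            if not m:
                raise ValueError(f"unterminated string in TextGrid at offset {pos}")
            tokens.append(m.group(1).replace('""', '"'))
            pos = m.end()
        elif ch.isdigit() or (ch in "-+." and _NUM.match(text, pos)):
            m = _NUM.match(text, pos)
            tokens.append(float(m.group(0)))
            pos = m.end()
        else:
            pos += 1
    return tokens


def parse_textgrid(path: str | Path) -> dict[str, list[tuple[float, float, str]]]:
    """Parse a Praat TextGrid into ``{tier name: [(xmin, xmax, text), ...]}``.

    Only interval tiers are returned; point tiers are skipped.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    if "TextGrid" not in text[:200]:
        raise ValueError(f"{path}: not a Praat TextGrid file")
    tokens = _tokenize_textgrid(text)
    # Long-format files interleave index decorations ("item [1]:",
    # "intervals [2]:") with the data; those surface as stray numbers in
    # the token stream, so intervals are recovered by scanning for the
    # (..., xmin, xmax, text) pattern rather than by fixed stride.
    idx = 0
    while idx < len(tokens) and tokens[idx] != "TextGrid":
        idx += 1
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    while idx < len(tokens):
        kind = tokens[idx]
        if kind not in ("IntervalTier", "TextTier"):
            idx += 1
            continue
        name = str(tokens[idx + 1])
        idx += 4  # kind, name, tier xmin, tier xmax
        if idx >= len(tokens) or isinstance(tokens[idx], str):
            raise ValueError(f"{path}: truncated tier {name!r}")
        n = int(tokens[idx])
        idx += 1
        if kind == "TextTier":  # point tier: skip n (time, mark) entries
            seen = 0
            while seen < n and idx < len(tokens):
                if isinstance(tokens[idx], str):
                    seen += 1
                idx += 1
            continue
        intervals = []
        for _ in range(n):
            numbuf: list[float] = []
            while idx < len(tokens) and not isinstance(tokens[idx], str):
                numbuf.append(float(tokens[idx]))
                idx += 1
            if idx >= len(tokens) or len(numbuf) < 2:
                raise ValueError(f"{path}: truncated interval in tier {name!r}")
            lab = str(tokens[idx])
            idx += 1
            intervals.append((numbuf[-2], numbuf[-1], lab))
        tiers[name] = intervals
    return tiers


def read_textgrid(
    path: str | Path,
    note_tier: str,
    phrase_tier: str | None = None,
    bout_id: str = "bout0",
    bird_id: str = "bird0",
) -> EventTable:
    """Build an :class:`EventTable` from TextGrid interval tiers.

    Non-empty-labelled intervals on ``note_tier`` become notes.  If
    ``phrase_tier`` is given, each note is assigned the phrase interval
    containing its onset; a note whose onset lies in no phrase interval
    is an error.  Without a phrase tier the table is returned with
    phrases underived.
    """
    tiers = parse_textgrid(path)
    if note_tier not in tiers:
        raise KeyError(
            f"tier {note_tier!r} not found; available interval tiers: {sorted(tiers)}"
        )
    notes = [(a, b, lab) for a, b, lab in tiers[note_tier] if lab.strip()]
    df = pd.DataFrame(
        {
            "onset": [a for a, _, _ in notes],
            "offset": [b for _, b, _ in notes],
            "label": [lab for _, _, lab in notes],
            "bout_id": bout_id,
            "bird_id": bird_id,
        }
    )
    if phrase_tier is None:
        return EventTable(df, has_phrases=False)
    if phrase_tier not in tiers:
        raise KeyError(
            f"tier {phrase_tier!r} not found; available interval tiers: {sorted(tiers)}"
        )
    spans = [(a, b) for a, b, lab in tiers[phrase_tier] if lab.strip()]
    spans.sort()
    pids = []
    orphans = []
    for i, (onset, _, _) in enumerate(notes):
        pid = next(
            (k for k, (a, b) in enumerate(spans) if a - 1e-9 <= onset < b),
            None,
        )
        if pid is None:
            orphans.append((i, onset))
        else:
            pids.append(pid)
    if orphans:
        raise ValidationError(
            "notes outside every phrase interval: "
            + ", ".join(f"#{i} at {t:.3f}s" for i, t in orphans)
        )
    df["phrase_id"] = pids
    return EventTable(df, has_phrases=True)


# ---------------------------------------------------------------------------
# phrase derivation


def derive_phrases(table: EventTable, max_gap: float = DEFAULT_MAX_GAP) -> EventTable:
    """Group notes into phrases by silent-gap threshold.

    Maximal runs of notes whose inter-note silent gap (next onset minus
    previous offset) stays below ``max_gap`` form one phrase; phrase ids
    are assigned 0..P-1 within each bout.  Idempotent for a fixed
    ``max_gap`` and never changes the number of notes.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    df = table.df.copy()
    pieces = []
    for (_, _), g in df.groupby(["bird_id", "bout_id"], sort=False):
        gaps = g["onset"].to_numpy()[1:] - g["offset"].to_numpy()[:-1]
        breaks = np.concatenate([[0], (gaps >= max_gap).astype(int)])
        g = g.copy()
        g["phrase_id"] = np.cumsum(breaks)
        pieces.append(g)
    out = pd.concat(pieces) if pieces else df
    return EventTable(out, has_phrases=True)
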