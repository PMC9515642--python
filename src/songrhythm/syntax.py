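"""Symbolic sequence machinery for song syntax.

A song is reduced to its note-label sequence (per bout; transitions are
never counted across bout boundaries).  This module fits order-k Markov
transition models, detects consistent first-order transitions against a
zero-order bootstrap null, synthesizes sequences from fitted models,
and measures long-range order as normalized Shannon entropy of the
sequence after fusing each note with h previous notes (its historical
context):

    eta(X) = -sum_i p(x_i) log p(x_i) / log(n)

with n the number of unique symbols in the expanded sequence (eta = 0
by convention when n = 1; the logarithm base cancels).  A sequence with
genuine order beyond a model's reach has lower eta than sequences
synthesized from that model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events_io import EventTable


@dataclass
class NoteSequence:
    """Ordered note labels grouped by bout."""

    bouts: list[list[str]]
    bird_id: str = "bird0"

    def __post_init__(self) -> None:
        self.bouts = [list(map(str, b)) for b in self.bouts]

    def __len__(self) -> int:
        return sum(len(b) for b in self.bouts)

    @property
    def alphabet(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.bouts:
            for s in b:
                seen.setdefault(s)
        return sorted(seen)

    def concatenated(self) -> list[str]:
        return [s for b in self.bouts for s in b]


def sequence_from_table(table: EventTable, bird_id: str | None = None) -> NoteSequence:
    """Extract the note-label sequence of one bird, one list per bout."""
    df = table.df
    if bird_id is None:
        birds = table.birds
        if len(birds) != 1:
            raise ValueError(f"table holds several birds {birds}; pass bird_id")
        bird_id = birds[0]
    df = df[df["bird_id"] == bird_id]
    bouts = [g["label"].tolist() for _, g in df.groupby("bout_id", sort=False)]
    return NoteSequence(bouts=bouts, bird_id=bird_id)


# ---------------------------------------------------------------------------
# transition models


@dataclass
class TransitionModel:
    """Order-k symbol transition counts and probabilities.

    ``counts`` maps a length-k context tuple to a Counter of successor
    symbols (the empty tuple for k = 0).  ``start_contexts`` holds the
    initial k symbols of each bout, used to seed synthesis.
    """

    order: int
    counts: dict[tuple, Counter] = field(repr=False)
    alphabet: list[str] = field(default_factory=list)
    start_contexts: list[tuple] = field(default_factory=list, repr=False)

    @property
    def probs(self) -> dict[tuple, dict[str, float]]:
        out = {}
        for ctx, ctr in self.counts.items():
            total = sum(ctr.values())
            out[ctx] = {sym: c / total for sym, c in ctr.items()}
        return out

    def prob(self, context: tuple, symbol: str) -> float:
        ctr = self.counts.get(tuple(context))
        if not ctr:
            return 0.0
        return ctr.get(symbol, 0) / sum(ctr.values())


def transition_table(seq: NoteSequence, order: int = 1) -> TransitionModel:
    """Fit an order-k transition model from within-bout counts.

    Contexts are the k symbols preceding each position; probabilities
    over each context sum to 1.  Bouts shorter than k + 1 contribute no
    transitions.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if len(seq) <= order:
        raise ValueError(f"sequence length {len(seq)} <= order {order}")
    counts: dict[tuple, Counter] = {}
    starts = []
    for bout in seq.bouts:
        if len(bout) >= order:
            starts.append(tuple(bout[:order]))
        for i in range(order, len(bout)):
            ctx = tuple(bout[i - order : i])
            counts.setdefault(ctx, Counter())[bout[i]] += 1
    return TransitionModel(
        order=order, counts=counts, alphabet=seq.alphabet, start_contexts=starts
    )


def uniform_model(alphabet: list[str]) -> TransitionModel:
    """Order-0 model that is i.i.d. uniform over the alphabet.

    The 'random' reference source: it preserves only which note types
    exist, not their frequencies.
    """
    if not alphabet:
        raise ValueError("empty alphabet")
    counts = {(): Counter({sym: 1 for sym in alphabet})}
    return TransitionModel(order=0, counts=counts, alphabet=sorted(alphabet), start_contexts=[()])


def synthesize_sequence(
    model: TransitionModel,
    length: int,
    seed: int | np.random.Generator | None = None,
) -> NoteSequence:
    """Draw one sequence of ``length`` symbols from a fitted model.

    The initial context is drawn from the empirical distribution of
    observed bout starts.  If the chain reaches a context with no
    observed continuation it re-seeds from a fresh start context; no
    artificial end tokens are introduced.
    """
    if not model.counts:
        raise ValueError("empty model")
    if length <= model.order:
        raise ValueError("length must exceed the model order")
    rng = np.random.default_rng(seed)
    order = model.order
    # cumulative successor weights per context: one uniform draw plus a
    # searchsorted replaces a categorical sample at every step
    ctx_syms: dict[tuple, tuple[list[str], np.ndarray]] = {}
    for ctx, ctr in model.counts.items():
        syms = sorted(ctr)
        w = np.cumsum([ctr[s] for s in syms]).astype(float)
        ctx_syms[ctx] = (syms, w / w[-1])
    starts = [s for s in model.start_contexts if len(s) == order]
    if not starts:
        starts = [next(iter(model.counts))]

    def fresh_start() -> list[str]:
        return list(starts[rng.integers(len(starts))])

    u = rng.random(length)
    ui = 0
    out: list[str] = fresh_start()[:length]
    while len(out) < length:
        ctx = tuple(out[-order:]) if order else ()
        entry = ctx_syms.get(ctx)
        if entry is None:  # dead-end context: re-seed the chain
            out.extend(fresh_start()[: length - len(out)])
            continue
        syms, cum = entry
        if ui >= u.size:
            u = rng.random(length)
            ui = 0
        j = int(np.searchsorted(cum, u[ui], side="right"))
        ui += 1
        out.append(syms[min(j, len(syms) - 1)])
    return NoteSequence(bouts=[out], bird_id="synthesized")


# ---------------------------------------------------------------------------
# consistent first-order transitions


def consistent_transitions(
    seq: NoteSequence,
    n_boot: int = 100,
    level: float = 0.95,
    min_frac: float = 0.01,
    seed: int | np.random.Generator | None = None,
    method: str = "replicates",
) -> pd.DataFrame:
    """Bigrams whose probability beats a zero-order bootstrap null.

    A first-order transition a->b is *consistent* when (i) its
    empirical P(b|a) exceeds the upper bound of the level-CI of P(b|a)
    under a null that preserves only label frequencies, and (ii) it
    occurs at least ``min_frac`` times the total sequence length.

    ``method='replicates'`` builds the null from ``n_boot`` i.i.d.
    unigram sequences of the observed length (upper bound = level
    quantile across replicates).  ``method='long_sequence'`` instead
    scores one 100x-length unigram sequence and uses a normal-
    approximation CI around its transition probabilities.

    Returns a frame with columns ``first, second, prob, count,
    null_upper, consistent``.
    """
    labels = np.asarray(seq.concatenated())
    total = labels.size
    if total < 2:
        raise ValueError("sequence too short for transitions")
    rng = np.random.default_rng(seed)
    model = transition_table(seq, order=1)
    alphabet = seq.alphabet
    sym_to_i = {s: i for i, s in enumerate(alphabet)}
    k = len(alphabet)
    uni = np.bincount([sym_to_i[s] for s in labels], minlength=k).astype(float)
    p_uni = uni / uni.sum()

    def bigram_probs(codes: np.ndarray) -> np.ndarray:
        """P(b|a) matrix from one integer-coded sequence."""
        mat = np.zeros((k, k))
        np.add.at(mat, (codes[:-1], codes[1:]), 1.0)
        row = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(row > 0, mat / row, 0.0)

    if method == "replicates":
        null = np.empty((n_boot, k, k))
        for b in range(n_boot):
            null[b] = bigram_probs(rng.choice(k, size=total, p=p_uni))
        upper = np.quantile(null, level, axis=0)
    elif method == "long_sequence":
        from scipy.stats import norm

        codes = rng.choice(k, size=100 * total, p=p_uni)
        mat = np.zeros((k, k))
        np.add.at(mat, (codes[:-1], codes[1:]), 1.0)
        row = mat.sum(axis=1, keepdims=True)
        phat = np.where(row > 0, mat / row, 0.0)
        z = float(norm.ppf(level))
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(np.where(row > 0, phat * (1 - phat) / row, 0.0))
        upper = phat + z * se
    else:
        raise ValueError("method must be 'replicates' or 'long_sequence'")

    rows = []
    min_count = min_frac * total
    for (a,), ctr in model.counts.items():
        out_total = sum(ctr.values())
        for b_sym, c in sorted(ctr.items()):
            p_emp = c / out_total
            ub = float(upper[sym_to_i[a], sym_to_i[b_sym]])
            rows.append(
                {
                    "first": a,
                    "second": b_sym,
                    "prob": p_emp,
                    "count": c,
                    "null_upper": ub,
                    "consistent": bool(p_emp > ub and c >= min_count),
                }
            )
    return pd.DataFrame(rows).sort_values(["first", "second"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# historical-context expansion and normalized entropy


def _encode(seq: NoteSequence) -> tuple[list[np.ndarray], int]:
    alphabet = seq.alphabet
    sym_to_i = {s: i for i, s in enumerate(alphabet)}
    return [np.array([sym_to_i[s] for s in b], dtype=np.int64) for b in seq.bouts], len(
        alphabet
    )


def context_expand(seq: NoteSequence, h: int) -> list[tuple]:
    """Fuse each note with its h previous notes into one symbol.

    ``h = 0`` returns the notes themselves (as 1-tuples are unwieldy,
    plain labels are kept); for ``h > 0`` every position p >= h within a
    bout yields the tuple ``(note_{p-h}, ..., note_p)``, so a bout of
    length L contributes max(L - h, 0) symbols and bouts shorter than
    h + 1 contribute none.
    """
    if h < 0:
        raise ValueError("historical context length must be >= 0")
    if h == 0:
        return [s for b in seq.bouts for s in b]
    out: list[tuple] = []
    for bout in seq.bouts:
        for p in range(h, len(bout)):
            out.append(tuple(bout[p - h : p + 1]))
    return out


def normalized_entropy(symbols: list | np.ndarray) -> float:
    """Shannon entropy of the empirical symbol distribution over log(n).

    n is the number of unique symbols in *this* sequence, so the base
    of the logarithm cancels; a single-symbol sequence has eta = 0 by
    convention.
    """
    if len(symbols) == 0:
        raise ValueError("empty symbol sequence")
    _, counts = np.unique(np.asarray(symbols, dtype=object), return_counts=True)
    return _entropy_from_counts(counts)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.size
    if n <= 1:
        return 0.0
    p = counts / counts.sum()
    H = -(p * np.log(p)).sum()
    return float(H / np.log(n))


def _eta_of_bouts(bouts: list[np.ndarray], h: int, k: int) -> float:
    """Normalized entropy of the h-expanded, integer-coded sequence.

    Each length-(h+1) window is packed into one base-k integer key and
    identical keys across bouts are merged before counting, mirroring
    symbol counting over the pooled expanded sequence.  When k**(h+1)
    would overflow 64 bits the windows are re-keyed in two stages.
    """
    if k > 1 and (h + 1) * np.log2(k) > 62:
        return _eta_of_bouts_rows(bouts, h)
    keys = _window_keys(bouts, h, k)
    if keys.size == 0:
        raise ValueError(f"no bout is longer than h = {h}")
    _, counts = np.unique(keys, return_counts=True)
    return _entropy_from_counts(counts)


def _window_keys(bouts: list[np.ndarray], h: int, k: int) -> np.ndarray:
    keys = []
    for codes in bouts:
        L = codes.size - h
        if L <= 0:
            continue
        key = np.zeros(L, dtype=np.uint64)
        for j in range(h + 1):
            key = key * np.uint64(k) + codes[j : j + L].astype(np.uint64)
        keys.append(key)
    return np.concatenate(keys) if keys else np.zeros(0, dtype=np.uint64)


def _eta_of_bouts_rows(bouts: list[np.ndarray], h: int) -> float:
    """Overflow-safe variant: count unique window rows directly."""
    from numpy.lib.stride_tricks import sliding_window_view

    windows = [
        sliding_window_view(codes, h + 1) for codes in bouts if codes.size > h
    ]
    if not windows:
        raise ValueError(f"no bout is longer than h = {h}")
    _, counts = np.unique(np.concatenate(windows, axis=0), axis=0, return_counts=True)
    return _entropy_from_counts(counts)


def entropy_curves(
    seq: NoteSequence,
    h_max: int = 20,
    n_reps: int = 100,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Normalized entropy versus historical context, observed vs models.

    For each h in 0..h_max computes eta of the observed sequence and,
    for each reference source — 'random' (i.i.d. uniform over the
    alphabet), and Markov models of order 0, 1 and 2 fitted to the
    observed sequence — the mean and central level-CI of eta over
    ``n_reps`` sequences synthesized at the observed length.

    Returns a tidy frame (h, source, eta, ci_lo, ci_hi); the observed
    source carries NaN bounds (single sequence).  A sequence with
    long-range order shows observed eta below the first-order band for
    h >= 1.
    """
    total = len(seq)
    if total < 3:
        raise ValueError("sequence too short for entropy curves")
    longest = max(len(b) for b in seq.bouts)
    if longest <= h_max:
        raise ValueError(
            f"h_max {h_max} infeasible: longest bout has {longest} notes; "
            f"maximal feasible h is {longest - 1}"
        )
    rng = np.random.default_rng(seed)
    k_alpha = len(seq.alphabet)
    models = {
        "random": uniform_model(seq.alphabet),
        "zeroth_order": transition_table(seq, 0),
        "first_order": transition_table(seq, 1),
        "second_order": transition_table(seq, 2) if total > 2 else None,
    }
    hs = np.arange(h_max + 1)
    obs_bouts, _ = _encode(seq)

    rows = [
        {"h": int(h), "source": "observed", "eta": _eta_of_bouts(obs_bouts, int(h), k_alpha),
         "ci_lo": np.nan, "ci_hi": np.nan}
        for h in hs
    ]
    tail = (1.0 - level) / 2.0
    for name, model in models.items():
        if model is None:
            continue
        etas = np.empty((n_reps, h_max + 1))
        for r in range(n_reps):
            synth = synthesize_sequence(model, total, seed=rng)
            # encode against the observed alphabet so packed keys match
            sym_to_i = {s: i for i, s in enumerate(seq.alphabet)}
            sb = [
                np.array([sym_to_i[s] for s in bout], dtype=np.int64)
                for bout in synth.bouts
            ]
            for h in hs:
                etas[r, h] = _eta_of_bouts(sb, int(h), k_alpha)
        for h in hs:
            col = etas[:, h]
            rows.append(
                {
                    "h": int(h),
                    "source": name,
                    "eta": float(col.mean()),
                    "ci_lo": float(np.quantile(col, tail)),
                    "ci_hi": float(np.quantile(col, 1.0 - tail)),
                }
            )
    return pd.DataFrame(rows)
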