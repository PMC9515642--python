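# songrhythm

Syntactic–rhythmic analysis of segmented birdsong.

Songbirds such as the Australian pied butcherbird deliver long nocturnal
song bouts organized into phrases of discrete, labelled notes. Two
traditions describe the temporal structure of such songs: a *syntactic*
one (transition statistics of the note-label sequence) and a *rhythmic*
one (relative timing of note onsets). `songrhythm` implements a complete,
tested pipeline for studying both and — crucially — their interaction,
starting from nothing more than a table of segmented events (onset,
offset, label, phrase, bout, bird).

## What it computes

**Rhythm ratios.** For consecutive inter-onset intervals (IOIs)
*i<sub>n</sub>* and *i<sub>n+1</sub>*, the rhythm ratio

&nbsp;&nbsp;&nbsp;&nbsp;*R = i<sub>n</sub> / (i<sub>n</sub> + i<sub>n+1</sub>)*

lies in (0, 1), with *R* = 0.5 marking isochrony. Ratios are computed at
the note level (within phrases; intervals spanning a phrase boundary are
excluded) and at the phrase level (from phrase onsets within a bout).

**Clusterability.** The Hopkins statistic
*H = Σu<sub>i</sub> / (Σu<sub>i</sub> + Σw<sub>i</sub>)* compares
reference-to-data and data-to-data nearest-neighbour distances:
*H* ≈ 0.5 for a homogeneous Poisson sample, *H* → 1 for categorically
clustered rhythm.

**Syntax-conditioned rhythm.** Consistent first-order transitions are
bigrams whose probability beats the 95% bound of a label-frequency-
preserving zero-order bootstrap null and that pass a 1%-of-sequence
occurrence floor. For each note type with two or more consistent
outgoing transitions, the ratio distributions grouped by transition are
compared with two-sample Kolmogorov–Smirnov tests
(*D = sup |F<sub>1,n</sub> − F<sub>2,m</sub>|*), Bonferroni-corrected
per bird.

**Variance explained.** The proportionate reduction of error,
*PRE = 1 − Σ(Y<sub>i</sub> − Ŷ<sub>i</sub>)² / Σ(Y<sub>i</sub> − Ȳ)²*,
measures how much rhythm variance the transition labels absorb, judged
against a shuffle-bootstrap null in which labels are permuted against
ratios (both marginals kept, their association destroyed).

**Long-range order.** Normalized entropy
*η = −Σ p(x<sub>i</sub>) log p(x<sub>i</sub>) / log n* is tracked while
each note is fused with *h* previous notes (historical context,
*h* = 0…20), for the observed sequence and for sequences synthesized
from random, zeroth-, first- and second-order Markov models.

**Null models.** Uniform-interval songs, order-shuffled intervals,
independently shuffled notes and gaps, and dissociated labels — each
preserving exactly the marginals its construction states.

**Ground truth.** A synthetic song generator plants a known syntax,
per-bigram gap distributions (categorical rhythms), and near-isochronous
phrase grids, with a coupling switch that ties gaps to bigrams or severs
that tie. Every pipeline stage is tested against what was planted.

## Worked example

Generate a song whose gaps are coupled to its syntax, then ask whether
the analysis recovers that coupling:

```python
import songrhythm as sr

table, truth = sr.generate_song(sr.preset("coupled", seed=1))
rec = sr.rhythm_ratios(sr.compute_iois(table, "note"))

H = sr.hopkins(rec["R"], seed=2).H
groups = sr.rhythm.bigram_labels(rec)
obs = sr.pre(rec["R"], groups)
lo, hi, _ = sr.pre_null_ci(rec["R"], groups, seed=3)
print(f"Hopkins {H:.3f}  PRE {obs.PRE:.3f}  CI [{lo:.3f}, {hi:.3f}]")

out = sr.interaction_table(table, sr.AnalysisConfig(seed=4))
print(out[["note_type", "transition_a", "transition_b", "D", "p_adjusted"]])
```

Output:

```
Hopkins 0.991  PRE 0.997  CI [0.001, 0.005]
note_type transition_a transition_b    D  p_adjusted
        P         P->A         P->B  1.0         0.0
        Q         Q->C         Q->D  1.0         0.0
```

Read: the 3473 rhythm ratios of this 4973-note song are almost perfectly
clustered (*H* = 0.991, against 0.5 for Poisson timing); the first-order
transitions explain 99.7% of rhythm variance while dissociated labels
explain at most 0.5%; and both planted hub note types (P and Q, each
with two consistent outgoing transitions) are flagged, their two ratio
distributions fully separated (*D* = 1.0) and significant after
Bonferroni correction. The same pipeline run on the `decoupled` preset
(identical except gaps are drawn independently of syntax) returns a PRE
inside the null interval and no significant pairs.

The same analyses are available from the shell:

```sh
songrhythm simulate --preset coupled --seed 1 --out song/
songrhythm report song/events.csv --seed 1 --out report/
```

`report/` then holds tidy CSVs (ratios, interaction table, entropy
curves, gap balance) plus `summary.json` with Hopkins, PRE + CI, KS-vs-
null and mean-IOI results.

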