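# Methods

This note records the models implemented by `songrhythm`, the parameter
choices that matter, and what the synthetic ground truth can and cannot
establish.

## Event model

A *note* is a segmented acoustic event with onset and offset in seconds
and an opaque, case-sensitive type label. Intervals are half-open
`[onset, offset)`: a note whose onset equals its predecessor's offset
touches without overlapping. A *phrase* is a maximal run of notes whose
silent gaps (next onset − previous offset) stay below a threshold
`max_gap`; a *bout* is one continuous recording. Phrase onsets/offsets
are those of the first/last member note.

`max_gap` defaults to 1.0 s. Field phrases of this kind span roughly
1–3 s of continuous singing bounded by silence; manual phrase boundaries
are not reproducible, so a threshold is required, and 1.0 s sits well
below typical between-phrase silences while far above within-phrase
gaps (tens to hundreds of milliseconds). CSV output carries times at
microsecond precision, comfortably below the millisecond scale at which
segmentation itself is defined.

## Rhythm ratios

For consecutive within-phrase inter-onset intervals, R = i_n / (i_n +
i_{n+1}); a phrase of k notes yields max(k − 2, 0) ratios. Intervals
spanning phrase boundaries are never used at the note level because
between-phrase silences live on a different timescale. Phrase-level
ratios use the full within-bout phrase-onset series, long silences
included.

Each ratio is attributed to the note opening its first interval and to
the bigram spanning that interval. The third participating note is not
part of the label; it influences the value of R (through i_{n+1}) but
not its grouping. R is invariant to a global tempo change (all times
scaled by c > 0), and reversing an interval pair maps R to 1 − R.

Note-length controls: `control_note_length` replaces every duration by
the bird's pooled mean duration while preserving each silent gap
exactly, rebuilding onsets left-to-right from the original phrase
onset. `find_length_minima` places exclusion thresholds at local minima
of a Gaussian KDE of note duration (Scott's-rule bandwidth by default —
the estimator is a free choice; only the thresholds themselves matter
downstream), and `filter_ratios_by_note_length` drops every ratio whose
three participating notes include one longer than the threshold.

## Hopkins statistic

Rhythm ratios are scalar, so the statistic is computed in one dimension
(exponent d = 1). Per replicate, m = ⌈0.1 n⌉ data points are sampled
without replacement and m reference points uniformly on the observed
[min, max]; u_i is each reference point's distance to the nearest data
point, w_i each sampled point's distance to the nearest *other* data
point; the replicate statistic is Σu/(Σu + Σw) and H is the mean of 100
replicates. The sampling fraction 0.1 is a convention (the standard
"small m relative to n" regime that keeps replicates weakly dependent);
the replicate count follows the usual 100-replicate averaging practice.
H ≈ 0.5 for Poisson-uniform data and → 1 for tight clusters. A
perfectly regular grid gives H ≈ 0.2, not 0: sometimes stated otherwise
in the literature, but the u terms do not vanish for a finite grid.

## Kolmogorov–Smirnov comparisons and the family correction

`ks_2sample` reports D = sup|F1,n − F2,m| with the standard asymptotic
two-sided p-value, plus the closed-form rejection bound
sqrt(−ln(α/2)·(1 + m/n)/(2m)). Within each bird, all pairwise
transition comparisons form one Bonferroni family (adjusted
p = min(1, p·k)).

The interaction analysis keeps a note type only if (i) it contributes
at least 1% of the bird's rhythm ratios and (ii) it has two or more
consistent outgoing transitions; with a single consistent transition a
pairwise test is undefined.

## Consistent transitions

The zero-order null preserves label frequencies only. The implementation
generates 100 replicate i.i.d. unigram sequences, each of the observed
length, computes every bigram's conditional probability per replicate,
and takes the 95% quantile as the null upper bound; a bigram is
consistent when its empirical probability exceeds that bound and it
occurs at least 0.01 × sequence length times. A single 100×-length null
sequence yields a point estimate rather than a distribution, so the
replicate construction is the default; the long-sequence variant (with
a normal-approximation CI) is available via `method="long_sequence"`.

## PRE and the dissociation null

PRE = 1 − SSE_groups/SSE_total with group means as predictor; 1 iff
groups absorb all variance, 0 when they explain nothing. The null
permutes labels against ratios 100 times — syntax marginal and rhythm
marginal each intact, association destroyed — and reports the central
95% quantile interval of the replicate PREs. With g balanced groups and
independent labels the replicates concentrate near (g − 1)/(n − 1).

Two caveats, verified by simulation and reflected in the test suite:
a 95% quantile band estimated from 100 replicates covers a fresh draw
at ~93–94%, not 95%; and consecutive rhythm ratios share an interval
(lag-1 anticorrelated) while transition labels are serially structured,
so the observed PRE of even a perfectly dissociated song is slightly
more variable than exchangeable permutation replicates. Coverage of the
null interval on dissociated synthetic songs is therefore ~85–90%
rather than nominal. For the effect sizes of interest (observed PRE an
order of magnitude above the null) this is immaterial.

## Sequence models and entropy curves

Transition models of order k ∈ {0, 1, 2} are fitted from within-bout
counts; no transition is counted across a bout boundary (transitions
across phrase boundaries within a bout do count — the note stream is
continuous in time within a bout — and a phrase-restricted variant is a
one-line filter on the input table). Synthesis starts from an observed
bout-start context and re-seeds from a fresh start context at dead ends,
avoiding artificial end tokens that would distort unigram statistics.
The "random" reference model is i.i.d. uniform over the observed
alphabet (preserves which note types exist, not their frequencies).

Historical-context expansion fuses each note with its h predecessors
into one symbol; a bout of length L contributes max(L − h, 0) symbols.
Normalized entropy divides the Shannon entropy of the empirical symbol
distribution by log n with n the number of unique symbols *in that
sequence* (the base cancels; η := 0 when n = 1). Normalizing by unique
notes instead of unique expanded symbols is exposed as an alternative
but the per-sequence definition is the default because it keeps η
comparable across h. Entropy curves run h = 0…20 and synthesize 100
sequences per model at the observed length; bands are the 2.5/97.5%
quantiles of replicate η. Quantile bands (not CIs of the replicate
mean) are the only band against which "the observed curve lies inside /
below" is a meaningful statement for a single observed sequence.

A structural fact worth stating: a first-order model fitted to any
stationary sequence reproduces its bigram distribution in expectation,
so at h = 1 the observed curve of a clean second-order source falls
*inside* the first-order band; the second-order signature appears from
h = 2 onward, where trigram statistics diverge. Real song, with
higher-order and non-stationary structure, can sit below synthesized
curves at every h; a pure order-2 chain cannot at h = 1.

## Null rhythm pools

* `uniform_ioi_null`: intervals i.i.d. uniform on the observed
  [min, max]; consecutive pairs form ratios.
* `shuffle_iois`: permutes intervals within their original scope (per
  phrase at note level, per bout at phrase level), preserving the
  interval multiset and the eligibility structure exactly; pooled count
  is the observed count × number of shuffles.
* `shuffle_notes_gaps`: permutes note durations and all within-bout
  silent gaps independently, rebuilds the bout as note–gap–note–gap,
  re-derives phrases with the standard `max_gap`, and recomputes
  ratios. Long silences land in new places, so the re-derived phrase
  structure — and hence the pooled ratio count — differs from shuffle
  to shuffle; this is the reading under which the pool can exceed
  observed × shuffles.
* `dissociate_labels`: permutes bigram labels over ratio records.

Shuffle counts default to 1000 for distribution comparisons and 100 for
the PRE bootstrap. Every pool is bit-reproducible under a fixed seed.

## Synthetic ground truth

The generator emulates the structure the analysis assumes: a per-bird
alphabet, first- or second-order note syntax, per-note-type lognormal
durations (floored at 10 ms), a per-bigram gap model (discrete
categories + Gaussian jitter, lognormal, or exponential), geometric
phrase lengths (capped so phrase contents fit the onset period), and
phrase onsets on a period grid with Gaussian jitter. Gaps — not note
durations — carry the coupled rhythm signal by default, matching the
view that silent intervals induce the rhythmic structure; a duration-
driven variant is a config edit away.

The `coupled` preset cycles P → {A|B} → Q → {C|D} → P with hub
transition probabilities of 0.5 and per-bigram gap categories between
0.05 and 0.30 s (jitter sd 3 ms, separations ≥ 13× jitter; durations
80 ms median, log-sd 0.02). The two gaps leaving each hub are equal, so
the interval *into* a hub is constant and every bigram group's ratio
distribution stays tight — this is what lets transition labels explain
essentially all rhythm variance (PRE > 0.95) while the two branches of
each hub remain fully separable. Defaults: 750 phrases, mean 8 notes
per phrase (≈ 5000 notes, the scale of a pooled per-bird field sample),
5 s phrase period. `decoupled` differs only in drawing each gap from
the pooled bigram mixture. `poisson_gaps` uses exponential gaps with
20 ms notes: ratios of i.i.d. exponential intervals are uniform on
(0, 1), the Hopkins Poisson reference. `isochronous_phrases` tightens
the phrase grid (3 s period, 20 ms jitter). `second_order` plants
"copy the note two back" dynamics (probability 0.9) on two symbols —
structure invisible to any first-order model.

What passing tests on this ground truth do *not* show: robustness to
segmentation error, drifting tempo, repertoire drift across bouts, or
non-stationary syntax — all present in field recordings and none
emulated here. Recovery results certify the estimators, not the
biology.

## Numerical choices

Times are float seconds; CSV round-trips at 1 µs. Entropy expansion
packs integer-coded windows into base-k keys (with a row-wise fallback
when k^(h+1) would overflow 64 bits). Nearest-neighbour searches for
the Hopkins statistic use sorted-array bisection; duplicated values
count as genuine zero-distance neighbours rather than self-matches.
Markov synthesis consumes pre-drawn uniforms against cumulative rows.
The degenerate cases are: all-equal values (Hopkins and PRE undefined,
both raise), single-symbol sequences (η := 0), phrases of fewer than
three notes (no ratios), and bouts shorter than h + 1 (no expanded
symbols, with an error only if no bout qualifies).
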