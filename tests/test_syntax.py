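"""Transition models, consistent transitions, synthesis, entropy."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import songrhythm as sr
from songrhythm.syntax import NoteSequence, uniform_model

label_lists = st.lists(st.sampled_from(list("ABC")), min_size=1, max_size=40)


def seq(*bouts):
    return NoteSequence(bouts=[list(b) for b in bouts])


class TestTransitionTable:
    def test_alternating_first_order(self):
        m = sr.transition_table(seq("ABAB"), order=1)
        assert m.prob(("A",), "B") == 1.0
        assert m.prob(("B",), "A") == 1.0

    def test_final_symbol_has_no_successor(self):
        m = sr.transition_table(seq("AABB"), order=1)
        assert m.prob(("A",), "A") == pytest.approx(0.5)
        assert m.prob(("A",), "B") == pytest.approx(0.5)
        assert m.prob(("B",), "B") == 1.0

    def test_zeroth_order_unigram(self):
        m = sr.transition_table(seq("ABAB"), order=0)
        assert m.prob((), "A") == pytest.approx(0.5)
        assert m.prob((), "B") == pytest.approx(0.5)

    def test_no_transitions_across_bouts(self):
        m = sr.transition_table(seq("AA", "BB"), order=1)
        assert m.prob(("A",), "B") == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sr.transition_table(seq(""), order=1)

    @given(label_lists)
    def test_rows_sum_to_one(self, labels):
        if len(labels) < 2:
            return
        m = sr.transition_table(NoteSequence([labels]), order=1)
        for ctx, row in m.probs.items():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)


class TestConsistentTransitions:
    def test_alternating_sequence_detected(self):
        s = seq("AB" * 200)
        out = sr.consistent_transitions(s, seed=0)
        cons = set(map(tuple, out.loc[out["consistent"], ["first", "second"]].values))
        assert cons == {("A", "B"), ("B", "A")}

    def test_iid_sequence_mostly_empty(self):
        rng = np.random.default_rng(7)
        s = NoteSequence([[str(c) for c in rng.choice(list("ABC"), 600)]])
        out = sr.consistent_transitions(s, seed=1)
        # false positives at roughly the per-test level
        assert out["consistent"].sum() <= 2

    def test_occurrence_floor_excludes_rare_bigrams(self):
        # C->D has probability 1 but occurs twice in ~600 symbols (< 1%)
        labels = list("AB" * 300) + list("CDCD")
        out = sr.consistent_transitions(NoteSequence([labels]), seed=2)
        cd = out[(out["first"] == "C") & (out["second"] == "D")]
        assert not bool(cd["consistent"].iloc[0])

    def test_long_sequence_variant_agrees_on_strong_signal(self):
        s = seq("AB" * 200)
        out = sr.consistent_transitions(s, seed=3, method="long_sequence")
        cons = set(map(tuple, out.loc[out["consistent"], ["first", "second"]].values))
        assert {("A", "B"), ("B", "A")} <= cons


class TestSynthesize:
    def test_deterministic_chain(self):
        m = sr.transition_table(seq("ABABAB"), order=1)
        out = sr.synthesize_sequence(m, 50, seed=0).concatenated()
        assert "".join(out) in ("AB" * 25, "BA" * 25)
        assert all(a != b for a, b in zip(out, out[1:]))

    def test_single_symbol_model(self):
        m = sr.transition_table(seq("AAAA"), order=1)
        out = sr.synthesize_sequence(m, 17, seed=0).concatenated()
        assert out == ["A"] * 17

    def test_zero_order_frequency_recovery(self):
        labels = ["A"] * 75 + ["B"] * 25
        m = sr.transition_table(NoteSequence([labels]), order=0)
        out = sr.synthesize_sequence(m, 10_000, seed=1).concatenated()
        frac_a = out.count("A") / 10_000
        # binomial 99% interval around 0.75 at n=10^4
        assert abs(frac_a - 0.75) < 2.58 * np.sqrt(0.75 * 0.25 / 10_000)

    def test_second_order_structure_needs_second_order_model(self):
        table, _ = sr.generate_song(sr.preset("second_order", n_phrases=400, seed=3))
        source = sr.sequence_from_table(table)

        def trigram_dist(symbols):
            c = Counter(zip(symbols, symbols[1:], symbols[2:]))
            total = sum(c.values())
            return {k: v / total for k, v in c.items()}

        ref = trigram_dist(source.concatenated())
        n = len(source)
        tv = {}
        for order in (1, 2):
            m = sr.transition_table(source, order=order)
            synth = sr.synthesize_sequence(m, n, seed=4).concatenated()
            d = trigram_dist(synth)
            keys = set(ref) | set(d)
            tv[order] = 0.5 * sum(abs(ref.get(k, 0) - d.get(k, 0)) for k in keys)
        assert tv[2] < 0.05
        assert tv[1] > 2 * tv[2]

    def test_length_must_exceed_order(self):
        m = sr.transition_table(seq("ABAB"), order=1)
        with pytest.raises(ValueError):
            sr.synthesize_sequence(m, 1, seed=0)


class TestContextExpand:
    @pytest.mark.parametrize(
        "h, expected",
        [
            (0, ["A", "B", "A", "C"]),
            (1, [("A", "B"), ("B", "A"), ("A", "C")]),
            (2, [("A", "B", "A"), ("B", "A", "C")]),
        ],
    )
    def test_printed_examples(self, h, expected):
        assert sr.context_expand(seq("ABAC"), h) == expected

    def test_matches_enumeration_oracle(self):
        # every sequence of length <= 6 over {A,B}, h <= 3
        for L in range(1, 7):
            for labels in itertools.product("AB", repeat=L):
                s = NoteSequence([list(labels)])
                for h in range(4):
                    expected = [
                        tuple(labels[p - h : p + 1]) for p in range(h, L)
                    ]
                    if h == 0:
                        expected = list(labels)
                    assert sr.context_expand(s, h) == expected

    @given(st.lists(label_lists, min_size=1, max_size=4), st.integers(0, 5))
    def test_output_length(self, bouts, h):
        s = NoteSequence(bouts)
        expected = sum(max(len(b) - h, 0) for b in bouts)
        assert len(sr.context_expand(s, h)) == expected

    def test_short_bout_contributes_nothing(self):
        assert sr.context_expand(seq("AB", "ABCD"), 2) == [
            ("A", "B", "C"),
            ("B", "C", "D"),
        ]


class TestNormalizedEntropy:
    @pytest.mark.parametrize(
        "symbols, expected",
        [
            (list("ABABABAB"), 1.0),
            (list("AAAA"), 0.0),
            (list("AABC"), 1.5 / np.log2(3)),
        ],
    )
    def test_printed_values(self, symbols, expected):
        assert sr.normalized_entropy(symbols) == pytest.approx(expected)

    def test_base_cancellation(self):
        # direct base-2 and base-e computations agree with the package
        rng = np.random.default_rng(0)
        symbols = list(rng.choice(list("ABCDE"), 500))
        counts = np.array(list(Counter(symbols).values()), float)
        p = counts / counts.sum()
        via_e = -(p * np.log(p)).sum() / np.log(p.size)
        via_2 = -(p * np.log2(p)).sum() / np.log2(p.size)
        eta = sr.normalized_entropy(symbols)
        assert eta == pytest.approx(via_e, abs=1e-12)
        assert eta == pytest.approx(via_2, abs=1e-12)

    @given(label_lists)
    def test_permutation_and_renaming_invariance(self, labels):
        base = sr.normalized_entropy(labels)
        rng = np.random.default_rng(0)
        assert sr.normalized_entropy(
            list(rng.permutation(labels))
        ) == pytest.approx(base)
        renamed = [l + "_x" for l in labels]
        assert sr.normalized_entropy(renamed) == pytest.approx(base)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sr.normalized_entropy([])


@pytest.fixture(scope="module")
def curves():
    table, _ = sr.generate_song(sr.preset("coupled", n_phrases=300, seed=11))
    s = sr.sequence_from_table(table)
    return sr.entropy_curves(s, h_max=8, n_reps=50, seed=5)


class TestEntropyCurves:
    def test_tidy_layout_and_bounds(self, curves):
        assert set(curves["source"]) == {
            "observed",
            "random",
            "zeroth_order",
            "first_order",
            "second_order",
        }
        assert ((curves["eta"] >= 0) & (curves["eta"] <= 1)).all()
        obs = curves[curves["source"] == "observed"]
        assert obs["ci_lo"].isna().all() and obs["ci_hi"].isna().all()

    def test_first_order_band_contains_observed(self, curves):
        # the song's syntax is first order, so the fitted first-order
        # model should reproduce the observed entropy at every context
        fo = curves[curves["source"] == "first_order"].set_index("h")
        ob = curves[curves["source"] == "observed"].set_index("h")
        inside = (ob["eta"] >= fo["ci_lo"]) & (ob["eta"] <= fo["ci_hi"])
        assert inside.all()

    def test_second_order_source_beats_first_order_model(self):
        table, _ = sr.generate_song(sr.preset("second_order", n_phrases=400, seed=3))
        s = sr.sequence_from_table(table)
        curves = sr.entropy_curves(s, h_max=8, n_reps=50, seed=6)
        fo = curves[curves["source"] == "first_order"].set_index("h")
        ob = curves[curves["source"] == "observed"].set_index("h")
        below = ob["eta"] < fo["ci_lo"]
        assert below.loc[2:].all()

    def test_infeasible_h_max_names_limit(self):
        with pytest.raises(ValueError, match="maximal feasible h"):
            sr.entropy_curves(seq("ABCAB"), h_max=20)


def test_uniform_model_is_uniform():
    m = uniform_model(["A", "B", "C"])
    assert m.prob((), "A") == pytest.approx(1 / 3)
    out = sr.synthesize_sequence(m, 3000, seed=0).concatenated()
    counts = Counter(out)
    for lab in "ABC":
        assert counts[lab] / 3000 == pytest.approx(1 / 3, abs=0.03)
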