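"""Segment extraction, Q, SOV, confusion and boundary evaluation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psspkit.alphabet import SS3, SS8, map_ss8_to_ss3
from psspkit.metrics import (Segment, boundary_accuracy, boundary_mask,
                             confusion_matrix, evaluate, extract_segments,
                             q_accuracy, sov)

from sov_oracle import sov_bruteforce


def label_pairs(alphabet, max_len):
    """Hypothesis strategy: equal-length (pred, obs) over an alphabet."""
    return st.integers(1, max_len).flatmap(
        lambda n: st.tuples(
            st.text(alphabet=alphabet, min_size=n, max_size=n),
            st.text(alphabet=alphabet, min_size=n, max_size=n)))


class TestSegments:
    @pytest.mark.parametrize("labels,expected", [
        ("HHHEE", [("H", 0, 3), ("E", 3, 5)]),
        ("H", [("H", 0, 1)]),
        ("HEHE", [("H", 0, 1), ("E", 1, 2), ("H", 2, 3), ("E", 3, 4)]),
    ])
    def test_runs(self, labels, expected):
        assert [(s.category, s.start, s.end)
                for s in extract_segments(labels)] == expected

    def test_segments_tile_input(self):
        labels = "HHGGEELLTTSSBBII"
        segs = extract_segments(labels)
        assert segs[0].start == 0 and segs[-1].end == len(labels)
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start and a.category != b.category

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_segments("")


class TestQ:
    def test_examples(self):
        assert q_accuracy("HHEE", "HHEE") == 100.0
        assert q_accuracy("HHEC", "HHEE") == 75.0
        assert q_accuracy("EEEE", "HHHH") == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            q_accuracy("HH", "H")

    @given(label_pairs(SS8, 30))
    @settings(max_examples=100, derandomize=True)
    def test_three_state_at_least_eight_state(self, pair):
        pred, obs = pair
        q8 = q_accuracy(pred, obs)
        q3 = q_accuracy(map_ss8_to_ss3(pred), map_ss8_to_ss3(obs))
        assert q3 >= q8 - 1e-9


class TestSOV:
    def test_identity_and_disjoint(self):
        assert sov("HHHH", "HHHH") == 100.0
        assert sov("EEEE", "HHHH") == 0.0

    def test_matches_bruteforce_on_hand_case(self):
        pred, obs = "HHHEEEEE", "HHHHEEEE"
        assert sov(pred, obs) == pytest.approx(
            sov_bruteforce(pred, obs, SS8))

    @given(label_pairs("HE", 8))
    @settings(max_examples=200, derandomize=True)
    def test_matches_bruteforce_two_letters(self, pair):
        pred, obs = pair
        assert sov(pred, obs, "HE") == pytest.approx(
            sov_bruteforce(pred, obs, "HE"))

    @given(label_pairs(SS8, 40))
    @settings(max_examples=150, derandomize=True)
    def test_matches_bruteforce_eight_letters(self, pair):
        pred, obs = pair
        assert sov(pred, obs) == pytest.approx(sov_bruteforce(pred, obs, SS8))

    @given(st.text(alphabet=SS8, min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_perfect_prediction_scores_100(self, labels):
        assert sov(labels, labels) == pytest.approx(100.0)
        assert q_accuracy(labels, labels) == 100.0

    @given(label_pairs("HEC", 20))
    @settings(max_examples=100, derandomize=True)
    def test_category_relabeling_invariance(self, pair):
        pred, obs = pair
        perm = {"H": "E", "E": "C", "C": "H"}
        pred2 = "".join(perm[c] for c in pred)
        obs2 = "".join(perm[c] for c in obs)
        assert sov(pred, obs, "HEC") == pytest.approx(sov(pred2, obs2, "HEC"))
        assert q_accuracy(pred, obs) == pytest.approx(q_accuracy(pred2, obs2))

    def test_bounded_in_0_100(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            pred = "".join(rng.choice(list(SS8), n))
            obs = "".join(rng.choice(list(SS8), n))
            assert 0.0 <= sov(pred, obs) <= 100.0 + 1e-9


class TestConfusion:
    def test_perfect_is_diagonal(self):
        cm = confusion_matrix("HHEE", "HHEE", normalized=True)
        assert cm.loc["H", "H"] == 1.0 and cm.loc["E", "E"] == 1.0
        assert cm.values.sum() == pytest.approx(2.0)  # two populated rows

    def test_swap_off_diagonal_and_total(self):
        cm = confusion_matrix("EH", "HE")
        assert cm.loc["H", "E"] == 1 and cm.loc["E", "H"] == 1
        assert cm.values.sum() == 2

    def test_normalized_rows_sum_to_one_or_zero(self):
        cm = confusion_matrix("HHHT", "HHTT", normalized=True)
        sums = cm.values.sum(axis=1)
        assert all(s == pytest.approx(1.0) or s == 0.0 for s in sums)


class TestBoundary:
    def test_uniform_sequence_marks_only_ends(self):
        bm = boundary_mask("HHHHH")
        assert bm.mask.sum() == 2
        assert bm.types[0] == 1 and bm.types[-1] == 1

    def test_single_residue(self):
        assert boundary_mask("H").mask.sum() == 1

    def test_alternating_all_marked(self):
        bm = boundary_mask("HEH")
        assert bm.mask.all()
        assert bm.types[1] == 3  # flanks agree, centre differs

    def test_type2_interior(self):
        # position 2 of HHEEE: flanks H and E differ
        assert boundary_mask("HHEEE").types[2] == 2

    def test_length_two_both_type1(self):
        bm = boundary_mask("HE")
        assert list(bm.types) == [1, 1]

    @given(st.text(alphabet=SS8, min_size=2, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_exactly_two_type1_marks(self, labels):
        assert (boundary_mask(labels).types == 1).sum() == 2

    def test_boundary_accuracy_restriction(self):
        obs = "HHHHHHHHHH"
        # only ends are boundary; correct there, wrong in the middle
        pred = "HEEEEEEEEH"
        assert boundary_accuracy(pred, obs) == 100.0
        assert q_accuracy(pred, obs) == 20.0

    def test_boundary_accuracy_hand_case(self):
        obs = "HHHEEETTSS"
        bm = boundary_mask(obs)
        pred = "HHHEEETTSC"
        expected = 100.0 * sum(
            pred[i] == obs[i] for i in np.flatnonzero(bm.mask)) / bm.mask.sum()
        assert boundary_accuracy(pred, obs) == pytest.approx(expected)


class TestEvaluate:
    def test_pooled_matches_direct_counts(self):
        pairs = [("HHEE", "HHET"), ("TTT", "TTS")]
        rep = evaluate(pairs)
        total = sum(len(o) for _, o in pairs)
        correct = sum(p == o for pr, ob in pairs for p, o in zip(pr, ob))
        assert rep["n_residues"] == total
        assert rep["q"] == pytest.approx(100.0 * correct / total)
        assert "ss3" in rep and rep["ss3"]["q"] >= rep["q"]

    def test_identity_gives_all_100(self):
        rep = evaluate([("HHHEETTS", "HHHEETTS")])
        assert rep["q"] == 100.0
        assert rep["sov"] == pytest.approx(100.0)
        assert rep["boundary_accuracy"] == 100.0
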