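import numpy as np
import pytest

from msatmap import (MiniMap, align_cost, align_pair, all_pairwise,
                     default_cost_model, explain_run, render_alignment)
from msatmap.cost_model import CostModel

from brute import BruteForce
from conftest import random_cost_model


def _mk(units, mid="m"):
    return MiniMap(mid, tuple(units))


class TestExplainRun:
    def test_empty_run_free(self, uniform3):
        cost, _ = explain_run("", "a", "b", "A", "both", uniform3)
        assert cost == 0.0

    def test_two_copies_from_left_seed(self):
        cm = default_cost_model(("x", "y"))
        cost, (u, v) = explain_run("xx", "x", "y", "B", "both", cm)
        assert cost == pytest.approx(1.0)  # two duplications beat 3.0 indel

    def test_three_way_tie_single_unit(self):
        cm = default_cost_model(("x", "y", "z"))
        cost, _ = explain_run("z", "x", "y", "B", "both", cm)
        assert cost == pytest.approx(1.5)

    def test_no_flank_means_indels(self, uniform3):
        cost, _ = explain_run("ab", None, None, "A", "both", uniform3)
        assert cost == pytest.approx(2 * uniform3.c_del)

    def test_mode_restriction_forces_segment_empty(self):
        cm = default_cost_model(("x", "y"))
        # left flank x could generate "xx" for 1.0, but right_to_left mode
        # must fall back to the right flank y (dup + mutations) or indels
        cost_rl, _ = explain_run("xx", "x", "y", "B", "right_to_left", cm)
        # best remaining: duplicate y, mutate the copy to x, duplicate it
        assert cost_rl == pytest.approx(2.0)
        assert cost_rl > 1.0  # strictly worse than the forbidden left option


class TestAlignPair:
    def test_identity_zero(self, uniform3):
        m = _mk("abcab")
        aln = align_pair(m, m, uniform3)
        assert aln.total_cost == 0.0
        assert len(aln.matches) == 5 and not any(r.length for r in aln.runs)

    def test_single_duplication(self, uniform3):
        aln = align_pair(_mk("ab", "A"), _mk("abb", "B"), uniform3)
        assert aln.total_cost == pytest.approx(0.5)
        run = [r for r in aln.runs if r.length][0]
        assert run.run_in == "B" and run.interval == (2, 3)

    def test_leading_run_modes(self, uniform3):
        A, B = _mk("ab", "A"), _mk("ccab", "B")
        assert align_cost(A, B, uniform3, "both") == pytest.approx(2.0)
        assert align_cost(A, B, uniform3, "left_to_right") == pytest.approx(3.0)
        assert align_cost(A, B, uniform3, "right_to_left") == pytest.approx(2.0)

    def test_empty_map_rejected(self, uniform3):
        with pytest.raises(ValueError):
            MiniMap("e", ())

    def test_alphabet_mismatch_rejected(self, uniform3):
        with pytest.raises(KeyError):
            align_pair(_mk("az", "A"), _mk("a", "B"), uniform3)

    def test_cost_symmetry_when_indels_equal(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            cm = random_cost_model(rng, k=3)
            cm = CostModel(cm.alphabet, cm.d_M, cm.c_dup, 1.2, 1.2)
            a = _mk(rng.choice(cm.alphabet, rng.integers(1, 7)), "a")
            b = _mk(rng.choice(cm.alphabet, rng.integers(1, 7)), "b")
            assert align_cost(a, b, cm) == pytest.approx(
                align_cost(b, a, cm), abs=1e-9)

    def test_mode_dominance(self):
        """Direction-restricted optima can never beat the unrestricted one
        (the foundation of the E_l / E_r counts)."""
        rng = np.random.default_rng(37)
        for _ in range(60):
            cm = random_cost_model(rng, k=3)
            a = _mk(rng.choice(cm.alphabet, rng.integers(1, 8)), "a")
            b = _mk(rng.choice(cm.alphabet, rng.integers(1, 8)), "b")
            c_both = align_cost(a, b, cm, "both")
            assert align_cost(a, b, cm, "left_to_right") >= c_both - 1e-9
            assert align_cost(a, b, cm, "right_to_left") >= c_both - 1e-9

    def test_upper_bound_total_indel(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            cm = random_cost_model(rng, k=2)
            a = _mk(rng.choice(cm.alphabet, rng.integers(1, 7)), "a")
            b = _mk(rng.choice(cm.alphabet, rng.integers(1, 7)), "b")
            bound = cm.c_del * len(a) + cm.c_ins * len(b)
            assert align_cost(a, b, cm) <= bound + 1e-9

    def test_reprice_and_coverage(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            cm = random_cost_model(rng, k=3)
            a = _mk(rng.choice(cm.alphabet, rng.integers(1, 8)), "a")
            b = _mk(rng.choice(cm.alphabet, rng.integers(1, 8)), "b")
            for mode in ("both", "left_to_right", "right_to_left"):
                aln = align_pair(a, b, cm, mode)
                assert aln.re_price() == pytest.approx(aln.total_cost, abs=1e-9)
                # every position covered exactly once
                cov_a = sorted([i for i, _, _ in aln.matches]
                               + [p for r in aln.runs if r.run_in == "A"
                                  for p in range(*r.interval)])
                cov_b = sorted([j for _, j, _ in aln.matches]
                               + [p for r in aln.runs if r.run_in == "B"
                                  for p in range(*r.interval)])
                assert cov_a == list(range(len(a)))
                assert cov_b == list(range(len(b)))
                ia = [i for i, _, _ in aln.matches]
                jb = [j for _, j, _ in aln.matches]
                assert ia == sorted(ia) and jb == sorted(jb)

    def test_matches_brute_force_on_random_sample(self):
        """Spot oracle-equivalence (the exhaustive sweep lives in the
        acceptance suite)."""
        rng = np.random.default_rng(47)
        for _ in range(8):
            cm = random_cost_model(rng, k=2)
            bf = BruteForce(cm)
            for _ in range(6):
                a = tuple(rng.choice(cm.alphabet, rng.integers(1, 5)))
                b = tuple(rng.choice(cm.alphabet, rng.integers(1, 5)))
                for mode in ("both", "left_to_right"):
                    got = align_cost(_mk(a, "a"), _mk(b, "b"), cm, mode)
                    assert got == pytest.approx(bf.align(a, b, mode), abs=1e-9), (
                        a, b, mode)


class TestAllPairwise:
    def test_three_maps_matrix(self, uniform3):
        maps = [_mk("ab", "m1"), _mk("ab", "m2"), _mk("abb", "m3")]
        labels, dm = all_pairwise(maps, uniform3)
        assert labels == ["m1", "m2", "m3"]
        assert dm[0, 1] == 0.0
        assert dm[0, 2] == pytest.approx(0.5) and dm[1, 2] == pytest.approx(0.5)
        assert np.allclose(dm, dm.T) and np.all(np.diag(dm) == 0)

    def test_normalize_divides_by_length_sum(self, uniform3):
        maps = [_mk("ab", "m1"), _mk("abb", "m2")]
        _, dm = all_pairwise(maps, uniform3, normalize=True)
        assert dm[0, 1] == pytest.approx(0.5 / 5)

    def test_duplicate_ids_rejected(self, uniform3):
        with pytest.raises(ValueError):
            all_pairwise([_mk("ab", "m"), _mk("ba", "m")], uniform3)


class TestRendering:
    def test_identity_render(self, uniform3):
        text = render_alignment(align_pair(_mk("ab", "A"), _mk("ab", "B"), uniform3))
        lines = text.splitlines()
        assert lines[1] == "A: a b" and lines[2] == "B: a b"
        assert not any(ln.startswith("arc") for ln in lines)

    def test_duplication_arc_record(self, uniform3):
        text = render_alignment(align_pair(_mk("ab", "A"), _mk("abb", "B"), uniform3))
        assert "arc: B:1 -> B:[2,3)" in text

    def test_indel_gap_symbol_and_reparse(self):
        cm = default_cost_model(("a", "b", "z"))
        # z has no cheap generation: with indel cost below dup+mut it is
        # explained as an insertion and rendered opposite a gap
        cm = CostModel(cm.alphabet, cm.d_M, 0.5, 1.2, 1.2)
        aln = align_pair(_mk("ab", "A"), _mk("azb", "B"), cm)
        text = render_alignment(aln)
        rows = [ln for ln in text.splitlines() if ln[:2] in ("A:", "B:")]
        got_a = [t for t in rows[0][2:].split() if t != "-"]
        got_b = [t for t in rows[1][2:].split() if t != "-"]
        assert got_a == ["a", "b"] and got_b == ["a", "z", "b"]
        assert "-" in rows[0]
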