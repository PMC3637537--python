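import dataclasses

import numpy as np
import pytest

from nsalign import benchmark_gen as bg
from nsalign.errors import NoSSEError
from nsalign.geometry import Superposition
from nsalign.residue_alignment import (
    AlignedSegment,
    Alignment,
    AlignParams,
    align_pair,
    best_segment,
    compute_d0,
    greedy_select,
    mtm_score,
    refine,
    similarity_matrix,
    stepwise_alignment,
)
from nsalign.sse_cess import assign_secondary_structure
from nsalign.structure_io import structure_from_coords

from conftest import random_rigid, transform_structure
from oracles import exhaustive_best_segment_score


def _matrix_from_values(values):
    values = np.asarray(values, dtype=float)
    from nsalign.residue_alignment import SimilarityMatrix

    return SimilarityMatrix(values, d_r=8.0, d0=3.0, superposition=Superposition.identity())


def _no_breaks(n, m):
    qb = np.zeros(n, dtype=bool)
    mb = np.zeros(m, dtype=bool)
    qb[0] = mb[0] = True
    return qb, mb


class TestD0:
    def test_reference_value(self):
        assert compute_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8, abs=1e-9)
        assert compute_d0(100) == pytest.approx(3.652, abs=1e-3)

    def test_clamped_for_short_chains(self):
        assert compute_d0(15) == 0.5
        assert compute_d0(1) == 0.5

    def test_monotone_nondecreasing(self):
        values = [compute_d0(n) for n in range(1, 300)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestSimilarityMatrix:
    @pytest.fixture
    def pair(self):
        # query residue 0 at origin, model residue 0 placed at chosen distances
        def build(distance, q_label, m_label, d_r=8.0):
            query = structure_from_coords([[0.0, 0.0, 0.0]])
            model = structure_from_coords([[distance, 0.0, 0.0]])
            params = AlignParams()
            mat = similarity_matrix(
                query, model, [q_label], [m_label],
                Superposition.identity(), d_r, params, d0=3.0,
            )
            return mat.values[0, 0]

        return build

    def test_zero_distance_same_label_is_one(self, pair):
        assert pair(0.0, "H", "H") == pytest.approx(1.0)

    def test_distance_d0_same_label_is_half(self, pair):
        assert pair(3.0, "H", "H") == pytest.approx(0.5)

    def test_zero_distance_cross_label_is_half(self, pair):
        assert pair(0.0, "H", "E") == pytest.approx(0.5)

    def test_beyond_cutoff_is_zero(self, pair):
        assert pair(8.0 + 1e-6, "H", "H") == 0.0


class TestBestSegment:
    def test_full_diagonal(self):
        mat = _matrix_from_values(np.eye(5))
        qb, mb = _no_breaks(5, 5)
        seg = best_segment(mat, np.zeros(5, bool), np.zeros(5, bool), qb, mb)
        assert (seg.alpha, seg.beta, seg.length) == (0, 0, 5)
        assert seg.score == pytest.approx(5.0)

    def test_argmax_between_disjoint_runs(self):
        values = np.zeros((8, 8))
        for k in range(4):  # run A: score 2.8
            values[k, k] = 0.7
        for k in range(4):  # run B: score 2.6
            values[4 + k, k] = 0.65
        mat = _matrix_from_values(values)
        qb, mb = _no_breaks(8, 8)
        seg = best_segment(mat, np.zeros(8, bool), np.zeros(8, bool), qb, mb)
        assert (seg.alpha, seg.beta) == (0, 0)
        assert seg.score == pytest.approx(2.8)

    def test_chain_break_terminates_run(self):
        values = np.eye(6)
        mat = _matrix_from_values(values)
        qb = np.zeros(6, bool)
        qb[[0, 3]] = True
        mb = np.zeros(6, bool)
        mb[0] = True
        seg = best_segment(mat, np.zeros(6, bool), np.zeros(6, bool), qb, mb)
        assert seg.length == 3

    @pytest.mark.parametrize("mode", ["forward", "mixed"])
    def test_matches_exhaustive_enumeration(self, mode):
        rng = np.random.default_rng(123)
        for _ in range(60):
            n, m = rng.integers(2, 13, size=2)
            values = np.where(rng.random((n, m)) < 0.5, rng.random((n, m)), 0.0)
            qb = rng.random(n) < 0.15
            mb = rng.random(m) < 0.15
            qb[0] = mb[0] = True
            mat = _matrix_from_values(values)
            seg = best_segment(mat, np.zeros(n, bool), np.zeros(m, bool), qb, mb, mode)
            expect = exhaustive_best_segment_score(values, qb, mb, mode)
            got = seg.score if seg is not None else 0.0
            assert got == pytest.approx(expect, abs=1e-12)


class TestGreedySelect:
    def test_all_zero_matrix_returns_carried(self):
        mat = _matrix_from_values(np.zeros((4, 4)))
        qb, mb = _no_breaks(4, 4)
        carried = [AlignedSegment(0, 0, 2, "forward", 2.0)]
        assert greedy_select(mat, 2.2, carried, "forward", qb, mb) == carried

    def test_two_cell_run_rejected_by_smin(self):
        values = np.zeros((5, 5))
        values[1, 1] = values[2, 2] = 1.0
        mat = _matrix_from_values(values)
        qb, mb = _no_breaks(5, 5)
        assert greedy_select(mat, 2.2, [], "forward", qb, mb) == []

    def test_accepted_segments_never_overlap(self):
        rng = np.random.default_rng(7)
        values = rng.random((12, 12)) * (rng.random((12, 12)) < 0.6)
        mat = _matrix_from_values(values)
        qb, mb = _no_breaks(12, 12)
        segs = greedy_select(mat, 2.2, [], "mixed", qb, mb)
        rows = [q for s in segs for q, _ in s.pairs()]
        cols = [m for s in segs for _, m in s.pairs()]
        assert len(rows) == len(set(rows))
        assert len(cols) == len(set(cols))


class TestStepwise:
    def test_self_alignment_full_coverage(self, toy_fold):
        labels = assign_secondary_structure(toy_fold)
        aln = stepwise_alignment(
            toy_fold, toy_fold, labels, labels, Superposition.identity(), AlignParams()
        )
        assert aln.n_pairs == len(toy_fold)
        assert aln.total_segment_score == pytest.approx(len(toy_fold))
        assert aln.mtm == pytest.approx(1.0)

    def test_displaced_sse_captured_at_wider_cutoff(self):
        # helix pair offset by 4 A: misses d1 = 3.2 A but within d2 = 4.8 A;
        # long enough that the d0 scale keeps the run score above s_min
        coords_a = bg._helix_coords(
            bg.ToyElement("H", 40, np.zeros(3), np.array([0.0, 0, 1.0]))
        )
        query = structure_from_coords(coords_a)
        model = structure_from_coords(coords_a + np.array([4.0, 0.0, 0.0]))
        labels = assign_secondary_structure(query)
        params = AlignParams()
        d1_only = dataclasses.replace(params, d_steps=(1.0,))
        aln_d1 = stepwise_alignment(
            query, model, labels, labels, Superposition.identity(), d1_only
        )
        aln_full = stepwise_alignment(
            query, model, labels, labels, Superposition.identity(), params
        )
        assert aln_d1.n_pairs == 0
        assert aln_full.n_pairs == len(query)


class TestMTM:
    def test_empty_alignment_scores_zero(self, toy_fold):
        labels = assign_secondary_structure(toy_fold)
        aln = Alignment([], Superposition.identity())
        assert mtm_score(aln, toy_fold, toy_fold, labels, labels, AlignParams()) == 0.0

    def test_hand_built_three_pair_alignment(self):
        # pairs engineered to M values {1.0, 0.5, 0.5}; query length 10 -> 0.2
        d0 = compute_d0(10)  # clamped region: d0 = 0.5
        coords_q = np.outer(np.arange(10), [3.8, 0, 0])
        coords_m = coords_q.copy()
        coords_m[1] += [0.0, d0, 0.0]  # distance d0, same label -> 0.5
        query = structure_from_coords(coords_q)
        model = structure_from_coords(coords_m)
        labels_q = ["H"] * 10
        labels_m = ["H"] * 10
        labels_m[2] = "E"  # distance 0, cross label -> 0.5
        seg = AlignedSegment(0, 0, 3, "forward")
        aln = Alignment([seg], Superposition.identity())
        score = mtm_score(aln, query, model, labels_q, labels_m, AlignParams())
        assert score == pytest.approx((1.0 + 0.5 + 0.5) / 10, abs=1e-12)


class TestRefine:
    def test_converged_self_alignment_unchanged(self, toy_fold):
        labels = assign_secondary_structure(toy_fold)
        params = AlignParams()
        initial = stepwise_alignment(
            toy_fold, toy_fold, labels, labels, Superposition.identity(), params
        )
        refined = refine(toy_fold, toy_fold, labels, labels, initial, params)
        assert refined.segment_key() == initial.segment_key()
        assert refined.n_refine_iters == 1

    def test_never_worse_than_initial(self, toy_pair):
        fold, permuted, _ = toy_pair
        q_labels = assign_secondary_structure(fold)
        m_labels = assign_secondary_structure(permuted)
        rng = np.random.default_rng(17)
        from scipy.spatial.transform import Rotation

        # perturb the exact-identity seed by ~5 degrees / 1 A
        perturb = Superposition(
            Rotation.from_rotvec(np.deg2rad(5) * np.array([0, 1, 0])).as_matrix(),
            np.array([1.0, 0.0, 0.0]),
        )
        initial = stepwise_alignment(fold, permuted, q_labels, m_labels, perturb, AlignParams())
        refined = refine(fold, permuted, q_labels, m_labels, initial, AlignParams())
        assert refined.mtm >= initial.mtm
        assert refined.n_refine_iters <= AlignParams().max_refine_iters


class TestAlignPair:
    def test_self_alignment_identity(self, toy_fold):
        ranked = align_pair(toy_fold, toy_fold)
        best = ranked[0]
        assert best.pairs() == [(i, i) for i in range(len(toy_fold))]
        assert best.mtm >= 0.99
        assert best.stats.rmsd < 1e-6

    def test_invariant_under_rigid_transform_of_model(self, toy_pair):
        fold, permuted, _ = toy_pair
        base = align_pair(fold, permuted)[0]
        moved = transform_structure(permuted, random_rigid(np.random.default_rng(23)))
        again = align_pair(fold, moved)[0]
        assert base.segment_key() == again.segment_key()

    def test_all_helix_vs_all_strand_is_empty(self):
        helix = structure_from_coords(
            bg._helix_coords(bg.ToyElement("H", 14, np.zeros(3), np.array([0.0, 0, 1.0])))
        )
        strand = bg.make_toy_structure(
            bg.ToyFoldSpec(
                [
                    bg.ToyElement("E", 10, np.zeros(3), np.array([0.0, 0, 1.0])),
                    bg.ToyElement("E", 10, np.array([5.2, 0, 29.7]), np.array([0.0, 0, -1.0])),
                ],
                loop_length=4,
                seed=5,
            )
        )
        assert align_pair(helix, strand) == []

    def test_too_few_sses_raises(self):
        tiny = structure_from_coords(np.outer(np.arange(5), [3.8, 0, 0]))
        with pytest.raises(NoSSEError):
            align_pair(tiny, tiny)

    def test_forward_mode_emits_no_reverse_segments(self, toy_pair):
        fold, permuted, _ = toy_pair
        for aln in align_pair(fold, permuted):
            assert all(seg.direction == "forward" for seg in aln.segments)
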