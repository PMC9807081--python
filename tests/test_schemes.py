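"""Discrete minimizer selection, density factor, baselines, and oracles."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import minilearn as ml
from minilearn.schemes import write_sketch_bed
from minilearn.seqio import DNA, Alphabet


def _params(l, w, k=1):
    return ml.SketchParams(k=k, w=w, l=l)


class TestSelection:
    def test_worked_example(self):
        scores = ml.ScoreAssignment(np.array([0.5, 0.2, 0.9, 0.1, 0.7]))
        sketch, trace = ml.select_positions(scores, _params(5, 3))
        assert list(trace.picks) == [1, 3, 3]
        assert list(sketch.positions) == [1, 3]
        assert ml.density_factor(sketch).density_factor == pytest.approx(2 * 4 / 3)

    def test_all_equal_scores_pick_leftmost_every_window(self):
        l, w = 30, 5
        sketch, trace = ml.select_positions(ml.ScoreAssignment(np.full(l, 0.5)), _params(l, w))
        assert list(trace.picks) == list(range(l - w + 1))
        assert sketch.size == l - w + 1
        assert ml.density_factor(sketch).density_factor == w + 1

    def test_strict_minimum_every_w_reaches_floor(self):
        w, reps = 7, 400
        scores = np.full(w * reps, 0.9)
        scores[::w] = 0.1
        sketch, _ = ml.select_positions(ml.ScoreAssignment(scores), _params(len(scores), w))
        d = ml.density_factor(sketch).density_factor
        assert d == pytest.approx(1 + 1 / w, abs=0.01)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            ml.select_positions(ml.ScoreAssignment(np.array([0.1, 0.2])), _params(5, 3))

    def test_window_coverage_and_forwardness_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            l = int(rng.integers(10, 300))
            w = int(rng.integers(2, min(l, 15) + 1))
            scores = ml.ScoreAssignment(rng.random(l))
            sketch, trace = ml.select_positions(scores, _params(l, w))
            sketch.validate()
            assert np.all(np.diff(trace.picks) >= 0)
            assert trace.changes.sum() == sketch.size

    @settings(derandomize=True, max_examples=200)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.integers(min_value=2, max_value=15),
        st.booleans(),
    )
    def test_oracle_equivalence_property(self, seed, w, tie_heavy):
        """Optimized selection is bit-identical to the naive per-window scan,
        including tie-heavy score vectors."""
        rng = np.random.default_rng(seed)
        l = int(rng.integers(w, 200))
        if tie_heavy:
            scores = rng.integers(0, 4, size=l) / 4.0
        else:
            scores = rng.random(l)
        sa, p = ml.ScoreAssignment(scores), _params(l, w)
        sk1, tr1 = ml.select_positions(sa, p)
        sk2, tr2 = ml.select_positions_oracle(sa, p)
        assert np.array_equal(sk1.positions, sk2.positions)
        assert np.array_equal(tr1.picks, tr2.picks)
        assert np.array_equal(tr1.changes, tr2.changes)

    def test_oracle_agrees_on_monotone_scores(self):
        l, w = 40, 6
        scores = ml.ScoreAssignment(np.linspace(0, 1, l))
        sk1, tr1 = ml.select_positions(scores, _params(l, w))
        sk2, tr2 = ml.select_positions_oracle(scores, _params(l, w))
        assert list(tr1.picks) == list(range(l - w + 1)) == list(tr2.picks)
        assert ml.density_factor(sk1).density_factor == w + 1

    def test_max_pool_mirror_produces_identical_sketch(self):
        """MIN-selection on s equals leftmost-argmax selection on 1 - s."""
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 5, size=200) / 5.0
        p = _params(200, 9)
        sk_min, _ = ml.select_positions(ml.ScoreAssignment(scores), p)
        flipped = 1.0 - scores
        picks = [t + int(np.argmax(flipped[t : t + 9])) for t in range(p.lw)]
        assert np.array_equal(sk_min.positions, np.unique(picks))


class TestDensityReport:
    def test_maximal_and_floor_density(self):
        p = _params(11, 4)
        full = ml.Sketch(positions=np.arange(p.lw), params=p)
        assert ml.density_factor(full).density_factor == 5.0
        two = ml.Sketch(positions=np.array([0, 4]), params=p)
        assert ml.density_factor(two).density_factor == pytest.approx(2 * 5 / 8)

    def test_json_round_trip(self, tmp_path):
        rep = ml.DensityReport(k=8, w=13, l=100, lw=88, sketch_size=20,
                               density_factor=20 * 14 / 88, unique_kmers=17)
        path = tmp_path / "d.json"
        rep.to_json(path)
        assert ml.DensityReport.from_json(path) == rep

    def test_kmer_stats(self, planted_seq, planted_params):
        codes = ml.kmer_codes(planted_seq, 8)
        scores = np.where(codes == codes[0], 0.0, 1.0)
        sketch, _ = ml.select_positions(ml.ScoreAssignment(scores), planted_params)
        rep = ml.sketch_kmer_stats(planted_seq, sketch)
        # only the sentinel is picked in the bulk; boundary windows may add a few
        assert rep.unique_kmers <= 3
        assert rep.unique_kmers <= rep.sketch_size

    def test_single_position_sketch(self, random_seq):
        p = ml.SketchParams(k=5, w=8, l=8)
        sk = ml.Sketch(positions=np.array([3]), params=p)
        rep = ml.sketch_kmer_stats(random_seq.slice(0, 12), sk)
        assert rep.unique_kmers == 1


class TestBaselines:
    def test_random_scores_consistent_per_kmer(self, repeat_seq):
        scores = ml.random_ordering_scores(repeat_seq, 8, seed=0).scores
        codes = ml.kmer_codes(repeat_seq, 8)
        for c in np.unique(codes)[:20]:
            grp = scores[codes == c]
            assert np.all(grp == grp[0])

    def test_random_scores_seed_sensitivity(self, random_seq):
        s0 = ml.random_ordering_scores(random_seq, 10, seed=0).scores
        s1 = ml.random_ordering_scores(random_seq, 10, seed=1).scores
        assert not np.array_equal(s0, s1)

    def test_random_ordering_density_near_two(self, random_seq):
        p = ml.SketchParams.for_sequence(random_seq, k=14, w=13)
        scores = ml.random_ordering_scores(random_seq, 14, seed=0)
        sketch, _ = ml.select_positions(scores, p)
        assert 1.9 < ml.density_factor(sketch).density_factor < 2.1

    def test_frequency_scores_degenerate_cases(self):
        distinct = ml.EncodedSequence(DNA.encode("ACGTAG"))
        s = ml.frequency_ordering_scores(distinct, 3).scores
        assert np.all(s == s[0])
        homo = ml.EncodedSequence(DNA.encode("AAAAAA"))
        s = ml.frequency_ordering_scores(homo, 2).scores
        assert np.all(s == s[0])

    def test_frequency_scores_rank_sentinel_highest(self, planted_seq):
        scores = ml.frequency_ordering_scores(planted_seq, 8).scores
        codes = ml.kmer_codes(planted_seq, 8)
        sentinel = scores[codes == codes[0]]
        background = scores[codes != codes[0]]
        assert sentinel.min() > background.max()


class TestExhaustive:
    def test_binary_alphabet_matches_manual_enumeration(self):
        ab = Alphabet(symbols=("A", "B"))
        seq = ml.EncodedSequence(ab.encode("ABABABAB"), alphabet=ab)
        best_d, order = ml.exhaustive_optimal_density(seq, k=1, w=2)
        # both orderings evaluated via the naive oracle
        p = ml.SketchParams.for_sequence(seq, k=1, w=2)
        ds = []
        for ranks in ([0.0, 1.0], [1.0, 0.0]):
            scores = ml.ScoreAssignment(np.array(ranks)[seq.codes])
            sk, _ = ml.select_positions_oracle(scores, p)
            ds.append(ml.density_factor(sk).density_factor)
        assert best_d == pytest.approx(min(ds))

    def test_optimum_dominates_random_orderings(self):
        ab = Alphabet(symbols=("A", "B"))
        rng = np.random.default_rng(0)
        seq = ml.EncodedSequence(rng.integers(0, 2, size=60), alphabet=ab)
        best_d, _ = ml.exhaustive_optimal_density(seq, k=3, w=4)
        p = ml.SketchParams.for_sequence(seq, k=3, w=4)
        for seed in range(5):
            scores = ml.random_ordering_scores(seq, 3, seed=seed)
            sk, _ = ml.select_positions(scores, p)
            assert best_d <= ml.density_factor(sk).density_factor + 1e-12
        assert best_d >= (1 + 1 / 4) - (4 + 1) / p.lw  # floor minus one boundary pick

    def test_capacity_guard(self, random_seq):
        with pytest.raises(ValueError, match="exhaustive"):
            ml.exhaustive_optimal_density(random_seq.slice(0, 100), k=2, w=3)


class TestExports:
    def test_constant_scores_export_lexicographic(self, tmp_path):
        rows = ml.export_total_order(lambda m: 0.5, k=2, out=tmp_path / "o.tsv")
        assert [r[0] for r in rows[:5]] == ["AA", "AC", "AG", "AT", "CA"]
        assert [r[2] for r in rows] == list(range(16))
        lines = (tmp_path / "o.tsv").read_text().splitlines()
        assert lines[0] == "kmer\tscore\trank"
        assert len(lines) == 17

    def test_reverse_score_reverses_order(self):
        order = {m: i for i, (m, _, _) in enumerate(ml.export_total_order(lambda m: 0.0, k=2))}
        rows = ml.export_total_order(lambda m: 1.0 - order[m] / 16, k=2)
        assert [r[0] for r in rows] == ["TT", "TG", "TC", "TA", "GT", "GG", "GC", "GA",
                                        "CT", "CG", "CC", "CA", "AT", "AG", "AC", "AA"]

    def test_rank_selection_equals_score_selection(self):
        """Selection by exported ranks reproduces selection by raw scores when
        the score function is collision-free."""
        k = 3
        rows = ml.export_total_order(
            lambda m: ml.random_ordering_scores(
                ml.EncodedSequence(DNA.encode(m)), k, seed=9
            ).scores[0],
            k=k,
        )
        rank_of = {m: r for m, _, r in rows}
        for seed in range(20):
            seq = ml.make_random_sequence(150, seed=seed)
            p = ml.SketchParams.for_sequence(seq, k=k, w=6)
            by_score, _ = ml.select_positions(ml.random_ordering_scores(seq, k, seed=9), p)
            text = seq.decode()
            ranks = np.array(
                [rank_of[text[i : i + k]] for i in range(p.l)], dtype=np.float64
            ) / (4**k)
            by_rank, _ = ml.select_positions(ml.ScoreAssignment(ranks), p)
            assert np.array_equal(by_score.positions, by_rank.positions)

    def test_capacity_guard_for_export(self):
        with pytest.raises(ValueError, match="guard"):
            ml.export_total_order(lambda m: 0.0, k=13)

    def test_bed_export(self, tmp_path):
        p = _params(20, 4, k=5)
        sk = ml.Sketch(positions=np.array([0, 7, 15]), params=p)
        write_sketch_bed(sk, "chr_test", tmp_path / "s.bed")
        lines = (tmp_path / "s.bed").read_text().splitlines()
        assert lines == ["chr_test\t0\t5", "chr_test\t7\t12", "chr_test\t15\t20"]
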