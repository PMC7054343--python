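import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stagecna import (
    AberrationCallMatrix,
    BinaryAberrationMatrix,
    DetectionConfig,
    PlantedRegion,
    RecurrentAberrationModel,
    SimConfig,
    bh_qvalues,
    detect_recurrent_regions,
    expand_peak,
    find_shared_runs,
    frequency_track,
    h_profile,
    homogeneity_matrix,
    marker_counts,
    permutation_pvalues,
    simulate_stage_calls,
    split_matrix,
)

from conftest import make_probe_map
from oracles import bh_by_hand, brute_force_biclusters, exact_pvalues


def binary(vals, n_probes=None, probe_map=None, kind="gain"):
    vals = np.asarray(vals, dtype=np.int8)
    pm = probe_map or make_probe_map(vals.shape[1])
    return BinaryAberrationMatrix(vals, kind, [f"S{i + 1}" for i in range(vals.shape[0])], pm)


class TestMarkerCounts:
    def test_fig1_hand_count(self, fig1_matrix):
        al, _ = split_matrix(fig1_matrix)
        np.testing.assert_array_equal(marker_counts(al), [0, 0, 0, 2, 3, 3, 2])

    def test_zero_and_single_row(self):
        assert marker_counts(binary(np.zeros((3, 4)))).sum() == 0
        row = np.array([[1, 0, 1, 1]])
        np.testing.assert_array_equal(marker_counts(binary(row)), row[0])


class TestPermutationPvalues:
    def test_all_zero_matrix_gives_p_one(self):
        prof = permutation_pvalues(binary(np.zeros((3, 5))), DetectionConfig(seed=0))
        np.testing.assert_array_equal(prof.p_values, np.ones(5))

    def test_fully_aberrant_matrix_gives_p_one(self):
        prof = permutation_pvalues(binary(np.ones((4, 5))), DetectionConfig(seed=0))
        np.testing.assert_array_equal(prof.p_values, np.ones(5))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            permutation_pvalues(binary(np.ones((1, 4))), DetectionConfig())

    def test_agrees_with_exact_enumeration_on_toy_matrix(self):
        """Monte-Carlo p within 3 SE (+ add-one offset) of the exhaustive
        per-row arrangement enumeration on a 3x4 matrix."""
        vals = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 0]], dtype=np.int8)
        cfg = DetectionConfig(n_perm=10_000, seed=123)
        prof = permutation_pvalues(binary(vals), cfg)
        exact = exact_pvalues(vals)
        se = np.sqrt(exact * (1 - exact) / cfg.n_perm)
        tol = 3 * se + 1.0 / (cfg.n_perm + 1)
        assert np.all(np.abs(prof.p_values - exact) <= tol)

    def test_respects_chromosome_blocks(self):
        """A fully loaded chromosome cannot look significant: its calls can
        only be permuted within itself."""
        from conftest import concat_probe_maps
        pm = concat_probe_maps(make_probe_map(3, "chr1"), make_probe_map(2, "chr2"))
        vals = np.array([[1, 1, 1, 0, 0]] * 4, dtype=np.int8)
        prof = permutation_pvalues(binary(vals, probe_map=pm), DetectionConfig(seed=0))
        np.testing.assert_array_equal(prof.p_values[:3], np.ones(3))


class TestBHQvalues:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_qvalues([0.01]), [0.01])

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_empty_vector(self):
        assert bh_qvalues([]).size == 0

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_step_up_oracle_and_preserves_order(self, p):
        q = bh_qvalues(p)
        np.testing.assert_allclose(q, bh_by_hand(np.array(p)), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestHomogeneity:
    def test_fully_aberrant_run_is_maximally_homogeneous(self):
        np.testing.assert_array_equal(homogeneity_matrix(np.array([[1, 1, 1]])), [[0, 0]])

    def test_state_change_scores_half(self):
        np.testing.assert_array_equal(homogeneity_matrix(np.array([[1, 0, 1]])), [[0.5, 0.5]])

    def test_opposite_aberrations_score_one(self):
        np.testing.assert_array_equal(homogeneity_matrix(np.array([[1, -1]])), [[1.0]])

    def test_single_marker_rejected(self):
        with pytest.raises(ValueError, match="2 markers"):
            homogeneity_matrix(np.array([[1], [0]]))

    def test_h_profile_is_column_mean(self):
        H = np.array([[0.0], [0.5], [1.0]])
        np.testing.assert_allclose(h_profile(H), [0.5])
        np.testing.assert_allclose(h_profile(np.zeros((3, 4))), np.zeros(4))
        np.testing.assert_allclose(h_profile(np.array([[0.5, 1.0]])), [0.5, 1.0])

    @settings(deadline=None, max_examples=50)
    @given(arrays(np.int8, (5, 8), elements=st.sampled_from([0, 1])))
    def test_h_always_within_unit_interval(self, vals):
        h = h_profile(homogeneity_matrix(vals))
        assert np.all((h >= 0) & (h <= 1))


class TestExpandPeak:
    cfg = DetectionConfig(q_thr=0.10, h_thr=0.12)

    def test_isolated_peak_does_not_expand(self):
        q = np.array([1.0, 1.0, 0.01, 1.0, 1.0])
        h = np.zeros(4)
        assert expand_peak(q, h, 2, self.cfg, (0, 5)) == (2, 2)

    def test_expands_over_significant_homogeneous_span(self):
        q = np.ones(30)
        q[10:21] = 0.05
        h = np.full(29, 0.5)
        h[10:20] = 0.05  # junctions inside ranks 10..20
        h[9] = 0.05
        assert expand_peak(q, h, 15, self.cfg, (0, 30)) == (10, 20)

    def test_h_thr_zero_blocks_any_expansion(self):
        q = np.full(5, 0.01)
        h = np.full(4, 1e-6)
        cfg = DetectionConfig(h_thr=0.0)
        assert expand_peak(q, h, 2, cfg, (0, 5)) == (2, 2)

    def test_never_crosses_chromosome_bounds(self):
        q = np.full(10, 0.01)
        h = np.zeros(9)
        assert expand_peak(q, h, 4, self.cfg, (3, 7)) == (3, 6)

    def test_rejects_insignificant_peak(self):
        with pytest.raises(ValueError, match="not significant"):
            expand_peak(np.array([0.5, 0.5]), np.array([0.0]), 0, self.cfg, (0, 2))

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_every_rank_in_region_is_significant(self, data):
        m = 12
        q = np.array(data.draw(st.lists(
            st.floats(0, 1), min_size=m, max_size=m)))
        h = np.array(data.draw(st.lists(
            st.floats(0, 1), min_size=m - 1, max_size=m - 1)))
        sig = np.flatnonzero(q <= self.cfg.q_thr)
        if sig.size == 0:
            return
        peak = int(sig[0])
        l, r = expand_peak(q, h, peak, self.cfg, (0, m))
        assert np.all(q[l:r + 1] <= self.cfg.q_thr)


def planted_cfg(seed, frequency=0.6, background=0.01, stage="t1"):
    return SimConfig(
        stages=[stage], n_samples_per_stage=[50], n_probes=500,
        chromosomes=[("chr1", 500)],
        planted_regions=[PlantedRegion(stage, "chr1", 240, 259, "gain", frequency)],
        background_rate=background, seed=seed,
    )


class TestDetector:
    def test_all_zero_matrix_yields_no_regions(self):
        assert detect_recurrent_regions(binary(np.zeros((3, 6))),
                                        DetectionConfig(seed=0)) == []

    def test_recovers_single_planted_region(self):
        mats, _, _ = simulate_stage_calls(planted_cfg(seed=100))
        al, _ = split_matrix(mats["t1"])
        regions = detect_recurrent_regions(al, DetectionConfig(seed=1))
        assert len(regions) == 1
        reg = regions[0]
        assert abs(reg.l - 240) <= 2 and abs(reg.r - 259) <= 2
        assert reg.peak_q <= 0.10
        assert 0.4 <= reg.frequency <= 0.8

    def test_two_plants_on_different_chromosomes_and_block_order(self):
        def run(chroms, plants):
            cfg = SimConfig(stages=["t1"], n_samples_per_stage=[40], n_probes=200,
                            chromosomes=chroms, planted_regions=plants,
                            background_rate=0.01, seed=8)
            mats, _, _ = simulate_stage_calls(cfg)
            al, _ = split_matrix(mats["t1"])
            regions = detect_recurrent_regions(al, DetectionConfig(seed=2))
            return sorted((r.chromosome, r.start_bp, r.end_bp) for r in regions)

        plants = [PlantedRegion("t1", "chr1", 20, 34, "gain", 0.6),
                  PlantedRegion("t1", "chr2", 50, 64, "gain", 0.6)]
        a = run([("chr1", 100), ("chr2", 100)], plants)
        b = run([("chr2", 100), ("chr1", 100)], plants)
        assert len(a) == 2 and {c for c, _, _ in a} == {"chr1", "chr2"}
        assert a == b

    def test_invariant_to_sample_order(self):
        mats, _, _ = simulate_stage_calls(planted_cfg(seed=5))
        al, _ = split_matrix(mats["t1"])
        perm = np.random.default_rng(0).permutation(al.n_samples)
        shuffled = BinaryAberrationMatrix(
            al.values[perm], "gain", [al.sample_ids[i] for i in perm], al.probe_map)
        cfg = DetectionConfig(seed=4)
        a = [(r.chromosome, r.l, r.r) for r in detect_recurrent_regions(al, cfg)]
        b = [(r.chromosome, r.l, r.r) for r in detect_recurrent_regions(shuffled, cfg)]
        assert a == b

    def test_peel_off_terminates_and_mass_decreases(self):
        rng = np.random.default_rng(3)
        vals = (rng.random((30, 80)) < 0.15).astype(np.int8)
        vals[:20, 10:25] = 1
        vals[:12, 50:60] = 1
        B = binary(vals)
        cfg = DetectionConfig(seed=6, max_iterations=10)
        res = RecurrentAberrationModel(B, cfg).fit()
        assert len(res.regions) <= cfg.max_iterations
        counts = [p.counts.sum() for p in res.profiles]
        emitted = len(res.regions)
        for i in range(emitted):
            if i + 1 < len(res.profiles):
                assert counts[i + 1] < counts[i]
        peaks = [r.peak_rank for r in res.regions]
        assert len(set(peaks)) == len(peaks)

    def test_detection_rate_monotone_in_frequency(self):
        """Raising the planted frequency never lowers the recovery rate
        (20 seeds, small cohort)."""
        def rate(freq):
            hits = 0
            for seed in range(20):
                cfg = SimConfig(stages=["t1"], n_samples_per_stage=[25], n_probes=120,
                                chromosomes=[("chr1", 120)],
                                planted_regions=[PlantedRegion("t1", "chr1", 40, 51,
                                                               "gain", freq)],
                                background_rate=0.01, seed=seed)
                mats, _, _ = simulate_stage_calls(cfg)
                al, _ = split_matrix(mats["t1"])
                regions = detect_recurrent_regions(
                    al, DetectionConfig(seed=seed, n_perm=2000))
                hits += any(r.l <= 45 <= r.r for r in regions)
            return hits

        assert rate(0.3) <= rate(0.6) <= rate(0.9)


class TestSharedRuns:
    def test_fig1_caption_biclusters(self, fig1_matrix):
        runs = find_shared_runs(fig1_matrix, min_samples=2, min_span=3)
        got = {(r.l, r.r, r.samples) for r in runs}
        assert got == {(3, 5, frozenset({"S1", "S2"})),
                       (4, 6, frozenset({"S2", "S3"}))}

    def test_fig1_min_span_two_adds_middle_block(self, fig1_matrix):
        runs = find_shared_runs(fig1_matrix, min_samples=2, min_span=2)
        got = {(r.l, r.r, r.samples) for r in runs}
        assert got == {(3, 5, frozenset({"S1", "S2"})),
                       (4, 6, frozenset({"S2", "S3"})),
                       (4, 5, frozenset({"S1", "S2", "S3"}))}

    def test_all_zero_matrix(self):
        A = AberrationCallMatrix(np.zeros((3, 5), dtype=np.int8),
                                 ["a", "b", "c"], make_probe_map(5), "t")
        assert find_shared_runs(A, 2, 1) == []

    @settings(deadline=None, max_examples=40)
    @given(arrays(np.int8, (4, 6), elements=st.sampled_from([-1, 0, 1])))
    def test_matches_exhaustive_bicluster_oracle(self, vals):
        ids = [f"S{i}" for i in range(4)]
        A = AberrationCallMatrix(vals, ids, make_probe_map(6), "t")
        got = {(r.state, r.l, r.r, r.samples) for r in find_shared_runs(A, 2, 2)}
        assert got == brute_force_biclusters(vals, ids, 2, 2)


class TestFrequencyTrack:
    def test_fig1_frequencies(self, fig1_matrix):
        al, _ = split_matrix(fig1_matrix)
        track = frequency_track(al)
        np.testing.assert_allclose(track["frequency"],
                                   [0, 0, 0, 2 / 3, 1, 1, 2 / 3])

    def test_zero_matrix(self):
        track = frequency_track(binary(np.zeros((4, 3))))
        assert (track["frequency"] == 0).all()
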