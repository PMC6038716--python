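"""Group-level inference: dimension reduction, t-tests, cluster
permutation, FDR, and the high-level drivers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decodem import (
    AnalysisConfig,
    ClassSpec,
    GroupConfig,
    cluster_permutation,
    compare_stats,
    compute_group_erp,
    compute_group_mvpa,
    decode_first_level,
    electrode_adjacency,
    fdr_correct,
    load_group_stats,
    reduce_dims,
    save_first_level,
    save_group_stats,
    simulate_group,
    ttest_vs_reference,
)

from conftest import planted_design


class TestReduceDims:
    def test_diag_extracts_diagonal(self, rng):
        M = rng.standard_normal((3, 6, 6))
        t = np.arange(6) * 10.0
        vals, times = reduce_dims(M, "diag", t, t)
        np.testing.assert_allclose(vals, np.diagonal(M, axis1=1, axis2=2))

    def test_avtrain_hand_average(self):
        t = np.array([0.0, 100.0, 200.0, 300.0, 400.0])
        M = np.arange(25, dtype=float).reshape(1, 5, 5)
        vals, times = reduce_dims(M, "avtrain", t, t, trainlim=(100, 300))
        np.testing.assert_allclose(vals[0], M[0, 1:4].mean(axis=0))
        np.testing.assert_allclose(times, t)

    def test_avtest_symmetric(self):
        t = np.array([0.0, 100.0, 200.0])
        M = np.arange(9, dtype=float).reshape(1, 3, 3)
        vals, times = reduce_dims(M, "avtest", t, t, testlim=(0, 100))
        np.testing.assert_allclose(vals[0], M[0, :, :2].mean(axis=1))

    def test_empty_window_errors(self, rng):
        M = rng.standard_normal((2, 4, 4))
        t = np.arange(4) * 10.0
        with pytest.raises(ValueError, match="no samples"):
            reduce_dims(M, "avtrain", t, t, trainlim=(500, 600))


class TestTTest:
    def test_at_reference_zero_t(self):
        vals = np.full((5, 7), 0.5)
        t, p = ttest_vs_reference(vals, 0.5)
        np.testing.assert_array_equal(t, 0.0)
        np.testing.assert_array_equal(p, 1.0)

    def test_textbook_one_sample(self):
        vals = np.array([0.6, 0.7, 0.55, 0.65, 0.6])[:, None]
        t, p = ttest_vs_reference(vals, 0.5)
        d = vals[:, 0] - 0.5
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t[0] == pytest.approx(t_hand, rel=1e-12)
        from scipy.stats import ttest_1samp

        ref = ttest_1samp(vals[:, 0], 0.5)
        assert t[0] == pytest.approx(ref.statistic, rel=1e-12)
        assert p[0] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_variance_offset_degenerate(self):
        vals = np.full((4, 3), 0.8)
        t, p = ttest_vs_reference(vals, 0.5)
        assert np.all(np.isinf(t))
        np.testing.assert_array_equal(p, 0.0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            ttest_vs_reference(np.ones((1, 4)), 0.5)


def brute_force_clusters_1d(mask):
    """Oracle cluster finder: explicit scan for contiguous runs."""
    clusters, current = [], []
    for i, m in enumerate(mask):
        if m:
            current.append(i)
        elif current:
            clusters.append(current)
            current = []
    if current:
        clusters.append(current)
    return clusters


class TestClusterPermutation:
    def test_planted_effect_found_with_bound_p(self, rng):
        n_sub, n_samp = 12, 80
        vals = 0.5 + 0.02 * rng.standard_normal((n_sub, n_samp))
        vals[:, 30:51] += 0.2  # effect 10x noise sd
        pos, neg, sig = cluster_permutation(
            vals, 0.5, n_iter=1000, seed=3, times=np.arange(n_samp) * 10.0
        )
        assert len(pos) >= 1
        top = pos[0]
        assert top.p_is_bound and top.clusterpval == pytest.approx(1 / 1000)
        assert abs(top.indices.min() - 30) <= 2
        assert abs(top.indices.max() - 50) <= 2
        # matches the oracle cluster finder on the thresholded t-map
        from scipy.stats import t as t_dist

        t_obs, _ = ttest_vs_reference(vals, 0.5)
        t_crit = t_dist.ppf(1 - 0.05 / 2, n_sub - 1)
        oracle = brute_force_clusters_1d(t_obs > t_crit)
        assert sorted(map(len, oracle)) == sorted(c.clustersize for c in pos)

    def test_constant_offset_full_axis_cluster(self, rng):
        vals = 0.7 + 0.001 * rng.standard_normal((8, 40))
        pos, neg, sig = cluster_permutation(vals, 0.5, n_iter=500, seed=1)
        assert len(pos) == 1
        assert pos[0].clustersize == pos[0].datasize == 40
        assert sig.all()

    def test_pvalues_on_permutation_grid(self, rng):
        vals = 0.5 + 0.05 * rng.standard_normal((6, 50))
        vals[:, 10:20] += 0.05
        pos, neg, _ = cluster_permutation(vals, 0.5, n_iter=200, seed=2)
        for c in pos + neg:
            if c.p_is_bound:
                assert c.clusterpval == pytest.approx(1 / 200)
            else:
                k = round(c.clusterpval * 200)
                assert c.clusterpval == pytest.approx(k / 200)
                assert k >= 1

    def test_deterministic_given_seed(self, rng):
        vals = 0.5 + 0.05 * rng.standard_normal((6, 30))
        vals[:, 5:12] += 0.08
        a = cluster_permutation(vals, 0.5, n_iter=300, seed=9)
        b = cluster_permutation(vals, 0.5, n_iter=300, seed=9)
        assert [c.clusterpval for c in a[0]] == [c.clusterpval for c in b[0]]
        np.testing.assert_array_equal(a[2], b[2])

    def test_matches_mne_reference_on_small_data(self, rng):
        # independent oracle: the reference cluster-permutation
        # implementation must find the same clusters and compatible p-values
        mne = pytest.importorskip("mne")
        from scipy.stats import t as t_dist

        vals = 0.5 + 0.05 * rng.standard_normal((10, 40))
        vals[:, 12:25] += 0.12
        thresh = t_dist.ppf(1 - 0.025, 9)
        t_ref, clusters_ref, p_ref, _ = mne.stats.permutation_cluster_1samp_test(
            vals - 0.5,
            threshold=thresh,
            n_permutations=1000,
            tail=0,
            seed=0,
            out_type="indices",
            verbose=False,
        )
        ref_sets = sorted(
            tuple(c[0]) for c, p in zip(clusters_ref, p_ref) if p < 0.05
        )
        pos, neg, sig = cluster_permutation(vals, 0.5, n_iter=1000, seed=0)
        our_sets = sorted(
            tuple(c.indices)
            for c in pos + neg
            if c.clusterpval < 0.05
        )
        assert our_sets == ref_sets

    def test_lattice_adjacency_on_matrix(self, rng):
        vals = 0.5 + 0.02 * rng.standard_normal((8, 12, 12))
        vals[:, 4:8, 4:8] += 0.15
        pos, neg, sig = cluster_permutation(
            vals, 0.5, n_iter=200, adjacency="lattice", seed=4
        )
        assert len(pos) >= 1
        assert sig[5, 5] and not sig[0, 11]

    def test_electrode_graph_clusters(self, rng):
        # 4x4 grid of sensors; effect on a connected 2x2 block
        pos_xy = np.array([(i % 4, i // 4) for i in range(16)], float)
        adj = electrode_adjacency(pos_xy)
        vals = 0.02 * rng.standard_normal((10, 16))
        block = [5, 6, 9, 10]
        vals[:, block] += 0.3
        chans = [f"E{i}" for i in range(16)]
        pos, neg, sig = cluster_permutation(
            vals, 0.0, n_iter=300, adjacency=adj, seed=5, channels=chans
        )
        assert len(pos) == 1
        assert sorted(pos[0].channels) == sorted(f"E{i}" for i in block)


def bh_oracle(p, q):
    """Benjamini-Hochberg step-up by hand."""
    m = len(p)
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    mask = np.zeros(m, bool)
    if len(passed):
        mask[order[: passed.max() + 1]] = True
    return mask


def by_oracle(p, q):
    """Benjamini-Yekutieli: BH at q divided by the harmonic sum."""
    m = len(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    return bh_oracle(p, q / c_m)


class TestFDR:
    def test_all_small_p_significant(self):
        assert fdr_correct(np.full(100, 0.001), q=0.05).all()

    def test_all_ones_none_significant(self):
        assert not fdr_correct(np.ones(50), q=0.05).any()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.1, 1.5]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=60,
        )
    )
    def test_by_mask_subset_of_bh_oracle(self, pvals):
        p = np.asarray(pvals)
        mask_by = fdr_correct(p, q=0.05)
        np.testing.assert_array_equal(mask_by, by_oracle(p, 0.05))
        assert not np.any(mask_by & ~bh_oracle(p, 0.05))

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=40)
        lo = fdr_correct(p, q=0.01)
        hi = fdr_correct(p, q=0.10)
        assert not np.any(lo & ~hi)


def make_cohort_results(amp, n_subjects=8, seed=0, crossclass=False, **kw):
    design = planted_design(amp=amp, latency=200.0, width=150.0, **kw)
    cohort = simulate_group(design, n_subjects, between_subject_sd=0.1, seed=seed)
    spec = ClassSpec.from_strings(["1", "2"])
    cfg = AnalysisConfig(nfolds=4, crossclass=crossclass, seed=5)
    return [decode_first_level(s, spec, cfg) for s in cohort]


class TestGroupDrivers:
    def test_planted_effect_recovered(self):
        results = make_cohort_results(amp=3.0, window=(-100.0, 500.0))
        gs = compute_group_mvpa(results, GroupConfig(iterations=500, seed=2))
        assert len(gs.clusters["posclusters"]) >= 1
        top = gs.clusters["posclusters"][0]
        assert top.start_time < 300 and top.stop_time > 100
        assert gs.sig_mask.any()
        # pStruct times lie on the sample grid
        for c in gs.clusters["posclusters"]:
            for t in (c.start_time, c.stop_time, c.peak_time):
                assert np.min(np.abs(gs.times - t)) < 1e-9
            assert c.start_time <= c.peak_time <= c.stop_time
            assert c.clustersize <= c.datasize

    def test_reference_at_data_mean_gives_no_clusters(self, rng):
        vals = 0.5 + 0.02 * rng.standard_normal((8, 40))
        pos, neg, sig = cluster_permutation(
            vals - vals.mean(axis=0, keepdims=True) + 0.5, 0.5, n_iter=200, seed=1
        )
        assert not sig.any()

    def test_folder_with_three_analyses(self, tmp_path):
        results = make_cohort_results(amp=1.5, n_subjects=3)
        for name in ("A_VS_B", "A_VS_C", "B_VS_C"):
            for r in results:
                save_first_level(
                    r, tmp_path / name / "ALL_NOSELECTION" / f"{r.subject_id}.flr"
                )
        stats = compute_group_mvpa(
            tmp_path, GroupConfig(mpcompcor_method="uncorrected")
        )
        assert isinstance(stats, list) and len(stats) == 3
        assert sorted(s.condname for s in stats) == ["A_VS_B", "A_VS_C", "B_VS_C"]

    def test_group_diag_of_crossclass_equals_diagonal_runs(self):
        results = make_cohort_results(amp=2.0, n_subjects=4, crossclass=True)
        gs = compute_group_mvpa(
            results,
            GroupConfig(reduce_dims="diag", mpcompcor_method="uncorrected"),
        )
        diag_results = make_cohort_results(amp=2.0, n_subjects=4, crossclass=False)
        gs_diag = compute_group_mvpa(
            diag_results, GroupConfig(mpcompcor_method="uncorrected")
        )
        np.testing.assert_allclose(gs.mean, gs_diag.mean, atol=1e-12)

    def test_shape_mismatch_names_subject(self):
        results = make_cohort_results(amp=1.0, n_subjects=3)
        results[1].performance = results[1].performance[:-3]
        with pytest.raises(ValueError, match="S02"):
            compute_group_mvpa(results, GroupConfig(mpcompcor_method="none"))


class TestGroupERP:
    def test_identical_classes_subtract_null(self, rng):
        # degenerate contract: identical class ERPs -> difference exactly 0,
        # t = 0 everywhere, nothing significant
        results = make_cohort_results(amp=0.0, n_subjects=5)
        for r in results:
            r.class_erps[1] = r.class_erps[0]
        cfg = GroupConfig(
            electrode_def=["CH01", "CH02"],
            condition_method="subtract",
            iterations=200,
            seed=1,
        )
        gs = compute_group_erp(results, cfg)
        np.testing.assert_array_equal(gs.tvals, 0.0)
        assert not gs.sig_mask.any()

    def test_planted_amplitude_difference_recovered(self):
        results = make_cohort_results(
            amp=2.0, n_subjects=12, window=(-100.0, 500.0)
        )
        cfg = GroupConfig(
            electrode_def=["CH01"],
            condition_method="subtract",
            iterations=500,
            seed=1,
        )
        gs = compute_group_erp(results, cfg)
        assert gs.sig_mask.any()
        sig_times = gs.times[gs.sig_mask]
        assert sig_times.min() > 0.0  # effect is stimulus-locked near 200 ms

    def test_electrode_average_hand_check(self):
        results = make_cohort_results(amp=1.0, n_subjects=3)
        cfg = GroupConfig(
            electrode_def=["CH01", "CH02"], mpcompcor_method="none"
        )
        stats = compute_group_erp(results, cfg)
        chans = results[0].channels
        i1, i2 = chans.index("CH01"), chans.index("CH02")
        manual = np.stack(
            [r.class_erps[0, [i1, i2], :].mean(axis=0) for r in results]
        )
        np.testing.assert_allclose(stats[0].subject_values, manual, atol=1e-12)

    def test_unknown_electrode_rejected(self):
        results = make_cohort_results(amp=1.0, n_subjects=3)
        cfg = GroupConfig(electrode_def=["NOPE"])
        with pytest.raises(ValueError, match="NOPE"):
            compute_group_erp(results, cfg)


class TestCompare:
    def test_identical_analyses_null(self):
        results = make_cohort_results(amp=2.0, n_subjects=5)
        cfg = GroupConfig(iterations=200, seed=3)
        gs = compute_group_mvpa(results, cfg)
        diff = compare_stats(gs, gs, cfg)
        np.testing.assert_array_equal(diff.tvals, 0.0)
        assert not diff.sig_mask.any()
        assert not diff.clusters["posclusters"]

    def test_planted_advantage_detected_with_sign(self):
        res_a = make_cohort_results(amp=0.0, n_subjects=8, seed=1)
        res_b = make_cohort_results(amp=3.0, n_subjects=8, seed=1)
        cfg = GroupConfig(iterations=300, seed=3)
        gs_a = compute_group_mvpa(res_a, cfg)
        gs_b = compute_group_mvpa(res_b, cfg)
        diff = compare_stats(gs_a, gs_b, cfg)
        # B better -> negative cluster (positive = A > B)
        assert len(diff.clusters["negclusters"]) >= 1

    def test_mismatched_subject_counts_rejected(self):
        res_a = make_cohort_results(amp=1.0, n_subjects=4)
        res_b = make_cohort_results(amp=1.0, n_subjects=5)
        cfg = GroupConfig(mpcompcor_method="none")
        gs_a = compute_group_mvpa(res_a, cfg)
        gs_b = compute_group_mvpa(res_b, cfg)
        with pytest.raises(ValueError, match="differ"):
            compare_stats(gs_a, gs_b, cfg)


class TestSerialization:
    def test_group_stats_roundtrip(self, tmp_path):
        results = make_cohort_results(amp=2.0, n_subjects=4)
        gs = compute_group_mvpa(results, GroupConfig(iterations=200, seed=2))
        path = save_group_stats(gs, tmp_path / "stats.gst")
        back = load_group_stats(path)
        np.testing.assert_allclose(back.mean, gs.mean)
        np.testing.assert_array_equal(back.sig_mask, gs.sig_mask)
        assert len(back.clusters["posclusters"]) == len(gs.clusters["posclusters"])
        if gs.clusters["posclusters"]:
            a, b = back.clusters["posclusters"][0], gs.clusters["posclusters"][0]
            assert a.clusterpval == b.clusterpval
            assert a.start_time == b.start_time
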