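import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from capdyn import caps as caps_mod
from capdyn.caps import (
    CapSet,
    SeedSpec,
    assign_frames_to_caps,
    cap_metrics,
    cluster_caps,
    coactivation_map,
    consensus_select_k,
    match_caps,
    resolve_seed,
    seed_series,
    select_active_frames,
)
from capdyn.preprocess import Volume4D
from capdyn.synthetic import CohortDesign, simulate_subject

from conftest import make_truth, pooled_selected_frames


def vol_on_grid(data, voxel=2.5):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return Volume4D(data, affine, np.ones(data.shape[:3], bool), 1.0)


class TestResolveSeed:
    def test_tiny_radius_selects_single_voxel(self):
        vol = vol_on_grid(np.zeros((8, 8, 8, 1)))
        center = (2.5 * 4, 2.5 * 4, 2.5 * 4)  # world coords of voxel (4,4,4)
        seed = resolve_seed(SeedSpec(centers=(center,), radius=1.0), vol)
        assert seed.sum() == 1 and seed[4, 4, 4]

    def test_disjoint_spheres_union(self):
        vol = vol_on_grid(np.zeros((12, 12, 12, 1)))
        s1 = resolve_seed(SeedSpec(centers=((5, 5, 5),), radius=3.0), vol)
        s2 = resolve_seed(SeedSpec(centers=((22.5, 22.5, 22.5),), radius=3.0), vol)
        both = resolve_seed(SeedSpec(centers=((5, 5, 5), (22.5, 22.5, 22.5)), radius=3.0), vol)
        assert not (s1 & s2).any()
        assert both.sum() == s1.sum() + s2.sum()

    def test_default_bilateral_seed_on_mni_like_grid(self):
        # 2.5 mm grid whose affine covers the posterior-midline coordinates
        affine = np.diag([2.5, 2.5, 2.5, 1.0])
        affine[:3, 3] = (-40, -90, 0)
        vol = Volume4D(np.zeros((32, 32, 32, 1)), affine, np.ones((32, 32, 32), bool), 1.0)
        seed = resolve_seed(SeedSpec(), vol)
        assert seed.sum() > 0

    def test_global_mode_returns_brain_mask(self):
        vol = vol_on_grid(np.zeros((4, 4, 4, 1)))
        assert resolve_seed(SeedSpec(mode="global"), vol).all()

    def test_empty_resolution_rejected(self):
        vol = vol_on_grid(np.zeros((4, 4, 4, 1)))
        with pytest.raises(ValueError):
            resolve_seed(SeedSpec(centers=((1000, 1000, 1000),), radius=1.0), vol)


class TestSeedSeries:
    def test_constant_volume(self):
        vol = vol_on_grid(np.full((4, 4, 4, 6), 3.0))
        seed = np.zeros((4, 4, 4), bool)
        seed[1, 1, 1] = True
        assert np.allclose(seed_series(vol, seed), 3.0)

    def test_whole_mask_equals_global_signal(self):
        from capdyn.preprocess import extract_global_signal

        rng = np.random.default_rng(0)
        vol = vol_on_grid(rng.standard_normal((4, 4, 4, 10)))
        assert np.allclose(seed_series(vol, vol.mask), extract_global_signal(vol))

    def test_noiseless_subject_series_tracks_states(self, noiseless_truth):
        truth = noiseless_truth
        design = CohortDesign(n_per_group=1, n_frames=100, tr=1.0, min_retained_seconds=50)
        vol, _, states = simulate_subject(truth, design, "control", "pre", 11)
        series = seed_series(vol, truth.seed_mask)
        active = states < truth.k
        assert series[active].min() > series[~active].max()


class TestSelectActiveFrames:
    def test_threshold_matches_inline_zscore_oracle(self):
        rng = np.random.default_rng(1)
        series = rng.standard_normal(40) * 2 + 1
        z = (series - series.mean()) / series.std()
        assert np.array_equal(select_active_frames(series), np.flatnonzero(z > 1))

    def test_standardized_series_thresholds_directly(self):
        # a series that is already mean-0/sd-1 is thresholded as-is
        series = np.array([0.0, 2.0, -2.0, 1.5, 0.5])
        series = (series - series.mean()) / series.std()
        expected = np.flatnonzero(series > 1)
        assert np.array_equal(select_active_frames(series), expected)

    def test_single_spike_selected(self):
        series = np.zeros(50)
        series[17] = 5.0
        assert select_active_frames(series).tolist() == [17]

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(2)
        series = rng.standard_normal(20000)
        frac = select_active_frames(series).size / series.size
        assert abs(frac - (1 - norm.cdf(1))) < 0.02

    def test_negative_excursions_excluded_by_default(self):
        series = np.concatenate([np.zeros(20), [4.0, -4.0]])
        sel = select_active_frames(series)
        assert 21 not in sel and 20 in sel

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            select_active_frames(np.ones(10))


class TestCoactivationMap:
    def test_single_frame_identity(self):
        rng = np.random.default_rng(3)
        vol = vol_on_grid(rng.standard_normal((4, 4, 4, 5)))
        m = coactivation_map(vol, np.array([2]), vol.mask)
        assert np.allclose(m, vol.data[..., 2])

    def test_two_frame_average(self):
        vol = vol_on_grid(np.stack([np.full((3, 3, 3), 1.0), np.full((3, 3, 3), 3.0)], axis=-1))
        m = coactivation_map(vol, np.array([0, 1]), vol.mask)
        assert np.allclose(m, 2.0)

    def test_noiseless_single_state_map_matches_truth(self, noiseless_truth):
        truth = noiseless_truth
        design = CohortDesign(n_per_group=1, n_frames=120, tr=1.0, min_retained_seconds=60)
        vol, _, states = simulate_subject(truth, design, "control", "pre", 19)
        frames = np.flatnonzero(states == 0)
        m = coactivation_map(vol, frames, truth.gm_mask)[truth.gm_mask]
        r = np.corrcoef(m, truth.cap_maps[0])[0, 1]
        assert r > 0.999

    def test_empty_frames_rejected(self):
        vol = vol_on_grid(np.zeros((3, 3, 3, 2)))
        with pytest.raises(ValueError):
            coactivation_map(vol, np.array([], dtype=int), vol.mask)


class TestClusterCaps:
    def test_orthogonal_states_recovered_exactly(self):
        rng = np.random.default_rng(4)
        maps = np.linalg.qr(rng.standard_normal((50, 3)))[0].T  # 3 orthogonal maps
        labels_true = rng.integers(0, 3, size=90)
        frames = maps[labels_true]
        caps, labels = cluster_caps(frames, 3, rng_seed=0)
        _, matched_r = match_caps(maps, caps.centroids)
        assert np.all(matched_r > 0.999)
        # perfect partition up to relabeling
        for c in range(3):
            assert len(set(labels_true[labels == c])) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        frames = rng.standard_normal((60, 30))
        _, l1 = cluster_caps(frames, 3, rng_seed=42)
        _, l2 = cluster_caps(frames, 3, rng_seed=42)
        assert np.array_equal(l1, l2)

    def test_centroids_z_scored_and_ordered_by_occurrence(self):
        rng = np.random.default_rng(6)
        frames = np.vstack([np.tile(rng.standard_normal(20), (30, 1)),
                            np.tile(rng.standard_normal(20), (10, 1))])
        frames += 0.01 * rng.standard_normal(frames.shape)
        caps, labels = cluster_caps(frames, 2, rng_seed=0)
        assert np.allclose(caps.centroids.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(caps.centroids.std(axis=1), 1, atol=1e-10)
        assert (labels == 0).sum() >= (labels == 1).sum()

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            cluster_caps(np.zeros((5, 10)), 3, rng_seed=0)

    def test_noisy_parameter_recovery(self, small_truth):
        frames, _, _ = pooled_selected_frames(small_truth, n_subjects=12, n_frames=100, seed=2)
        caps, _ = cluster_caps(frames, 3, rng_seed=1)
        _, matched_r = match_caps(small_truth.cap_maps, caps.centroids)
        assert matched_r.mean() >= 0.9


class TestConsensusSelectK:
    def test_noiseless_three_states_chosen(self):
        rng = np.random.default_rng(7)
        maps = np.linalg.qr(rng.standard_normal((40, 3)))[0].T
        labels = np.repeat(np.arange(3), 40)
        frames = maps[labels] + 1e-6 * rng.standard_normal((120, 40))
        subj = np.tile(np.repeat(np.arange(4), 10), 3)
        report = consensus_select_k(frames, range(2, 7), rng_seed=0, n_boot=20, subject_ids=subj)
        assert report.chosen_k == 3
        cm = report.consensus_matrices[3]
        finite = cm[np.isfinite(cm)]
        assert np.all((finite < 1e-9) | (finite > 1 - 1e-9))

    def test_pure_noise_stability_decreases_with_k(self):
        rng = np.random.default_rng(8)
        frames = rng.standard_normal((300, 40))
        report = consensus_select_k(frames, [2, 6], rng_seed=0, n_boot=20)
        s = report.table.set_index("k")["stability"]
        assert s[2] > s[6]

    def test_invalid_k_range_rejected(self):
        with pytest.raises(ValueError):
            consensus_select_k(np.zeros((50, 5)), [2, 30], rng_seed=0)


class TestCapMetrics:
    def test_hand_enumerated_example(self):
        # selected frames {2,3,4,9,10,20}, labels (1,1,2,2,2,3) -> runs:
        # CAP1 {2,3}; CAP2 {4}, {9,10}; CAP3 {20}
        selected = np.array([2, 3, 4, 9, 10, 20])
        labels = np.array([0, 0, 1, 1, 1, 2])
        keep = np.ones(600, bool)
        m = cap_metrics(labels, selected, keep, tr=1.0, k=3)
        assert np.allclose(m.occurrence, [2 / 6, 3 / 6, 1 / 6])
        assert np.allclose(m.duration_s, [2.0, 1.5, 1.0])
        assert np.allclose(m.frequency_per_min, [1 / 10, 2 / 10, 1 / 10])
        assert m.n_active_frames == 6
        assert m.active_fraction == pytest.approx(6 / 600)

    def test_single_cap_indicator(self):
        m = cap_metrics(np.zeros(5, int), np.arange(5), np.ones(100, bool), 1.0, k=3)
        assert m.occurrence.tolist() == [1.0, 0.0, 0.0]

    def test_empty_selection_flagged(self):
        m = cap_metrics(np.array([], int), np.array([], int), np.ones(10, bool), 1.0, k=2)
        assert m.flagged_empty and np.allclose(m.occurrence, 0)

    @given(st.data())
    def test_metric_identities_random_sequences(self, data):
        # occurrence_c * n_selected = sum of run lengths of c;
        # frequency_c * retained minutes = number of runs of c;
        # duration * frequency * minutes / n_selected = occurrence (frame units)
        n_total = data.draw(st.integers(20, 120))
        k = data.draw(st.integers(2, 4))
        n_sel = data.draw(st.integers(1, n_total))
        idx = data.draw(
            st.lists(st.integers(0, n_total - 1), min_size=n_sel, max_size=n_sel, unique=True)
        )
        selected = np.sort(np.array(idx))
        labels = np.array(
            data.draw(st.lists(st.integers(0, k - 1), min_size=n_sel, max_size=n_sel))
        )
        tr = 1.0
        keep = np.ones(n_total, bool)
        m = cap_metrics(labels, selected, keep, tr, k)
        minutes = n_total * tr / 60.0
        assert m.occurrence.sum() == pytest.approx(1.0)
        n_runs = m.frequency_per_min * minutes
        mean_len_frames = np.where(n_runs > 0, m.duration_s / tr, 0.0)
        recovered_occ = mean_len_frames * n_runs / selected.size
        assert np.allclose(recovered_occ, m.occurrence, atol=1e-12)


class TestAssignFrames:
    def _caps(self, centroids):
        z = (centroids - centroids.mean(axis=1, keepdims=True)) / centroids.std(
            axis=1, keepdims=True
        )
        return CapSet(k=len(centroids), centroids=z)

    def test_exact_centroid_assigned(self):
        rng = np.random.default_rng(9)
        cents = rng.standard_normal((3, 25))
        caps = self._caps(cents)
        labels, corr = assign_frames_to_caps(caps.centroids[[1]], caps)
        assert labels[0] == 1 and corr[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_frame_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(10)
        q = np.linalg.qr(rng.standard_normal((30, 3)))[0].T  # orthogonal, zero-mean-ish
        q = (q - q.mean(axis=1, keepdims=True)) / q.std(axis=1, keepdims=True)
        caps = CapSet(k=3, centroids=q)
        frame = -q[[0]]
        labels, corr = assign_frames_to_caps(frame, caps)
        assert corr[0, 0] == pytest.approx(-1.0, abs=1e-6)
        assert labels[0] == int(np.argmax(corr[0]))  # max r wins; ties to lower index

    def test_noisy_state_frames_classified_correctly(self, small_truth):
        rng = np.random.default_rng(11)
        true_states = rng.integers(0, 3, size=400)
        frames = small_truth.cap_maps[true_states] + 0.5 * rng.standard_normal(
            (400, small_truth.cap_maps.shape[1])
        )
        caps = self._caps(small_truth.cap_maps)
        labels, _ = assign_frames_to_caps(frames, caps)
        assert (labels == true_states).mean() >= 0.95

    def test_zero_variance_frame_unassigned(self):
        rng = np.random.default_rng(12)
        caps = self._caps(rng.standard_normal((2, 10)))
        with pytest.warns(RuntimeWarning):
            labels, _ = assign_frames_to_caps(np.zeros((1, 10)), caps)
        assert labels[0] == -1


class TestTrainingSetRobustness:
    def test_controls_only_vs_pooled_centroids_match(self, small_truth):
        frames, subj, _ = pooled_selected_frames(small_truth, n_subjects=20, n_frames=100, seed=3)
        controls = subj < 10
        caps_all, _ = cluster_caps(frames, 3, rng_seed=5)
        caps_ctrl, _ = cluster_caps(frames[controls], 3, rng_seed=5)
        _, matched_r = match_caps(caps_all.centroids, caps_ctrl.centroids)
        assert matched_r.min() >= 0.95

    def test_k4_preserves_planted_states(self, small_truth):
        frames, _, _ = pooled_selected_frames(small_truth, n_subjects=20, n_frames=100, seed=4)
        caps4, _ = cluster_caps(frames, 4, rng_seed=6)
        z_truth = small_truth.cap_maps - small_truth.cap_maps.mean(axis=1, keepdims=True)
        z_truth /= z_truth.std(axis=1, keepdims=True)
        corr = z_truth @ caps4.centroids.T / caps4.centroids.shape[1]
        assert corr.max(axis=1).min() >= 0.8
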