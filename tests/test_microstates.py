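"""Microstate core: GFP, peak-map clustering, labeling, back-fitting, parameters."""

import numpy as np
import pytest

from microact import (
    GFPSeries,
    MicrostateModel,
    StateSequenceSpec,
    aggregate_group_maps,
    assign_canonical_labels,
    backfit,
    canonical_templates,
    compute_gev,
    compute_gfp,
    compute_parameters,
    find_gfp_peaks,
    modified_kmeans,
    simulate_state_sequence,
)
from microact.microstates import (
    LabeledSegmentation,
    _runs,
    export_model,
    parameters_table,
    read_model,
    segmentation_table,
    transitions_table,
)

from conftest import orthogonal_templates


class TestGFP:
    def test_two_channel_hand_value(self):
        assert compute_gfp(np.array([[1.0], [-1.0]])).values[0] == pytest.approx(1.0)

    def test_constant_column_zero(self):
        vals = compute_gfp(np.full((5, 3), 2.7)).values
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_worked_column_sqrt3(self):
        # column [3, -1, -1, -1]: mean 0, sum of squares 12, /4, sqrt -> sqrt(3)
        vals = compute_gfp(np.array([[3.0], [-1.0], [-1.0], [-1.0]])).values
        assert vals[0] == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_matches_direct_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((19, 200))
        direct = np.empty(200)
        for t in range(200):
            col = X[:, t]
            direct[t] = np.sqrt(np.sum((col - col.mean()) ** 2) / len(col))
        np.testing.assert_allclose(compute_gfp(X).values, direct, atol=1e-12)


class TestGFPPeaks:
    def test_simple_peaks(self):
        peaks = find_gfp_peaks(GFPSeries(np.array([0.0, 1, 0, 2, 0])))
        np.testing.assert_array_equal(peaks, [1, 3])

    def test_monotone_no_peaks(self):
        assert len(find_gfp_peaks(GFPSeries(np.arange(5.0)))) == 0

    def test_plateau_no_strict_peak(self):
        assert len(find_gfp_peaks(GFPSeries(np.array([0.0, 1, 1, 0])))) == 0

    def test_min_separation_keeps_larger(self):
        peaks = find_gfp_peaks(GFPSeries(np.array([0.0, 1, 0, 0.9, 0])), 3)
        np.testing.assert_array_equal(peaks, [1])


class TestModifiedKmeans:
    def test_noiseless_polarity_flipped_recovery(self):
        truth = orthogonal_templates(19, 4, seed=2)
        rng = np.random.default_rng(3)
        idx = rng.integers(0, 4, 400)
        signs = rng.choice([-1.0, 1.0], 400)
        scales = rng.uniform(0.5, 3.0, 400)
        peak_maps = truth[idx] * (signs * scales)[:, None]
        model = modified_kmeans(peak_maps, k=4, n_restarts=20, seed=4)
        corr = np.abs(model.maps @ truth.T)
        # each truth template recovered exactly up to permutation/sign
        assert np.allclose(np.sort(corr.max(axis=0)), 1.0, atol=1e-9)
        assert model.gev == pytest.approx(1.0, abs=1e-9)

    def test_polarity_invariance_of_fit(self):
        rng = np.random.default_rng(5)
        maps = rng.standard_normal((100, 19))
        flipped = maps * rng.choice([-1.0, 1.0], 100)[:, None]
        a = modified_kmeans(maps, k=3, n_restarts=10, seed=6)
        b = modified_kmeans(flipped, k=3, n_restarts=10, seed=6)
        corr = np.abs(a.maps @ b.maps.T)
        assert a.gev == pytest.approx(b.gev, abs=1e-9)
        assert np.allclose(corr.max(axis=1), 1.0, atol=1e-9)

    def test_k1_equals_weighted_pc1(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 19)) * rng.uniform(0.5, 2, (50, 1))
        model = modified_kmeans(X, k=1, n_restarts=3, seed=8)
        Xc = X - X.mean(axis=1, keepdims=True)
        S = Xc.T @ Xc
        vals, vecs = np.linalg.eigh(S)
        pc1 = vecs[:, -1]
        assert abs(abs(model.maps[0] @ pc1) - 1.0) < 1e-9
        # GEV closed form: leading eigenvalue over total weighted power
        assert model.gev == pytest.approx(vals[-1] / np.trace(S), abs=1e-9)

    def test_too_few_maps_raises(self):
        with pytest.raises(ValueError, match="at least"):
            modified_kmeans(np.eye(3), k=4)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        maps = rng.standard_normal((80, 19))
        a = modified_kmeans(maps, k=4, n_restarts=5, seed=10)
        b = modified_kmeans(maps, k=4, n_restarts=5, seed=10)
        np.testing.assert_array_equal(a.maps, b.maps)


class TestGEV:
    def test_perfect_assignment_gev_one(self):
        truth = orthogonal_templates(10, 2, seed=11)
        lab = np.array([0, 1, 0, 1, 1])
        data = (truth[lab] * np.array([1.0, 2, 3, 4, 5])[:, None]).T
        assert compute_gev(truth, data, lab) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_assignment_gev_zero(self):
        truth = orthogonal_templates(10, 4, seed=12)
        lab = np.array([2, 3, 2, 3])
        data = (truth[[0, 1, 0, 1]]).T
        assert compute_gev(truth, data, lab) == pytest.approx(0.0, abs=1e-12)

    def test_random_assignment_never_beats_exhaustive_best(self):
        rng = np.random.default_rng(13)
        maps = orthogonal_templates(8, 2, seed=14)
        data = rng.standard_normal((8, 6))
        best = max(
            compute_gev(maps, data, np.array([(m >> t) & 1 for t in range(6)]))
            for m in range(64)
        )
        for _ in range(20):
            lab = rng.integers(0, 2, 6)
            assert compute_gev(maps, data, lab) <= best + 1e-12


class TestGroupAggregation:
    def test_permuted_flipped_models_realigned(self):
        truth = orthogonal_templates(19, 4, seed=15)
        m1 = MicrostateModel(maps=truth, gev=0.9, k=4)
        m2 = MicrostateModel(maps=truth[[2, 0, 3, 1]] * np.array([[-1], [1], [-1], [1]]), gev=0.9, k=4)
        group = aggregate_group_maps([m1, m2])
        corr = np.abs(group.maps @ truth.T)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-9)

    def test_single_model_unchanged(self):
        truth = orthogonal_templates(19, 4, seed=16)
        model = MicrostateModel(maps=truth, gev=0.8, k=4)
        group = aggregate_group_maps([model])
        np.testing.assert_allclose(np.abs(np.diag(group.maps @ truth.T)), 1.0, atol=1e-9)

    def test_averaging_beats_median_individual(self):
        rng = np.random.default_rng(17)
        truth = orthogonal_templates(19, 4, seed=18)
        models = []
        indiv_corr = []
        for _ in range(10):
            noisy = truth + 0.3 * rng.standard_normal(truth.shape)
            noisy -= noisy.mean(axis=1, keepdims=True)
            noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
            models.append(MicrostateModel(maps=noisy, gev=0.5, k=4))
            indiv_corr.append(np.abs(np.diag(noisy @ truth.T)).mean())
        group = aggregate_group_maps(models)
        group_corr = np.abs(np.diag(group.maps @ truth.T)).mean()
        assert group_corr > np.median(indiv_corr)

    def test_inconsistent_k_rejected(self):
        a = MicrostateModel(maps=orthogonal_templates(19, 4, seed=1), gev=0.5, k=4)
        b = MicrostateModel(maps=orthogonal_templates(19, 3, seed=1), gev=0.5, k=3)
        with pytest.raises(ValueError, match="share"):
            aggregate_group_maps([a, b])


class TestCanonicalLabels:
    def test_shuffled_canonicals_restored(self):
        canon = canonical_templates()
        order = [3, 1, 0, 2]
        model = MicrostateModel(maps=canon.maps[order], gev=1.0, k=4)
        labeled = assign_canonical_labels(model)
        assert labeled.labels == ("A", "B", "C", "D")
        np.testing.assert_allclose(np.abs(np.diag(labeled.maps @ canon.maps.T)), 1.0, atol=1e-12)

    def test_polarity_ignored(self):
        canon = canonical_templates()
        model = MicrostateModel(maps=-canon.maps, gev=1.0, k=4)
        labeled = assign_canonical_labels(model)
        assert labeled.labels == ("A", "B", "C", "D")
        np.testing.assert_allclose(np.abs(np.diag(labeled.maps @ canon.maps.T)), 1.0, atol=1e-12)

    def test_canonical_set_distinguishable(self):
        canon = canonical_templates()
        corr = np.abs(canon.maps @ canon.maps.T)
        assert np.all(corr[~np.eye(4, dtype=bool)] < 0.8)

    def test_size_mismatch_rejected(self):
        model = MicrostateModel(maps=orthogonal_templates(19, 3, seed=1), gev=0.5, k=3)
        with pytest.raises(ValueError, match="k="):
            assign_canonical_labels(model)


class TestBackfit:
    def test_noiseless_labels_exact(self, templates4):
        spec = StateSequenceSpec(total_duration_s=4.0, seed=20)
        truth = simulate_state_sequence(spec)
        data = (templates4.maps[truth]).T * 40.0
        model = MicrostateModel(maps=templates4.maps, gev=1.0, k=4)
        seg = backfit([data], model, sampling_rate_hz=500.0)
        np.testing.assert_array_equal(seg.labels[0], truth)

    def test_scale_invariance(self, templates4, short_synthetic):
        eeg, _ = short_synthetic
        model = MicrostateModel(maps=templates4.maps, gev=1.0, k=4)
        rng = np.random.default_rng(21)
        scales = rng.uniform(0.1, 10.0, eeg.data.shape[1])
        a = backfit([eeg.data], model, sampling_rate_hz=500.0)
        b = backfit([eeg.data * scales], model, sampling_rate_hz=500.0)
        np.testing.assert_array_equal(a.labels[0], b.labels[0])

    def test_single_map_one_segment_per_epoch(self, short_synthetic):
        eeg, _ = short_synthetic
        model = MicrostateModel(maps=eeg.truth_templates.maps[:1], gev=1.0, k=1)
        seg = backfit([eeg.data[:, :500], eeg.data[:, 500:1000]], model, sampling_rate_hz=500.0)
        assert all(len(s) == 1 for s in seg.segments)

    def test_min_duration_merge_removes_short_runs(self, templates4, short_synthetic):
        eeg, _ = short_synthetic
        model = MicrostateModel(maps=templates4.maps, gev=1.0, k=4)
        seg = backfit([eeg.data], model, sampling_rate_hz=500.0, min_duration_ms=20.0)
        lengths = [length for s in seg.segments for (_, _, length) in s]
        assert min(lengths) >= 10  # 20 ms at 500 Hz


class TestParameters:
    def test_hand_enumerated_oracle(self):
        # one epoch at 500 Hz: A x50, B x25, A x25
        labels = np.array([0] * 50 + [1] * 25 + [0] * 25)
        seg = LabeledSegmentation([labels], [_runs(labels)], 500.0, 2)
        p = compute_parameters(seg)
        np.testing.assert_allclose(p.coverage, [0.75, 0.25])
        np.testing.assert_allclose(p.duration_ms, [75.0, 50.0])  # mean of 100&50, and 50
        np.testing.assert_allclose(p.occurrence_per_s, [10.0, 5.0])  # 2 and 1 runs in 0.2 s
        assert p.transition[0, 1] == pytest.approx(1.0)
        assert p.transition[1, 0] == pytest.approx(1.0)

    def test_all_one_state(self):
        labels = np.zeros(500, dtype=int)
        seg = LabeledSegmentation(
            [labels, labels], [_runs(labels), _runs(labels)], 500.0, 2
        )
        p = compute_parameters(seg)
        assert p.coverage[0] == pytest.approx(1.0)
        assert p.occurrence_per_s[0] == pytest.approx(2 / 2.0)  # 2 epochs over 2 s
        assert not p.transition_defined[0]
        assert np.isnan(p.transition[0]).all()

    def test_absent_state_zero_and_undefined(self):
        labels = np.array([0, 0, 1, 1, 0])
        seg = LabeledSegmentation([labels], [_runs(labels)], 500.0, 3)
        p = compute_parameters(seg)
        assert p.coverage[2] == 0 and p.occurrence_per_s[2] == 0 and p.duration_ms[2] == 0
        assert not p.transition_defined[2]

    def test_transition_recovery_from_simulated_sequence(self):
        P = np.array([[0.0, 0.7, 0.3], [0.2, 0.0, 0.8], [0.5, 0.5, 0.0]])
        spec = StateSequenceSpec(k=3, transition_matrix=P, total_duration_s=200.0, seed=22)
        labels = simulate_state_sequence(spec)
        seg = LabeledSegmentation([labels], [_runs(labels)], 500.0, 3)
        p = compute_parameters(seg)
        n_trans = len(_runs(labels)) - 1
        assert n_trans >= 2000
        assert np.nanmax(np.abs(p.transition - P)) <= 0.05

    def test_duration_recovered_in_high_snr_limit(self, templates4):
        """With negligible noise the mean back-fitted run length matches the
        generative 60 ms dwell; at realistic snr, samplewise label noise
        fragments runs, so duration is only interpretable after smoothing."""
        spec = StateSequenceSpec(total_duration_s=50.0, seed=30)
        truth = simulate_state_sequence(spec)
        from microact import synthesize_eeg

        eeg = synthesize_eeg(templates4, truth, 500.0, snr=1e6, seed=30)
        model = MicrostateModel(maps=templates4.maps, gev=1.0, k=4)
        epochs = [eeg.data[:, i * 5000 : (i + 1) * 5000] for i in range(5)]
        seg = backfit(epochs, model, sampling_rate_hz=500.0)
        p = compute_parameters(seg)
        assert abs(p.duration_ms.mean() - 60.0) / 60.0 <= 0.15

    def test_coverage_occurrence_duration_identity(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            epochs = [rng.integers(0, 4, rng.integers(200, 800)) for _ in range(3)]
            seg = LabeledSegmentation(epochs, [_runs(e) for e in epochs], 500.0, 4)
            p = compute_parameters(seg)
            product = p.occurrence_per_s * p.duration_ms / 1000.0
            mask = p.coverage > 0
            np.testing.assert_allclose(product[mask], p.coverage[mask], rtol=0.02)


class TestExports:
    def test_model_round_trip(self, tmp_path, templates4):
        model = MicrostateModel(maps=templates4.maps, gev=0.912345, k=4,
                                labels=("A", "B", "C", "D"))
        path = tmp_path / "model.csv"
        export_model(path, model, [f"ch{i}" for i in range(19)])
        back = read_model(path)
        assert back.k == 4 and back.labels == ("A", "B", "C", "D")
        assert back.gev == pytest.approx(0.912345, abs=1e-6)
        np.testing.assert_allclose(back.maps, model.maps, atol=1e-12)

    def test_tables_shapes(self, short_synthetic, templates4):
        eeg, _ = short_synthetic
        model = MicrostateModel(maps=templates4.maps, gev=1.0, k=4)
        seg = backfit([eeg.data], model, sampling_rate_hz=500.0)
        p = compute_parameters(seg)
        pt = parameters_table("S1", p)
        tt = transitions_table("S1", p)
        st = segmentation_table(seg)
        assert list(pt.columns) == ["subject_id", "state", "coverage", "duration_ms",
                                    "occurrence_per_s"]
        assert len(pt) == 4 and len(tt) == 12
        assert st["duration_ms"].sum() == pytest.approx(10_000.0)
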