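"""Color calling: unmixing, smoothing, normalization, bit calls, consistency."""

import numpy as np
import pytest

from bitbow.calling import (
    DEFAULT_THRESHOLD,
    IllConditionedMatrixError,
    MixingMatrix,
    TraceIntensitySeries,
    UnlabeledCellError,
    assignment_accuracy,
    auto_thresholds,
    call_bits,
    call_cells,
    consistency_stats,
    normalize_channels,
    smooth,
    unmix,
)


def make_series(values, label="neurite", coords=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    if coords is None:
        coords = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)])
    return TraceIntensitySeries(
        node_ids=np.arange(1, n + 1), coords=coords, intensities=values, label=label
    )


class TestUnmix:
    def test_identity_matrix_passthrough(self):
        M = MixingMatrix(np.eye(5))
        y = np.array([0.1, 0.0, 2.0, 0.3, 0.0])
        np.testing.assert_allclose(unmix(y, M), y)

    def test_noiseless_mixture_recovered_exactly(self):
        rng = np.random.default_rng(0)
        m = np.eye(5) * 0.8 + rng.uniform(0, 0.05, (5, 5))
        M = MixingMatrix(m)
        a_true = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        y = M.matrix @ a_true
        np.testing.assert_allclose(unmix(y, M), a_true, atol=1e-9)

    def test_remixing_round_trip(self):
        rng = np.random.default_rng(1)
        M = MixingMatrix(np.eye(5) * 0.7 + rng.uniform(0, 0.08, (5, 5)))
        A_true = rng.uniform(0, 2, (20, 5))
        Y = A_true @ M.matrix.T
        A = unmix(Y, M)
        np.testing.assert_allclose(A @ M.matrix.T, Y, atol=1e-9)

    def test_zero_input_zero_abundance(self):
        M = MixingMatrix(np.eye(5))
        np.testing.assert_allclose(unmix(np.zeros(5), M), 0.0)

    def test_more_channels_than_fluorophores(self):
        rng = np.random.default_rng(2)
        M = MixingMatrix(rng.uniform(0.1, 1.0, (8, 5)))
        a_true = rng.uniform(0, 1, 5)
        y = M.matrix @ a_true
        np.testing.assert_allclose(unmix(y, M), a_true, atol=1e-8)

    def test_rank_deficient_matrix_rejected(self):
        m = np.ones((5, 5))
        with pytest.raises(IllConditionedMatrixError):
            MixingMatrix(m)

    def test_nonnegativity_enforced_on_noisy_input(self):
        rng = np.random.default_rng(3)
        M = MixingMatrix(np.eye(5) * 0.6 + 0.1)
        Y = np.abs(rng.normal(0, 0.05, (100, 5)))
        assert np.all(unmix(Y, M) >= 0)


class TestSmooth:
    def test_constant_series_unchanged(self):
        s = make_series(np.full((20, 5), 0.4))
        out = smooth(s)
        np.testing.assert_allclose(out.intensities, 0.4)

    def test_impulse_removed_by_median(self):
        vals = np.full((15, 5), 1.0)
        vals[7, 2] = 50.0
        out = smooth(make_series(vals), window=1)  # isolate the median step
        assert out.intensities[7, 2] == pytest.approx(1.0)

    def test_window_larger_than_series_gives_global_mean(self):
        vals = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 5))
        out = smooth(make_series(vals), window=10)
        # median step keeps values (monotone), rolling window covers all
        np.testing.assert_allclose(out.intensities[1], 2.0)

    def test_never_increases_channel_range(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, (40, 5))
        out = smooth(make_series(vals))
        assert np.all(out.intensities.max(0) <= vals.max(0) + 1e-12)
        assert np.all(out.intensities.min(0) >= vals.min(0) - 1e-12)

    def test_volumetric_median_at_nodes(self):
        vol = np.full((5, 7, 7, 7), 2.0)
        vol[:, 3, 3, 3] = 100.0  # impulse at the node itself
        coords = np.array([[3.0, 3.0, 3.0]])
        s = make_series(np.array([[100.0] * 5]), coords=coords)
        out = smooth(s, volume=vol, window=1)
        np.testing.assert_allclose(out.intensities, 2.0)

    def test_node_outside_volume_names_node(self):
        vol = np.zeros((5, 4, 4, 4))
        s = make_series(np.zeros((1, 5)), coords=np.array([[9.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="node 1"):
            smooth(s, volume=vol)


class TestNormalize:
    def test_unit_sum(self):
        v, bg = normalize_channels(np.array([2.0, 1.0, 1.0, 0.0, 0.0]))
        np.testing.assert_allclose(v, [0.5, 0.25, 0.25, 0.0, 0.0])
        assert not bg

    def test_scaling_invariance(self):
        x = np.array([0.2, 0.1, 0.7, 0.0, 0.0])
        a, _ = normalize_channels(x)
        b, _ = normalize_channels(17.3 * x)
        np.testing.assert_allclose(a, b)

    def test_idempotent(self):
        x = np.array([3.0, 1.0, 0.0, 0.0, 1.0])
        once, _ = normalize_channels(x)
        twice, _ = normalize_channels(once)
        np.testing.assert_allclose(once, twice)

    def test_zero_vector_flagged_background(self):
        _, bg = normalize_channels(np.zeros(5))
        assert bg

    def test_floor_flags_dim_pixels(self):
        v = np.array([[0.001] * 5, [1.0] * 5])
        _, bg = normalize_channels(v, floor=0.1)
        assert bg.tolist() == [True, False]

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_channels(np.array([-0.1, 1, 1, 1, 1]))


class TestCallBits:
    def test_fixed_threshold_call(self):
        cell = call_bits(np.array([0.5, 0.45, 0.02, 0.02, 0.01]), thresholds=0.1)
        assert str(cell.code) == "11000"

    def test_tie_at_threshold_is_on(self):
        cell = call_bits(np.array([0.1, 0.0, 0.9, 0.0, 0.0]), thresholds=0.1)
        assert cell.code.bits[0] == 1

    def test_margins_are_absolute_distances(self):
        cell = call_bits(np.array([0.5, 0.02, 0.0, 0.0, 0.48]), thresholds=0.1)
        np.testing.assert_allclose(cell.margins, [0.4, 0.08, 0.1, 0.1, 0.38])

    def test_median_aggregation_robust_to_bright_outlier(self):
        px = np.tile([0.3, 0.7, 0.0, 0.0, 0.0], (9, 1))
        px[0] = [0.0, 0.0, 1.0, 0.0, 0.0]
        cell = call_bits(px, thresholds=0.1)
        assert str(cell.code) == "11000"

    def test_all_background_raises(self):
        with pytest.raises(UnlabeledCellError):
            call_bits(np.zeros((3, 5)))

    def test_auto_threshold_separates_two_populations(self):
        rng = np.random.default_rng(8)
        n = 200
        on = rng.random(n) < 0.5
        ch = np.where(on, rng.normal(0.4, 0.03, n), rng.normal(0.02, 0.03, n))
        aggs = np.zeros((n, 5))
        aggs[:, 0] = np.clip(ch, 0, None)
        aggs[:, 1] = 0.5  # constant channel: unimodal, falls back
        thr = auto_thresholds(aggs)
        called_on = aggs[:, 0] >= thr[0]
        assert np.array_equal(called_on, on)
        assert thr[1] == DEFAULT_THRESHOLD

    def test_call_cells_auto_end_to_end(self):
        # codes with equal ON-bit counts: every channel's ON population is
        # a single well-separated mode, the regime auto mode is built for
        rng = np.random.default_rng(9)
        truth = ["11000", "00110", "10010", "01001", "00101"] * 20
        pixels = []
        for code in truth:
            bits = np.array([int(c) for c in code], dtype=float)
            base = bits / bits.sum()
            px = np.clip(base + rng.normal(0, 0.02, (12, 5)), 0, None)
            pixels.append(px)
        cells = call_cells(pixels, thresholds="auto")
        called = [str(c.code) for c in cells]
        assert np.mean([a == b for a, b in zip(called, truth)]) == 1.0


class TestConsistency:
    def test_identical_distributions_zero_distance(self):
        s = make_series(np.tile([0.5, 0.5, 0, 0, 0], (10, 1)), label="soma")
        n = make_series(np.tile([0.5, 0.5, 0, 0, 0], (10, 1)))
        out = consistency_stats(s, n)
        assert out["distance"] == 0.0

    def test_median_shift_measured(self):
        s = make_series(np.tile([0.5, 0.5, 0, 0, 0], (10, 1)), label="soma")
        n = make_series(np.tile([0.4, 0.6, 0, 0, 0], (10, 1)))
        out = consistency_stats(s, n)
        assert out["distance"] == pytest.approx(0.1)
        np.testing.assert_allclose(out["per_channel"], [0.1, 0.1, 0, 0, 0])

    def test_empty_series_rejected(self):
        s = make_series(np.tile([0.2] * 5, (3, 1)))
        with pytest.raises(ValueError):
            consistency_stats(s, make_series(np.empty((0, 5))))

    def test_nearest_centroid_accuracy_with_separated_colors(self):
        rng = np.random.default_rng(10)
        somas, neurites = [], []
        for i in range(21):
            color = rng.dirichlet(np.ones(5) * 0.4)
            somas.append(
                make_series(np.clip(color + rng.normal(0, 0.005, (15, 5)), 0, None),
                            label="soma")
            )
            neurites.append(
                make_series(np.clip(color + rng.normal(0, 0.005, (15, 5)), 0, None))
            )
        assert assignment_accuracy(somas, neurites) == 1.0
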