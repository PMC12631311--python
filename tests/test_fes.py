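"""Block-averaged histograms, Boltzmann inversion, error propagation."""

import math

import numpy as np
import pytest

from mutadyn.core import CVSeries
from mutadyn.fes import (KB_KJ_PER_MOL_K, BlockHistogramStack, average_histogram,
                         basin_delta_g, block_histograms, boltzmann_invert,
                         fes_error, project_1d, surface)
from mutadyn.synthetic import TwoStateSpec, gen_two_state_cv

KT = KB_KJ_PER_MOL_K * 298.15


def _series(values1, values2, dt=0.4):
    t = np.arange(len(values1)) * dt
    return (CVSeries("cv1", "", t, np.asarray(values1, dtype=float)),
            CVSeries("cv2", "", t, np.asarray(values2, dtype=float)))


def _stack_from(hists, window_ns=10.0):
    hists = np.asarray(hists, dtype=float)
    n1, n2 = hists.shape[1:]
    return BlockHistogramStack(hists, np.arange(n1 + 1, dtype=float),
                               np.arange(n2 + 1, dtype=float), window_ns, 0.0)


class TestBlockHistograms:
    def test_window_count_200ns(self):
        """200 ns sampled at 0.4 ns, discard 50, window 10 → 15 windows."""
        rng = np.random.default_rng(0)
        cv1, cv2 = _series(rng.random(500), rng.random(500))
        stack = block_histograms(cv1, cv2, discard_ns=50, window_ns=10, bins=20)
        assert stack.n_windows == 15

    def test_constant_pair_single_bin(self):
        cv1, cv2 = _series(np.full(100, 1.5), np.full(100, 3.0))
        stack = block_histograms(cv1, cv2, discard_ns=0, window_ns=10, bins=10)
        for h in stack.histograms:
            assert h.max() == pytest.approx(1.0)
            assert h.sum() == pytest.approx(1.0)

    def test_counts_match_manual_binning(self):
        """20-sample fixture against an independently coded binning loop."""
        rng = np.random.default_rng(5)
        v1, v2 = rng.random(20), rng.random(20)
        cv1, cv2 = _series(v1, v2, dt=1.0)
        stack = block_histograms(cv1, cv2, discard_ns=0, window_ns=10, bins=4,
                                 ranges=((0.0, 1.0), (0.0, 1.0)))
        edges = np.linspace(0.0, 1.0, 5)
        for w in range(2):
            manual = np.zeros((4, 4))
            for x, y in zip(v1[10 * w:10 * (w + 1)], v2[10 * w:10 * (w + 1)]):
                i = min(int(np.searchsorted(edges, x, "right")) - 1, 3)
                j = min(int(np.searchsorted(edges, y, "right")) - 1, 3)
                manual[i, j] += 1
            assert np.allclose(stack.histograms[w], manual / 10.0, atol=1e-12)

    def test_too_few_windows_raises(self):
        cv1, cv2 = _series(np.ones(20), np.ones(20), dt=0.4)
        with pytest.raises(ValueError, match="windows"):
            block_histograms(cv1, cv2, discard_ns=0, window_ns=10)

    def test_misaligned_series_raise(self):
        cv1, _ = _series(np.ones(50), np.ones(50))
        cv2 = CVSeries("b", "", np.arange(50) * 0.5, np.ones(50))
        with pytest.raises(ValueError, match="align"):
            block_histograms(cv1, cv2, 0, 5)


class TestAverageHistogram:
    def test_identical_windows(self):
        h = np.zeros((3, 2, 2))
        h[:, 0, 1] = 1.0
        assert np.allclose(average_histogram(_stack_from(h)), h[0])

    def test_disjoint_windows_average_to_half(self):
        h = np.zeros((2, 2, 2))
        h[0, 0, 0] = 1.0
        h[1, 1, 1] = 1.0
        avg = average_histogram(_stack_from(h))
        assert avg[0, 0] == pytest.approx(0.5) and avg[1, 1] == pytest.approx(0.5)

    def test_matches_independent_mean(self):
        rng = np.random.default_rng(8)
        h = rng.random((6, 4, 5))
        h /= h.sum(axis=(1, 2), keepdims=True)
        manual = sum(h[j] for j in range(6)) / 6.0
        assert np.allclose(average_histogram(_stack_from(h)), manual, atol=1e-15)


class TestBoltzmannInversion:
    def test_modal_bin_is_zero(self):
        h = np.array([[0.5, 0.3], [0.2, 0.0]])
        fes = boltzmann_invert(h, 298.15)
        assert fes.free_energy[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_one_over_e_bin(self):
        h = np.array([[math.e, 1.0]]) / (math.e + 1.0)
        fes = boltzmann_invert(h, 298.15)
        assert fes.free_energy[0, 1] == pytest.approx(KT, abs=1e-9)
        assert fes.free_energy[0, 1] == pytest.approx(2.479, abs=1e-3)

    def test_half_max_bin(self):
        h = np.array([[2.0, 1.0]]) / 3.0
        fes = boltzmann_invert(h, 298.15)
        assert fes.free_energy[0, 1] == pytest.approx(KT * math.log(2), abs=1e-9)

    def test_scale_invariance(self):
        """Unnormalized histograms give the same surface (Eq. is max-referenced)."""
        rng = np.random.default_rng(2)
        h = rng.random((5, 5))
        f1 = boltzmann_invert(h / h.sum(), 300.0).free_energy
        f2 = boltzmann_invert(7.3 * h / h.sum(), 300.0).free_energy
        assert np.allclose(f1, f2, atol=1e-10)

    def test_unvisited_bins_masked(self):
        h = np.array([[0.9, 0.1], [0.0, 0.0]])
        fes = boltzmann_invert(h, 298.15)
        assert np.isnan(fes.free_energy[1]).all()
        assert not fes.mask[1].any()
        assert np.nanmin(fes.free_energy) == pytest.approx(0.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            boltzmann_invert(np.zeros((3, 3)), 298.15)

    def test_nonpositive_temperature_raises(self):
        with pytest.raises(ValueError):
            boltzmann_invert(np.ones((2, 2)) / 4, 0.0)


class TestFesError:
    def test_identical_windows_zero_error(self):
        h = np.tile(np.array([[0.6, 0.4]]) , (4, 1)).reshape(4, 1, 2)
        err = fes_error(_stack_from(h), 298.15)
        assert np.allclose(err[0], 0.0)

    def test_two_window_hand_propagation(self):
        h = np.array([[[0.6, 0.4]], [[0.8, 0.2]]])
        err = fes_error(_stack_from(h), 298.15)
        sem0 = np.std([0.6, 0.8], ddof=1) / math.sqrt(2)
        assert err[0, 0] == pytest.approx(KT * sem0 / 0.7, abs=1e-12)

    def test_error_shrinks_as_sqrt_n(self):
        """iid windows: the propagated error scales like 1/√N."""
        rng = np.random.default_rng(3)

        def mean_err(n):
            p = np.clip(0.5 + 0.05 * rng.standard_normal(n), 0.01, 0.99)
            h = np.stack([np.array([[pi, 1 - pi]]) for pi in p])
            return np.nanmean(fes_error(_stack_from(h), 298.15))

        e10 = np.mean([mean_err(10) for _ in range(300)])
        e40 = np.mean([mean_err(40) for _ in range(300)])
        assert e40 == pytest.approx(e10 / 2.0, rel=0.15)


class TestProjection:
    def test_single_column_equals_column_inversion(self):
        h = np.zeros((3, 4, 2))
        h[:, 1, 0] = 0.7
        h[:, 2, 0] = 0.3
        prof = project_1d(_stack_from(h), "cv1", 298.15)
        expected = -KT * (np.log([0.7, 0.3]) - math.log(0.7))
        assert prof.free_energy[1] == pytest.approx(expected[0], abs=1e-12)
        assert prof.free_energy[2] == pytest.approx(expected[1], abs=1e-12)

    def test_separable_distribution_recovers_marginal(self):
        p1 = np.array([0.2, 0.5, 0.3])
        p2 = np.array([0.6, 0.4])
        h = np.tile(np.outer(p1, p2)[None], (3, 1, 1))
        prof = project_1d(_stack_from(h), "cv1", 298.15)
        expected = -KT * (np.log(p1) - math.log(p1.max()))
        assert np.allclose(prof.free_energy, expected, atol=1e-12)

    def test_commutes_with_marginalize_then_invert(self):
        rng = np.random.default_rng(9)
        h = rng.random((5, 6, 7))
        h /= h.sum(axis=(1, 2), keepdims=True)
        stack = _stack_from(h)
        prof = project_1d(stack, "cv2", 310.0)
        marg = average_histogram(stack).sum(axis=0)
        direct = -KB_KJ_PER_MOL_K * 310.0 * (np.log(marg) - np.log(marg.max()))
        assert np.allclose(prof.free_energy, direct, atol=1e-10)


class TestTwoStateRecovery:
    def test_basin_delta_g_within_confidence_band(self):
        """The designed ΔG = k_B T ln(p_f/p_u) is recovered from the 1D
        marginal within the 95% block-averaging confidence band."""
        spec = TwoStateSpec(seed=12)
        cv_beta, cv_dist, _ = gen_two_state_cv(spec)
        stack = block_histograms(cv_beta, cv_dist, 50, 10, 50)
        dg, err, ci = basin_delta_g(stack, "cv2", split=14.75)
        truth = KT * math.log(spec.p_folded / (1 - spec.p_folded))
        assert abs(dg - truth) <= ci
        assert err > 0

    def test_surface_shows_both_basins(self):
        cv_beta, cv_dist, _ = gen_two_state_cv(TwoStateSpec(seed=4))
        stack = block_histograms(cv_beta, cv_dist, 50, 10, 30)
        fes2d = surface(stack)
        assert np.nanmin(fes2d.free_energy) == pytest.approx(0.0, abs=1e-12)
        prof = project_1d(stack, "cv2")
        left = prof.free_energy[prof.centers < 14.75]
        right = prof.free_energy[prof.centers >= 14.75]
        assert np.nanmin(left) < 1.0 and np.nanmin(right) < 3.0
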