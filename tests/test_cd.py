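"""CD unit conversion, smoothing and basis-set deconvolution."""

import numpy as np
import pytest

from mutadyn.cd import (BasisSet, CDSpectrum, average_and_correct, deconvolve,
                        group_classes, select_basis, smooth, to_mre)
from mutadyn.synthetic import gen_cd_spectrum

WL = np.arange(200.0, 250.5, 0.5)


def _spec(values, unit="MRE", **kw):
    return CDSpectrum(WL, np.broadcast_to(values, WL.shape).copy(), unit, **kw)


class TestToMre:
    def test_zero_maps_to_zero(self):
        out = to_mre(_spec(0.0, "mdeg"), mw_kda=16.6, path_length_cm=0.1,
                     concentration_mg_ml=0.62)
        assert np.allclose(out.values, 0.0)
        assert out.unit == "MRE"

    def test_hand_arithmetic(self):
        """−5 mdeg, Mw 16.6 kDa, L 0.1 cm, C 0.62 mg/mL → −133.87."""
        out = to_mre(_spec(-5.0, "mdeg"), mw_kda=16.6, path_length_cm=0.1,
                     concentration_mg_ml=0.62)
        assert out.values[0] == pytest.approx(-133.87, abs=0.01)

    def test_linearity_and_inverse_proportionality(self):
        base = to_mre(_spec(-5.0, "mdeg"), 16.6, 0.1, 0.62).values
        doubled_c = to_mre(_spec(-5.0, "mdeg"), 16.6, 0.1, 1.24).values
        doubled_mdeg = to_mre(_spec(-10.0, "mdeg"), 16.6, 0.1, 0.62).values
        assert np.allclose(doubled_c, base / 2)
        assert np.allclose(doubled_mdeg, base * 2)

    @pytest.mark.parametrize("kw", [dict(mw_kda=0), dict(path_length_cm=-1),
                                    dict(concentration_mg_ml=0)])
    def test_nonpositive_parameters_raise(self, kw):
        full = dict(mw_kda=16.6, path_length_cm=0.1, concentration_mg_ml=0.62)
        full.update(kw)
        with pytest.raises(ValueError):
            to_mre(_spec(-5.0, "mdeg"), **full)


class TestAverageAndCorrect:
    def test_identity(self):
        s = _spec(-3.0)
        out = average_and_correct([s, s, s], baseline=_spec(0.0))
        assert np.allclose(out.values, -3.0)

    def test_opposite_spectra_cancel(self):
        out = average_and_correct([_spec(1.0), _spec(-1.0)])
        assert np.allclose(out.values, 0.0)

    def test_three_spectra_with_baseline_hand_computed(self):
        vals = [2.0, 4.0, 9.0]
        out = average_and_correct([_spec(v) for v in vals], baseline=_spec(1.0))
        assert np.allclose(out.values, np.mean(vals) - 1.0)

    def test_grid_mismatch_raises(self):
        other = CDSpectrum(WL + 1.0, np.zeros_like(WL), "MRE")
        with pytest.raises(ValueError, match="grid"):
            average_and_correct([_spec(0.0), other])


class TestSmooth:
    def test_cubic_polynomial_unchanged(self):
        x = WL - 225.0
        cubic = 0.01 * x**3 - 0.2 * x**2 + 3 * x - 7
        out = smooth(CDSpectrum(WL, cubic, "MRE"), order=3, window=9)
        assert np.allclose(out.values, cubic, atol=1e-10)

    def test_constant_unchanged(self):
        out = smooth(_spec(5.0))
        assert np.allclose(out.values, 5.0, atol=1e-12)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        x = WL - 225.0
        clean = 0.005 * x**3 + x
        noisy = clean + rng.standard_normal(WL.shape)
        out = smooth(CDSpectrum(WL, noisy, "MRE"))
        assert np.var(out.values - clean) < np.var(noisy - clean)

    def test_invalid_window_raises(self):
        with pytest.raises(ValueError):
            smooth(_spec(0.0), order=3, window=8)

    def test_non_uniform_grid_raises(self):
        wl = np.array([200.0, 201.0, 203.0, 204.0, 205.0, 206.0, 207.0,
                       208.0, 209.0, 210.0])
        with pytest.raises(ValueError, match="uniform"):
            smooth(CDSpectrum(wl, np.zeros_like(wl), "MRE"))


class TestDeconvolve:
    def test_exact_round_trip(self, basis3):
        truth = np.array([0.4, 0.1, 0.5])
        spec = gen_cd_spectrum(truth, basis3)
        res = deconvolve(spec, basis3)
        got = np.array([res.fractions[c] for c in basis3.classes])
        assert np.max(np.abs(got - truth)) < 1e-8
        assert res.rmsd < 1e-6
        assert res.scale == pytest.approx(1.0, abs=1e-8)

    def test_single_component(self, basis3):
        spec = gen_cd_spectrum([0.0, 1.0, 0.0], basis3)
        res = deconvolve(spec, basis3)
        assert res.fractions["strand"] == pytest.approx(1.0, abs=1e-9)

    def test_scale_recovery(self, basis3):
        """A spectrum scaled by 1/s is compensated by the fitted scale s."""
        spec = gen_cd_spectrum([0.3, 0.2, 0.5], basis3)
        scaled = CDSpectrum(spec.wavelengths, spec.values / 0.8, "MRE")
        res = deconvolve(scaled, basis3)
        assert res.scale == pytest.approx(0.8, abs=1e-6)
        assert res.fractions["coil"] == pytest.approx(0.5, abs=1e-6)

    def test_permutation_equivariance(self, basis3):
        reordered = BasisSet("perm", basis3.wavelengths,
                             {c: basis3.components[c]
                              for c in ["coil", "helix", "strand"]},
                             {c: c for c in ["coil", "helix", "strand"]})
        spec = gen_cd_spectrum([0.4, 0.1, 0.5], basis3)
        a = deconvolve(spec, basis3).fractions
        b = deconvolve(spec, reordered).fractions
        for cls in ("helix", "strand", "coil"):
            assert a[cls] == pytest.approx(b[cls], abs=1e-9)

    def test_noisy_recovery_within_tolerance(self, basis3):
        """Three noisy acquisitions (σ = 2% of the basis maximum), averaged
        as in the measurement protocol, recover fractions within 0.05."""
        truth = np.array([0.4, 0.1, 0.5])
        sigma = 0.02 * np.abs(basis3.matrix()).max()
        reps = [gen_cd_spectrum(truth, basis3, noise_sigma=sigma, seed=k)
                for k in (21, 22, 23)]
        res = deconvolve(average_and_correct(reps), basis3)
        got = np.array([res.fractions[c] for c in basis3.classes])
        assert np.max(np.abs(got - truth)) < 0.05

    def test_no_overlap_raises(self, basis3):
        far = CDSpectrum(WL + 200.0, np.ones_like(WL), "MRE")
        with pytest.raises(ValueError, match="overlap"):
            deconvolve(far, basis3)


class TestSelectBasisAndGrouping:
    def test_generating_basis_selected(self, basis3, basis6):
        spec = gen_cd_spectrum([0.4, 0.1, 0.5], basis3)
        best, table = select_basis(spec, [basis6, basis3])
        assert best.name == basis3.name
        assert len(table) == 2

    def test_single_candidate(self, basis3):
        spec = gen_cd_spectrum([1.0, 0.0, 0.0], basis3)
        best, _ = select_basis(spec, [basis3])
        assert best is basis3

    def test_rmsd_table_matches_direct_deconvolution(self, basis3, basis6):
        spec = gen_cd_spectrum([0.2, 0.3, 0.5], basis3, noise_sigma=300, seed=9)
        _, table = select_basis(spec, [basis3, basis6])
        for name, rmsd in table:
            cand = basis3 if name == basis3.name else basis6
            assert rmsd == pytest.approx(deconvolve(spec, cand).rmsd, rel=1e-9)

    def test_grouping_preserves_total(self, basis6):
        fractions = {c: 1.0 / 6 for c in basis6.classes}
        grouped = group_classes(fractions, basis6)
        assert sum(grouped.values()) == pytest.approx(1.0, abs=1e-12)
        assert grouped["helix"] == pytest.approx(2.0 / 6, abs=1e-12)

    def test_identity_grouping(self, basis3):
        fractions = {"helix": 0.4, "strand": 0.1, "coil": 0.5}
        assert group_classes(fractions, basis3) == pytest.approx(fractions)

    def test_unmapped_class_raises(self, basis3):
        with pytest.raises(ValueError, match="grouping"):
            group_classes({"mystery": 1.0}, basis3)
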