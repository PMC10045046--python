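import numpy as np
import pytest

from lungcad import denoise as dn
from lungcad import phantoms


def _toy_subband_set():
    """4-subband 2-D set engineered for exact threshold arithmetic."""
    hh = np.full((4, 4), 0.6745)        # median |HH| = 0.6745 -> sigma_N = 1
    lh = np.full((4, 4), np.sqrt(5.0))  # RMS = sqrt(5) -> sigma_y^2 = 5
    ll = np.full((4, 4), 10.0)
    hl = np.full((4, 4), 1.0)           # sigma_y = sigma_N -> pure noise
    return dn.SubbandSet(subbands={"LL": ll, "LH": lh, "HL": hl, "HH": hh},
                         wavelet_name="sym4", original_shape=(8, 8))


class TestWaveletTransform:
    def test_constant_volume_energy_in_approximation(self):
        sb = dn.wavelet_decompose(np.full((8, 8, 8), 3.0))
        assert set(sb.subbands) == {"LLL", "LLH", "LHL", "LHH",
                                    "HLL", "HLH", "HHL", "HHH"}
        for name, band in sb.subbands.items():
            if name != "LLL":
                assert np.abs(band).max() < 1e-10

    def test_perfect_reconstruction(self, rng):
        v = rng.normal(size=(16, 16, 16))
        r = dn.wavelet_reconstruct(dn.wavelet_decompose(v))
        assert np.abs(r - v).max() < 1e-8

    def test_parseval_energy_split(self, rng):
        v = rng.normal(size=(16, 16, 16))
        sb = dn.wavelet_decompose(v)
        e_in = np.sum(v ** 2)
        e_sb = sum(np.sum(b ** 2) for b in sb.subbands.values())
        assert abs(e_in - e_sb) / e_in < 1e-8

    def test_2d_slices_use_four_subbands(self, rng):
        x = rng.normal(size=(12, 12))
        sb = dn.wavelet_decompose(x)
        assert set(sb.subbands) == {"LL", "LH", "HL", "HH"}
        assert np.abs(dn.wavelet_reconstruct(sb) - x).max() < 1e-8

    def test_subband_shapes_are_ceil_half(self, rng):
        sb = dn.wavelet_decompose(rng.normal(size=(10, 14)))
        assert all(b.shape == (5, 7) for b in sb.subbands.values())

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError, match="wavelet"):
            dn.wavelet_decompose(np.zeros((8, 8)), "not-a-wavelet")


class TestThresholdEstimate:
    def test_mad_scaling_and_bayes_arithmetic(self):
        est = dn.estimate_threshold(_toy_subband_set())
        assert est["HH"].sigma_n == pytest.approx(1.0)
        # sigma_y^2 = 5, sigma_N^2 = 1 -> sigma_s = 2, T_B = 1/2
        assert est["LH"].sigma_s == pytest.approx(2.0)
        assert est["LH"].t_b == pytest.approx(0.5)

    def test_pure_noise_subband_hits_sentinel(self):
        est = dn.estimate_threshold(_toy_subband_set())
        assert est["HL"].is_sentinel
        assert est["HL"].sigma_s == 0.0
        assert est["HL"].t_b == pytest.approx(1.0)  # max |coefficient|

    def test_noise_sigma_recovery_on_pure_noise(self, rng):
        v = rng.normal(0.0, 15.0, size=(32, 32, 32))
        est = dn.estimate_threshold(dn.wavelet_decompose(v))
        assert abs(est["HHH"].sigma_n - 15.0) / 15.0 < 0.20


class TestGammaModifier:
    def test_printed_coefficients(self):
        assert dn.gamma_modifier(0.0) == pytest.approx(-1.10843, abs=1e-5)
        assert dn.gamma_modifier(1.0) == pytest.approx(3.97439, abs=1e-5)

    def test_zero_numerator(self):
        curve = dn.CurveCoefficients(p1=0, p2=0, p3=0, q=0.5)
        assert dn.gamma_modifier(2.0, curve) == 0.0

    def test_pole_rejected(self):
        with pytest.raises(ValueError, match="pole"):
            dn.gamma_modifier(-0.1245)


class TestCollaborativeThreshold:
    def test_zero_threshold_is_identity(self, rng):
        g = rng.normal(size=(24, 24))
        out = dn.collaborative_threshold(g, t_b=0.0, gamma=5.0)
        assert np.abs(out - g).max() < 1e-8

    def test_constant_grid_unchanged(self):
        g = np.full((24, 24), 7.0)
        out = dn.collaborative_threshold(g, t_b=100.0, gamma=1.0)
        assert np.allclose(out, 7.0, atol=1e-8)

    def test_reduces_noise_mse(self, rng):
        clean = np.zeros((32, 32))
        clean[8:24, 8:24] = 50.0
        noisy = clean + rng.normal(0, 15, size=clean.shape)
        out = dn.collaborative_threshold(noisy, t_b=10.0, gamma=2.0)
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_never_increases_max_abs_coefficient(self, rng):
        g = rng.normal(size=(24, 24))
        for op in ("hard", "soft"):
            out = dn.collaborative_threshold(
                g, t_b=0.5, gamma=1.0,
                config=dn.DenoiseConfig(threshold_operator=op))
            assert np.abs(out).max() <= np.abs(g).max() + 1e-9

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            dn.DenoiseConfig(group_size=0)
        with pytest.raises(ValueError):
            dn.DenoiseConfig(block_size=1)


class TestDenoiseVolume:
    def test_clean_phantom_nearly_unchanged(self):
        clean = phantoms.make_phantom(phantoms.PhantomSpec(seed=1)).image
        out = dn.denoise_volume(clean)
        rel = np.mean((out - clean) ** 2) / np.mean(clean ** 2)
        assert rel < 0.02

    def test_improves_filtering_accuracy(self):
        clean = phantoms.make_phantom(phantoms.PhantomSpec(seed=2)).image
        noisy = phantoms.add_noise(clean, 15.0, seed=3)
        out = dn.denoise_volume(noisy)
        assert dn.filtering_accuracy(clean, out) > \
            dn.filtering_accuracy(clean, noisy)

    def test_second_pass_changes_less_than_first(self):
        clean = phantoms.make_phantom(phantoms.PhantomSpec(seed=4)).image
        noisy = phantoms.add_noise(clean, 15.0, seed=5)
        once = dn.denoise_volume(noisy)
        twice = dn.denoise_volume(once)
        mse = lambda a, b: np.mean((a - b) ** 2)
        first_improvement = mse(noisy, clean) - mse(once, clean)
        assert abs(mse(twice, clean) - mse(once, clean)) < first_improvement


class TestFilteringAccuracy:
    def test_direct_arithmetic(self):
        ref = np.zeros((2, 2))
        assert dn.filtering_accuracy(ref, np.full((2, 2), 2.0)) == \
            pytest.approx(25.0)   # MSE 4 -> 25%
        assert dn.filtering_accuracy(ref, np.ones((2, 2))) == \
            pytest.approx(100.0)  # MSE 1 -> 100%

    def test_exact_match_capped_and_flagged(self):
        x = np.ones((4, 4))
        with pytest.warns(UserWarning, match="capped"):
            acc = dn.filtering_accuracy(x, x)
        assert acc == dn.FILTERING_ACCURACY_CAP

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dn.filtering_accuracy(np.zeros((2, 2)), np.zeros((3, 3)))
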