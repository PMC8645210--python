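"""Unit and property tests of the image-formation model."""

import numpy as np
import pytest

from qhcr.config import (AmplifierParams, BackgroundParams, ChannelSpec,
                         OpticsParams, ParameterError)
from qhcr.sim import (generate_truth, render, simulate_amplification,
                      simulate_background, simulate_detection,
                      simulate_experiment)

from conftest import small_config


# ---------------------------------------------------------------------------
# ground truth

class TestGenerateTruth:
    def test_empty_field(self):
        cfg = small_config(n_cells=0, channels=(ChannelSpec(target_id="t"),))
        truth = generate_truth(cfg)
        assert not truth.cell_labels.any()
        assert not truth.molecule_counts["t"].any()

    def test_deterministic_density_hand_count(self):
        """Total molecules = cell area (pixels) x density, by hand count."""
        cfg = small_config(n_cells=1, channels=(ChannelSpec(target_id="t"),))
        truth = generate_truth(cfg)
        n_pix = int((truth.cell_labels == 1).sum())
        assert n_pix > 0
        assert truth.molecule_counts["t"].sum() == 5 * n_pix
        # counts live exactly on the cell's pixels
        assert (truth.molecule_counts["t"] > 0).sum() == n_pix

    def test_seed_determinism(self):
        cfg = small_config(seed=7, channels=(ChannelSpec(target_id="t"),),
                           law={"name": "lognormal", "mean_density": 5,
                                "sigma": 0.6})
        t1, t2 = generate_truth(cfg), generate_truth(cfg)
        np.testing.assert_array_equal(t1.cell_labels, t2.cell_labels)
        np.testing.assert_array_equal(t1.molecule_counts["t"],
                                      t2.molecule_counts["t"])

    def test_oversized_cell_names_dimension(self):
        cfg = small_config(shape=(16, 256), n_cells=1,
                           channels=(ChannelSpec(target_id="t"),),
                           cell_axes_um=(2.0, 2.0))  # 12.5 px > 16-row field
        with pytest.raises(ValueError, match="rows"):
            generate_truth(cfg)

    def test_redundant_pair_shares_one_truth_field(self):
        chans = (ChannelSpec(target_id="t"), ChannelSpec(target_id="t"))
        truth = generate_truth(small_config(channels=chans))
        assert truth.target_ids == ("t",)
        assert truth.counts_for(chans[0]) is truth.counts_for(chans[1])


# ---------------------------------------------------------------------------
# detection

class TestDetection:
    def test_certain_binding(self):
        ch = ChannelSpec(target_id="t", binding_efficiency=1.0)
        mol = np.array([[10, 0], [3, 7]])
        out = simulate_detection(mol, ch, seed=0)
        np.testing.assert_array_equal(out, mol)

    def test_full_interference_blocks_everything(self):
        ch = ChannelSpec(target_id="t", binding_efficiency=1.0, interference=1.0)
        out = simulate_detection(np.full((8, 8), 50), ch, seed=0)
        assert not out.any()

    def test_split_pair_squares_the_efficiency(self):
        """Both half-probes must bind: mean initiators = 0.5^2 x 10^4."""
        ch = ChannelSpec(target_id="t", probe_kind="split_initiator_pair",
                         binding_efficiency=0.5)
        mol = np.full((1,), 10_000)
        draws = np.array([simulate_detection(mol, ch, seed=s)[0]
                          for s in range(100)], dtype=float)
        p = 0.25
        se = np.sqrt(10_000 * p * (1 - p) / draws.size)
        assert abs(draws.mean() - 2500.0) < 3 * se

    def test_initiators_per_probe_multiplies_trials(self):
        ch = ChannelSpec(target_id="t", binding_efficiency=1.0,
                         initiators_per_probe=3)
        out = simulate_detection(np.array([4]), ch, seed=0)
        assert out[0] == 12

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ParameterError):
            ChannelSpec(target_id="t", binding_efficiency=1.5)


# ---------------------------------------------------------------------------
# amplification

class TestAmplification:
    def test_h1_only_one_hairpin_per_initiator(self):
        amp = AmplifierParams(mean_polymer_length=180, hairpin_mode="h1_only")
        out = simulate_amplification(np.array([7]), amp, seed=0)
        assert out[0] == 7.0

    def test_deterministic_polymer_length(self):
        amp = AmplifierParams(mean_polymer_length=180,
                              length_law="deterministic")
        out = simulate_amplification(np.array([1]), amp, seed=0)
        assert out[0] == 180.0

    def test_geometric_mean_recovery(self):
        amp = AmplifierParams(mean_polymer_length=50, length_law="geometric")
        out = simulate_amplification(np.full(1, 10_000), amp, seed=1)
        p = 1 / 50
        se = np.sqrt((1 - p) / p**2 / 10_000)
        assert abs(out[0] / 10_000 - 50.0) < 3 * se

    def test_geometric_sampler_moments(self):
        """Empirical mean/variance of 10^5 single-polymer draws match the
        closed-form 1/p and (1-p)/p^2 within 3 SE (SE from exact moments)."""
        m = 30.0
        p = 1.0 / m
        amp = AmplifierParams(mean_polymer_length=m, length_law="geometric")
        draws = simulate_amplification(np.ones(100_000, dtype=int), amp, seed=3)
        # exact central moments by direct summation of the pmf (oracle)
        k = np.arange(1, 5000)
        pmf = (1 - p) ** (k - 1) * p
        mean = (k * pmf).sum()
        var = ((k - mean) ** 2 * pmf).sum()
        mu4 = ((k - mean) ** 4 * pmf).sum()
        n = draws.size
        assert abs(draws.mean() - mean) < 3 * np.sqrt(var / n)
        se_var = np.sqrt((mu4 - var**2) / n)
        assert abs(draws.var(ddof=1) - var) < 3 * se_var

    def test_support_is_at_least_one(self):
        amp = AmplifierParams(mean_polymer_length=1.5, length_law="geometric")
        out = simulate_amplification(np.ones(10_000, dtype=int), amp, seed=0)
        assert out.min() >= 1.0

    def test_mean_length_below_one_rejected(self):
        with pytest.raises(ParameterError):
            AmplifierParams(mean_polymer_length=0.5)


# ---------------------------------------------------------------------------
# background

class TestBackground:
    def test_all_rates_zero(self):
        ch = ChannelSpec(target_id="t", background=BackgroundParams())
        bg = simulate_background((32, 32), ch, 0.16, seed=0)
        assert not bg.total.any()
        assert not bg.af.any() and not bg.nsd.any() and not bg.nsa.any()

    def test_nsd_amplifies_only_with_a_full_initiator(self):
        """Antibody NSD ~ rate x length x n_pix; split-initiator NSD stays at
        single-hairpin scale (automatic background suppression)."""
        amp = AmplifierParams(mean_polymer_length=100,
                              length_law="deterministic")
        bgp = BackgroundParams(nsd_rate=1.0)
        ab = ChannelSpec(target_id="t", probe_kind="antibody_full_initiator",
                         amplifier=amp, background=bgp)
        sp = ChannelSpec(target_id="t", probe_kind="split_initiator_pair",
                         amplifier=amp, background=bgp)
        n = 100 * 100
        bg_ab = simulate_background((100, 100), ab, 0.16, seed=0)
        bg_sp = simulate_background((100, 100), sp, 0.16, seed=0)
        se = 3 * np.sqrt(n)  # Poisson total, per unit scale
        assert abs(bg_ab.nsd.sum() - 100 * n) < 100 * se
        assert abs(bg_sp.nsd.sum() - n) < se

    def test_af_field_mean_is_preserved(self):
        ch = ChannelSpec(target_id="t",
                         background=BackgroundParams(af_mean=5.0,
                                                     af_corr_length=1.0))
        means = [simulate_background((100, 100), ch, 0.16, seed=s).af.mean()
                 for s in range(20)]
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 5.0) < 3 * se

    def test_negative_rates_rejected(self):
        with pytest.raises(ParameterError):
            BackgroundParams(nsd_rate=-1)


# ---------------------------------------------------------------------------
# optics

class TestRender:
    def test_dark_offset_only(self):
        optics = OpticsParams(psf_sigma=0, shot_noise=False, read_noise_sd=0,
                              dark_offset=100)
        img = render(np.zeros((16, 16)), optics, 0.16, seed=0)
        np.testing.assert_array_equal(img, np.full((16, 16), 100.0))

    def test_psf_conserves_total_intensity(self):
        """Convolving an isolated centred spot conserves the sum to 1e-6."""
        field = np.zeros((65, 65))
        field[32, 32] = 1000.0
        optics = OpticsParams(psf_sigma=0.5, shot_noise=False,
                              read_noise_sd=0, dark_offset=0)
        img = render(field, optics, 0.16, seed=0)
        assert abs(img.sum() - 1000.0) < 1e-6 * 1000.0

    def test_photon_scale_arithmetic(self):
        optics = OpticsParams(psf_sigma=0, photon_scale=2.0, shot_noise=False,
                              read_noise_sd=0, dark_offset=7.0)
        field = np.zeros((4, 4))
        field[1, 2] = 10.0
        img = render(field, optics, 0.16, seed=0)
        assert img[1, 2] == 10 * 2 + 7
        assert img[0, 0] == 7.0

    def test_noise_free_rendering_is_deterministic(self):
        optics = OpticsParams(psf_sigma=0.3, shot_noise=False, read_noise_sd=0)
        field = np.random.default_rng(0).random((32, 32)) * 100
        a = render(field, optics, 0.16, seed=1)
        b = render(field, optics, 0.16, seed=99)
        np.testing.assert_array_equal(a, b)

    def test_output_clipped_nonnegative(self):
        optics = OpticsParams(psf_sigma=0, shot_noise=False,
                              read_noise_sd=50.0, dark_offset=0)
        img = render(np.zeros((64, 64)), optics, 0.16, seed=0)
        assert img.min() >= 0.0


# ---------------------------------------------------------------------------
# full experiment

class TestExperiment:
    def test_redundant_pair_proportional_without_noise(self):
        amp = AmplifierParams(mean_polymer_length=100,
                              length_law="deterministic")
        ch = ChannelSpec(target_id="t", binding_efficiency=1.0, amplifier=amp)
        cfg = small_config(channels=(ch, ch))
        res = simulate_experiment(cfg)
        np.testing.assert_allclose(res.stack.channel(0), res.stack.channel(1),
                                   rtol=1e-12)

    def test_unstained_control_is_af_only(self):
        ch = ChannelSpec(target_id="t",
                         background=BackgroundParams(af_mean=10.0))
        cfg = small_config(channels=(ch,))
        res = simulate_experiment(cfg)
        # deterministic optics: the unstained render is exactly the AF field
        np.testing.assert_allclose(res.controls["unstained"].channel(0),
                                   res.backgrounds[0].af, rtol=1e-12)

    def test_bit_identical_reruns(self):
        ch = ChannelSpec(target_id="t", binding_efficiency=0.7,
                         background=BackgroundParams(af_mean=5, nsd_rate=0.1,
                                                     nsa_rate=0.1))
        cfg = small_config(seed=11, channels=(ch,),
                           law={"name": "lognormal", "mean_density": 5,
                                "sigma": 0.5},
                           optics=OpticsParams(psf_sigma=0.3, shot_noise=True,
                                               read_noise_sd=2,
                                               dark_offset=100))
        r1, r2 = simulate_experiment(cfg), simulate_experiment(cfg)
        np.testing.assert_array_equal(r1.stack.data, r2.stack.data)
        for name in r1.controls:
            np.testing.assert_array_equal(r1.controls[name].data,
                                          r2.controls[name].data)

    def test_linearity_closed_form(self):
        """Noise off, certain binding, deterministic amplification: total
        rendered intensity is affine in total molecules with slope
        p_eff x initiators_per_probe x length x fluors x photon_scale and
        intercept dark x n_pixels, to 1e-6 relative."""
        L, f, ipp, ps, dark = 40.0, 2, 3, 1.5, 10.0
        amp = AmplifierParams(mean_polymer_length=L,
                              length_law="deterministic",
                              fluors_per_hairpin=f)
        ch = ChannelSpec(target_id="t", binding_efficiency=1.0,
                         initiators_per_probe=ipp, amplifier=amp)
        cfg = small_config(
            channels=(ch,), seed=5,
            optics=OpticsParams(psf_sigma=0.3, photon_scale=ps,
                                shot_noise=False, read_noise_sd=0,
                                dark_offset=dark))
        res = simulate_experiment(cfg)
        total_mol = res.truth.molecule_counts["t"].sum()
        img = res.stack.channel(0)
        expected = total_mol * ipp * L * f * ps + dark * img.size
        assert abs(img.sum() - expected) < 1e-6 * expected
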