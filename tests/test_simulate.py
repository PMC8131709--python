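"""Synthetic mesocosm generator: spectra, tilt, echoes, dataset structure."""

import numpy as np
import pytest

from echospecies.pulse import default_frc_grid
from echospecies.simulate import (
    MesocosmDesign,
    SpeciesSpectrumModel,
    default_species_models,
    draw_response_effect,
    identical_species_models,
    logistic_amplitude,
    orientation_tilt,
    simulate_echo,
    simulate_mesocosm_dataset,
    simulate_species_spectrum,
    smooth_gaussian_field,
)


@pytest.fixture()
def noise_free_model():
    base = default_species_models()["whitefish"]
    return SpeciesSpectrumModel(
        species="whitefish",
        mean_logit_amplitude=base.mean_logit_amplitude,
        inter_sd=0.0,
        intra_sd=0.0,
    )


class TestSpeciesSpectrum:
    def test_noise_free_identity(self, noise_free_model, grid):
        rng = np.random.default_rng(0)
        curve = simulate_species_spectrum(noise_free_model, rng, 0.0, grid)
        np.testing.assert_array_equal(
            curve, noise_free_model.mean_logit_amplitude(grid)
        )

    def test_fish_effect_reused_across_responses(self, grid):
        model = default_species_models()["stickleback"]
        rng = np.random.default_rng(1)
        effect = model.inter_sd * model.inter_profile(grid) * smooth_gaussian_field(
            rng, grid, model.smoothness_scale
        )
        c1 = simulate_species_spectrum(model, rng, 10.0, grid, fish_effect=effect)
        c2 = simulate_species_spectrum(model, rng, 10.0, grid, fish_effect=effect)
        np.testing.assert_array_equal(c1, c2)

    def test_angle_out_of_range_rejected(self, noise_free_model, grid):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="orientation"):
            simulate_species_spectrum(noise_free_model, rng, 95.0, grid)

    def test_species_divergence_concentrated_in_high_band(self, grid):
        models = default_species_models()
        diff = np.abs(
            models["stickleback"].mean_logit_amplitude(grid)
            - models["whitefish"].mean_logit_amplitude(grid)
        )
        high = (grid >= 135e3) & (grid <= 170e3)
        low = (grid >= 90e3) & (grid <= 120e3)
        assert diff[high].max() > diff[low].max()

    def test_identical_models_share_distribution(self, grid):
        models = identical_species_models()
        a, b = models["stickleback"], models["whitefish"]
        np.testing.assert_array_equal(
            a.mean_logit_amplitude(grid), b.mean_logit_amplitude(grid)
        )
        assert (a.inter_sd, a.intra_sd) == (b.inter_sd, b.intra_sd)


class TestOrientationTilt:
    def test_band_energy_ratio_strictly_decreasing_in_angle(self, noise_free_model, grid):
        high = (grid >= 140e3) & (grid <= 170e3)
        low = (grid >= 90e3) & (grid <= 120e3)
        rng = np.random.default_rng(0)
        ratios = []
        for angle in np.linspace(0.0, 90.0, 10):
            amp = logistic_amplitude(
                simulate_species_spectrum(noise_free_model, rng, angle, grid)
            )
            ratios.append(amp[high].sum() / amp[low].sum())
        assert np.all(np.diff(ratios) < 0)

    def test_zero_angle_is_no_tilt(self, grid):
        np.testing.assert_array_equal(orientation_tilt(0.0, grid), np.zeros(grid.size))


class TestSimulateEcho:
    def test_flat_target_is_delayed_scaled_chirp(self, chirp_config, replica):
        # range chosen so the two-way delay is an integer number of samples
        echo = simulate_echo(chirp_config, np.ones(656), range_m=1.45)
        fs = chirp_config.sample_rate
        i0 = int(round(2 * 1.45 / 1450.0 * fs))
        segment = echo.samples[i0 : i0 + replica.size]
        scale = np.dot(segment, replica) / np.dot(replica, replica)
        residual = segment - scale * replica
        assert np.sqrt(np.mean(residual**2)) < 0.02 * np.abs(segment).max()

    def test_zero_noise_is_deterministic(self, chirp_config):
        spectrum = np.linspace(1.0, 0.4, 656)
        e1 = simulate_echo(chirp_config, spectrum, range_m=3.0)
        e2 = simulate_echo(chirp_config, spectrum, range_m=3.0)
        np.testing.assert_array_equal(e1.samples, e2.samples)

    def test_nonpositive_range_rejected(self, chirp_config):
        with pytest.raises(ValueError, match="range"):
            simulate_echo(chirp_config, np.ones(656), range_m=0.0)


class TestMesocosmDataset:
    def test_replication_counts(self, frc_table):
        train = frc_table[frc_table["day"].isin((1, 3))]
        test = frc_table[frc_table["day"] == 2]
        assert len(train) == 1400
        assert len(test) == 470

    def test_ten_responses_per_fish(self, frc_table):
        assert (frc_table.groupby("fish_id").size() == 10).all()

    def test_each_fish_has_a_track(self, frc_table, tracks):
        assert {t.fish_id for t in tracks} == set(frc_table["fish_id"])
        for track in tracks:
            assert track.positions.shape[0] >= 2

    def test_identical_seed_bit_identical(self):
        design = MesocosmDesign(
            n_train_stickleback=3, n_train_whitefish=3,
            n_test_stickleback=2, n_test_whitefish=2, seed=9,
        )
        t1, _ = simulate_mesocosm_dataset(design)
        t2, _ = simulate_mesocosm_dataset(design)
        assert t1.equals(t2)

    def test_zero_variation_gives_identical_curves_within_species(self, grid):
        models = {
            sp: SpeciesSpectrumModel(
                species=sp,
                mean_logit_amplitude=m.mean_logit_amplitude,
                inter_sd=0.0,
                intra_sd=0.0,
                tilt_strength=0.0,
            )
            for sp, m in default_species_models().items()
        }
        design = MesocosmDesign(
            n_train_stickleback=3, n_train_whitefish=3,
            n_test_stickleback=1, n_test_whitefish=1,
            seed=4, acoustic_chain=False,
        )
        table, _ = simulate_mesocosm_dataset(design, models)
        amp_cols = [c for c in table.columns if c.startswith("a_")]
        for _, sub in table.groupby("species"):
            values = sub[amp_cols].to_numpy()
            assert np.allclose(values, values[0], atol=1e-12)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MesocosmDesign(n_train_stickleback=0)
        with pytest.raises(ValueError, match="sum to 1"):
            MesocosmDesign(orientation_mixture={"stickleback": (0.5, 0.1, 0.1),
                                                "whitefish": (0.6, 0.3, 0.1)})

    def test_response_effect_varies_per_response(self, grid):
        model = default_species_models()["whitefish"]
        rng = np.random.default_rng(2)
        e1 = draw_response_effect(model, rng, grid)
        e2 = draw_response_effect(model, rng, grid)
        assert not np.allclose(e1, e2)
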