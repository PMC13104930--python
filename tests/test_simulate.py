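"""Fingerprint simulator: mixture classes, forward model, noise calibration."""

import numpy as np
import pytest

import paf
from paf.simulate import (
    ANATOMICAL_CLASSES,
    CLASS_ORDER,
    MIXTURE_CLASSES,
    MixtureClass,
    SimConfig,
    SimulatedDataset,
    add_noise,
    clean_fingerprint,
    fluence_profile,
    generate_dataset,
    normalize_max,
    sample_concentrations,
    snr_scale,
    structural_class,
)


@pytest.fixture(scope="module")
def draws(lib):
    rng = np.random.default_rng(7)
    return {
        cls: sample_concentrations(cls, 2000, rng, n_chromophores=5)
        for cls in CLASS_ORDER
    }


class TestConcentrationSampling:
    @pytest.mark.parametrize("cls", CLASS_ORDER, ids=lambda c: c.value)
    def test_simplex(self, draws, cls):
        C = draws[cls]
        np.testing.assert_allclose(C.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(C >= 0)

    def test_pure_is_one_hot(self, draws):
        C = draws[MixtureClass.PURE]
        assert np.all(C.max(axis=1) == 1.0)
        assert np.all((C > 0).sum(axis=1) == 1)

    def test_extreme_dominant_ranges(self, draws):
        m = draws[MixtureClass.EXTREME].max(axis=1)
        assert np.all((m >= 0.90) & (m <= 0.99))
        m = draws[MixtureClass.DOMINANT].max(axis=1)
        assert np.all((m >= 0.70) & (m <= 0.90))

    def test_binary_support_and_floor(self, draws):
        C = draws[MixtureClass.BINARY]
        nz = C > 0
        assert np.all(nz.sum(axis=1) == 2)
        assert np.all(C[nz] > 0.01)

    def test_anatomical_dominant_group_ranges(self, draws):
        hb = draws[MixtureClass.VESSEL_LIKE][:, 0] + draws[MixtureClass.VESSEL_LIKE][:, 1]
        assert np.all((hb >= 0.7) & (hb <= 1.0))
        assert np.all(draws[MixtureClass.FAT_DOMINANT][:, 2] >= 0.6)
        assert np.all(draws[MixtureClass.COLLAGEN_RICH][:, 4] >= 0.5)
        assert np.all(draws[MixtureClass.BACKGROUND][:, 3] >= 0.7)

    def test_vessel_like_arterial_oxygenation_bias(self, draws):
        C = draws[MixtureClass.VESSEL_LIKE]
        s = C[:, 0] / (C[:, 0] + C[:, 1])
        assert np.all(s >= 0.5)

    def test_structural_classification(self):
        assert structural_class(np.array([0, 1.0, 0, 0, 0])) is MixtureClass.PURE
        assert structural_class(np.array([0.6, 0.4, 0, 0, 0])) is MixtureClass.BINARY
        assert structural_class(np.array([0.95, 0.02, 0.01, 0.01, 0.01])) is MixtureClass.EXTREME
        assert structural_class(np.array([0.8, 0.05, 0.05, 0.05, 0.05])) is MixtureClass.DOMINANT
        assert structural_class(np.array([0.3, 0.3, 0.2, 0.1, 0.1])) is MixtureClass.RANDOM


class TestFluenceProfile:
    def test_zero_severity_is_unity(self, lib):
        np.testing.assert_array_equal(fluence_profile(0.0, lib.grid), 1.0)

    def test_longest_wavelength_unattenuated(self, lib):
        for x in (0.5, 5.0, 20.0):
            assert fluence_profile(x, lib.grid)[-1] == pytest.approx(1.0)

    def test_shortest_wavelength_at_max_severity(self, lib):
        phi = fluence_profile(20.0, lib.grid)
        assert phi[0] == pytest.approx(np.exp(-20.0), rel=1e-12)
        assert phi[0] == pytest.approx(2.061e-9, rel=1e-3)

    def test_monotone_in_wavelength_and_severity(self, lib):
        prev = None
        for x in np.linspace(0, 20, 9):
            phi = fluence_profile(x, lib.grid)
            assert np.all(np.diff(phi) >= 0)
            if prev is not None:
                assert np.all(phi <= prev + 1e-15)
            prev = phi

    def test_negative_severity_rejected(self, lib):
        with pytest.raises(ValueError):
            fluence_profile(-1.0, lib.grid)


class TestForwardModel:
    def test_pure_equals_library_column(self, lib):
        c = np.zeros(5)
        c[2] = 1.0
        f = clean_fingerprint(c, lib)
        np.testing.assert_array_equal(f.amplitudes, lib.matrix[:, 2])

    def test_linearity_half_half(self, lib):
        c = np.array([0.5, 0.5, 0, 0, 0.0])
        f = clean_fingerprint(c, lib)
        np.testing.assert_allclose(
            f.amplitudes, 0.5 * (lib.matrix[:, 0] + lib.matrix[:, 1])
        )

    def test_fluence_scales_elementwise(self, lib, rng):
        c = rng.dirichlet(np.ones(5))
        half = np.full(53, 0.5)
        f = clean_fingerprint(c, lib, half)
        np.testing.assert_allclose(f.amplitudes, 0.5 * (lib.matrix @ c))

    def test_dimension_mismatch(self, lib):
        with pytest.raises(ValueError):
            clean_fingerprint(np.ones(4) / 4, lib)


class TestNoise:
    def test_alpha_solves_power_equation(self):
        # all-ones fingerprint: P_s = 1, so alpha = sqrt(10^(20/10)) = 10
        assert snr_scale(np.ones(53), 20.0) == pytest.approx(10.0)

    def test_realized_snr_calibrated(self, lib, rng):
        # Monte-Carlo realised SNR within 0.2 dB of target
        C = sample_concentrations(MixtureClass.RANDOM, 10_000, rng)
        f0 = C @ lib.matrix.T
        for target in (5.0, 10.0, 20.0, 40.0):
            alpha = snr_scale(f0, target)
            eps = rng.standard_normal(f0.shape)
            realized = 10 * np.log10(
                np.mean((alpha[:, None] * f0) ** 2, axis=1) / np.mean(eps**2, axis=1)
            )
            assert abs(realized.mean() - target) < 0.2

    def test_high_snr_limit_preserves_shape(self, lib, rng):
        c = rng.dirichlet(np.ones(5))
        f0 = clean_fingerprint(c, lib)
        noisy = add_noise(f0, 120.0, rng)
        alpha = snr_scale(f0.amplitudes, 120.0)
        np.testing.assert_allclose(noisy.amplitudes, alpha * f0.amplitudes, rtol=1e-4)

    def test_all_zero_rejected(self, lib, rng):
        f = paf.Fingerprint(np.zeros(53), lib.grid)
        with pytest.raises(ValueError):
            add_noise(f, 20.0, rng)

    def test_metadata_records_snr(self, lib, rng):
        f0 = clean_fingerprint(np.array([1.0, 0, 0, 0, 0]), lib)
        assert add_noise(f0, 17.0, rng).snr_db == 17.0


class TestNormalizeMax:
    def test_divides_by_max(self, lib):
        f = paf.Fingerprint(np.array([2.0, 4.0, 8.0] + [1.0] * 50), lib.grid)
        out = normalize_max(f)
        assert out.amplitudes[2] == 1.0
        assert out.amplitudes[0] == 0.25 and out.amplitudes[1] == 0.5
        assert out.normalized

    def test_idempotent(self, lib, rng):
        f = paf.Fingerprint(rng.uniform(0.1, 3.0, 53), lib.grid)
        once = normalize_max(f)
        twice = normalize_max(once)
        np.testing.assert_array_equal(once.amplitudes, twice.amplitudes)

    def test_negative_entries_allowed(self, lib, rng):
        amps = rng.normal(0, 1, 53)
        amps[10] = 2.0
        out = normalize_max(paf.Fingerprint(amps, lib.grid))
        assert out.amplitudes.max() == 1.0
        assert np.all(out.amplitudes <= 1.0)
        assert np.any(out.amplitudes < 0)

    def test_all_zero_rejected(self, lib):
        with pytest.raises(ValueError):
            normalize_max(paf.Fingerprint(np.zeros(53), lib.grid))


class TestGenerateDataset:
    def test_composition_counts(self, lib):
        ds = generate_dataset(SimConfig(size=1000), lib, seed=3)
        assert len(ds) == 1000
        for cls in MIXTURE_CLASSES:
            assert ds.class_mask(cls).sum() == 100
        for cls in ANATOMICAL_CLASSES:
            assert ds.class_mask(cls).sum() == 125

    def test_unit_fluence_mode(self, lib):
        ds = generate_dataset(SimConfig(size=200, fluence_mode="unit"), lib, seed=3)
        assert np.all(ds.fluence_x == 0.0)

    def test_seed_reproducibility(self, lib):
        cfg = SimConfig(size=500, fluence_mode="random")
        a = generate_dataset(cfg, lib, seed=42)
        b = generate_dataset(cfg, lib, seed=42)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)
        np.testing.assert_array_equal(a.concentrations, b.concentrations)
        c = generate_dataset(cfg, lib, seed=43)
        assert not np.array_equal(a.amplitudes, c.amplitudes)

    def test_noiseless_pure_records_equal_columns(self, lib):
        cfg = SimConfig(
            size=50,
            class_proportions={MixtureClass.PURE: 1.0},
            snr_range_db=None,
        )
        ds = generate_dataset(cfg, lib, seed=5)
        for i in range(len(ds)):
            j = int(ds.concentrations[i].argmax())
            np.testing.assert_array_equal(ds.amplitudes[i], lib.matrix[:, j])

    def test_invalid_proportions_rejected(self, lib):
        cfg = SimConfig(size=10, class_proportions={MixtureClass.PURE: 0.5})
        with pytest.raises(ValueError, match="proportions"):
            generate_dataset(cfg, lib, seed=0)

    def test_config_yaml_round_trip(self, lib, tmp_path):
        cfg = SimConfig(size=64, fluence_mode="random", snr_range_db=(5.0, 30.0))
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = SimConfig.from_yaml(tmp_path / "sim.yaml")
        assert back == cfg
        a = generate_dataset(cfg, lib, seed=4)
        b = generate_dataset(back, lib, seed=4)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    def test_csv_export_columns(self, lib, tmp_path):
        import pandas as pd

        ds = generate_dataset(SimConfig(size=20), lib, seed=2)
        ds.to_csv(tmp_path / "ds.csv")
        df = pd.read_csv(tmp_path / "ds.csv")
        assert len(df) == 20
        assert "amp_700nm" in df.columns and "true_collagen" in df.columns
        assert set(df["mixture_class"]) <= {c.value for c in CLASS_ORDER}

    def test_hdf5_round_trip(self, lib, tmp_path):
        ds = generate_dataset(SimConfig(size=200, fluence_mode="random"), lib, seed=9)
        p = tmp_path / "ds.h5"
        ds.to_hdf5(p)
        back = SimulatedDataset.from_hdf5(p)
        np.testing.assert_array_equal(back.amplitudes, ds.amplitudes)
        np.testing.assert_array_equal(back.concentrations, ds.concentrations)
        np.testing.assert_array_equal(back.mixture_class, ds.mixture_class)
        assert back.seed == ds.seed
        assert back.library_hash == ds.library_hash
        assert back.grid.band_edges == ds.grid.band_edges
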