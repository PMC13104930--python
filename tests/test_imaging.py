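"""Image pipeline: energy normalization, MAP projection, per-pixel unmixing."""

import numpy as np
import pandas as pd
import pytest

import paf
from paf.imaging import (
    MultispectralStack,
    energy_normalize,
    fold_change,
    load_stack_tiff,
    map_projection,
    read_pulse_energies,
    region_stats,
    unmix_image,
)
from paf.library import SpectralLibrary
from paf.synthetic import five_region_phantom


@pytest.fixture(scope="module")
def phantom(lib):
    stack_data, labels, comps = five_region_phantom(lib, snr_db=None, seed=0)
    return MultispectralStack(stack_data, lib.grid), labels, comps


class TestEnergyNormalize:
    def test_frame_divided_by_energy(self, lib, rng):
        data = rng.uniform(1, 2, (53, 8, 8))
        energies = np.ones(53)
        energies[7] = 2.0
        stack = MultispectralStack(data, lib.grid, pulse_energy=energies)
        out = energy_normalize(stack)
        np.testing.assert_allclose(out.data[7], data[7] / 2.0)
        np.testing.assert_allclose(out.data[0], data[0])

    def test_uniform_energies_global_constant(self, lib, rng):
        data = rng.uniform(1, 2, (53, 4, 4))
        stack = MultispectralStack(data, lib.grid, pulse_energy=np.full(53, 4.0))
        out = energy_normalize(stack)
        np.testing.assert_allclose(out.data, data / 4.0)

    def test_idempotent_after_first_application(self, lib, rng):
        data = rng.uniform(1, 2, (53, 4, 4))
        stack = MultispectralStack(data, lib.grid, pulse_energy=rng.uniform(0.5, 2, 53))
        once = energy_normalize(stack)
        twice = energy_normalize(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_missing_or_bad_energy_rejected(self, lib, rng):
        data = rng.uniform(1, 2, (53, 4, 4))
        with pytest.raises(ValueError):
            energy_normalize(MultispectralStack(data, lib.grid))
        with pytest.raises(ValueError):
            MultispectralStack(data, lib.grid, pulse_energy=np.zeros(53))

    def test_energy_table_round_trip(self, lib, tmp_path, rng):
        energies = rng.uniform(0.5, 2.0, 53)
        pd.DataFrame(
            {"wavelength_nm": lib.grid.wavelengths_nm, "energy_mj": energies}
        ).to_csv(tmp_path / "e.csv", index=False)
        out = read_pulse_energies(tmp_path / "e.csv", lib.grid)
        np.testing.assert_allclose(out, energies)


class TestMapProjection:
    def test_single_slice_identity(self, lib, rng):
        vol = rng.uniform(0, 1, (53, 1, 6, 6))
        out = map_projection(MultispectralStack(vol, lib.grid))
        np.testing.assert_array_equal(out.data, vol[:, 0])

    def test_ramp_max_is_last_slice(self, lib):
        vol = np.broadcast_to(
            np.arange(4.0)[None, :, None, None], (53, 4, 5, 5)
        ).copy()
        out = map_projection(MultispectralStack(vol, lib.grid))
        np.testing.assert_array_equal(out.data, vol[:, -1])

    def test_commutes_with_positive_scaling(self, lib, rng):
        vol = rng.uniform(0, 1, (53, 3, 4, 4))
        scale = rng.uniform(0.5, 2.0, 53)[:, None, None, None]
        a = map_projection(MultispectralStack(vol * scale, lib.grid)).data
        b = map_projection(MultispectralStack(vol, lib.grid)).data * scale[:, :, 0, :]
        np.testing.assert_allclose(a, b.reshape(a.shape))

    def test_2d_stack_rejected(self, lib, rng):
        flat = MultispectralStack(rng.uniform(0, 1, (53, 4, 4)), lib.grid)
        with pytest.raises(ValueError):
            map_projection(flat)


class TestUnmixImage:
    def test_noiseless_phantom_nnls_exact_per_region(self, lib, phantom):
        stack, labels, comps = phantom
        cmap = unmix_image(stack, lib, method="nnls")
        for idx, (name, c_true) in enumerate(comps.items(), start=1):
            m = (labels == idx) & cmap.mask
            assert m.any()
            for j in range(5):
                np.testing.assert_allclose(cmap.fractions[j][m], c_true[j], atol=1e-6)

    def test_background_masked(self, lib, phantom):
        stack, labels, _ = phantom
        cmap = unmix_image(stack, lib, method="nnls")
        assert not cmap.mask[labels == 0].any()
        assert np.all(np.isnan(cmap.fractions[:, ~cmap.mask]))

    def test_so2_in_unit_interval_where_defined(self, lib, phantom):
        stack, _, _ = phantom
        cmap = unmix_image(stack, lib, method="nnls")
        vals = cmap.so2[np.isfinite(cmap.so2)]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_chromophore_relabeling_permutes_channels(self, lib, phantom):
        stack, _, _ = phantom
        perm = [2, 0, 4, 1, 3]
        plib = SpectralLibrary(
            lib.grid,
            tuple(lib.chromophore_names[i] for i in perm),
            lib.matrix[:, perm],
        )
        a = unmix_image(stack, lib, method="nnls")
        b = unmix_image(stack, plib, method="nnls")
        for k, name in enumerate(plib.chromophore_names):
            np.testing.assert_allclose(
                b.fractions[k][b.mask], a.channel(name)[a.mask], atol=1e-9
            )

    def test_grid_mismatch_rejected(self, lib, phantom, rng):
        stack, _, _ = phantom
        sub = lib.subset(np.arange(0, 53, 2))
        with pytest.raises(ValueError, match="grid"):
            unmix_image(stack, sub)

    def test_unfitted_model_rejected(self, lib, phantom):
        stack, _, _ = phantom
        with pytest.raises(RuntimeError):
            unmix_image(stack, lib, method=paf.PAFRegressor())


class TestRegionStats:
    def test_constant_region_stats(self, lib, phantom):
        stack, labels, comps = phantom
        cmap = unmix_image(stack, lib, method="nnls")
        stats = region_stats(cmap, labels)
        water = stats.loc[5]  # pure-water droplet region
        assert water["water_mean"] == pytest.approx(0.95, abs=1e-6)
        assert water["water_sd"] == pytest.approx(0.0, abs=1e-6)

    def test_rois_independent(self, lib, phantom):
        stack, labels, _ = phantom
        cmap = unmix_image(stack, lib, method="nnls")
        both = region_stats(cmap, labels)
        only1 = region_stats(cmap, np.where(labels == 1, 1, 0))
        for col in both.columns:
            assert both.loc[1, col] == pytest.approx(only1.loc[1, col], nan_ok=True)

    def test_fold_change_ratio(self, lib, phantom):
        stack, labels, _ = phantom
        cmap = unmix_image(stack, lib, method="nnls")
        stats = region_stats(cmap, labels)
        fc = fold_change(stats, 3, 4, "lipid")  # lipid-rich vs collagen+water
        assert fc == pytest.approx(0.90 / 0.05, rel=1e-4)

    def test_empty_roi_rejected(self, lib, phantom):
        stack, labels, _ = phantom
        cmap = unmix_image(stack, lib, method="nnls")
        rois = np.zeros_like(labels)
        rois[0, 0] = 9  # background pixel only -> masked
        with pytest.raises(ValueError, match="ROI 9"):
            region_stats(cmap, rois)


class TestTiffIO:
    def test_stack_round_trip(self, lib, tmp_path, rng):
        import tifffile

        data = rng.uniform(0, 1, (53, 6, 6)).astype(np.float32)
        tifffile.imwrite(tmp_path / "s.tif", data)
        stack = load_stack_tiff(tmp_path / "s.tif", lib.grid)
        np.testing.assert_allclose(stack.data, data)
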