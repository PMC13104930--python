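"""Synthetic spectral libraries and imaging phantoms.

The literature absorption tables behind a real photoacoustic spectral library
are distributed by their original compilations and are not shipped here.  For
self-contained simulation and testing this module generates smooth synthetic
spectra as sums of Gaussians in wavelength.  The default five-chromophore
library mirrors the qualitative near-infrared features practitioners rely on:
the deoxyhemoglobin peak near 760 nm, the slow rise of oxyhemoglobin towards
900 nm, the lipid peak near 1210 nm, the water overtone near 970 nm with a
strong rise towards 1450 nm, and a broad collagen band overlapping both lipid
and water.  The collagen/lipid/water overlap is deliberate: it is the regime
where linear unmixing struggles most.

A generic generator with a controllable pairwise-overlap parameter is also
provided for stress tests, along with a five-region imaging phantom that
emulates a multi-component phantom scan (blood tubes, butter, collagen
droplet, water droplet) forward-modelled through a library at configurable
SNR and fluence.
"""

from __future__ import annotations

import numpy as np

from .library import (
    CHROMOPHORES,
    AbsorptionSpectrum,
    SpectralLibrary,
    WavelengthGrid,
    build_library,
    default_grid,
)

# (center nm, width nm, height) Gaussian components per chromophore, plus a
# small positive baseline so absorption never vanishes entirely.  The shared
# broad components are intentional: the two hemoglobins share most of their
# NIR shape and differ mainly around the 760 nm deoxy peak, while lipid,
# water and collagen share broad idle-band absorption — the collinearity
# structure that makes real spectral unmixing ill-conditioned.
_DEFAULT_COMPONENTS = {
    "HbO2": [(880.0, 150.0, 0.60), (1030.0, 120.0, 0.25), (740.0, 50.0, 0.08)],
    "HbR": [(760.0, 50.0, 0.55), (880.0, 150.0, 0.45), (1030.0, 120.0, 0.15)],
    "lipid": [(1210.0, 45.0, 0.85), (1250.0, 150.0, 0.35), (930.0, 40.0, 0.18),
              (1390.0, 70.0, 0.22)],
    "water": [(970.0, 50.0, 0.35), (1440.0, 90.0, 1.10), (1190.0, 80.0, 0.28),
              (1250.0, 150.0, 0.30)],
    "collagen": [(1200.0, 80.0, 0.65), (1250.0, 150.0, 0.30), (1030.0, 80.0, 0.28),
                 (1340.0, 100.0, 0.40)],
}
_BASELINE = 0.03
_SUPPORT_NM = (640.0, 1460.0, 2.0)  # native tabulation: start, stop, step


def _gaussian_sum(wl: np.ndarray, components) -> np.ndarray:
    out = np.full_like(wl, _BASELINE, dtype=float)
    for center, width, height in components:
        out += height * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def synthetic_spectrum(name: str) -> AbsorptionSpectrum:
    """One of the five built-in synthetic chromophore spectra, densely tabulated."""
    start, stop, step = _SUPPORT_NM
    wl = np.arange(start, stop + step / 2, step)
    return AbsorptionSpectrum(name, wl, _gaussian_sum(wl, _DEFAULT_COMPONENTS[name]))


def synthetic_library(grid: WavelengthGrid | None = None) -> SpectralLibrary:
    """The default five-chromophore synthetic library on the dual-band grid."""
    if grid is None:
        grid = default_grid()
    return build_library([synthetic_spectrum(n) for n in CHROMOPHORES], grid)


def random_overlap_spectra(
    n: int,
    overlap: float = 0.3,
    rng: np.random.Generator | None = None,
    support_nm: tuple[float, float] = (640.0, 1460.0),
) -> list[AbsorptionSpectrum]:
    """Random smooth spectra whose pairwise spectral overlap grows with `overlap`.

    Peak centers are spread evenly across the support with random jitter; the
    Gaussian widths scale from narrow (overlap=0, nearly orthogonal columns)
    to broad (overlap=1, strongly correlated columns).
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    lo, hi = support_nm
    wl = np.arange(lo, hi + 1.0, 2.0)
    margin = 0.1 * (hi - lo)
    centers = np.linspace(lo + margin, hi - margin, n)
    spacing = (hi - lo - 2 * margin) / max(n - 1, 1)
    spectra = []
    for i, c0 in enumerate(centers):
        center = c0 + rng.uniform(-0.2, 0.2) * spacing
        width = spacing * (0.15 + 1.6 * overlap) * rng.uniform(0.8, 1.2)
        height = rng.uniform(0.6, 1.4)
        comps = [(center, width, height)]
        # secondary shoulder to keep shapes non-trivial
        comps.append((center + rng.uniform(-1.5, 1.5) * spacing, width * 1.5, 0.3 * height))
        spectra.append(AbsorptionSpectrum(f"chr{i}", wl, _gaussian_sum(wl, comps)))
    return spectra


# ---------------------------------------------------------------------------
# Imaging phantom

#: Region label -> (ground-truth concentration over CHROMOPHORES order)
PHANTOM_COMPOSITIONS = {
    "HbO2_rich": np.array([0.90, 0.05, 0.00, 0.05, 0.00]),
    "HbR_rich": np.array([0.05, 0.90, 0.00, 0.05, 0.00]),
    "lipid": np.array([0.00, 0.00, 0.90, 0.05, 0.05]),
    "collagen_water": np.array([0.00, 0.00, 0.05, 0.40, 0.55]),
    "water": np.array([0.00, 0.00, 0.00, 0.95, 0.05]),
}


def five_region_phantom(
    lib: SpectralLibrary,
    shape: tuple[int, int] = (48, 48),
    snr_db: float | None = 10.0,
    fluence_x: float = 0.0,
    seed: int | None = 0,
):
    """Synthetic five-region multispectral phantom image.

    Returns ``(stack, labels, compositions)`` where ``stack`` is a
    (K, H, W) array of per-wavelength images, ``labels`` an integer image
    (0 = background, 1..5 = regions in ``PHANTOM_COMPOSITIONS`` order) and
    ``compositions`` the dict of ground-truth concentration vectors.

    Each in-region pixel is the clean forward-model fingerprint of its
    region's composition under the given fluence severity, noise-corrupted at
    ``snr_db`` (per-pixel, the same calibration used for training data).
    Background pixels carry no signal.
    """
    from .simulate import add_noise_array, clean_fingerprint_array, fluence_profile

    rng = np.random.default_rng(seed)
    H, W = shape
    K = lib.n_wavelengths
    labels = np.zeros(shape, dtype=int)
    names = list(PHANTOM_COMPOSITIONS)
    # five disks on a 2x3 layout
    centers = [
        (H // 4, W // 6), (H // 4, W // 2), (H // 4, 5 * W // 6),
        (3 * H // 4, W // 4), (3 * H // 4, 3 * W // 4),
    ]
    radius = min(H, W) // 8
    yy, xx = np.mgrid[0:H, 0:W]
    for idx, (cy, cx) in enumerate(centers, start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = idx

    phi = fluence_profile(fluence_x, lib.grid)
    stack = np.zeros((K, H, W))
    for idx, name in enumerate(names, start=1):
        c = PHANTOM_COMPOSITIONS[name]
        f0 = clean_fingerprint_array(c, lib, phi)
        mask = labels == idx
        n_pix = int(mask.sum())
        if snr_db is None:
            pix = np.tile(f0, (n_pix, 1))
        else:
            pix = add_noise_array(np.tile(f0, (n_pix, 1)), np.full(n_pix, float(snr_db)), rng)
        stack[:, mask] = pix.T
    return stack, labels, {n: PHANTOM_COMPOSITIONS[n].copy() for n in names}
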