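"""End-to-end unmixing of multispectral photoacoustic image stacks.

A stack holds one image (or one volume) per wavelength.  The pipeline:
divide each wavelength frame by its pulse energy (removing pulse-to-pulse
laser fluctuations), optionally collapse the depth axis by maximum amplitude
projection (MAP), extract a fingerprint per pixel, and unmix it with either
the recurrent model (max-normalised input) or NNLS (raw energy-normalised
input).  Pixels whose peak amplitude falls below a relative threshold, or
containing non-finite values, are masked rather than unmixed.  Oxygen
saturation sO2 = HbO2 / (HbO2 + HbR) is derived at every unmasked pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import CHROMOPHORES, SpectralLibrary, WavelengthGrid
from .metrics import so2 as _so2
from .model import PAFRegressor
from .nnls import NNLSUnmixer


@dataclass
class MultispectralStack:
    """Per-wavelength image data, (K, Z, Y, X) volumes or (K, Y, X) planes."""

    data: np.ndarray
    grid: WavelengthGrid
    pulse_energy: np.ndarray | None = None
    pixel_size_mm: float | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim not in (3, 4):
            raise ValueError("stack must be (K, Y, X) or (K, Z, Y, X)")
        if data.shape[0] != len(self.grid):
            raise ValueError(
                f"wavelength axis {data.shape[0]} does not match grid K={len(self.grid)}"
            )
        if self.pulse_energy is not None:
            pe = np.asarray(self.pulse_energy, dtype=float)
            if pe.shape != (data.shape[0],):
                raise ValueError("one pulse energy per wavelength is required")
            if np.any(~np.isfinite(pe)) or np.any(pe <= 0):
                raise ValueError("pulse energies must be finite and positive")
            self.pulse_energy = pe
        self.data = data

    @property
    def is_volume(self) -> bool:
        return self.data.ndim == 4


def load_stack_tiff(
    path: str | Path,
    grid: WavelengthGrid,
    energy_csv: str | Path | None = None,
) -> MultispectralStack:
    """Read a TIFF whose first axis is wavelength; optionally attach energies."""
    import tifffile

    data = np.asarray(tifffile.imread(path), dtype=float)
    energies = read_pulse_energies(energy_csv, grid) if energy_csv else None
    return MultispectralStack(data, grid, pulse_energy=energies)


def read_pulse_energies(path: str | Path, grid: WavelengthGrid) -> np.ndarray:
    """Per-wavelength pulse-energy table (CSV: wavelength_nm, energy)."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    wl = df[cols[0]].to_numpy(float)
    en = df[cols[1]].to_numpy(float)
    out = np.empty(len(grid))
    for i, w in enumerate(grid.wavelengths_nm):
        m = np.isclose(wl, w)
        if not m.any():
            raise ValueError(f"no pulse energy tabulated for {w:g} nm")
        out[i] = en[np.argmax(m)]
    return out


def energy_normalize(stack: MultispectralStack) -> MultispectralStack:
    """Divide each wavelength frame by its pulse energy; idempotent afterwards."""
    if stack.pulse_energy is None:
        raise ValueError("stack carries no pulse-energy table")
    shape = (-1,) + (1,) * (stack.data.ndim - 1)
    data = stack.data / stack.pulse_energy.reshape(shape)
    return MultispectralStack(
        data, stack.grid, pulse_energy=np.ones_like(stack.pulse_energy),
        pixel_size_mm=stack.pixel_size_mm,
    )


def map_projection(stack: MultispectralStack) -> MultispectralStack:
    """Maximum amplitude projection over the depth axis, per wavelength."""
    if not stack.is_volume:
        raise ValueError("MAP projection requires a (K, Z, Y, X) volume")
    if stack.data.shape[1] == 0:
        raise ValueError("empty depth axis")
    return MultispectralStack(
        stack.data.max(axis=1), stack.grid, pulse_energy=stack.pulse_energy,
        pixel_size_mm=stack.pixel_size_mm,
    )


@dataclass
class ConcentrationMap:
    """Per-pixel chromophore fractions, derived sO2, and the validity mask."""

    fractions: np.ndarray  # (N, Y, X)
    so2: np.ndarray  # (Y, X), NaN where undefined or masked
    mask: np.ndarray  # (Y, X) bool, True where unmixed
    method: str
    chromophore_names: tuple[str, ...] = CHROMOPHORES
    amplitude_threshold: float = 0.05
    extras: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return self.fractions[list(self.chromophore_names).index(name)]


def unmix_image(
    stack: MultispectralStack,
    lib: SpectralLibrary,
    method: str | PAFRegressor = "nnls",
    amplitude_threshold: float = 0.05,
) -> ConcentrationMap:
    """Per-pixel spectral unmixing of a 2D multispectral stack.

    ``method`` is either the string ``"nnls"`` or a fitted
    :class:`~paf.model.PAFRegressor`.  The model path max-normalises each
    pixel's fingerprint internally; NNLS consumes the raw vector and its
    fractions are renormalised.  Pixels with peak amplitude below
    ``amplitude_threshold`` (relative to the stack maximum) are masked.
    """
    if stack.is_volume:
        raise ValueError("run map_projection first: unmix_image expects (K, Y, X)")
    if not np.array_equal(stack.grid.wavelengths_nm, lib.grid.wavelengths_nm):
        raise ValueError("stack and library wavelength grids differ")
    K, H, W = stack.data.shape
    pixels = stack.data.reshape(K, -1).T  # (H*W, K)
    finite = np.all(np.isfinite(pixels), axis=1)
    peak = pixels.max(axis=1)
    global_max = peak[finite].max() if finite.any() else 0.0
    with np.errstate(invalid="ignore"):
        valid = finite & (peak >= amplitude_threshold * global_max) & (peak > 0)

    N = lib.n_chromophores
    fractions = np.full((H * W, N), np.nan)
    if valid.any():
        if isinstance(method, PAFRegressor):
            fractions[valid] = method.predict(
                pixels[valid], wavelengths=stack.grid.wavelengths_nm
            )
            tag = "PAF"
        elif method == "nnls":
            fractions[valid] = NNLSUnmixer(lib).fit().predict(pixels[valid])
            tag = "NNLS"
        else:
            raise ValueError(f"unknown unmixing method {method!r}")
    else:
        tag = "PAF" if isinstance(method, PAFRegressor) else "NNLS"

    frac_img = fractions.T.reshape(N, H, W)
    so2_img = _so2(np.moveaxis(frac_img, 0, -1), lib.chromophore_names)
    return ConcentrationMap(
        fractions=frac_img,
        so2=np.asarray(so2_img, dtype=float),
        mask=valid.reshape(H, W),
        method=tag,
        chromophore_names=lib.chromophore_names,
        amplitude_threshold=amplitude_threshold,
    )


def region_stats(cmap: ConcentrationMap, rois: np.ndarray) -> pd.DataFrame:
    """Per-ROI, per-chromophore mean and s.d. over unmasked pixels.

    ``rois`` is an integer-labelled image of the map's (Y, X) shape; label 0
    is background and is ignored.
    """
    rois = np.asarray(rois)
    if rois.shape != cmap.mask.shape:
        raise ValueError("ROI image shape does not match map shape")
    rows = []
    for label in np.unique(rois):
        if label == 0:
            continue
        m = (rois == label) & cmap.mask
        if not m.any():
            raise ValueError(f"ROI {label} contains no unmasked pixels")
        row = {"roi": int(label), "n_pixels": int(m.sum())}
        for j, name in enumerate(cmap.chromophore_names):
            vals = cmap.fractions[j][m]
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_sd"] = float(vals.std())
        s = cmap.so2[m]
        s = s[np.isfinite(s)]
        row["so2_mean"] = float(s.mean()) if s.size else float("nan")
        row["so2_sd"] = float(s.std()) if s.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("roi")


def fold_change(stats_df: pd.DataFrame, roi_a: int, roi_b: int, channel: str) -> float:
    """Ratio of a channel's mean between two ROIs (e.g. lesion vs control)."""
    a = stats_df.loc[roi_a, f"{channel}_mean"]
    b = stats_df.loc[roi_b, f"{channel}_mean"]
    if b == 0:
        raise ZeroDivisionError(f"ROI {roi_b} has zero mean {channel}")
    return float(a / b)
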