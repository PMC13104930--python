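"""Photoacoustic spectral library.

Per-chromophore absorption-coefficient spectra are linearly interpolated onto
a common, dual-band wavelength grid (the laser's signal and idle OPO ranges).
Values are kept in whatever raw absorbance units the source tables use; the
library never rescales them.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical chromophore ordering used throughout the package.  Fixing one
#: index mapping prevents silent column swaps between simulation, unmixing
#: and imaging.
CHROMOPHORES = ("HbO2", "HbR", "lipid", "water", "collagen")

#: Dual-band acquisition ranges in nm: signal (700-970) and idle (1160-1400).
DEFAULT_BANDS = ((700.0, 970.0), (1160.0, 1400.0))
DEFAULT_STEP_NM = 10.0


class SpectrumRangeError(ValueError):
    """A grid point falls outside a source spectrum's wavelength support."""


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """A single chromophore's absorption spectrum on its native wavelengths."""

    chromophore_name: str
    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError(
                f"spectrum {self.chromophore_name!r} needs at least 2 points, got {wl.size}"
            )
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError(f"spectrum {self.chromophore_name!r} contains non-finite entries")
        order = np.argsort(wl, kind="stable")
        wl, vals = wl[order], vals[order]
        if np.any(np.diff(wl) <= 0):
            raise ValueError(
                f"spectrum {self.chromophore_name!r} has duplicate wavelengths"
            )
        if np.any(vals < 0):
            bad = int(np.argmax(vals < 0))
            raise ValueError(
                f"spectrum {self.chromophore_name!r} has negative value at "
                f"{wl[bad]:g} nm"
            )
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def interpolate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation; raises outside the native support."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        outside = (wl < lo) | (wl > hi)
        if np.any(outside):
            bad = wl[outside][0]
            raise SpectrumRangeError(
                f"wavelength {bad:g} nm outside support [{lo:g}, {hi:g}] nm of "
                f"chromophore {self.chromophore_name!r}"
            )
        return np.interp(wl, self.wavelengths_nm, self.values)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing sampling wavelengths partitioned into bands."""

    wavelengths_nm: np.ndarray
    band_edges: tuple[tuple[float, float], ...]

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("grid needs at least one wavelength")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("grid wavelengths must be strictly increasing")
        edges = tuple((float(a), float(b)) for a, b in self.band_edges)
        membership = np.zeros(wl.size, dtype=int)
        for a, b in edges:
            membership += ((wl >= a) & (wl <= b)).astype(int)
        if np.any(membership != 1):
            bad = wl[membership != 1][0]
            raise ValueError(f"grid point {bad:g} nm lies in {0} or >1 bands")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "band_edges", edges)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def normalized(self) -> np.ndarray:
        """Min-max normalised wavelengths over the full grid, in [0, 1]."""
        wl = self.wavelengths_nm
        if wl.size == 1:
            return np.zeros(1)
        return (wl - wl[0]) / (wl[-1] - wl[0])

    def subset(self, indices: Sequence[int]) -> "WavelengthGrid":
        return WavelengthGrid(self.wavelengths_nm[np.asarray(indices)], self.band_edges)


def default_grid(bands=DEFAULT_BANDS, step_nm: float = DEFAULT_STEP_NM) -> WavelengthGrid:
    """Dual-band grid at 10 nm steps: 700-970 nm and 1160-1400 nm inclusive."""
    pts = []
    for a, b in bands:
        n = int(round((b - a) / step_nm)) + 1
        pts.append(a + step_nm * np.arange(n))
    return WavelengthGrid(np.concatenate(pts), tuple(bands))


@dataclass(frozen=True)
class SpectralLibrary:
    """K x N matrix of absorption values; column i is chromophore i on the grid."""

    grid: WavelengthGrid
    chromophore_names: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.grid), len(self.chromophore_names)):
            raise ValueError(
                f"matrix shape {m.shape} does not match K={len(self.grid)}, "
                f"N={len(self.chromophore_names)}"
            )
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("library entries must be finite and non-negative")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "chromophore_names", tuple(self.chromophore_names))
        maxima = m.max(axis=0)
        pos = maxima[maxima > 0]
        if pos.size >= 2 and pos.max() / pos.min() > 1e3:
            warnings.warn(
                "library column maxima differ by more than 1000x; check that all "
                "source spectra use consistent units",
                stacklevel=2,
            )

    @property
    def n_wavelengths(self) -> int:
        return len(self.grid)

    @property
    def n_chromophores(self) -> int:
        return len(self.chromophore_names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.chromophore_names.index(name)]

    def subset(self, indices: Sequence[int]) -> "SpectralLibrary":
        """Library restricted to a subset of grid points (wavelength down-sampling)."""
        idx = np.asarray(indices)
        return SpectralLibrary(self.grid.subset(idx), self.chromophore_names, self.matrix[idx])

    def content_hash(self) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.grid.wavelengths_nm).tobytes())
        h.update(np.ascontiguousarray(self.matrix).tobytes())
        h.update(",".join(self.chromophore_names).encode())
        return h.hexdigest()


def load_spectrum(path: str | Path, name: str | None = None) -> AbsorptionSpectrum:
    """Load a two-column CSV table (wavelength_nm, value); header optional."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two comma-separated columns")
            try:
                wl, val = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell in row {parts!r}"
                ) from None
            rows.append((wl, val))
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    arr = np.asarray(rows)
    return AbsorptionSpectrum(name or path.stem, arr[:, 0], arr[:, 1])


def build_library(
    spectra: Sequence[AbsorptionSpectrum], grid: WavelengthGrid | None = None
) -> SpectralLibrary:
    """Interpolate spectra onto a common grid; raw units are preserved."""
    if grid is None:
        grid = default_grid()
    cols = [s.interpolate(grid.wavelengths_nm) for s in spectra]
    names = tuple(s.chromophore_name for s in spectra)
    return SpectralLibrary(grid, names, np.column_stack(cols))


def save_library(lib: SpectralLibrary, csv_path: str | Path, yaml_path: str | Path | None = None):
    """Write CSV (wavelength_nm + one column per chromophore) and a YAML sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(lib.matrix, columns=list(lib.chromophore_names))
    df.insert(0, "wavelength_nm", lib.grid.wavelengths_nm)
    df.to_csv(csv_path, index=False, float_format="%.17g")
    if yaml_path is None:
        yaml_path = csv_path.with_suffix(".yaml")
    meta = {
        "band_edges": [list(edge) for edge in lib.grid.band_edges],
        "chromophores": list(lib.chromophore_names),
        "content_hash": lib.content_hash(),
    }
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(meta, fh)


def load_library(csv_path: str | Path, yaml_path: str | Path | None = None) -> SpectralLibrary:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if "wavelength_nm" not in df.columns:
        raise ValueError(f"{csv_path}: first column must be 'wavelength_nm'")
    if yaml_path is None:
        yaml_path = csv_path.with_suffix(".yaml")
    if Path(yaml_path).exists():
        with open(yaml_path) as fh:
            meta = yaml.safe_load(fh)
        bands = tuple(tuple(edge) for edge in meta["band_edges"])
    else:
        wl = df["wavelength_nm"].to_numpy()
        bands = ((float(wl[0]), float(wl[-1])),)
    names = [c for c in df.columns if c != "wavelength_nm"]
    grid = WavelengthGrid(df["wavelength_nm"].to_numpy(float), bands)
    return SpectralLibrary(grid, tuple(names), df[names].to_numpy(float))
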