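"""Synthetic fingerprint generation.

A fingerprint is the vector of photoacoustic amplitudes across the sampled
wavelength grid for one voxel.  The forward model is

    f0 = phi(lambda; x) * (M @ c)

where M is the K x N spectral library, c a concentration vector on the
simplex, and phi a parametric one-dimensional fluence prior

    phi(lambda; x) = exp(-(1 - lam)^2 * x),   lam = min-max normalised wavelength,

so shorter wavelengths are attenuated more strongly and the longest grid
wavelength is never attenuated.  Gaussian noise of unit power is added after
scaling the clean fingerprint to a target signal-to-noise ratio:

    P_s = mean(f0^2),  alpha = sqrt(10^(SNR_dB/10) / P_s),
    f_noisy = alpha * f0 + eps,  eps ~ N(0, 1) per wavelength,

which makes the realised power ratio of alpha*f0 to eps equal the target.

Concentration vectors are drawn either from five spectral-complexity mixture
classes (pure / extreme / dominant / random / binary) or from four anatomical
patterns (vessel-like, fat-dominant, collagen-rich, water background).  The
anatomical recipes sample total hemoglobin as one group and split it into
HbO2/HbR with a random oxygenation fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np

from .library import SpectralLibrary, WavelengthGrid

_HBO2, _HBR, _LIPID, _WATER, _COLLAGEN = range(5)


class MixtureClass(Enum):
    """Concentration-sampling regimes used to build training data."""

    PURE = "Pure"
    EXTREME = "Extreme"
    DOMINANT = "Dominant"
    RANDOM = "Random"
    BINARY = "Binary"
    VESSEL_LIKE = "VesselLike"
    FAT_DOMINANT = "FatDominant"
    COLLAGEN_RICH = "CollagenRich"
    BACKGROUND = "Background"


MIXTURE_CLASSES = (
    MixtureClass.PURE,
    MixtureClass.EXTREME,
    MixtureClass.DOMINANT,
    MixtureClass.RANDOM,
    MixtureClass.BINARY,
)
ANATOMICAL_CLASSES = (
    MixtureClass.VESSEL_LIKE,
    MixtureClass.FAT_DOMINANT,
    MixtureClass.COLLAGEN_RICH,
    MixtureClass.BACKGROUND,
)
CLASS_ORDER = MIXTURE_CLASSES + ANATOMICAL_CLASSES


def default_class_proportions() -> dict[MixtureClass, float]:
    """Half the data equally over the five mixture classes, half over the four
    anatomical patterns."""
    props = {cls: 0.5 / 5 for cls in MIXTURE_CLASSES}
    props.update({cls: 0.5 / 4 for cls in ANATOMICAL_CLASSES})
    return props


@dataclass(frozen=True)
class Fingerprint:
    """One fingerprint with provenance metadata."""

    amplitudes: np.ndarray
    grid: WavelengthGrid
    true_concentration: np.ndarray | None = None
    snr_db: float | None = None
    fluence_x: float | None = None
    mixture_class: MixtureClass | None = None
    normalized: bool = False

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim != 1 or amps.size != len(self.grid):
            raise ValueError(
                f"amplitudes length {amps.size} does not match grid K={len(self.grid)}"
            )
        object.__setattr__(self, "amplitudes", amps)


# ---------------------------------------------------------------------------
# Concentration sampling


def _dirichlet(rng: np.random.Generator, alpha: float, n: int, k: int) -> np.ndarray:
    if k == 0:
        return np.zeros((n, 0))
    return rng.dirichlet(np.full(k, alpha), size=n)


def sample_concentrations(
    cls: MixtureClass,
    n: int,
    rng: np.random.Generator,
    *,
    n_chromophores: int = 5,
    dirichlet_alpha: float = 1.0,
    hb_split_range: tuple[float, float] = (0.0, 1.0),
    vessel_split_range: tuple[float, float] = (0.5, 1.0),
) -> np.ndarray:
    """Draw ``n`` concentration vectors of the given class; rows sum to 1.

    The five mixture classes act directly on the N chromophores.  The
    anatomical classes treat hemoglobin as one group whose mass is split into
    HbO2/HbR by an oxygenation fraction s (uniform over ``hb_split_range``,
    or ``vessel_split_range`` for the vessel-like class, biasing arterial
    oxygenation); they require the canonical five-chromophore ordering.
    """
    N = n_chromophores
    C = np.zeros((n, N))

    def _with_dominant(idx: np.ndarray, dom: np.ndarray) -> np.ndarray:
        out = np.zeros((n, N))
        rest = _dirichlet(rng, dirichlet_alpha, n, N - 1) * (1.0 - dom)[:, None]
        for i in range(n):
            others = [j for j in range(N) if j != idx[i]]
            out[i, idx[i]] = dom[i]
            out[i, others] = rest[i]
        return out

    if cls is MixtureClass.PURE:
        idx = rng.integers(0, N, size=n)
        C[np.arange(n), idx] = 1.0
    elif cls is MixtureClass.EXTREME:
        C = _with_dominant(rng.integers(0, N, size=n), rng.uniform(0.90, 0.99, size=n))
    elif cls is MixtureClass.DOMINANT:
        C = _with_dominant(rng.integers(0, N, size=n), rng.uniform(0.70, 0.90, size=n))
    elif cls is MixtureClass.RANDOM:
        C = _dirichlet(rng, dirichlet_alpha, n, N)
    elif cls is MixtureClass.BINARY:
        pairs = np.stack([rng.permutation(N)[:2] for _ in range(n)])
        p = rng.uniform(0.01, 0.99, size=n)
        C[np.arange(n), pairs[:, 0]] = p
        C[np.arange(n), pairs[:, 1]] = 1.0 - p
    elif cls in ANATOMICAL_CLASSES:
        if N != 5:
            raise ValueError("anatomical classes require the 5-chromophore ordering")
        recipes = {
            MixtureClass.VESSEL_LIKE: ("hb", (0.7, 1.0)),
            MixtureClass.FAT_DOMINANT: (_LIPID, (0.6, 0.95)),
            MixtureClass.COLLAGEN_RICH: (_COLLAGEN, (0.5, 0.9)),
            MixtureClass.BACKGROUND: (_WATER, (0.7, 1.0)),
        }
        target, (lo, hi) = recipes[cls]
        dom = rng.uniform(lo, hi, size=n)
        split_lo, split_hi = (
            vessel_split_range if cls is MixtureClass.VESSEL_LIKE else hb_split_range
        )
        s = rng.uniform(split_lo, split_hi, size=n)
        if target == "hb":
            # remainder over lipid / water / collagen
            rest = _dirichlet(rng, dirichlet_alpha, n, 3) * (1.0 - dom)[:, None]
            C[:, _HBO2] = s * dom
            C[:, _HBR] = (1.0 - s) * dom
            C[:, [_LIPID, _WATER, _COLLAGEN]] = rest
        else:
            # remainder over hemoglobin group + the two other non-dominant groups
            others = [g for g in ("hb", _LIPID, _WATER, _COLLAGEN) if g != target]
            rest = _dirichlet(rng, dirichlet_alpha, n, 3) * (1.0 - dom)[:, None]
            C[:, target] = dom
            for j, g in enumerate(others):
                if g == "hb":
                    C[:, _HBO2] += s * rest[:, j]
                    C[:, _HBR] += (1.0 - s) * rest[:, j]
                else:
                    C[:, g] += rest[:, j]
    else:  # pragma: no cover - closed enumeration
        raise ValueError(f"unknown mixture class {cls!r}")

    # guard against floating-point drift off the simplex
    C /= C.sum(axis=1, keepdims=True)
    return C


def sample_concentration(cls: MixtureClass, rng: np.random.Generator, **kwargs) -> np.ndarray:
    """Single concentration vector of the given class."""
    return sample_concentrations(cls, 1, rng, **kwargs)[0]


def structural_class(c: np.ndarray, atol: float = 1e-12) -> MixtureClass:
    """Post-hoc structural classification of a concentration vector.

    One-hot -> Pure; exactly-2 support -> Binary; max in [0.9, 0.99] ->
    Extreme; max in [0.7, 0.9) -> Dominant; otherwise Random.  Useful when
    accounting by realised structure rather than generating class.
    """
    c = np.asarray(c, dtype=float)
    support = int(np.sum(c > atol))
    m = float(c.max())
    if support == 1:
        return MixtureClass.PURE
    if support == 2:
        return MixtureClass.BINARY
    if 0.9 <= m <= 0.99:
        return MixtureClass.EXTREME
    if 0.7 <= m < 0.9:
        return MixtureClass.DOMINANT
    return MixtureClass.RANDOM


# ---------------------------------------------------------------------------
# Forward model


def fluence_profile(x: float, grid: WavelengthGrid) -> np.ndarray:
    """Parametric fluence prior exp(-(1-lam)^2 x) over the grid; in (0, 1]."""
    if x < 0:
        raise ValueError(f"fluence severity must be non-negative, got {x}")
    lam = grid.normalized
    return np.exp(-((1.0 - lam) ** 2) * float(x))


def clean_fingerprint_array(
    c: np.ndarray, lib: SpectralLibrary, fluence: np.ndarray | None = None
) -> np.ndarray:
    """Noise-free amplitudes fluence * (M @ c) as a plain array."""
    c = np.asarray(c, dtype=float)
    if c.shape != (lib.n_chromophores,):
        raise ValueError(
            f"concentration length {c.shape} does not match N={lib.n_chromophores}"
        )
    f0 = lib.matrix @ c
    if fluence is not None:
        fluence = np.asarray(fluence, dtype=float)
        if fluence.shape != (lib.n_wavelengths,):
            raise ValueError("fluence length does not match grid")
        if np.any(fluence <= 0) or np.any(fluence > 1):
            raise ValueError("fluence entries must lie in (0, 1]")
        f0 = fluence * f0
    return f0


def clean_fingerprint(
    c: np.ndarray,
    lib: SpectralLibrary,
    fluence: np.ndarray | None = None,
    *,
    fluence_x: float | None = None,
    mixture_class: MixtureClass | None = None,
) -> Fingerprint:
    """Forward-model a concentration vector into a noise-free Fingerprint."""
    amps = clean_fingerprint_array(c, lib, fluence)
    return Fingerprint(
        amps, lib.grid, true_concentration=np.asarray(c, float),
        fluence_x=fluence_x, mixture_class=mixture_class,
    )


def snr_scale(f0: np.ndarray, snr_db: np.ndarray | float) -> np.ndarray | float:
    """Scaling alpha that makes power(alpha*f0) / power(unit noise) hit the target."""
    f0 = np.asarray(f0, dtype=float)
    p_s = np.mean(f0**2, axis=-1)
    if np.any(p_s == 0):
        raise ValueError("cannot set SNR of an all-zero fingerprint")
    return np.sqrt(10.0 ** (np.asarray(snr_db, float) / 10.0) / p_s)


def add_noise_array(
    f0: np.ndarray, snr_db: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised alpha*f0 + N(0,1) over rows of f0."""
    f0 = np.atleast_2d(np.asarray(f0, dtype=float))
    alpha = np.asarray(snr_scale(f0, snr_db), dtype=float).reshape(-1, 1)
    return alpha * f0 + rng.standard_normal(f0.shape)


def add_noise(f0: Fingerprint, snr_db: float, rng: np.random.Generator) -> Fingerprint:
    """Scale a clean fingerprint to the target SNR and add unit-power noise."""
    noisy = add_noise_array(f0.amplitudes, np.array([snr_db]), rng)[0]
    return Fingerprint(
        noisy, f0.grid, true_concentration=f0.true_concentration,
        snr_db=float(snr_db), fluence_x=f0.fluence_x,
        mixture_class=f0.mixture_class, normalized=False,
    )


def normalize_max(f: Fingerprint) -> Fingerprint:
    """Divide amplitudes by their maximum value; idempotent; flags the result."""
    m = float(f.amplitudes.max())
    if m <= 0:
        raise ValueError("cannot max-normalize a fingerprint with non-positive maximum")
    return Fingerprint(
        f.amplitudes / m, f.grid, true_concentration=f.true_concentration,
        snr_db=f.snr_db, fluence_x=f.fluence_x,
        mixture_class=f.mixture_class, normalized=True,
    )


# ---------------------------------------------------------------------------
# Dataset generation


@dataclass
class SimConfig:
    """Study conditions for synthetic dataset generation.

    Defaults follow the training protocol: half the records split equally
    over the five mixture classes and half over the four anatomical classes,
    SNR drawn uniformly from [3, 40] dB, and fluence severity x drawn
    uniformly from [0, 20] when ``fluence_mode='random'`` (x = 0 for
    ``'unit'``).  ``snr_range_db=None`` generates noiseless fingerprints.
    """

    size: int = 1_000_000
    class_proportions: dict[MixtureClass, float] = field(
        default_factory=default_class_proportions
    )
    fluence_mode: str = "unit"  # "unit" | "random"
    x_range: tuple[float, float] = (0.0, 20.0)
    snr_range_db: tuple[float, float] | None = (3.0, 40.0)
    dirichlet_alpha: float = 1.0
    hb_split_range: tuple[float, float] = (0.0, 1.0)
    vessel_split_range: tuple[float, float] = (0.5, 1.0)

    def validate(self):
        if self.size <= 0:
            raise ValueError("size must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.fluence_mode not in ("unit", "random"):
            raise ValueError(f"unknown fluence mode {self.fluence_mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_proportions"] = {c.value: p for c, p in self.class_proportions.items()}
        return d

    def to_yaml(self, path):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "class_proportions" in d:
            d["class_proportions"] = {
                MixtureClass(k): float(v) for k, v in d["class_proportions"].items()
            }
        for key in ("x_range", "snr_range_db", "hb_split_range", "vessel_split_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedDataset:
    """Paired fingerprints and ground-truth concentrations with provenance.

    ``amplitudes`` holds the raw (noisy, un-normalised) fingerprints: that is
    the convention the NNLS baseline consumes; the model path max-normalises
    on input.
    """

    amplitudes: np.ndarray  # (n, K)
    concentrations: np.ndarray  # (n, N)
    snr_db: np.ndarray  # (n,), NaN where noiseless
    fluence_x: np.ndarray  # (n,)
    mixture_class: np.ndarray  # (n,), int codes into CLASS_ORDER
    grid: WavelengthGrid
    chromophore_names: tuple[str, ...]
    seed: int | None = None
    config: dict | None = None
    library_hash: str | None = None

    def __len__(self) -> int:
        return self.amplitudes.shape[0]

    def class_of(self, i: int) -> MixtureClass:
        return CLASS_ORDER[int(self.mixture_class[i])]

    def class_mask(self, cls: MixtureClass) -> np.ndarray:
        return self.mixture_class == CLASS_ORDER.index(cls)

    def fingerprint(self, i: int) -> Fingerprint:
        snr = float(self.snr_db[i])
        return Fingerprint(
            self.amplitudes[i], self.grid,
            true_concentration=self.concentrations[i],
            snr_db=None if np.isnan(snr) else snr,
            fluence_x=float(self.fluence_x[i]),
            mixture_class=self.class_of(i),
        )

    def to_dataframe(self):
        """Flat table view: per-wavelength amplitudes, truths, and metadata."""
        import pandas as pd

        amp_cols = {
            f"amp_{wl:g}nm": self.amplitudes[:, k]
            for k, wl in enumerate(self.grid.wavelengths_nm)
        }
        conc_cols = {
            f"true_{name}": self.concentrations[:, j]
            for j, name in enumerate(self.chromophore_names)
        }
        meta = {
            "snr_db": self.snr_db,
            "fluence_x": self.fluence_x,
            "mixture_class": [CLASS_ORDER[int(i)].value for i in self.mixture_class],
        }
        return pd.DataFrame({**amp_cols, **conc_cols, **meta})

    def to_csv(self, path: str | Path):
        """CSV export intended for small datasets; HDF5 is the scalable format."""
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path: str | Path):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("amplitudes", data=self.amplitudes)
            fh.create_dataset("concentrations", data=self.concentrations)
            fh.create_dataset("snr_db", data=self.snr_db)
            fh.create_dataset("fluence_x", data=self.fluence_x)
            fh.create_dataset("mixture_class", data=self.mixture_class.astype(np.int8))
            fh.create_dataset("wavelengths_nm", data=self.grid.wavelengths_nm)
            fh.create_dataset("band_edges", data=np.asarray(self.grid.band_edges))
            fh.attrs["chromophores"] = list(self.chromophore_names)
            if self.seed is not None:
                fh.attrs["seed"] = int(self.seed)
            if self.library_hash is not None:
                fh.attrs["library_hash"] = self.library_hash
            if self.config is not None:
                import json

                fh.attrs["config_json"] = json.dumps(self.config, default=str)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SimulatedDataset":
        import json

        with h5py.File(path, "r") as fh:
            grid = WavelengthGrid(
                fh["wavelengths_nm"][:],
                tuple(tuple(e) for e in fh["band_edges"][:]),
            )
            return cls(
                amplitudes=fh["amplitudes"][:],
                concentrations=fh["concentrations"][:],
                snr_db=fh["snr_db"][:],
                fluence_x=fh["fluence_x"][:],
                mixture_class=fh["mixture_class"][:].astype(int),
                grid=grid,
                chromophore_names=tuple(fh.attrs["chromophores"]),
                seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
                config=json.loads(fh.attrs["config_json"])
                if "config_json" in fh.attrs
                else None,
                library_hash=fh.attrs.get("library_hash"),
            )


def _class_counts(size: int, proportions: Mapping[MixtureClass, float]) -> dict:
    """Largest-remainder apportionment of `size` records to classes."""
    classes = [c for c in CLASS_ORDER if proportions.get(c, 0.0) > 0]
    exact = np.array([size * proportions[c] for c in classes])
    counts = np.floor(exact).astype(int)
    rem = size - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:rem]] += 1
    return dict(zip(classes, counts))


def generate_dataset(
    config: SimConfig, lib: SpectralLibrary, seed: int
) -> SimulatedDataset:
    """Generate a fully reproducible dataset of noisy fingerprints.

    Each class is generated from its own deterministic substream spawned from
    ``seed``, so the dataset is bit-identical for identical
    (seed, config, library) regardless of how other classes are resized.
    """
    config.validate()
    counts = _class_counts(config.size, config.class_proportions)
    N, K = lib.n_chromophores, lib.n_wavelengths
    lam = lib.grid.normalized

    all_C, all_F, all_snr, all_x, all_cls = [], [], [], [], []
    for cls, n_c in counts.items():
        if n_c == 0:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), CLASS_ORDER.index(cls)])
        )
        C = sample_concentrations(
            cls, n_c, rng,
            n_chromophores=N,
            dirichlet_alpha=config.dirichlet_alpha,
            hb_split_range=config.hb_split_range,
            vessel_split_range=config.vessel_split_range,
        )
        if config.fluence_mode == "random":
            x = rng.uniform(*config.x_range, size=n_c)
        else:
            x = np.zeros(n_c)
        phi = np.exp(-((1.0 - lam)[None, :] ** 2) * x[:, None])
        f0 = (C @ lib.matrix.T) * phi
        if config.snr_range_db is None:
            snr = np.full(n_c, np.nan)
            f = f0
        else:
            snr = rng.uniform(*config.snr_range_db, size=n_c)
            f = add_noise_array(f0, snr, rng)
        all_C.append(C)
        all_F.append(f)
        all_snr.append(snr)
        all_x.append(x)
        all_cls.append(np.full(n_c, CLASS_ORDER.index(cls), dtype=np.int8))

    return SimulatedDataset(
        amplitudes=np.concatenate(all_F),
        concentrations=np.concatenate(all_C),
        snr_db=np.concatenate(all_snr),
        fluence_x=np.concatenate(all_x),
        mixture_class=np.concatenate(all_cls).astype(int),
        grid=lib.grid,
        chromophore_names=lib.chromophore_names,
        seed=int(seed),
        config=config.to_dict(),
        library_hash=lib.content_hash(),
    )
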