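"""Protocol helpers for the simulation benchmarks.

These functions assemble the standard study designs — matched test sets,
NNLS vs model evaluation across independent test sets, error-vs-sampling
and error-vs-fluence sweeps, SNR calibration audits — from the lower-level
modules, so scripts and tests share one implementation of each protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .library import SpectralLibrary
from .metrics import MetricsReport, compare_cohorts, parity_metrics
from .model import PAFRegressor
from .nnls import NNLSUnmixer
from .simulate import (
    MIXTURE_CLASSES,
    MixtureClass,
    SimConfig,
    SimulatedDataset,
    add_noise_array,
    generate_dataset,
    sample_concentrations,
)


def make_test_sets(
    lib: SpectralLibrary,
    n_sets: int = 5,
    size: int = 50_000,
    fluence_mode: str = "unit",
    snr_range_db=(3.0, 40.0),
    seed: int = 0,
) -> list[SimulatedDataset]:
    """Independent test sets drawn with distinct deterministic sub-seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(n_sets) % (2**31)
    cfg = SimConfig(size=size, fluence_mode=fluence_mode, snr_range_db=snr_range_db)
    return [generate_dataset(cfg, lib, int(s)) for s in seeds]


def evaluate_nnls(lib: SpectralLibrary, ds: SimulatedDataset) -> MetricsReport:
    """NNLS on the raw noisy fingerprints, scored on simplex fractions."""
    pred = NNLSUnmixer(lib).fit().predict(ds.amplitudes)
    return parity_metrics(ds.concentrations, pred, ds.chromophore_names)


def evaluate_model(model: PAFRegressor, ds: SimulatedDataset) -> MetricsReport:
    pred = model.predict(ds.amplitudes, wavelengths=ds.grid.wavelengths_nm)
    return parity_metrics(ds.concentrations, pred, ds.chromophore_names)


def evaluate_methods(
    lib: SpectralLibrary,
    model: PAFRegressor | None,
    test_sets: list[SimulatedDataset],
) -> pd.DataFrame:
    """Per-test-set parity metrics for NNLS and (optionally) the model."""
    rows = []
    for i, ds in enumerate(test_sets):
        rep = evaluate_nnls(lib, ds)
        rows.append({"test_set": i, "method": "NNLS", "r2": rep.r2,
                     "rmse": rep.rmse, "slope": rep.slope, "n": rep.n})
        if model is not None:
            rep = evaluate_model(model, ds)
            rows.append({"test_set": i, "method": "PAF", "r2": rep.r2,
                         "rmse": rep.rmse, "slope": rep.slope, "n": rep.n})
    return pd.DataFrame(rows)


def cohort_tests(summary: pd.DataFrame) -> dict:
    """Welch t-tests between the PAF and NNLS cohorts of evaluate_methods."""
    out = {}
    for metric in ("r2", "rmse", "slope"):
        a = summary.loc[summary["method"] == "PAF", metric].to_numpy()
        b = summary.loc[summary["method"] == "NNLS", metric].to_numpy()
        if a.size >= 2 and b.size >= 2:
            out[metric] = compare_cohorts(a, b, metric_name=metric)
    return out


def mixture_group_r2(
    ds: SimulatedDataset, pred: np.ndarray, classes=MIXTURE_CLASSES
) -> dict[MixtureClass, float]:
    """Pooled parity R^2 within each generating mixture class."""
    out = {}
    for cls in classes:
        m = ds.class_mask(cls)
        if m.sum() < 2:
            continue
        out[cls] = parity_metrics(ds.concentrations[m], pred[m]).r2
    return out


def wavelength_subset_indices(K_full: int, k: int) -> np.ndarray:
    """k grid indices spread evenly (endpoints included) over the full grid."""
    if not 1 <= k <= K_full:
        raise ValueError(f"k must lie in [1, {K_full}]")
    return np.unique(np.round(np.linspace(0, K_full - 1, k)).astype(int))


def aae_vs_num_wavelengths(
    lib: SpectralLibrary,
    k_values,
    snr_db: float,
    size: int = 2000,
    seed: int = 0,
    fluence_x: float = 0.0,
) -> pd.DataFrame:
    """NNLS mean AAE as wavelength sampling grows, at fixed SNR and fluence.

    One fixed set of concentration vectors (drawn from the default class
    mixture) is forward-modelled on the full grid; each sweep point keeps an
    evenly spaced subset of wavelengths, noise-corrupts the sub-fingerprint
    at the target SNR, and unmixes with the sub-library.
    """
    cfg = SimConfig(size=size, fluence_mode="unit", snr_range_db=None)
    base = generate_dataset(cfg, lib, seed)
    lam = lib.grid.normalized
    phi = np.exp(-((1.0 - lam) ** 2) * fluence_x)
    clean_full = base.amplitudes * phi  # noiseless at generation
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    rows = []
    for k in k_values:
        idx = wavelength_subset_indices(lib.n_wavelengths, int(k))
        sub = lib.subset(idx)
        noisy = add_noise_array(clean_full[:, idx], np.full(size, snr_db), rng)
        pred = NNLSUnmixer(sub).fit().predict(noisy)
        err = np.abs(pred - base.concentrations)
        rows.append({"k": int(idx.size), "aae": float(err.mean())})
    return pd.DataFrame(rows)


def aae_vs_fluence(
    lib: SpectralLibrary,
    x_values,
    snr_db: float,
    size: int = 2000,
    seed: int = 0,
    model: PAFRegressor | None = None,
) -> pd.DataFrame:
    """Mean AAE as fluence severity grows, at fixed SNR, full grid.

    The same concentration vectors are reused across severities so that the
    sweep isolates the fluence effect.
    """
    cfg = SimConfig(size=size, fluence_mode="unit", snr_range_db=None)
    base = generate_dataset(cfg, lib, seed)
    lam = lib.grid.normalized
    rng = np.random.default_rng(np.random.SeedSequence([seed, 131]))
    rows = []
    for x in x_values:
        phi = np.exp(-((1.0 - lam) ** 2) * float(x))
        noisy = add_noise_array(base.amplitudes * phi, np.full(size, snr_db), rng)
        row = {"x": float(x)}
        pred = NNLSUnmixer(lib).fit().predict(noisy)
        row["nnls_aae"] = float(np.abs(pred - base.concentrations).mean())
        if model is not None:
            pred = model.predict(noisy, wavelengths=lib.grid.wavelengths_nm)
            row["paf_aae"] = float(np.abs(pred - base.concentrations).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def realized_snr_db(
    lib: SpectralLibrary, target_db: float, n: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo mean of the realised per-fingerprint SNR at a target.

    Draws random-ratio concentration vectors, forward-models them at unit
    fluence, applies the SNR scaling, and measures
    10*log10(power(alpha*f0) / power(eps)) per fingerprint.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    C = sample_concentrations(MixtureClass.RANDOM, n, rng,
                              n_chromophores=lib.n_chromophores)
    f0 = C @ lib.matrix.T
    p_s = np.mean(f0**2, axis=1)
    alpha = np.sqrt(10.0 ** (target_db / 10.0) / p_s)
    eps = rng.standard_normal(f0.shape)
    sig_power = np.mean((alpha[:, None] * f0) ** 2, axis=1)
    noise_power = np.mean(eps**2, axis=1)
    return float(np.mean(10.0 * np.log10(sig_power / noise_power)))


def projected_gradient_nnls(
    M: np.ndarray, f: np.ndarray, max_iter: int = 20_000, tol: float = 1e-12
) -> np.ndarray:
    """Reference non-negative least squares by projected gradient descent.

    Independent of the active-set solver used in production; intended as a
    validation oracle on small instances.
    """
    M = np.asarray(M, dtype=float)
    f = np.asarray(f, dtype=float)
    L = np.linalg.norm(M.T @ M, 2)
    if L == 0:
        return np.zeros(M.shape[1])
    step = 1.0 / L
    c = np.zeros(M.shape[1])
    for _ in range(max_iter):
        grad = M.T @ (M @ c - f)
        c_new = np.maximum(c - step * grad, 0.0)
        if np.max(np.abs(c_new - c)) < tol:
            c = c_new
            break
        c = c_new
    return c
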