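"""Non-negative least squares baseline unmixing.

Solves ``min ||M c - f||_2  s.t.  c >= 0`` per fingerprint with the
Lawson-Hanson active-set solver, then renormalises the coefficients onto the
simplex for comparison with ground-truth fractions (the fluence and SNR
scalings make the raw coefficient scale arbitrary).  An all-zero solution
leaves the fraction vector undefined; downstream metrics score it as a zero
prediction and flag it, rather than silently rewarding degeneracy.

The baseline consumes raw (energy-normalised) fingerprints without
max-scaling, matching how it is applied to measured data; fractions are
scale-invariant so secondary scaling has little effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _lawson_hanson
from sklearn.base import BaseEstimator

from .library import SpectralLibrary
from .simulate import Fingerprint


@dataclass(frozen=True)
class NNLSResult:
    """Raw non-negative coefficients, simplex fractions, and residual norm."""

    raw_coefficients: np.ndarray
    fractions: np.ndarray | None  # None when all coefficients are zero
    residual_norm: float

    @property
    def defined(self) -> bool:
        return self.fractions is not None


def _solve_array(matrix: np.ndarray, f: np.ndarray) -> NNLSResult:
    if not np.all(np.isfinite(f)):
        raise ValueError("fingerprint contains non-finite amplitudes")
    coef, resid = _lawson_hanson(matrix, f)
    total = coef.sum()
    fractions = coef / total if total > 0 else None
    return NNLSResult(coef, fractions, float(resid))


def nnls_solve(lib: SpectralLibrary, f: Fingerprint | np.ndarray) -> NNLSResult:
    """Solve one fingerprint against the library."""
    if isinstance(f, Fingerprint):
        if f.amplitudes.size != lib.n_wavelengths:
            raise ValueError("fingerprint grid does not match library grid")
        if not np.array_equal(f.grid.wavelengths_nm, lib.grid.wavelengths_nm):
            raise ValueError("fingerprint and library use different wavelength grids")
        amps = f.amplitudes
    else:
        amps = np.asarray(f, dtype=float)
        if amps.shape != (lib.n_wavelengths,):
            raise ValueError(
                f"amplitude length {amps.shape} does not match K={lib.n_wavelengths}"
            )
    return _solve_array(lib.matrix, amps)


def unmix_batch(lib: SpectralLibrary, fingerprints) -> list[NNLSResult]:
    """Elementwise nnls_solve over an iterable of fingerprints, order preserved."""
    results = []
    for i, f in enumerate(fingerprints):
        try:
            results.append(nnls_solve(lib, f))
        except ValueError as exc:
            raise ValueError(f"record {i}: {exc}") from exc
    return results


def fractions_matrix(results: list[NNLSResult]) -> tuple[np.ndarray, np.ndarray]:
    """Stack fractions into (n, N); undefined rows are zero and flagged False."""
    if not results:
        return np.zeros((0, 0)), np.zeros(0, dtype=bool)
    n_out = results[0].raw_coefficients.size
    out = np.zeros((len(results), n_out))
    defined = np.zeros(len(results), dtype=bool)
    for i, r in enumerate(results):
        if r.defined:
            out[i] = r.fractions
            defined[i] = True
    return out, defined


class NNLSUnmixer(BaseEstimator):
    """Scikit-learn style wrapper around per-fingerprint NNLS unmixing.

    Parameters
    ----------
    library : SpectralLibrary
        The K x N spectral library shared with the fingerprint model.

    Attributes
    ----------
    components_ : ndarray of shape (n_chromophores, n_wavelengths)
        The library matrix transposed into scikit-learn's components layout.
    n_features_in_ : int
        Number of wavelengths K.
    """

    def __init__(self, library: SpectralLibrary = None):
        self.library = library

    def fit(self, X=None, y=None):
        if self.library is None:
            raise ValueError("NNLSUnmixer requires a spectral library")
        self.components_ = self.library.matrix.T.copy()
        self.n_features_in_ = self.library.n_wavelengths
        return self

    def _check_is_fitted(self):
        if not hasattr(self, "components_"):
            self.fit()

    def solve(self, X: np.ndarray) -> list[NNLSResult]:
        """Full per-row results (raw coefficients, fractions, residuals)."""
        self._check_is_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} wavelengths, library has {self.n_features_in_}"
            )
        return [_solve_array(self.library.matrix, row) for row in X]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Simplex fractions per row; undefined (all-zero) rows come out as zeros."""
        fracs, _ = fractions_matrix(self.solve(X))
        return fracs

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.predict(X)
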