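"""The fingerprint-to-concentration regressor.

``PAFRegressor`` maps a max-normalised multispectral fingerprint (treated as
an ordered wavelength sequence) to a concentration vector on the simplex:
per-step features run through stacked LSTM layers, the hidden states are
pooled over valid steps (masked mean by default), and a linear readout with
softmax enforces that the predicted fractions are non-negative and sum to 1.

Training follows the reference recipe by default: AdamW (betas 0.9/0.999,
weight decay 1e-5), smooth-L1 (Huber) loss between predicted and true
fractions, batch size 32, learning rate 1e-4, 100 epochs, with an 80/20
train/validation split.  All of these are estimator parameters, so scaled-
down CPU configurations are just different constructor arguments.

Because every input is divided by its maximum before entering the network,
predictions are invariant to positive rescaling of a fingerprint: the model
sees spectral shape, not absolute amplitude.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import _rnn


def max_normalize_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise division by the maximum value, with a safe fallback.

    Rows whose maximum is non-positive (possible for heavily noise-dominated
    fingerprints) are scaled by their maximum absolute value instead, and
    all-zero rows are passed through unchanged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.max(axis=1)
    fallback = np.abs(X).max(axis=1)
    scale = np.where(m > 0, m, np.where(fallback > 0, fallback, 1.0))
    return X / scale[:, None]


class PAFRegressor(BaseEstimator):
    """Recurrent spectral-unmixing regressor with a simplex output.

    Parameters
    ----------
    n_outputs : int, default=5
        Number of chromophores N.
    hidden_size, num_layers : LSTM width and depth.
    include_wavelength_feature : bool, default=True
        Append the min-max normalised wavelength to each step's amplitude so
        one model generalises across wavelength grids.  With False the
        per-step input is the amplitude alone.
    pooling : {"mean", "max"}
        Statistic applied over valid steps of the top hidden sequence.
    wavelengths : array-like or None
        Grid wavelengths in nm used to build the per-step wavelength feature;
        None falls back to a uniform ramp over the steps.
    batch_size, learning_rate, epochs, betas, weight_decay, huber_delta,
    validation_fraction, random_state : training recipe.

    Attributes
    ----------
    params_ : dict of weight arrays.
    history_ : {"train_loss": [...], "val_loss": [...]} per epoch.
    n_features_in_ : number of wavelengths seen during fit.
    n_train_, n_val_ : split sizes.
    """

    def __init__(
        self,
        n_outputs: int = 5,
        hidden_size: int = 128,
        num_layers: int = 2,
        include_wavelength_feature: bool = True,
        pooling: str = "mean",
        wavelengths=None,
        batch_size: int = 32,
        learning_rate: float = 1e-4,
        epochs: int = 100,
        betas: tuple = (0.9, 0.999),
        weight_decay: float = 1e-5,
        huber_delta: float = 1.0,
        validation_fraction: float = 0.2,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.n_outputs = n_outputs
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.include_wavelength_feature = include_wavelength_feature
        self.pooling = pooling
        self.wavelengths = wavelengths
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.betas = betas
        self.weight_decay = weight_decay
        self.huber_delta = huber_delta
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- feature construction -------------------------------------------------

    def _wavelength_ramp(self, K: int) -> np.ndarray:
        if self.wavelengths is not None:
            wl = np.asarray(self.wavelengths, dtype=float)
            if wl.size != K:
                raise ValueError(
                    f"input has {K} wavelengths but estimator was given "
                    f"{wl.size} grid wavelengths"
                )
            if wl.size == 1:
                return np.zeros(1)
            return (wl - wl.min()) / (wl.max() - wl.min())
        return np.linspace(0.0, 1.0, K) if K > 1 else np.zeros(1)

    def _features(self, X: np.ndarray, wavelengths=None) -> np.ndarray:
        X = max_normalize_rows(X)
        B, K = X.shape
        if not self.include_wavelength_feature:
            return X[:, :, None]
        if wavelengths is not None:
            wl = np.asarray(wavelengths, dtype=float)
            ramp = (wl - wl.min()) / (wl.max() - wl.min()) if wl.size > 1 else np.zeros(1)
        else:
            ramp = self._wavelength_ramp(K)
        return np.stack([X, np.broadcast_to(ramp, (B, K))], axis=2)

    @property
    def _input_size(self) -> int:
        return 2 if self.include_wavelength_feature else 1

    # -- training -------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, K) and y (n, N) with matching n")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if y.shape[1] != self.n_outputs:
            raise ValueError(
                f"y has {y.shape[1]} components but n_outputs={self.n_outputs}"
            )
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        rng = np.random.default_rng(self.random_state)
        feats = self._features(X)
        n = X.shape[0]

        perm = rng.permutation(n)
        n_val = int(round(self.validation_fraction * n))
        n_val = min(max(n_val, 0), n - 1)
        train_idx, val_idx = perm[: n - n_val], perm[n - n_val :]
        self.n_train_, self.n_val_ = train_idx.size, val_idx.size

        self.params_ = _rnn.init_params(
            self._input_size, self.hidden_size, self.num_layers, self.n_outputs, rng
        )
        opt = _rnn.AdamW(
            self.params_, lr=self.learning_rate, betas=tuple(self.betas),
            weight_decay=self.weight_decay,
        )
        history = {"train_loss": [], "val_loss": []}
        for epoch in range(self.epochs):
            order = rng.permutation(train_idx)
            losses = []
            for start in range(0, order.size, self.batch_size):
                idx = order[start : start + self.batch_size]
                probs, cache = _rnn.forward(self.params_, feats[idx], pooling=self.pooling)
                loss, dprobs = _rnn.huber_loss(probs, y[idx], self.huber_delta)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch "
                        f"{start // self.batch_size}; try a lower learning rate"
                    )
                grads = _rnn.backward(self.params_, cache, dprobs)
                opt.step(self.params_, grads)
                losses.append(loss)
            history["train_loss"].append(float(np.mean(losses)))
            if val_idx.size:
                vp = self._forward_chunked(feats[val_idx])
                vloss, _ = _rnn.huber_loss(vp, y[val_idx], self.huber_delta)
            else:
                vloss = float("nan")
            history["val_loss"].append(vloss)
            if self.verbose:
                print(
                    f"epoch {epoch + 1}/{self.epochs}: "
                    f"train={history['train_loss'][-1]:.5f} val={vloss:.5f}"
                )
        self.history_ = history
        self.n_features_in_ = X.shape[1]
        return self

    def _forward_chunked(self, feats: np.ndarray, chunk: int = 4096) -> np.ndarray:
        outs = []
        for start in range(0, feats.shape[0], chunk):
            probs, _ = _rnn.forward(
                self.params_, feats[start : start + chunk],
                pooling=self.pooling, want_cache=False,
            )
            outs.append(probs)
        return np.concatenate(outs)

    # -- inference ------------------------------------------------------------

    def predict(self, X: np.ndarray, wavelengths=None) -> np.ndarray:
        """Simplex fractions, one row per fingerprint.

        ``wavelengths`` overrides the grid used for the per-step wavelength
        feature, enabling inference on grids other than the training grid.
        """
        if not hasattr(self, "params_"):
            raise RuntimeError("PAFRegressor is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._forward_chunked(self._features(X, wavelengths))

    def predict_sequences(self, sequences, wavelength_lists=None) -> np.ndarray:
        """Predict on variable-length fingerprints via padding and masking."""
        if not hasattr(self, "params_"):
            raise RuntimeError("PAFRegressor is not fitted")
        B = len(sequences)
        T = max(len(s) for s in sequences)
        feats = np.zeros((B, T, self._input_size))
        mask = np.zeros((B, T))
        for i, seq in enumerate(sequences):
            seq = np.asarray(seq, dtype=float)
            k = seq.size
            row = max_normalize_rows(seq[None, :])[0]
            feats[i, :k, 0] = row
            if self.include_wavelength_feature:
                if wavelength_lists is not None:
                    wl = np.asarray(wavelength_lists[i], dtype=float)
                    ramp = (
                        (wl - wl.min()) / (wl.max() - wl.min())
                        if wl.size > 1 else np.zeros(1)
                    )
                else:
                    ramp = np.linspace(0.0, 1.0, k) if k > 1 else np.zeros(1)
                feats[i, :k, 1] = ramp
            mask[i, :k] = 1.0
        probs, _ = _rnn.forward(
            self.params_, feats, mask=mask, pooling=self.pooling, want_cache=False
        )
        return probs


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(
    model: PAFRegressor, path: str | Path, library_hash: str | None = None
):
    """Single-file archive: weights plus a JSON manifest of config and history."""
    if not hasattr(model, "params_"):
        raise RuntimeError("cannot checkpoint an unfitted model")
    params = model.get_params()
    wl = params.pop("wavelengths")
    manifest = {
        "config": params,
        "history": model.history_,
        "n_features_in": int(model.n_features_in_),
        "n_train": int(model.n_train_),
        "n_val": int(model.n_val_),
        "library_hash": library_hash,
    }
    arrays = {f"param_{k}": v for k, v in model.params_.items()}
    if wl is not None:
        arrays["wavelengths"] = np.asarray(wl, dtype=float)
    np.savez(path, manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> PAFRegressor:
    """Restore an estimator that reproduces predictions bit-identically."""
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        cfg = manifest["config"]
        cfg["betas"] = tuple(cfg["betas"])
        model = PAFRegressor(**cfg)
        if "wavelengths" in data:
            model.wavelengths = data["wavelengths"]
        model.params_ = {
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        }
    model.history_ = manifest["history"]
    model.n_features_in_ = manifest["n_features_in"]
    model.n_train_ = manifest["n_train"]
    model.n_val_ = manifest["n_val"]
    return model
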