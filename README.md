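# pafingerprint

Spectral unmixing of multispectral photoacoustic data by **photoacoustic
fingerprinting**: a recurrent neural network maps the *shape* of a
per-voxel multiwavelength amplitude vector (the "fingerprint") to the
relative concentrations of endogenous chromophores — oxy- and
deoxyhemoglobin (HbO₂, HbR), lipid, water and collagen — and is benchmarked
against conventional non-negative least squares (NNLS) unmixing.  The
package targets photoacoustic imaging researchers who need quantitative
molecular maps (including oxygen saturation sO₂) under the two conditions
that break linear unmixing in practice: low SNR and unknown,
wavelength-dependent optical fluence.

## The model

The measured photoacoustic amplitude at wavelength λ follows the linear
forward model

    PA(λ) = Φ(λ) · Σᵢ μₐ,ᵢ(λ) Cᵢ ,

where μₐ,ᵢ is chromophore *i*'s absorption spectrum, Cᵢ its fractional
concentration (Σ Cᵢ = 1), and Φ(λ) the unknown local fluence.  A
*fingerprint* is the vector **f** = (PA(λ₁), …, PA(λ_K)) sampled on an
oversampled dual-band grid (700–970 nm and 1160–1400 nm at 10 nm steps,
K = 53 ≫ N = 5).

Training data are simulated: concentration vectors are drawn from five
mixture classes (pure, extreme, dominant, random, binary) and four
anatomical patterns (vessel-like, fat-dominant, collagen-rich, water
background); fluence distortion uses the parametric prior
Φ(λ; x) = exp(−(1−λ̃)² x) with severity x ~ U[0, 20] (λ̃ the min-max
normalised wavelength); and each clean fingerprint f₀ is scaled by
α = √(10^(SNR/10)/P_s), P_s = mean(f₀²), before adding unit-power Gaussian
noise, with SNR ~ U[3, 40] dB.

The regressor (`PAFRegressor`, scikit-learn style) feeds the max-normalised
fingerprint step by step through stacked LSTM layers, pools the hidden
states over valid steps, and applies a linear + softmax readout so
predictions live on the probability simplex.  It is trained with AdamW and
Huber loss.  The NNLS baseline (`NNLSUnmixer`) solves
min‖M c − f‖₂ s.t. c ≥ 0 per fingerprint and renormalises the coefficients.
The whole network, including backpropagation through time, is implemented
in NumPy and verified against finite differences.

## Worked example

```python
import paf

lib = paf.synthetic_library()                     # K=53 x N=5 library
cfg = paf.SimConfig(size=20_000, fluence_mode="random")
train = paf.generate_dataset(cfg, lib, seed=11)

model = paf.PAFRegressor(hidden_size=48, num_layers=1, batch_size=256,
                         learning_rate=2e-3, epochs=15, random_state=0,
                         wavelengths=lib.grid.wavelengths_nm)
model.fit(train.amplitudes, train.concentrations)

test = paf.generate_dataset(paf.SimConfig(size=4000, fluence_mode="random"),
                            lib, seed=99)
paf_rep = paf.parity_metrics(
    test.concentrations,
    model.predict(test.amplitudes, wavelengths=lib.grid.wavelengths_nm))
nnls_rep = paf.parity_metrics(
    test.concentrations, paf.NNLSUnmixer(lib).fit().predict(test.amplitudes))
print(f"PAF  R2={paf_rep.r2:.3f} RMSE={paf_rep.rmse:.3f}")
print(f"NNLS R2={nnls_rep.r2:.3f} RMSE={nnls_rep.rmse:.3f}")
```

Output from this exact script:

```
PAF  R2=0.524 RMSE=0.209
NNLS R2=-0.405 RMSE=0.359
```

Under random fluence distortion the NNLS baseline collapses (negative
pooled R²: worse than predicting the mean) while even this briefly trained
recurrent model recovers a large fraction of the concentration variance —
the central robustness result.  `paf.unmix_image` applies either method
per pixel to an energy-normalised multispectral stack and derives sO₂ maps;
`paf.region_stats` summarises concentration maps over labelled ROIs.

A thin CLI mirrors the library: `paf simulate`, `paf train`, `paf predict`,
`paf nnls`, `paf make-library`.

## Layout

- `paf.library` — absorption spectra, dual-band wavelength grid, spectral library I/O
- `paf.simulate` — mixture/anatomical sampling, fluence prior, SNR-calibrated noise, dataset generation (HDF5)
- `paf.synthetic` — synthetic spectra and imaging phantoms
- `paf.model`, `paf._rnn` — the recurrent regressor and its NumPy core
- `paf.nnls` — Lawson–Hanson NNLS baseline
- `paf.metrics` — parity metrics, AAE stratification, cohort tests, sO₂
- `paf.imaging` — energy normalisation, MAP projection, per-pixel unmixing, ROI statistics
- `paf.experiments` — shared study protocols
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
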