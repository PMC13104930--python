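# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package, in the order data flows through it.

## Spectral library

Chromophore absorption spectra are kept in their source units ("raw
absorbance"): the methods here only ever compare *relative* amplitudes, and
cross-source unit conversions would add error without changing any result.
A warning is emitted when library column maxima differ by more than 10³×,
the usual symptom of mixed units.  Spectra are linearly interpolated onto
the dual-band acquisition grid (700–970 nm and 1160–1400 nm, 10 nm steps,
K = 53); extrapolation outside a spectrum's tabulated support is refused
rather than guessed.  The chromophore order [HbO₂, HbR, lipid, water,
collagen] is fixed package-wide so column indices can never silently swap.

The built-in synthetic library replaces the third-party digitized
compilations (which cannot be redistributed) with sums of Gaussians chosen
once to reproduce the *collinearity structure* that makes real unmixing
hard: the two hemoglobins share their broad NIR shape and differ mainly
around the 760 nm deoxy peak (column cosine ≈ 0.95), and lipid, water and
collagen share broad idle-band absorption (collagen–lipid cosine ≈ 0.98,
collagen–water ≈ 0.90).  Absolute numbers computed on this library are
therefore library-specific; the qualitative comparisons (model vs. NNLS,
error trends, group orderings) are the portable results, and users with
digitized literature spectra can drop them in via `load_spectrum`.

## Concentration sampling

The five spectral-complexity mixture classes act directly on the five
chromophores, so their structural invariants hold verbatim: pure = one-hot;
extreme/dominant = dominant component uniform in [0.90, 0.99] / [0.70,
0.90] with the remainder shared by a symmetric Dirichlet(1) draw; random =
Dirichlet(1) on the simplex; binary = exactly two components, the split
uniform in [0.01, 0.99].  The four anatomical patterns are specified at the
group level (hemoglobin, lipid, water, collagen); where a recipe assigns
mass m to "hemoglobin" it is split HbO₂ = s·m, HbR = (1−s)·m with
s ~ U(0, 1), except vessel-like which uses s ~ U(0.5, 1.0) to bias towards
arterial oxygenation.  Group dominances: vessel-like hemoglobin ~ U(0.7,
1.0); fat-dominant lipid ~ U(0.6, 0.95); collagen-rich collagen ~ U(0.5,
0.9); background water ~ U(0.7, 1.0); remainders are Dirichlet(1) over the
other groups.  These recipes are declared defaults, not inferred facts, and
every range is a `SimConfig` parameter.

A post-hoc `structural_class` function reclassifies any vector by its
realised structure (support size and maximum), for accountings that bin
anatomical draws back into the five structural groups.

## Forward model, fluence and noise

Clean fingerprints are f₀ = Φ ⊙ (M c).  The fluence prior is
Φ(λ; x) = exp(−(1−λ̃)² x) with λ̃ min-max normalised over the grid: unity at
the longest wavelength, monotonically stronger attenuation toward shorter
wavelengths, and x ~ U[0, 20] spanning near-uniform fluence to severe
spectral reddening.  This one-dimensional prior deliberately ignores
lateral heterogeneity and real radiative transport; it is a training prior,
not a light-transport model.

Noise is calibrated in power: with P_s = mean(f₀²) over the K wavelengths
and unit-power Gaussian noise, scaling the signal by
α = √(10^(SNR_dB/10)/P_s) makes the realised ratio
10·log₁₀(power(α f₀)/power(ε)) equal the target.  (Solving the power
equations for α requires the square root; the Monte-Carlo calibration test
confirms the realised SNR is within 0.2 dB of target across 5–40 dB.)
SNR ~ U[3, 40] dB per fingerprint.  Noise is added *before* any
normalisation; max-normalisation is applied only on the model-input path,
matching the convention that NNLS consumes raw energy-normalised
fingerprints while the model consumes shape only.

Dataset generation derives one deterministic RNG substream per mixture
class from the user seed (numpy `SeedSequence` spawning), so datasets are
bit-reproducible from (seed, config, library) and class blocks can be
resized independently.  Vectorised per-class sampling was preferred over
per-record substreams because constructing 10⁶ generator objects costs tens
of seconds without changing any statistical property.

## The recurrent regressor

Per-step input is the max-normalised amplitude plus (by default) the
min-max normalised wavelength, so one model can run on sub-sampled grids;
a strict amplitude-only mode is a flag.  Stacked LSTM layers (gate order
input/forget/cell/output, forget bias 1) process the K steps; hidden states
are pooled by a masked mean (masked max available), which supports
variable-length fingerprints; a linear layer plus softmax yields simplex
outputs.  The loss is smooth-L1 (Huber, transition 1.0 — at simplex scale
residuals stay in the quadratic regime, making it effectively half-MSE with
a safeguard) and the optimizer AdamW (betas 0.9/0.999, weight decay 1e-5,
biases excluded from decay).  Defaults follow the reference recipe (batch
32, learning rate 1e-4, 100 epochs, 80/20 train/validation split).

The core is pure NumPy with hand-written backpropagation through time,
checked against central finite differences for both pooling modes and for
padded variable-length batches.  Training is deterministic given
`random_state`; exact bitwise reproducibility across BLAS backends is not
guaranteed, so statistical rather than bitwise criteria are used for
trained-model behaviour (checkpoint save/load, by contrast, is bitwise).

### Scaled-down protocol

The reference-scale recipe (10⁶ fingerprints, 100 epochs) is impractical
for a CPU test cycle.  The package's standard scaled protocol — used by the
end-to-end tests and `scripts/acceptance.py` — trains on 60 000
fluence-distorted fingerprints for 30 epochs with hidden size 48, one LSTM
layer, batch 256 and learning rate 2e-3 (the larger batch and rate
compensate for the smaller sample budget), and a 20 000-sample/15-epoch
unit-fluence counterpart.  These sizes preserve every qualitative
comparison (model ≫ NNLS under fluence, flat error-vs-fluence curve, group
orderings, phantom identification) while keeping absolute accuracy below
what full-scale training reaches; reported R² values from scaled models
should be read with that in mind.

## NNLS baseline

Per-fingerprint min‖Mc − f‖₂ s.t. c ≥ 0 via scipy's Lawson–Hanson
active-set solver; an independent projected-gradient solver with a
1/L(MᵀM) step serves as the validation oracle.  Because α and Φ make the
raw coefficient scale arbitrary, comparisons use simplex-renormalised
fractions.  An all-zero solution (possible when noise drives the best fit
to the boundary) leaves the fraction vector undefined; metrics score it as
a zero prediction and flag it, which penalises rather than rewards
degeneracy.  The baseline consumes raw fingerprints without max-scaling
(fractions are scale-invariant, so secondary scaling is immaterial; a flag
allows testing the alternative).

## Metrics

Parity metrics pool all (true, predicted) component pairs: R² = 1 −
SS_res/SS_tot about the mean of the true values, RMSE over pooled
components, and the free-intercept OLS slope of predicted on true.  The
squared Pearson correlation is emitted alongside as the regression-r²
sensitivity variant, and per-chromophore tables accompany every pooled
number.  AAE is mean |pred − true| per chromophore, stratified on request
by SNR (5 dB bins over [3, 40]), fluence (width-2 bins over [0, 20]) or
mixture class; empty strata are reported as absent, never as zero.  Cohort
comparisons across independent test sets use Welch's unequal-variance
two-tailed t-test, with a degenerate-variance rule (identical constant
cohorts → t = 0, p = 1; distinct constant cohorts → p = 0).
sO₂ = HbO₂/(HbO₂+HbR), undefined (NaN) when both vanish.

## Image pipeline

Stacks are indexed (wavelength, z, y, x); energy normalisation divides each
wavelength frame by its pulse energy and resets the stored energies to 1
(making the operation idempotent); MAP projection takes the per-wavelength
maximum over depth.  Per-pixel unmixing masks pixels whose peak amplitude
falls below 5 % of the stack maximum (default, exposed) or containing
non-finite values — masked, not imputed.  The five-region phantom generator
stands in for a physical multi-component phantom scan: five disk regions
(HbO₂-rich, HbR-rich, lipid, collagen+water, water) forward-modelled
through the library at configurable SNR and fluence, with signal-free
background.  The collagen+water region uses a 0.55/0.40 split rather than a
near-tie so that region-level argmax identification is well-posed.

## What the synthetic study does and does not show

The generator reproduces the simulation conditions exactly (mixture
classes, fluence prior, SNR calibration), so passing tests demonstrate the
method's behaviour *under that forward model*.  It does not emulate real
tissue: no radiative transport beyond the 1-D exponential prior, no
acoustic propagation or reconstruction artefacts, wavelength-independent
Gaussian noise only, and synthetic rather than measured absorption spectra.
Results on measured data additionally depend on energy calibration, the
fidelity of the supplied spectral library, and the domain gap between the
fluence prior and real light transport.  Liver- and artery-style analyses
are supported at the operation level (ROI statistics, fold changes, sO₂
maps) but no claim about real tissue is tested here.

## Numerical choices

- Simplex tolerance 1e-9 for sampled vectors, 1e-6 for softmax outputs.
- Interpolation refuses extrapolation; grids must lie inside every
  spectrum's support.
- NNLS active-set determinism comes from scipy's implementation; oracle
  equivalence is asserted on the objective (1e-8) rather than on
  coefficients, which may be non-unique for rank-deficient instances.
- `normalize_max` divides by the (signed) maximum and errors when it is
  non-positive; the model's internal path falls back to the maximum
  absolute value for noise-dominated rows so inference never aborts on
  measured data.
- Fluence profiles are clipped nowhere: exp(−20) ≈ 2e-9 is representable
  and keeps the model exact.
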