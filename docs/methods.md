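# Methods

## Problem

Leaf functional traits — chlorophyll a+b content (CHL, µg/cm²), equivalent
water thickness (EWT, g/cm²) and leaf mass per area (LMA, g/cm²) — can be
estimated from 400–2400 nm leaf reflectance, but regressors trained on one
spectral dataset transfer poorly to others (different ecosystems, species,
instruments). This package implements a two-stage remedy:

1. **Physics pretraining.** A leaf radiative-transfer simulator generates
   arbitrarily large spectra–trait corpora; a residual convolutional
   regressor is pretrained on them, so its features encode biophysical
   structure rather than dataset idiosyncrasies.
2. **Adversarial domain adaptation.** The pretrained model is fine-tuned on
   a labeled source domain plus a target domain of which only a small
   ("few-shot") subset is labeled, while an adversarial alignment head
   pushes the encoder toward domain-invariant features.

## Leaf radiative transfer (generalized plate model)

The leaf is modeled as `N ≥ 1` identical absorbing plates separated by air.
Per-plate optical depth at wavelength λ is the concentration-weighted
mixture

    k(λ) = (Cab·k_ab + Ccx·k_cx + Can·k_an + Cbp·k_bp + Cw·k_w + Cm·k_m) / N

with specific absorption coefficients for chlorophylls, carotenoids,
anthocyanins, brown pigments, water and dry matter. A plate transmits
isotropic light with

    τ(k) = (1 − k)·e^(−k) + k²·E1(k),

E1 the exponential integral (evaluated by `scipy.special.exp1`, accurate to
machine precision; τ(0)=1 by continuity). Interfaces follow Fresnel theory
averaged over an incidence cone:

    tav(α, n) = ∫₀^α t_F(θ, n) sinθ cosθ dθ / ∫₀^α sinθ cosθ dθ,

computed by 64-node Gauss–Legendre quadrature (no closed form is used; the
test oracle is independent adaptive quadrature, agreement ≤ 1e−6). The top
surface sees direct light within α = 40° (the standard convention;
configurable); internal interfaces see isotropic light (α = 90°). The
single top plate with directional incidence is combined with the remaining
N−1 plates through the classic two-stream (Stokes) composition for stacks
of identical layers; non-integer N uses real-valued exponents `b^(N−1)`.
Where the single-plate reflectance and transmittance satisfy r + t ≥ 1
(vanishing absorption) the Stokes discriminant degenerates and the analytic
limit `T_sub = t / (t + (1−t)(N−1))`, `R_sub = 1 − T_sub` is used, so the
zero-absorption case conserves energy to 1e−8 instead of producing NaN.
τ is floored at 1e−128 to keep the Stokes exponentials inside double range
for numerically opaque leaves.

Trait conversion: CHL = Cab; EWT = Cw × ρ_water with ρ_water = 1 g/cm³
(numerically the identity); LMA = Cm.

## Synthetic data: the stated world

Parameter box (defaults of `ParamRanges`): N 1.0–1.9, Cab 0.1–100 µg/cm²,
Ccx 1.0–25.0 µg/cm², Can 1.2–1.8 µg/cm², Cbp 0.01–1.0, Cw 0.01–0.05 cm,
Cm 0.004–0.009 g/cm². Sampling is plain Latin hypercube: one point per
equal-width bin per dimension, independent random bin permutations, no
correlation control. Pretraining corpora are noiseless by default.

**Optical constants.** The published plate-model coefficient tables are not
bundled; `load_optical_constants` reads them from CSV when available, and a
deterministic synthetic stand-in (`synthetic_optical_constants`) is the
default substrate. It places Gaussian absorption bands at the canonical
features (chlorophyll 670/430 nm, carotenoids 490 nm, anthocyanins 550 nm,
water 1450/1940 nm, broad dry-matter rise beyond 1700 nm, brown pigments
decaying from 400 nm) with amplitudes chosen so that typical concentrations
give optical depths of order 0.1–5, and a smooth refractive index falling
from 1.45 to 1.33. It reproduces the qualitative shape of real leaf
spectra (green peak, red edge, NIR plateau, SWIR water dips) but not their
exact values — green tests therefore establish correctness of the
machinery and the qualitative orderings, not agreement with any measured
leaf.

**Domain shift scenarios** (`make_domain_pair`) distort a second draw of
the generator: shifted/narrowed trait ranges (label shift), a linear
band-wise gain ramp, additive offset, Gaussian smoothing and additive noise
with clipping to [0, 1] (covariate shift), plus a seeded few-shot labeled
subset (default 10 % of target rows). This emulates cross-instrument and
cross-ecosystem transfer; it does not emulate specific instruments'
response functions or structured (non-i.i.d.) sensor noise.

## Model

Spectra (2000 bands, 400–2399 nm at 1 nm — 2000 bands exactly; the grid is
configurable and recorded in outputs) are linearly interpolated to side²
samples, filled row-major into a square plane and replicated into three
channels; the mapping is approximately invertible (round-trip error
< 1e−3 for smooth spectra), so no spectral information is destroyed beyond
interpolation. Zero-padding is available as an ablation alternative.

The encoder is a bottleneck residual network: 7×7 stride-2 stem + 3×3
max-pool, four stages of 1×1→3×3→1×1 blocks with ×4 expansion and stride-2
transitions, global average pooling. Two presets:

| preset | input | stage channels | blocks | features |
|--------|-------|----------------|--------|----------|
| paper  | 224×224×3 | 64→256→512→1024 | 1,2,2,2 (22 convs + stem) | 1024 |
| small  | 32×32×3   | 16→32→64→128    | 1,1,1,1 | 128 |

"small" is the default for tests and desk-scale experiments; "paper" is the
full-scale architecture. An MLP head (hidden = features/2) regresses the
three traits jointly. Targets are min–max scaled to [0, 1] per training
split (they span four orders of magnitude across units); predictions are
returned unscaled. Deep models consume raw reflectance so simulated and
measured spectra share a scale; the PLSR baseline consumes per-band
standardized reflectance (train statistics only).

The framework is implemented in numpy (float64) with explicit
backpropagation and finite-difference-verified gradients for every layer;
runs are bit-reproducible given seeds on a single thread.

## Training

Stage 1: Adam, 200 epochs (default; desk-scale runs use 20–60), batch 64,
learning rate decaying linearly 1e−3 → 1e−5 ("decaying by 1e−5" is
ambiguous; linear decay to 1e−5 is this package's reading). Loss: sum over
traits of per-trait mean squared error. 15 % of the corpus is held out for
the validation-loss history and optional early stopping (patience 10 when
enabled by the protocols).

Stage 2: Adam, 100 epochs (default), batch 32, learning rate 1e−4. Each
step takes half a batch from each domain and makes one encoder pass; the
regression loss uses the labeled rows (all source + few-shot target), the
alignment loss all rows. Composite objective L = λ1·L_MSE + λ2·L_DA with
λ1 = 1.0, λ2 = 0.3 (λ2 borrowed from the adversarial strength λ = 0.3, as
no tuned value is published).

**Alignment head.** A contrastive attention module weights each feature row
by its best cosine similarity to the other domain's batch, clipped to
[0, 1] (weights are treated as constants in the backward pass — no gradient
flows through the max). The default alignment loss is DANN-style: a
two-layer domain classifier on the weighted features behind a gradient
reversal layer (identity forward, −λ_grl× gradient backward, λ_grl = 0.3),
trained with binary cross-entropy; adversarial confusion makes the encoder
domain-invariant. A direct cosine penalty, 1 − cos of the two domain
prototype means with no reversal, is available as `da_mode="cosine"` —
the two realizations reflect two plausible readings of the published
description, and neither is labeled the true intent.

## Evaluation

R² = 1 − Σ(ŷ−y)²/Σ(y−ȳ)²; nRMSE = RMSE/ȳ (the normalization sits outside
the root). Protocols:

- **Stratified k-fold** on pooled datasets, stratification key = dataset
  label, per-fold dataset counts proportional within ±1, 15 % of each
  training split reserved for early stopping.
- **Leave-one-dataset-out** and ordered **pairwise** transfers. Band
  statistics, target scalers and early stopping are fit on training rows
  only. The held-out dataset is passed to adaptive models as the target
  domain with a seeded few-shot labeled subset; metrics are computed on the
  non-few-shot rows, identically for every model in a comparison.
- **Holdout**: fixed training pool, one independent test dataset.

The benchmark zoo: PLSR (component count by internal 5-fold CV over 1–20
unless fixed), plain ResNet, physics-pretrained ResNet (λ2 = 0),
adversarial ResNet-GRL (no pretraining), and the full two-stage model. The
two ablations are literally configurations of the full model (corpus on/off,
λ2 zero/non-zero), asserted by construction.

## Known limitations

- The synthetic optical constants are qualitative stand-ins; absolute
  reflectance values and any downstream numbers differ from runs on the
  published coefficient tables.
- The published real-data results pool five measured datasets that are not
  bundled here; the package reproduces the protocols and qualitative
  orderings on simulated scenarios, not those numbers.
- Under strong label shift (e.g. a shifted Cab range), marginal feature
  alignment is mis-specified for the shifted trait: the adversarial term
  mainly helps the covariate-shift component (gain/noise), and can be
  neutral or slightly adverse for the label-shifted trait. This is visible
  in the desk-scale efficacy runs and is a property of DANN-style
  alignment, not an implementation artifact.
- The 1-D-convolution baseline variant mentioned alongside the 2-D reshape
  pipeline is not implemented; the 2-D path is canonical here.
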