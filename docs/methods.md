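# Methods

`cropnpp` estimates monthly and growing-season net primary productivity
(NPP) of cropland from multispectral surface reflectance and monthly
station meteorology. The chain is: vegetation indices → FPAR retrieval
(a small 1-D CNN on RFE-selected indices, with the classic empirical
NDVI/RVI stretch as the built-in baseline) → the CASA light-use-
efficiency model. A synthetic scene generator provides ground truth so
that every stage is verifiable without external data.

## The CASA light-use-efficiency model

Monthly NPP per pixel x and month t:

    NPP(x,t)  = APAR(x,t) · ε(x,t)                      [gC/m²/month]
    APAR(x,t) = SOL(x,t) · FPAR(x,t) · 0.5              [MJ/m²/month]
    ε(x,t)    = Tε1(x) · Tε2(x,t) · Wε(x,t) · ε_max     [gC/MJ]

SOL is total monthly shortwave radiation; the factor 0.5 is the PAR
fraction of shortwave. ε_max defaults to 0.389 gC/MJ, a standard crop
value; a per-crop lookup can replace the scalar. The growing season is
April–October inclusive; the seasonal total is the pointwise sum, with
a strict masking policy by default (a pixel masked in any month is
masked in the total; a "partial" mode sums the available months).

The stress scalars use the standard regional-CASA forms, since only
their role — down-regulation by temperature and water — is prescribed:

* `Tε1 = 0.8 + 0.02·Topt − 0.0005·Topt²`, clamped to [0,1], and zero in
  months whose mean temperature is ≤ −10 °C (dormant vegetation).
* `Tε2 = 1.1814 / [(1 + e^{0.2(Topt−10−T)})(1 + e^{0.3(−Topt−10+T)})]`,
  clamped to [0,1]; it peaks near T = Topt (≈0.9914) and decays for
  cold or hot excursions.
* `Wε = 0.5 + 0.5·EET/PET ∈ [0.5, 1]`, with estimated
  evapotranspiration `EET = min(P, PET)` (supply–demand bound) and PET
  from the Thornthwaite monthly formulation (heat index from the full
  year of monthly temperatures; 12-hour day length assumed, i.e. no
  latitude correction). Where PET = 0 there is no atmospheric demand
  and Wε = 1. Externally computed EET/PET grids can be supplied for
  users who run a full regional-evapotranspiration chain.

Topt, the optimal growth temperature, is the mean temperature of the
month in which the NDVI (or, in the generator, LAI) seasonal profile
peaks; ties resolve to the earliest month.

## Vegetation indices

Fifteen indices are computed from Sentinel-2-style bands B2–B8A:
ARVI, DVI, EVI, GEMI, GNDVI, MSAVI, NDI45, NDVI, PVI, RVI, REIP, SAVI,
TNDVI, TSAVI, WDVI. Soil-adjusted indices use the soil-line slope
s = 1.2, intercept a = 0.08, soil-noise factor X = 0.08 and SAVI
L = 0.5 (standard published values, all overridable). Conventions where
published typography is ambiguous:

* ARVI uses the γ = 1 atmospheric correction rb = 2·B4 − B2.
* MSAVI is the closed form (2·B8+1 − √((2·B8+1)² − 8·(B8−B4)))/2.
* TNDVI = √(NDVI + 0.5), masked where the radicand is negative.
* GEMI uses n = (2(B8A²−B4²) + 1.5·B8A + 0.5·B4)/(B8A+B4+0.5) and
  GEMI = n(1−0.25n) − (B4−0.125)/(1−B4).
* In PVI, WDVI and TSAVI the coefficient multiplying the red band is
  the slope s and the additive constant the intercept a, one consistent
  convention across all three (the canonical literature reading).
* GNDVI is computed from B7 and B3.

Reflectance in (−0.01, 0) is clamped to 0; values outside [−0.01, 1.2]
are masked. Any denominator (or radicand) within 1e-9 of zero masks the
pixel rather than producing an infinity.

## FPAR retrieval

**Feature preparation.** Features are min-max normalized to [0,1] per
feature; the scaling is recorded in the model archive and re-applied at
prediction time. FPAR targets are already a fraction and stay in [0,1].

**Recursive feature elimination.** A gradient-boosted regression tree
(100 trees, depth 3) is fit on the remaining features; the feature with
the smallest impurity importance is removed, one per step, optionally
recording a 5-fold cross-validated R² per step. Survivors are ranked by
final-fit importance. The default final set size is 10 of 15: smaller
sets were observed to discard informative soil-adjusted indices and
measurably degrade the retrieval on synthetic scenes, while 10 keeps
the selection meaningful and the downstream accuracy high.

**The CNN.** Three 1-D convolutional layers (16, 32, 64 filters, kernel
size 2, 'same' padding, ReLU), max-pooling of size 2 after each
(ceil mode, so a 15-long input survives three poolings: 15→8→4→2),
dropout 0.3 on the flattened activations, then dense layers 64→32→1
with a linear scalar output. Adam at learning rate 0.001, MSE loss,
10 epochs, batch size 16, 7:3 train/test split by seeded shuffle
(protocol seed 42). The scalar linear output replaces the softmax the
source text mentions, which is ill-defined for scalar MSE regression.
Numerics: Glorot-uniform initialization and internal target
standardization (the network fits standardized targets and inverts the
transform at prediction time; FPAR's small variance otherwise
under-scales a 10-epoch optimization). Predictions are clipped to
[0,1]. The implementation is plain numpy with analytic backpropagation,
verified against numerical gradients in the test suite.

**Tree baselines.** GBDT (scikit-learn) and XGBoost regressors with
500 trees, depth 6, learning rate 0.05, using the same split protocol.

**Empirical baseline.** The classic FPAR is the average of two linear
stretches: NDVI between (ndvi_min, ndvi_max) and the simple ratio RVI
between (sr_min, sr_max), each mapped onto (0.001, 0.95) and clamped.
Bounds default to the 5th/95th percentiles of vegetated pixels
(NDVI ≥ 0.2) in the scene at hand, overridable by config.

## Station meteorology

Daily radiation (J/m²/day) converts to monthly totals as
value · days_in_month / 1e6 (MJ/m²/month). Interpolation to the grid is
ordinary kriging with an exponential variogram
γ(h) = nugget + sill·(1 − e^{−h/range}) fitted by weighted least
squares to the binned empirical semivariogram (nugget 0 by default, so
the surface is exact at stations); with fewer than 3 stations, or a
singular kriging system, inverse-distance weighting (power 2) is used.

## The synthetic scene generator

The generator emulates the statistical structure the pipeline assumes,
at the study's climate: per-class LAI follows a double-logistic
seasonal curve (green-up and senescence logistics; peak LAI ≈ 5 for
rice/corn), modulated by a smooth per-pixel heterogeneity field (±15%);
FPAR = 1 − exp(−k·LAI) with extinction k = 0.5 (Beer–Lambert); band
reflectance is a linear canopy/soil endmember mixture weighted by FPAR,
plus independent Gaussian band noise (σ = 0.005); meteorology is a
seasonal sinusoid whose annual statistics match the configured climate
(defaults 9.3 °C mean temperature, 710.2 mm precipitation,
summer-peaking radiation ~400 ± 250 MJ/m²/month); true NPP is the CASA
forward model run on the true FPAR, so forward self-consistency holds
to machine precision by construction. Cloud contamination injects
bright, spectrally flat rectangular patches into configured months and
flags them; the stored truth is untouched (contamination is
observational).

What the generator does **not** emulate: radiative-transfer canopy
physics (no PROSAIL-grade BRDF, no view/illumination geometry), band-
correlated or spatially correlated noise, topography, atmosphere, mixed
pixels at field boundaries, or real label error (reference FPAR in the
field comes from an external biophysical processor with its own ~0.07
RMSE). Passing tests therefore demonstrate internal correctness and
the *direction* of the CNN-over-empirical improvement, not real-data
accuracy levels.

## Verification scales and numerical choices

Tests and the acceptance script run on 24×24–40×40 scenes, full-year
meteorology, and n = 2756 regression samples (mirroring the reference
sample count) — sizes chosen so the whole suite runs in minutes on one
CPU while every property remains sharply testable. Zero-denominator
tolerance 1e-9; NPP MAPE is evaluated on pixels with true annual NPP
> 1 gC/m² (relative error is undefined on bare soil); ties in the Topt
peak-month rule break toward the earlier month; the annual-sum masking
policy is strict by default. Model archives are versioned JSON
(weights, feature order, feature and target scaling, config hash).

## Known limitations

* A single scalar ε_max does not distinguish C3 and C4 crops; the
  per-crop lookup hook exists but no calibration is shipped.
* Thornthwaite PET ignores day-length latitude correction and wind/
  humidity; Wε is a coarse supply–demand proxy.
* The CNN is trained per scene/config; no transfer across regions.
* Kriging assumes second-order stationarity; trends are not modeled
  (no universal kriging), and very small station networks fall back to
  IDW.
* Tree baselines are not serialized to the JSON archive; they are
  evaluated in-session only.
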