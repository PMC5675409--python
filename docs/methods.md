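# Methods

This note documents the models, parameters and design choices behind
`grassnpp`, in the spirit of a model-description appendix: what is
computed, under which assumptions, and what the synthetic experiments do
and do not demonstrate.

## The CASA chain

Monthly NPP is APAR × ε. The pieces:

**NDVI and compositing.** NDVI = (NIR − red)/(NIR + red) per sub-monthly
reflectance layer; monthly NDVI is the per-pixel maximum-value composite
(MVC), the standard choice for suppressing cloud and atmospheric
depression of the vegetation signal. A pixel is nodata only if every
sub-monthly layer is nodata.

**FPAR.** Two linear estimates — from NDVI between per-class bounds
(NDVI_min → 0.001, NDVI_max → 0.95) and from SR = (1+NDVI)/(1−NDVI)
between the corresponding SR bounds — are averaged. Out-of-range values
are clamped rather than rejected: remote-sensing inputs are noisy, and a
hard error on a single saturated pixel would be unhelpful. Class bounds
are calibrated from the NDVI history as the 5th/95th percentiles of each
class's valid samples (configurable); SR bounds are SR evaluated at those
NDVI percentiles, not percentiles of SR — the two differ because SR is
convex in NDVI, and evaluating SR at the NDVI quantiles keeps the two FPAR
estimates consistent at the bounds.

**Stress scalars.** Tε1 = 0.8 + 0.02·T_opt − 0.0005·T_opt², floored at 0,
and set to 0 in months with mean temperature ≤ −10 °C. T_opt is the mean
temperature of the month in which NDVI peaks, computed per pixel per year
(rather than once for the whole record): the optimum then tracks the
year's actual phenology, and either convention gives identical results on
worlds with a stable seasonal cycle. Tε2 = 1.1814 / (1 + e^{0.2(T_opt − 10
− T)}) / (1 + e^{0.3(−T_opt − 10 + T)}); above T_opt + 10 the value is
capped at the scalar's value at T_opt (the raw curve is already decreasing
there, so the cap is a safeguard rather than an active constraint). Wε =
0.5 + 0.5·EET/PET clamped to [0.5, 1], the driest limit 0.5 applying when
PET = 0.

**Evapotranspiration.** PET is Thornthwaite's monthly formulation
(annual heat index per pixel-year, day-length/month-length correction).
EET comes from a single-layer soil-moisture bucket iterated
chronologically: EET_m = min(PET_m, P_m + soil water), with the residual
recharging the bucket up to a configurable capacity (default 100 mm,
a typical plant-available water capacity for steppe soils) and the
bucket initialised at half capacity. The bucket is the simplest model that
gives EET/PET the right qualitative behaviour (supply-limited in dry
months, demand-limited after rain) and is isolated behind one function so
a different regional ET model can be swapped in.

**Efficiency and NPP.** ε = Tε1·Tε2·Wε·ε_max with ε_max = 0.542 gC·MJ⁻¹
(grassland) and 0.429 gC·MJ⁻¹ (shrub); APAR = SOL·FPAR·0.5; NPP =
APAR·ε, floored at 0. December–February NPP is forced to zero —
temperature and moisture stress make winter production negligible and
snow contaminates winter NDVI — so annual NPP is growing-season NPP, and
the annual total is exactly the spring + summer + autumn sum (the sums
are accumulated season-wise so the identity holds bit-exactly).

## Climate fields

Station monthly temperature, precipitation and sunshine are spread to the
grid with inverse-distance weighting, power 2 by default (configurable).
Two exactness rules: a pixel whose footprint contains a station takes that
station's value, and coincident duplicate stations are rejected. Positive
weights bound every interpolated value by the station extremes. Sunshine
duration converts to total monthly solar radiation with
Ångström–Prescott, SOL = (a + b·n/N)·Ra, using FAO-56 defaults a = 0.25,
b = 0.50 and FAO-56 solar geometry (mid-month declination, day length N,
extraterrestrial radiation Ra); n/N > 1 is clipped to 1 with a warning.
Kriging with a fitted variogram is out of scope by design — IDW is
deterministic, parameter-light, and adequate for a nine-station network.

## Attribution

Per-pixel Pearson correlations over years, and first-order partial
correlations Rp = (r12 − r13·r23)/√((1−r13²)(1−r23²)) computed from the
three pairwise coefficients. Significance is a two-tailed t-test with
t = r·√((n−k)/(1−r²)), k = 2 (plain) or 3 (partial). No multiple-testing
correction is applied by default, matching the per-pixel-map convention
in this literature; a Benjamini–Hochberg FDR flag is available. With a
13-year record the per-pixel power is low — a true-zero partial
correlation has median |r| ≈ 0.2 at n = 13 — so maps carry n_years and
consumers should read them as patterns, not per-pixel inference. County
tables average NPP/precipitation (sums) and temperature (means) over each
county's pixels first, then correlate the county series.

## The synthetic world

The generator emulates the study conditions of a semi-arid steppe:
13 years (2001 onward), a 9-station network on a jittered 3×3 layout, a
3×3 block county partition, mean annual precipitation 295 mm with a +50%
west→east gradient and 56% of the total in July–September, a continental
temperature cycle with annual mean 3.36 °C and ±19 °C seasonal amplitude,
yearly anomalies of 15% (precipitation, fractional) and 0.9 °C
(temperature). Latent relative productivity is multiplicative:

    rel = template(month) × base(x) × (1 + g_p·precip_anom)
          × (1 + g_t·temp_anom) × (1 + noise_sd·z)

with g_p = 0.8, g_t = 0 and noise_sd = 0.05 by default. NDVI is the scaled
latent curve (peak 0.65) and reflectance is back-solved from it with red
fixed at 0.08, so NDVI recomputed from reflectance is exact; each month's
sub-period layers degrade NDVI except one, so the MVC recovers the target
exactly. Latent NPP is the same curve scaled to a 240 gC·m⁻²·yr⁻¹ regional
mean — a typical plain-steppe productivity — with winter zeroed. Because
the coupling is linear in annual precipitation, the noiseless world has
per-pixel NPP–precipitation correlation exactly 1, making sign-recovery
expectations analytic rather than approximate.

Two deliberate conditioning choices. First, yearly temperature anomalies
are Gram–Schmidt-conditioned on the precipitation year factors so the
configured temperature–precipitation correlation (−0.6, wet years cooler)
is realised *exactly in-sample*: with only 13 shared draws a free sample
correlation scatters roughly ±0.2 around its target, i.e. the world would
express a coupling other than the configured one. Second, with g_t = 0
temperature influences latent productivity only through that correlation,
which is precisely the regime where partialling out precipitation should
flatten the apparent temperature effect — the behaviour the attribution
experiments verify.

Validation plots sit on vegetated pixels (jittered within the pixel);
total biomass equals latent NPP summed January–July divided by 0.475,
plus Gaussian observation noise (default sd 15 g·m⁻² biomass, a free
knob — plot-level observation error is not externally constrained; set
to 0 the conversion inverts exactly). Livestock series are linear trends
per county in standard sheep units (1 large head = 5 sheep), clipped at
zero.

**What the generator does not emulate:** sensor physics and atmospheric
effects, real station geometry or orography, spatially structured
temperature fields, snow/NDVI winter artefacts, grazing feedbacks on
NDVI, and spatial autocorrelation of noise. Passing tests therefore
demonstrate correctness of the formulas, couplings and plumbing — not
that the model reproduces any particular real landscape's statistics.

## Numerical choices

- Nodata is NaN internally; the sentinel (−9999) exists only on disk.
  Nodata propagates through every operation and never enters aggregates.
- NDVI = 1 gives SR nodata; zero-variance series give correlation nodata;
  collinear controls (|r| = 1) give partial-correlation nodata.
- Degenerate calibration (constant NDVI, < 20 samples per class) is a
  hard error naming the class.
- Validation regression is estimated (y) on observed (x); bias is
  mean(observed − estimated), so a negative bias means the model runs
  high. RMSE ≥ |bias| always.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; a fixed configuration reproduces the world
  bit-identically, and rerunning any stage on unchanged inputs rewrites
  byte-identical outputs (atomic temp-file + rename writes).

## Problem sizes

The default demo world is 20×20 pixels × 13 years; the attribution
experiments use 50×50 × 13. These sizes give thousands of vegetated
pixels — ample for the fraction/median summaries the experiments check —
while keeping a full pipeline run to seconds.

## Known limitations

- The soil bucket has no runoff partition, snowpack or deep drainage;
  EET/PET is a coarse moisture index, not a water balance.
- IDW cannot extrapolate beyond station extremes (by design) and ignores
  elevation lapse rates.
- One control variable only in partial correlations; no lagged effects.
- The Tε2 high-temperature cap and the ET sub-model are one published
  variant of the modified-CASA family; both are isolated behind single
  functions with coefficients in configuration.
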