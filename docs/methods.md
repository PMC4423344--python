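# Methods

## Scope and design

The package reconstructs a complete field-analysis chain for co-occurring
oaks and pines: leaf-level photosynthesis and stomatal models fitted from
chamber curves, leaf-composition efficiency indices, and a whole-tree chain
from thermal-dissipation sap-flow signals to canopy stomatal conductance
and its sensitivity to atmospheric demand. Because raw field data of this
kind are rarely released, the first-class `synthetic` module forward-
simulates all five inputs from a declared `TruePhysiology`, making every
stage testable by parameter recovery.

## Leaf gas exchange

**Light response.** The non-rectangular hyperbola (NRH) is fitted by
bounded nonlinear least squares with deterministic initialization:
A_max ≈ max(A) + R_d0 (R_d0 from the darkest point), φ from the secant of
the two darkest points, θ = 0.7. The exponential form is always fitted as
well; the NRH is accepted only when it converges with θ ∈ (0, 1] and does
not lose to the exponential on residual sum of squares — an objective
surrogate for the qualitative "satisfactory fit" judgment used in field
practice. The light compensation point is closed-form for the exponential
(Q = −(A_max/φ)·ln(1 − R_d/A_max)) and solved by Brent's method for the NRH.

**FvCB A/Ci fitting.** For fixed limitation labels the model is *linear* in
(V_cmax, J, TPU, R_day): each Rubisco point contributes
A = V_cmax·x_c − R_day with x_c = (C_i − Γ*)/(C_i + K_m), each RuBP point
A = J·x_j − R_day with x_j = (C_i − Γ*)/(4C_i + 8Γ*), each TPU point
A = 3·TPU − R_day. The fit therefore enumerates all ordered partitions of
the C_i-sorted points (Rubisco → RuBP → optional TPU tail, minimum two
points in each of the first two regimes), solves each as a bounded linear
least-squares problem, and keeps the minimum-RSS partition, breaking ties
toward fewer TPU-limited points. This is exhaustive, deterministic and
reproducible — no multi-start nonlinear optimization. Parameters fitted at
leaf temperature are normalized to 25 °C by Arrhenius factors
exp(ΔH_a/R·(1/298.15 − 1/T_K)); kinetic constants use the
exp(c − ΔH_a/(R·T_K)) parameterization (Γ*: c = 11.187, ΔH_a = 24.46 kJ;
K_c: 35.9774, 80.99; K_o: 12.3772, 23.72; V_cmax: 65.33; J: 43.9;
TPU: 53.1; R_day: 46.39 kJ mol⁻¹), converted from partial pressures to mole
fractions at 101.325 kPa (Γ*₍₂₅₎ ≈ 36.9 µmol mol⁻¹, K_c ≈ 269 µmol mol⁻¹,
K_o ≈ 164 mmol mol⁻¹, O = 207 mmol mol⁻¹). The constants are a module-level
mapping and can be swapped per call. J at saturating light (curves measured
at 1500 µmol m⁻² s⁻¹) is identified with J_max. A curve with no TPU-limited
point reports TPU as not identified (`None`) rather than a bound estimate;
any capacity parameter pinned at its lower bound flags the fit.

TPU limitation is temperature-fragile: TPU carries a larger activation
energy than J, so warming lifts A_p above A_j and the TPU regime can vanish
from the measurable C_i range (it does at 30 °C under the default
physiology). The temperature-normalization recovery tests therefore run at
22 °C, where all four parameters stay identified, and check V_cmax/J_max
recovery at 30 °C.

**Γ and Ball–Berry.** Γ is the x-intercept of an OLS line through the
initial A/C_i points; the window defaults to C_i ≤ 150 µmol mol⁻¹
(configurable) since no standard definition exists. The Ball–Berry slope
and intercept come from OLS of g_s on A·rh_s/(C_s − Γ); points with
C_s ≤ Γ are excluded with a warning, and g_0 is not constrained to be
non-negative (an unconstrained intercept makes the estimator exactly the
normal-equations solution the tests cross-check).

## Leaf chemistry

Discrimination, c_i/c_a and iWUE use the simple linear discrimination model
with fixed end members 4.4 ‰ (diffusion) and 27 ‰ (Rubisco) and the 1.6
H₂O/CO₂ diffusivity ratio; c_a defaults to 400 µmol mol⁻¹. Indices are
computed per leaf and then averaged — because the map Δ → iWUE is affine
but the δ¹³C → Δ map is not, computing on trait means does not commute with
averaging, and per-leaf-first is the convention adopted throughout. Source
air δ¹³C is supplied per sample (growing-season yearly means differ by
~2 ‰), which is why a group-mean δ¹³C paired with a single year's source
air does not reproduce a mean Δ computed per leaf over mixed years.

## Sap flow

**Baselines.** Zero-flow ΔT_max windows require VPD < 0.05 kPa sustained
for ≥ 2 h and a stable signal: ΔT range within 0.5 % of the window mean
(configurable). Runs that fail stability as a whole are scanned with 2-h
sub-windows. Each qualifying window contributes its maximum ΔT at its
midpoint; the schedule linearly interpolates between windows and holds the
nearest value beyond the ends. A series with no qualifying window raises an
error carrying the near misses (calm-but-unstable or too-short runs).

**Conversion and scaling.** J_S = 0.119(ΔT_max/ΔT − 1)^1.23; ΔT ≥ ΔT_max
(routine at night under noise) is clamped to zero flow and flagged rather
than erroring. The ring-porous underestimation correction for oaks is a
named pluggable hook — identity by default (with a logged warning) plus a
multiplicative power law a·J^b whose coefficients must come from an
external calibration; no coefficients are invented here. Radial
integration area-weights the outer (0–2 cm) and inner (2–4 cm) sensors;
sapwood deeper than the inner sensor carries the inner rate by default
(configurable to zero) — a continuity assumption, since deep sapwood still
conducts in most conifers. Oak sapwood area uses the logistic
A_S = 0.0188/(1 + e^(−(DBH − 20.97)/4.791)): the curly alternative with a
minus sign in the denominator has a pole at DBH = 20.97 cm and negative
values below it, so only the logistic reading is a usable sigmoid; the
difference matters below ~35 cm DBH. Pine sapwood/leaf-area allometries
are site-specific external equations and enter as pluggable callables;
single-sided pine leaf area is all-sided area divided by π.

## Canopy conductance and sensitivity

G_S = K_G(T)·E_L/VPD with K_G = 115.8 + 0.4236·T (kPa m³ kg⁻¹), valid for
well-coupled canopies with negligible stem storage. Molar conversion
divides by 0.0224·T_K/273 m³ mol⁻¹ with T_K = T + 273.15 (the 0.15 K
difference from using 273 is < 0.06 %). A step is *daytime* when VPD
exceeds 0.5 kPa **and** the sun is up (PPFD > 0) when light data exist:
after sunset VPD often remains above threshold while flow is zero, and
those zero-conductance points would otherwise flatten the lnVPD slope;
sap-flow-derived G_S is physically meaningful only while stomata are
light-activated. Daily daytime means of G_S and VPD run over the same
qualifying steps.

Sensitivity fits are OLS of G_S on ln VPD with classical t-test slope
p-values; sensitivity = −slope, G_Sref = intercept (VPD = 1 kPa), ratio =
sensitivity/G_Sref (undefined when G_Sref ≤ 0). `fit_vpd_response` accepts
any paired (G_S, VPD) sample: the daily-mean table (the field protocol) or
the half-hourly qualifying steps. Note that regressing daily-mean G_S on
ln(daily-mean VPD) is subject to a Jensen gap — the mean of ln VPD within
a day is below the ln of the mean — which biases the fitted intercept and
ratio by several percent when within-day VPD spread is wide; recovery
tests therefore fit at the half-hourly level, where the generating
relation is recovered exactly at zero noise.

Binning uses equal-width bins anchored at zero (defaults: 10 percentage
points of relative soil moisture; 5 mol m⁻² d⁻¹ of daily PPFD), drops bins
with fewer than 5 days, pools days within a bin for the lnVPD fit, and
regresses per-bin sensitivity on bin midpoints. Relative soil moisture is
100·θ/max(θ) per site (the observed maximum standing in for field
capacity); the daily PPFD integral is Σ(PPFD·Δt)/10⁶ mol m⁻² d⁻¹.

## Synthetic data: what it emulates and what it does not

The met template is a sinusoidal diurnal cycle (T peaking at 14:00, RH
anti-phased, PPFD a half-sine between 06:00 and 18:00) with day-to-day
temperature anomalies (sd 3 °C) and cloudiness factors (0.55–1.0), giving
daytime VPD spanning ~0.05–3 kPa. VPD follows Goff–Gratch (1946, over
liquid water) exactly from the generated T and RH. Soil moisture is
pulse-decay: recharge to field capacity (0.12 m³ m⁻³, sandy-soil scale) on
Bernoulli rain days (p = 0.12 d⁻¹), exponential drawdown (0.08 d⁻¹)
between. One night per week is forced to saturation for three hours so
baseline detection always has material. Default run length is 60 days at
1800 s.

The sap-flow generator writes half-hourly
G_S = max(0, G_Sref(1 − r·lnVPD)) during sunlit steps (zero at night),
converts it through the same K_G/molar-volume relations the analysis
inverts, scales by leaf-to-sapwood area, and inverts the Granier equation
around a configured ΔT_max = 10 °C. Noise is additive Gaussian per channel,
independent across steps — no autocorrelation, drift, sensor failure or
rain-on-sensor artifacts. The default ΔT noise sd is 0.01 °C: the loggers
average 30-s samples over 30 min, which suppresses instantaneous sensor
noise by nearly an order of magnitude, and a step-level noise much larger
than this is incompatible with the 0.5 % baseline-stability criterion that
any successful field deployment implicitly satisfies. No channel has a
published error magnitude, so all noise defaults are plausible placeholders
rather than calibrated values.

Passing recovery tests therefore demonstrate correctness of the
computational chain under the stated generating model; they do not
demonstrate robustness to the nastier features of real sensor data
(gaps, drift, storms, radial profiles that differ from the assumed
two-annulus layout).

The A/Ci generator solves, at each chamber CO₂ step, the self-consistent
(A, g_s, C_i) balancing FvCB demand against Ball–Berry supply
g_s(C_s − C_i)/1.6 by Brent root-finding (g_s clamped below at g_0); steps
below the compensation point settle near A = −R_day with C_i slightly
above C_s. Chamber CO₂ follows the standard protocol
(400 → 50 → 400 → +200 ppm steps), topping at 2000 ppm so a TPU-limited
tail exists at 25 °C. The Ball–Berry Γ used in generation is Γ* at leaf
temperature — a slight simplification relative to the fitted Γ (the net
compensation point, ~50 µmol mol⁻¹ under defaults), which affects no
round-trip because the A/Ci fit uses (C_i, A) only and the Ball–Berry
recovery tests supply their own Γ.

Default generating physiology: V_cmax25 = 60, J_max25 = 110, TPU25 = 8,
R_day25 = 1 µmol m⁻² s⁻¹; A_max = 16, φ = 0.05, θ = 0.7, R_d = 1.2;
m = 8, g_0 = 0.01 mol m⁻² s⁻¹; G_Sref = 0.12 mol m⁻² s⁻¹, ratio = 0.6;
Δ = 19.1 ‰, LMA = 100.4 g m⁻², N = 2.16 % — mid-range values for
temperate oaks measured on sunlit foliage, with the composition values at
the oak group means.

## Numerical choices

- Nonlinear light-response fits use `scipy.optimize.least_squares` with
  ftol = xtol = gtol = 1e-15 so noiseless round trips recover parameters
  to 1e-6 relative.
- Partitioned A/Ci fits use `scipy.optimize.lsq_linear` with non-negativity
  bounds; RSS ties (within 1e-12) break toward fewer TPU points.
- All simple regressions (Γ window, Ball–Berry, lnVPD response, covariate
  and cross-bin fits) are explicit normal-equations OLS, cross-checked in
  the tests against an independent least-squares oracle at 1e-10.
- The NRH discriminant is clamped at zero before the square root; at
  θ → 1 the model approaches min(φQ, A_max) − R_d at O(1−θ) away from the
  φQ = A_max kink and O(√(1−θ)) at it.
- Granier conversion clamps ΔT ≥ ΔT_max to zero flow with a quality flag;
  ΔT ≤ 0 is a hard error.
- Root seeds are split deterministically per generator (seed·1000 + fixed
  offset, mod 2³¹−1) so pipeline reruns are byte-identical.

## Known limitations

- No mesophyll conductance: V_cmax/J_max are "apparent" C_i-based values.
- R_day is fitted freely from the A/Ci curve, not constrained by the dark
  respiration of the paired light curve.
- The exponential light-response member and the Γ window are conventions;
  alternatives from the same families would change estimates slightly.
- Binned sensitivity defaults (widths, 5-day minimum, pooled-within-bin
  fits) are deterministic conventions for "grouped under similar
  conditions"; per-individual-then-averaged fits are available but not the
  default.
- Mixed-effects group comparisons, post-hoc tests and leaf-area field
  protocols are out of scope; the pluggable allometry/correction hooks are
  deliberately inert until supplied with external coefficients.
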