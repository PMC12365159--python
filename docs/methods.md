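# Methods

This note documents the models implemented in `pestivol`, the
assumptions they make, the defaults and why, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Surface-layer similarity (`micromet`)

Transfer between the canopy and a reference height is described by
Monin–Obukhov similarity. The integrated scalar stability correction
Ψ_H uses the Businger–Dyer form for unstable stratification,
Ψ_H = 2 ln((1+x²)/2) with x = (1−16ζ)^¼, and a linear form Ψ_H = −5.2 ζ
for stable stratification (ζ = (z−d)/L). The momentum counterpart Ψ_M
(used only to build wind profiles for the dispersion core) keeps the
same stable coefficient for consistency. ζ is clamped to [−5, 2]: calm,
strongly stable nights otherwise produce unbounded resistances that are
measurement artefacts rather than physics. Both choices are
configuration points, not hard-wired constants.

Resistances:

- aerodynamic: R_a(z_ref) = (ln((z_ref−d)/z₀) − Ψ_H)/(k u*);
- quasi-laminar boundary layer: R_b = 2/(k u*) (Sc/Pr)^(2/3).

No measured diffusivity exists for chlorothalonil, so its Schmidt
number is estimated by Graham's-law scaling of the water-vapour
diffusivity, D = D_H₂O √(M_H₂O/M), giving Sc ≈ 2.3; this is the
conventional fallback for semivolatile pesticides and is exposed as a
parameter. The displacement height defaults to d = (2/3)·h_c. Under the
default diurnal met cycle these give R_a ≈ 15–90 s m⁻¹ and
R_b ≈ 25–60 s m⁻¹, inside the 10–100 and 20–400 s m⁻¹ operating ranges
reported for this kind of wheat-field campaign.

## Area-source dispersion (`dispersion`)

The dispersion coefficient D relating a uniform area-source flux to the
receptor concentration is computed from the analytical similarity
solution of the crosswind-integrated advection–diffusion equation for
power-law profiles u = a z^p, K = b z^n (the Philip/Huang ground-source
solution). The exponents and coefficients are matched to the
Monin–Obukhov wind speed and scalar diffusivity at two heights, z_ref−d
and a tenth of it (kept above 2 z₀), so atmospheric stability enters
through the profile curvature; heights are measured above the
displacement plane.

For an upwind strip of fetch X the per-unit-flux concentration at
height z has the closed form

    D(X) = z^{α(1−s)} / (α b Γ(s)) · Γ_u(s−1, a z^α/(α² b X)),

α = 2+p−n, s = (p+1)/α, with Γ_u the upper incomplete gamma function
(continued to non-positive first argument by the standard recurrence —
near-neutral profiles land exactly on s = 1, where Γ_u(0, ·) is the
exponential integral E₁).

Polygon sources are rotated into the wind frame; the upwind ray through
the receptor is intersected with each polygon (shapely) and every
in-polygon interval [x₀, x₁] contributes D(x₁) − D(x₀) **exactly**. The
originally envisaged ≤1-m adaptive strip discretisation is therefore
unnecessary in the default crosswind-integrated mode: the strip
integral is analytical and the only geometry operation is the line
intersection. A Gaussian lateral mode (spread σ_y = x σ_w / u(z_ref),
geometric upwind steps starting at 1 m) exists for narrow or laterally
offset sources; the default is the strip mode because the intended
receptor stands 40 m inside a ~20 ha field, where lateral dispersion is
second order. The analytical solution is validated in the tests against
an independent finite-volume solution of the same PDE (agreement ~0.1 %,
tolerance 10 %) and by a mass-conservation quadrature (∫u·c dz equals
the emitted fetch within 2 %).

Limitations: the solution is strictly a surface-layer model (receptor
heights of a few metres), assumes along-wind homogeneous turbulence, no
chemistry and no deposition in transit, and the stability response is
taken directly from the similarity profiles rather than re-tuned
against a Lagrangian stochastic reference; the numerical-oracle test
substitutes for that tuning.

## Flux retrieval (`flux_inference`)

Inversion is the exact algebra F = (C − C_bgd)/D. Steps with
D < 10⁻³ s m⁻¹ are masked, not zero-filled: the inversion variance
grows as 1/D², so calm or wrong-wind-sector steps carry no usable
information. The background is a constant mean ± sd estimated from a
pre-application window; its diurnal variation is neglected (it is an
order of magnitude below post-application concentrations).

The aerodynamic gradient method fits C against ln(z−d) − Ψ_H by
ordinary least squares over the available heights (no weighting) and
evaluates F = −u*·k·slope. Emission is positive everywhere in the
package, and every output header says so.

Source attribution weights each polygon's D by its relative emission
factor (dose-scaled); contributions are per-step shares of the modelled
concentration and sum to one over upwind sources.

## Surface vapour pressure and availability (`surface_vapour`)

C(z₀) = C(z_ref) + F (R_b + R_a) inverts the big-leaf resistance
equation exactly. Concentrations convert to partial pressures by the
ideal gas law with R = 8.314 J mol⁻¹ K⁻¹ and M = 265.9 g mol⁻¹. The
saturation pressure follows a Clausius–Clapeyron curve anchored at
7.6·10⁻⁵ Pa / 25 °C with an activation energy of 95 kJ mol⁻¹; the
curve's gas constant is kept at the rounded 8.3 J mol⁻¹ K⁻¹ of the
published parameterisation so the anchor reproduces exactly. Air
temperature is used for both pressures: it sits between the sunlit
canopy-top and shaded soil temperatures and is the least biased single
proxy for the emitting surface.

The availability ratio r = p_vap(z₀)/p_sat(T_air) is aggregated to
daily values from daytime steps (09–17 h by default) before fitting —
nighttime resistances are largest and noisiest — and fitted with a
double exponential a₁e^(−k₁t) + a₂e^(−k₂t) by nonlinear least squares
(`scipy.optimize.curve_fit`, non-negative bounds, components ordered
fast-first, standard errors from the covariance). A plateau variant
pins k₂ = 0 for remaining-content fits. Non-convergence raises with
diagnostics; it is never silent. At least 8 daily points are required.

The modelled flux inverts the chain: C(z₀) = r_fit(t)·p_sat(T)·M/(R T_K)
and F = (C(z₀) − C(z_ref))/(R_b + R_a). Gap-filling rescales this model
to the measured flux with a through-origin linear fit over a 7-day
moving window (windows with under 50 % usable overlap fall back to the
nearest fitted window, counted in the output attrs); gaps take the
rescaled model and the series integrates by the trapezoid rule on the
30-min grid, normalised by the applied dose (1 g ha⁻¹ = 10⁵ ng m⁻²).

## Monte-Carlo uncertainty (`uncertainty_mc`)

Default distributions: z₀ log-normal with arithmetic mean 0.0035 m and
sd 0.0004 m (converted internally to log-space parameters); d normal
sd 0.03 m; sensor position (1, 1, 0.1) m; u*, σ_w and C ±14 %
multiplicative; wind direction ±12.5°; L ±40 % multiplicative
(sign-preserving, from 14 % errors on u* and the heat flux); background
5.7 ± 2.2 ng m⁻³; 100 draws. All draws are independent; multiplicative
factors are truncated positive by redrawing, which keeps u* and σ_w
physical and L in its stability regime. Sensor-position perturbations
re-enter the dispersion geometry, not the concentration.

Two sampling schemes, chosen deliberately:

- **per-step** (flux bands): fresh joint draws at every 30-min step —
  the model re-run n times at each time step; reported as empirical
  5/50/95 percentiles, failing a step when over half its draws are
  masked;
- **per-trajectory** (cumulative bounds): one joint draw held over the
  whole campaign per replicate, each replicate gap-filled and
  integrated, percentiles taken over the cumulative trajectories.
  Redrawing per step would let systematic parameter error average out
  of the ~1000-step integral and collapse the cumulative band to a few
  per cent, which misrepresents how calibration-type errors propagate
  into a time integral.

## PTR-TOF quantification (`ptr_calibration`)

Isotope envelopes convolve per-element natural isotope distributions
(masses and abundances from `pyteomics`' NIST tables), aggregated in
nominal-mass bins that keep abundance-weighted exact masses. For
C₈Cl₄N₂+H the envelope sits at nominal m/z 265 and the water cluster at
283; with the significance threshold at 20 % of the base peak each
massif keeps 3 peaks (the Cl₄ M+6 isotopologue, near 10 %, is excluded
by design — the threshold is configurable), so quantification sums 6
windows. Peak summing uses fixed ±0.2 Da windows around the significant
peaks and collapses overlaps with a warning.

Calibration against a co-located reference series is a zero-intercept
least-squares slope; its uncertainty is a nonparametric bootstrap
relative sd by default, with a half-range mode matching the
slope-interval convention. Mixing-ratio conversion uses the molar
volume at 25 °C / 1013.25 hPa (configurable): 1 ppt of a 265.9 g mol⁻¹
gas is 10.87 ng m⁻³, so 0.7 cps (ng m⁻³)⁻¹ ≈ 7.6 cps ppt⁻¹. Detection
limits come either from counting statistics (the concentration giving
one ion count over the averaging window) or from a measured zero-air
noise count rate.

## Dose assessment (`dose_assessment`)

Filter pairs (pooled by two, the extraction unit) are the statistical
unit; the areal dose is content/area converted to g ha⁻¹. Method
comparison is a Welch two-sample t-test from summary statistics
(scipy), appropriate for the small unequal samples involved.

## Synthetic campaigns (`synthetic_data`)

The generator emulates the campaign the analysis is designed for:
22 days at 30 min, application after day 1 at 544 g ha⁻¹, availability
truth r(t) = 0.18·(57 e^(−0.61 t) + 43 e^(−0.012 t))/100, a smooth
diurnal met cycle (u* 0.18 night – 0.45 day; T_air 15 ± 9 °C peaking at
14 h; 1/L cycling from +0.05 m⁻¹ stable nights to −0.02 m⁻¹ unstable
middays; wd ~ N(200°, 30°)), a 450 m × 450 m source with the receptor
40 m inside at 1.9 m, 14 % multiplicative concentration noise, a
5.7 ± 2.2 ng m⁻³ background, 3-height gradient samples
(0.63/1.23/2.03 m) over the first 3 days, two outages and 9 + 9 filter
pairs. The night-time u* is set so the generated aerodynamic
resistances stay inside the 10–100 s m⁻¹ range reported for such
campaigns. The truth flux solves the surface scheme self-consistently
with the ambient feedback C_ref = D F + C_bgd; because the feedback is
linear the fixed point is algebraic, F = (C(z₀) − C_bgd)/(R_a + R_b + D).
Before application the truth flux is exactly zero (no compound on the
surface), which keeps the zero-noise forward–inverse round trip exact.

What the generator does **not** emulate: wind-speed-dependent source
heterogeneity, rain/wash-off events, humidity-dependent instrument
sensitivity, deposition to off-field surfaces, and real wind-rose
asymmetries. Passing tests therefore demonstrate the correctness and
internal consistency of the inference chain under the stated
statistical structure — not the field accuracy of any specific campaign
number.

## Problem sizes in the test and acceptance runs

The test suite exercises reduced problem sizes chosen as adequate for
the properties under test: 12-day campaigns for round trips and
parameter-recovery (50 seeds), 12-day campaigns with a 3-day outage and
40 trajectory draws for the 20-seed cumulative-coverage experiment, and
a 350×900-node finite-volume grid for the dispersion oracle. The
analysis drivers run the full 22-day, 100-draw configuration.

## Known limitations

- The availability fit is phenomenological; rate constants are
  interpretable against photodegradation/penetration literature but the
  package deliberately implements no mechanistic leaf-penetration or
  photolysis model.
- The double exponential is weakly identifiable when k₁ ≈ k₂ or when
  the fast phase is under-sampled; standard errors from the covariance
  are first-order only.
- Strip-mode dispersion treats every upwind source slice as infinitely
  wide crosswind; for distant narrow fields this overestimates their
  contribution, so head-on single-direction attributions are upper
  bounds (campaign means over a realistic wind rose are the meaningful
  quantity).
- Gap-filling assumes the modelled flux is proportional to the true
  flux within each 7-day window; long outages with regime changes
  (e.g. rain) violate this silently.
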