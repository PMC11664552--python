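# Methods

## The leaf model

At saturating light, C3 assimilation is taken as Rubisco-limited:

    A = Vcmax (Cc − Γ*) / (Cc + Km),        Km = Kc (1 + O/Ko).

CO2 reaches the chloroplast through two conductances in series,
Ci = Cs − A/gs and Cc = Ci − A/gm, and the stomata follow the unified
stomatal optimality (USO) closure gs = (1 + g1/√VPD) · A/Cs, where g1
(kPa^0.5) is inversely related to the marginal carbon cost of water. Leaf
respiration Rd is set to zero by default (it is small against
light-saturated assimilation and was neglected in the deriving experiment);
it is a field of `PhotosyntheticKinetics` and can be overridden.

The √VPD convention is used consistently in the forward closure and its
inversion g1 = (Ci/Cs)√VPD/(1 − Ci/Cs). Two supporting facts make this the
only dimensionally coherent reading: g1 is reported in kPa^0.5, and the ½
coefficient of the VPD term in the USO limitation scheme is exactly
d(√VPD)/√VPD.

Under the USO closure, Ci/Cs = g1/(g1 + √VPD) independently of A, so the
coupled system reduces to one scalar equation in A. Its residual is
strictly monotone on the bracket (0, min[A(Cc=Ci), gm(Ci − Γ*)]) — the
upper cap keeps Cc above the compensation point, away from the pole of the
FvCB ratio at Cc = −Km — so Brent's method returns the unique root
(`synthetic.coupled_leaf_solve`, residual tolerance ~1e-14).

### Kinetic constants

Two tobacco-calibrated sets are provided; the chloroplast-based (Cc) set is
the default because the variable-J workflow resolves Cc explicitly:

| basis | Kc25 (µmol mol⁻¹) | Ko25 (mmol mol⁻¹) | Γ*25 (µmol mol⁻¹) | Ea (Kc/Ko/Γ*, kJ mol⁻¹) |
|---|---|---|---|---|
| Cc (default) | 272.38 | 165.82 | 37.43 | 80.99 / 23.72 / 24.46 |
| Ci (option)  | 404.9  | 278.4  | 42.75 | 79.43 / 36.38 / 37.83 |

O2 mixing ratio 210 mmol mol⁻¹. Normalization to 25 °C uses
f(T) = exp[Ea(T − 298.15)/(298.15 R T)] with Ea,Vcmax = 65.33 kJ mol⁻¹ and
Ea,gm = 49.6 kJ mol⁻¹. The gm activation energy is a package default in
the range of published tobacco estimates, not a value asserted by the
deriving study; a peaked (deactivation) form is deliberately out of scope —
both Ea values are plain config fields. The headline limitation numbers are
insensitive to the basis choice (the stomatal/mesophyll crossover moves by
< 0.001 REW between bases; contribution percentages by ≤ 3 points).

### Quality rules

Records with Asat ≤ 0 are excluded; fluorescence pairs with Fs > Fm′ are
rejected; gm (and the Vcmax that depends on it through Cc) is retained only
when Ci ∈ [150, 350] µmol mol⁻¹ (inclusive), the range where variable-J
errors from Rd and Γ* stay small. g1 and Ci/Cs are kept regardless of the
gm filter. The α·βPSII calibration regresses φCO2 on φPSII through the
origin using PPFD > 0 points at ≤ 2% O2; the intercept-free form makes the
factor 4 of α·βPSII = 4k exact under φe− = 4 φCO2.

## Drought responses

Variables are averaged per (measurement day, treatment) — measurements of
one day share meteorological and soil conditions — and regressed on REW
with the continuous linear-plateau model (3 free parameters a, b, REW_th;
y_max = a·REW_th + b by construction). The threshold is profiled over
midpoints of consecutive observed REW values (the (a, b) subproblem is
solved exactly per candidate), then refined by bounded scalar minimization;
the refinement bracket extends to the data maximum so the pure-line limit
(plateau shrinking to a point) stays reachable and the linear model is
properly nested. Flat data (|a| ≈ 0) are flagged degenerate rather than
assigned a meaningless threshold.

Model choice follows AICc with k counting the error variance (segmented
k = 4, linear k = 3); the segmented model is retained unless the linear one
wins by ≥ 7 AICc units, reflecting prior evidence of threshold behaviour in
this crop.

**Parameter uncertainty.** The reported threshold SD is the largest of
three estimators: the linearized covariance at the optimum, an HC3
(heteroscedasticity-robust) sandwich, and the half-width of the 95%
profile-likelihood interval rescaled by the normal quantile. The plain
linearized SD understates breakpoint uncertainty badly in two regimes this
data class inhabits — multiplicative (variance-increasing) scatter, and
sparse sampling that leaves the kink interval-identified between adjacent
REW values, where the profile interval widens but the local curvature does
not. In simulation the robust convention brings the 2-SD interval to
≥ 92% coverage for Asat-like responses at R² ≈ 0.7, versus ~88% for the
linearized SD alone. Threshold differences between variables are tested
with a two-sided z statistic |Δ|/√(sd₁² + sd₂²) (the fits provide values
and SDs but no clean df); a Welch-t variant with df from the residual
degrees of freedom is available via `compare_thresholds(..., method="t")`.

## Limitation partitioning

Relative variations follow dy/y = (y_max − y(REW)) / (y_max − y(REW_min)):
0 on the plateau, magnitude 1 at the driest observed REW (default
REW_min = 0.24), for declining and rising variables alike. y(REW_min) is
the fitted curve evaluated at REW_min, not a raw data minimum, so the
convention is reproducible from published parameters alone. dVPD/VPD uses
the same convention on the fitted linear VPD–REW relation; for a line the
normalized variation reduces to (1 − REW)/(1 − REW_min), independent of the
line's coefficients, with VPD's sign carried explicitly by the minus in the
USO scheme (drier air always costs assimilation).

Curves are evaluated at 25 °C (Vcmax25, gm25, 25 °C constants): temperature
is already factored out by the normalization, light by measuring at
saturation, so REW and VPD are the only remaining drivers. Cs is fixed at
the chamber setting, 400 µmol mol⁻¹. The grid is 200 uniform points on
[REW_min, 1]; grid points where a fitted response line is non-positive or
the implied Cc falls below Γ* (possible with noisy fits near the dry end)
are dropped with a warning. The Grassi–Magnani weights

    l_gs = (gt/gs)·d/(gt + d),  l_gm = (gt/gm)·d/(gt + d),  l_vcmax = gt/(gt + d)

(d = ∂A/∂Cc = Vcmax(Km + Γ*)/(Cc + Km)², 1/gt = 1/gs + 1/gm) sum to one
identically. The USO coefficients are l_gs/(1 − l_gs)·(Ci/Cs) for g1,
l_gm/(1 − l_gs) and l_vcmax/(1 − l_gs) for the diffusion/biochemistry
terms, and −½·l_gs/(1 − l_gs)·(Ci/Cs) for VPD; each equals the log-log
sensitivity of the fully coupled solver to its driver (validated by central
finite differences to < 1% at 100 random states). The stomatal-closure
decomposition L_gs = (L_gm,USO − L_gm) + (L_Vcmax,USO − L_Vcmax) +
L_VPD,USO + L_g1,USO is an exact identity when dA/A is the Grassi-scheme
sum; on fitted curves the two schemes' totals differ slightly, and that
difference is reported as the decomposition residual rather than hidden.

The stomatal/mesophyll crossover is the root of L_gm − L_gs, located by
sign change on the grid and refined by bisection on the continuous curve;
with several crossings the smallest REW is returned with a warning.

**Published parameters as inputs.** The packaged potato table stores the
published plateau/slope/intercept/threshold values exactly as printed.
Because the four numbers per row were rounded independently, the segment
does not meet the plateau exactly (the constructor warns for external
inputs); the printed line is used below the threshold and the plateau above
it. A consistency caveat follows: the six responses were fitted
independently, so reconstructing A from the fitted Vcmax25, gm25 and Ci/Cs
via the FvCB equation does not reproduce the fitted Asat curve pointwise —
deviations reach tens of percent near the dry end even for fits taken from
a noise-free synthetic experiment, because the coupled model's emergent
responses are convex where the fits are piecewise-linear, and Cc is a
difference of two fitted quantities. The per-point deviation is exported as
the `a_consistency` column; treat it as a diagnostic, not an error to be
minimized.

## The synthetic experiment generator

The generator emulates a two-treatment greenhouse drying experiment:
non-irrigated REW declines linearly from 1.0 to 0.24 over 34 days while the
irrigated control oscillates deterministically above 0.83 (hand watering);
VPD and leaf temperature follow decreasing linear relations in REW (package
defaults: VPD = 4.0 − 3.0·REW kPa, T = 38 − 10·REW °C, staying below the
observed greenhouse maxima of ~4.1 kPa and ~39 °C); leaves are measured on
14 dates, three per treatment per date, at PPFD 1200 and Cs 400. True
response curves for Vcmax25, gm25 and g1 are the packaged potato parameters
with continuity-restored intercepts (a real leaf responds continuously; the
printed intercepts' rounding jumps would bias any continuity-constrained
refit). Soil moisture is emitted through the inverted REW definition with a
van Genuchten parameter set (θr = 0.10, θs = 0.38, α = 0.006 cm⁻¹,
n = 1.38) whose wilting point and field capacity (15.0%, 35.1%) match the
experimental horizon; fluorescence pairs are built by inverting the
variable-J chain (Fm′ fixed at 2000 arbitrary units — only the ratio
matters) so that a scatter-free dataset is inverted exactly by the analysis
pipeline (verified to ~1e-8 relative).

**Scatter model.** Leaf-to-leaf biological variability is lognormal and
multiplicative on the physiological drivers (Vcmax25 σ = 0.19,
gm25 σ = 0.18, g1 σ = 0.30), applied before the coupled solve so one leaf's
observables co-vary coherently — as real replicate leaves do. Instrument
noise is small and multiplicative on the observables (A 5%, gsw 7%, VPD 5%,
Fs 1%, SWC 0.5%), and Ci is emitted through Fick's law from the noisy
fluxes, as a gas analyzer computes it. A purely independent
observable-noise model was tried first and rejected: gm inherits any
inconsistency between A and J_F so violently that no setting reproduces the
observed per-variable R² pattern. The adopted defaults land the fitted R²
of Asat, Vcmax25, gm25 and Ci/Cs within ±0.15 of the field values (0.70 /
0.74 / 0.66 / 0.47). Two variables cannot be matched that closely *jointly*:
the USO closure ties gs scatter to g1 scatter, so with gs fully emergent the
generator yields R²(gs) ≈ 0.39 vs 0.55 observed and R²(g1) ≈ 0.92 vs 0.77
observed. Passing tests therefore demonstrate pipeline correctness and
threshold recovery, not that the generator reproduces every second moment
of real field data — real gs error has an instrument component uncorrelated
with the derived g1 that this forward model cannot create.

**What passing tests show.** Under the calibrated scatter, 200 replicate
experiments recover the three ground-truth thresholds within 2 reported SD
in ~94% of checks (pooled; Vcmax25 and gm25 individually ≥ 95%) and
preserve the two-stage ordering REW_th(gs, gm) > REW_th(Vcmax25) >
REW_th(g1) in ~98% of replicates. g1 alone sits near 84%: its response is
so steep relative to scatter that the threshold is effectively
interval-identified between adjacent measurement dates and occasionally
snaps one sampling gap over — a limit of the 14-date design, not of the
fitting code.

## Numerical choices and degenerate inputs

- Van Genuchten fitting: conditionally-linear (θr, θs) over a 24×20
  log-spaced (α, n) grid, then bounded least squares in
  (θr, θs, ln α, ln(n−1)); retention fitting is multi-modal and the grid
  stage avoids the spurious local optima. Mualem constraint m = 1 − 1/n.
  Fewer than 4 distinct pF points is an error.
- SWC units: fractions and percent both accepted; values ≤ 1 are treated as
  fractions and scaled, so printed horizon constants (15.6, 35.01) work
  directly. REW outside [0, 1] is clipped with a logged warning (sensor
  noise near saturation), not an error.
- AICc requires n > k + 1; an interpolating fit's RSS is floored at 1e-300
  inside the log.
- Sampling-day REW gaps bound threshold identifiability; candidate
  thresholds require ≥ 2 distinct REW values at or below and ≥ 1 above.
- The limitation grid refuses to extend below REW_min (the response fits
  would be extrapolated beyond observation).

## Known limitations

- Only the Rubisco-limited FvCB branch is implemented (consistent with
  measuring at light saturation); electron-transport- and TPU-limited
  branches, cuticular conductance corrections, drought responses of Rd and
  Γ*, and 3-D mesophyll decompositions are out of scope.
- The Grassi-scheme weights assume infinitesimal changes; contributions at
  the drought extreme interpret finite declines through local sensitivities.
- The VPD–REW relation is treated as linear; only its convention-normalized
  variation enters the results, which for a line is coefficient-free.
- The generator's irrigated-control REW pattern and the leaf-temperature
  relation are stylized (deterministic); they anchor the plateaus but do
  not emulate day-to-day weather.
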