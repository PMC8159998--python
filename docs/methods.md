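# Methods

## Carbonate-system speciation

The solver treats a seawater sample as a closed equilibrium system
described by its two measured state variables, total alkalinity (TA) and
dissolved inorganic carbon (DIC). At a trial pH (total scale,
[H⁺]_T = [H⁺]_F + [HSO₄⁻]) the modelled alkalinity is

TA(pH; DIC) = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]_F − [HSO₄⁻] − [HF],

with optional phosphate ([HPO₄²⁻] + 2[PO₄³⁻] − [H₃PO₄]) and silicate
([SiO(OH)₃⁻]) terms behind keyword arguments that default to off: nutrient
alkalinity contributes < 0.01 pH at reef nutrient levels (the package
tests this), and whether it was enabled in a given historical dataset is
rarely documented. The root of TA(pH) − TA_obs is found with Brent's
method on pH ∈ [3, 12] at 10⁻⁸ pH absolute tolerance. The balance is
strictly monotone in pH, so the bracketed root is unique and convergence
is unconditional; Newton iterations would be faster but can escape the
physical branch at extreme TA/DIC ratios, and speed is irrelevant at
bottle-sample scale.

Equilibrium constants (surface pressure throughout; all samples the
package targets are < 5 m deep):

- K₀: Weiss (1974) CO₂ solubility, mol kg⁻¹ atm⁻¹.
- K₁, K₂: Mehrbach et al. (1973) as refit by Dickson & Millero (1987),
  native seawater scale, converted to total.
- K_B: Dickson (1990), native total scale.
- K_W: Millero (1995), seawater scale, converted.
- K_S: Dickson (1990), free scale (used for scale conversions and the
  bisulfate term).
- K_F: Dickson & Riley (1979), free scale.
- K_sp(aragonite): Mucci (1983).
- Totals: boron by the Uppström salinity ratio, sulfate and fluoride by
  their standard ratios, calcium as [Ca²⁺] = 0.01028·S/35 mol kg⁻¹.

Scale conversions multiply by ratios of (1 + S_T/K_S) and
(1 + S_T/K_S + F_T/K_F); the round trip is exact to machine precision.
pCO₂ is fCO₂ divided by the Weiss virial fugacity factor (≈ 0.997 at
30 °C). The speciated fractions sum to DIC by construction; the test
suite enforces closure at ≤ 10⁻⁶ µmol kg⁻¹ and alkalinity residuals at
≤ 10⁻⁴ µmol kg⁻¹.

Two independent checks guard the solver. First, a frozen reference table
(`tests/data/`) computed with PyCO2SYS v1.8.3.4 under matching constant
options, covering an 800-point seeded subsample of a 20×20×5×5 grid over
TA 1900–2400, DIC 1600–2200 µmol kg⁻¹, S 30–36, T 25–32 °C; agreement is
required within 0.005 pH, 1% pCO₂ and 1% Ω (measured: ≤ 10⁻⁶ pH,
≤ 10⁻⁴% pCO₂, ≤ 0.05% Ω — the Ω offset is the calcium-ratio convention).
Second, an exhaustive pH-grid scan at 10⁻⁵ resolution, implemented
independently of the root finder, must agree within the grid resolution.

pCO₂ isolines for TA–DIC diagrams invert the solver: for each DIC, the TA
giving the target pCO₂ is found by a second Brent solve, valid because
pCO₂ is strictly decreasing in TA at fixed DIC (verified numerically on a
20×20 grid).

## Residence-time budget

The bay is one well-mixed box. Salinity normalization (nX = X·S_ref/S,
S_ref = 33.02 by default) strips evaporation/dilution; sampling near
sunset and sunrise brackets the diel cycle in a closed system, so the
midpoint of the two samples estimates the daily mean, and a station
missing either phase is excluded from group means (and reported). The
interior-minus-offshore anomalies split into a slope-2 calcification
vector (ΔDIC_calc = ΔTA/2) and a TA-neutral organic vector
(ΔDIC_org = ΔDIC − ΔTA/2); the split is additive by construction.
Assuming anomalies accumulate over one residence time τ in a column of
depth d and density ρ,

G_n = −(ΔTA/2)·ρ·d/τ/1000,  P_n = −ΔDIC_org·ρ·d/τ/1000,

with the single µmol kg⁻¹ → mmol m⁻² d⁻¹ conversion centralized in one
helper. ρ is not usually reported alongside such budgets; the default is
the one-atmosphere seawater equation of state (Millero & Poisson 1981) at
(S_ref, mean bay temperature), ≈ 1020.2 kg m⁻³ at (33.02, 30 °C), and an
explicit value can be passed instead. The air–sea flux correction
subtracts the CO₂ efflux from P_n: carbon lost to the atmosphere was not
fixed by the benthos.

Standard errors: the box model is linear in the group-mean anomalies, so
SEs propagate exactly from the group SEs. By default the within-group
variance is pooled across the interior and end-member groups
(homoskedastic titration noise dominates at bottle precision); with only
a handful of offshore stations a per-group estimate has so few degrees of
freedom that nominal 3-SE coverage fails, while the pooled estimator is
both better calibrated and conservative when interior spatial variance
exceeds offshore variance. `variance="per_group"` restores the
unpooled estimate.

Open choices resolved here: the bay mean midpoints per site before
averaging across sites (the `pooling="pooled"` option averages all
samples directly; the two coincide for balanced tables, which the tests
check), and speciation uses in-situ temperature.

## Air–sea CO₂ flux

F = k·K₀·ρ·ΔpCO₂, positive = efflux, in mmol C m⁻² d⁻¹ with k in cm h⁻¹.
The registry ships a quadratic (k₆₆₀ = 0.251·u²) and a cubic
(k₆₆₀ = 0.0283·u³) wind-speed law, Schmidt-normalized with a standard
S = 35 polynomial in temperature (documented approximation), plus a
fixed-k mode. Because published reef budgets often cite a gas-exchange
coefficient that cannot be reconstructed from the text, `calibrate_k`
inverts the flux equation to the constant k that reproduces a stated flux
exactly — the calibration pinned to a 5.6 mmol m⁻² d⁻¹ efflux at
ΔpCO₂ = 670 − 390 µatm, S = 33.02, T = 30 °C yields k ≈ 3.2 cm h⁻¹,
physically plausible for a sheltered, low-wind embayment.

## Coral metabolism

Buoyant-weight calcimetry: W_dry = W_buoyant/(1 − ρ_sw/ρ_aragonite) with
ρ_aragonite = 2.94 g cm⁻³; replicate weighings are averaged before
conversion. Calcification = ΔW_dry·1000/(SA·Δt), mg CaCO₃ cm⁻² d⁻¹,
negative for net dissolution.

Chamber incubations: the O₂ change is an OLS slope over the timed
readings (default; an endpoint-difference option exists and coincides with
OLS for linear data — with three readings the two differ only through
noise on the middle point, which OLS damps). The coral-free control
chamber's slope is subtracted when present (default on), attributing
shared drift to the chamber rather than the animal. The areal rate is
slope·(V_chamber − V_coral)/SA with the net volume in litres. Sign
convention: dark consumption makes R negative; P_g = P_n − R therefore
adds the respiratory magnitude to net photosynthesis, and the energy
ratio is P_g:|R| (undefined and flagged at R = 0; a positive dark slope
is logged as suspect). Coral volume defaults to 0 with a warning when the
displacement measurement is absent.

## Benthic cover

Point-count annotations (five random points per photo, 50 photos per
transect in the standard protocol) aggregate to per-transect percent
cover (points-in-category / 250), then to site cover as the unweighted
transect mean. Category labels are validated against a controlled
vocabulary and photos with the wrong point count abort with their IDs;
silent coercion is the classic way cover tables rot.

## Synthetic data

Each generator inverts its estimator. The bay generator places interior
normalized TA/DIC at exactly the values the box model maps back to the
prescribed (G_n, P_n), splits them antisymmetrically into sunset/sunrise
values (so midpoints recover the daily mean identically), de-normalizes
to per-station salinities, then adds Gaussian measurement noise. Default
conditions emulate the target campaign: τ = 71 d, d = 18 m,
S_ref = 33.02, G_n = 22.7 mmol CaCO₃ m⁻² d⁻¹, P_n = −6.9 mmol C m⁻² d⁻¹,
37 interior stations sampled in both phases (74 interior samples) plus 3
offshore end-member stations, TA/DIC noise at the titrator accuracies
(2–3 µmol kg⁻¹). The default end member (nTA = 2250, nDIC = 1930
µmol kg⁻¹) was chosen once so the implied carbonate chemistry is
realistic for an inner-reef system: offshore pH_T ≈ 8.03, pCO₂ ≈ 405 µatm,
Ω_arag ≈ 3.8; interior pH_T ≈ 7.83, pCO₂ ≈ 660 µatm, Ω_arag ≈ 2.5.

The transplant generator builds a 2×2 reciprocal design (12 colonies per
origin, 18-day deployment, 400 ml chambers, readings at 0/20/40 min, 9 of
12 nubbins incubated) from per-group true rates, including a drifting
blank chamber so the blank correction is exercised; the point-count
generator draws per-point categories from prescribed cover fractions.
All randomness flows from one `numpy.random.SeedSequence` per call,
spawned into independent streams per noise source, so identical seeds
give identical tables.

What the synthetic data do not emulate: spatial autocorrelation and
within-bay gradients (all interior stations share one mean), covariance
between TA and DIC errors, tidal aliasing of the sunset/sunrise sampling,
and any biology behind the rates. Passing recovery tests therefore
demonstrate that the estimators invert the stated model under its own
assumptions — not that the box model is an adequate description of a real
bay (residence time, in particular, enters as an external input and its
error propagates multiplicatively).

## Problem sizes and numerical conventions

The acceptance script and tests use an 800-point reference subsample for
solver validation, 100 random pairs against the 10⁻⁵ pH-grid scan,
200–500 replicates for noisy-recovery rates, and the campaign-scale bay
(74 interior samples) throughout; these sizes give stable pass/fail
behaviour at interactive runtimes. Ties in the grid scan resolve to the
first minimum (irrelevant at 10⁻⁵ resolution). Degenerate inputs fail
loudly: non-positive TA/DIC, salinity ≤ 0, chamber volume ≤ coral volume,
missing day or night samples, unknown constant sets, categories or
station roles. Constant fits warn (not fail) outside their S/T fit
ranges.

## Known limitations

- TA+DIC is the only supported input pair; no pressure corrections; no
  uncertainty propagation through the equilibrium constants.
- The budget assumes steady state over τ and complete mixing; it cannot
  resolve per-station rates or separate nighttime dissolution.
- The gas-flux registry's Schmidt polynomial is a S = 35 approximation;
  at reef salinities the error is well under other flux uncertainties.
- Statistical comparison of transplant groups (mixed models, multiple
  comparisons) is deliberately out of scope; the results table is tidy
  input for any statistics package.
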