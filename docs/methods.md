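# Methods

`docpump` diagnoses net dissolved organic carbon (DOC) production (NDP) and
export (NDX) from a tracer climatology and an ocean transport matrix, and
exercises the whole chain on a synthetic ocean whose biological truth is
known exactly. This note documents the model, the numerical choices, the
synthetic world and its deliberate simplifications, and what the tests do
and do not demonstrate.

## The diagnostic model

Let `T` (yr⁻¹) be a sparse linear operator advecting and mixing a tracer
concentration `C` (µmol kg⁻¹) between grid boxes, satisfying
`massᵀT = 0` (no tracer created or destroyed by transport) and `T·1 = 0`
(uniform fields are steady). Partitioning boxes into surface (above a
chosen depth) and interior blocks, the steady-state mass balance reads

    0 = T_ss C_s + T_si C_i + J,
    0 = T_is C_s + T_ii C_i + L,

with `J` and `L` the net biological source/sink at the surface and in the
interior. Only `J` is sought, so the interior is pinned to observations and
the surface row is closed by restoring with a timescale τ:

    (T_ss − I/τ) C_s = −T_si C_i,obs − C_s,obs/τ,
    NDP  = J_pr = (C_s,obs − C_s)/τ        (DOC),
    J_up = (C_s − C_s,obs)/τ               (nitrate uptake).

For τ > 0 and a conservative `T`, the system matrix is strictly diagonally
dominant; a sparse LU factorization solves it and the relative residual is
checked against 1e-10.

**Exact-recovery identity.** If the observed fields are themselves a steady
state of the same physics with net surface source `J_net`, then
`J_diag = (I − τ T_ss)⁻¹ J_net` exactly, so `J_diag → J_net` linearly as
τ → 0. This identity is the backbone of the test battery: the inversion is
verified as a parameter-recovery problem, not against tuned numbers.

**Export.** NDX across a reference depth (default 74 m, the base of model
layer 2) is diagnosed by re-running the diagnosed production through the
full circulation with a first-order sink `k = 10¹² yr⁻¹` confined to the
layer directly below the export depth:

    (T − K) C = −J_pr,   NDX = k·C on the absorbing layer.

The absorbing rows are rescaled by their largest entry before
factorization so the huge `k` does not damage conditioning. An exact
elimination variant (treat the absorbing layer as a `C = 0` boundary; read
export as the incoming transport flux) agrees with the big-`k` solve to
better than 1e-6 relative and serves as a permanent cross-check. Because
`massᵀT = 0`, mass-weighted global NDX equals global NDP identically — the
conservation test asserts 1e-8 relative over a τ × circulation × scenario
sweep.

Unit conversions: areal flux = molar rate × density × layer thickness ×
atomic weight × 1e-6 (gC m⁻² yr⁻¹ or gN m⁻² yr⁻¹); global integrals are
area sums in Pg yr⁻¹. Density is constant 1025 kg m⁻³ by default (per-box
overridable), which keeps the conversions exactly testable; a full equation
of state is out of scope.

## The synthetic ocean

Geometry: latitude bands between ±80° (default 36), longitude sectors
standing in for basins (default 3: Atlantic/Pacific/Indian), 24 layers with
interfaces at 36 m and 74 m and a 5180 m flat bottom. Areas are spherical;
boxes are full-depth everywhere (no bathymetry).

Transport is assembled from a meridional overturning streamfunction
(volume transport, ψ = Ψ₀ · sin(3π φ/80°) · sin(π ζ(z)) with
ζ an upper-ocean-concentrated coordinate, e-folding 500 m) plus constant
diffusivities (isopycnal 1e3 m² s⁻¹, diapycnal 2e-5 m² s⁻¹, zonal mixing
at 25% of isopycnal). The harmonic gives equatorial and ~±55° upwelling and
downwelling centered on ±30°; the upper-ocean vertical shape ensures the
convergence/divergence pattern is felt at the 74 m export depth, as
wind-driven cells are. Advection is upwind in flux form and diffusion is a
symmetric exchange, so both conservation invariants hold to rounding for
*any* parameters — fluxes are differences of ψ, which is divergence-free by
construction. The circulation "ensemble" perturbs ψ node-wise and the
diffusivities globally by ±10% and re-derives fluxes, so every member is
exactly conservative. The default overturning amplitude is 20 Sv.

Biological truth: DOC production (default 5 µmol C kg⁻¹ yr⁻¹ scale) peaks
in the subtropics at ±28° and is surface-intensified (75%/25% over layers
1–2); interior consumption is first-order (0.1 yr⁻¹) toward a 40 µmol kg⁻¹
refractory floor. Nitrate uptake (4.2 µmol N kg⁻¹ yr⁻¹ scale) shares the
horizontal pattern but is deeper-weighted (25%/75%, a crude deep
chlorophyll maximum), and regeneration is a first-order relaxation
(0.25 yr⁻¹) toward a prescribed nutricline whose surface end-member rises
poleward (weakly stratified high latitudes). The uptake amplitude and layer
weights were set, once, by a linear calibration so the world realizes the
regionalization conditions the analysis assumes: oligotrophic gyres with
0–74 m mean NO₃⁻ below the 0.5 µmol kg⁻¹ marker in every basin, an
Antarctic zone above 20 µmol kg⁻¹, and a strictly positive field. A
consequence of forcing both thresholds into one small linear world is that
the NDP:NO₃-uptake mol ratio (≈4.5 above 36 m, ≈1.1 above 74 m) is lower
than open-ocean estimates; the depth *ordering* of the ratio — the property
the diagnostics are tested on — is unaffected.

Basin contrast: production is modulated ±8% across sectors, uptake only
±0.8% (larger nutrient contrasts would straddle the 0.5 threshold
inconsistently), and SST carries a ±0.8 °C sector offset so the mapping
step has a physical predictor encoding basin identity.

Ancillary fields mimic the satellite products the regional analysis
consumes: NPP follows light × Michaelis nutrient limitation (high equator
and subpolar, low gyres), the export ratio decays with SST (≤ 0.42), the
picoplankton fraction decays with surface nitrate (so it is negatively
rank-correlated with NO₃⁻ and positively with export efficiency), and a
family of nine export "algorithms" spreads the built-in ratio ±20% to
emulate algorithm spread. Observations are Bernoulli samples per box with
surface-biased inclusion (e-folding 500 m), Gaussian noise (default
2 µmol kg⁻¹, optionally surface-amplified), and per-seed determinism.

What the synthetic world does **not** emulate: seasonality, mixed-layer
physics, bathymetry and shelves, a real equation of state, spatially
correlated observation error from cruise tracks, and the geographic
arrangement of the real Southern Ocean (the nutrient-based SAZ/AAZ split
can label polar downwelling columns SAZ). Passing tests therefore
demonstrate the correctness and stability of the *method* under known
truth, not the accuracy of any real-ocean number.

## Gap-filling ensemble

Members are single-hidden-layer networks (15 logistic units, linear
output) fit by L-BFGS on the L2-penalized squared loss (penalty 1e-2,
tolerance 1e-6, iteration cap 10⁴), each on an independent random 70% of
the observations with per-predictor z-scores computed from its own
training subset; the 30% validation split never touches the weights.
A member that hits the iteration cap is flagged non-converged and dropped;
fewer than half surviving is an error, and an optional validation-R²
retention threshold mirrors ensemble-screening practice. The ensemble
prediction is the member mean; the member standard deviation is the
mapping uncertainty and the member fields are the pool the Monte Carlo
draws from, which propagates spatially correlated mapping error.
Predictions outside the axis-aligned training range are returned but
flagged in an extrapolation mask. The skill benchmark runs on a finer
64 × 6 × 24 world (~9,200 boxes, ~460 observations at 5% sampling — the
sparsity regime the method targets); holdout R² ≈ 0.93 and
leave-one-basin-out R² ≈ 0.9 against fresh noisy observations.

## Monte Carlo

Each run draws independently, with replacement: a mapped DOC field (pool
of 20), a circulation (pool of 10 perturbed matrices), and τ uniform on
3–9 months, then repeats the NDP, uptake, and NDX solves. Per-box means
and standard deviations accumulate streaming (Welford); each run's draws
and global/band integrals are logged. Ratio uncertainties are computed
from *paired* per-run draws and then summarized — never as ratios of
summaries — because numerator and denominator are correlated through the
shared draws. The desk default is 200 runs; 2000 (the production setting)
changes only the Monte Carlo error. Single-run failures are skipped and
logged; more than 1% failing aborts.

## Regionalization and regression

Columns are labelled by basin and by the thickness-weighted 0–74 m mean
nitrate: below 0.5 µmol kg⁻¹ → subtropical gyre of the basin (STP/STA/STI);
otherwise southern-sector columns split SAZ/AAZ at 20 µmol kg⁻¹, northern
columns are NP/NA (the synthetic Indian sector has no northern analogue
and folds into TI), and the rest are tropical (TP/TA/TI). Boundary values
go to the high-nutrient side. The 0.5 marker flags the gyre edge, not
nutrient limitation, and both thresholds are configurable metadata.

Efficiency ratios (NDP:C-export, NDX:C-export, NDP:NPP) are ratios of
regionally area-integrated fluxes — never means of pointwise ratios — with
zero denominators reported as undefined (NaN). The export-efficiency
regression regresses regional NDP:C-export on export-weighted regional
means of F_pico and log₁₀(NO₃⁻) (floored at 0.01 µmol kg⁻¹ before the
log), with no intercept by default; standardized coefficients are
raw × sd(predictor)/sd(response) and their ratio compares predictor
importance. Collinear designs (condition number > 1e8) raise. On the
reference world the fit gives a positive picoplankton coefficient, a
negative log-nitrate coefficient, and R² ≈ 0.96 — the covariance structure
the generator builds in.

A note on the recovery test: with 10 regions and two predictors the
residual t distribution has 8 degrees of freedom, for which ±2·SE is ~93%
coverage per coefficient; the recovery battery therefore checks
per-coefficient coverage (≥90% over 500 replicates), the calibrated
version of the check.

## Numerical choices and degenerate inputs

Sparse LU everywhere (systems are ≤ ~10⁴ boxes and diagonally dominant);
residual guards at 1e-10 (solves) and 1e-8 (forward consistency). A zero
interior rate makes the forward operator singular — the error message says
to pin a reference box or use λ > 0. A euphotic depth shallower than layer
1 keeps layer 1 as surface (logged, not an error). Production below the
export depth is rejected, as the absorbing construction requires. A zero
transport operator is legal and yields `C_s = C_s,obs`, `J = 0`.
End-to-end runs under a fixed master seed are bit-identical, including
output file hashes recorded in the run manifest.

## Problem sizes

The default test battery uses the 36 × 3 × 24 world (2592 boxes) for all
inversion, export, Monte Carlo, and regional tests, the 64 × 6 × 24 world
for mapping skill, and 2000-run Monte Carlo for the stability checks;
the full suite runs in about three minutes on one CPU.
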