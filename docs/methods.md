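# Methods

## Free-energy model

The liquid is described by an extended Scatchard–Hildebrand model: a
Flory–Huggins entropy of mixing that accounts for molecular size asymmetry
plus a regular-solution residual,

    βΔG_mix = Σᵢ xᵢ ln φᵢ + (v/v_ref) Σ_{i<j} χᵢⱼ φᵢ φⱼ,

with φᵢ = xᵢvᵢ/v, v = Σ xᵢvᵢ, and the solvent's effective volume as
reference (v_ref = v₁).  Differentiating n·βΔG exactly gives

    ln γᵢ = ln(φᵢ/xᵢ) + 1 − vᵢ/v + (vᵢ/v_ref)[Σ_{j≠i} χᵢⱼφⱼ − Σ_{j<k} χⱼₖφⱼφₖ].

All γ derivatives used by the package (thermodynamic factors, spinodal) are
analytic; central finite differences of ln γ and of βΔG appear only in the
test suite as independent oracles (agreement ≤ 1e−6, Gibbs–Duhem residual
≤ 1e−8 at random interior points).

Limits are taken by continuity: 0·ln 0 = 0 and φᵢ/xᵢ → vᵢ/v as xᵢ → 0, so
activities, Γ and fluxes are regular on the boundary faces of the simplex.
Only the chemical potential itself (ln xᵢγᵢ) rejects absent species.

Two distinct volume sets coexist deliberately.  The *effective* volumes vᵢ
are fitting parameters of the activity model (v₂/v₁ = 1.50 for ethanol); the
*physical* volumes Vᵢ are pure-component molar volumes defining the transport
reference frame (V₂/V₁ = 3.23 from 25 °C densities).  Conflating them changes
both the phase diagram and the flux closure.

### Parameters (defaults, dimensionless at 298 K)

| parameter | value | role |
|---|---|---|
| χ₀₁ | 0.59 | solute/solvent interaction |
| χ₀₂ | 2.075 | solute/antisolvent interaction (drives demixing) |
| χ₁₂ | 1.07 | solvent/antisolvent interaction |
| v₀/v₁, v₂/v₁ | 3.58, 1.50 | effective volumes (activity model) |
| β(μ₀ˢ−μ₀°) | −2.2 | solubility constant |
| V₀/V₁, V₂/V₁ | 3.58, 3.23 | physical volumes (volume frame) |
| Đ₀₁, Đ₀₂, Đ₁₂ | 1e−9 m²/s | Maxwell–Stefan diffusivities; sweep range 0.40–1.25e−9 |

Temperature is a fixed label; no temperature dependence is implemented.

## Supersaturation, two ways

* nonideal: S = x₀γ₀e^{−β(μ₀ˢ−μ₀°)} — the activity ratio; the saturation
  activity is composition independent, so one activity evaluation suffices.
* ideal: S = x₀ / x_sat(w) — concentration against the *model's own*
  solubility at the local solute-free solvent composition w (ethanol mass per
  solvent mass).  A composition-independent reference would make overshoot
  impossible in ideal simulations; tying it to the local solvent ratio is the
  definition under which the ideal/nonideal initial pair 0.85/0.89 and the
  classical overshoot picture both emerge.  Both definitions equal 1 on the
  solubility curve by construction.

The simulator evaluates x_sat via a 201-point monotone (PCHIP) interpolant of
the saturation curve; its error (~1e−7 relative) is far below discretization
error.  Direct root solves (Brent, residual < 1e−10, bracket (1e−10, 0.9))
are used everywhere a single point is needed.

## Phase diagram

* Solubility: ln(x₀γ₀) = β(μ₀ˢ−μ₀°) solved along rays of fixed water:ethanol
  ratio.
* Spinodal: zero contour of the smaller eigenvalue of Γ (antisolvent taken as
  dependent species; the stable/unstable classification is invariant to that
  choice, which the tests verify), scanned on a barycentric grid and refined
  by bisection to |min eig| < 1e−6.
* Binodal: equal chemical potentials of all species in two phases.  The first
  tie line is the solute/antisolvent binary pair (solved in logit variables
  to keep iterates in (0,1)); continuation marches the solute-lean phase's
  water content in steps of 0.01 (halved on failure) until the phases merge
  at the plait point.  Tie-line residuals are ≤ 1e−8 (typically 1e−15).
* Classification: unstable = min eig Γ ≤ 0; metastable = locally stable but
  inside the tie-line envelope (shapely polygon containment, with an optional
  tolerance that absorbs the continuation discretization where binodal and
  spinodal touch at the plait point); supersaturated = S_nonideal > 1.

## Maxwell–Stefan fluxes

Driving forces dᵢ = Σⱼ Γᵢⱼ ∂xⱼ/∂z (Γ = I in ideal mode).  Rather than
transcribing a closed-form ternary inverse, the species velocities solve the
linear system of (n_present − 1) Maxwell–Stefan relations, the volume-frame
closure Σ φᵢuᵢ = 0, and pins uₖ = 0 for species below a mole-fraction floor
of 1e−12 (an absent species moves with the frame, so its flux is exactly
zero).  This is algebraically equivalent to the matrix inverse, robust at the
simplex boundary, and is checked against a brute-force least-squares solve of
the overdetermined four-equation system to 1e−10.  The closure Σ VᵢJᵢ = 0
holds to round-off for every solved face, which is what preserves Σφᵢ = 1 in
the channel.  The sign convention is anchored by the ideal limit
Jᵢ = −c_t Đ ∂xᵢ/∂z.

Diffusivities are composition independent by default; a callable hook for
composition dependence exists but nothing ships using it.  Binary Fick↔MS
conversion uses D_fick = Đ·Γ_b with Γ_b = 1 + x ∂ln γ/∂x, and is refused
inside a binary miscibility gap where Γ_b ≤ 0.

## Finite-volume channel

State is the physical volume-fraction field φ (3 × n cells).  The evolved
unknowns are solute and antisolvent; water — present everywhere in every
scenario of interest — absorbs the Σφ = 1 constraint.  Face fluxes use
arithmetic-mean face compositions and central-difference gradients; walls are
zero flux.  Per-species volume is conserved to round-off by construction
(telescoping fluxes), and the tests require ≤ 1e−8 over full runs.

**Mobility limiting.**  With a sharp interface, uphill (activity-driven)
solute transport can drain a cell that holds none of a species when the face
mobility is the arithmetic mean.  The transported fraction at each face is
therefore limited to twice the donor (upwind) cell's value,
w = min(φ_face, 2φ_donor): inactive in smooth regions (second-order accuracy
retained — the equal-coefficient ideal run matches the closed-form cosine
series to < 1e−3 at 256 cells), but a cell holding nothing of a species
cannot export it.

**Time integration.**  Default is backward Euler with the face flux matrices
lagged and updated by Picard iteration (tolerance 1e−10, ≤ 50 sweeps), which
supports the 0.1 s reference step where explicit stability would demand
~1e−4 s at 1024 cells.  The linear system is block-tridiagonal and solved as
a banded matrix (bandwidth 3 with interleaved unknowns).  If a step still
produces a negative fraction (it can, at a steep depletion front), the step is
halved and retried recursively — a positivity-driven local refinement that
terminates because donor-limited fluxes vanish with the donor.  A fully
explicit adaptive sub-stepping integrator is retained as a validation oracle;
the two agree to < 1e−4 per 0.1 s step on smooth fields.

**Diagnostics.**  Every output interval (0.1 s by default) the run records
both supersaturation fields, the peak cell (leftmost on ties) with its
composition, running maxima, and the first time the fields come within 0.01
of the fully mixed state (the relaxation time — the paper-style comparison is
only qualitative, so this concrete definition is the package's own).  In
nonideal mode with `halt_on_spinodal`, the smaller Γ eigenvalue is evaluated
per cell at each output interval and the run stops at the first non-positive
value, reporting time, cell and composition; post-spinodal demixing dynamics
are outside the model.  The fully mixed reference is the volume-weighted
average of the two initial sides (no volume change of mixing is assumed
throughout, consistent with constant pure-component volumes).

**Initial conditions.**  Sharp step at the cell boundary nearest the
interface position (no smoothing by default; a configurable width was
considered and rejected as an extra free parameter).  Convenience
constructors specify the solution by a target concentration-ratio
supersaturation against pure-water solubility, and the antisolvent by ethanol
weight percent (molar masses) or volume percent (physical molar volumes).
The baseline contrast scenario uses equal volumes of solution and antisolvent
(interface mid-channel); the liquid–liquid demixing scenario uses 7:3
antisolvent:solution, which steers the mixing path through the spinodal.

## Analysis conventions

Peak localization is at cell resolution with a leftmost tie-break; no
sub-cell interpolation.  Trajectories are reported at 1 s spacing in
mass-fraction (barycentric) coordinates; if a run's output grid differs, the
path is interpolated linearly in time.  The overshoot metric is
max S (over cells and output times) divided by S of the fully mixed state.
The diffusivity cube runs the 8 low/high combinations (0.40/1.25 × 1e−9
m²/s) of the three pair diffusivities on one scenario; the corners split into
two clusters by the solvent/antisolvent coefficient Đ₁₂.  The all-low and
all-high corners are exact time rescalings of each other, so their overshoot
metrics coincide — the grouping inequality is strict only between
non-degenerate pairs.

Converged behavior of the baseline nonideal scenario: the supersaturation
maximum exceeds the fully mixed value by about 2.4% (grid- and step-size
independent from 64 to 512 cells, confirmed by the explicit integrator).  It
is a late-time solute enrichment at the solution-side wall — solvent
composition homogenizes before the solute finishes redistributing — not an
interface overshoot; the ideal model's metric on the same scenario is ~2.2.

## Calibration and synthetic data

The generator evaluates the model's own solubility curve (even grid of
solvent ratios) or a binary activity-coefficient curve and applies
multiplicative lognormal noise at a stated relative scale, seeded and
reproducible.  It emulates the *structure* of gravimetric solubility and
VLE-derived activity tables — smooth curves with unbiased multiplicative
noise — not their real error processes (no systematic bias, no
heteroscedasticity beyond the log scale, no composition-dependent detection
limits).  Passing recovery tests therefore show identifiability and
correctness of the fitting pipeline on model-generated data, not robustness
to real measurement pathologies.

Fits minimize squared residuals of log solubility (the antisolvent-rich
branch spans orders of magnitude, and is where measurement is hardest) or of
ln γ, with bounded parameters (χ ∈ [0,10], constant ∈ [−10,0], volume ratios
∈ [0.1,10]) and a 3-start seeded multi-start.  Noiseless tables are recovered
to ≤ 1e−4; at 1–2% noise, recovery is within 5–10% for the seeded cases the
tests pin.

## Problem sizes and numerical tolerances

Tests and examples run at 64–256 cells (the study protocol's 1024 remains
the library default); mesh/step refinement at the test scale changes fields
by < 1e−3, and the headline metrics (overshoot 1.0245, halt time, cube
grouping) are resolution independent to 4–5 digits.  Root solves: Brent to
xtol 1e−15.  Picard: 1e−10, max 50 sweeps.  Positivity retry depth ≤ 20.
Spinodal refinement: |min eig| < 1e−6.

## Known limitations

One spatial dimension; no convection (zero volume-average velocity by
construction); no nucleation, growth or population balance — supersaturation
fields are read as propensity maps only.  No heat of mixing or volume change
of mixing.  The model stops at spinodal entry; coexisting-phase dynamics are
not simulated.  Composition-independent diffusivities.  Activity model is not
temperature dependent and covers exactly three components.
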