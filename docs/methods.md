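# Methods

## The question the pipeline answers

Projections of oceanic deoxygenation from biogeochemical ocean models
depend on parameters that cannot be observed directly. `oxymap`
quantifies, per location, how much of the spread in a
perturbed-parameter ensemble of water-column oxygen minima is
attributable to each uncertain parameter, for the contemporary state
and for the projected change — and uses that attribution to locate
*benchmarking regions*: places where present-day observations would
most effectively constrain a specific parameter.

## Uncertain parameters and their priors

Three parameters are uncertain; everything else is held fixed.

| symbol | meaning                         | units   | mean   | rel. sd | floor |
|--------|---------------------------------|---------|--------|---------|-------|
| w      | detritus sinking speed          | m/day   | 15     | 50 %    | 5 % of mean |
| kappa  | vertical background diffusivity | m²/s    | 3·10⁻⁵ | 50 %    | 5 % of mean |
| a      | max. phytoplankton growth rate  | 1/day   | 0.6    | 25 %    | 5 % of mean |

Each prior is an independent Gaussian in physical units, specified by
mean and relative standard deviation and truncated from below.
Truncation is applied to the collocation *nodes* only, leaving the
quadrature weights untouched: this mirrors running a designed ensemble
whose inputs were clipped to physically admissible values, rather than
re-deriving a quadrature for a renormalized prior. With floors at 5 %
of the mean the clipped prior mass is below 3 % per parameter (normal
CDF), and a dedicated test verifies that the clipping moves Sobol
indices of smooth responses by less than one percentage point. The
means are order-of-magnitude-typical for coarse biogeochemical models
and are configuration inputs; no correctness property depends on them.

## Collocation design, polynomial chaos, Sobol indices

The design is the full tensor product of the 1-D Gauss–Hermite rule
for the standard-normal weight (physicists' nodes scaled by √2,
weights divided by √π, renormalized to sum to 1). Five points per
dimension give 125 runs; an n-point rule is exact to degree 2n−1 per
axis, so all inner products needed below are integrated exactly.

Outputs are expanded in the orthonormal probabilists' Hermite basis
ψ_α(ξ) = Π_i He_{α_i}(ξ_i)/√(α_i!) over standardized coordinates
ξ = (x − mean)/sd, keeping all multi-indices of total order ≤ 3
(20 terms). The probabilists' convention is the natural one because
the priors are Gaussian in physical units. Coefficients come from
discrete projection, c_α = Σ_q w_q Y_q ψ_α(ξ_q) — not least-squares
regression — because on a full tensor quadrature the projection is
exact for the retained basis; the constant coefficient is then exactly
the weighted ensemble mean.

Orthonormality makes the variance decomposition trivial:
D = Σ_{α≠0} c_α², and the Sobol fraction of a parameter subset U is
the sum of c_α² over multi-indices whose nonzero positions are exactly
U, divided by D (in %). Main effects, the three pairwise interactions
and the triple interaction partition the non-constant basis, so they
sum to 100 % wherever D > 0 — an invariant the tests assert to 10⁻⁶
relative. The triple interaction is computed and reported even where a
summary table would omit it, precisely so that completeness holds.

Numerical choices: a column whose expansion variance is numerically
zero (sd below 10⁻¹² · (1 + |mean|), i.e. projection residue of a
constant output) reports NaN fractions, never 0 % — zero would falsely
assert insensitivity. `max_order` is configurable but no automatic
order-selection is implemented; order 3 is the default because higher
Hermite contributions of the smooth column responses are negligible.

## The synthetic ocean

The generator replaces a 3-D Earth-system model with independent
steady-state water columns so that a full ensemble is a seconds-scale
computation while the causal pathways from (w, kappa, a) to oxygen are
preserved:

* Steady diffusion–consumption balance
  d/dz[(κ + s·κ_dyn(z)) dO₂/dz] = J(z), Dirichlet surface condition at
  the linearized saturation O₂_sat = 350 − 6·T (mmol/m³), zero-flux
  bottom; uniform grid H = 1000 m, Δz = 10 m (halving Δz moves column
  minima by < 1 %).
* Export F₀ = F_max·L·a/(a + K_a) with F_max = 40 mmol m⁻² day⁻¹ and
  K_a = 0.3 day⁻¹; sinking flux F(z) = F₀ e^{−rz/w} with r = 0.1 day⁻¹,
  consumed as the exact cell-averaged flux divergence, so the discrete
  column integral of J equals F₀(1 − e^{−rH/w}) to machine precision
  and the solved surface influx balances total consumption to 10⁻⁸
  relative (asserted per column).
* Consumption is O₂-independent, which keeps the solve linear and
  unique; negative concentrations are clipped to zero afterwards and
  flagged (`suboxic`), so tests can exclude clipped columns from
  smooth-response checks.

Three regime families (fractions 0.2 / 0.4 / 0.4 over 100 columns,
with per-column jitter of production, temperature, mixed-layer depth
and deep mixing) realize the qualitative contracts the diagnostics
must detect:

* **deep_water_formation** — cold, vigorous dynamic mixing throughout
  the column, low production, strong projected warming and
  stratification collapse: large projected change driven by solubility
  and ventilation, almost insensitive to (w, κ, a).
* **tropical_omz** — warm, weak mixing below a shallow mixed layer,
  productive: low contemporary minima, smaller absolute change, and
  strong sensitivity to all three parameters (ventilation hinges on
  the uncertain background κ; demand on a and w).
* **intermediate** — between the two.

The regime constants (temperatures per slice, stratification factors,
mixing profiles, production factors) were fixed once when the world
was designed, at values typical for the respective environments; they
are configuration, not fitted quantities. What passing tests show is
that the pipeline detects regime-dependent sensitivity structure in an
ensemble that has it — not that any specific ocean's field values are
reproduced. A single seed governs world generation; design and solver
are deterministic, so archives reproduce bitwise.

Structural simplifications: no horizontal transport (manifestations of
parameter uncertainty cannot be advected between regions), no seasonal
cycle, no nutrient/carbon coupling, no air–sea gas-exchange kinetics,
no transient spin-up — each slice is an equilibrium under its own
forcing.

## Diagnostics

All ensemble statistics are quadrature-weighted by default: the 125
members sit at collocation nodes and are not equiprobable, so
unweighted statistics would over-represent the tails. An unweighted
mode exists for comparison (`--unweighted`).

* **mean change**: weighted ensemble mean of (projected −
  preindustrial) per column.
* **noise-to-signal** (%): weighted sd of the change over |weighted
  mean change|; denominators below ε = 10⁻⁶ mmol/m³ yield NaN, not
  infinity.
* **contemporary spread / CV**: weighted sd of the year-2000 field,
  and the same normalized by the mean (identically the noise-to-signal
  of the raw field).
* **low-variance mask**: columns whose ensemble sd is below 6 % of the
  local mean magnitude (|mean|, so the rule extends to signed change
  fields) are excluded from interpretation; zero-variance columns are
  always masked.
* **regional averages**: unweighted arithmetic means of the per-column
  percentage indices over the unmasked columns of non-overlapping
  named regions (selected by regime label, explicit column ids, or a
  lat/lon box for external archives). Averaging the percentages —
  rather than pooling variances first — treats every location equally
  regardless of its local variance; the pooled alternative would weight
  high-variance columns more. A partition of all columns recovers the
  global mean exactly (tested to 10⁻¹⁰).
* **benchmark scores**: a column is eligible if unmasked and its
  contemporary spread exceeds a quantile (default: the median over
  unmasked columns — a deliberate free choice, since "preferably high
  spread" fixes no threshold); its score per parameter is that
  parameter's contemporary main effect in %. The report lists the
  top-k columns per parameter with regime labels.
* **rank correlation** between contemporary CV and projected
  noise-to-signal is computed and reported; no particular value is
  asserted, only that the two maps need not coincide.

## Problem sizes and runtime

The default end-to-end configuration — 125 runs × 100 columns × 3
slices (37 500 column solves), 20-term expansions per column and
slice, all diagnostics and reports — completes in well under a minute
on one CPU; the test suite's Monte-Carlo cross-checks (pick-and-freeze
Sobol estimation at n = 10⁵ on 20 random cubic polynomials, and
direct Saltelli estimation on the column solver itself) dominate the
suite's runtime. These sizes are the package's defaults because they
match the structure of the archives the pipeline targets (125-member
designs over three parameters and three time slices).

## Known limitations

* The column model cannot express cross-region transport; benchmarking
  logic is validated on within-archive statistical structure only.
* Clipped (suboxic) columns make the response piecewise-linear; the
  third-order expansion then mixes the kink into interaction terms.
  This is physically meaningful (suboxia is a real threshold) but
  means interaction fractions in heavily clipped regions should be
  read as "nonlinear/threshold variance", not smooth synergy.
* Only parametric uncertainty is addressed; structural and forcing
  uncertainty are out of scope.
* Priors are independent truncated Gaussians; correlated priors and
  other families are not supported.
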