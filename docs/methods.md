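# Methods

This note documents the models, numerical choices and known limitations of
`ppase-kinetics`.  It describes what the code computes; every empirical
number quoted here is produced by the test suite or `scripts/acceptance.py`.

## Substrate speciation

Membrane pyrophosphatases hydrolyse the dimagnesium–pyrophosphate complex,
so the fitting abscissa of a saturation experiment is S = [Mg₂PPi], not the
analytical PPi concentration.  The speciation model treats fully
deprotonated PPi⁴⁻ as the reference ligand and includes the stepwise
complexes HPPi, H₂PPi, MgPPi, Mg₂PPi, MgHPPi, KPPi and NaPPi, each defined
by a dissociation constant Kd = [M][L]/[ML] in mM.  Assumptions:

* **Buffered pH.**  [H⁺] is an input (default pH 7.2), never solved.
* **Monovalents free.**  K⁺ and Na⁺ totals exceed PPi by ≥100× in the
  assays modelled, so their free concentrations are taken equal to totals
  (no monovalent mass balance).
* **Conditional constants.**  No activity-coefficient model is applied; the
  constants are conditional at assay ionic strength.  The shipped defaults
  (`src/ppase_kinetics/data/ppi_constants.tsv`: pKa 8.94 and 6.13 for the
  protonations; Kd 0.004 mM MgPPi, 2.5 mM Mg₂PPi, 0.8 mM MgHPPi, 12 mM
  KPPi, 11 mM NaPPi) come from a standard PPi-complexation compilation and
  are a documented stand-in: any serious analysis should supply its own
  table (`--constants`, `ComplexationConstants.from_table`); every run
  manifest records the constants actually used.

**Solver.**  Two unknowns remain: free PPi and free Mg²⁺.  For fixed free
Mg every PPi species is *linear* in free PPi, so the PPi balance is solved
in closed form, and the Mg balance becomes a one-dimensional root-find on
[0, total Mg] whose residual brackets the unique root; Brent's method with
relative tolerance 1e−10 (max 200 iterations) closes it.  This nested
closed-form/Brent scheme was chosen over a 2-D damped Newton on log
concentrations because it cannot leave the feasible region or diverge, and
the structure of the system makes the inner solve exact.  Both mass
balances are verified after the solve; tests additionally check the solver
against an independent nested-bisection oracle (agreement within 1e−6 mM)
and the closed-form single-equilibrium quadratic ([MgPPi] ≈ 0.0916 mM for
Kd = 0.01 mM with totals 0.1/0.2 mM).

Degenerate inputs short-circuit: zero ligand, zero Mg, or no Mg-binding
species give the trivial state directly.

## Rate laws

* **Hill**: v = Vm·Sⁿᴴ/(K₀.₅ⁿᴴ + Sⁿᴴ) — the standard empirical form; the
  ratio (S/K₀.₅)ⁿᴴ is computed on the log scale so large nH cannot
  overflow.
* **Two-state allosteric model**: a concerted (MWC-type) model for a
  homodimer with two catalytic sites; R (active) and T (inactive) states in
  equilibrium L = [T]/[R]; exclusive substrate binding to R with
  dissociation constant K_R; substrate also stabilises R, implemented by
  dividing L by (1 + S/K_R)².  With u = 1 + S/K_R the saturation function
  is Ŷ = (u⁴ − u³)/(u⁴ + L), evaluated as u³·(S/K_R)/(u⁴ + L) so that
  neither tiny S (cancellation) nor large S (overflow before division)
  loses precision.  Tests verify the algebraic identity with the textbook
  ratio form to 1e−12, strict monotonicity in S, strict decrease in L, and
  the bounds 0 ≤ Ŷ < 1.
* **Proportionality.**  v = Vm·Ŷ with proportionality constant 1, so the
  fitted Vm is the true asymptote — the convention under which allosteric
  parameter tables report Vm directly.
* **Units.**  Substrate is mM everywhere internally; K_R is carried in µM
  on `MWCParams` (the scale on which these fits are conventionally
  reported) and converted at the boundary.  Rates are U/mg
  (µmol PPi·min⁻¹·mg⁻¹).
* **`effective_hill`** reports the apparent cooperativity
  n_eff = log 81 / log(S₉₀/S₁₀) of an allosteric parameter set
  (root-finding on Ŷ), a diagnostic linking L to the Hill coefficient an
  empirical fit would see: n_eff = 1 at L = 0 and increases monotonically
  with L.

## Weighted fitting

Replicate rates at each substrate level are collapsed to the mean, the
unbiased (n−1) sample variance and the count.  A level with a single
replicate has no variance; the contract is explicit — error by default, or
pooled-variance substitution with a warning (`single_replicate="pooled"`).

Weights are 1/(replicate variance) per point — the reading of
"1/variance" adopted here; 1/(variance of the mean) is available as
`weights="sem"`, and `"unit"` disables weighting.  A zero or undefined
variance would give an infinite weight, so such points receive the smallest
positive variance in the dataset (warning logged); if no positive variance
exists the fit falls back to unit weights.

The optimiser is SciPy's bounded trust-region-reflective least squares on
residuals √wᵢ·(yᵢ − f(sᵢ)), ftol = xtol = 1e−12, with a deterministic
multi-start: Vm₀ = max mean rate, K₀ = first s at half-max, and a grid over
the cooperativity parameter (nH ∈ {1, 2, 3, 5}; L ∈ {0, 10, 10³, 10⁵});
lowest final cost wins, ties to the first start.  Bounds keep parameters on
their natural scale (Vm ≤ 10× max rate, K ≤ 10× max s, nH ∈ [0.5, 8],
L ∈ [0, 10⁷]); no log-transform is used, so reported values match the
convention of kinetic parameter tables.  A parameter landing on a bound is
flagged in the result, and non-convergence of every start raises — a
clipped answer is never returned silently.

Standard errors use cov = s²(JᵀWJ)⁻¹ with s² = wSSE/(N − p), the common
nonlinear-regression convention; point estimates are invariant to rescaling
all variances by a constant, and the SEs absorb the scale through s²
(asserted by test).

**Substrate-inhibition truncation.**  High PPi inhibits some of these
enzymes and neither rate law models that regime, so points above a
configurable cutoff are dropped before fitting (`--truncate-max-s`,
per-enzyme or global); the truncation is recorded in the fit result and the
fit errors out if fewer than p + 1 points remain.  Published analyses of
this enzyme family quote cutoffs of 0.2 mM in one place and 0.175/0.25 mM
(per enzyme) in another; the package takes the cutoff as user input rather
than resolving that discrepancy.

## Synthetic assay generator

The generator stands in for raw microsomal assay data, emulating the two
standard designs:

* **matched_mg** — total Mg = 2 × total PPi at every point, the design used
  for substrate-saturation series plotted against [Mg₂PPi];
* **fixed_mg** — MgCl₂ fixed (1 or 2.5 mM) while PPi is titrated (up to
  0.25 mM), leaving free Mg²⁺ in excess.

Both carry 100 mM KCl by default, added NaCl per level, and the basal
Na⁺ = 4 × PPi of the tetrasodium salt.  Because the matched-Mg design is
conventionally read on the substrate scale, `matched_design_for_substrate`
inverts the speciation map (strictly increasing, solved by bracketed
bisection) to find the PPi totals whose speciated S hits the requested
grid.  The default grid is 8 points at S = 0.025–0.5 mM, chosen so the top
point sits at ≳80% saturation for allosteric parameter sets with
K_R ≈ 35–90 µM and L up to ~10³ — the regime the package targets — giving
Vm identifiability without entering the substrate-inhibited region.  The
inversion uses the lowest NaCl level of the series, as one stock dilution
series would serve all salt conditions.

Noise is Gaussian on each replicate rate with SD = CV·(true rate) + floor;
defaults CV = 8% and floor = 0.005 U/mg, chosen to match the error bars
typical of figure-scale microsomal assay data (the replicate error model is
not published anywhere; this is an explicit modelling choice).  Negative
draws are redrawn rather than clipped, keeping the mean unbiased at the
cost of slight variance shrinkage — negligible at these CVs (the mean sits
>12 SD from zero).  Replicates default to 4, the midpoint of the 3–5 used
experimentally; counts outside [3, 5] require an explicit override (used
by the moment-convergence tests at n = 10⁴).

Randomness: each (point, replicate) pair draws from
`numpy.random.default_rng((seed, point_index, replicate_index))`, so runs
are bit-identical per seed and subsetting a design never changes the draws
at shared points.

**What passing tests show.**  The simulator reproduces the designs' ionic
arithmetic and a homoscedastic-CV noise model.  It does not model day/batch
effects, pipetting covariance between points, enzyme inactivation over a
titration, or the substrate-inhibition regime itself; recovery results on
synthetic data therefore demonstrate correctness of the estimator under the
stated noise model, not robustness to every artefact of real assays.

## Pipeline conventions

* **Abscissa.**  Matched-Mg conditions are fitted against speciated
  S = [Mg₂PPi]; fixed-Mg titrations default to total PPi (the axis such
  experiments are plotted on), switchable to speciated S.
* **Reporting.**  Machine-readable tables keep full precision; the display
  columns round the SE to two significant figures and the estimate to the
  SE's decimal place.  Percent Vm decreases are reported raw and rounded to
  the nearest ten points (the granularity of narrative summaries such as
  "a 20% and 50% decrease").
* **Failure isolation.**  A condition whose speciation, aggregation or fit
  fails is flagged in its rows (converged = False, note filled) and logged;
  the run continues.  Every run emits a manifest with the configuration
  hash and the dissociation constants used.

## Parameter recovery at assay scale

The acceptance suite simulates the matched-Mg salt series (8 substrate
points, 4 replicates, 8% CV, NaCl ∈ {0, 50, 100} mM) from published
allosteric parameter sets for an H⁺-pump (Vm 0.51/0.40/0.24 U/mg,
L 17/50/106, K_R 84/64/69 µM) and a Na⁺-pump (Vm 0.46/0.47/0.34, L
615/123/7·10³, K_R 62/90/35 µM) and refits over 20 seeds.  Median Vm error
is ≤10% in every condition; median L is recovered within a factor of 3 for
generating L ∈ [10, 1000].  Beyond L ≈ 10³ the half-saturation point moves
toward the top of the grid and L's curvature flattens (only the product
regime Ŷ ≈ u⁴/(u⁴+L) is sampled), so L becomes weakly identified — a
design limitation of figure-scale grids, not of the estimator; Vm remains
within tolerance there.

Problem sizes throughout (8-point grids, 20 seeds, 50-instance oracle
comparisons, 10⁴-replicate moment checks) were chosen as the smallest that
make the statistical assertions stable.
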