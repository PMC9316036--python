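# Methods

## Thermolysis fitting

Non-enzymatic glycohydrolysis of the pyridine nucleotides is treated as
first order in the substrate with an Arrhenius temperature law
`k(T) = A·exp(−Ea/(R·T))`, `R = 8.314 J/(mol·K)`.  The bundled measurement
table gives, per compound, hydrolysis rates in %/min at 50, 75 and 90 °C
with standard deviations.

The default fit is **unweighted nonlinear least squares on the rate scale**,
including below-detection (0.00) points as data.  A log-linear regression is
available behind the `scale="log"` option but is not the default: on these
three-point series it down-weights the fastest, best-determined rate and
moves the NR activation energy from ≈ 72.6 to ≈ 52.5 kJ/mol.  An
inverse-variance weighting option exists for sensitivity analysis.

Numerically the fit is parameterized as `(ln k_ref, Ea)` with `1/T` centred
at the harmonic-mean temperature; the raw `(A, Ea)` pair is so strongly
correlated that optimizers stall on the ridge.  A multistart over
`Ea = 20…200 kJ/mol` (19 starts, Levenberg–Marquardt, `xtol = ftol = 1e-12`,
≤ 2000 evaluations) makes the fit deterministic and seed-free; the best-SSE
solution is returned.  `Ea` is invariant under a change of rate unit, `A`
scales linearly with it, so every parameter set carries a `rate_unit` tag
(`percent_per_min`, `fraction_per_s`, `fraction_per_ms`; the per-millisecond
convention, (%/min)/6×10⁶, matches the scale on which literature prefactors
for these compounds are quoted).  An all-zero series (no detectable
hydrolysis, e.g. NAAD) returns the degenerate `A = 0` result with `Ea`
undefined, explicitly flagged.

A caveat on reproducing printed parameter values from rounded rate means:
the SSE valley is extremely flat along the ridge `d ln A = dEa/(R·T_harm)`,
so a 0.2 % change in `Ea` moves `A` by ≈ 6 %.  Fits quoted from unrounded
replicate data can therefore differ from the optimum over the rounded means
by several percent in `A` while agreeing closely in `Ea`; the test suite
checks prefactor agreement up to this ridge bound and additionally verifies
that the converged fit has no worse SSE than the quoted pair.

## The kinetic model

Eight pyridine-moiety species (Nam, NA, NR, NAR, NMN, NAMN, NAD, NAAD) form
a closed system: every reaction moves exactly one moiety, so the summed
concentration is conserved (0.3 mM by default, the measured free-NAD pool;
the standard initial condition puts the whole pool in NAD).  Thirteen
enzyme-catalysed steps are carried by nine enzymes — NadD, NadR, SurE and
PNP each act on both an amidated and a deamidated substrate through two
reactions sharing one abundance; SurE is included because it appears in the
allocation argument set even though its substrate range is uncertain — plus
five hydrolysis reactions (NAD/NMN/NR → Nam, NAR/NAMN → NA; none for NAAD).

Rate laws are deliberately minimal: irreversible Michaelis–Menten in the
pyridine substrate only, `v = kcat(T)·E·S/(Km + S)` with enzymes in nM
(converted to mM internally), and first-order hydrolysis `v = k_hyd(T)·S`.
ATP, PRPP, phosphate and ribose cosubstrates are held constant and absorbed
into `kcat`; ADP-ribose and other non-pyridine products are not tracked; no
reversibility, substrate competition, enzyme thermal denaturation, de novo
synthesis, influx or growth dilution.  Temperature enters every rate
constant through `k(T) = k(T₀)·exp(−(Ea/R)(1/T − 1/T₀))`, T₀ = 310.65 K.

Default parameters (all overridable through the config mapping):

* enzymatic `kcat` 5–30 s⁻¹ and `Km` 0.005–1 mM per reaction, within the
  documented bands `kcat ∈ [1, 50] s⁻¹`, `Km ∈ [0.005, 1] mM`;
* enzymatic `Ea = 65 kJ/mol` uniformly, giving Q10 ≈ 2.19 at T₀ — inside
  the physiological 2–3 band that the defaults are required to satisfy;
* hydrolysis `k(T₀)` and `Ea` taken from the package's own Arrhenius fits
  to the bundled measurement table (`hydrolysis: "fitted"`); explicit values
  may be substituted.

ATP accounting: Nampt, PncB, both NadD branches and both NadR branches
consume one ATP equivalent per turnover (the non-stoichiometric
autophosphorylation ATP of the phosphoribosyltransferases is counted as one
for both Nampt and PncB, so it cancels between routes); NadE counts two
(ATP → AMP).  NAD production is `J_NadE + J_NadD,NMN` — both NadD branches
burn ATP but only the NMN branch makes NAD, a disambiguation recorded in
the `EnergyAccount` type.

## Steady states

The conserved total makes the full Jacobian singular, so Nam is eliminated
structurally (`Nam = total − Σ others`) and the solver works on the reduced
7-dimensional system; the returned total is therefore exact by construction.
Two routes to the fixed point:

* **hybrid** (default): stiff integration (LSODA, analytic Jacobian,
  `rtol 1e-8`/`atol 1e-12`) over geometrically growing horizons up to 10⁶ s,
  stopping early when the relative derivative norm falls below 10⁻¹⁰,
  followed by Newton refinement;
* **newton** (fast path): damped Newton embedded in pseudo-transient
  continuation — each step solves `(I/dt − J)·d = f` with the timestep
  adapted to the residual decrease (SER), so the iteration is implicit
  Euler far from the solution and quadratic Newton near it.  The inner loop
  is JIT-compiled and solves in ~20 µs, which is what makes thousand-run
  optimization studies affordable; warm starts from a parent's steady state
  cut it further.

Convergence requires `‖dC/dt‖∞ < 1e-16 + tol_rel·max|v|` with
`tol_rel = 1e-10` by default (10⁻¹¹–10⁻¹² where control coefficients are
differenced), deliberately far below the optimizer's discrimination scale so
steady-state error never masquerades as objective signal.  Non-convergence
is always reported explicitly in the result, never silently.  The test
suite cross-checks the two routes against each other on random enzyme
profiles (agreement < 10⁻⁶ mM componentwise) and verifies
initial-condition independence at fixed total.

## Enzyme allocation by evolutionary programming

The allocation problem mirrors the published formulation: abundances of the
entry enzymes PncA and Nampt in [10⁻¹⁰, 100] nM, the other seven in
[0.01, 100] nM, total ≤ 1000 nM, and — for the two flux objectives — the
steady-state NAD concentration strictly inside (0.1, 0.3) mM (the
NAD-maximization objective carries no NAD window).  Constraint violations
add a penalty proportional to the violation plus a fixed offset (10³), so
any feasible point outranks any infeasible one; a non-converged steady
state is treated as a violation.  Runs are classified `pnca_pathway` /
`nampt_pathway` when the minority entry enzyme falls below 10⁻² of the
majority one (the published wording is only "very small"), else `mixed`.

The optimizer is classical self-adaptive EP: 20 parents, one offspring
each by Gaussian mutation in log₁₀-abundance space with per-coordinate
widths updated lognormally (τ = 1/√(2√n), τ′ = 1/√(2n)), survivor selection
by stochastic tournament against q = 5 random opponents over parents plus
offspring, 200 generations, deterministic given the seed, best-ever
feasible solution returned after a tight re-solve.

**Mutation-width policy (a consequential design choice).**  Mutation widths
start at 0.25 decades and are clipped to [0.01, 1] decades — steps relative
to the current abundance and at most one order of magnitude, the behaviour
of optimizers that mutate parameters on their native scale.  With wide
width limits the population freely crosses the selection-neutral plateau at
tiny entry-enzyme abundances, every run finds the globally cheapest (two-
step) route, and the empirically observed bimodal outcome disappears; with
relative steps, a route whose entry enzyme collapsed early stays collapsed,
and the run is committed to the basin its initialization favoured.  Under
the defaults, repeat studies of the ATP-minimization and NAD-maximization
objectives populate both pure-route classes at every temperature with the
mixed class a clear minority, and the deamidation-route class pays ≈ 4 ATP
per NAD versus ≈ 2 — the expected stoichiometric ordering.

**A negative result worth stating.**  For the ratio objective
(`J_ATP/J_NAD`) no deamidation-route local optimum exists under these rate
laws: invading a PncA-type steady state with Nampt flux changes the ratio
by the marginal cost `(1 + φ)/φ` ATP per NAD, where φ is the fraction of
new NMN captured by NadD; a trap would require φ < 1/3, but NadD capture
dominates every NMN leak channel (hydrolysis, the SurE/PNP futile loop) for
any parameterization inside the documented bands, so invasion always pays
and every ratio-objective run ends on the two-step route.  Reports of both
route classes under ratio minimization therefore depend on optimizer
trapping or on richer rate laws (substrate competition at shared enzymes
was prototyped and does not change this); the package's repeat studies
exercise the cross-class efficiency comparison on the other two objectives.

Repeat studies default to 100 seeded repeats (the original design used
1000; class fractions at 100 are subject to ordinary binomial noise) over a
temperature grid from T₀ to 363.15 K, the hottest measured thermolysis
point.  All repeat seeds derive from a single stream, so entire studies are
reproducible from one integer.

## Metabolic control analysis

Scaled concentration control coefficients `C^S_p = ∂ln S/∂ln p` are
estimated for all 14 rate processes (9 enzyme abundances + 5 hydrolysis
constants) by central differences on multiplicative perturbations
`p → p·e^(±h)`.  The default `h = 5·10⁻³` keeps the O(h²) truncation error
of the per-species summation over all processes below 10⁻⁴ (scaling all
processes together only rescales time, so the sum is zero in theory — the
suite's summation oracle).  Every coefficient is recomputed at `h/2` and
flagged when the two estimates disagree by more than 10⁻³ relative; a
species at exactly zero, or a zero-magnitude process, gets a zero
coefficient by convention.  Finite differences were chosen over analytic
Jacobian algebra because the conserved moiety makes the naive Jacobian
singular; the Richardson check substitutes for a closed form.

## Synthetic data

The rate-table generator emulates the bundled table's design — three
temperatures, multiplicative Gaussian noise truncated at zero (matching the
printed 0.00 entries), default relative SD 5 % as the printed SD/mean
values cluster at a few percent.  It does not model replicate structure,
temperature error or detection limits beyond truncation, so
parameter-recovery results speak to the fitting code, not to NMR
measurement error.  Enzyme profiles are log-uniform over the allocation box
with budget rejection; perturbed configurations jitter kcat/Km log-
uniformly within a fold range for robustness sweeps of the distributional
claims.  All generators are pure functions of (spec, seed).

## Problem sizes

The bundled suite runs the repeat studies at 100 seeded repeats per
objective and temperature on a three-point temperature grid, the solver
cross-checks at 50 random profiles, and parameter recovery at 200
replicates; the pipeline's `run-study` exposes the full grid and repeat
count as flags.

## Known limitations

* Kinetic constants are documented defaults, not database-curated values;
  all parameter-dependent claims (control-coefficient signs, class
  fractions) should be read conditional on the bundled configuration, and
  `gen_perturbed_configs` exists to probe that dependence.
* The minimal rate laws omit substrate competition at the dual-substrate
  enzymes, product inhibition and explicit adenylate pools.
* Printed Arrhenius parameters for the slower compounds (NMN, NAD, NAR,
  NAMN) are not recovered from the rounded rate means by any least-squares
  variant tried (rate-scale, log-scale, weighted); the package uses its own
  converged fits to parameterize hydrolysis.
* Fitted prefactors are meaningful only together with their unit tag and
  the flat-ridge caveat above.
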