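# Methods

This note documents the models, numerical choices and design decisions
behind `nlfba`, and what the shipped synthetic benchmarks do and do not
demonstrate.

## The modeling problem

Flux balance analysis predicts steady-state reaction rates `v` by optimizing
an objective subject to `S·v = 0` and flux bounds. In C4 leaves the ratio of
Rubisco oxygenation to carboxylation, `v_o/v_c = (1/S_R)·(P_O2/P_CO2)`,
depends on the bundle-sheath gas levels, which are themselves functions of
the C4-cycle fluxes and of diffusion back to the mesophyll. `nlfba`
therefore treats the bundle-sheath CO2 and O2 levels as optimization
variables and imposes the kinetic laws as constraints of the same nonlinear
program that contains the stoichiometric rows.

### Kinetic constraints and units

Gas levels are equivalent partial pressures in μbar (≡ μmol mol⁻¹ at 1 bar),
one scalar per cell shared across subcellular compartments; the mesophyll
level equals the intercellular level (wall resistance neglected). Default
kinetic constants are values typical of C4 species:

| parameter | default | unit | meaning |
|---|---|---|---|
| k_C | 650 | μmol mol⁻¹ | Rubisco CO2 half-saturation |
| k_O | 450 | mmol mol⁻¹ | Rubisco O2 half-saturation |
| S_R | 2590 | – | Rubisco specificity |
| k_C,p | 80 | μmol mol⁻¹ | PEPC CO2 half-saturation |
| g_s | 1.03 | mmol m⁻² s⁻¹ bar⁻¹ | bundle-sheath CO2 conductance |
| g_s,O | 0.047·g_s | mmol m⁻² s⁻¹ bar⁻¹ | bundle-sheath O2 conductance |
| CO2_ME | 150 | μbar | mesophyll CO2 |
| O2_ME | 210000 | μbar | mesophyll O2 (21% at 1 bar) |
| r_d, r_m | 0 | μmol m⁻² s⁻¹ | respiration (comparison condition) |

Published sources print k_C,p and g_s with mutually inconsistent unit
strings (k_C,p as "mmol mol⁻¹" where the underlying physiology literature
uses the ~80 μbar scale; g_s as "μmol m⁻² s⁻¹" where conductances are
mmol m⁻² s⁻¹ bar⁻¹). `C4Params` stores the interpretations that make the
kinetic laws dimensionally consistent with the enzyme-limited physiology
model and records the alternative in the `*_unit` metadata fields; the
single μbar→flux conversion (factor 10⁻³) lives in `diffusive_flux`.

### Capacities as bounded variables

Each kinetic law is an equality tying the flux to its capacity
(`v_c = v_c,max·f_c(C,O)` etc.). In "optimizable" mode the capacity is a
variable in `[0, cap]`; because an assimilation-maximizing objective always
benefits from more capacity, the solution realizes the physiological
`min(·, ·)` between competing limits (e.g. PEPC kinetics vs the
decarboxylase cap, the effective PEP-regeneration limit) without any
non-smooth min() in the program. A zero optimizable capacity is a degenerate
interval and collapses to the fixed numeric 0, making the law a linear
zero-flux row; linear "nonlinear" constraints are routed to the linear block
generally, so programs that are actually LPs stay recognizable to the LP
path. "Fixed" mode keeps the capacity as a parameter for comparison with
models parameterized in those terms.

## Solver architecture

Constraints and objectives are sympy expressions; gradients and Hessians are
differentiated term-by-term (so large separable least-squares objectives
stay cheap to compile) and lambdified once per compile, with sparsity
patterns exposed. Conserved moieties (ATP/ADP, NADP pools) make
stoichiometric rows linearly dependent; a pivoted-QR pass selects a
full-rank equality subset for the solver while feasibility is always
reported against the full row set. Per-variable scales (gas levels ~10³–10⁵
μbar vs fluxes ~10¹) equilibrate the solver's coordinates.

The solver is an adapter over scipy.optimize:

* purely linear programs: `linprog` (HiGHS) on the dedicated LP path;
* the general path (`solve`): active-set SQP (SLSQP) for problems up to
  ~1200 variables, the sparse interior-point method (`trust-constr`,
  analytic sparse Hessians) as fallback and for larger problems;
* polishing: interior-point iterates stop short of active constraints by
  the barrier slack, so small problems get an SLSQP polish, and purely
  linear programs additionally get a crossover — a primal active-set walk
  (projected-gradient direction, exact ratio test, multiplier-based bound
  release) that lands on the exact optimal vertex/face. This is what makes
  the nonlinear path reproduce LP objectives to ~1e-15.
* robustness: a multistart option with seeded perturbations; failed or
  suspicious results (an "optimum" that never left the start point, a
  known SLSQP failure mode) trigger a cross-check with the other method.

Convergence tolerance defaults to 1e-5 (1e-4 in variability runs). Statuses
are faithful: optimal, infeasible, iteration-limit and failed are distinct,
and `optimal` implies the reported residual is within tolerance.

## The toy C4 network

The fixture is a deliberately small single-cell base (~25 reactions) whose
two-cell assembly (~55 reactions) carries the motifs the analysis depends
on: PEPC → malate shuttle → NADP-ME (and optional PEPCK) decarboxylation,
Rubisco carboxylase/oxygenase, a photorespiratory pathway releasing exactly
0.5 CO2 per oxygenation, the 3-PGA/triose-phosphate shuttle, PPDK, sucrose
and glycine synthesis (both phloem-mobile), respiration, a glycolytic
GAPDH for heterotrophic tissue, an alternative-oxidase-style NADPH valve,
and biomass sinks in fixed-ratio or flexible form.

Stoichiometries were chosen so that every internal reaction conserves three
independent quantities — carbon, a water-equivalent, and degree of
reduction (electrons, with NADPH = 2e⁻ and O2 = −4e⁻) — in addition to the
adenylate and NADP moiety pools. This makes the network provably mass-leak
free, which `check_mass_leaks` verifies by LP (one solve per species and
direction, exchanges closed, light exempt).

Cell-type separation is strict NADP-ME type: Rubisco and photorespiration
only in the bundle sheath, PEPC, photosystem II (the O2-evolving light
reaction), the NADPH valve and glycine decarboxylase only in the mesophyll.
The exclusions are not cosmetic: an unconstrained bundle-sheath carboxylase,
O2-consuming valve, or glycine-fed CO2 source would let the optimizer
bypass the diffusive leak or the oxygen balance that the kinetic comparison
is about — the two-cell model must realize the same physics as the
enzyme-limited oracle for the Fig-2-style validation to be meaningful.

## The physiology oracle

`enzyme_limited_A` solves the steady-state enzyme-limited C4 system
(`v_p = min(MM, V_pr)`; mesophyll and bundle-sheath carbon balances;
competitive Rubisco laws; O2 balance with conductance `g_s,O` and a
configurable bundle-sheath O2-evolution fraction, default 0 for the
NADP-ME-like arrangement) by nested bracketed root finding (brentq in O2_BS
inside brentq in CO2_BS; both residuals are monotone, so bracketing is
robust, to |residual| ≤ 1e-9). It shares the kinetic-law expressions with
the constraint module but none of the optimization machinery, making it an
independent check: maximizing assimilation on the toy two-cell model
reproduces the oracle's A to ~1e-9 relative over the full capacity grids
(v_p,max ∈ {110…30} × mesophyll CO2 sweep; decarboxylase cap sweep at
v_c,max ∈ {70…30}; r_d = r_m = 0). In `maximize_assimilation` the vascular
exchanges are export-only (the mature-source comparison condition) and a
tiny quadratic flux penalty (1e-8) picks the minimal-norm optimum among
cost-free futile cycles; its effect on A is orders of magnitude below the
comparison resolution.

## Leaf assembly

Two-cell models use `ms_`/`bs_` prefixes; leaf models add `segNN_` prefixes,
one load/unload reaction per segment and phloem metabolite (positive =
segment → phloem), and a single shared phloem pool per metabolite with no
spatial resistance and no imposed transport direction. The phloem is closed
by default (no external exchange), so segment loads must sum to zero —
source segments can only export what sink segments import. Counting
formulas are exact: n segments give n·(two-cell compartments) + 1
compartments, n·(two-cell species) + |phloem metabolites| species, and
n·(two-cell reactions − replaced vascular exchanges) + n·|phloem
metabolites| reactions.

## The expression fit

* **Aggregation**: reaction data are the sum of the associated genes' FPKM
  (ignoring AND/OR structure — an evidence total); uncertainties are
  root-sum-square of gene sds, floored at 10% of max(d, 1) so zero-variance
  replicates cannot acquire infinite weight. The root-sum-square combination
  and the floor fraction are package choices; replicate structure in real
  data may justify others.
* **Directions**: reversible data-bearing reactions are split into
  nonnegative components in every segment and oriented by a preliminary fit
  with both components free. The preliminary fit minimizes the
  uncertainty-weighted L1 residual — the linear-programming analogue of the
  least-squares objective with identical weights — so the orientation step
  is a single exact global solve; when the two components cancel (a
  degenerate optimum the split objective cannot distinguish), the two
  one-sided restrictions are compared and the cheaper one wins, ties going
  forward.
* **Objective**: `F(v,s) = Σ(e^{s_i}v_ij − d_ij)²/δ_ij² + α·Σ s_i²` with
  α = 1, one `s_i` per reaction identity shared across cell types and
  segments, bounded to [−5, 5] (the lower bound mirrors a technical
  exp(−5) floor; the upper bound is its symmetric counterpart).
* **Warm start**: an alternating scheme — weighted-L1 LP projection of the
  fluxes onto the steady-state polytope (targets `e^{−s}d`), closed-form
  Newton update of each scale factor — run twice, then gas levels and
  capacities back-computed from the kinetic laws. This lands close enough
  to the optimum that the joint solve is cheap.
* **Joint solve**: dispatched on the warm-start residual. Near-consistent
  data (F at start ≤ 1) go to the active-set method, which certifies the
  generative optimum (F ~ 1e-20 at zero noise) in a handful of iterations.
  Noisy data produce a degenerate active set; the interior-point method
  converges in objective value long before its gradient certificate, so it
  runs under a capped iteration budget (400) and the returned status
  (`iteration-limit`, with feasibility residuals ~1e-6) reports exactly
  that. The reported F is always re-evaluated independently from (v, s).
* **Uniqueness regularizer**: a 1e-9 quadratic penalty on all fluxes is on
  by default — it gives the data-free degrees of freedom (futile cycles,
  parallel routes) a unique optimum and a positive-definite Hessian. Its
  bias on fitted fluxes is ~1e-6 flux units, well below every reported
  tolerance; it is excluded from the reported objective, and `FitConfig`
  can switch it off.
* **Rescue**: reactions with appreciable data but all-zero flux are
  re-solved from a perturbed start (temporary 0.01 lower bound on the
  largest-data segment, solve, release, re-solve) and the re-solve is
  accepted only if F strictly decreases; candidate count and per-solve
  iterations are capped (2 and 80) to bound runtime.
* **Activity constraints**: one linear row per enzyme and segment,
  `E_jk ≥ Σ group`, where groups may contain reaction fluxes or kinetic
  capacity variables (Rubisco and PEPC activities cap `v_c,max`/`v_p,max`).
* **E-Flux baseline**: |v| ≤ scale·d with one global scale, biological
  objective maximized by LP (no kinetic laws — it is the linear baseline).

## Synthetic gradient generator

The generator defines the study conditions: 15 segments, source-sink
transition at segment 6, tip capacities v_c,max = 50 and v_p,max = 110
μmol m⁻² s⁻¹ ramping linearly across the source region, sinks with zero C4
capacity, dim light (2 μmol m⁻² s⁻¹) and equal-share sucrose/glycine import
quotas, 20% multiplicative expression noise (truncated Gaussian, seeded),
true log scale factors ~N(0, 0.4²), and activity caps 15% above the true
per-segment requirement for Rubisco, PEPC and the decarboxylases. Source
segments maximize assimilation with a small forced glycine export (2% of
v_c,max); sink segments maximize biomass by exact LP. Phloem loads balance
by construction, and per-segment net CO2 exchange changes sign exactly at
the transition.

Because the objective value at the generative optimum equals α·Σ s*², the
noise-free consistency check (F ≤ 1e-3) runs with both noise channels off —
noise_cv = 0 and scale_spread = 0; the noisy recovery check keeps the
spread. Near-constant truth profiles (std below 1e-6 of their magnitude)
are excluded from profile-correlation summaries, since correlation is
undefined there (reactions with zero predicted flux take r = 0 by
convention in the diagnostics).

What passing these benchmarks shows: the machinery — aggregation,
orientation, the coupled nonlinear program, the diagnostics — recovers a
known generative state through realistic noise at desk scale. What it does
not show: real transcript-flux coupling (the generator assumes the fit's
own generative model), real gene multiplicity (tens of genes per reaction,
shared isozymes), or genome-scale problem conditioning (18780-reaction
whole-leaf programs).

## Variability bounds

`quasi_optimal_bounds` minimizes and maximizes each selected variable under
the original constraints plus an objective budget
`f* ± (fraction·|f*| + 1e-6)` — the absolute floor keeps the budget
meaningful when f* ≈ 0 — warm-started from the incumbent, which guarantees
the budget set is nonempty and the incumbent's value is always contained.
Linear programs use the exact LP path; per-variable solver failures are
recorded, not raised. Variables are selected rather than exhaustive; an
all-variable sweep on a genome-scale model is a long-running option, not a
test requirement.

## Known limitations

* Local optimality only: nonconvex programs may have better optima than the
  one found; the multistart and rescue machinery reduces but cannot remove
  this risk (the Fig-2-style cross-check is the evidence that the global
  optimum is found in the assimilation setting).
* The solver adapter sits on scipy; very large programs (≫10⁴ variables)
  would need an external interior-point solver behind the same contract.
* The toy network's lumped stoichiometry conserves carbon, water-equivalents
  and electrons but is not elementally balanced in H/O/P detail.
* Light-limited and transport-limited photosynthesis regimes, temperature
  dependence of kinetic constants and mesophyll conductance are out of
  scope throughout.
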