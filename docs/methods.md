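# Methods

## Model representation and sign convention

A `MetabolicModel` stores the sparse stoichiometry matrix S (m metabolites ×
n reactions), per-reaction bounds, and a three-way reaction classification:
internal, nutrient import (exchange), and sink. Boundary reactions are
identified structurally — exactly one nonzero stoichiometric entry — with id
prefixes (`SK_`, `sink_`, `DM_` vs. everything else) used only to separate
sinks from imports, so synthetic fixtures need not follow BiGG naming.

Internally every import is oriented so that **uptake is a nonnegative flux**
(0 ≤ v_i ≤ v_i^max); SBML/BiGG files use the opposite convention (uptake
negative through `EX_` reactions) and are re-oriented on read and translated
back on write. This keeps the optimization box nonnegative and makes the
medium semantics literal: the import upper bound *is* the supplied amount.
Sinks are likewise oriented to consume their metabolite, and are excluded
from the import set by construction so a production floor (positive sink
lower bound) can never be relaxed by the medium optimizer.

Provenance: the run manifest records a model checksum over the
canonicalized, sorted-id stoichiometry and bounds (with −0.0 folded into
0.0), so dialect round-trips do not change identity.

## Inner solver

Standard FBA is solved with HiGHS (`scipy.optimize.linprog`), feasibility
and optimality tolerances 1e-9. The returned vertex is whichever the solver
reports; alternate optima are possible and documented. Parsimonious FBA is
the usual two-stage LP: stage 2 minimizes Σ|v| via forward/backward flux
splitting subject to c′v ≥ (1 − tol)·opt — an inequality rather than an
equality, which is robust to round-off. Note the parsimonious optimum
legitimately sits *at* that floor whenever slack in the objective saves
total flux; tests account for this. Infeasible solves are propagated, never
silently zeroed. On fixtures with ≤ 6 reactions the solver is verified
against exhaustive basic-solution (vertex) enumeration to 1e-9 relative
error, and cross-checked against an independent cobrapy/GLPK solve.

## Medium model and unit conversions

Concentrations (mM) convert to flux bounds by multiplication with a factor
of 0.5 so that 20 mM glucose maps to the canonical 10 mmol gDW⁻¹ h⁻¹ uptake
cap. Dimensionally this factor reads as litres of medium supplied per gram
dry weight over a supply period (0.5 l per gDW per 24 h); the package
implements the numeric mapping (flux = concentration × factor) and leaves
the supply-period interpretation to this note, since the per-24-h reading
and the per-hour flux unit do not literally cancel. The calibration anchor
is the growth band ln 2 / t_d = 0.77–1.39 h⁻¹ implied by a 42 ± 12 min
doubling time.

Cost is z′u over the *supplied* decision-variable bounds only — it never
depends on the realized flux, so a medium is charged for what it offers,
not what the cell imports. Infeasible or failed inner solves score
f_growth = f_prod = 0 while the cost is still charged; the raw status is
kept in the dataset so the surrogate learns infeasible regions instead of
having them discarded.

Objective orientation for the surrogate: production and cost are min-max
scaled to [0, 1] over the *accumulated* dataset (recomputed every
iteration, not frozen at initialization) and cost is inverted (1 − scaled);
growth passes through unchanged when its observed range lies in [0, 1] and
is min-max scaled with a logged warning otherwise (toy-model growth rates
exceed 1 h⁻¹ by design, so the warning is routine there). A constant
objective column maps to 0.5 — the center of the unit box — to avoid biasing
the Chebyshev scalarization toward or away from a degenerate dimension.

## The outer loop

ParEGO-style batch Bayesian optimization:

* **Surrogate.** One independent Gaussian process per objective over
  unit-box compositions: constant mean, Matérn-5/2 kernel with per-dimension
  lengthscales, plus a small white-noise term; hyperparameters by marginal-
  likelihood maximization, refit from scratch each iteration (a warm-start
  flag exists but is off by default). Degenerate kernel matrices escalate
  jitter before failing.
* **Scalarization.** Augmented Chebyshev, min_j(w_j y_j) + ρ Σ_j(w_j y_j),
  with ρ = 0.05 by default and weights drawn uniformly from the probability
  simplex, independently per batch candidate.
* **Acquisition.** Log expected improvement of the scalarized posterior.
  Because the min of independent Gaussians is not Gaussian, EI is estimated
  with 64 fixed standard-normal draws (common random numbers), which keeps
  the surface smooth and deterministic. Maximization is multi-start
  quasi-Newton (L-BFGS-B, or SLSQP under constraints) from the best of a
  scrambled-Sobol screen, with batched forward-difference gradients; if all
  restarts fail the best raw sample is used and logged.
* **Batches.** Sequential greedy with Kriging-believer fantasies: each
  accepted candidate is appended to the GP data at its posterior mean with
  hyperparameters fixed. Cheaper than joint q-point optimization and
  order-deterministic for a fixed seed.
* **Constraints.** Linear equalities/inequalities among components are
  enforced in the acquisition optimizer and by least-squares projection of
  random initial points; violations are bounded by 1e-6 in unit coordinates.
  Nonlinear constraints can be layered as user-side predicates on proposals.
* **Randomness.** One master seed spawns named substreams (initialization,
  proposals/weights, acquisition, restart padding) via `SeedSequence`, so
  runs replay exactly and adding a feature cannot shift another stream.
* **Restarts.** Chained runs seed their initialization with the previous
  run's full Pareto set (no truncation when it exceeds `n_init`), padded
  with fresh random media.

Budget accounting is exact: every run evaluates n_init + n_iter × batch_size
media.

## Pareto analysis

Dominance is weak dominance with at least one strict improvement; duplicates
are mutually non-dominating and all retained. Perturbation sensitivity draws
isotropic Gaussians in box-normalized coordinates (σ as a fraction of the
box, default grid 0.01/0.05/0.1), clips to the box, re-evaluates, and
classifies each draw as *inward* (dominated by the existing front) or
*outside-envelope* (non-dominated against it) — a dominance-based reading of
"outside the solution envelope"; a geometric-envelope reading would be an
alternative. PCA of compositions centers and unit-scales components by
default (heterogeneous physical ranges); scaling is a flag. Dominated
hypervolume (reference at the oriented-objective origin, 2-d/3-d sweep
algorithms) is a repository diagnostic for front quality, not a quantity of
the underlying media-design method.

## Synthetic fixtures and what they do (not) show

The toy generator builds mass-balanced networks where import flux must equal
consumption, so growth has the closed form μ* = min_i u_i/a_i, and an
optional product branch obeys a_k μ + y p = u_k at the binding nutrient —
linear, piecewise structure that makes exhaustive grid enumeration and
vertex enumeration exact oracles. The standard fixture is a 2-nutrient
network with demands (1, 2), prices (1, 0.5) and a 4 × 4 flux box; the
benchmark workloads on it use a 61-point-per-axis oracle grid (~3.7k inner
LP solves), a scaled-down loop of 20 + 30 × 5 = 170 evaluations over 3
seeds, and 20 perturbations per front member over 5 seeds. These fixtures
exercise every code path, but they are low-dimensional, noiseless and
piecewise-linear: passing them shows the machinery is correct, not that a
13-component genome-scale campaign will converge in any given budget.
Genome-scale behavior (degenerate alternate optima, dense precursor
coupling, growth plateaus) is only probed through the optional downloaded
models.

## Defaults worth knowing

| parameter | default | unit | rationale |
|---|---|---|---|
| conversion factor | 0.5 | l gDW⁻¹ (per supply period) | glucose 20 mM ↦ flux cap 10 |
| oxygen cap | 20 | mmol gDW⁻¹ h⁻¹ | midpoint of observed E. coli uptake |
| sink floor | 1e-4 | mmol gDW⁻¹ h⁻¹ | forces nonzero lipopeptide export |
| ρ (Chebyshev) | 0.05 | — | standard mild augmentation |
| n_init / n_iter / batch | 50 / 100 / 15 | — | full-campaign scale |
| LP tolerances | 1e-9 | — | exactness vs. enumeration oracle |
| pFBA optimality tol | 1e-6 | fraction | avoids round-off infeasibility |
| GP kernel | Matérn-5/2 ARD + white noise | — | smooth but not over-smooth surrogate |
| gas prices | 0 | currency | stirring-supplied, configurable |

Case-study templates ship the published component lists (10 for the
wild-type E. coli M9 design; 13 with glutamine/arginine/asparagine
supplementation at 9.9/9.5/6.1 mM for the antibody strain; 12 for the
B. subtilis lipopeptide case, which drops chloride and sodium and adds iron,
protons, water and CO₂) with *placeholder prices and search boxes* — vendor
quotes and the exact acyl-ACP metabolite identifiers must be supplied by the
user, as these are model- and procurement-specific.

## Known limitations

* Plain FBA returns solver-dependent vertices under alternate optima; use
  pFBA for canonical flux vectors.
* The cost model is linear; bulk-pricing curves are only expressible through
  user-side constraint/objective hooks.
* No pH/buffering, osmolarity or solubility chemistry — constraints among
  components are the intended vehicle for such requirements.
* Grid oracles are capped at 4 decision variables; beyond that only the
  Bayesian path is available and has no exactness guarantee.
* FVA, flux sampling, dynamic FBA and GPU execution are out of scope.
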