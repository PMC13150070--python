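"""Synthetic toy metabolic networks with analytically known optima.

These fixtures stand in for published genome-scale reconstructions at desk
scale, so the whole stack — model I/O, the inner LP, the outer Bayesian loop
and the Pareto analyses — is testable without downloads.

The basic toy network has ``d`` nutrients, each with an import reaction
``IMP_i`` (uptake-positive, bound ``u_i``) feeding a pool metabolite ``X_i``,
and one biomass reaction consuming ``a_i`` units of each pool per unit
growth. Mass balance forces import flux to equal consumption, so the FBA
growth optimum has the closed form

    mu* = min_i u_i / a_i                       (limiting-nutrient law)

With an optional product branch consuming ``y`` units of the precursor
``X_k`` per unit product, flux conservation at the branch point gives

    a_k * mu + y * p = u_k     whenever nutrient k is limiting,

a linear growth-production trade-off used as the oracle front.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse

from .fba import FluxObjective, solve_fba
from .medium import MediumComponent, MediumSpec, ObjectiveVector, PriceTable, evaluate_objectives
from .model_io import DEFAULT_BOUND, MetabolicModel
from .pareto import ParetoFront, pareto_mask

__all__ = [
    "ToyGemSpec",
    "make_toy_gem",
    "toy_medium_spec",
    "make_redundant_pathway_model",
    "brute_force_pareto",
    "enumerate_vertices",
    "make_case_study_config",
]


@dataclass(frozen=True)
class ToyGemSpec:
    """Parameters of a synthetic toy network.

    ``pathway_yields`` are the per-nutrient biomass demands ``a_i`` (> 0);
    ``product_branch`` is an optional ``(nutrient_index, yield)`` pair adding
    a product pathway competing for that nutrient's pool.
    """

    n_nutrients: int = 2
    pathway_yields: tuple[float, ...] = (1.0, 2.0)
    product_branch: tuple[int, float] | None = None
    prices: tuple[float, ...] = (1.0, 1.0)
    box_upper: tuple[float, ...] = (10.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nutrients < 2:
            raise ValueError("need at least 2 nutrients")
        for name in ("pathway_yields", "prices", "box_upper"):
            vals = getattr(self, name)
            if len(vals) != self.n_nutrients:
                raise ValueError(f"{name} must have length n_nutrients")
        if any(a <= 0 for a in self.pathway_yields):
            raise ValueError("pathway yields must be positive")
        if self.product_branch is not None:
            k, y = self.product_branch
            if not (0 <= k < self.n_nutrients) or y <= 0:
                raise ValueError("invalid product branch")

    @classmethod
    def random(cls, n_nutrients: int, rng: np.random.Generator) -> "ToyGemSpec":
        return cls(
            n_nutrients=n_nutrients,
            pathway_yields=tuple(rng.uniform(0.5, 3.0, n_nutrients)),
            prices=tuple(rng.uniform(0.1, 2.0, n_nutrients)),
            box_upper=tuple(rng.uniform(2.0, 15.0, n_nutrients)),
        )


def make_toy_gem(
    spec: ToyGemSpec,
) -> tuple[MetabolicModel, Callable[[Sequence[float]], float]]:
    """Build the toy model and return it with its closed-form growth law.

    The returned callable maps uptake bounds ``u`` to the growth-only FBA
    optimum ``min_i u_i / a_i``.
    """
    d = spec.n_nutrients
    a = np.asarray(spec.pathway_yields, float)
    met_ids = [f"X{i}" for i in range(d)]
    rxn_ids = [f"IMP_X{i}" for i in range(d)] + ["GROWTH"]

    rows, cols, vals = [], [], []
    for i in range(d):
        rows.append(i), cols.append(i), vals.append(1.0)  # import produces X_i
        rows.append(i), cols.append(d), vals.append(-a[i])  # biomass consumes
    v_min = np.zeros(d + 1)
    v_max = np.concatenate([np.asarray(spec.box_upper, float), [DEFAULT_BOUND]])

    production = None
    if spec.product_branch is not None:
        k, y = spec.product_branch
        met_ids.append("PRODUCT")  # metabolite row index d
        j_prod = len(rxn_ids)
        rxn_ids.append("PROD")  # consumes y X_k, produces 1 PRODUCT
        rows += [k, d]
        cols += [j_prod, j_prod]
        vals += [-float(y), 1.0]
        j_sink = len(rxn_ids)
        rxn_ids.append("SK_PRODUCT")  # boundary drain for the product
        rows.append(d)
        cols.append(j_sink)
        vals.append(-1.0)
        v_min = np.concatenate([v_min, [0.0, 0.0]])
        v_max = np.concatenate([v_max, [DEFAULT_BOUND, DEFAULT_BOUND]])
        production = "PROD"

    S = sparse.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    model = MetabolicModel(
        metabolite_ids=tuple(met_ids),
        reaction_ids=tuple(rxn_ids),
        S=S,
        v_min=v_min,
        v_max=v_max,
        exchange_ids=frozenset(f"IMP_X{i}" for i in range(d)),
        sink_ids=frozenset({"SK_PRODUCT"} if production else ()),
        biomass_reaction="GROWTH",
        production_reaction=production,
    )

    def closed_form_growth(u: Sequence[float]) -> float:
        u = np.asarray(u, float)
        return float(np.min(u / a))

    return model, closed_form_growth


def toy_medium_spec(spec: ToyGemSpec) -> tuple[MediumSpec, PriceTable]:
    """Medium spec and price table matching a toy model (all decision vars)."""
    comps = tuple(
        MediumComponent(
            name=f"X{i}",
            reaction_id=f"IMP_X{i}",
            role="decision",
            box_upper=float(spec.box_upper[i]),
            unit="flux",
        )
        for i in range(spec.n_nutrients)
    )
    prices = PriceTable(prices={f"X{i}": float(spec.prices[i]) for i in range(spec.n_nutrients)})
    return MediumSpec(components=comps), prices


def make_redundant_pathway_model() -> MetabolicModel:
    """Two routes from substrate to biomass precursor: one direct reaction and
    a two-step detour. FBA may split flux arbitrarily; parsimonious FBA must
    route everything through the single-step path."""
    met_ids = ("A", "B", "C")
    rxn_ids = ("IMP_A", "DIRECT", "DETOUR1", "DETOUR2", "GROWTH")
    entries = {
        ("A", "IMP_A"): 1.0,
        ("A", "DIRECT"): -1.0,
        ("B", "DIRECT"): 1.0,
        ("A", "DETOUR1"): -1.0,
        ("C", "DETOUR1"): 1.0,
        ("C", "DETOUR2"): -1.0,
        ("B", "DETOUR2"): 1.0,
        ("B", "GROWTH"): -1.0,
    }
    rows = [met_ids.index(m) for m, _ in entries]
    cols = [rxn_ids.index(r) for _, r in entries]
    S = sparse.csc_matrix((list(entries.values()), (rows, cols)), shape=(3, 5))
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        v_min=np.zeros(5),
        v_max=np.array([10.0, DEFAULT_BOUND, DEFAULT_BOUND, DEFAULT_BOUND, DEFAULT_BOUND]),
        exchange_ids=frozenset({"IMP_A"}),
        sink_ids=frozenset(),
        biomass_reaction="GROWTH",
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_pareto(
    model: MetabolicModel,
    spec: MediumSpec,
    prices: PriceTable,
    fba_objective: FluxObjective,
    grid_per_dim: int = 21,
    objectives: Sequence[str] = ("growth", "cost"),
    solver: str = "fba",
) -> tuple[ParetoFront, np.ndarray, np.ndarray]:
    """Ground-truth front by exhaustive grid enumeration over the box.

    Inclusive endpoints, so the all-zero and all-max media are always
    evaluated. Only tractable for <= 4 decision variables. Returns the front
    plus the full grid (X, oriented Y) for diagnostics.
    """
    d = len(spec.decision_names)
    if d > 4:
        raise ValueError(
            "grid enumeration is limited to 4 decision variables; "
            "use the Bayesian loop for larger spaces"
        )
    from .medium import orient_objectives
    import pandas as pd

    box = spec.box_upper
    axes = [np.linspace(0.0, b, grid_per_dim) for b in box]
    X = np.array(list(itertools.product(*axes)))
    results = [
        evaluate_objectives(model, spec, x, prices, fba_objective, solver) for x in X
    ]
    Y_raw = pd.DataFrame(
        {
            "growth": [r.f_growth for r in results],
            "production": [r.f_prod for r in results],
            "cost": [r.f_cost for r in results],
        }
    )
    Y = orient_objectives(Y_raw, objectives)
    mask = pareto_mask(Y)
    idx = np.flatnonzero(mask)
    return (
        ParetoFront(member_indices=idx, Y_members=Y[idx], X_members=X[idx]),
        X,
        Y,
    )


def enumerate_vertices(model: MetabolicModel) -> np.ndarray:
    """All vertices of the flux polytope {S v = 0, v_min <= v <= v_max}.

    Basic-solution enumeration: fix every choice of n - rank(S) reactions at
    a lower or upper bound, solve the equality system for the rest, keep
    feasible solutions. Exponential — intended as an exact oracle for
    fixtures with at most ~6 reactions.
    """
    S = model.S.toarray()
    m, n = S.shape
    if n > 8:
        raise ValueError("vertex enumeration is an oracle for tiny fixtures only")
    rank = np.linalg.matrix_rank(S)
    n_fix = n - rank
    verts = []
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for choice in itertools.product((0, 1), repeat=n_fix):
            v = np.zeros(n)
            for j, c in zip(fixed, choice):
                v[j] = model.v_max[j] if c else model.v_min[j]
            if not np.all(np.isfinite(v[list(fixed)])):
                continue
            b = -S[:, list(fixed)] @ v[list(fixed)]
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.linalg.norm(A @ sol - b) > 1e-8:
                continue
            v[free] = sol
            if np.all(v >= model.v_min - 1e-9) and np.all(v <= model.v_max + 1e-9):
                verts.append(np.clip(v, model.v_min, model.v_max))
    if not verts:
        return np.empty((0, n))
    V = np.array(verts)
    # deduplicate
    V = np.unique(np.round(V, 9), axis=0)
    return V


# ---------------------------------------------------------------------------
# case-study configuration skeletons
# ---------------------------------------------------------------------------

_M9_COMPONENTS = [
    # (name, BiGG exchange id, baseline mM) — placeholder baselines except glucose
    ("ammonium", "EX_nh4_e", 18.7),
    ("calcium", "EX_ca2_e", 0.1),
    ("chloride", "EX_cl_e", 0.2),
    ("glucose", "EX_glc__D_e", 20.0),
    ("magnesium", "EX_mg2_e", 2.0),
    ("potassium", "EX_k_e", 22.0),
    ("phosphate", "EX_pi_e", 64.0),
    ("sodium", "EX_na1_e", 22.0),
    ("sulfate", "EX_so4_e", 2.0),
]

#: oxygen uptake cap, mmol gDW^-1 h^-1 — midpoint of observed E. coli range
OXYGEN_CAP = 20.0
#: glucose flux cap calibrated to wild-type growth
GLUCOSE_CAP = 10.0
#: minimum forced flux through lipopeptide sink reactions
SINK_FLOOR = 1e-4

#: placeholder per-component prices, NOT sourced from any vendor table
_PLACEHOLDER_PRICE = 1.0


def make_case_study_config(case: str) -> tuple[MediumSpec, PriceTable, dict]:
    """Editable configuration skeletons for the published case studies.

    ``case`` is ``ecoli_m9`` (10 decision variables: the M9 salts, glucose
    and oxygen), ``ecoli_antibody`` (those plus glutamine/arginine/asparagine
    supplementation at 9.9/9.5/6.1 mM baselines, 13 decision variables, FBA
    biomass:production 99:1) or ``bsubtilis_surfactin`` (13 decision
    variables excluding chloride and sodium but adding iron, protons, water
    and CO2; 95:5 ratio and a 1e-4 sink floor).

    Prices are uniform placeholders to be replaced with vendor quotes; metal
    ion / gas exchange identifiers follow BiGG naming and must be adapted to
    the actual model's namespace.
    """
    def comp(name, rid, baseline, box_mM):
        return MediumComponent(
            name=name, reaction_id=rid, role="decision",
            baseline_value=baseline, box_upper=box_mM, unit="mM",
        )

    oxygen = MediumComponent(
        name="oxygen", reaction_id="EX_o2_e", role="decision",
        baseline_value=OXYGEN_CAP, box_upper=OXYGEN_CAP, unit="flux",
    )

    extras: dict = {"sink_floor": SINK_FLOOR, "glucose_flux_cap": GLUCOSE_CAP}

    if case == "ecoli_m9":
        comps = [comp(n, r, b, 2 * b) for n, r, b in _M9_COMPONENTS] + [oxygen]
        extras["fba_ratio"] = (1.0, 0.0)
    elif case == "ecoli_antibody":
        amino = [
            ("glutamine", "EX_gln__L_e", 9.9),
            ("arginine", "EX_arg__L_e", 9.5),
            ("asparagine", "EX_asn__L_e", 6.1),
        ]
        comps = (
            [comp(n, r, b, 2 * b) for n, r, b in _M9_COMPONENTS]
            + [oxygen]
            + [comp(n, r, b, 2 * b) for n, r, b in amino]
        )
        extras["fba_ratio"] = (99.0, 1.0)
    elif case == "bsubtilis_surfactin":
        keep = [c for c in _M9_COMPONENTS if c[0] not in ("chloride", "sodium")]
        additional = [
            ("iron", "EX_fe3_e", 0.1),
            ("protons", "EX_h_e", 10.0),
            ("water", "EX_h2o_e", 100.0),
            ("co2", "EX_co2_e", 10.0),
        ]
        comps = [comp(n, r, b, 2 * b) for n, r, b in keep + additional] + [
            MediumComponent(
                name="oxygen", reaction_id="EX_cpd00007_e", role="decision",
                baseline_value=OXYGEN_CAP, box_upper=OXYGEN_CAP, unit="flux",
            )
        ]
        extras["fba_ratio"] = (95.0, 5.0)
    else:
        raise ValueError(f"unknown case {case!r}")

    spec = MediumSpec(components=tuple(comps))
    prices = PriceTable(
        prices={c.name: (0.0 if c.name == "oxygen" else _PLACEHOLDER_PRICE) for c in comps},
        currency="placeholder",
    )
    return spec, prices, extras
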