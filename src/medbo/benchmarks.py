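"""Self-contained validation experiments on the synthetic fixtures.

These are the package's reproducibility workloads: each builds its inputs
from :mod:`medbo.toys`, runs the method, and measures the result against an
independent oracle (grid enumeration, closed forms). They are deliberately
small — a 2-nutrient network, short loops — so a full pass stays in the
minutes range on one core.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .engine import OptimizationConfig, run
from .fba import make_combined_objective
from .medium import orient_objectives
from .model_io import write_samples
from .pareto import dominated_hypervolume, extract_front, perturb_pareto
from .toys import ToyGemSpec, brute_force_pareto, make_toy_gem, toy_medium_spec

__all__ = [
    "standard_toy",
    "oracle_recovery",
    "reproducibility",
    "front_sensitivity",
]

#: the reference 2-nutrient fixture: demands (1, 2), prices (1, 0.5), box 4x4
STANDARD_TOY = ToyGemSpec(
    n_nutrients=2,
    pathway_yields=(1.0, 2.0),
    prices=(1.0, 0.5),
    box_upper=(4.0, 4.0),
)


def standard_toy():
    """The reference toy problem: model, medium spec, prices, FBA objective."""
    model, closed_form = make_toy_gem(STANDARD_TOY)
    spec, prices = toy_medium_spec(STANDARD_TOY)
    objective = make_combined_objective(model, 1.0)
    return model, spec, prices, objective, closed_form


def oracle_recovery(
    seeds: Sequence[int] = (0, 1, 2),
    n_init: int = 20,
    n_iter: int = 30,
    batch_size: int = 5,
    grid_per_dim: int = 61,
) -> dict:
    """Fraction of the grid-oracle front's hypervolume a short loop recovers.

    The oracle is exhaustive enumeration over the 2-d box; both fronts are
    scored in the same oriented space (growth up, cost negated and shifted to
    the oracle's worst cost), reference point at the origin.
    """
    model, spec, prices, objective, _ = standard_toy()
    oracle_front, _, oracle_Y = brute_force_pareto(
        model, spec, prices, objective, grid_per_dim=grid_per_dim
    )
    shift = np.array([0.0, -oracle_Y[:, 1].min()])
    hv_oracle = dominated_hypervolume(oracle_front.Y_members + shift)

    fractions = []
    for seed in seeds:
        config = OptimizationConfig(
            n_init=n_init, n_iter=n_iter, batch_size=batch_size, seed=int(seed)
        )
        dataset = run(model, spec, prices, objective, ("growth", "cost"), config)
        Y = orient_objectives(dataset.Y_raw, dataset.objectives)
        fractions.append(dominated_hypervolume(Y + shift) / hv_oracle)
    return {
        "fractions": fractions,
        "median_fraction": float(np.median(fractions)),
        "hv_oracle": float(hv_oracle),
        "n_evaluations": n_init + n_iter * batch_size,
        "oracle_grid": grid_per_dim,
    }


def reproducibility(seed: int = 11, n_init: int = 8, n_iter: int = 3, batch_size: int = 2) -> dict:
    """Two identically seeded runs: byte-identical tables, exact budgets."""
    import tempfile
    from pathlib import Path

    model, spec, prices, objective, _ = standard_toy()
    config = OptimizationConfig(
        n_init=n_init, n_iter=n_iter, batch_size=batch_size, seed=seed
    )
    payloads = []
    budgets_ok = True
    for _ in range(2):
        dataset = run(model, spec, prices, objective, ("growth", "cost"), config)
        budgets_ok &= len(dataset) == n_init + n_iter * batch_size
        with tempfile.TemporaryDirectory() as td:
            paths = write_samples(dataset, extract_front(dataset), Path(td))
            payloads.append(paths["samples"].read_bytes())
    return {
        "byte_identical": payloads[0] == payloads[1],
        "budget_exact": bool(budgets_ok),
        "n_evaluations": n_init + n_iter * batch_size,
    }


def front_sensitivity(
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    sigmas: Sequence[float] = (0.01, 0.05, 0.1),
    n_per_center: int = 20,
    grid_per_dim: int = 21,
) -> dict:
    """Median inward fraction of Gaussian perturbations around the oracle front.

    Perturbations of Pareto-optimal media are mostly suboptimal — they project
    inward in objective space — and the inward fraction should grow with the
    perturbation scale.
    """
    model, spec, prices, objective, _ = standard_toy()
    front, _, _ = brute_force_pareto(
        model, spec, prices, objective, grid_per_dim=grid_per_dim
    )
    box = spec.box_upper

    import pandas as pd

    def evaluator(Xp: np.ndarray) -> np.ndarray:
        from .medium import evaluate_objectives

        rows = []
        for x in Xp:
            ov = evaluate_objectives(model, spec, x, prices, objective)
            rows.append({"growth": ov.f_growth, "cost": ov.f_cost})
        return orient_objectives(pd.DataFrame(rows), ("growth", "cost"))

    per_sigma: dict[float, list[float]] = {float(s): [] for s in sigmas}
    for seed in seeds:
        results = perturb_pareto(
            front, box, sigmas, n_per_center, evaluator, seed=int(seed)
        )
        for sigma in per_sigma:
            cls = np.concatenate(
                [r.classification for r in results if r.sigma == sigma]
            )
            per_sigma[sigma].append(float(np.mean(cls == "inward")))
    medians = {s: float(np.median(v)) for s, v in per_sigma.items()}
    return {
        "median_inward_fraction": medians,
        "per_seed": {s: v for s, v in per_sigma.items()},
        "front_size": len(front),
        "n_per_center": n_per_center,
    }
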