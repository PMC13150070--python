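"""Medium design space, unit conversions and the outer objective vector.

A growth medium is described in laboratory units (molar concentrations) but a
genome-scale model consumes flux bounds in mmol gDW^-1 h^-1. The bridge is a
linear conversion factor calibrated so that 20 mM glucose in M9 maps to the
canonical 10 mmol gDW^-1 h^-1 glucose uptake cap (factor 0.5, interpretable
as litres of medium supplied per gram dry weight per supply period).

The outer objectives for a candidate medium ``u`` (vector of import upper
bounds for the decision variables) are

* ``f_growth`` — biomass flux of the inner FBA solution, h^-1;
* ``f_prod``   — production-reaction flux of the inner solution;
* ``f_cost``   — ``z'u``, the priced sum of *supplied* bounds. Cost depends
  only on what the medium offers, never on what the cell actually imports.

Infeasible or failed inner solves score ``f_growth = f_prod = 0`` while the
cost is still charged, so the surrogate sees a strong penalty; the raw solver
status is retained alongside.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fba import FluxObjective, apply_medium, solve_fba, solve_pfba
from .model_io import MetabolicModel

__all__ = [
    "MediumComponent",
    "MediumSpec",
    "PriceTable",
    "ObjectiveVector",
    "concentration_to_flux",
    "flux_to_concentration",
    "doubling_time_to_growth",
    "medium_cost",
    "evaluate_objectives",
    "orient_objectives",
    "orient_and_normalize",
]

logger = logging.getLogger(__name__)

#: calibrated litres-per-gDW conversion factor (20 mM glucose -> flux cap 10)
DEFAULT_CONVERSION_FACTOR = 0.5

ROLES = ("decision", "fixed", "absent")


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def concentration_to_flux(
    concentration_mM: float, factor: float = DEFAULT_CONVERSION_FACTOR
) -> float:
    """Molar concentration (mM) -> import flux bound (mmol gDW^-1 h^-1)."""
    if concentration_mM < 0:
        raise ValueError(f"negative concentration {concentration_mM}")
    if factor <= 0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return concentration_mM * factor


def flux_to_concentration(
    flux: float, factor: float = DEFAULT_CONVERSION_FACTOR
) -> float:
    """Inverse of :func:`concentration_to_flux` (round-trip identity)."""
    if flux < 0:
        raise ValueError(f"negative flux {flux}")
    if factor <= 0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return flux / factor


def doubling_time_to_growth(doubling_time_min: float) -> float:
    """Doubling time in minutes -> exponential growth rate in h^-1.

    ``mu = ln 2 / t_d[h]``; e.g. 54 min -> 0.77 h^-1, 30 min -> 1.39 h^-1.
    """
    if doubling_time_min <= 0:
        raise ValueError(f"doubling time must be positive, got {doubling_time_min}")
    return math.log(2.0) / (doubling_time_min / 60.0)


# ---------------------------------------------------------------------------
# medium specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediumComponent:
    """One medium component and its mapping to an import reaction.

    ``role`` is ``decision`` (optimized within ``[0, box_upper]``), ``fixed``
    (held at ``baseline_value``) or ``absent`` (upper bound 0).
    ``unit`` is ``mM`` (converted via the MediumSpec conversion factor) or ``flux``
    (already mmol gDW^-1 h^-1).
    """

    name: str
    reaction_id: str
    role: str = "decision"
    baseline_value: float = 0.0
    box_upper: float = 0.0
    unit: str = "flux"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.unit not in ("mM", "flux"):
            raise ValueError(f"unit must be 'mM' or 'flux', got {self.unit!r}")
        if self.baseline_value < 0 or self.box_upper < 0:
            raise ValueError(f"negative value in component {self.name!r}")
        if self.role == "decision" and self.box_upper <= 0:
            raise ValueError(
                f"decision variable {self.name!r} needs a positive box_upper"
            )


@dataclass(frozen=True)
class MediumSpec:
    """The media design space: decision variables, search box, fixed parts."""

    components: tuple[MediumComponent, ...]
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names in medium spec")

    # -- views -------------------------------------------------------------
    @property
    def decision(self) -> tuple[MediumComponent, ...]:
        return tuple(c for c in self.components if c.role == "decision")

    @property
    def decision_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.decision)

    @property
    def box_upper(self) -> np.ndarray:
        """Per-decision-variable search upper limit, in flux units."""
        return np.array([self._to_flux(c, c.box_upper) for c in self.decision])

    def _to_flux(self, comp: MediumComponent, value: float) -> float:
        if comp.unit == "mM":
            return concentration_to_flux(value, self.conversion_factor)
        return float(value)

    def component(self, name: str) -> MediumComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"unknown component {name!r}")

    def validate_against(self, model: MetabolicModel) -> None:
        for c in self.components:
            if c.reaction_id not in model.exchange_ids:
                raise ValueError(
                    f"component {c.name!r}: {c.reaction_id!r} is not an import "
                    "reaction of the model"
                )

    def medium_bounds(self, decision_bounds: Sequence[float]) -> dict[str, float]:
        """Assemble the full import-bound map for one candidate medium.

        ``decision_bounds`` are flux-unit upper bounds ordered as
        ``decision_names``. Fixed components contribute their baseline value;
        absent components contribute 0.
        """
        decision_bounds = np.asarray(decision_bounds, float)
        dec = self.decision
        if decision_bounds.shape != (len(dec),):
            raise ValueError(
                f"expected {len(dec)} decision bounds, got {decision_bounds.shape}"
            )
        box = self.box_upper
        if np.any(decision_bounds < -1e-12) or np.any(decision_bounds > box + 1e-9):
            raise ValueError("candidate bounds outside [0, box_upper]")
        out: dict[str, float] = {}
        for c, b in zip(dec, decision_bounds):
            out[c.reaction_id] = float(np.clip(b, 0.0, None))
        for c in self.components:
            if c.role == "fixed":
                out[c.reaction_id] = self._to_flux(c, c.baseline_value)
            elif c.role == "absent":
                out[c.reaction_id] = 0.0
        return out

    def baseline_bounds(self) -> np.ndarray:
        """Baseline composition (e.g. M9) restricted to decision variables."""
        return np.array([self._to_flux(c, c.baseline_value) for c in self.decision])

    # -- serialization -----------------------------------------------------
    COLUMNS = ("component", "reaction_id", "role", "baseline_value", "box_upper", "unit")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.name, c.reaction_id, c.role, c.baseline_value, c.box_upper, c.unit)
                for c in self.components
            ],
            columns=list(self.COLUMNS),
        )

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, index=False, sep=sep)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, conversion_factor: float = DEFAULT_CONVERSION_FACTOR) -> "MediumSpec":
        comps = tuple(
            MediumComponent(
                name=str(r.component),
                reaction_id=str(r.reaction_id),
                role=str(r.role),
                baseline_value=float(r.baseline_value),
                box_upper=float(r.box_upper),
                unit=str(r.unit),
            )
            for r in df.itertuples()
        )
        return cls(components=comps, conversion_factor=conversion_factor)

    @classmethod
    def from_csv(cls, path: str | Path, conversion_factor: float = DEFAULT_CONVERSION_FACTOR, sep: str = ",") -> "MediumSpec":
        return cls.from_frame(pd.read_csv(path, sep=sep), conversion_factor)


@dataclass(frozen=True)
class PriceTable:
    """Per-component prices, currency per unit of supplied flux bound."""

    prices: Mapping[str, float]
    currency: str = "EUR"

    def __post_init__(self) -> None:
        for name, p in self.prices.items():
            if p < 0:
                raise ValueError(f"negative price for {name!r}")

    def vector(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.prices]
        if missing:
            raise KeyError(f"missing prices for components {missing!r}")
        return np.array([float(self.prices[n]) for n in names])

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        pd.DataFrame(
            {"component": list(self.prices), "price": list(self.prices.values()),
             "currency": self.currency}
        ).to_csv(path, index=False, sep=sep)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "PriceTable":
        df = pd.read_csv(path, sep=sep)
        currency = str(df["currency"].iloc[0]) if "currency" in df and len(df) else "EUR"
        return cls(
            prices={str(r.component): float(r.price) for r in df.itertuples()},
            currency=currency,
        )


@dataclass(frozen=True)
class ObjectiveVector:
    """Raw outer objectives for one candidate medium."""

    f_growth: float
    f_prod: float
    f_cost: float
    feasible: bool
    status: str = "optimal"


def medium_cost(bounds: Sequence[float], prices: np.ndarray) -> float:
    """Linear medium cost ``z' u`` of the supplied decision-variable bounds."""
    bounds = np.asarray(bounds, float)
    prices = np.asarray(prices, float)
    if bounds.shape != prices.shape:
        raise ValueError("bounds and prices must align")
    return float(prices @ bounds)


def evaluate_objectives(
    model: MetabolicModel,
    spec: MediumSpec,
    bounds: Sequence[float],
    prices: PriceTable,
    fba_objective: FluxObjective,
    solver: str = "fba",
) -> ObjectiveVector:
    """Apply a candidate medium, solve the inner problem, read the objectives.

    Deterministic for a fixed solver configuration; the input model is never
    mutated.
    """
    z = prices.vector(spec.decision_names)
    cost = medium_cost(bounds, z)
    constrained = apply_medium(model, spec.medium_bounds(bounds))
    if solver == "fba":
        sol = solve_fba(constrained, fba_objective)
    elif solver == "pfba":
        sol = solve_pfba(constrained, fba_objective)
    else:
        raise ValueError(f"unknown solver {solver!r}")

    if sol.status in ("infeasible", "optimal"):
        if sol.optimal:
            growth = sol.flux(constrained, model.biomass_reaction)
            prod = (
                sol.flux(constrained, model.production_reaction)
                if model.production_reaction is not None
                else 0.0
            )
            return ObjectiveVector(growth, prod, cost, feasible=True, status="optimal")
        return ObjectiveVector(0.0, 0.0, cost, feasible=False, status="infeasible")
    raise RuntimeError(
        f"inner LP {sol.status} for candidate bounds {np.asarray(bounds, float)!r}: "
        f"{sol.message}"
    )


# ---------------------------------------------------------------------------
# orientation and normalization of the outer objectives
# ---------------------------------------------------------------------------

OBJECTIVES = ("growth", "production", "cost")


def orient_objectives(Y_raw: pd.DataFrame, objectives: Sequence[str]) -> np.ndarray:
    """Raw objectives -> all-maximized orientation without rescaling.

    Growth and production pass through; cost is negated (cheaper is better).
    Used by grid oracles and Pareto extraction where normalization constants
    would be irrelevant monotone maps.
    """
    cols = []
    for name in objectives:
        y = Y_raw[name].to_numpy(float)
        cols.append(-y if name == "cost" else y)
    return np.column_stack(cols)


def orient_and_normalize(
    Y_raw: pd.DataFrame, objectives: Sequence[str]
) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Normalize raw objectives to the surrogate's all-maximized scale.

    Production and cost are min-max scaled to [0, 1] over the current dataset
    and cost is then inverted (``1 - scaled``). Growth passes through
    unchanged when its observed range already lies within [0, 1]; otherwise it
    is min-max scaled with a logged warning. A constant column maps to 0.5
    (center of the unit box) with a warning. Returns the oriented matrix and
    the ``(min, max)`` constants used per objective.
    """
    if len(Y_raw) < 1:
        raise ValueError("empty objective table")
    out = []
    constants: dict[str, tuple[float, float]] = {}
    for name in objectives:
        if name not in OBJECTIVES:
            raise ValueError(f"unknown objective {name!r}")
        y = Y_raw[name].to_numpy(float)
        lo, hi = float(np.min(y)), float(np.max(y))
        constants[name] = (lo, hi)
        if hi - lo < 1e-15:
            warnings.warn(
                f"objective {name!r} is constant over the dataset; mapped to 0.5",
                stacklevel=2,
            )
            col = np.full_like(y, 0.5)
        elif name == "growth":
            if lo >= 0.0 and hi <= 1.0:
                col = y
                constants[name] = (0.0, 1.0)
            else:
                logger.warning(
                    "growth range [%.3g, %.3g] outside [0, 1]; min-max scaling", lo, hi
                )
                col = (y - lo) / (hi - lo)
        elif name == "production":
            col = (y - lo) / (hi - lo)
        else:  # cost: scale then invert so larger = cheaper = better
            col = 1.0 - (y - lo) / (hi - lo)
        out.append(col)
    return np.column_stack(out), constants
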