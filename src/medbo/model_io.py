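"""Genome-scale model containers and file I/O.

A :class:`MetabolicModel` is an immutable stoichiometric snapshot: the sparse
stoichiometry matrix ``S`` (m metabolites x n reactions), per-reaction flux
bounds, and a classification of reactions into internal reactions, nutrient
import (exchange) reactions and sink reactions.

Sign convention
---------------
Internally every import reaction is oriented so that *uptake is a nonnegative
flux*: the reaction produces its metabolite into the network and its upper
bound encodes medium availability (``0 <= v_i <= v_i_max`` for imports).
SBML/BiGG files use the opposite convention (uptake as negative flux through
``EX_`` reactions); :func:`read_model` re-orients on read and
:func:`write_model` translates back, so round-trips through either dialect are
identity on ``(S, bounds, index sets)``.

File parsing and serialization are delegated to :mod:`cobra.io`; this module
owns only the conversion between the cobrapy object model and the package's
uptake-positive representation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "MetabolicModel",
    "ReactionRecipe",
    "read_model",
    "write_model",
    "add_production_reaction",
    "drop_reaction",
    "add_sink",
    "model_checksum",
    "write_samples",
    "read_samples",
]

#: bound used for "effectively unconstrained" reactions, matching the COBRA default
DEFAULT_BOUND = 1000.0

_EXCHANGE_PREFIXES = ("EX_", "R_EX_")
_SINK_PREFIXES = ("SK_", "sink_", "DM_")


class ModelError(ValueError):
    """Raised for structurally invalid models or model edits."""


@dataclass(frozen=True)
class ReactionRecipe:
    """A reaction to graft onto a model, e.g. a heterologous production step.

    ``stoichiometry`` maps metabolite id to signed coefficient (negative =
    consumed). Bounds are in mmol gDW^-1 h^-1.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"recipe {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"recipe {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


@dataclass(frozen=True)
class MetabolicModel:
    """Stoichiometric model with uptake-positive exchange orientation."""

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: sparse.csc_matrix
    v_min: np.ndarray
    v_max: np.ndarray
    exchange_ids: frozenset[str]
    sink_ids: frozenset[str]
    biomass_reaction: str
    production_reaction: str | None = None
    metabolite_formulas: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m, n = self.S.shape
        if m != len(self.metabolite_ids) or n != len(self.reaction_ids):
            raise ModelError("S shape disagrees with id lists")
        if np.any(self.v_min > self.v_max + 1e-12):
            bad = self.reaction_ids[int(np.argmax(self.v_min > self.v_max))]
            raise ModelError(f"v_min > v_max for reaction {bad!r}")
        if self.biomass_reaction not in self.reaction_ids:
            raise ModelError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )
        if self.exchange_ids & self.sink_ids:
            raise ModelError("a reaction cannot be both exchange and sink")
        nnz_per_col = np.diff(self.S.tocsc().indptr)
        for rid in self.exchange_ids | self.sink_ids:
            if nnz_per_col[self.reaction_index(rid)] != 1:
                raise ModelError(
                    f"boundary reaction {rid!r} must have exactly one "
                    "stoichiometric entry"
                )

    # -- index helpers -----------------------------------------------------
    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    def metabolite_index(self, mid: str) -> int:
        try:
            return self.metabolite_ids.index(mid)
        except ValueError:
            raise KeyError(f"unknown metabolite {mid!r}") from None

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def I_ext(self) -> np.ndarray:
        """Indices of nutrient-import reactions (sorted)."""
        return np.array(
            sorted(self.reaction_index(r) for r in self.exchange_ids), dtype=int
        )

    @property
    def I_sink(self) -> np.ndarray:
        return np.array(
            sorted(self.reaction_index(r) for r in self.sink_ids), dtype=int
        )

    @property
    def I_int(self) -> np.ndarray:
        """Indices of internal reactions: everything that is not a boundary."""
        boundary = self.exchange_ids | self.sink_ids
        return np.array(
            [i for i, r in enumerate(self.reaction_ids) if r not in boundary],
            dtype=int,
        )

    def with_bounds(self, v_min: np.ndarray, v_max: np.ndarray) -> "MetabolicModel":
        return replace(self, v_min=np.asarray(v_min, float), v_max=np.asarray(v_max, float))


# ---------------------------------------------------------------------------
# cobrapy conversion
# ---------------------------------------------------------------------------

def _is_boundary_column(S: sparse.csc_matrix, j: int) -> bool:
    return S.indptr[j + 1] - S.indptr[j] == 1


def _from_cobra(cmodel, biomass_reaction: str | None = None) -> MetabolicModel:
    import cobra  # local import keeps module import light

    met_ids = tuple(m.id for m in cmodel.metabolites)
    rxn_ids = tuple(r.id for r in cmodel.reactions)
    met_pos = {m: i for i, m in enumerate(met_ids)}

    rows, cols, vals = [], [], []
    v_min = np.zeros(len(rxn_ids))
    v_max = np.zeros(len(rxn_ids))
    for j, rxn in enumerate(cmodel.reactions):
        v_min[j], v_max[j] = rxn.lower_bound, rxn.upper_bound
        for met, coef in rxn.metabolites.items():
            rows.append(met_pos[met.id])
            cols.append(j)
            vals.append(float(coef))
    S = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )

    exchange, sinks = set(), set()
    for j, rid in enumerate(rxn_ids):
        if not _is_boundary_column(S, j):
            continue
        if rid.startswith(_SINK_PREFIXES):
            sinks.add(rid)
        else:
            exchange.add(rid)

    # re-orient boundary reactions so uptake (production into the network)
    # is a nonnegative flux and sinks consume their metabolite
    flip = []
    for rid in exchange:
        j = rxn_ids.index(rid)
        coef = S.data[S.indptr[j]]
        if coef < 0:  # file convention: metabolite consumed, uptake negative
            flip.append(j)
    for rid in sinks:
        j = rxn_ids.index(rid)
        coef = S.data[S.indptr[j]]
        if coef > 0:  # internal convention: sinks consume (negative entry)
            flip.append(j)
    if flip:
        S = S.tolil()
        for j in flip:
            S[:, j] = -S[:, j]
            v_min[j], v_max[j] = -v_max[j], -v_min[j]
        S = S.tocsc()
    v_min = v_min + 0.0  # normalize any -0.0 introduced by flips
    v_max = v_max + 0.0

    if biomass_reaction is None:
        biomass_reaction = _guess_biomass(cmodel)
    formulas = {
        m.id: m.formula for m in cmodel.metabolites if getattr(m, "formula", None)
    }
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        v_min=v_min,
        v_max=v_max,
        exchange_ids=frozenset(exchange),
        sink_ids=frozenset(sinks),
        biomass_reaction=biomass_reaction,
        metabolite_formulas=formulas,
    )


def _guess_biomass(cmodel) -> str:
    # objective coefficients first, then name heuristics
    from cobra.util.solver import linear_reaction_coefficients

    coefs = linear_reaction_coefficients(cmodel)
    if coefs:
        return max(coefs, key=lambda r: abs(coefs[r])).id
    for rxn in cmodel.reactions:
        if "biomass" in rxn.id.lower() or "growth" in rxn.id.lower():
            return rxn.id
    raise ModelError(
        "model declares no objective and no biomass-like reaction id; "
        "pass biomass_reaction= explicitly"
    )


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model("medbo_model")
    mets = {
        mid: cobra.Metabolite(mid, formula=model.metabolite_formulas.get(mid))
        for mid in model.metabolite_ids
    }
    # BiGG JSON requires a compartment for every metabolite
    for met in mets.values():
        met.compartment = "c"
    S = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        lo, hi = float(model.v_min[j]), float(model.v_max[j])
        stoich = {
            mets[model.metabolite_ids[S.indices[k]]]: float(S.data[k])
            for k in range(S.indptr[j], S.indptr[j + 1])
        }
        if rid in model.exchange_ids:
            # back to file convention: uptake negative
            stoich = {m: -c for m, c in stoich.items()}
            lo, hi = -float(model.v_max[j]), -float(model.v_min[j])
        elif rid in model.sink_ids:
            stoich = {m: -c for m, c in stoich.items()}
            lo, hi = -float(model.v_max[j]), -float(model.v_min[j])
        rxn.add_metabolites(stoich)
        rxn.bounds = (lo, hi)
        reactions.append(rxn)
    cmodel.add_reactions(reactions)
    cmodel.objective = model.biomass_reaction
    return cmodel


def read_model(
    path: str | Path,
    dialect: str = "bigg-json",
    biomass_reaction: str | None = None,
) -> MetabolicModel:
    """Read a genome-scale model from SBML or BiGG-style JSON.

    Exchange reactions are identified structurally (single nonzero
    stoichiometric entry), with id prefixes (``EX_``, ``SK_`` ...) used only
    to separate sinks from imports. Imports are re-oriented uptake-positive.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if dialect == "sbml":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmodel = cobra.io.read_sbml_model(str(path))
        elif dialect == "bigg-json":
            cmodel = cobra.io.load_json_model(str(path))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except (ValueError, KeyError, OSError) as exc:
        if isinstance(exc, ValueError) and "dialect" in str(exc):
            raise
        raise ModelError(f"cannot parse {path} as {dialect}: {exc}") from exc
    return _from_cobra(cmodel, biomass_reaction=biomass_reaction)


def write_model(model: MetabolicModel, path: str | Path, dialect: str = "bigg-json") -> None:
    """Serialize a model in the file convention (uptake-negative exchanges)."""
    import cobra.io

    path = Path(path)
    cmodel = _to_cobra(model)
    if dialect == "sbml":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(cmodel, str(path))
    elif dialect == "bigg-json":
        cobra.io.save_json_model(cmodel, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# model edits
# ---------------------------------------------------------------------------

_ELEMENT_RE = None


def _parse_formula(formula: str) -> dict[str, int]:
    global _ELEMENT_RE
    import re

    if _ELEMENT_RE is None:
        _ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
    out: dict[str, int] = {}
    for el, count in _ELEMENT_RE.findall(formula):
        if el:
            out[el] = out.get(el, 0) + int(count or 1)
    return out


def add_production_reaction(
    model: MetabolicModel,
    recipe: ReactionRecipe,
    create_missing: bool = False,
    set_as_production: bool = True,
) -> MetabolicModel:
    """Append a production reaction column to ``S``.

    Pre-existing columns are untouched. When elemental formulas are known for
    every participating metabolite the elemental balance of the new reaction
    is checked and imbalances reported as a warning; otherwise the check is
    skipped with a warning.
    """
    if recipe.id in model.reaction_ids:
        raise ModelError(f"duplicate reaction id {recipe.id!r}")
    missing = [m for m in recipe.stoichiometry if m not in model.metabolite_ids]
    if missing and not create_missing:
        raise ModelError(
            f"unknown metabolites {missing!r}; pass create_missing=True to add them"
        )
    met_ids = model.metabolite_ids + tuple(missing)
    met_pos = {m: i for i, m in enumerate(met_ids)}

    S_old = model.S.tocoo()
    rows = list(S_old.row)
    cols = list(S_old.col)
    vals = list(S_old.data)
    j_new = model.n_reactions
    for met, coef in recipe.stoichiometry.items():
        rows.append(met_pos[met])
        cols.append(j_new)
        vals.append(float(coef))
    S = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), j_new + 1)
    )

    known = model.metabolite_formulas
    if all(m in known for m in recipe.stoichiometry):
        balance: dict[str, float] = {}
        for met, coef in recipe.stoichiometry.items():
            for el, cnt in _parse_formula(known[met]).items():
                balance[el] = balance.get(el, 0.0) + coef * cnt
        imbalanced = {el: b for el, b in balance.items() if abs(b) > 1e-6}
        if imbalanced:
            warnings.warn(
                f"reaction {recipe.id!r} is elementally imbalanced: {imbalanced}",
                stacklevel=2,
            )
    else:
        warnings.warn(
            f"mass balance of {recipe.id!r} not checked: formulas unavailable",
            stacklevel=2,
        )

    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=model.reaction_ids + (recipe.id,),
        S=S,
        v_min=np.append(model.v_min, recipe.lower_bound),
        v_max=np.append(model.v_max, recipe.upper_bound),
        exchange_ids=model.exchange_ids,
        sink_ids=model.sink_ids,
        biomass_reaction=model.biomass_reaction,
        production_reaction=recipe.id if set_as_production else model.production_reaction,
        metabolite_formulas=model.metabolite_formulas,
    )


def drop_reaction(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Remove a reaction column (inverse of an add); orphan metabolites kept
    only if they participate elsewhere."""
    j = model.reaction_index(reaction_id)
    keep = [k for k in range(model.n_reactions) if k != j]
    S = model.S.tocsc()[:, keep]
    used = np.asarray((S != 0).sum(axis=1)).ravel() > 0
    # keep metabolites used by remaining reactions, preserving original order
    keep_mets = [i for i in range(model.n_metabolites) if used[i]]
    S = S.tocsr()[keep_mets, :].tocsc()
    met_ids = tuple(model.metabolite_ids[i] for i in keep_mets)
    rxn_ids = tuple(model.reaction_ids[k] for k in keep)
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        v_min=model.v_min[keep],
        v_max=model.v_max[keep],
        exchange_ids=model.exchange_ids - {reaction_id},
        sink_ids=model.sink_ids - {reaction_id},
        biomass_reaction=model.biomass_reaction,
        production_reaction=(
            None if model.production_reaction == reaction_id else model.production_reaction
        ),
        metabolite_formulas=model.metabolite_formulas,
    )


def add_sink(
    model: MetabolicModel, metabolite: str, lower_bound: float = 0.0
) -> MetabolicModel:
    """Append a sink (boundary drain) for ``metabolite``.

    A positive lower bound forces a minimum flux through the sink, e.g. the
    production floor used for lipopeptide sinks. Sinks are never medium
    decision variables: they are excluded from the import set by construction.
    """
    sink_id = f"SK_{metabolite}"
    if sink_id in model.reaction_ids:
        raise ModelError(f"sink for {metabolite!r} already present")
    i = model.metabolite_index(metabolite)

    S_old = model.S.tocoo()
    j_new = model.n_reactions
    S = sparse.csc_matrix(
        (
            list(S_old.data) + [-1.0],
            (list(S_old.row) + [i], list(S_old.col) + [j_new]),
        ),
        shape=(model.n_metabolites, j_new + 1),
    )
    return MetabolicModel(
        metabolite_ids=model.metabolite_ids,
        reaction_ids=model.reaction_ids + (sink_id,),
        S=S,
        v_min=np.append(model.v_min, float(lower_bound)),
        v_max=np.append(model.v_max, DEFAULT_BOUND),
        exchange_ids=model.exchange_ids,
        sink_ids=model.sink_ids | {sink_id},
        biomass_reaction=model.biomass_reaction,
        production_reaction=model.production_reaction,
        metabolite_formulas=model.metabolite_formulas,
    )


# ---------------------------------------------------------------------------
# provenance and run artifacts
# ---------------------------------------------------------------------------

def model_checksum(model: MetabolicModel) -> str:
    """Hash of the canonicalized (sorted-id) stoichiometry and bounds.

    Dialect round-trips and column reorderings leave the checksum unchanged.
    """
    h = hashlib.sha256()
    order = np.argsort(np.array(model.reaction_ids))
    met_order = {m: i for i, m in enumerate(sorted(model.metabolite_ids))}
    S = model.S.tocsc()
    for j in order:
        rid = model.reaction_ids[j]
        entries = sorted(
            (met_order[model.metabolite_ids[S.indices[k]]], round(float(S.data[k]), 9) + 0.0)
            for k in range(S.indptr[j], S.indptr[j + 1])
        )
        h.update(
            json.dumps(
                [
                    rid,
                    round(float(model.v_min[j]), 9) + 0.0,  # +0.0 folds -0.0 into 0.0
                    round(float(model.v_max[j]), 9) + 0.0,
                    entries,
                ]
            ).encode()
        )
    return h.hexdigest()


def write_samples(dataset, front, out_dir: str | Path, manifest_extra: dict | None = None) -> dict[str, Path]:
    """Write the run artifacts: samples table, front table, JSON manifest.

    Column order is fixed: iteration, one raw-bound column per decision
    variable, raw objectives, oriented (normalized) objectives, feasibility
    flag and Pareto flag.
    """
    from .pareto import pareto_mask

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(dataset) == 0:
        raise ValueError("dataset is empty")

    samples = dataset.to_frame()
    mask = np.zeros(len(dataset), dtype=bool)
    mask[np.asarray(front.member_indices, dtype=int)] = True
    samples["pareto"] = mask
    samples_path = out_dir / "samples.csv"
    samples.to_csv(samples_path, index=False)

    front_path = out_dir / "front.csv"
    samples.loc[mask].to_csv(front_path, index=False)

    manifest = {
        "n_samples": int(len(dataset)),
        "objectives": list(dataset.objectives),
        "components": list(dataset.component_names),
        "box_upper": [float(b) for b in dataset.box_upper],
        "n_front": int(mask.sum()),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return {"samples": samples_path, "front": front_path, "manifest": manifest_path}


def read_samples(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the samples/front CSV tables."""
    return pd.read_csv(path)
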