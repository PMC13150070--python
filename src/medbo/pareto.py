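"""Pareto-front extraction and downstream analyses.

Dominance is weak dominance with at least one strict improvement: row ``a``
dominates row ``b`` iff ``a >= b`` component-wise and ``a > b`` somewhere.
All objectives must be oriented for maximization before calling into this
module (cost negated or inverted upstream). Duplicate rows are mutually
non-dominating and are all retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "ParetoFront",
    "PerturbationResult",
    "pareto_mask",
    "extract_front",
    "best_ratio_trace",
    "filter_low_growth",
    "pca_media",
    "component_distributions",
    "perturb_pareto",
    "dominated_hypervolume",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParetoFront:
    """Non-dominated subset of a sample dataset."""

    member_indices: np.ndarray
    Y_members: np.ndarray  # oriented objective values
    X_members: np.ndarray  # raw compositions

    def __len__(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class PerturbationResult:
    """Gaussian perturbations around one front member at one noise scale."""

    center_index: int
    sigma: float
    perturbed_X: np.ndarray
    perturbed_Y: np.ndarray
    classification: np.ndarray  # "inward" | "outside-envelope" per sample

    @property
    def inward_fraction(self) -> float:
        if len(self.classification) == 0:
            return np.nan
        return float(np.mean(self.classification == "inward"))


def pareto_mask(Y: np.ndarray) -> np.ndarray:
    """Boolean mask of non-dominated rows of an all-maximized matrix.

    Vectorized pairwise comparison in blocks; O(n^2) worst case but cheap for
    the dataset sizes a run produces.
    """
    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("Y must be a non-empty 2-d matrix")
    n = Y.shape[0]
    mask = np.ones(n, dtype=bool)
    # a dominates b: all(a >= b) and any(a > b)
    for i in range(n):
        if not mask[i]:
            continue
        ge = np.all(Y >= Y[i], axis=1)
        gt = np.any(Y > Y[i], axis=1)
        if np.any(ge & gt):
            mask[i] = False
    return mask


def extract_front(dataset) -> ParetoFront:
    """Non-dominated subset of a :class:`~medbo.engine.SampleDataset`.

    Orientation uses the raw objectives with cost negated (no normalization:
    min-max maps are monotone, so the front is the same either way).
    """
    from .medium import orient_objectives

    oriented = orient_objectives(dataset.Y_raw, dataset.objectives)
    mask = pareto_mask(oriented)
    idx = np.flatnonzero(mask)
    return ParetoFront(
        member_indices=idx,
        Y_members=oriented[idx],
        X_members=dataset.X_raw[idx],
    )


def best_ratio_trace(
    numerator: Sequence[float], denominator: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample objective ratio and its running maximum in evaluation order.

    Samples with a non-positive denominator (e.g. zero-cost media) are
    excluded with a log note. Returns (kept indices, ratios, running max).
    """
    num = np.asarray(numerator, float)
    den = np.asarray(denominator, float)
    keep = den > 0
    if not np.any(keep):
        raise ValueError("all denominator values are zero or negative")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("best_ratio_trace: excluded %d samples with denominator <= 0", n_dropped)
    idx = np.flatnonzero(keep)
    ratio = num[keep] / den[keep]
    return idx, ratio, np.maximum.accumulate(ratio)


def filter_low_growth(dataset, threshold: float = 0.001) -> np.ndarray:
    """Indices of samples with predicted growth >= threshold (h^-1).

    A plot-only view: the underlying dataset is untouched. The conventional
    cut of 0.001 h^-1 removes effectively non-growing media from figures.
    """
    growth = dataset.Y_raw["growth"].to_numpy(float)
    return np.flatnonzero(growth >= threshold)


def pca_media(
    X: np.ndarray, scale: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of medium compositions: (scores, loadings, explained fractions).

    Columns are centered and, by default, unit-scaled (components live on
    heterogeneous physical ranges). Constant columns make scaling degenerate
    and raise, naming the offenders.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 components")
    sd = X.std(axis=0)
    if np.any(sd < 1e-15):
        dead = np.flatnonzero(sd < 1e-15).tolist()
        raise ValueError(f"constant composition columns at indices {dead}")
    Z = X - X.mean(axis=0)
    if scale:
        Z = Z / sd
    p = PCA(n_components=min(Z.shape), svd_solver="full")
    scores = p.fit_transform(Z)
    return scores, p.components_, p.explained_variance_ratio_


def component_distributions(
    front: ParetoFront,
    component_names: Sequence[str],
    box_upper: np.ndarray,
    tight_iqr_fraction: float = 0.1,
) -> pd.DataFrame:
    """Five-number summary of box-normalized Pareto compositions per component.

    Flags "tight" components whose interquartile range is below
    ``tight_iqr_fraction`` of the box — the nutrients a front pins down (the
    way glucose and oxygen concentrate in optimized media).
    """
    if len(front) == 0:
        raise ValueError("empty front")
    Xn = front.X_members / np.asarray(box_upper, float)
    q = np.quantile(Xn, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)
    df = pd.DataFrame(
        {
            "component": list(component_names),
            "min": q[0],
            "q1": q[1],
            "median": q[2],
            "q3": q[3],
            "max": q[4],
        }
    )
    df["iqr"] = df["q3"] - df["q1"]
    df["tight"] = df["iqr"] < tight_iqr_fraction
    return df


def perturb_pareto(
    front: ParetoFront,
    box_upper: np.ndarray,
    sigmas: Sequence[float],
    n_per_center: int,
    evaluator: Callable[[np.ndarray], np.ndarray],
    seed: int = 0,
) -> list[PerturbationResult]:
    """Gaussian sensitivity analysis around each front member.

    For each member and noise scale, draws isotropic normal perturbations in
    box-normalized coordinates, clips to the box, evaluates the oriented
    objectives via ``evaluator`` (maps raw compositions (n, d) -> oriented
    objectives (n, k)), and classifies each draw as ``inward`` (dominated by
    the existing front) or ``outside-envelope`` (non-dominated against it).
    """
    if len(front) == 0:
        raise ValueError("empty front")
    sigmas = [float(s) for s in sigmas]
    if any(s <= 0 for s in sigmas):
        raise ValueError("sigmas must be positive")
    box = np.asarray(box_upper, float)
    rng = np.random.default_rng(seed)
    out: list[PerturbationResult] = []
    for sigma in sigmas:
        for c, center in enumerate(front.X_members):
            center_unit = center / box
            Z = rng.standard_normal((n_per_center, box.size))
            Xu = np.clip(center_unit + sigma * Z, 0.0, 1.0)
            Xp = Xu * box
            if n_per_center == 0:
                Yp = np.empty((0, front.Y_members.shape[1]))
            else:
                Yp = np.asarray(evaluator(Xp), float)
            cls = np.array(
                [
                    "inward" if _dominated_by(y, front.Y_members) else "outside-envelope"
                    for y in Yp
                ],
                dtype=object,
            )
            out.append(
                PerturbationResult(
                    center_index=int(front.member_indices[c]),
                    sigma=sigma,
                    perturbed_X=Xp,
                    perturbed_Y=Yp,
                    classification=cls,
                )
            )
    return out


def _dominated_by(y: np.ndarray, front_Y: np.ndarray) -> bool:
    ge = np.all(front_Y >= y, axis=1)
    gt = np.any(front_Y > y, axis=1)
    return bool(np.any(ge & gt))


def dominated_hypervolume(Y: np.ndarray, ref: np.ndarray | None = None) -> float:
    """Hypervolume dominated by a point set, maximization, 2-d or 3-d.

    Reference point defaults to the origin of the oriented objective space;
    coordinates below the reference are clipped. A repo diagnostic for front
    quality, not a quantity of the underlying media-design method.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    k = Y.shape[1]
    ref = np.zeros(k) if ref is None else np.asarray(ref, float)
    P = np.maximum(Y - ref, 0.0)
    P = P[np.any(P > 0, axis=1)]
    if P.shape[0] == 0:
        return 0.0
    if k == 2:
        return _hv2(P)
    if k == 3:
        return _hv3(P)
    raise ValueError("hypervolume implemented for 2 or 3 objectives")


def _hv2(P: np.ndarray) -> float:
    # sweep in decreasing first coordinate, accumulating new strips
    P = P[np.lexsort((-P[:, 1], -P[:, 0]))]
    hv, best_y = 0.0, 0.0
    for x, y in P:
        if y > best_y:
            hv += x * (y - best_y)
            best_y = y
    return hv


def _hv3(P: np.ndarray) -> float:
    # slice along the third coordinate
    zs = np.unique(P[:, 2])[::-1]
    hv = 0.0
    for i in range(len(zs)):
        upper = zs[i]
        lower = zs[i + 1] if i + 1 < len(zs) else 0.0
        layer = P[P[:, 2] >= upper][:, :2]
        hv += _hv2(layer) * (upper - lower)
    return hv
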