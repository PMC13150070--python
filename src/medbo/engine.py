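"""Outer multiobjective Bayesian-optimization loop.

The medium-design problem is bi-level: an outer optimizer tunes import-flux
upper bounds inside a box, each candidate scored by the inner FBA solve. The
outer loop here is a ParEGO-style batch Bayesian optimizer:

1. initialize with random media, evaluate the outer objectives;
2. each iteration: re-normalize the accumulated objectives, fit one Gaussian
   process per objective on the unit-box compositions (Matern-5/2, per-
   dimension lengthscales, constant mean), then build a batch of ``q``
   candidates — each with a fresh random simplex weight vector, scoring
   points by log expected improvement of the augmented Chebyshev
   scalarization of the GP posterior, maximized over the unit box by
   multi-start quasi-Newton from a Sobol screen;
3. evaluate the batch with the inner solver, append, repeat.

Batch candidates are conditioned sequentially (Kriging-believer fantasies:
each accepted candidate is added to the GP data at its posterior mean with
hyperparameters held fixed), so batches are diverse and order-deterministic.

Randomness discipline: one master seed spawns named substreams
(initialization, scalarization weights, acquisition) via
``numpy.random.SeedSequence``, so runs are exactly reproducible and adding a
feature cannot silently shift another stream.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .fba import FluxObjective
from .medium import (
    MediumSpec,
    ObjectiveVector,
    PriceTable,
    evaluate_objectives,
    orient_and_normalize,
)
from .model_io import MetabolicModel

__all__ = [
    "LinearConstraint",
    "OptimizationConfig",
    "SampleDataset",
    "SurrogateModel",
    "chebyshev_scalarize",
    "init_random_media",
    "fit_surrogate",
    "propose_batch",
    "run",
    "restart_from_pareto",
]

logger = logging.getLogger(__name__)

_CONSTRAINT_TOL = 1e-6
_N_MC = 64  # quasi-MC draws for the scalarized-posterior acquisition


@dataclass(frozen=True)
class LinearConstraint:
    """Linear relation among decision-variable bounds, in physical flux units.

    ``kind`` is ``"equality"`` (a'u = rhs) or ``"inequality-le"`` (a'u <= rhs).
    ``coefficients`` maps component name -> weight.
    """

    coefficients: Mapping[str, float]
    rhs: float
    kind: str = "equality"

    def __post_init__(self) -> None:
        if self.kind not in ("equality", "inequality-le"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if not any(v != 0 for v in self.coefficients.values()):
            raise ValueError("constraint has no nonzero coefficient")

    def unit_row(self, names: Sequence[str], box_upper: np.ndarray) -> np.ndarray:
        """Coefficient row in unit-box coordinates x = u / box_upper."""
        a = np.zeros(len(names))
        for comp, w in self.coefficients.items():
            if comp not in names:
                raise KeyError(f"constraint names unknown component {comp!r}")
            i = list(names).index(comp)
            a[i] = w * box_upper[i]
        return a


@dataclass(frozen=True)
class OptimizationConfig:
    """Run settings for the outer loop."""

    n_init: int = 50
    n_iter: int = 100
    batch_size: int = 15
    seed: int = 0
    rho: float = 0.05  # Chebyshev augmentation coefficient
    constraints: tuple[LinearConstraint, ...] = ()
    solver: str = "fba"
    acquisition_restarts: int = 3
    raw_samples: int = 256
    warm_start_surrogate: bool = False  # refit-from-scratch each iteration by default

    def __post_init__(self) -> None:
        if self.n_init < 2 or self.n_iter < 1 or self.batch_size < 1:
            raise ValueError("need n_init >= 2, n_iter >= 1, batch_size >= 1")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.solver not in ("fba", "pfba"):
            raise ValueError(f"unknown solver {self.solver!r}")
        object.__setattr__(self, "constraints", tuple(self.constraints))

    def to_dict(self) -> dict:
        return {
            "n_init": self.n_init,
            "n_iter": self.n_iter,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "rho": self.rho,
            "solver": self.solver,
            "acquisition_restarts": self.acquisition_restarts,
            "raw_samples": self.raw_samples,
            "constraints": [
                {"coefficients": dict(c.coefficients), "rhs": c.rhs, "kind": c.kind}
                for c in self.constraints
            ],
        }


class SampleDataset:
    """Accumulated (medium, objective-vector) pairs with normalization state.

    ``X_raw`` holds physical bounds, ``X_unit = X_raw / box_upper`` the
    unit-box coordinates the surrogate sees. ``iteration_label`` is 0 for the
    initialization batch, then 1..n_iter.
    """

    def __init__(
        self,
        component_names: Sequence[str],
        box_upper: np.ndarray,
        objectives: Sequence[str],
    ):
        self.component_names = tuple(component_names)
        self.box_upper = np.asarray(box_upper, float)
        self.objectives = tuple(objectives)
        self.X_raw = np.empty((0, len(self.component_names)))
        self._records: list[dict] = []
        self.iteration_label = np.empty(0, dtype=int)

    def __len__(self) -> int:
        return self.X_raw.shape[0]

    @property
    def X_unit(self) -> np.ndarray:
        return self.X_raw / self.box_upper

    @property
    def Y_raw(self) -> pd.DataFrame:
        return pd.DataFrame(self._records)

    def oriented(self) -> tuple[np.ndarray, dict]:
        """All-maximized normalized objective matrix over the current data."""
        return orient_and_normalize(self.Y_raw, self.objectives)

    def append(
        self, X: np.ndarray, results: Sequence[ObjectiveVector], iteration: int
    ) -> None:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != len(results):
            raise ValueError("X rows and results must align")
        self.X_raw = np.vstack([self.X_raw, X])
        for r in results:
            self._records.append(
                {
                    "growth": r.f_growth,
                    "production": r.f_prod,
                    "cost": r.f_cost,
                    "feasible": r.feasible,
                    "status": r.status,
                }
            )
        self.iteration_label = np.concatenate(
            [self.iteration_label, np.full(X.shape[0], iteration, dtype=int)]
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples table with the documented fixed column order."""
        df = pd.DataFrame({"iteration": self.iteration_label})
        for k, name in enumerate(self.component_names):
            df[f"bound_{name}"] = self.X_raw[:, k]
        raw = self.Y_raw
        for name in self.objectives:
            df[name] = raw[name].to_numpy()
        oriented, _ = self.oriented()
        for j, name in enumerate(self.objectives):
            df[f"{name}_oriented"] = oriented[:, j]
        df["feasible"] = raw["feasible"].to_numpy()
        df["status"] = raw["status"].to_numpy()
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, box_upper: np.ndarray | None = None
    ) -> "SampleDataset":
        comp = [c[len("bound_"):] for c in df.columns if c.startswith("bound_")]
        objectives = [o for o in ("growth", "production", "cost") if o in df.columns]
        X = df[[f"bound_{c}" for c in comp]].to_numpy(float)
        if box_upper is None:
            box_upper = np.maximum(X.max(axis=0), 1e-12)
        ds = cls(comp, box_upper, objectives)
        results = [
            ObjectiveVector(
                f_growth=float(r.growth) if "growth" in objectives else 0.0,
                f_prod=float(getattr(r, "production", 0.0)),
                f_cost=float(getattr(r, "cost", 0.0)),
                feasible=bool(getattr(r, "feasible", True)),
                status=str(getattr(r, "status", "optimal")),
            )
            for r in df.itertuples()
        ]
        ds.append(X, results, 0)
        ds.iteration_label = df["iteration"].to_numpy(int)
        return ds


# ---------------------------------------------------------------------------
# surrogate
# ---------------------------------------------------------------------------

@dataclass
class SurrogateModel:
    """Independent GP per objective over the unit box."""

    gps: list[GaussianProcessRegressor]
    objectives: tuple[str, ...]
    fingerprint: str

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and std per objective; shapes (n, n_obj)."""
        X = np.atleast_2d(X)
        means, stds = [], []
        for gp in self.gps:
            mu, sd = gp.predict(X, return_std=True)
            means.append(mu)
            stds.append(sd)
        return np.column_stack(means), np.column_stack(stds)

    def conditioned(self, X_new: np.ndarray, Y_new: np.ndarray) -> "SurrogateModel":
        """Fantasy update: append points at fixed hyperparameters."""
        new_gps = []
        for j, gp in enumerate(self.gps):
            Xc = np.vstack([gp.X_train_, np.atleast_2d(X_new)])
            y_orig = gp.y_train_ * gp._y_train_std + gp._y_train_mean
            yc = np.concatenate([np.ravel(y_orig), np.atleast_1d(Y_new[..., j])])
            clone = GaussianProcessRegressor(
                kernel=gp.kernel_, optimizer=None, normalize_y=True, alpha=gp.alpha
            )
            clone.fit(Xc, yc)
            new_gps.append(clone)
        return SurrogateModel(new_gps, self.objectives, self.fingerprint + "+f")


def _default_kernel(d: int):
    return ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))


def fit_surrogate(dataset: SampleDataset) -> SurrogateModel:
    """Fit one GP per objective on (X_unit, oriented objectives).

    Hyperparameters are set by marginal-likelihood maximization, refit from
    scratch on the full accumulated dataset. A degenerate kernel matrix is
    handled by escalating jitter before giving up.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 samples to fit a surrogate")
    X = dataset.X_unit
    Y, _ = dataset.oriented()
    d = X.shape[1]
    gps = []
    for j in range(Y.shape[1]):
        last_err: Exception | None = None
        for jitter in (1e-10, 1e-8, 1e-6, 1e-4):
            gp = GaussianProcessRegressor(
                kernel=_default_kernel(d),
                alpha=jitter,
                normalize_y=True,
                n_restarts_optimizer=0,
                random_state=0,
            )
            try:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    gp.fit(X, Y[:, j])
                last_err = None
                break
            except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
                last_err = exc
        if last_err is not None:  # pragma: no cover
            raise RuntimeError(
                f"GP fit failed for objective {dataset.objectives[j]!r}"
            ) from last_err
        gps.append(gp)
    fp = hashlib.sha256(
        np.ascontiguousarray(np.column_stack([X.ravel()[:0]]) if X.size == 0 else X).tobytes()
        + Y.tobytes()
    ).hexdigest()[:16]
    return SurrogateModel(gps, dataset.objectives, fp)


# ---------------------------------------------------------------------------
# scalarization
# ---------------------------------------------------------------------------

def chebyshev_scalarize(
    y: np.ndarray, weights: np.ndarray, rho: float
) -> np.ndarray | float:
    """Augmented Chebyshev scalarization ``min_j(w_j y_j) + rho * sum_j(w_j y_j)``.

    ``y`` may be a single oriented objective vector or a matrix of rows.
    Weights must be a nonnegative simplex vector.
    """
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    w = w / total
    wy = y * w
    return wy.min(axis=-1) + rho * wy.sum(axis=-1)


def _sample_simplex(rng: np.random.Generator, k: int) -> np.ndarray:
    """Uniform draw from the probability simplex (normalized exponentials)."""
    e = rng.exponential(size=k)
    return e / e.sum()


# ---------------------------------------------------------------------------
# constraints in the unit box
# ---------------------------------------------------------------------------

def _unit_constraints(
    constraints: Sequence[LinearConstraint],
    names: Sequence[str],
    box_upper: np.ndarray,
) -> list[tuple[np.ndarray, float, str]]:
    return [
        (c.unit_row(names, box_upper), float(c.rhs), c.kind) for c in constraints
    ]


def _violation(x: np.ndarray, rows: list[tuple[np.ndarray, float, str]]) -> float:
    v = 0.0
    for a, b, kind in rows:
        r = float(a @ x) - b
        v = max(v, abs(r) if kind == "equality" else max(r, 0.0))
    return v


def _project_to_feasible(
    x0: np.ndarray, rows: list[tuple[np.ndarray, float, str]]
) -> np.ndarray:
    """Nearest point of the constrained unit box (small QP via SLSQP)."""
    if not rows:
        return np.clip(x0, 0.0, 1.0)
    cons = []
    for a, b, kind in rows:
        if kind == "equality":
            cons.append({"type": "eq", "fun": (lambda x, a=a, b=b: a @ x - b)})
        else:
            cons.append({"type": "ineq", "fun": (lambda x, a=a, b=b: b - a @ x)})
    res = minimize(
        lambda x: float(((x - x0) ** 2).sum()),
        np.clip(x0, 0.0, 1.0),
        jac=lambda x: 2.0 * (x - x0),
        bounds=[(0.0, 1.0)] * len(x0),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-14},
    )
    x = np.clip(res.x, 0.0, 1.0)
    if _violation(x, rows) > _CONSTRAINT_TOL:
        raise RuntimeError(
            "could not project a candidate into the constrained box; "
            "the feasible set may be empty"
        )
    return x


def init_random_media(
    spec: MediumSpec,
    n: int,
    constraints: Sequence[LinearConstraint] = (),
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """``n`` random media, uniform on the box, projected onto constraints.

    Returns physical bounds (n x d). Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    box = spec.box_upper
    rows = _unit_constraints(constraints, spec.decision_names, box)
    X = rng.uniform(size=(n, box.size))
    if rows:
        X = np.array([_project_to_feasible(x, rows) for x in X])
    return X * box


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

def _log_ei_factory(
    surrogate: SurrogateModel,
    weights: np.ndarray,
    rho: float,
    best: float,
    z_draws: np.ndarray,
) -> Callable[[np.ndarray], np.ndarray]:
    """Batched log-EI of the scalarized posterior, smoothed by fixed qMC draws.

    The scalarized objective of independent Gaussian posteriors is not
    Gaussian (the min is involved), so EI is estimated with common random
    numbers: fixed standard-normal draws reused at every evaluation point,
    which keeps the surface smooth and the optimizer deterministic.
    """

    def log_ei(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        mu, sd = surrogate.predict(X)  # (n, k)
        # samples: (n, n_mc, k)
        samp = mu[:, None, :] + sd[:, None, :] * z_draws[None, :, :]
        s = chebyshev_scalarize(samp, weights, rho)  # (n, n_mc)
        improvement = np.maximum(s - best, 0.0).mean(axis=1)
        return np.log(improvement + 1e-25)

    return log_ei


def _maximize_acquisition(
    acq: Callable[[np.ndarray], np.ndarray],
    d: int,
    rows: list[tuple[np.ndarray, float, str]],
    rng: np.random.Generator,
    n_restarts: int,
    raw_samples: int,
) -> np.ndarray:
    """Multi-start quasi-Newton from the best of a Sobol screen."""
    sobol = qmc.Sobol(d, scramble=True, seed=int(rng.integers(2**31)))
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # Sobol prefers powers of two; fine here
        raw = sobol.random(raw_samples)
    if rows:
        raw = np.array([_project_to_feasible(x, rows) for x in raw])
    vals = acq(raw)
    order = np.argsort(vals)[::-1]
    starts = raw[order[: max(n_restarts, 1)]]

    def neg(x: np.ndarray) -> float:
        return -float(acq(x[None, :])[0])

    def neg_grad(x: np.ndarray) -> np.ndarray:
        # batched forward differences: one surrogate call for d+1 points
        h = 1e-6
        pts = np.vstack([x[None, :], x[None, :] + h * np.eye(d)])
        v = -acq(pts)
        return (v[1:] - v[0]) / h

    best_x, best_v = starts[0], -np.inf
    for x0 in starts:
        if rows:
            cons = []
            for a, b, kind in rows:
                if kind == "equality":
                    cons.append({"type": "eq", "fun": (lambda x, a=a, b=b: a @ x - b),
                                 "jac": (lambda x, a=a: a)})
                else:
                    cons.append({"type": "ineq", "fun": (lambda x, a=a, b=b: b - a @ x),
                                 "jac": (lambda x, a=a: -a)})
            res = minimize(
                neg, x0, jac=neg_grad, bounds=[(0.0, 1.0)] * d,
                constraints=cons, method="SLSQP", options={"maxiter": 60},
            )
        else:
            res = minimize(
                neg, x0, jac=neg_grad, bounds=[(0.0, 1.0)] * d,
                method="L-BFGS-B", options={"maxiter": 60},
            )
        x = np.clip(res.x, 0.0, 1.0)
        if rows and _violation(x, rows) > _CONSTRAINT_TOL:
            continue
        v = float(acq(x[None, :])[0])
        if np.isfinite(v) and v > best_v:
            best_x, best_v = x, v
    if not np.isfinite(best_v):
        # all restarts failed: fall back to the best raw sample
        logger.warning("acquisition optimizer failed on all restarts; using raw best")
        best_x = raw[int(order[0])]
    return best_x


def propose_batch(
    surrogate: SurrogateModel,
    dataset: SampleDataset,
    config: OptimizationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Propose ``q`` unit-box candidates via scalarized log-EI.

    Each candidate draws an independent simplex weight vector; earlier
    candidates condition later ones through Kriging-believer fantasies.
    Returns unit-box coordinates (q x d).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = len(dataset.component_names)
    rows = _unit_constraints(config.constraints, dataset.component_names, dataset.box_upper)
    Y, _ = dataset.oriented()
    k = Y.shape[1]

    model = surrogate
    X_known = dataset.X_unit
    Y_known = Y
    batch = []
    for _ in range(config.batch_size):
        w = _sample_simplex(rng, k)
        best = float(np.max(chebyshev_scalarize(Y_known, w, config.rho)))
        z = rng.standard_normal((_N_MC, k))
        acq = _log_ei_factory(model, w, config.rho, best, z)
        x = _maximize_acquisition(
            acq, d, rows, rng, config.acquisition_restarts, config.raw_samples
        )
        batch.append(x)
        mu, _sd = model.predict(x[None, :])
        model = model.conditioned(x[None, :], mu)
        Y_known = np.vstack([Y_known, mu])
    return np.array(batch)


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def _spawn_streams(seed: int) -> dict[str, np.random.SeedSequence]:
    """Named substreams off one master seed: initialization, proposals, acq."""
    init_ss, weights_ss, acq_ss, restart_ss = np.random.SeedSequence(seed).spawn(4)
    return {"init": init_ss, "proposal": weights_ss, "acq": acq_ss, "restart": restart_ss}


def run(
    model: MetabolicModel,
    spec: MediumSpec,
    prices: PriceTable,
    fba_objective: FluxObjective,
    objectives: Sequence[str] = ("growth", "cost"),
    config: OptimizationConfig = OptimizationConfig(),
    initial_X: np.ndarray | None = None,
    flush_dir: str | Path | None = None,
    iteration_callback: Callable[[int, SampleDataset], None] | None = None,
) -> SampleDataset:
    """Execute the full outer loop: init -> [fit, propose, evaluate] x n_iter.

    ``initial_X`` (physical bounds) overrides random initialization, e.g. for
    Pareto-seeded restarts. Total evaluations are exactly
    ``n_init + n_iter * batch_size``. Fully reproducible for a fixed seed and
    solver configuration. On error the partial dataset is flushed to
    ``flush_dir`` (if given) before re-raising.
    """
    objectives = tuple(objectives)
    if not 2 <= len(objectives) <= 3:
        raise ValueError("choose 2 or 3 objectives")
    if "production" in objectives and model.production_reaction is None:
        raise ValueError("production objective requires a production reaction")
    spec.validate_against(model)

    streams = _spawn_streams(config.seed)
    proposal_rng = np.random.default_rng(streams["proposal"])
    box = spec.box_upper
    dataset = SampleDataset(spec.decision_names, box, objectives)

    def evaluate(X_phys: np.ndarray, iteration: int) -> None:
        results = [
            evaluate_objectives(model, spec, x, prices, fba_objective, config.solver)
            for x in X_phys
        ]
        dataset.append(X_phys, results, iteration)

    try:
        if initial_X is None:
            X0 = init_random_media(spec, config.n_init, config.constraints, streams["init"])
        else:
            # Pareto-seeded restarts may carry more than n_init points (keep-all)
            X0 = np.atleast_2d(np.asarray(initial_X, float))
            if X0.shape[0] < 2:
                raise ValueError("initial_X must contain at least 2 media")
        evaluate(X0, 0)

        for it in range(1, config.n_iter + 1):
            t0 = time.perf_counter()
            surrogate = fit_surrogate(dataset)
            X_unit = propose_batch(surrogate, dataset, config, proposal_rng)
            evaluate(X_unit * box, it)
            if logger.isEnabledFor(logging.INFO):
                from .pareto import pareto_mask
                from .medium import orient_objectives

                oriented = orient_objectives(dataset.Y_raw, objectives)
                front_size = int(pareto_mask(oriented).sum())
                Yn, _ = dataset.oriented()
                logger.info(
                    "iter=%d n=%d front=%d best_scalarized=%.4f dt=%.2fs",
                    it,
                    len(dataset),
                    front_size,
                    float(np.max(chebyshev_scalarize(Yn, np.full(len(objectives), 1.0 / len(objectives)), config.rho))),
                    time.perf_counter() - t0,
                )
            if iteration_callback is not None:
                iteration_callback(it, dataset)
    except Exception:
        if flush_dir is not None and len(dataset) > 0:
            Path(flush_dir).mkdir(parents=True, exist_ok=True)
            dataset.to_frame().to_csv(Path(flush_dir) / "partial_samples.csv", index=False)
        raise
    return dataset


def restart_from_pareto(
    previous: SampleDataset,
    spec: MediumSpec,
    config: OptimizationConfig,
) -> np.ndarray:
    """Initialization set for a chained run, seeded from the previous front.

    The previous run's Pareto-optimal compositions are all carried over (no
    truncation even if the front exceeds ``n_init``) and padded with fresh
    random media up to ``n_init``.
    """
    from .medium import orient_objectives
    from .pareto import pareto_mask

    if len(previous) == 0:
        raise ValueError("previous dataset is empty")
    oriented = orient_objectives(previous.Y_raw, previous.objectives)
    mask = pareto_mask(oriented)
    X_front = previous.X_raw[mask]
    n_pad = config.n_init - X_front.shape[0]
    if n_pad <= 0:
        return X_front
    X_pad = init_random_media(
        spec, n_pad, config.constraints, _spawn_streams(config.seed)["restart"]
    )
    return np.vstack([X_front, X_pad])
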