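"""Generalized-method-of-moments estimation from snapshot data.

The estimator minimizes  sum_t g_t(theta)' W_t g_t(theta)  where g_t stacks
the differences between sample moments (pure and mixed, orders 1..r) and
theoretical moments from a moment engine.  Weight-matrix variants:

* ``identity``          W = I (least squares; "2-Step I")
* ``two_step``          W = pinv(F1(theta_tilde)) after an identity first
                        step ("2-Step II")
* ``demean``            W = pinv(F2), the demeaned monomial covariance
* ``demean_diagonal``   inverse of diag(F2)
* ``iterated``          repeated two-step updates
* ``continuous_update`` W(theta) = pinv(F1(theta)) inside the objective

Theoretical moments for a requested order r come from an engine derived and
closed at order r+1, of which only orders <= r are exposed (the top closure
order is the least accurate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .hybrid import derive_hybrid_system, integrate_hybrid_system, reconstruct_unconditional_moments
from .moments import closed_moment_system, enumerate_moment_indices, integrate_moment_system
from .network import ModelError, ParameterVector, ReactionNetwork
from .ssa import SnapshotDataset

__all__ = [
    "EstimationError",
    "MomentConditionSpec",
    "WeightMatrix",
    "OptimizerConfig",
    "GMMStep",
    "GMMResult",
    "ESTIMATORS",
    "sample_moment_vector",
    "theoretical_moment_vector",
    "weight_identity",
    "estimate_F1",
    "estimate_F2",
    "gmm_objective",
    "estimate_parameters",
    "diagnose_weights",
    "symmetric_pinv",
]

ESTIMATORS = (
    "identity",
    "two_step",
    "demean",
    "demean_diagonal",
    "iterated",
    "continuous_update",
)


class EstimationError(RuntimeError):
    """Estimation cannot proceed (under-identification, no convergence...)."""


@dataclass(frozen=True)
class MomentConditionSpec:
    """Which moment conditions to match: species, maximal order, times."""

    observed_species: tuple[str, ...]
    max_order: int
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if not self.times:
            raise ValueError("at least one observation time required")
        if not self.observed_species:
            raise ValueError("at least one observed species required")

    @property
    def indices(self) -> list[tuple[int, ...]]:
        """Moment multi-indices over the observed species, orders 1..max_order."""
        return enumerate_moment_indices(len(self.observed_species), 1, self.max_order)

    @property
    def n_conditions_per_time(self) -> int:
        return len(self.indices)

    @property
    def n_conditions(self) -> int:
        return self.n_conditions_per_time * len(self.times)


def _monomial_matrix(samples: np.ndarray, indices: Sequence[tuple[int, ...]]) -> np.ndarray:
    """(N, K) matrix of sample monomials Y^r."""
    s = samples.astype(float)
    out = np.empty((s.shape[0], len(indices)))
    for k, idx in enumerate(indices):
        col = np.ones(s.shape[0])
        for j, e in enumerate(idx):
            if e:
                col = col * s[:, j] ** e
        out[:, k] = col
    return out


def _dataset_matrices(dataset: SnapshotDataset, spec: MomentConditionSpec) -> dict[float, np.ndarray]:
    col_of = {name: i for i, name in enumerate(dataset.species)}
    missing = [s for s in spec.observed_species if s not in col_of]
    if missing:
        raise ModelError(f"species {missing} not present in dataset")
    cols = [col_of[s] for s in spec.observed_species]
    out = {}
    for t in spec.times:
        samples = dataset.samples_at(t)
        if samples.shape[0] == 0:
            raise ModelError("dataset has zero samples")
        out[t] = _monomial_matrix(samples[:, cols], spec.indices)
    return out


def sample_moment_vector(
    dataset: SnapshotDataset, spec: MomentConditionSpec
) -> dict[float, np.ndarray]:
    """Raw sample moments m_hat (pure and mixed) per observation time."""
    return {t: mat.mean(axis=0) for t, mat in _dataset_matrices(dataset, spec).items()}


# ---------------------------------------------------------------------------
# theoretical moments (engine wrapper, cached per network/engine/order)
# ---------------------------------------------------------------------------

_ENGINE_CACHE: dict[tuple[str, str, int], object] = {}


def _get_engine(network: ReactionNetwork, engine: str, order: int):
    key = (network.fingerprint(), engine, order)
    if key not in _ENGINE_CACHE:
        if engine == "standard":
            _ENGINE_CACHE[key] = closed_moment_system(network, order)
        elif engine == "hybrid":
            _ENGINE_CACHE[key] = derive_hybrid_system(network, max_order=order)
        else:
            raise ValueError(f"unknown engine {engine!r}; use 'standard' or 'hybrid'")
    return _ENGINE_CACHE[key]


def _full_indices(
    network: ReactionNetwork, spec: MomentConditionSpec
) -> list[tuple[int, ...]]:
    obs_idx = [network.species_index(s) for s in spec.observed_species]
    full = []
    for idx in spec.indices:
        vec = [0] * network.n_species
        for pos, e in zip(obs_idx, idx):
            vec[pos] = e
        full.append(tuple(vec))
    return full


def theoretical_moment_vector(
    network: ReactionNetwork,
    theta: Mapping[str, float] | ParameterVector,
    spec: MomentConditionSpec,
    engine: str = "standard",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[float, np.ndarray]:
    """Theoretical raw moments m(theta) per time, from the chosen engine.

    The engine is derived/closed at order ``spec.max_order + 1``; only the
    requested orders are returned.
    """
    sysm = _get_engine(network, engine, spec.max_order + 1)
    full = _full_indices(network, spec)
    times = sorted(spec.times)
    if engine == "standard":
        traj = integrate_moment_system(sysm, theta, times, rtol=rtol, atol=atol)
        rows = {t: np.array([traj.at(t)[idx] for idx in full]) for t in times}
    else:
        htraj = integrate_hybrid_system(sysm, theta, times, rtol=rtol, atol=atol)
        recon = reconstruct_unconditional_moments(htraj, full)
        rows = {t: recon.values[i] for i, t in enumerate(times)}
    return {t: rows[t] for t in spec.times}


# ---------------------------------------------------------------------------
# weight matrices
# ---------------------------------------------------------------------------

@dataclass
class WeightMatrix:
    """Per-time symmetric PSD weighting matrices plus conditioning info."""

    matrices: dict[float, np.ndarray]
    method: str
    eig_range: dict[float, tuple[float, float]] = field(default_factory=dict)
    rank: dict[float, int] = field(default_factory=dict)
    singular: bool = False

    def __post_init__(self) -> None:
        for t, W in self.matrices.items():
            if not np.allclose(W, W.T, atol=1e-10):
                raise ValueError(f"weight matrix at t={t} is not symmetric")


def symmetric_pinv(F: np.ndarray, rcond: float = 1e-12) -> tuple[np.ndarray, dict]:
    """Pseudo-inverse of a symmetric PSD matrix with a relative eigenvalue cutoff."""
    F = 0.5 * (F + F.T)
    evals, evecs = np.linalg.eigh(F)
    cutoff = rcond * max(evals.max(), 0.0)
    inv = np.where(evals > cutoff, 1.0 / np.where(evals > cutoff, evals, 1.0), 0.0)
    W = (evecs * inv) @ evecs.T
    info = {
        "eig_range": (float(evals.min()), float(evals.max())),
        "rank": int((evals > cutoff).sum()),
        "singular": bool((evals <= cutoff).any()),
    }
    return 0.5 * (W + W.T), info


def weight_identity(spec: MomentConditionSpec) -> WeightMatrix:
    """W = I per time: the plain least-squares objective."""
    K = spec.n_conditions_per_time
    return WeightMatrix(
        matrices={t: np.eye(K) for t in spec.times},
        method="identity",
        eig_range={t: (1.0, 1.0) for t in spec.times},
        rank={t: K for t in spec.times},
    )


def estimate_F1(
    dataset: SnapshotDataset,
    theta: Mapping[str, float] | ParameterVector,
    spec: MomentConditionSpec,
    network: ReactionNetwork,
    engine: str = "standard",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[float, np.ndarray]:
    """F1(theta) per time: mean outer product of f(Y_l, theta) = Y^r - m(theta)."""
    mono = _dataset_matrices(dataset, spec)
    m_theta = theoretical_moment_vector(network, theta, spec, engine, rtol=rtol, atol=atol)
    out = {}
    for t in spec.times:
        f = mono[t] - m_theta[t]
        out[t] = f.T @ f / f.shape[0]
    return out


def estimate_F2(dataset: SnapshotDataset, spec: MomentConditionSpec) -> dict[float, np.ndarray]:
    """F2 per time: demeaned covariance of the monomial vectors (1/N normalized)."""
    out = {}
    for t, mono in _dataset_matrices(dataset, spec).items():
        if mono.shape[0] < 2:
            raise ModelError("demeaned covariance needs at least 2 samples")
        c = mono - mono.mean(axis=0)
        out[t] = c.T @ c / c.shape[0]
    return out


def _weight_from_F(F_per_time: dict[float, np.ndarray], method: str) -> WeightMatrix:
    mats, eigr, rank = {}, {}, {}
    singular = False
    for t, F in F_per_time.items():
        W, info = symmetric_pinv(F)
        mats[t] = W
        eigr[t] = info["eig_range"]
        rank[t] = info["rank"]
        singular |= info["singular"]
    return WeightMatrix(matrices=mats, method=method, eig_range=eigr, rank=rank, singular=singular)


def _weight_diagonal(F_per_time: dict[float, np.ndarray]) -> WeightMatrix:
    mats = {}
    singular = False
    for t, F in F_per_time.items():
        d = np.diag(F).copy()
        bad = d <= 1e-12 * max(d.max(), 1.0)
        singular |= bool(bad.any())
        inv = np.where(bad, 0.0, 1.0 / np.where(bad, 1.0, d))
        mats[t] = np.diag(inv)
    return WeightMatrix(matrices=mats, method="demean_diagonal", singular=singular)


def gmm_objective(
    g: Mapping[float, np.ndarray], W: WeightMatrix | Mapping[float, np.ndarray]
) -> float:
    """Sum over times of the quadratic forms g' W g (non-negative for PSD W)."""
    mats = W.matrices if isinstance(W, WeightMatrix) else W
    total = 0.0
    for t, vec in g.items():
        mat = mats[t]
        if mat.shape != (vec.shape[0], vec.shape[0]):
            raise ValueError(f"dimension mismatch at t={t}")
        total += float(vec @ mat @ vec)
    return total


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    """Bounded multistart local optimization settings."""

    n_starts: int = 50
    initial_point: dict[str, float] | None = None
    maxiter: int = 200
    rtol: float = 1e-6  # integration tolerance inside the objective
    atol: float = 1e-8
    prescale: bool = False  # scale conditions by sample SD (conditioning only)
    iterated_max_steps: int = 2
    iterated_tol: float = 1e-4


@dataclass
class GMMStep:
    theta: dict[str, float]
    objective: float
    weights: WeightMatrix
    candidate_objectives: tuple[float, ...] = ()


@dataclass
class GMMResult:
    theta: dict[str, float]
    estimator: str
    engine: str
    spec: MomentConditionSpec
    steps: list[GMMStep]
    free_parameters: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    n_starts: int
    n_converged: int

    @property
    def objective(self) -> float:
        return self.steps[-1].objective


class _Problem:
    """Shared state for one estimation run."""

    def __init__(self, dataset, network, spec, engine, free, fixed, config):
        self.network = network
        self.spec = spec
        self.engine = engine
        self.free = free
        self.fixed = fixed
        self.config = config
        self.m_hat = sample_moment_vector(dataset, spec)
        self.dataset = dataset
        self.scale = {t: np.ones_like(v) for t, v in self.m_hat.items()}
        if config.prescale:
            for t, F in estimate_F2(dataset, spec).items():
                sd = np.sqrt(np.clip(np.diag(F), 1e-300, None))
                self.scale[t] = 1.0 / np.where(sd > 0, sd, 1.0)

    def theta_map(self, x: np.ndarray) -> dict[str, float]:
        th = dict(self.fixed)
        th.update(zip(self.free, x))
        return th

    def cost_vector(self, x: np.ndarray) -> dict[float, np.ndarray]:
        m_theta = theoretical_moment_vector(
            self.network,
            self.theta_map(x),
            self.spec,
            self.engine,
            rtol=self.config.rtol,
            atol=self.config.atol,
        )
        return {
            t: self.scale[t] * (self.m_hat[t] - m_theta[t]) for t in self.spec.times
        }

    def scaled_F1(self, x: np.ndarray) -> dict[float, np.ndarray]:
        F1 = estimate_F1(
            self.dataset,
            self.theta_map(x),
            self.spec,
            self.network,
            self.engine,
            rtol=self.config.rtol,
            atol=self.config.atol,
        )
        return {t: np.outer(self.scale[t], self.scale[t]) * F for t, F in F1.items()}

    def scaled_F2(self) -> dict[float, np.ndarray]:
        return {
            t: np.outer(self.scale[t], self.scale[t]) * F
            for t, F in estimate_F2(self.dataset, self.spec).items()
        }


def _multistart_minimize(
    objfn: Callable[[np.ndarray], float],
    free: Sequence[str],
    bounds: dict[str, tuple[float, float]],
    config: OptimizerConfig,
    seed,
    extra_starts: Sequence[np.ndarray] = (),
) -> tuple[np.ndarray, float, int, tuple[float, ...]]:
    lo = np.array([bounds[p][0] for p in free])
    hi = np.array([bounds[p][1] for p in free])
    starts: list[np.ndarray] = [np.asarray(s, dtype=float) for s in extra_starts]
    if config.initial_point is not None:
        starts.append(np.array([config.initial_point[p] for p in free]))
    if config.n_starts > 0:
        sampler = qmc.LatinHypercube(d=len(free), seed=np.random.default_rng(seed))
        starts.extend(lo + sampler.random(config.n_starts) * (hi - lo))
    scipy_bounds = list(zip(lo, hi))

    def safe_obj(x: np.ndarray) -> float:
        try:
            val = objfn(x)
        except Exception:
            return 1e100
        return val if np.isfinite(val) else 1e100

    candidates = []
    n_converged = 0
    for x0 in starts:
        res = minimize(
            safe_obj,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=scipy_bounds,
            options={"maxiter": config.maxiter},
        )
        if res.fun < 1e99:
            n_converged += int(res.success)
            candidates.append((float(res.fun), tuple(res.x)))
    if not candidates:
        raise EstimationError("optimizer failed to converge from every start")
    # deterministic tie break: objective, then lexicographic parameter order
    fun, x = min(candidates)
    return np.array(x), fun, n_converged, tuple(c[0] for c in candidates)


def estimate_parameters(
    dataset: SnapshotDataset,
    network: ReactionNetwork,
    spec: MomentConditionSpec,
    estimator: str = "demean",
    engine: str = "standard",
    free_parameters: Sequence[str] | None = None,
    fixed_values: Mapping[str, float] | None = None,
    config: OptimizerConfig | None = None,
    seed: int = 0,
    allow_underidentified: bool = False,
) -> GMMResult:
    """Run one GMM estimation; see the module docstring for variant semantics.

    ``allow_underidentified`` skips the q <= (conditions) prerequisite, for
    deliberately degenerate study cells (identification is then impossible
    and only a rough estimate results).
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    config = config or OptimizerConfig()
    fixed = dict(network.parameters.values)
    if fixed_values:
        fixed.update(fixed_values)
    if free_parameters is None:
        free = tuple(p for p in network.parameter_names if p not in fixed)
    else:
        free = tuple(free_parameters)
        for p in free:
            fixed.pop(p, None)
    if not free:
        raise EstimationError("no free parameters to estimate")
    q = len(free)
    if q > spec.n_conditions and not allow_underidentified:
        raise EstimationError(
            f"under-identified: {q} unknown parameters but only "
            f"{spec.n_conditions} moment conditions"
        )
    bounds = {}
    for p in free:
        if p not in network.parameters.bounds:
            raise EstimationError(f"free parameter {p!r} has no bounds")
        lo, hi = network.parameters.bounds[p]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise EstimationError(f"free parameter {p!r} has unbounded interval")
        bounds[p] = (lo, hi)

    prob = _Problem(dataset, network, spec, engine, free, fixed, config)
    root = np.random.SeedSequence(seed)
    steps: list[GMMStep] = []
    n_conv_total = 0

    def run(weights: WeightMatrix, extra=()):
        nonlocal n_conv_total
        objfn = lambda x: gmm_objective(prob.cost_vector(x), weights)
        x, fun, n_conv, cand = _multistart_minimize(
            objfn, free, bounds, config, root.spawn(1)[0], extra
        )
        n_conv_total += n_conv
        steps.append(
            GMMStep(
                theta=prob.theta_map(x),
                objective=fun,
                weights=weights,
                candidate_objectives=cand,
            )
        )
        return x

    if estimator == "identity":
        run(weight_identity(spec))
    elif estimator == "demean":
        run(_weight_from_F(prob.scaled_F2(), "demean"))
    elif estimator == "demean_diagonal":
        run(_weight_diagonal(prob.scaled_F2()))
    elif estimator in ("two_step", "iterated"):
        x = run(weight_identity(spec))
        n_updates = 1 if estimator == "two_step" else min(config.iterated_max_steps, 10)
        for _ in range(n_updates):
            W = _weight_from_F(prob.scaled_F1(x), "two_step_F1")
            x_new = run(W, extra=[x])
            if np.max(np.abs(x_new - x)) < config.iterated_tol:
                x = x_new
                break
            x = x_new
    else:  # continuous_update
        def cu_objective(x: np.ndarray) -> float:
            W = _weight_from_F(prob.scaled_F1(x), "continuous_update")
            return gmm_objective(prob.cost_vector(x), W)

        x, fun, n_conv, cand = _multistart_minimize(
            cu_objective, free, bounds, config, root.spawn(1)[0]
        )
        n_conv_total += n_conv
        steps.append(
            GMMStep(
                theta=prob.theta_map(x),
                objective=fun,
                weights=_weight_from_F(prob.scaled_F1(x), "continuous_update"),
                candidate_objectives=cand,
            )
        )

    final = steps[-1]
    theta_hat = {p: final.theta[p] for p in free}
    return GMMResult(
        theta=theta_hat,
        estimator=estimator,
        engine=engine,
        spec=spec,
        steps=steps,
        free_parameters=free,
        bounds=bounds,
        n_starts=config.n_starts,
        n_converged=n_conv_total,
    )


def diagnose_weights(
    W_twostep: WeightMatrix | Mapping[float, np.ndarray],
    W_demean: WeightMatrix | Mapping[float, np.ndarray],
) -> dict:
    """Compare two weight choices, each normalized by its mean-condition weight.

    Returns per-time normalized matrices (entry (0,0), the weight of the
    first mean condition, becomes 1) and the maximum absolute discrepancy.
    The two are expected — not asserted — to be close for large N near the
    truth.
    """
    a = W_twostep.matrices if isinstance(W_twostep, WeightMatrix) else dict(W_twostep)
    b = W_demean.matrices if isinstance(W_demean, WeightMatrix) else dict(W_demean)
    if set(a) != set(b):
        raise ValueError("weight matrices cover different time points")
    out = {"normalized_twostep": {}, "normalized_demean": {}, "max_discrepancy": 0.0}
    for t in a:
        na = a[t] / a[t][0, 0]
        nb = b[t] / b[t][0, 0]
        out["normalized_twostep"][t] = na
        out["normalized_demean"][t] = nb
        out["max_discrepancy"] = max(
            out["max_discrepancy"], float(np.abs(na - nb).max())
        )
    return out
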