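"""Raw-moment ODE systems for mass-action networks, with zero closure.

For a multi-index a the raw moment E[X^a] evolves as
    d/dt E[X^a] = sum_j E[ alpha_j(X) * ((X + v_j)^a - X^a) ],
which for polynomial (mass-action) propensities is an exact linear
combination of raw moments.  Bimolecular reactions make moments of order
k+1 appear in the order-k equations; the system is closed by rewriting
every over-order raw moment through its central-moment expansion about the
mean and setting all central moments of order > k to zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, prod
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .network import ModelError, ParameterVector, ReactionNetwork

__all__ = [
    "IntegrationError",
    "MomentSystem",
    "MomentTrajectory",
    "enumerate_moment_indices",
    "moment_symbol",
    "derive_moment_odes",
    "apply_zero_closure",
    "closed_moment_system",
    "integrate_moment_system",
]


class IntegrationError(RuntimeError):
    """ODE integration failed (stiffness / step-size collapse)."""


# ---------------------------------------------------------------------------
# multi-index bookkeeping
# ---------------------------------------------------------------------------

def enumerate_moment_indices(
    n_species: int, min_order: int, max_order: int
) -> list[tuple[int, ...]]:
    """All multi-indices over ``n_species`` with total order in [min_order, max_order].

    Graded lexicographic order: ascending total order, then lexicographically
    descending exponent tuples (so the means come first, in species order).
    """
    if n_species < 0 or min_order < 0 or max_order < 0:
        raise ValueError("arguments must be non-negative")
    out: list[tuple[int, ...]] = []
    for order in range(min_order, max_order + 1):
        level = [
            idx
            for idx in itertools.product(range(order + 1), repeat=n_species)
            if sum(idx) == order
        ]
        level.sort(key=lambda idx: tuple(-e for e in idx))
        out.extend(level)
    return out


def moment_symbol(index: Sequence[int]) -> sp.Symbol:
    """Symbol standing for the raw moment E[X^index]."""
    return sp.Symbol("M_" + "_".join(str(e) for e in index))


def _index_label(index: Sequence[int], names: Sequence[str]) -> str:
    parts = [
        name if e == 1 else f"{name}^{e}"
        for e, name in zip(index, names)
        if e
    ]
    return "E[" + ("*".join(parts) if parts else "1") + "]"


def _sub_multiindices(beta: Sequence[int]):
    return itertools.product(*(range(b + 1) for b in beta))


def _central_in_raw(gamma: Sequence[int], msym: Callable[[tuple[int, ...]], sp.Expr]) -> sp.Expr:
    """Central moment E[prod (X_i - mu_i)^gamma_i] in terms of raw moments."""
    n = len(gamma)
    mu = [msym(tuple(1 if j == i else 0 for j in range(n))) for i in range(n)]
    total = sp.Integer(0)
    for delta in _sub_multiindices(gamma):
        coeff = prod(comb(g, d) for g, d in zip(gamma, delta))
        sign = (-1) ** (sum(gamma) - sum(delta))
        mu_pow = prod(m ** (g - d) for m, g, d in zip(mu, gamma, delta))
        raw = msym(tuple(delta)) if sum(delta) > 0 else sp.Integer(1)
        total += sign * coeff * mu_pow * raw
    return total


def closed_raw_moment(
    beta: Sequence[int], k: int, msym: Callable[[tuple[int, ...]], sp.Expr]
) -> sp.Expr:
    """E[X^beta] with every central moment of order > k set to zero.

    Expansion about the mean:  E[X^beta] = sum_gamma C(beta, gamma)
    mu^(beta-gamma) * central_gamma; terms with |gamma| > k are dropped and
    the surviving central moments are rewritten in raw moments of order <= k.
    """
    n = len(beta)
    mu = [msym(tuple(1 if j == i else 0 for j in range(n))) for i in range(n)]
    total = sp.Integer(0)
    for gamma in _sub_multiindices(beta):
        g = sum(gamma)
        if g > k or g == 1:  # first central moment vanishes identically
            continue
        coeff = prod(comb(b, gm) for b, gm in zip(beta, gamma))
        mu_pow = prod(m ** (b - gm) for m, b, gm in zip(mu, beta, gamma))
        central = sp.Integer(1) if g == 0 else _central_in_raw(gamma, msym)
        total += coeff * mu_pow * central
    return sp.expand(total)


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------

@dataclass
class MomentSystem:
    """ODE system d/dt E[X^a] = rhs[a] over a graded-lex index list."""

    network: ReactionNetwork
    max_order: int
    indices: list[tuple[int, ...]]
    rhs: dict[tuple[int, ...], sp.Expr]
    closed: bool = False
    _rhs_fn: Callable | None = field(default=None, repr=False, compare=False)

    @property
    def symbols(self) -> list[sp.Symbol]:
        return [moment_symbol(idx) for idx in self.indices]

    def overhang_indices(self) -> list[tuple[int, ...]]:
        """Moment indices of order > max_order appearing in any rhs."""
        known = set(self.indices)
        extra: set[tuple[int, ...]] = set()
        for expr in self.rhs.values():
            for sym in expr.free_symbols:
                name = sym.name
                if name.startswith("M_"):
                    idx = tuple(int(p) for p in name[2:].split("_"))
                    if idx not in known:
                        extra.add(idx)
        return sorted(extra, key=lambda i: (sum(i), tuple(-e for e in i)))

    def to_text(self) -> str:
        """Human-readable one-ODE-per-line listing."""
        names = self.network.species_names
        subs = {
            moment_symbol(idx): sp.Symbol(_index_label(idx, names))
            for idx in self.indices + self.overhang_indices()
        }
        lines = []
        for idx in self.indices:
            lhs = _index_label(idx, names)
            lines.append(f"d/dt {lhs} = {self.rhs[idx].xreplace(subs)}")
        return "\n".join(lines)

    def rhs_function(self) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
        """Compiled rhs f(y, params) -> dy; params in network.parameter_names order."""
        if self._rhs_fn is None:
            from ._polyrhs import compile_poly_system

            msyms = self.symbols
            psyms = [sp.Symbol(p) for p in self.network.parameter_names]
            exprs = [self.rhs[idx] for idx in self.indices]
            core = compile_poly_system(exprs, [*msyms, *psyms])
            n_m = len(msyms)
            n_v = n_m + len(psyms)

            def fn(y: np.ndarray, p: np.ndarray) -> np.ndarray:
                varvals = np.empty(n_v)
                varvals[:n_m] = y
                varvals[n_m:] = p
                out = np.empty(n_m)
                core(varvals, out)
                return out

            self._rhs_fn = fn
        return self._rhs_fn


def _propensity_expr(network: ReactionNetwork, j: int, xsyms: Sequence[sp.Symbol]) -> sp.Expr:
    rx = network.reactions[j]
    expr = sp.Symbol(rx.rate_parameter)
    for i, r in enumerate(rx.reactant_counts):
        if r == 1:
            expr *= xsyms[i]
        elif r == 2:
            expr *= xsyms[i] * (xsyms[i] - 1) / 2
    return expr


def _expectation(expr: sp.Expr, xsyms: Sequence[sp.Symbol]) -> sp.Expr:
    """Replace every state monomial by the corresponding raw-moment symbol."""
    poly = sp.Poly(sp.expand(expr), *xsyms)
    total = sp.Integer(0)
    for exponents, coeff in poly.terms():
        if sum(exponents) == 0:
            total += coeff
        else:
            total += coeff * moment_symbol(tuple(exponents))
    return total


def derive_moment_odes(network: ReactionNetwork, max_order: int) -> MomentSystem:
    """Exact (pre-closure) raw-moment ODEs for all orders 1..max_order."""
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    n = network.n_species
    xsyms = [sp.Symbol(f"x{i}") for i in range(n)]
    props = [_propensity_expr(network, j, xsyms) for j in range(len(network.reactions))]
    changes = [rx.change for rx in network.reactions]
    indices = enumerate_moment_indices(n, 1, max_order)
    rhs: dict[tuple[int, ...], sp.Expr] = {}
    for idx in indices:
        mono = prod(x**e for x, e in zip(xsyms, idx))
        total = sp.Integer(0)
        for a_j, v_j in zip(props, changes):
            shifted = prod((x + v) ** e for x, v, e in zip(xsyms, v_j, idx))
            total += a_j * (shifted - mono)
        rhs[idx] = _expectation(total, xsyms)
    return MomentSystem(network=network, max_order=max_order, indices=indices, rhs=rhs)


def apply_zero_closure(system: MomentSystem, k: int | None = None) -> MomentSystem:
    """Close the hierarchy at order k by zeroing central moments of order > k."""
    k = system.max_order if k is None else k
    overhang = system.overhang_indices()
    if any(sum(idx) > k + 1 for idx in overhang):
        raise ModelError(
            "rhs contains moments of order > k+1; propensities exceed the "
            "mass-action degree bound"
        )
    if not overhang:
        return MomentSystem(
            network=system.network,
            max_order=system.max_order,
            indices=list(system.indices),
            rhs=dict(system.rhs),
            closed=True,
        )
    subs = {
        moment_symbol(idx): closed_raw_moment(idx, k, moment_symbol) for idx in overhang
    }
    rhs = {idx: expr.xreplace(subs) for idx, expr in system.rhs.items()}
    return MomentSystem(
        network=system.network,
        max_order=system.max_order,
        indices=list(system.indices),
        rhs=rhs,
        closed=True,
    )


def closed_moment_system(network: ReactionNetwork, max_order: int) -> MomentSystem:
    """Derive and close in one step."""
    return apply_zero_closure(derive_moment_odes(network, max_order))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class MomentTrajectory:
    """Raw-moment values on a time grid; columns follow ``indices``."""

    times: np.ndarray
    values: np.ndarray  # (len(times), len(indices))
    indices: list[tuple[int, ...]]

    def column(self, index: Sequence[int]) -> np.ndarray:
        idx = tuple(index)
        try:
            col = self.indices.index(idx)
        except ValueError:
            raise KeyError(f"moment index {idx} not in trajectory") from None
        return self.values[:, col]

    def at(self, time: float) -> dict[tuple[int, ...], float]:
        where = np.flatnonzero(np.isclose(self.times, time))
        if where.size == 0:
            raise KeyError(f"time {time} not on trajectory grid")
        row = self.values[where[0]]
        return dict(zip(self.indices, row))


def initial_moments(indices: Sequence[tuple[int, ...]], initial_state: Sequence[int]) -> np.ndarray:
    """Moments of the point mass at ``initial_state``: E[X^a](0) = x0^a."""
    x0 = np.asarray(initial_state, dtype=float)
    return np.array([prod(x**e for x, e in zip(x0, idx)) for idx in indices])


def _solve(rhs, y0, times, rtol, atol, what):
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    t0 = min(0.0, times[0])
    if times[-1] == t0:
        return np.tile(y0, (len(times), 1))
    sol = solve_ivp(
        rhs,
        (t0, times[-1]),
        y0,
        method="RK45",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"{what}: {sol.message}")
    return sol.y.T


def integrate_moment_system(
    system: MomentSystem,
    theta: Mapping[str, float] | ParameterVector,
    times: Sequence[float],
    initial_state: Sequence[int] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> MomentTrajectory:
    """Integrate a closed moment system with RK45 and report at ``times``."""
    if not system.closed and system.overhang_indices():
        raise ModelError("moment system must be closed before integration")
    if isinstance(theta, ParameterVector):
        values = theta.require(system.network.parameter_names)
    else:
        values = {p: float(theta[p]) for p in system.network.parameter_names}
    pvec = np.array([values[p] for p in system.network.parameter_names])
    fn = system.rhs_function()
    x0 = system.network.initial_state if initial_state is None else initial_state
    y0 = initial_moments(system.indices, x0)
    values_t = _solve(
        lambda t, y: fn(y, pvec), y0, times, rtol, atol, "moment system integration"
    )
    return MomentTrajectory(
        times=np.asarray(times, dtype=float), values=values_t, indices=list(system.indices)
    )
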