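"""Hybrid conditional-moment engine.

Low-copy species (promoter/gene states) are tracked by a small master
equation over their reachable configurations ("modes"); high-copy species
are tracked by moments conditioned on the mode.  The integrated state holds
partial moments  Z[h, a] = E[Xhigh^a | mode h] * p(h)  rather than
conditional moments, so the system stays an ODE system even while a mode
probability is zero.  Conditional zero closure introduces terms of the form
(product of partial moments) / p^(d-1); denominators are guarded by
max(p, truncation_threshold), which realises mode truncation without ever
freezing inflow into an empty mode.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from math import prod
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

from .moments import (
    MomentTrajectory,
    _index_label,
    _solve,
    closed_raw_moment,
    enumerate_moment_indices,
)
from .network import ModelError, ParameterVector, ReactionNetwork

__all__ = [
    "ModeSpace",
    "HybridMomentSystem",
    "HybridTrajectory",
    "enumerate_modes",
    "derive_hybrid_system",
    "integrate_hybrid_system",
    "reconstruct_unconditional_moments",
]


@dataclass
class ModeSpace:
    """Reachable low-copy configurations and per-reaction mode jumps."""

    low_species: tuple[int, ...]
    high_species: tuple[int, ...]
    modes: list[tuple[int, ...]]
    mode_change: list[tuple[int, ...]]  # per reaction, low subvector of v_j

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def mode_index(self, mode: Sequence[int]) -> int:
        return self.modes.index(tuple(mode))


def enumerate_modes(
    network: ReactionNetwork,
    low_species: Sequence[int] | None = None,
    initial_state: Sequence[int] | None = None,
    cap: int = 1024,
) -> ModeSpace:
    """Breadth-first reachability over the low-copy subvector."""
    low = tuple(low_species) if low_species is not None else network.low_species
    if not low:
        raise ModelError("no low-copy species to build a mode space from")
    high = tuple(i for i in range(network.n_species) if i not in low)
    x0 = network.initial_state if initial_state is None else tuple(initial_state)
    start = tuple(x0[i] for i in low)
    jumps = []
    for rx in network.reactions:
        jumps.append(
            (
                tuple(rx.change[i] for i in low),
                tuple(rx.reactant_change[i] for i in low),
            )
        )
    seen = {start}
    queue = deque([start])
    while queue:
        mode = queue.popleft()
        for change, consumed in jumps:
            if all(c == 0 for c in change):
                continue
            if any(m + cs < 0 for m, cs in zip(mode, consumed)):
                continue
            nxt = tuple(m + c for m, c in zip(mode, change))
            if any(v < 0 for v in nxt):
                continue
            if nxt not in seen:
                if len(seen) >= cap:
                    raise ModelError(
                        f"more than {cap} reachable modes; are the low-copy "
                        "species classified correctly?"
                    )
                seen.add(nxt)
                queue.append(nxt)
    modes = sorted(seen)
    # keep the initial mode first for readability of listings
    modes.remove(start)
    modes.insert(0, start)
    return ModeSpace(
        low_species=low,
        high_species=high,
        modes=modes,
        mode_change=[c for c, _ in jumps],
    )


def _p_symbol(h: int) -> sp.Symbol:
    return sp.Symbol(f"P_{h}")


def _pd_symbol(h: int) -> sp.Symbol:
    """Guarded (floored) mode probability used only in denominators."""
    return sp.Symbol(f"Pd_{h}")


def _z_symbol(h: int, idx: Sequence[int]) -> sp.Symbol:
    return sp.Symbol(f"Z_{h}__" + "_".join(str(e) for e in idx))


@dataclass
class HybridMomentSystem:
    """Mode-probability + partial-moment ODEs, closed at ``max_order``.

    State layout: all mode probabilities first, then per mode the partial
    moments over the high-copy species in graded-lex order.
    """

    network: ReactionNetwork
    mode_space: ModeSpace
    max_order: int
    indices: list[tuple[int, ...]]  # over high species, orders 1..max_order
    rhs: list[sp.Expr]  # aligned with state layout
    truncation_threshold: float = 1e-12
    _rhs_fn: Callable | None = field(default=None, repr=False, compare=False)

    @property
    def n_modes(self) -> int:
        return self.mode_space.n_modes

    @property
    def n_equations(self) -> int:
        return len(self.rhs)

    @property
    def partial_equations_per_mode(self) -> int:
        return len(self.indices)

    def state_symbols(self) -> list[sp.Symbol]:
        syms = [_p_symbol(h) for h in range(self.n_modes)]
        for h in range(self.n_modes):
            syms.extend(_z_symbol(h, idx) for idx in self.indices)
        return syms

    def _labels(self) -> list[str]:
        high_names = [self.network.species_names[i] for i in self.mode_space.high_species]
        labels = []
        for h in range(self.n_modes):
            labels.append(f"p{self.mode_space.modes[h]}")
        for h in range(self.n_modes):
            mode = self.mode_space.modes[h]
            for idx in self.indices:
                inner = _index_label(idx, high_names)[2:-1]
                labels.append(f"E[{inner}|{mode}]*p{mode}")
        return labels

    def to_text(self) -> str:
        labels = self._labels()
        subs = dict(zip(self.state_symbols(), (sp.Symbol(lb) for lb in labels)))
        subs.update(
            {_pd_symbol(h): sp.Symbol(f"p{self.mode_space.modes[h]}") for h in range(self.n_modes)}
        )
        return "\n".join(
            f"d/dt {lb} = {expr.xreplace(subs)}" for lb, expr in zip(labels, self.rhs)
        )

    def rhs_function(self) -> Callable:
        """Compiled rhs f(state, pd, params) -> dstate."""
        if self._rhs_fn is None:
            from ._polyrhs import compile_poly_system

            state = self.state_symbols()
            pd = [_pd_symbol(h) for h in range(self.n_modes)]
            psyms = [sp.Symbol(p) for p in self.network.parameter_names]
            core = compile_poly_system(self.rhs, [*state, *pd, *psyms])
            n_s, n_pd = len(state), len(pd)
            n_v = n_s + n_pd + len(psyms)

            def fn(y: np.ndarray, pdv: np.ndarray, p: np.ndarray) -> np.ndarray:
                varvals = np.empty(n_v)
                varvals[:n_s] = y
                varvals[n_s : n_s + n_pd] = pdv
                varvals[n_s + n_pd :] = p
                out = np.empty(n_s)
                core(varvals, out)
                return out

            self._rhs_fn = fn
        return self._rhs_fn


def derive_hybrid_system(
    network: ReactionNetwork,
    mode_space: ModeSpace | None = None,
    max_order: int = 2,
    truncation_threshold: float = 1e-12,
) -> HybridMomentSystem:
    """Derive the closed hybrid system at conditional-moment order ``max_order``."""
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    ms = mode_space if mode_space is not None else enumerate_modes(network)
    low, high = ms.low_species, ms.high_species
    n_high = len(high)
    xt = [sp.Symbol(f"xt{i}") for i in range(n_high)]
    indices = enumerate_moment_indices(n_high, 1, max_order)
    mode_of = {m: h for h, m in enumerate(ms.modes)}
    k = max_order

    # conditional propensity polynomials: propensity with the low-copy
    # symbols fixed at the mode values -> polynomial in the high-copy state
    xfull: list[sp.Expr] = [sp.Integer(0)] * network.n_species
    for pos, i in enumerate(high):
        xfull[i] = xt[pos]

    def cond_propensity(j: int, mode: tuple[int, ...]) -> sp.Expr:
        rx = network.reactions[j]
        expr: sp.Expr = sp.Symbol(rx.rate_parameter)
        vals = dict(zip(low, mode))
        for i, r in enumerate(rx.reactant_counts):
            xi = sp.Integer(vals[i]) if i in vals else xfull[i]
            if r == 1:
                expr *= xi
            elif r == 2:
                expr *= xi * (xi - 1) / 2
        return sp.expand(expr)

    def partial_expect(expr: sp.Expr, h: int) -> sp.Expr:
        """E[expr(Xhigh) ; mode=h] in partial-moment variables."""
        expr = sp.expand(expr)
        if expr == 0:
            return sp.Integer(0)
        poly = sp.Poly(expr, *xt) if n_high else None
        total = sp.Integer(0)
        if poly is None:
            return expr * _p_symbol(h)
        for exponents, coeff in poly.terms():
            order = sum(exponents)
            if order == 0:
                total += coeff * _p_symbol(h)
            elif order <= k:
                total += coeff * _z_symbol(h, exponents)
            else:
                cond = closed_raw_moment(
                    exponents,
                    k,
                    lambda d: _z_symbol(h, d) / _pd_symbol(h),
                )
                total += coeff * _p_symbol(h) * cond
        return total

    vtilde = [tuple(rx.change[i] for i in high) for rx in network.reactions]

    rhs: list[sp.Expr] = []
    targets: list[tuple[int, tuple[int, ...]]] = [
        (h, (0,) * n_high) for h in range(ms.n_modes)
    ]
    for h in range(ms.n_modes):
        targets.extend((h, idx) for idx in indices)
    for h, gamma in targets:
        mode = ms.modes[h]
        mono = prod(x**e for x, e in zip(xt, gamma)) if sum(gamma) else sp.Integer(1)
        expr = sp.Integer(0)
        for j in range(len(network.reactions)):
            vhat = ms.mode_change[j]
            # loss: reaction fires while in this mode
            expr -= partial_expect(cond_propensity(j, mode) * mono, h)
            # gain: reaction fires in the source mode and lands here
            src = tuple(m - c for m, c in zip(mode, vhat))
            if src in mode_of:
                shifted = (
                    prod((x + v) ** e for x, v, e in zip(xt, vtilde[j], gamma))
                    if sum(gamma)
                    else sp.Integer(1)
                )
                expr += partial_expect(cond_propensity(j, src) * shifted, mode_of[src])
        rhs.append(sp.together(expr))
    return HybridMomentSystem(
        network=network,
        mode_space=ms,
        max_order=max_order,
        indices=indices,
        rhs=rhs,
        truncation_threshold=truncation_threshold,
    )


@dataclass
class HybridTrajectory:
    """Mode probabilities and partial moments on a time grid."""

    times: np.ndarray
    mode_probs: np.ndarray  # (T, H)
    partial: np.ndarray  # (T, H, K)
    mode_space: ModeSpace
    indices: list[tuple[int, ...]]
    truncation_threshold: float = 1e-12

    def conditional_moments(self) -> np.ndarray:
        """(T, H, K) conditional moments; NaN where a mode is below threshold."""
        p = self.mode_probs[:, :, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = self.partial / p
        cond[np.broadcast_to(p < self.truncation_threshold, cond.shape)] = np.nan
        return cond


def integrate_hybrid_system(
    system: HybridMomentSystem,
    theta: Mapping[str, float] | ParameterVector,
    times: Sequence[float],
    initial_state: Sequence[int] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> HybridTrajectory:
    """Integrate the hybrid system; initial condition is a point mass."""
    network = system.network
    if isinstance(theta, ParameterVector):
        values = theta.require(network.parameter_names)
    else:
        values = {p: float(theta[p]) for p in network.parameter_names}
    pvec = np.array([values[p] for p in network.parameter_names])
    ms = system.mode_space
    x0 = network.initial_state if initial_state is None else tuple(initial_state)
    start_mode = tuple(x0[i] for i in ms.low_species)
    if start_mode not in ms.modes:
        raise ModelError("initial low-copy configuration is not an enumerated mode")
    h0 = ms.mode_index(start_mode)
    H, K = ms.n_modes, len(system.indices)
    y0 = np.zeros(H + H * K)
    y0[h0] = 1.0
    xt0 = [float(x0[i]) for i in ms.high_species]
    for kk, idx in enumerate(system.indices):
        y0[H + h0 * K + kk] = prod(x**e for x, e in zip(xt0, idx))
    fn = system.rhs_function()
    floor = system.truncation_threshold

    def rhs(t, y):
        pd = np.maximum(y[:H], floor)
        return fn(y, pd, pvec)

    values_t = _solve(rhs, y0, times, rtol, atol, "hybrid system integration")
    T = values_t.shape[0]
    return HybridTrajectory(
        times=np.asarray(times, dtype=float),
        mode_probs=values_t[:, :H],
        partial=values_t[:, H:].reshape(T, H, K),
        mode_space=ms,
        indices=list(system.indices),
        truncation_threshold=floor,
    )


def reconstruct_unconditional_moments(
    trajectory: HybridTrajectory,
    target_indices: Sequence[Sequence[int]],
) -> MomentTrajectory:
    """Unconditional raw moments E[X^a] = sum_h xhat_h^ahat * Z[h, ahigh].

    Works for any full-species multi-index whose high-copy part has order at
    most the system's closure order; low-copy exponents only re-weight the
    mode values.
    """
    ms = trajectory.mode_space
    pos_of_high = {i: pos for pos, i in enumerate(ms.high_species)}
    pos_of_low = {i: pos for pos, i in enumerate(ms.low_species)}
    T = trajectory.times.shape[0]
    out = np.zeros((T, len(target_indices)))
    for col, full_idx in enumerate(target_indices):
        full_idx = tuple(full_idx)
        high_part = [0] * len(ms.high_species)
        low_part = [0] * len(ms.low_species)
        for i, e in enumerate(full_idx):
            if e == 0:
                continue
            if i in pos_of_high:
                high_part[pos_of_high[i]] = e
            else:
                low_part[pos_of_low[i]] = e
        high_part = tuple(high_part)
        if sum(high_part) == 0:
            weights_src = trajectory.mode_probs  # (T, H)
        else:
            try:
                kk = trajectory.indices.index(high_part)
            except ValueError:
                raise KeyError(
                    f"high-copy moment {high_part} beyond the derived order"
                ) from None
            weights_src = trajectory.partial[:, :, kk]
        mode_w = np.array(
            [prod(m**e for m, e in zip(mode, low_part)) for mode in ms.modes],
            dtype=float,
        )
        out[:, col] = weights_src @ mode_w
    return MomentTrajectory(
        times=trajectory.times.copy(),
        values=out,
        indices=[tuple(i) for i in target_indices],
    )
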