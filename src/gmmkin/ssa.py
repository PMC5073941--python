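"""Exact stochastic simulation (Gillespie direct method) and snapshot data.

Snapshot datasets mimic flow-cytometry style population data: N independent
cells observed at each measurement time, with fresh simulation runs per time
point so that samples at different times are statistically independent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numba as nb
import numpy as np
import pandas as pd

from .network import ModelError, ParameterVector, ReactionNetwork

__all__ = [
    "SnapshotDataset",
    "SnapshotFormatError",
    "simulate_ssa",
    "sample_snapshots",
    "write_snapshots",
    "read_snapshots",
]


class SnapshotFormatError(ValueError):
    """Malformed snapshot table."""


@nb.njit(cache=False)
def _ssa_batch(x0, rates, rcount, change, t_end, seeds, out):  # pragma: no cover
    n_traj = seeds.shape[0]
    m = rates.shape[0]
    n = x0.shape[0]
    cum = np.empty(m, dtype=np.float64)
    for traj in range(n_traj):
        np.random.seed(seeds[traj])
        x = x0.copy()
        t = 0.0
        while True:
            total = 0.0
            for j in range(m):
                a = rates[j]
                if a > 0.0:
                    for i in range(n):
                        r = rcount[j, i]
                        if r == 1:
                            a *= x[i]
                        elif r == 2:
                            a *= x[i] * (x[i] - 1) * 0.5
                        if a == 0.0:
                            break
                total += a
                cum[j] = total
            if total <= 0.0:
                break
            t -= np.log(np.random.random()) / total
            if t > t_end:
                break
            u = np.random.random() * total
            j = 0
            while j < m - 1 and cum[j] < u:
                j += 1
            for i in range(n):
                x[i] += change[j, i]
        for i in range(n):
            out[traj, i] = x[i]


def _rate_vector(network: ReactionNetwork, theta) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        values = theta.require(network.parameter_names)
    else:
        values = {}
        for p in network.parameter_names:
            if p not in theta:
                raise ModelError(f"parameter {p!r} has no numeric value")
            values[p] = float(theta[p])
    return np.array([values[rx.rate_parameter] for rx in network.reactions], dtype=np.float64)


def _run_batch(network: ReactionNetwork, theta, t_end: float, seeds: np.ndarray) -> np.ndarray:
    rates = _rate_vector(network, theta)
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    x0 = np.array(network.initial_state, dtype=np.int64)
    out = np.empty((seeds.shape[0], x0.shape[0]), dtype=np.int64)
    _ssa_batch(
        x0,
        rates,
        network.reactant_count_matrix(),
        network.change_matrix(),
        float(t_end),
        seeds.astype(np.int64),
        out,
    )
    return out


def simulate_ssa(
    network: ReactionNetwork,
    theta: Mapping[str, float] | ParameterVector,
    t_end: float,
    seed: int,
) -> np.ndarray:
    """Exact sample of the state at ``t_end``; deterministic in ``seed``."""
    kernel_seed = np.random.SeedSequence(seed).generate_state(1, dtype=np.uint32)
    return _run_batch(network, theta, t_end, kernel_seed)[0]


@dataclass
class SnapshotDataset:
    """Population snapshots: counts[t, l, s] is sample l of species s at times[t]."""

    times: tuple[float, ...]
    species: tuple[str, ...]
    counts: np.ndarray  # shape (T, N, S), non-negative integers
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise SnapshotFormatError("counts must have shape (times, samples, species)")
        if self.counts.shape[0] != len(self.times):
            raise SnapshotFormatError("counts first axis must match number of times")
        if self.counts.shape[2] != len(self.species):
            raise SnapshotFormatError("counts last axis must match number of species")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise SnapshotFormatError("counts must be integers")
        if (self.counts < 0).any():
            raise SnapshotFormatError("counts must be non-negative")
        if len(self.times) != len(set(self.times)):
            raise SnapshotFormatError("duplicate observation times")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_at(self, time: float) -> np.ndarray:
        """(N, S) matrix of counts at one observation time."""
        for i, t in enumerate(self.times):
            if t == time:
                return self.counts[i]
        raise KeyError(f"no samples at time {time}")


def sample_snapshots(
    network: ReactionNetwork,
    theta: Mapping[str, float] | ParameterVector,
    times: Sequence[float],
    observed_species: Sequence[str],
    n_samples: int,
    seed: int,
) -> SnapshotDataset:
    """Draw N independent SSA samples of the observed species per time point.

    Each time point uses fresh, independent runs (never one trajectory
    observed twice).  Per-trajectory kernel seeds come from
    ``SeedSequence((seed, time_index))`` so that enlarging N extends the
    dataset and adding times never reshuffles existing trajectories.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    obs_idx = [network.species_index(s) for s in observed_species]
    blocks = []
    for t_idx, t in enumerate(times):
        seeds = np.random.SeedSequence((seed, t_idx)).generate_state(
            n_samples, dtype=np.uint32
        )
        states = _run_batch(network, theta, t, seeds)
        blocks.append(states[:, obs_idx])
    theta_vals = (
        theta.values if isinstance(theta, ParameterVector) else dict(theta)
    )
    prov = (
        f"species={','.join(network.species_names)}; "
        f"theta={ {k: theta_vals[k] for k in sorted(theta_vals)} }; "
        f"N={n_samples}"
    )
    return SnapshotDataset(
        times=tuple(float(t) for t in times),
        species=tuple(observed_species),
        counts=np.stack(blocks, axis=0),
        seed=seed,
        provenance=prov,
    )


def write_snapshots(dataset: SnapshotDataset, path: str | Path) -> None:
    """Write a dataset as a commented TSV (columns: time, sample_id, species...)."""
    path = Path(path)
    frames = []
    for t_idx, t in enumerate(dataset.times):
        df = pd.DataFrame(dataset.counts[t_idx], columns=list(dataset.species))
        df.insert(0, "sample_id", np.arange(dataset.n_samples))
        df.insert(0, "time", t)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    with path.open("w") as fh:
        if dataset.seed is not None:
            fh.write(f"# seed: {dataset.seed}\n")
        for line in dataset.provenance.splitlines():
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_snapshots(path: str | Path, network: ReactionNetwork | None = None) -> SnapshotDataset:
    """Read a dataset written by :func:`write_snapshots` (lossless round trip)."""
    path = Path(path)
    seed = None
    prov_lines = []
    body_lines = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("seed:"):
                    seed = int(stripped.split(":", 1)[1])
                else:
                    prov_lines.append(stripped)
            else:
                body_lines.append(line)
    try:
        table = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t")
    except pd.errors.ParserError as exc:
        raise SnapshotFormatError(f"malformed snapshot table: {exc}") from None
    for col in ("time", "sample_id"):
        if col not in table.columns:
            raise SnapshotFormatError(f"missing required column {col!r}")
    species = [c for c in table.columns if c not in ("time", "sample_id")]
    if not species:
        raise SnapshotFormatError("no species columns")
    if network is not None:
        known = set(network.species_names)
        unknown = [s for s in species if s not in known]
        if unknown:
            raise SnapshotFormatError(f"unknown species column(s): {unknown}")
    if table[species].isna().any().any():
        raise SnapshotFormatError("missing values in snapshot table")
    values = table[species].to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(values == np.floor(values)):
            raise SnapshotFormatError("non-integer counts in snapshot table")
        values = values.astype(np.int64)
    times = list(dict.fromkeys(table["time"].tolist()))
    blocks = []
    n_ref = None
    for t in times:
        block = values[table["time"].to_numpy() == t]
        if n_ref is None:
            n_ref = block.shape[0]
        elif block.shape[0] != n_ref:
            raise SnapshotFormatError("inconsistent number of samples across times")
        blocks.append(block)
    return SnapshotDataset(
        times=tuple(float(t) for t in times),
        species=tuple(species),
        counts=np.stack(blocks, axis=0),
        seed=seed,
        provenance="\n".join(prov_lines),
    )
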