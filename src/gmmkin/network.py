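"""Mass-action reaction networks over discrete molecular counts.

A network is a set of named species, a set of reactions given by split
stoichiometry (consumed / produced parts), and a table of rate parameters
that either carry a numeric value or only a bounding interval.  Propensities
are never user-supplied expressions: they are derived from the consumed
stoichiometry under mass-action kinetics (number of distinct reactant
combinations), which keeps every propensity a polynomial of degree <= 2 in
the state — the property the moment engines rely on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelError",
    "ModelParseError",
    "Species",
    "Reaction",
    "ParameterVector",
    "ReactionNetwork",
    "parse_network",
    "write_network",
    "builtin_model",
    "propensity",
    "BUILTIN_MODELS",
]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


class ModelError(ValueError):
    """Invalid network definition."""


class ModelParseError(ModelError):
    """Malformed model-definition document."""


@dataclass(frozen=True)
class Species:
    """A chemical species with a stable 0-based index.

    ``copy_class`` partitions species for the hybrid engine: ``"low"`` species
    span the discrete mode space, ``"high"`` species are treated by
    (conditional) moments.
    """

    name: str
    index: int
    copy_class: str = "high"

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise ModelError(f"invalid species name {self.name!r}")
        if self.copy_class not in ("low", "high"):
            raise ModelError(f"copy_class must be 'low' or 'high', got {self.copy_class!r}")


@dataclass(frozen=True)
class Reaction:
    """One reaction channel with split stoichiometry.

    ``reactant_change`` has only non-positive entries (molecules consumed),
    ``product_change`` only non-negative ones; their sum is the net change
    vector.  The total consumed count is limited to 2 (at most bimolecular
    mass action).
    """

    reactant_change: tuple[int, ...]
    product_change: tuple[int, ...]
    rate_parameter: str

    def __post_init__(self) -> None:
        if len(self.reactant_change) != len(self.product_change):
            raise ModelError("reactant/product change vectors differ in length")
        if any(r > 0 for r in self.reactant_change):
            raise ModelError("reactant_change must be non-positive")
        if any(p < 0 for p in self.product_change):
            raise ModelError("product_change must be non-negative")
        if self.order > 2:
            raise ModelError(
                "at most bimolecular mass-action reactions are supported "
                f"(total reactant count {self.order})"
            )
        if all(c == 0 for c in self.change):
            raise ModelError("reaction has a zero net change vector")
        if not _NAME_RE.match(self.rate_parameter):
            raise ModelError(f"invalid parameter name {self.rate_parameter!r}")

    @property
    def change(self) -> tuple[int, ...]:
        """Net change vector v = v- + v+."""
        return tuple(r + p for r, p in zip(self.reactant_change, self.product_change))

    @property
    def reactant_counts(self) -> tuple[int, ...]:
        """Molecules required of each species (|v-| entrywise)."""
        return tuple(-r for r in self.reactant_change)

    @property
    def order(self) -> int:
        return sum(-r for r in self.reactant_change)


@dataclass
class ParameterVector:
    """Rate-constant values and/or bounding intervals, keyed by name."""

    values: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo <= hi:
                raise ModelError(f"bounds for {name!r} are inverted: [{lo}, {hi}]")
        for name, v in self.values.items():
            if v < 0:
                raise ModelError(f"rate constant {name!r} is negative")
            if name in self.bounds:
                lo, hi = self.bounds[name]
                if not lo <= v <= hi:
                    raise ModelError(f"value of {name!r} ({v}) outside bounds [{lo}, {hi}]")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys([*self.values, *self.bounds]))

    def require(self, names: Iterable[str]) -> dict[str, float]:
        """Return a complete name->value mapping or raise ModelError."""
        out = {}
        for name in names:
            if name not in self.values:
                raise ModelError(f"parameter {name!r} has no numeric value")
            out[name] = self.values[name]
        return out

    def updated(self, values: Mapping[str, float]) -> "ParameterVector":
        merged = dict(self.values)
        merged.update(values)
        return ParameterVector(values=merged, bounds=dict(self.bounds))


@dataclass
class ReactionNetwork:
    """Species, reactions and parameters of one stochastic kinetic model."""

    species: list[Species]
    reactions: list[Reaction]
    initial_state: tuple[int, ...]
    parameters: ParameterVector = field(default_factory=ParameterVector)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError("duplicate species name")
        if [s.index for s in self.species] != list(range(len(self.species))):
            raise ModelError("species indices must be contiguous from 0")
        if not self.reactions:
            raise ModelError("network has no reactions")
        n = len(self.species)
        seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
        for rx in self.reactions:
            if len(rx.reactant_change) != n:
                raise ModelError("reaction stoichiometry length != number of species")
            key = (rx.reactant_change, rx.product_change)
            if key in seen:
                raise ModelError("duplicate reaction stoichiometry")
            seen.add(key)
        if len(self.initial_state) != n:
            raise ModelError("initial_state length != number of species")
        if any(x < 0 for x in self.initial_state):
            raise ModelError("initial_state must be non-negative")
        used = {rx.rate_parameter for rx in self.reactions}
        declared = set(self.parameters.names)
        if declared and not used <= declared:
            raise ModelError(f"undeclared rate parameter(s): {sorted(used - declared)}")
        if declared - used:
            raise ModelError(f"declared but unused parameter(s): {sorted(declared - used)}")
        if not declared:
            # parameters implicitly declared by reactions, all unknown, no bounds
            self.parameters = ParameterVector(bounds={p: (0.0, np.inf) for p in sorted(used)})

    # -- convenience views ------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rx in self.reactions:
            seen.setdefault(rx.rate_parameter)
        return tuple(seen)

    @property
    def low_species(self) -> tuple[int, ...]:
        return tuple(s.index for s in self.species if s.copy_class == "low")

    @property
    def high_species(self) -> tuple[int, ...]:
        return tuple(s.index for s in self.species if s.copy_class == "high")

    def species_index(self, name: str) -> int:
        for s in self.species:
            if s.name == name:
                return s.index
        raise ModelError(f"unknown species {name!r}")

    def reactant_count_matrix(self) -> np.ndarray:
        """(m, n) integer matrix of required reactant molecules."""
        return np.array([rx.reactant_counts for rx in self.reactions], dtype=np.int64)

    def change_matrix(self) -> np.ndarray:
        """(m, n) integer matrix of net change vectors."""
        return np.array([rx.change for rx in self.reactions], dtype=np.int64)

    def fingerprint(self) -> str:
        """Canonical text form, used as a cache key by the moment engines."""
        return write_network(self)


def propensity(
    network: ReactionNetwork,
    j: int,
    x: Sequence[int],
    theta: Mapping[str, float] | ParameterVector,
) -> float:
    """Mass-action propensity of reaction ``j`` in state ``x``.

    rate * product over reactant species of the number of distinct
    combinations: x_i for a single molecule, x_i*(x_i-1)/2 for a homodimer,
    x_i*x_k for two distinct reactants.  Zero whenever a required reactant
    is missing.
    """
    rx = network.reactions[j]
    if isinstance(theta, ParameterVector):
        rate = theta.require([rx.rate_parameter])[rx.rate_parameter]
    else:
        if rx.rate_parameter not in theta:
            raise ModelError(f"parameter {rx.rate_parameter!r} has no numeric value")
        rate = float(theta[rx.rate_parameter])
    a = rate
    for xi, r in zip(x, rx.reactant_counts):
        if r == 0:
            continue
        if xi < r:
            return 0.0
        if r == 1:
            a *= xi
        else:  # r == 2, homodimer combinations
            a *= xi * (xi - 1) / 2.0
    return a


# ---------------------------------------------------------------------------
# model-definition document
# ---------------------------------------------------------------------------
#
#   [species]
#   <name> <initial count> [low|high]          (copy_class defaults to high)
#
#   [reactions]
#   <side> -> <side> @ <parameter>             side: "0" or "c1 S1 + c2 S2"
#
#   [parameters]
#   <name> = <value>
#   <name> in [<lo>, <hi>]
#   <name> = <value> in [<lo>, <hi>]
#
# '#' starts a comment; unknown sections or malformed lines are rejected.


def _parse_side(text: str, index_of: Mapping[str, int], n: int, where: str) -> np.ndarray:
    counts = np.zeros(n, dtype=int)
    text = text.strip()
    if text == "0" or text == "":
        return counts
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            coef, name = 1, parts[0]
        elif len(parts) == 2:
            try:
                coef = int(parts[0])
            except ValueError:
                raise ModelParseError(f"bad stoichiometric coefficient in {where}: {term!r}")
            name = parts[1]
        else:
            raise ModelParseError(f"malformed reaction term in {where}: {term!r}")
        if name not in index_of:
            raise ModelParseError(f"unknown species {name!r} in {where}")
        if coef < 1:
            raise ModelParseError(f"non-positive coefficient in {where}: {term!r}")
        counts[index_of[name]] += coef
    return counts


_PARAM_RE = re.compile(
    r"^(?P<name>[A-Za-z_][A-Za-z0-9_.]*)\s*"
    r"(?:=\s*(?P<value>[-+0-9.eE]+)\s*)?"
    r"(?:in\s*\[\s*(?P<lo>[-+0-9.eE]+)\s*,\s*(?P<hi>[-+0-9.eE]+)\s*\])?$"
)


def parse_network(config_text: str) -> ReactionNetwork:
    """Parse a model-definition document into a :class:`ReactionNetwork`."""
    species: list[Species] = []
    initial: list[int] = []
    raw_reactions: list[tuple[str, str, str]] = []
    values: dict[str, float] = {}
    bounds: dict[str, tuple[float, float]] = {}
    section = None
    for lineno, raw in enumerate(config_text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("species", "reactions", "parameters"):
                raise ModelParseError(f"line {lineno}: unknown section [{section}]")
            continue
        if section is None:
            raise ModelParseError(f"line {lineno}: content before any section header")
        if section == "species":
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ModelParseError(f"line {lineno}: expected '<name> <count> [low|high]'")
            name = parts[0]
            if any(s.name == name for s in species):
                raise ModelParseError(f"line {lineno}: duplicate species name {name!r}")
            try:
                count = int(parts[1])
            except ValueError:
                raise ModelParseError(f"line {lineno}: bad initial count {parts[1]!r}")
            copy_class = parts[2] if len(parts) == 3 else "high"
            if copy_class not in ("low", "high"):
                raise ModelParseError(f"line {lineno}: bad copy class {copy_class!r}")
            species.append(Species(name, len(species), copy_class))
            initial.append(count)
        elif section == "reactions":
            if "->" not in line or "@" not in line:
                raise ModelParseError(f"line {lineno}: expected '<side> -> <side> @ <param>'")
            body, param = line.rsplit("@", 1)
            lhs, rhs = body.split("->", 1)
            raw_reactions.append((lhs, rhs, param.strip()))
        else:  # parameters
            m = _PARAM_RE.match(line)
            if not m or (m.group("value") is None and m.group("lo") is None):
                raise ModelParseError(f"line {lineno}: malformed parameter line {line!r}")
            name = m.group("name")
            if name in values or name in bounds:
                raise ModelParseError(f"line {lineno}: duplicate parameter {name!r}")
            if m.group("value") is not None:
                values[name] = float(m.group("value"))
            if m.group("lo") is not None:
                bounds[name] = (float(m.group("lo")), float(m.group("hi")))

    index_of = {s.name: s.index for s in species}
    n = len(species)
    reactions = []
    for lhs, rhs, param in raw_reactions:
        consumed = _parse_side(lhs, index_of, n, f"reaction {lhs.strip()} -> {rhs.strip()}")
        produced = _parse_side(rhs, index_of, n, f"reaction {lhs.strip()} -> {rhs.strip()}")
        reactions.append(
            Reaction(
                reactant_change=tuple(int(-c) for c in consumed),
                product_change=tuple(int(c) for c in produced),
                rate_parameter=param,
            )
        )
    try:
        return ReactionNetwork(
            species=species,
            reactions=reactions,
            initial_state=tuple(initial),
            parameters=ParameterVector(values=values, bounds=bounds),
        )
    except ModelError as exc:
        raise type(exc)(str(exc)) from None


def _format_side(counts: Sequence[int], names: Sequence[str]) -> str:
    terms = []
    for c, name in zip(counts, names):
        if c == 0:
            continue
        terms.append(name if c == 1 else f"{c} {name}")
    return " + ".join(terms) if terms else "0"


def write_network(network: ReactionNetwork) -> str:
    """Serialize to the model-definition format; round-trips bit-identically."""
    lines = ["[species]"]
    for s, x0 in zip(network.species, network.initial_state):
        lines.append(f"{s.name} {x0} {s.copy_class}")
    lines.append("")
    lines.append("[reactions]")
    names = network.species_names
    for rx in network.reactions:
        lhs = _format_side(rx.reactant_counts, names)
        rhs = _format_side(rx.product_change, names)
        lines.append(f"{lhs} -> {rhs} @ {rx.rate_parameter}")
    lines.append("")
    lines.append("[parameters]")
    pv = network.parameters
    for name in sorted(pv.names):
        part = name
        if name in pv.values:
            part += f" = {pv.values[name]!r}"
        if name in pv.bounds:
            lo, hi = pv.bounds[name]
            part += f" in [{lo!r}, {hi!r}]"
        lines.append(part)
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# builtin fixture models
# ---------------------------------------------------------------------------

_GENE_EXPRESSION = """\
[species]
DNA_ON 0 low
DNA_OFF 1 low
mRNA 10 high

[reactions]
DNA_ON -> DNA_OFF @ b
DNA_OFF -> DNA_ON @ a
DNA_ON -> DNA_ON + mRNA @ c

[parameters]
a in [0.0, 0.5]
b in [0.0, 0.5]
c in [0.0, 0.5]
"""

_EXCLUSIVE_SWITCH = """\
[species]
DNA 1 low
DNA.P1 0 low
DNA.P2 0 low
P1 0 high
P2 0 high

[reactions]
DNA -> DNA + P1 @ p1
DNA.P1 -> DNA.P1 + P1 @ p1
P1 -> 0 @ d1
DNA + P1 -> DNA.P1 @ b1
DNA.P1 -> DNA + P1 @ u1
DNA -> DNA + P2 @ p2
DNA.P2 -> DNA.P2 + P2 @ p2
P2 -> 0 @ d2
DNA + P2 -> DNA.P2 @ b2
DNA.P2 -> DNA + P2 @ u2

[parameters]
p1 in [0.5, 1.5]
p2 in [0.5, 1.5]
d1 in [0.0, 0.05]
d2 in [0.0, 0.05]
b1 in [0.0, 0.1]
b2 in [0.0, 0.1]
u1 in [0.0, 0.1]
u2 in [0.0, 0.1]
"""

BUILTIN_MODELS: dict[str, str] = {
    "gene_expression": _GENE_EXPRESSION,
    "exclusive_switch": _EXCLUSIVE_SWITCH,
}

#: documented "truth" values used by the replication harness; the promoter
#: binding study fixes d1, d2 and estimates the remaining six parameters.
FIXTURE_TRUTH: dict[str, dict[str, float]] = {
    "gene_expression": {"a": 0.3, "b": 0.2, "c": 0.4},
    "exclusive_switch": {
        "p1": 1.0, "p2": 1.0, "d1": 0.02, "d2": 0.02,
        "b1": 0.05, "b2": 0.05, "u1": 0.05, "u2": 0.05,
    },
}


def builtin_model(name: str) -> ReactionNetwork:
    """Return one of the two bundled fixture networks.

    ``gene_expression``: a two-state promoter producing mRNA (3 species,
    3 reactions, parameters a, b, c all bounded by [0, 0.5]); initial state
    has the promoter off and 10 mRNA molecules.

    ``exclusive_switch``: two proteins competing for one promoter site
    (5 species, 10 reactions, parameters p_i, d_i, b_i, u_i); initial state
    is a single free promoter and no protein.
    """
    try:
        text = BUILTIN_MODELS[name]
    except KeyError:
        raise ModelError(
            f"unknown builtin model {name!r}; available: {sorted(BUILTIN_MODELS)}"
        ) from None
    return parse_network(text)
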