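"""Signed directed interaction networks and the image-vector update rule.

A :class:`RegulatoryNetwork` is a list of named entities (cells or
molecules) plus signed edges: ``+1`` for a stimulator, ``-1`` for an
inhibitor. Dynamics are qualitative: given a :class:`SystemState` assigning
each entity a balanced-ternary value, :func:`image_vector` computes the
*image* — the preferred value of every entity on the next step, obtained by
pooling its stimulatory and inhibitory inputs and combining them with the
PASS operator. A state equal to its own image is a fixed point (steady
state) of the model.

File format: tab-separated edge list, one edge per row as
``source <TAB> sign <TAB> target`` with sign in ``{+, -, +1, 1, -1}``.
Comment lines start with ``#``; optional entity declarations
``@ <TAB> name <TAB> role`` pin the entity order and role tags.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .logic import LogicTables, default_logic_tables

__all__ = [
    "Interaction",
    "RegulatoryNetwork",
    "SystemState",
    "ImageVector",
    "image_vector",
    "image_batch",
    "read_network",
    "write_network",
]

_ROLES = ("cell", "molecule")


@dataclass(frozen=True)
class Interaction:
    """One signed edge: ``source`` stimulates (+1) or inhibits (-1) ``target``."""

    source: str
    target: str
    sign: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValidationError(
                f"interaction sign must be +1 or -1, got {self.sign!r} "
                f"({self.source} -> {self.target})"
            )


class RegulatoryNetwork:
    """An ordered set of entities plus signed interactions between them.

    Entity names must be unique, every edge endpoint must resolve, and a
    (source, target) pair may carry at most one edge — so the stimulator and
    inhibitor input lists of any node are automatically disjoint.
    """

    def __init__(
        self,
        entities: Sequence[str],
        interactions: Iterable[Interaction | tuple],
        roles: Mapping[str, str] | None = None,
    ) -> None:
        self.entities: tuple[str, ...] = tuple(str(e) for e in entities)
        if len(set(self.entities)) != len(self.entities):
            raise ValidationError("entity names must be unique")
        self._index = {name: k for k, name in enumerate(self.entities)}
        roles = dict(roles or {})
        for name, role in roles.items():
            if name not in self._index:
                raise ValidationError(f"role given for unknown entity {name!r}")
            if role not in _ROLES:
                raise ValidationError(f"unknown role {role!r} for {name!r}")
        self.roles: dict[str, str] = {
            name: roles.get(name, "molecule") for name in self.entities
        }

        edges: list[Interaction] = []
        seen: set[tuple[str, str]] = set()
        for item in interactions:
            if isinstance(item, Interaction):
                edge = item
            else:  # tuples read (source, sign, target[, note]) like the file rows
                source, sign, target, *note = item
                edge = Interaction(source, target, sign, note[0] if note else "")
            for endpoint in (edge.source, edge.target):
                if endpoint not in self._index:
                    raise ValidationError(
                        f"edge {edge.source} -> {edge.target} references "
                        f"undeclared entity {endpoint!r}"
                    )
            key = (edge.source, edge.target)
            if key in seen:
                raise ValidationError(f"duplicate edge {edge.source} -> {edge.target}")
            seen.add(key)
            edges.append(edge)
        self.interactions: tuple[Interaction, ...] = tuple(edges)

        n = len(self.entities)
        act = np.zeros((n, n), dtype=np.float32)  # act[j, i]: j stimulates i
        inh = np.zeros((n, n), dtype=np.float32)
        for edge in self.interactions:
            j, i = self._index[edge.source], self._index[edge.target]
            (act if edge.sign > 0 else inh)[j, i] = 1.0
        self.act_matrix = act
        self.inh_matrix = inh
        self.has_act = act.any(axis=0)
        self.has_inh = inh.any(axis=0)

    # -- queries ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.entities)

    def index(self, entity: str) -> int:
        try:
            return self._index[entity]
        except KeyError:
            raise ValidationError(f"unknown entity {entity!r}") from None

    def activators(self, target: str) -> tuple[str, ...]:
        i = self.index(target)
        return tuple(self.entities[j] for j in np.flatnonzero(self.act_matrix[:, i]))

    def inhibitors(self, target: str) -> tuple[str, ...]:
        i = self.index(target)
        return tuple(self.entities[j] for j in np.flatnonzero(self.inh_matrix[:, i]))

    def identity_hash(self) -> str:
        """Stable hash of the entity order and signed edge set."""
        h = hashlib.sha256()
        for name in self.entities:
            h.update(f"e:{name}:{self.roles[name]}\n".encode())
        for edge in sorted(self.interactions, key=lambda e: (e.source, e.target)):
            h.update(f"i:{edge.source}:{edge.sign:+d}:{edge.target}\n".encode())
        return h.hexdigest()[:16]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RegulatoryNetwork({self.n} entities, "
            f"{len(self.interactions)} interactions)"
        )


@dataclass(frozen=True)
class SystemState:
    """A full assignment of ternary values to the entities of a network."""

    values: tuple[int, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        vals = tuple(int(v) for v in self.values)
        if any(v not in (-1, 0, 1) for v in vals):
            raise ValidationError(f"state values must be in {{-1, 0, 1}}: {vals}")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_mapping(
        cls,
        network: RegulatoryNetwork,
        assignment: Mapping[str, int],
        default: int = 0,
        label: str | None = None,
    ) -> "SystemState":
        for name in assignment:
            network.index(name)  # raises on unknown entity
        return cls(
            tuple(assignment.get(name, default) for name in network.entities),
            label=label,
        )

    def as_dict(self, network: RegulatoryNetwork) -> dict[str, int]:
        if len(self.values) != network.n:
            raise ValidationError(
                f"state has {len(self.values)} values, network has {network.n} entities"
            )
        return dict(zip(network.entities, self.values))

    @property
    def array(self) -> np.ndarray:
        return np.array(self.values, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.values)


class ImageVector(SystemState):
    """The preferred next state of a system (same layout as a state)."""


def image_vector(
    state: SystemState,
    network: RegulatoryNetwork,
    tables: LogicTables | None = None,
) -> ImageVector:
    """Compute the image of ``state`` one entity at a time.

    Per entity: pooled stimulation and inhibition are combined with PASS
    when both input modes exist; a node with stimulators only takes the
    pooled stimulation, with inhibitors only the NOT of the pooled
    inhibition; a node with no inputs keeps its current value (inertial).
    """
    tables = tables if tables is not None else default_logic_tables()
    if len(state) != network.n:
        raise ValidationError(
            f"state has {len(state)} values, network has {network.n} entities"
        )
    out = []
    for i, name in enumerate(network.entities):
        acts = [state.values[network.index(s)] for s in network.activators(name)]
        inhs = [state.values[network.index(s)] for s in network.inhibitors(name)]
        if acts and inhs:
            out.append(tables.pass_(tables.aggregate(acts), tables.aggregate(inhs)))
        elif acts:
            out.append(tables.aggregate(acts))
        elif inhs:
            out.append(tables.not_(tables.aggregate(inhs)))
        else:
            out.append(state.values[i])
    return ImageVector(tuple(out))


def image_batch(
    states: np.ndarray,
    network: RegulatoryNetwork,
    tables: LogicTables | None = None,
) -> np.ndarray:
    """Vectorized image computation for a batch of states.

    ``states`` is an (M, N) integer array of ternary values; returns the
    (M, N) int8 array of images. Semantics are identical to
    :func:`image_vector` applied row by row.
    """
    tables = tables if tables is not None else default_logic_tables()
    S = np.asarray(states)
    if S.ndim != 2 or S.shape[1] != network.n:
        raise ValidationError(
            f"batch shape {S.shape} does not match network size {network.n}"
        )
    Sf = S.astype(np.float32, copy=False)
    act = np.sign(Sf @ network.act_matrix).astype(np.int8)
    inh = np.sign(Sf @ network.inh_matrix).astype(np.int8)
    passed = tables.array[act.astype(np.intp) + 1, inh.astype(np.intp) + 1]
    both = network.has_act & network.has_inh
    act_only = network.has_act & ~network.has_inh
    inh_only = ~network.has_act & network.has_inh
    img = np.where(
        both, passed, np.where(act_only, act, np.where(inh_only, -inh, S))
    )
    return img.astype(np.int8)


# -- file format ---------------------------------------------------------

_SIGN_TOKENS = {"+": 1, "+1": 1, "1": 1, "-": -1, "-1": -1}


def write_network(network: RegulatoryNetwork, path) -> None:
    """Write a network as a tab-separated edge list with entity declarations.

    Edge provenance notes are emitted as trailing ``#`` comments so the file
    doubles as human-readable documentation of the model's evidence base.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# glionet signed interaction network\n")
        fh.write("# source\tsign\ttarget\t# note\n")
        for name in network.entities:
            fh.write(f"@\t{name}\t{network.roles[name]}\n")
        for edge in network.interactions:
            sign = "+" if edge.sign > 0 else "-"
            line = f"{edge.source}\t{sign}\t{edge.target}"
            if edge.note:
                line += f"\t# {edge.note}"
            fh.write(line + "\n")


def read_network(path) -> RegulatoryNetwork:
    """Parse a tab-separated edge list written by :func:`write_network`.

    Entity declarations are optional; without them, entities are inferred
    from edge endpoints in order of first appearance (role "molecule").
    Malformed rows raise :class:`ValidationError` with the line number.
    """
    declared: list[str] = []
    roles: dict[str, str] = {}
    edges: list[Interaction] = []
    inferred: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip() == "@":
                if len(fields) < 2:
                    raise ValidationError(f"{path}:{lineno}: bad entity declaration")
                name = fields[1].strip()
                role = fields[2].strip() if len(fields) > 2 else "molecule"
                if name in roles:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate entity declaration {name!r}"
                    )
                declared.append(name)
                roles[name] = role
                continue
            note = ""
            if len(fields) > 3 and fields[3].lstrip().startswith("#"):
                note = fields[3].lstrip()[1:].strip()
                fields = fields[:3]
            if len(fields) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'source<TAB>sign<TAB>target', "
                    f"got {line!r}"
                )
            source, token, target = (f.strip() for f in fields)
            if token not in _SIGN_TOKENS:
                raise ValidationError(f"{path}:{lineno}: unknown sign token {token!r}")
            for endpoint in (source, target):
                if declared and endpoint not in roles:
                    raise ValidationError(
                        f"{path}:{lineno}: undeclared entity {endpoint!r}"
                    )
                if not declared and endpoint not in inferred:
                    inferred.append(endpoint)
            if any(e.source == source and e.target == target for e in edges):
                raise ValidationError(
                    f"{path}:{lineno}: duplicate edge {source} -> {target}"
                )
            edges.append(Interaction(source, target, _SIGN_TOKENS[token], note))
    entities = declared if declared else inferred
    return RegulatoryNetwork(entities, edges, roles=roles if declared else None)
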