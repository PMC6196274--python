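"""Exhaustive fixed-point enumeration and pass-table calibration.

A fixed point (steady state) is a state equal to its own image. For an
N-entity ternary network the state space holds 3**N states; enumeration
scans it exhaustively in lexicographic order (entity 0 most significant,
-1 < 0 < +1) in vectorized chunks, so memory stays bounded at N = 15
(~14.3 M states). Only point attractors are enumerated; limit cycles show
up downstream as non-convergent Monte-Carlo walks.

Because the PASS operator's truth table is only pinned down up to the
monotonicity/consistency constraints, :func:`calibrate_pass_operator`
searches the 25 admissible tables for those whose fixed-point set matches
a required list of signatures at a required total count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .errors import ResourceError, ValidationError
from .logic import LogicTables, default_logic_tables, iter_admissible_pass_tables
from .model import StateSignature
from .network import RegulatoryNetwork, SystemState, image_batch

__all__ = [
    "AttractorReport",
    "SignatureMatch",
    "enumerate_fixed_points",
    "match_signature",
    "calibrate_pass_operator",
    "CalibrationReport",
]

DEFAULT_SCAN_BUDGET = 16  # largest N scanned without an explicit override
DEFAULT_CHUNK_SIZE = 1 << 20


@dataclass(frozen=True)
class AttractorReport:
    """Result of an exhaustive fixed-point scan."""

    fixed_points: tuple[SystemState, ...]
    n_states_scanned: int
    network_hash: str
    tables_name: str

    def as_dicts(self, network: RegulatoryNetwork) -> list[dict[str, int]]:
        return [fp.as_dict(network) for fp in self.fixed_points]


def enumerate_fixed_points(
    network: RegulatoryNetwork,
    tables: LogicTables | None = None,
    *,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    scan_budget: int = DEFAULT_SCAN_BUDGET,
) -> AttractorReport:
    """Return every state with ``image(state) == state``, in lexicographic order.

    The scan is deterministic and chunked; ``chunk_size`` trades memory for
    speed. Networks larger than ``scan_budget`` entities raise
    :class:`ResourceError` rather than silently grinding through >3**16
    states.
    """
    tables = tables if tables is not None else default_logic_tables()
    n = network.n
    if n > scan_budget:
        raise ResourceError(
            f"{n} entities means 3^{n} = {3 ** n:,} states; raise scan_budget "
            f"and/or lower chunk_size to scan this network deliberately"
        )
    total = 3 ** n
    powers = 3 ** np.arange(n - 1, -1, -1, dtype=np.int64)
    found: list[SystemState] = []
    for start in range(0, total, chunk_size):
        idx = np.arange(start, min(start + chunk_size, total), dtype=np.int64)
        states = ((idx[:, None] // powers) % 3 - 1).astype(np.int8)
        img = image_batch(states, network, tables)
        hits = np.flatnonzero((img == states).all(axis=1))
        found.extend(SystemState(tuple(int(v) for v in states[h])) for h in hits)
    return AttractorReport(
        fixed_points=tuple(found),
        n_states_scanned=total,
        network_hash=network.identity_hash(),
        tables_name=tables.name,
    )


@dataclass(frozen=True)
class SignatureMatch:
    """Outcome of comparing a full state against a partial signature."""

    matched: bool
    mismatches: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.matched


def match_signature(
    state: SystemState,
    signature: StateSignature,
    network: RegulatoryNetwork,
) -> SignatureMatch:
    """True iff every entity constrained by ``signature`` agrees with ``state``."""
    if len(state) != network.n:
        raise ValidationError(
            f"state has {len(state)} values, network has {network.n} entities"
        )
    mismatches = []
    for entity, value in signature.items():
        if state.values[network.index(entity)] != value:
            mismatches.append(entity)
    return SignatureMatch(matched=not mismatches, mismatches=tuple(mismatches))


def _signature_fixed_completions(
    network: RegulatoryNetwork,
    signature: StateSignature,
    tables: LogicTables,
) -> list[SystemState]:
    """All fixed points matching ``signature``, found by completing its free entities.

    Exact: any fixed point matching the signature is one of its 3**k
    completions, so only those need checking (k = number of unconstrained
    entities; cheap whenever the signature is nearly full).
    """
    signature.validate_against(network)
    constrained = signature.as_dict()
    free = [name for name in network.entities if name not in constrained]
    base = np.array(
        [constrained.get(name, 0) for name in network.entities], dtype=np.int8
    )
    combos = np.array(list(product((-1, 0, 1), repeat=len(free))), dtype=np.int8)
    states = np.tile(base, (len(combos), 1))
    free_idx = [network.index(name) for name in free]
    if free_idx:
        states[:, free_idx] = combos
    img = image_batch(states, network, tables)
    hits = np.flatnonzero((img == states).all(axis=1))
    return [SystemState(tuple(int(v) for v in states[h])) for h in hits]


@dataclass(frozen=True)
class CalibrationReport:
    """Search result over admissible pass tables."""

    matching: tuple[LogicTables, ...]
    diagnostics: tuple[dict, ...] = field(default_factory=tuple)


def calibrate_pass_operator(
    network: RegulatoryNetwork,
    required: Sequence[StateSignature],
    target_count: int,
    *,
    candidates: Iterable[LogicTables] | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    scan_budget: int = DEFAULT_SCAN_BUDGET,
) -> CalibrationReport:
    """Find pass tables whose fixed-point set realises the required signatures.

    A table matches when (a) every signature in ``required`` is matched by at
    least one fixed point and (b) the total number of fixed points equals
    ``target_count``. Candidates failing (a) are rejected by the cheap
    signature-completion check; only survivors pay for a full scan. An empty
    result is a finding, not an error: per-candidate diagnostics record the
    reason each table was rejected.
    """
    if target_count < 0:
        raise ValidationError("target_count must be nonnegative")
    candidates = (
        list(candidates) if candidates is not None else list(iter_admissible_pass_tables())
    )
    matching: list[LogicTables] = []
    diagnostics: list[dict] = []
    for tables in candidates:
        entry: dict = {"tables": tables.name, "pass_table": tables.pass_table}
        missing = [
            sig.name
            for sig in required
            if not _signature_fixed_completions(network, sig, tables)
        ]
        if missing:
            entry["rejected"] = f"no fixed completion for {', '.join(missing)}"
            diagnostics.append(entry)
            continue
        report = enumerate_fixed_points(
            network, tables, chunk_size=chunk_size, scan_budget=scan_budget
        )
        entry["n_fixed_points"] = len(report.fixed_points)
        entry["fixed_points"] = report.as_dicts(network)
        if len(report.fixed_points) == target_count:
            matching.append(tables)
            entry["matched"] = True
        else:
            entry["rejected"] = (
                f"{len(report.fixed_points)} fixed points, wanted {target_count}"
            )
        diagnostics.append(entry)
    return CalibrationReport(matching=tuple(matching), diagnostics=tuple(diagnostics))
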