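"""Balanced-ternary value algebra for qualitative regulatory models.

Every variable of the model takes one of three discrete values:

* ``-1`` — below the typical healthy level,
* ``0``  — at the typical healthy level,
* ``+1`` — above the typical healthy level.

Three operators act on these values. Unary NOT is sign flip. The OR used to
pool the signals arriving on one side of a node (all stimulators, or all
inhibitors) is a majority-style aggregation: the sign of the arithmetic sum.
It is deliberately defined n-ary rather than as a fold of a binary operator,
because majority aggregation is not associative. The HIGH/LOW PASS operator
combines the pooled stimulatory signal ``a`` with the pooled inhibitory
signal ``i`` into the preferred next value of the target node; its truth
table is injectable via :class:`LogicTables` and defaults to ``sign(a - i)``
("the target rises when stimulation outweighs inhibition").

Admissible pass tables are constrained so that the three input cases of a
node (both sides present / stimulators only / inhibitors only) stay
mutually consistent: ``pass(a, 0) = a`` (an absent inhibitor side is
neutral), with ``pass`` nondecreasing in the stimulatory argument and
nonincreasing in the inhibitory one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "TERNARY_VALUES",
    "ternary_not",
    "aggregate_signals",
    "pass_operator",
    "state_space_size",
    "LogicTables",
    "default_logic_tables",
    "iter_admissible_pass_tables",
]

TERNARY_VALUES = (-1, 0, 1)


def _as_ternary(v, what: str = "value") -> int:
    try:
        iv = int(v)
    except (TypeError, ValueError):
        raise ValidationError(f"{what} {v!r} is not a ternary value") from None
    if iv != v or iv not in TERNARY_VALUES:
        raise ValidationError(f"{what} {v!r} is not in {{-1, 0, 1}}")
    return iv


def ternary_not(v: int) -> int:
    """NOT: map +1 to -1 and vice versa; 0 is its own negation."""
    return -_as_ternary(v)


def aggregate_signals(values: Iterable[int]) -> int:
    """Pool parallel signals of one mode of action into a single value.

    Returns the sign of the arithmetic sum, so the pooled signal is positive
    exactly when the raised inputs outnumber the lowered ones. An empty input
    pool contributes a neutral 0.
    """
    total = 0
    for v in values:
        total += _as_ternary(v)
    return (total > 0) - (total < 0)


def state_space_size(n: int) -> int:
    """Number of distinct states of an ``n``-variable ternary system (3**n)."""
    if int(n) != n or n < 0:
        raise ValidationError(f"entity count must be a nonnegative integer, got {n!r}")
    return 3 ** int(n)


def _rows_from(obj) -> tuple[tuple[int, int, int], ...]:
    rows = tuple(tuple(_as_ternary(v, "pass-table entry") for v in row) for row in obj)
    if len(rows) != 3 or any(len(r) != 3 for r in rows):
        raise ConfigurationError("pass table must be 3x3")
    return rows


@dataclass(frozen=True)
class LogicTables:
    """Injectable truth tables for the ternary operators.

    ``pass_table[a + 1][i + 1]`` holds the value of the PASS operator for a
    pooled stimulatory signal ``a`` and pooled inhibitory signal ``i``.
    ``or_mode`` names the aggregation rule (only ``"sum-sign"`` is defined);
    NOT is fixed to sign flip. Construction validates the consistency
    invariants, so every held table collapses the three input cases of a node
    into one formula and responds monotonically to its inputs.
    """

    pass_table: tuple[tuple[int, int, int], ...]
    name: str = "custom"
    or_mode: str = "sum-sign"

    def __post_init__(self) -> None:
        rows = _rows_from(self.pass_table)
        object.__setattr__(self, "pass_table", rows)
        if self.or_mode != "sum-sign":
            raise ConfigurationError(f"unknown or_mode {self.or_mode!r}")
        for a in TERNARY_VALUES:
            if rows[a + 1][1] != a:
                raise ConfigurationError(
                    f"pass({a}, 0) must equal {a} (activator-only consistency), "
                    f"got {rows[a + 1][1]}"
                )
        for i in TERNARY_VALUES:  # monotone nondecreasing in the stimulatory arg
            col = [rows[a + 1][i + 1] for a in TERNARY_VALUES]
            if not (col[0] <= col[1] <= col[2]):
                raise ConfigurationError(f"pass table not nondecreasing in a at i={i}")
        for a in TERNARY_VALUES:  # monotone nonincreasing in the inhibitory arg
            row = rows[a + 1]
            if not (row[0] >= row[1] >= row[2]):
                raise ConfigurationError(f"pass table not nonincreasing in i at a={a}")

    # -- operator access -------------------------------------------------

    def pass_(self, a: int, i: int) -> int:
        return self.pass_table[_as_ternary(a, "a") + 1][_as_ternary(i, "i") + 1]

    def not_(self, v: int) -> int:
        return ternary_not(v)

    def aggregate(self, values: Iterable[int]) -> int:
        return aggregate_signals(values)

    @cached_property
    def array(self) -> np.ndarray:
        """The pass table as a 3x3 int8 array indexed by ``[a + 1, i + 1]``."""
        return np.array(self.pass_table, dtype=np.int8)

    @property
    def is_odd(self) -> bool:
        """True when pass(-a, -i) == -pass(a, i) for all inputs.

        Odd tables force a sign-mirrored partner for every nonzero fixed
        point of a network whose every node has at least one input.
        """
        return all(
            self.pass_(-a, -i) == -self.pass_(a, i)
            for a in TERNARY_VALUES
            for i in TERNARY_VALUES
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"LogicTables({self.name})"


def pass_operator(a: int, i: int, tables: LogicTables | None = None) -> int:
    """HIGH/LOW PASS: combine pooled stimulation ``a`` with pooled inhibition ``i``."""
    tables = tables if tables is not None else default_logic_tables()
    return tables.pass_(a, i)


def default_logic_tables() -> LogicTables:
    """The sign-difference semantics: ``pass(a, i) = sign(a - i)``."""
    rows = tuple(
        tuple((a - i > 0) - (a - i < 0) for i in TERNARY_VALUES) for a in TERNARY_VALUES
    )
    return LogicTables(pass_table=rows, name="sign-difference")


def iter_admissible_pass_tables() -> Iterator[LogicTables]:
    """Enumerate every pass table satisfying the :class:`LogicTables` invariants.

    The middle column is pinned to ``pass(a, 0) = a``, leaving six free
    entries; monotonicity cuts the 3**6 raw combinations down to 25
    admissible tables (the sign-difference default among them). Order is
    deterministic (lexicographic in the free entries).
    """
    for free in itertools.product(TERNARY_VALUES, repeat=6):
        rows = tuple(
            (free[k], a, free[k + 3]) for k, a in enumerate(TERNARY_VALUES)
        )
        try:
            yield LogicTables(pass_table=rows, name=f"pass{free}")
        except ConfigurationError:
            continue
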