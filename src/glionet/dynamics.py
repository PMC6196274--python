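"""Asynchronous Monte-Carlo evolution and treatment simulation.

The update scheme is generalized asynchronous logical dynamics: at each
step, every entity whose current value differs from its image defines one
allowable transition, in which that entity alone moves a single step toward
its image (a -1 whose image is +1 passes through 0). The realized successor
is drawn uniformly at random. A state with no allowable transitions is a
fixed point and ends the walk.

Treatments are node shifts: each treated entity is displaced one level in
the treatment's direction (delta mode, with clipping at the ternary bounds)
or pinned to the mode value (set mode), applied instantaneously at the
start of a trial; the system then evolves freely. A trial succeeds when the
walk terminates in the goal signature (typical health). Repeating 1000
trials per batch over 10 seeded batches gives a success distribution per
strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .logic import LogicTables, default_logic_tables
from .model import StateSignature
from .network import RegulatoryNetwork, SystemState, image_batch, image_vector

__all__ = [
    "TreatmentSpec",
    "TrialConfig",
    "TrajectoryRecord",
    "TreatmentOutcome",
    "async_successors",
    "evolve_to_attractor",
    "apply_treatment",
    "run_treatment_trials",
    "standard_treatments",
]


@dataclass(frozen=True)
class TreatmentSpec:
    """A named intervention: entity -> mode in {-1 suppress, 0 untreated, +1 elevate}."""

    name: str
    shifts: tuple[tuple[str, int], ...]
    application: str = "delta"

    def __post_init__(self) -> None:
        if self.application not in ("delta", "set"):
            raise ValidationError(f"unknown application mode {self.application!r}")
        shifts = tuple((str(e), int(m)) for e, m in dict(self.shifts).items())
        for entity, mode in shifts:
            if mode not in (-1, 0, 1):
                raise ValidationError(f"shift mode {mode!r} for {entity!r}")
        object.__setattr__(self, "shifts", shifts)

    @classmethod
    def from_mapping(
        cls, name: str, shifts: Mapping[str, int], application: str = "delta"
    ) -> "TreatmentSpec":
        return cls(name, tuple(shifts.items()), application)

    def validate_against(self, network: RegulatoryNetwork) -> None:
        for entity, _ in self.shifts:
            network.index(entity)


def standard_treatments(application: str = "delta") -> dict[str, TreatmentSpec]:
    """The four candidate strategies against persistent neuroinflammation.

    GRB — glucocorticoid receptor blockade (suppress CORT signaling);
    IST — immunosuppressive therapy (suppress IL-1β, IL-6, TNF-α);
    BAA — broad-acting anti-inflammatory (IST plus microglial suppression);
    IST+GRB — combined cytokine and glucocorticoid suppression.
    """
    ist = {"IL1b": -1, "IL6": -1, "TNFa": -1}
    specs = {
        "GRB": {"CORT": -1},
        "IST": ist,
        "BAA": {**ist, "Microglia": -1},
        "IST+GRB": {**ist, "CORT": -1},
    }
    return {
        name: TreatmentSpec.from_mapping(name, shifts, application)
        for name, shifts in specs.items()
    }


@dataclass(frozen=True)
class TrialConfig:
    """Monte-Carlo protocol: trials per batch, batch count, step cap, base seed."""

    n_trials: int = 1000
    n_batches: int = 10
    max_steps: int = 10_000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trials, self.n_batches, self.max_steps) <= 0:
            raise ValidationError("n_trials, n_batches and max_steps must be positive")


@dataclass(frozen=True)
class TrajectoryRecord:
    """One random walk: start, terminal state (None if non-convergent), steps, seed."""

    start: SystemState
    terminal: SystemState | None
    steps: int
    seed: object

    @property
    def converged(self) -> bool:
        return self.terminal is not None


@dataclass(frozen=True)
class TreatmentOutcome:
    """Per-batch success fractions for one treatment strategy."""

    treatment: str
    batch_fractions: tuple[float, ...]
    n_trials: int
    n_nonconvergent: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.batch_fractions))

    @property
    def std(self) -> float:
        return float(np.std(self.batch_fractions, ddof=1)) if len(
            self.batch_fractions
        ) > 1 else 0.0

    @property
    def percent(self) -> float:
        return 100.0 * self.mean


class _Imager:
    """Precomputed single-state image evaluator (hot path of the random walk)."""

    def __init__(self, network: RegulatoryNetwork, tables: LogicTables) -> None:
        self.act = network.act_matrix
        self.inh = network.inh_matrix
        self.table = tables.array
        both = network.has_act & network.has_inh
        self.both = both
        self.act_only = network.has_act & ~network.has_inh
        self.inh_only = ~network.has_act & network.has_inh
        self.no_input = ~(network.has_act | network.has_inh)

    def image(self, x: np.ndarray) -> np.ndarray:
        a = np.sign(x @ self.act).astype(np.intp)
        i = np.sign(x @ self.inh).astype(np.intp)
        img = self.table[a + 1, i + 1].astype(np.float32)
        out = np.where(self.both, img, 0.0)
        out += np.where(self.act_only, a, 0)
        out -= np.where(self.inh_only, i, 0)
        out += np.where(self.no_input, x, 0.0)
        return out


def async_successors(
    state: SystemState,
    network: RegulatoryNetwork,
    tables: LogicTables | None = None,
) -> list[SystemState]:
    """All single-entity one-step moves toward the image; empty iff fixed point."""
    tables = tables if tables is not None else default_logic_tables()
    img = image_vector(state, network, tables)
    successors = []
    for k, (cur, pref) in enumerate(zip(state.values, img.values)):
        if pref != cur:
            step = 1 if pref > cur else -1
            vals = list(state.values)
            vals[k] = cur + step
            successors.append(SystemState(tuple(vals)))
    return successors


def evolve_to_attractor(
    state: SystemState,
    network: RegulatoryNetwork,
    tables: LogicTables | None = None,
    seed=0,
    max_steps: int = 10_000,
) -> TrajectoryRecord:
    """Random walk under the asynchronous scheme until a fixed point or step cap.

    Reproducible: the same (state, network, tables, seed) always yields the
    same trajectory. Non-convergence (limit cycle or cap) is a recorded
    outcome, not an exception.
    """
    tables = tables if tables is not None else default_logic_tables()
    if len(state) != network.n:
        raise ValidationError(
            f"state has {len(state)} values, network has {network.n} entities"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    imager = _Imager(network, tables)
    x = state.array.astype(np.float32)
    for step in range(max_steps + 1):
        img = imager.image(x)
        movable = np.flatnonzero(img != x)
        if movable.size == 0:
            terminal = SystemState(tuple(int(v) for v in x))
            return TrajectoryRecord(state, terminal, step, seed)
        if step == max_steps:
            break
        k = movable[rng.integers(movable.size)]
        x[k] += 1.0 if img[k] > x[k] else -1.0
    return TrajectoryRecord(state, None, max_steps, seed)


def apply_treatment(
    state: SystemState,
    treatment: TreatmentSpec,
    network: RegulatoryNetwork,
) -> SystemState:
    """Shift treated entities (delta: clipped one-step displacement; set: pin)."""
    treatment.validate_against(network)
    vals = list(state.values)
    for entity, mode in treatment.shifts:
        k = network.index(entity)
        if treatment.application == "delta":
            vals[k] = int(np.clip(vals[k] + mode, -1, 1))
        else:
            vals[k] = mode
    return SystemState(tuple(vals), label=state.label)


def run_treatment_trials(
    network: RegulatoryNetwork,
    tables: LogicTables | None,
    treatment: TreatmentSpec,
    start: SystemState,
    goal: StateSignature,
    config: TrialConfig = TrialConfig(),
) -> TreatmentOutcome:
    """Monte-Carlo estimate of a treatment's probability of restoring the goal.

    ``start`` must be a fixed point (the pathological steady state being
    treated). Each trial applies the shift once, evolves to an attractor,
    and scores success when the terminal state satisfies ``goal``. Per-trial
    seeds derive deterministically from (base seed, batch, trial), so any
    single trajectory can be replayed in isolation. Non-convergent trials
    count as failures and are tallied separately.
    """
    from .attractors import match_signature  # local import to avoid a cycle

    tables = tables if tables is not None else default_logic_tables()
    if image_vector(start, network, tables).values != start.values:
        raise ValidationError("start state is not a fixed point under these tables")
    goal.validate_against(network)
    goal_map = goal.as_dict()
    goal_idx = np.array([network.index(e) for e in goal_map], dtype=np.intp)
    goal_vals = np.array([goal_map[e] for e in goal_map], dtype=np.int8)

    perturbed = apply_treatment(start, treatment, network)
    fractions: list[float] = []
    nonconvergent = 0
    for batch in range(config.n_batches):
        successes = 0
        for trial in range(config.n_trials):
            seed = np.random.SeedSequence(
                (int(config.base_seed), int(batch), int(trial))
            )
            record = evolve_to_attractor(
                perturbed, network, tables, seed=seed, max_steps=config.max_steps
            )
            if record.terminal is None:
                nonconvergent += 1
                continue
            term = record.terminal.array
            if (term[goal_idx] == goal_vals).all():
                successes += 1
        fractions.append(successes / config.n_trials)
    return TreatmentOutcome(
        treatment=treatment.name,
        batch_fractions=tuple(fractions),
        n_trials=config.n_trials,
        n_nonconvergent=nonconvergent,
    )
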