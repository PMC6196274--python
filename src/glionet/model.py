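"""The literature-reconstructed neuroimmune signaling network.

Fifteen entities — 5 cell populations (microglia, astrocytes, neurons,
endothelial cells / blood-brain-barrier integrity, T cells) and 10 signaling
molecules (corticosterone, acetylcholine, CD200, IL-1β, IL-6, TNF-α, IL-4,
IGF-1, VEGF, BDNF) — linked by 50 signed edges, each annotated with a short
note on the physiological mechanism it encodes. Cell states mean: microglia
+1 activated / -1 dystrophic; astrocytes +1 reactive / -1 atrophic; neurons
+1 heightened cognitive activity / -1 dysfunction; endothelial +1 tightened
BBB / -1 leaky BBB; T cells +1 Th2 (anti-inflammatory) / -1 Th1
(pro-inflammatory) polarization.

Two homeostatic programs are of interest: SS0, typical health (every entity
at baseline), and SS1, self-sustaining neuroinflammation (glucocorticoid,
pro-inflammatory cytokines, VEGF and microglial activation high;
acetylcholine, neuronal function, BBB integrity, IL-4 and Th2 polarization
low). :func:`ss_signatures` returns both as partial signatures;
:func:`neuroinflammatory_state` returns the full SS1 fixed point.

The module also maps model entities to the 12 marker genes used when
aligning the model against cortical RNAseq profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

from .errors import ValidationError
from .network import RegulatoryNetwork, SystemState

__all__ = [
    "StateSignature",
    "MarkerMap",
    "default_network",
    "ss_signatures",
    "neuroinflammatory_state",
    "default_marker_map",
    "typical_health_state",
    "CELLS",
    "MOLECULES",
]

CELLS = ("Microglia", "Astrocytes", "Neurons", "Endothelial", "Tcells")
MOLECULES = (
    "CORT",
    "ACh",
    "CD200",
    "IL1b",
    "IL6",
    "TNFa",
    "IL4",
    "IGF1",
    "VEGF",
    "BDNF",
)

# (source, sign, target, mechanism note). Grouped by target.
_EDGES = (
    # Microglia: primed by glucocorticoids, self-amplified through the
    # pro-inflammatory cytokines they secrete, restrained by IL-4, neuronal
    # CD200 and cholinergic tone.
    ("CORT", +1, "Microglia", "exogenous glucocorticoids prime microglial activation"),
    ("IL1b", +1, "Microglia", "IL-1b both activates and is secreted by microglia"),
    ("IL6", +1, "Microglia", "IL-6 both activates and is secreted by microglia"),
    ("TNFa", +1, "Microglia", "TNF-a both activates and is secreted by microglia"),
    ("IL4", -1, "Microglia", "IL-4 reverses microglial inflammatory toxicity"),
    ("CD200", -1, "Microglia", "CD200 ligation keeps microglia quiescent"),
    ("ACh", -1, "Microglia", "cholinergic tone limits microglial cytokine release"),
    # Astrocytes: proliferate under pro-inflammatory cytokines and IL-4;
    # glucocorticoids block astrogliogenesis.
    ("IL1b", +1, "Astrocytes", "IL-1 drives reactive astrogliosis"),
    ("IL6", +1, "Astrocytes", "IL-6 induces astrocyte proliferation"),
    ("TNFa", +1, "Astrocytes", "TNF-a induces astrocyte proliferation"),
    ("IL4", +1, "Astrocytes", "IL-4 enhances astrocytic trophic output"),
    ("CORT", -1, "Astrocytes", "glucocorticoids block astrogliogenesis"),
    # Neurons: sustained by cholinergic signaling, growth factors and T-cell
    # support; impaired by pro-inflammatory cytokines and chronic stress.
    ("ACh", +1, "Neurons", "acetylcholine facilitates LTP, learning and memory"),
    ("BDNF", +1, "Neurons", "BDNF promotes synapse and dendritic spine formation"),
    ("VEGF", +1, "Neurons", "VEGF promotes proliferation of neuron precursors"),
    ("IGF1", +1, "Neurons", "IGF-1 supports memory, plasticity and neuron rescue"),
    ("Tcells", +1, "Neurons", "T-cell surveillance supports neurogenesis/cognition"),
    ("IL1b", -1, "Neurons", "IL-1b interferes with neurotrophin signaling"),
    ("IL6", -1, "Neurons", "elevated IL-6 impairs memory formation"),
    ("TNFa", -1, "Neurons", "TNF-a promotes neuronal apoptosis"),
    ("CORT", -1, "Neurons", "sustained glucocorticoid exposure impairs cognition"),
    # Endothelial cells / BBB integrity: tightened by IGF-1, loosened by
    # inflammation.
    ("IGF1", +1, "Endothelial", "IGF-1 reduces BBB permeability"),
    ("IL1b", -1, "Endothelial", "inflammation weakens endothelial tight junctions"),
    ("IL6", -1, "Endothelial", "inflammation weakens endothelial tight junctions"),
    ("TNFa", -1, "Endothelial", "inflammation weakens endothelial tight junctions"),
    # T cells: pro-inflammatory cytokines polarize toward Th1 (away from Th2).
    ("IL1b", -1, "Tcells", "IL-1b primes T cells toward a Th1 profile"),
    ("IL6", -1, "Tcells", "IL-6 primes T cells toward a Th1 profile"),
    ("TNFa", -1, "Tcells", "TNF-a primes T cells toward a Th1 profile"),
    # HPA axis: brain cytokines drive glucocorticoid release.
    ("IL1b", +1, "CORT", "IL-1b is an essential mediator of the HPA stress response"),
    ("IL6", +1, "CORT", "IL-6 induces an HPA stress response even without CRH"),
    ("TNFa", +1, "CORT", "central cytokines activate the HPA axis"),
    # Molecules secreted by cells.
    ("Neurons", +1, "ACh", "active neurons sustain cholinergic neurotransmission"),
    ("Neurons", +1, "CD200", "healthy neurons express CD200"),
    ("Astrocytes", +1, "CD200", "astrocytes express CD200"),
    ("Microglia", +1, "IL1b", "activated microglia secrete IL-1b"),
    ("Astrocytes", +1, "IL1b", "reactive astrocytes produce IL-1"),
    ("Endothelial", -1, "IL1b", "BBB disruption raises brain cytokine levels"),
    ("Microglia", +1, "IL6", "activated microglia secrete IL-6"),
    ("Astrocytes", +1, "IL6", "reactive astrocytes produce IL-6"),
    ("Endothelial", -1, "IL6", "BBB disruption raises brain cytokine levels"),
    ("Microglia", +1, "TNFa", "activated microglia secrete TNF-a"),
    ("Astrocytes", +1, "TNFa", "reactive astrocytes produce TNF-a"),
    ("Endothelial", -1, "TNFa", "BBB disruption raises brain cytokine levels"),
    ("Tcells", +1, "IL4", "Th2-polarized T cells produce IL-4"),
    ("Astrocytes", +1, "IGF1", "active astrocytes secrete IGF-1"),
    ("Astrocytes", +1, "VEGF", "astrocytes secrete VEGF"),
    ("IL1b", +1, "VEGF", "IL-1 signaling drives astrocytic VEGF secretion"),
    ("Neurons", +1, "BDNF", "neurons produce BDNF"),
    ("Astrocytes", +1, "BDNF", "active astrocytes secrete BDNF"),
    ("IL4", +1, "BDNF", "IL-4 enhances astrocytic BDNF secretion"),
)


def default_network() -> RegulatoryNetwork:
    """The 15-entity, 50-edge neuroimmune network."""
    roles = {name: "cell" for name in CELLS}
    roles.update({name: "molecule" for name in MOLECULES})
    return RegulatoryNetwork(CELLS + MOLECULES, _EDGES, roles=roles)


@dataclass(frozen=True)
class StateSignature:
    """A partial assignment of ternary values; unlisted entities are free."""

    name: str
    assignments: tuple[tuple[str, int], ...]

    @classmethod
    def from_mapping(cls, name: str, mapping: Mapping[str, int]) -> "StateSignature":
        return cls(name, tuple((k, int(v)) for k, v in mapping.items()))

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self.assignments)

    def as_dict(self) -> dict[str, int]:
        return dict(self.assignments)

    def __getitem__(self, entity: str) -> int:
        for name, value in self.assignments:
            if name == entity:
                return value
        raise KeyError(entity)

    def validate_against(self, network: RegulatoryNetwork) -> None:
        for name, value in self.assignments:
            network.index(name)
            if value not in (-1, 0, 1):
                raise ValidationError(f"signature value {value!r} for {name!r}")


_SS1_SIGNATURE = {
    "CORT": 1,
    "IL1b": 1,
    "IL6": 1,
    "TNFa": 1,
    "VEGF": 1,
    "Microglia": 1,
    "ACh": -1,
    "Neurons": -1,
    "Endothelial": -1,
    "IL4": -1,
    "Tcells": -1,
}

# Completion of the SS1 signature to a full fixed point. Forced for every
# admissible pass table that keeps the signature fixed: astrocytes balance
# cytokine drive against glucocorticoid suppression, hence IGF-1 at baseline;
# depressed neurons and absent Th2 support pull CD200 and BDNF down.
_SS1_COMPLETION = {"Astrocytes": 0, "IGF1": 0, "CD200": -1, "BDNF": -1}


def ss_signatures() -> tuple[StateSignature, StateSignature]:
    """The two homeostatic programs: (SS0 typical health, SS1 neuroinflammation).

    SS0 constrains every entity to baseline. SS1 constrains the 11 entities
    of the neuroinflammatory profile and leaves astrocytes, BDNF, IGF-1 and
    CD200 free.
    """
    ss0 = StateSignature.from_mapping("SS0", {name: 0 for name in CELLS + MOLECULES})
    ss1 = StateSignature.from_mapping("SS1", _SS1_SIGNATURE)
    return ss0, ss1


def neuroinflammatory_state(network: RegulatoryNetwork | None = None) -> SystemState:
    """The full SS1 fixed point of the default network."""
    network = network if network is not None else default_network()
    full = dict(_SS1_SIGNATURE)
    full.update(_SS1_COMPLETION)
    return SystemState.from_mapping(network, full, label="SS1")


def typical_health_state(network: RegulatoryNetwork | None = None) -> SystemState:
    """The all-baseline SS0 fixed point."""
    network = network if network is not None else default_network()
    return SystemState((0,) * network.n, label="SS0")


@dataclass(frozen=True)
class MarkerMap:
    """Model entity -> marker gene symbols measured for it.

    Aggregate entities contribute one test per constituent gene (microglial
    activation is read out through LIF, OSM and CCL2).
    """

    mapping: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        genes = [g for _, gs in self.mapping for g in gs]
        if len(set(genes)) != len(genes):
            raise ValidationError("gene symbols must be unique across the marker map")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[str, ...]]) -> "MarkerMap":
        return cls(tuple((k, tuple(v)) for k, v in mapping.items()))

    def validate_against(self, network: RegulatoryNetwork) -> None:
        for entity, _ in self.mapping:
            network.index(entity)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for _, gs in self.mapping for g in gs)

    @property
    def entities(self) -> tuple[str, ...]:
        return tuple(e for e, _ in self.mapping)

    def genes_for(self, entity: str) -> tuple[str, ...]:
        for name, gs in self.mapping:
            if name == entity:
                return gs
        raise KeyError(entity)

    def entity_of(self, gene: str) -> str:
        for name, gs in self.mapping:
            if gene in gs:
                return name
        raise KeyError(gene)

    def items(self) -> Iterator[tuple[str, tuple[str, ...]]]:
        return iter(self.mapping)


def default_marker_map() -> MarkerMap:
    """The 12 marker genes over 10 model entities used for RNAseq alignment."""
    m = MarkerMap.from_mapping(
        {
            "BDNF": ("BDNF",),
            "IGF1": ("IGF1",),
            "IL1b": ("IL1B",),
            "IL6": ("IL6",),
            "IL4": ("IL4",),
            "TNFa": ("TNF",),
            "CD200": ("CD200",),
            "VEGF": ("VEGFA",),
            "Astrocytes": ("GFAP",),
            "Microglia": ("LIF", "OSM", "CCL2"),
        }
    )
    m.validate_against(default_network())
    return m
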