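"""Synthetic cortical expression matrices with known ground truth.

The generator emulates the statistical structure the concordance analysis
assumes: normalized nonnegative counts with log-normal marginals, a
control-group correlation structure over the 12 marker genes (Gaussian
copula: one multivariate-normal draw on the log scale per sample), and
per-exposure-group mean shifts that are concordant — fully or partially —
with a predicted discrete state. Effect sizes are expressed in units of the
control standard deviation of each gene, applied with the sign the target
state predicts for the gene's owning entity; the concordance fraction κ
selects how many of the predicted-nonzero genes are actually shifted.

The default design mirrors the study layout this analysis is meant for:
a saline control plus three exposure groups of six animals each, where the
glucocorticoid-alone group shifts weakly and half-concordantly toward the
neuroinflammatory state while the organophosphate groups shift strongly and
fully concordantly toward it. What the generator deliberately does not
emulate: count discreteness, batch effects, covariates, and gene-specific
dispersion beyond a common coefficient of variation.

Everything is deterministic given (design, seed): the same design always
yields byte-identical CSV fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .concordance import CorrelationModel, ExpressionMatrix, read_expression, write_expression
from .model import default_marker_map, default_network, neuroinflammatory_state

__all__ = [
    "EffectSpec",
    "SynthDesign",
    "SynthTruth",
    "default_design",
    "generate_expression",
    "write_fixture",
    "read_fixture_truth",
    "replay_fixture",
    "DEFAULT_BASELINE_MEANS",
    "default_correlation",
]

# Baseline mean normalized counts per marker gene. Fixed once for the
# package: order-of-magnitude spread typical of normalized RNAseq counts
# (structural/abundant genes high, cytokines low).
DEFAULT_BASELINE_MEANS: dict[str, float] = {
    "BDNF": 2400.0,
    "IGF1": 1300.0,
    "IL1B": 160.0,
    "IL6": 90.0,
    "IL4": 40.0,
    "TNF": 130.0,
    "CD200": 3100.0,
    "VEGFA": 950.0,
    "GFAP": 5200.0,
    "LIF": 60.0,
    "OSM": 45.0,
    "CCL2": 210.0,
}

_INFLAMMATORY = ("IL1B", "IL6", "TNF", "LIF", "OSM", "CCL2")
_TROPHIC = ("BDNF", "IGF1", "CD200", "VEGFA", "IL4")


def default_correlation(genes: Sequence[str] | None = None) -> CorrelationModel:
    """Block correlation target for the control samples.

    Pro-inflammatory markers co-express at 0.5, trophic markers at 0.3, the
    astrocytic marker GFAP couples at 0.3 to the inflammatory block; the
    blocks are mutually uncorrelated. The matrix is positive definite.
    """
    genes = tuple(genes) if genes is not None else tuple(DEFAULT_BASELINE_MEANS)
    k = len(genes)
    rho = np.eye(k)
    idx = {g: i for i, g in enumerate(genes)}

    def couple(a: str, b: str, r: float) -> None:
        if a in idx and b in idx and a != b:
            rho[idx[a], idx[b]] = rho[idx[b], idx[a]] = r

    for i, a in enumerate(_INFLAMMATORY):
        for b in _INFLAMMATORY[i + 1:]:
            couple(a, b, 0.5)
    for i, a in enumerate(_TROPHIC):
        for b in _TROPHIC[i + 1:]:
            couple(a, b, 0.3)
    for a in _INFLAMMATORY:
        couple("GFAP", a, 0.3)
    return CorrelationModel(genes, rho)


@dataclass(frozen=True)
class EffectSpec:
    """One exposure group's shift: target state, effect size (control SD), κ."""

    target_state: tuple[tuple[str, int], ...]
    effect_size: float
    concordance: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "target_state", tuple((str(k), int(v)) for k, v in dict(self.target_state).items())
        )
        if self.effect_size < 0:
            raise ValidationError("effect size must be nonnegative")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValidationError("concordance fraction must lie in [0, 1]")

    @classmethod
    def toward(
        cls, state: Mapping[str, int], effect_size: float, concordance: float = 1.0
    ) -> "EffectSpec":
        return cls(tuple(state.items()), effect_size, concordance)


@dataclass(frozen=True)
class SynthDesign:
    """Full specification of one synthetic dataset."""

    n_per_group: int = 6
    groups: tuple[str, ...] = ("saline", "CORT", "DFP", "CORT+DFP")
    control_group: str = "saline"
    baseline_means: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_BASELINE_MEANS.items()
    )
    cv: float = 0.25
    correlation: tuple[tuple[float, ...], ...] | None = None  # None -> default blocks
    effects: tuple[tuple[str, EffectSpec], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 samples per group")
        if self.control_group not in self.groups:
            raise ValidationError("control group must be listed in groups")
        if self.cv <= 0:
            raise ValidationError("coefficient of variation must be positive")
        for group, _ in self.effects:
            if group not in self.groups:
                raise ValidationError(f"effect for unknown group {group!r}")
            if group == self.control_group:
                raise ValidationError("control group cannot carry an effect")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.baseline_means)

    def correlation_model(self) -> CorrelationModel:
        if self.correlation is None:
            return default_correlation(self.genes)
        m = np.array(self.correlation, dtype=float)
        model = CorrelationModel(self.genes, m)
        eigvals = np.linalg.eigvalsh(model.matrix)
        if eigvals.min() < -1e-10:
            raise ValidationError(
                f"correlation target not PSD (smallest eigenvalue {eigvals.min():.3e})"
            )
        return model

    def effect_for(self, group: str) -> EffectSpec | None:
        return dict(self.effects).get(group)

    # -- (de)serialization, used by fixtures and the CLI -----------------

    def to_dict(self) -> dict:
        return {
            "n_per_group": self.n_per_group,
            "groups": list(self.groups),
            "control_group": self.control_group,
            "baseline_means": [[g, m] for g, m in self.baseline_means],
            "cv": self.cv,
            "correlation": None
            if self.correlation is None
            else [list(row) for row in self.correlation],
            "effects": {
                g: {
                    "target_state": dict(e.target_state),
                    "effect_size": e.effect_size,
                    "concordance": e.concordance,
                }
                for g, e in self.effects
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SynthDesign":
        effects = tuple(
            (
                g,
                EffectSpec.toward(
                    spec["target_state"],
                    float(spec["effect_size"]),
                    float(spec.get("concordance", 1.0)),
                ),
            )
            for g, spec in payload.get("effects", {}).items()
        )
        corr = payload.get("correlation")
        return cls(
            n_per_group=int(payload.get("n_per_group", 6)),
            groups=tuple(payload.get("groups", ("saline",))),
            control_group=str(payload.get("control_group", "saline")),
            baseline_means=tuple(
                (g, float(m))
                for g, m in (
                    payload["baseline_means"].items()
                    if isinstance(payload["baseline_means"], Mapping)
                    else payload["baseline_means"]
                )
            ),
            cv=float(payload.get("cv", 0.25)),
            correlation=None
            if corr is None
            else tuple(tuple(float(x) for x in row) for row in corr),
            effects=effects,
            seed=int(payload.get("seed", 0)),
        )


def default_design(seed: int = 0) -> SynthDesign:
    """The study-layout design: saline + CORT + DFP + CORT+DFP, n = 6 each.

    Exposure effects point toward the neuroinflammatory fixed point:
    glucocorticoid priming alone is weak and half-concordant (0.5 SD,
    κ = 0.5); the organophosphate insult is strong and fully concordant
    (2 SD, κ = 1), slightly stronger with priming (2.5 SD).
    """
    net = default_network()
    ss1 = neuroinflammatory_state(net).as_dict(net)
    return SynthDesign(
        effects=(
            ("CORT", EffectSpec.toward(ss1, 0.5, 0.5)),
            ("DFP", EffectSpec.toward(ss1, 2.0, 1.0)),
            ("CORT+DFP", EffectSpec.toward(ss1, 2.5, 1.0)),
        ),
        seed=seed,
    )


@dataclass(frozen=True)
class SynthTruth:
    """Realized shifts: per group and gene, the applied direction and magnitude."""

    directions: pd.DataFrame  # groups x genes, in {-1, 0, 1}
    magnitudes: pd.DataFrame  # groups x genes, additive shift in count units
    design: SynthDesign
    seed: int


def generate_expression(design: SynthDesign) -> tuple[ExpressionMatrix, SynthTruth]:
    """Draw one synthetic dataset; fully determined by the design (incl. seed).

    Control-law samples are log-normal with the design's per-gene means and
    common CV; cross-gene dependence comes from a Gaussian copula whose
    log-scale correlation is the design target (the realized Pearson
    correlation of the counts approaches it for moderate CV). Exposure
    groups add ``effect_size x control SD x predicted sign`` to the genes
    selected by κ, then clip at zero.
    """
    rng = np.random.default_rng(design.seed)
    genes = design.genes
    means = np.array([m for _, m in design.baseline_means], dtype=float)
    if (means <= 0).any():
        raise ValidationError("baseline means must be positive")
    rho = design.correlation_model().matrix
    # log-normal parameters reproducing the requested mean and CV
    sigma2 = np.log1p(design.cv ** 2)
    sigma = np.sqrt(sigma2)
    mu = np.log(means) - sigma2 / 2.0
    # invert the lognormal attenuation so the count-scale Pearson correlation
    # matches the design target in expectation
    rho = np.log1p(rho * np.expm1(sigma2)) / sigma2
    np.fill_diagonal(rho, 1.0)
    eigvals, eigvecs = np.linalg.eigh(rho)
    root = eigvecs @ np.diag(np.sqrt(np.maximum(eigvals, 0.0))) @ eigvecs.T

    marker_map = default_marker_map()
    gene_entity = {}
    for entity, gs in marker_map.items():
        for g in gs:
            gene_entity[g] = entity

    columns: dict[str, np.ndarray] = {}
    sample_names: list[str] = []
    sample_groups: list[str] = []
    directions = pd.DataFrame(
        0, index=list(design.groups), columns=list(genes), dtype=int
    )
    magnitudes = pd.DataFrame(
        0.0, index=list(design.groups), columns=list(genes), dtype=float
    )
    control_sd = means * design.cv

    for group in design.groups:
        z = rng.standard_normal((design.n_per_group, len(genes))) @ root.T
        x = np.exp(mu + sigma * z)
        effect = design.effect_for(group)
        if effect is not None and effect.effect_size > 0:
            target = dict(effect.target_state)
            candidates = [
                k
                for k, g in enumerate(genes)
                if target.get(gene_entity.get(g, ""), 0) != 0
            ]
            n_shift = int(round(effect.concordance * len(candidates)))
            chosen = sorted(
                rng.choice(candidates, size=n_shift, replace=False).tolist()
            ) if n_shift else []
            for k in chosen:
                sign = target[gene_entity[genes[k]]]
                shift = effect.effect_size * control_sd[k] * sign
                x[:, k] = np.maximum(x[:, k] + shift, 0.0)
                directions.loc[group, genes[k]] = int(np.sign(sign))
                magnitudes.loc[group, genes[k]] = float(shift)
        for s in range(design.n_per_group):
            name = f"{group}_{s + 1}"
            sample_names.append(name)
            sample_groups.append(group)
            columns[name] = x[s]

    values = pd.DataFrame(columns, index=list(genes))
    data = ExpressionMatrix(
        values, pd.Series(sample_groups, index=sample_names), design.control_group
    )
    truth = SynthTruth(
        directions=directions, magnitudes=magnitudes, design=design, seed=design.seed
    )
    return data, truth


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(data: ExpressionMatrix, truth: SynthTruth, directory) -> dict[str, Path]:
    """Write expr.csv + groups.csv + truth.json into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expr.csv",
        "groups": directory / "groups.csv",
        "truth": directory / "truth.json",
    }
    write_expression(data, paths["expression"], paths["groups"])
    payload = {
        "seed": truth.seed,
        "design": truth.design.to_dict(),
        "directions": {g: truth.directions.loc[g].to_dict() for g in truth.directions.index},
        "magnitudes": {g: truth.magnitudes.loc[g].to_dict() for g in truth.magnitudes.index},
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths


def read_fixture_truth(path) -> SynthTruth:
    payload = json.loads(Path(path).read_text())
    design = SynthDesign.from_dict(payload["design"])
    directions = pd.DataFrame(payload["directions"]).T.loc[
        list(design.groups), list(design.genes)
    ]
    magnitudes = pd.DataFrame(payload["magnitudes"]).T.loc[
        list(design.groups), list(design.genes)
    ]
    return SynthTruth(
        directions=directions.astype(int),
        magnitudes=magnitudes.astype(float),
        design=design,
        seed=int(payload["seed"]),
    )


def replay_fixture(truth_path) -> tuple[ExpressionMatrix, SynthTruth]:
    """Regenerate the exact matrix a truth.json was written from."""
    truth = read_fixture_truth(truth_path)
    return generate_expression(truth.design)
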