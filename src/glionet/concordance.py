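"""Aligning expression profiles with model-predicted discrete states.

The alignment statistic asks: does the measured expression of the marker
genes agree with a predicted ternary profile? Per gene a directional
two-sample t-test compares an exposure group against control — right-tailed
when the model predicts +1, left-tailed for -1, and for a predicted 0 the
complement 1 - p_two-tail, the probability of observing the predicted
*absence* of change. Because the markers co-express, the per-gene p-values
are dependent; they are pooled with Brown's extension of Fisher's method:

    T0 = -2 * sum(ln p_i)                     (Fisher statistic)
    sigma^2 = 4N + 2 * sum_{i<j} cov_ij       (variance under dependence)
    cov_ij = rho(3.25 + 0.75 rho)  for rho >= 0
           = rho(3.27 + 0.71 rho)  for -0.5 <= rho < 0
    c = sigma^2 / 4N,   P = Pr[chi2_{2N/c} > T0 / c]

with rho the pairwise Pearson correlation of the markers estimated in
control samples. Small aggregate P means the profile aligns with the
predicted state. State-to-state aggregate P uses the fixed convention
p_i = 0.05 where the two states agree on a marker's entity and p_i = 1
where they disagree. A matrix of aggregate P values doubles as a distance
matrix and is projected to 2-D by Sammon's nonlinear mapping for
visualization; signed fold changes quantify the direction and magnitude of
each marker's response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import MarkerMap
from .network import RegulatoryNetwork, SystemState

__all__ = [
    "ExpressionMatrix",
    "CorrelationModel",
    "BrownResult",
    "EmbeddingResult",
    "directional_pvalue",
    "brown_covariance",
    "combine_pvalues_brown",
    "estimate_correlation",
    "state_alignment_pvalue",
    "state_state_pvalue",
    "profile_distance_matrix",
    "sammon_embed",
    "signed_fold_change",
    "fold_change_profile",
    "read_expression",
    "write_expression",
]

P_FLOOR = 1e-15  # clipping bounds: keep ln(p) finite
P_CEIL = 1.0 - 1e-15
STATE_AGREE_P = 0.05  # conventional floor for state-vs-state agreement


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized nonnegative expression values.

    ``values``: DataFrame indexed by gene symbol, one column per sample.
    ``groups``: Series mapping sample id -> group label (control + exposures).
    """

    values: pd.DataFrame
    groups: pd.Series
    control_group: str = "saline"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups)
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be nonnegative")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene symbols: {dup}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        counts = self.groups.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValidationError(
                f"each group needs >= 2 samples; too small: {dict(small)}"
            )
        if self.control_group not in set(self.groups):
            raise ValidationError(f"control group {self.control_group!r} absent")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def group_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def samples_of(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise ValidationError(f"unknown group {group!r}")
        return [s for s, g in self.groups.items() if g == group]

    def gene_values(self, gene: str, group: str) -> np.ndarray:
        if gene not in self.values.index:
            raise ValidationError(f"gene {gene!r} missing from expression matrix")
        return self.values.loc[gene, self.samples_of(group)].to_numpy(dtype=float)


@dataclass(frozen=True)
class CorrelationModel:
    """Pairwise Pearson correlations of the marker genes (control samples)."""

    genes: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        k = len(self.genes)
        if m.shape != (k, k):
            raise ValidationError(f"correlation matrix shape {m.shape} != ({k}, {k})")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(m)) > 1 + 1e-10:
            raise ValidationError("correlation entries must lie in [-1, 1]")

    def submatrix(self, genes: Sequence[str]) -> "CorrelationModel":
        idx = []
        for g in genes:
            if g not in self.genes:
                raise ValidationError(f"gene {g!r} absent from correlation model")
            idx.append(self.genes.index(g))
        return CorrelationModel(tuple(genes), self.matrix[np.ix_(idx, idx)])


def estimate_correlation(
    data: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    group: str | None = None,
) -> CorrelationModel:
    """Pairwise Pearson correlation across the samples of one group (default control)."""
    group = group if group is not None else data.control_group
    genes = tuple(genes) if genes is not None else data.genes
    block = np.vstack([data.gene_values(g, group) for g in genes])
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(block)
    rho = np.nan_to_num(rho, nan=0.0)  # constant gene -> undefined -> uncorrelated
    np.fill_diagonal(rho, 1.0)
    return CorrelationModel(genes, rho)


@dataclass(frozen=True)
class BrownResult:
    """Brown's dependent meta-analysis of one set of directional tests."""

    p_values: tuple[float, ...]
    t0: float
    sigma2: float
    c: float
    df: float
    p_combined: float

    @property
    def n(self) -> int:
        return len(self.p_values)


# ---------------------------------------------------------------------------
# per-gene directional tests


def _two_sample_t(treated, control, alternative: str, equal_var: bool) -> float:
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise ValidationError("each group needs >= 2 samples for a t-test")
    if treated.std(ddof=1) == 0.0 and control.std(ddof=1) == 0.0:
        # degenerate: both groups constant; decide by the means alone
        equal = treated.mean() == control.mean()
        if alternative == "two-sided":
            return 1.0 if equal else 0.0
        if equal:
            return 0.5
        higher = treated.mean() > control.mean()
        return 0.0 if (higher == (alternative == "greater")) else 1.0
    res = stats.ttest_ind(treated, control, equal_var=equal_var, alternative=alternative)
    return float(res.pvalue)


def directional_pvalue(
    treated,
    control,
    predicted: int,
    *,
    equal_var: bool = True,
) -> float:
    """P-value that the treated group realizes the predicted ternary direction.

    predicted +1: right-tailed (treated above control); -1: left-tailed;
    0: complement of the two-tailed p, i.e. the probability of the predicted
    *no change*. Pooled-variance Student's t by default (``equal_var=False``
    switches to Welch). The result is clipped away from 0 and 1 so its log
    stays finite downstream.
    """
    if predicted not in (-1, 0, 1):
        raise ValidationError(f"predicted value must be ternary, got {predicted!r}")
    if predicted == 1:
        p = _two_sample_t(treated, control, "greater", equal_var)
    elif predicted == -1:
        p = _two_sample_t(treated, control, "less", equal_var)
    else:
        p = 1.0 - _two_sample_t(treated, control, "two-sided", equal_var)
    return float(np.clip(p, P_FLOOR, P_CEIL))


# ---------------------------------------------------------------------------
# Brown's method


def brown_covariance(rho: float) -> float:
    """Covariance of -2 ln p_i and -2 ln p_j as a polynomial in their correlation.

    Defined piecewise on [-0.5, 1]; stronger negative correlations are
    clamped to -0.5 with a warning.
    """
    rho = float(rho)
    if not np.isfinite(rho):
        raise ValidationError(f"correlation must be finite, got {rho!r}")
    if rho > 1.0 + 1e-12:
        raise ValidationError(f"correlation must be <= 1, got {rho}")
    rho = min(rho, 1.0)
    if rho < -0.5:
        warnings.warn(
            f"correlation {rho:.3f} below -0.5 clamped to the domain edge",
            stacklevel=2,
        )
        rho = -0.5
    if rho >= 0:
        return rho * (3.25 + 0.75 * rho)
    return rho * (3.27 + 0.71 * rho)


def combine_pvalues_brown(
    p_values: Sequence[float],
    rho: CorrelationModel | np.ndarray,
) -> BrownResult:
    """Pool dependent p-values into one aggregate significance.

    With a diagonal correlation matrix this reduces exactly to Fisher's
    method (c = 1, df = 2N); for N = 1 the aggregate equals the single
    input p-value.
    """
    matrix = rho.matrix if isinstance(rho, CorrelationModel) else np.asarray(rho, float)
    p = np.clip(np.asarray(p_values, dtype=float), P_FLOOR, P_CEIL)
    n = len(p)
    if n == 0:
        raise ValidationError("need at least one p-value")
    if matrix.shape != (n, n):
        raise ValidationError(
            f"correlation matrix shape {matrix.shape} does not match {n} p-values"
        )
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p >= 1):
        raise ValidationError("p-values must lie strictly inside (0, 1) after clipping")
    t0 = -2.0 * float(np.log(p).sum())
    cov_sum = 0.0
    n_clamped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n - 1):
            for j in range(i + 1, n):
                n_clamped += matrix[i, j] < -0.5
                cov_sum += brown_covariance(matrix[i, j])
    if n_clamped:
        warnings.warn(
            f"{n_clamped} correlation pair(s) below -0.5 clamped to the domain edge",
            stacklevel=2,
        )
    sigma2 = 4.0 * n + 2.0 * cov_sum
    if sigma2 <= 0:
        raise ValidationError(f"nonpositive variance {sigma2}; correlations too negative")
    c = sigma2 / (4.0 * n)
    df = 2.0 * n / c
    p_combined = float(stats.chi2.sf(t0 / c, df))
    return BrownResult(
        p_values=tuple(float(x) for x in p),
        t0=t0,
        sigma2=sigma2,
        c=c,
        df=df,
        p_combined=p_combined,
    )


# ---------------------------------------------------------------------------
# state alignment


def _state_mapping(
    state: SystemState | Mapping[str, int],
    network: RegulatoryNetwork | None,
) -> Mapping[str, int]:
    if isinstance(state, SystemState):
        if network is None:
            raise ValidationError("a network is required to interpret a SystemState")
        return state.as_dict(network)
    return state


def _marker_tests(marker_map: MarkerMap) -> list[tuple[str, str]]:
    """(gene, owning entity) pairs in marker-map order; one test per gene."""
    return [(g, entity) for entity, genes in marker_map.items() for g in genes]


def state_alignment_pvalue(
    data: ExpressionMatrix,
    group: str,
    state: SystemState | Mapping[str, int],
    marker_map: MarkerMap,
    rho: CorrelationModel,
    *,
    network: RegulatoryNetwork | None = None,
    equal_var: bool = True,
) -> BrownResult:
    """Aggregate significance that ``group``'s expression matches a predicted state.

    One directional test per marker gene (aggregate entities contribute one
    test per constituent gene), pooled by Brown's method over the
    control-sample correlations.
    """
    values = _state_mapping(state, network)
    pairs = _marker_tests(marker_map)
    control = data.control_group
    p = []
    for gene, entity in pairs:
        if entity not in values:
            raise ValidationError(f"state does not assign entity {entity!r}")
        p.append(
            directional_pvalue(
                data.gene_values(gene, group),
                data.gene_values(gene, control),
                values[entity],
                equal_var=equal_var,
            )
        )
    sub = rho.submatrix([g for g, _ in pairs])
    return combine_pvalues_brown(p, sub)


def state_state_pvalue(
    a: SystemState | Mapping[str, int],
    b: SystemState | Mapping[str, int],
    marker_map: MarkerMap,
    rho: CorrelationModel,
    *,
    network: RegulatoryNetwork | None = None,
) -> BrownResult:
    """Aggregate P between two predicted states over the mapped markers.

    Per gene the conventional p is 0.05 where the owning entities agree and
    1 where they disagree (clipped just below 1 for numerical stability);
    unmapped entities contribute nothing.
    """
    va = _state_mapping(a, network)
    vb = _state_mapping(b, network)
    pairs = _marker_tests(marker_map)
    p = [STATE_AGREE_P if va[e] == vb[e] else 1.0 for _, e in pairs]
    sub = rho.submatrix([g for g, _ in pairs])
    return combine_pvalues_brown(p, sub)


def _group_group_pvalue(
    data: ExpressionMatrix,
    group_a: str,
    group_b: str,
    marker_map: MarkerMap,
    rho: CorrelationModel,
    equal_var: bool = True,
) -> BrownResult:
    """Aggregate P between two exposure groups (small P = similar profiles).

    Per gene: 1 - p_two-tail between the groups — the same convention as a
    predicted 0, so identical groups pool to a small aggregate P.
    """
    pairs = _marker_tests(marker_map)
    p = []
    for gene, _ in pairs:
        p2 = _two_sample_t(
            data.gene_values(gene, group_a),
            data.gene_values(gene, group_b),
            "two-sided",
            equal_var,
        )
        p.append(float(np.clip(1.0 - p2, P_FLOOR, P_CEIL)))
    sub = rho.submatrix([g for g, _ in pairs])
    return combine_pvalues_brown(p, sub)


def profile_distance_matrix(
    profiles: Sequence[tuple[str, SystemState | Mapping[str, int]] | str],
    marker_map: MarkerMap,
    rho: CorrelationModel,
    *,
    data: ExpressionMatrix | None = None,
    network: RegulatoryNetwork | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Symmetric matrix of aggregate P values between predicted states and groups.

    Each profile is either ``(label, state)`` for a predicted state or a
    bare string naming an exposure group in ``data``. Distances are the raw
    aggregate P of the matching comparison (state-state, group-state, or
    group-group); the diagonal is zero.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    labels: list[str] = []
    kinds: list[str] = []
    payload: list = []
    for item in profiles:
        if isinstance(item, str):
            if data is None:
                raise ValidationError("expression data required for group profiles")
            labels.append(item)
            kinds.append("group")
            payload.append(item)
        else:
            label, state = item
            labels.append(label)
            kinds.append("state")
            payload.append(_state_mapping(state, network))
    k = len(labels)
    d = np.zeros((k, k), dtype=float)
    for i in range(k - 1):
        for j in range(i + 1, k):
            ki, kj = kinds[i], kinds[j]
            if ki == "state" and kj == "state":
                res = state_state_pvalue(payload[i], payload[j], marker_map, rho)
            elif ki == "group" and kj == "group":
                res = _group_group_pvalue(
                    data, payload[i], payload[j], marker_map, rho, equal_var
                )
            else:
                group = payload[i] if ki == "group" else payload[j]
                state = payload[j] if ki == "group" else payload[i]
                res = state_alignment_pvalue(
                    data, group, state, marker_map, rho, equal_var=equal_var
                )
            d[i, j] = d[j, i] = res.p_combined
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Sammon mapping


@dataclass(frozen=True)
class EmbeddingResult:
    """2-D Sammon projection of a distance matrix."""

    coordinates: np.ndarray  # (n, 2)
    stress: float
    seed: int
    iterations: int
    labels: tuple[str, ...] = ()


def _sammon_stress(d: np.ndarray, y: np.ndarray) -> float:
    diff = y[:, None, :] - y[None, :, :]
    emb = np.sqrt((diff ** 2).sum(axis=2))
    iu = np.triu_indices(len(y), 1)
    return float(((d[iu] - emb[iu]) ** 2 / d[iu]).sum() / d[iu].sum())


def sammon_embed(
    distances,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
    magic: float = 0.3,
) -> EmbeddingResult:
    """Project a distance matrix to 2-D by minimizing Sammon's stress.

    E = (1 / sum d_ij) * sum (d_ij - D_ij)^2 / d_ij over pairs i < j, with
    D the embedded Euclidean distances. Initialization is classical metric
    scaling plus a small seeded jitter; iteration is Sammon's
    diagonal-Newton step scaled by ``magic``, with step halving so the
    stress never increases. Zero off-diagonal input distances (exact
    duplicate profiles) are jittered with a warning.
    """
    labels: tuple[str, ...] = ()
    if isinstance(distances, pd.DataFrame):
        labels = tuple(str(c) for c in distances.columns)
        distances = distances.to_numpy(dtype=float)
    d = np.array(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be square and symmetric")
    if (d < 0).any() or not np.allclose(np.diag(d), 0.0):
        raise ValidationError("distances must be nonnegative with a zero diagonal")
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        warnings.warn("zero off-diagonal distances jittered by 1e-6", stacklevel=2)
        d[off & (d == 0)] = 1e-6

    # classical MDS start
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    y = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    rng = np.random.default_rng(seed)
    scale = d[off].mean()
    y = y + rng.normal(scale=1e-4 * scale, size=y.shape)

    c = d[np.triu_indices(n, 1)].sum()
    stress = _sammon_stress(d, y)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        diff = y[:, None, :] - y[None, :, :]
        emb = np.sqrt((diff ** 2).sum(axis=2))
        np.fill_diagonal(emb, 1.0)
        dd = d.copy()
        np.fill_diagonal(dd, 1.0)
        delta = dd - emb
        w1 = delta / (dd * emb)
        np.fill_diagonal(w1, 0.0)
        grad = (-2.0 / c) * (w1[:, :, None] * diff).sum(axis=1)
        # diagonal second derivative, Sammon's original form
        inv = 1.0 / (dd * emb)
        np.fill_diagonal(inv, 0.0)
        term = delta[:, :, None] - (diff ** 2) / emb[:, :, None] * (
            1.0 + delta / emb
        )[:, :, None]
        hess = (-2.0 / c) * (inv[:, :, None] * term).sum(axis=1)
        step = magic * grad / np.maximum(np.abs(hess), 1e-12)
        factor = 1.0
        for _ in range(20):  # halve until the stress does not increase
            y_new = y - factor * step
            new_stress = _sammon_stress(d, y_new)
            if new_stress <= stress:
                break
            factor *= 0.5
        else:
            break
        if stress - new_stress < tol:
            y, stress = y_new, new_stress
            break
        y, stress = y_new, new_stress
    return EmbeddingResult(
        coordinates=y, stress=stress, seed=seed, iterations=iterations, labels=labels
    )


# ---------------------------------------------------------------------------
# fold changes


def signed_fold_change(treated, control) -> float:
    """Ratio of group means, signed: +r for increases, -1/r for decreases."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    mc = control.mean()
    if mc <= 0:
        raise ValidationError(f"control mean must be positive, got {mc}")
    r = treated.mean() / mc
    return float(r) if r >= 1.0 else float(-1.0 / r)


def fold_change_profile(
    data: ExpressionMatrix,
    group: str,
    genes: Sequence[str] | None = None,
) -> pd.Series:
    """Per-gene signed fold change of ``group`` against the control group."""
    genes = tuple(genes) if genes is not None else data.genes
    values = {
        g: signed_fold_change(
            data.gene_values(g, group), data.gene_values(g, data.control_group)
        )
        for g in genes
    }
    return pd.Series(values, name=group)


# ---------------------------------------------------------------------------
# i/o


def write_expression(data: ExpressionMatrix, expr_path, groups_path) -> None:
    """Write the matrix (first column gene symbol) and the sample->group sidecar."""
    out = data.values.copy()
    out.index.name = "gene"
    out.to_csv(expr_path, float_format="%.12g")
    sidecar = pd.DataFrame(
        {"sample": list(data.groups.index), "group": list(data.groups)}
    )
    sidecar.to_csv(groups_path, index=False)


def read_expression(
    expr_path, groups_path, control_group: str = "saline"
) -> ExpressionMatrix:
    """Read an expression CSV plus its sample->group sidecar CSV."""
    try:
        values = pd.read_csv(expr_path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse expression CSV {expr_path}: {exc}") from exc
    sidecar = pd.read_csv(groups_path)
    for col in ("sample", "group"):
        if col not in sidecar.columns:
            raise ValidationError(f"groups CSV {groups_path} lacks a {col!r} column")
    if sidecar["group"].isna().any():
        row = int(sidecar.index[sidecar["group"].isna()][0]) + 2  # header is line 1
        raise ValidationError(f"{groups_path}:{row}: sample without a group label")
    groups = pd.Series(sidecar["group"].values, index=sidecar["sample"].values)
    return ExpressionMatrix(values, groups, control_group=control_group)
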