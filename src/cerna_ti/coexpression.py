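"""Stage 2: weighted co-expression network, module detection and module-trait association.

The network is unsigned: adjacency ``a_ij = |cor(x_i, x_j)|**beta`` on
log(x+1)-transformed abundances, with the soft-threshold power ``beta``
chosen as the smallest integer whose connectivity distribution fits a
scale-free topology at the target R-squared (default 0.9). Similarity is
smoothed by the topological overlap measure (TOM); modules are branches of
an average-linkage tree on ``1 - TOM`` cut at a fixed height, filtered by a
minimum size. Each module is summarized by its eigengene (first principal
component of the standardized member submatrix) and associated with the
reperfusion-injury trait by Pearson correlation with a t-distributed
two-sided p-value.

The trait itself is configurable because a post-intervention "injury
exposure" has no canonical numeric encoding: the default is a binary
indicator (0 before reperfusion, 1 after), with elapsed-hours and
log-hours encodings available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix, ValidationError

logger = logging.getLogger("cerna_ti")

DEFAULT_TARGET_R2 = 0.9
DEFAULT_MIN_MODULE_SIZE = 20
DEFAULT_CUT_HEIGHT = 0.95

TRAIT_ENCODINGS = ("binary", "hours", "log_hours")


# ---------------------------------------------------------------------------
# Trait
# ---------------------------------------------------------------------------

@dataclass
class TraitVector:
    """Per-sample numeric encoding of reperfusion-injury exposure."""

    values: pd.Series
    encoding_name: str

    def __post_init__(self) -> None:
        if self.values.nunique() < 2:
            raise ValidationError("trait vector is constant")


def make_trait(sample_meta: pd.DataFrame, encoding: str = "binary") -> TraitVector:
    """Encode the trait from sample metadata.

    ``binary``: 0 at time 0 (pre-intervention), 1 at every later time point.
    ``hours``: the time point itself. ``log_hours``: log(1 + hours).
    """
    t = sample_meta["time_hours"].astype(float)
    if encoding == "binary":
        vals = (t > 0).astype(float)
    elif encoding == "hours":
        vals = t
    elif encoding == "log_hours":
        vals = np.log1p(t)
    else:
        raise ValidationError(
            f"unknown trait encoding {encoding!r}; choose from {TRAIT_ENCODINGS}"
        )
    return TraitVector(values=pd.Series(vals, index=sample_meta.index),
                       encoding_name=encoding)


# ---------------------------------------------------------------------------
# Adjacency and power selection
# ---------------------------------------------------------------------------

def _log_transform(expr: ExpressionMatrix) -> pd.DataFrame:
    """log(x+1) per gene; drops constant rows (undefined correlation) with a warning."""
    logged = np.log1p(expr.values.astype(float))
    sd = logged.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant gene row(s) before correlation",
                       int(constant.sum()))
        logged = logged.loc[~constant]
    return logged


def adjacency_matrix(expr: ExpressionMatrix, beta: int) -> pd.DataFrame:
    """Unsigned weighted adjacency |cor|^beta with zero diagonal."""
    logged = _log_transform(expr)
    r = np.corrcoef(logged.to_numpy())
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=logged.index, columns=logged.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R-squared of the log-log regression of the connectivity distribution.

    Connectivities are discretized into ``n_bins`` equal-width bins; empty
    bins are dropped; the fit is the squared Pearson correlation of
    log10(mean k per bin) against log10(fraction of genes per bin).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    means, freqs = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            means.append(k[mask].mean())
            freqs.append(mask.mean())
    if len(means) < 3:
        return 0.0
    log_k = np.log10(means)
    log_p = np.log10(freqs)
    if np.ptp(log_k) == 0 or np.ptp(log_p) == 0:
        return 1.0  # degenerate: all mass on one point of the log-log line
    r, _ = stats.pearsonr(log_k, log_p)
    return float(r ** 2)


@dataclass
class PowerScan:
    """Result of the soft-threshold scan over candidate powers."""

    powers: list[int]
    fit_r2: list[float]
    mean_connectivity: list[float]
    selected: int
    flagged: bool = False   # True when no power reached the target R-squared

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "power": self.powers,
            "scale_free_r2": self.fit_r2,
            "mean_connectivity": self.mean_connectivity,
        })


def select_power(
    expr: ExpressionMatrix,
    target_r2: float = DEFAULT_TARGET_R2,
    powers: list[int] | None = None,
) -> PowerScan:
    """Scan integer powers 1..20 and pick the smallest with scale-free fit >= target.

    Falls back (flagged) to the power with maximal R-squared when none reach
    the target.
    """
    if len(expr.samples) < 3:
        raise ValidationError("power selection needs >= 3 samples")
    if len(expr.gene_ids) < 10:
        raise ValidationError("power selection needs >= 10 genes")
    powers = powers or list(range(1, 21))
    logged = _log_transform(expr)
    r = np.abs(np.corrcoef(logged.to_numpy()))
    np.fill_diagonal(r, 0.0)
    fit, mean_k = [], []
    for beta in powers:
        a = r ** beta
        k = a.sum(axis=1)
        fit.append(scale_free_fit(k))
        mean_k.append(float(k.mean()))
    reaching = [b for b, f in zip(powers, fit) if f >= target_r2]
    if reaching:
        selected, flagged = reaching[0], False
    else:
        selected, flagged = powers[int(np.argmax(fit))], True
        logger.warning("no power reached scale-free R2 >= %g; falling back to "
                       "power %d (R2 = %.3f)", target_r2, selected, max(fit))
    return PowerScan(powers=powers, fit_r2=fit, mean_connectivity=mean_k,
                     selected=selected, flagged=flagged)


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def topological_overlap(adjacency: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Unsigned TOM: ``(l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``, unit diagonal.

    ``l_ij`` counts shared-neighbour weight ``sum_u a_iu a_uj``; with a zero
    diagonal the matrix product gives exactly that sum.
    """
    labels = None
    a = adjacency
    if isinstance(a, pd.DataFrame):
        labels = a.index
        a = a.to_numpy(dtype=float)
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValidationError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # symmetrize away rounding
    if labels is not None:
        return pd.DataFrame(tom, index=labels, columns=labels)
    return tom


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionModule:
    """A detected module with its summary statistics (filled in stages)."""

    label: str
    members: list[str]
    eigengene: pd.Series | None = None
    explained_variance: float | None = None
    trait_correlation: float | None = None
    trait_p: float | None = None


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> tuple[list[CoexpressionModule], list[str]]:
    """Cut the average-linkage tree on ``1 - TOM`` into modules.

    Branches below ``cut_height`` with at least ``min_size`` genes become
    modules, labelled ``M1, M2, ...`` by decreasing size; everything else is
    returned as the unassigned pool. (This is a static cut; the dynamic-hybrid
    refinement of the reference tool is deliberately not reproduced.)
    """
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    genes = list(tom.index)
    if len(genes) < 2:
        return [], genes
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(g)
    big = sorted(
        (members for members in clusters.values() if len(members) >= min_size),
        key=lambda m: (-len(m), m[0]),
    )
    modules = [CoexpressionModule(label=f"M{i + 1}", members=members)
               for i, members in enumerate(big)]
    assigned = {g for m in modules for g in m.members}
    unassigned = [g for g in genes if g not in assigned]
    logger.info("detected %d module(s) (sizes %s); %d gene(s) unassigned",
                len(modules), [len(m.members) for m in modules], len(unassigned))
    return modules, unassigned


def module_eigengene(expr: ExpressionMatrix, module: CoexpressionModule) -> pd.Series:
    """First principal component of the module's standardized member profiles.

    Genes are z-scored across samples on log(x+1) values; the eigengene is the
    first right-singular vector (unit norm), sign-oriented so its correlation
    with the mean standardized member profile is non-negative. The explained
    variance share is stored on the module.
    """
    sub = expr.subset_genes(module.members)
    logged = np.log1p(sub.values.to_numpy(dtype=float))
    sd = logged.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValidationError("module contains constant gene(s); cannot standardize")
    z = (logged - logged.mean(axis=1, keepdims=True)) / sd[:, None]
    if z.shape[0] == 1:
        v = z[0] / np.linalg.norm(z[0])
        module.explained_variance = 1.0
    else:
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        module.explained_variance = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    eig = pd.Series(v, index=sub.samples, name=module.label)
    module.eigengene = eig
    return eig


def module_trait_association(
    modules: list[CoexpressionModule],
    trait: TraitVector,
) -> list[CoexpressionModule]:
    """Fill Pearson r and two-sided p (t distribution, n-2 df) per module; rank by |r|."""
    for module in modules:
        if module.eigengene is None:
            raise ValidationError(f"module {module.label} has no eigengene yet")
        t = trait.values.loc[module.eigengene.index].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            raise ValidationError("trait is constant over the module's samples")
        r, p = stats.pearsonr(module.eigengene.to_numpy(), t)
        module.trait_correlation = float(r)
        module.trait_p = float(p)
    modules.sort(key=lambda m: -abs(m.trait_correlation))
    return modules
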