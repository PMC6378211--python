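"""Stage 3: short time-series clustering against enumerable model profiles.

Genes are summarized as one series per RNA — the patient-mean log(x+1)
value at each time point, anchored by subtracting the time-0 value — and
assigned to the model profile (integer template starting at 0 with bounded
unit changes) they correlate with best. Profile significance comes from a
permutation null that independently shuffles each gene's time-point order
and re-assigns, so a profile is significant when it attracts more genes
than chance ordering of the same values would.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ValidationError

logger = logging.getLogger("cerna_ti")

DEFAULT_MAX_UNIT_CHANGE = 1       # c: bound on |successive difference|
DEFAULT_N_REPRESENTATIVES = 50    # m: greedily chosen distinct model profiles
DEFAULT_N_PERMUTATIONS = 1000


@dataclass(frozen=True)
class ModelProfile:
    """An integer template time course anchored at 0 with steps in {-c..c}."""

    profile_id: str
    vector: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.vector[0] != 0:
            raise ValidationError("model profile must start at 0")


def enumerate_profiles(T: int = 5, c: int = DEFAULT_MAX_UNIT_CHANGE) -> list[ModelProfile]:
    """All ``(2c+1)**(T-1) - 1`` non-flat integer profiles anchored at 0.

    Profiles are generated in lexicographic order of their difference
    vectors; ids ``P0001, P0002, ...`` follow that order, so id order is a
    deterministic total order used for tie-breaking everywhere downstream.
    """
    if T < 2:
        raise ValidationError("need T >= 2 time points")
    if c < 1:
        raise ValidationError("need unit-change bound c >= 1")
    profiles = []
    i = 0
    for diffs in itertools.product(range(-c, c + 1), repeat=T - 1):
        if all(d == 0 for d in diffs):
            continue  # the flat profile carries no time tendency
        i += 1
        vec = (0, *itertools.accumulate(diffs))
        profiles.append(ModelProfile(profile_id=f"P{i:04d}", vector=tuple(vec)))
    return profiles


def _profile_matrix(profiles: list[ModelProfile]) -> np.ndarray:
    return np.array([p.vector for p in profiles], dtype=float)


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centred and scaled to unit norm; returns (z, keep-mask of non-constant rows)."""
    centred = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    keep = norms > 0
    z = np.zeros_like(centred)
    z[keep] = centred[keep] / norms[keep, None]
    return z, keep


def select_representatives(
    profiles: list[ModelProfile],
    m: int = DEFAULT_N_REPRESENTATIVES,
) -> list[ModelProfile]:
    """Greedy max-min subset of ``m`` profiles under distance 1 - Pearson r.

    Starts from the lexicographically first profile id and repeatedly adds the
    profile whose minimum distance to the chosen set is largest, breaking ties
    by lowest profile id; returns all profiles when ``m`` covers them.
    """
    if m < 1:
        raise ValidationError("need m >= 1 representatives")
    ordered = sorted(profiles, key=lambda p: p.profile_id)
    if m >= len(ordered):
        return ordered
    z, _ = _standardize_rows(_profile_matrix(ordered))
    dist = 1.0 - z @ z.T
    chosen = [0]
    min_dist = dist[0].copy()
    while len(chosen) < m:
        min_dist[chosen] = -np.inf
        nxt = int(np.argmax(min_dist))  # argmax takes the first = lowest id on ties
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
    return [ordered[i] for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# Gene series and assignment
# ---------------------------------------------------------------------------

def gene_time_series(expr: ExpressionMatrix) -> pd.DataFrame:
    """One anchored series per gene: log of the patient-mean abundance per
    time point, minus the time-0 value.

    The cross-patient mean is taken on the raw scale first, then logged, so a
    multiplicative signal shared by patients survives the transform exactly.
    Genes whose mean abundance is zero at any time point have no defined log
    series and are dropped (logged count). Columns are the sorted time
    points; the first column is 0 for every retained gene.
    """
    meta = expr.sample_meta.loc[expr.samples]
    times = sorted(set(meta["time_hours"]))
    vals = expr.values.to_numpy(dtype=float)
    cols = []
    for t in times:
        mask = (meta["time_hours"] == t).to_numpy()
        cols.append(vals[:, mask].mean(axis=1))
    mean = np.column_stack(cols)
    ok = (mean > 0).all(axis=1)
    if (~ok).any():
        logger.info("dropping %d gene(s) with a zero-mean time point from the "
                    "time-series view", int((~ok).sum()))
    series = np.log(mean[ok])
    series = series - series[:, [0]]
    return pd.DataFrame(series, index=expr.values.index[ok], columns=times)


def _assign(series: np.ndarray, prof_z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-correlated profile index per gene; returns (assignments, eligible-mask)."""
    z, keep = _standardize_rows(series)
    corr = z @ prof_z.T                    # Pearson r since rows are unit-norm centred
    best = np.argmax(corr, axis=1)         # first (lowest id) wins exact ties
    return best, keep


def assign_genes(
    series: pd.DataFrame,
    representatives: list[ModelProfile],
) -> pd.Series:
    """Assign each gene series to its best-correlated representative profile.

    Zero-variance (flat) series are excluded. Returns gene_id -> profile_id.
    """
    reps = sorted(representatives, key=lambda p: p.profile_id)
    if series.shape[1] != len(reps[0].vector):
        raise ValidationError(
            f"series has {series.shape[1]} time points but profiles have "
            f"{len(reps[0].vector)}"
        )
    prof_z, _ = _standardize_rows(_profile_matrix(reps))
    best, keep = _assign(series.to_numpy(dtype=float), prof_z)
    ids = np.array([p.profile_id for p in reps])
    out = pd.Series(ids[best], index=series.index)[keep]
    if (~keep).any():
        logger.info("excluded %d flat gene series from profile assignment",
                    int((~keep).sum()))
    return out


@dataclass
class ProfileSignificance:
    """Observed vs permutation-null gene counts per model profile."""

    table: pd.DataFrame  # index profile_id; columns observed, expected, p
    n_permutations: int

    def significant(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return list(t.index[(t["p"] < alpha) & (t["observed"] > 0)])


def profile_significance(
    series: pd.DataFrame,
    representatives: list[ModelProfile],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> ProfileSignificance:
    """Permutation test of per-profile gene counts.

    Null: each gene's time-point order is permuted independently, series are
    re-anchored at the new first value, and genes are re-assigned. The
    p-value is the add-one-smoothed upper tail
    ``(#{null count >= observed} + 1) / (n_permutations + 1)``; the expected
    count is the mean assigned count over permutations.
    """
    if n_permutations < 1:
        raise ValidationError("need n_permutations >= 1")
    reps = sorted(representatives, key=lambda p: p.profile_id)
    prof_z, _ = _standardize_rows(_profile_matrix(reps))
    x = series.to_numpy(dtype=float)
    n_genes, T = x.shape
    m = len(reps)

    best, keep = _assign(x, prof_z)
    observed = np.bincount(best[keep], minlength=m)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(m, dtype=int)
    total = np.zeros(m, dtype=float)
    base = np.tile(np.arange(T), (n_genes, 1))
    for _ in range(n_permutations):
        idx = rng.permuted(base, axis=1)
        perm = np.take_along_axis(x, idx, axis=1)
        perm = perm - perm[:, [0]]          # re-anchor at the permuted first point
        b, k = _assign(perm, prof_z)
        counts = np.bincount(b[k], minlength=m)
        exceed += counts >= observed
        total += counts
    p = (exceed + 1) / (n_permutations + 1)
    table = pd.DataFrame(
        {"observed": observed, "expected": total / n_permutations, "p": p},
        index=[r.profile_id for r in reps],
    )
    table.insert(0, "profile", [",".join(map(str, r.vector)) for r in reps])
    return ProfileSignificance(table=table, n_permutations=n_permutations)
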