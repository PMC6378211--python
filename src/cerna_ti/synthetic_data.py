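"""Synthetic time-course expression data with planted, recoverable structure.

The generator emulates the study design the pipeline targets: 2 patients
sampled at 0 (pre-reperfusion), 2, 12, 24 and 72 hours, a mixed
lncRNA/mRNA expression universe with a separate miRNA id universe used
only in the regulatory pair files, and three planted signal classes on a
log-normal background:

* a trait-correlated co-expression module — members share a latent time
  trajectory built so the module summary profile correlates with the
  binary pre/post-reperfusion trait at a chosen level;
* model-profile followers — genes tracking one of six canonical integer
  time templates (monotone rise/fall, peak/dip at 12 h, late rise, early
  step) scaled per gene;
* ceRNA triplets — lncRNA/mRNA partners drawn from the planted module
  that share a miRNA in the emitted pair files and additionally share
  their sample-level fluctuations, so true partners are near-perfectly
  co-expressed, as competing-endogenous regulation predicts.

Noise is multiplicative log-normal: expression = exp(N(mu, sigma^2)),
matching the non-negative right-skewed character of FPKM-like abundances.
All randomness flows from a single integer seed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import TraitVector, make_trait
from .io_formats import (
    EDGE_LNC_MIRNA,
    EDGE_LNC_MRNA,
    EDGE_MIRNA_MRNA,
    AnnotationMap,
    ExpressionMatrix,
    TargetPairSet,
    ValidationError,
)

#: the six planted difference templates (peak structure over 5 time points)
PLANTED_PROFILE_DIFFS = (
    (1, 1, 1, 1),      # monotone rise
    (-1, -1, -1, -1),  # monotone fall
    (1, 1, -1, -1),    # peak at 12 h
    (-1, -1, 1, 1),    # dip at 12 h
    (0, 0, 1, 1),      # late rise
    (1, 0, 0, 0),      # early step up
)

STRESS_TERM_ID = "TERM:0001"
STRESS_TERM_NAME = "cellular response to stress"


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_patients: int = 2
    time_points: tuple[float, ...] = (0, 2, 12, 24, 72)
    n_mrna: int = 400
    n_lncrna: int = 150
    n_mirna: int = 60
    n_planted_modules: int = 1
    planted_module_size: int = 30
    planted_trait_correlation: float = 0.8
    n_planted_triplets: int = 6
    n_planted_profile_genes: int = 60
    profile_scale: float = 0.8          # log-units per template step
    module_amplitude: float = 1.0       # log-units per latent-trajectory sd
    triplet_jitter_frac: float = 0.15   # independent noise of a ceRNA pair, x noise_sigma
    noise_sigma: float = 0.4            # sd of log-scale multiplicative noise
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    n_candidate_lnc_mrna: int = 300     # background candidate pairs per type
    n_lnc_mirna_pairs: int = 300
    n_mirna_mrna_pairs: int = 400
    n_background_terms: int = 20
    seed: int = 0

    def validate(self) -> None:
        tp = tuple(self.time_points)
        if len(tp) < 2 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValidationError(
                "time_points must be strictly increasing and start at 0"
            )
        if self.n_planted_modules > 0 and self.planted_module_size < 20:
            raise ValidationError("planted_module_size must be >= 20 (detectability)")
        for name in ("n_patients", "n_mrna", "n_lncrna", "n_mirna",
                     "n_planted_modules", "n_planted_triplets",
                     "n_planted_profile_genes", "n_candidate_lnc_mrna",
                     "n_lnc_mirna_pairs", "n_mirna_mrna_pairs", "n_background_terms"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0 <= self.planted_trait_correlation <= 1:
            raise ValidationError("planted_trait_correlation must lie in [0, 1]")
        n_module_genes = self.n_planted_modules * self.planted_module_size
        n_lnc_needed = self.n_planted_modules * self._module_lnc_count()
        n_mrna_needed = n_module_genes - n_lnc_needed
        prof_lnc = self.n_planted_profile_genes // 4
        prof_mrna = self.n_planted_profile_genes - prof_lnc
        if n_lnc_needed + prof_lnc > self.n_lncrna:
            raise ValidationError("planted lncRNA genes exceed the lncRNA universe")
        if n_mrna_needed + prof_mrna > self.n_mrna:
            raise ValidationError("planted mRNA genes exceed the mRNA universe")
        if self.n_planted_triplets > self.n_mirna:
            raise ValidationError("planted triplets exceed the miRNA universe")
        if self.n_planted_modules == 0 and self.n_planted_triplets > 0:
            raise ValidationError("planted triplets require a planted module")
        if self.n_planted_triplets > min(self._module_lnc_count(),
                                         self.planted_module_size
                                         - self._module_lnc_count()) \
                and self.n_planted_modules > 0:
            raise ValidationError("planted triplets exceed the planted module's "
                                  "lncRNA/mRNA membership")

    def _module_lnc_count(self) -> int:
        # roughly the shared-DEL : shared-DEM proportion of the emulated study
        return max(1, self.planted_module_size // 4) if self.planted_module_size else 0


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    planted_module_members: dict[str, set[str]]
    planted_profiles: dict[str, tuple[int, ...]]
    planted_triplets: list[tuple[str, str, str]]  # (lncRNA, miRNA, mRNA)
    trait: TraitVector


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _latent_trajectory(
    trait: np.ndarray, t_idx: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample latent time trajectory with exact sample correlation ``rho``
    with the trait.

    Built as ``rho * z_trait + sqrt(1-rho^2) * z_orth`` where ``z_orth`` is a
    standardized time-only contrast (identical across patients) orthogonal to
    the centred trait, so the trajectory is a pure function of time.
    """
    z_t = _standardize(trait)
    # random per-time-point contrast, broadcast to samples, then projected
    # orthogonal to the trait and the constant vector
    u = rng.normal(size=int(t_idx.max()) + 1)[t_idx]
    u = u - u.mean()
    u = u - (u @ z_t) / (z_t @ z_t) * z_t
    if np.allclose(u, 0):
        raise ValidationError("degenerate orthogonal contrast; change the seed")
    z_u = _standardize(u)
    return rho * z_t + np.sqrt(1.0 - rho ** 2) * z_u


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TargetPairSet, AnnotationMap, TraitVector, GroundTruth]:
    """Generate one synthetic dataset; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = tuple(config.time_points)
    T = len(times)

    patients = [f"P{i + 1}" for i in range(config.n_patients)]
    samples = [f"{p}_t{t:g}" for p in patients for t in times]
    sample_meta = pd.DataFrame(
        {"patient": [s.split("_t")[0] for s in samples],
         "time_hours": [float(s.split("_t")[1]) for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    trait = make_trait(sample_meta, "binary")
    trait_vals = trait.values.to_numpy(dtype=float)
    # index of a sample's time point, for time-only signals
    t_idx = np.array([times.index(t) for t in sample_meta["time_hours"]])

    mrna_ids = [f"MRNA_{i + 1:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC_{i + 1:04d}" for i in range(config.n_lncrna)]
    mir_ids = [f"MIR_{i + 1:04d}" for i in range(config.n_mirna)]
    gene_ids = mrna_ids + lnc_ids
    n_genes = len(gene_ids)
    biotype = pd.Series(
        ["mRNA"] * len(mrna_ids) + ["lncRNA"] * len(lnc_ids),
        index=pd.Index(gene_ids), name="biotype",
    )

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    log_expr = baseline[:, None] + rng.normal(
        0.0, config.noise_sigma, size=(n_genes, len(samples))
    )
    row = {g: i for i, g in enumerate(gene_ids)}

    # --- planted co-expression modules -----------------------------------
    module_members: dict[str, set[str]] = {}
    free_mrna = iter(mrna_ids)
    free_lnc = iter(lnc_ids)
    module_latents: dict[str, np.ndarray] = {}
    for m in range(config.n_planted_modules):
        n_lnc = config._module_lnc_count()
        members_lnc = list(itertools.islice(free_lnc, n_lnc))
        members_mrna = list(itertools.islice(free_mrna,
                                             config.planted_module_size - n_lnc))
        members = members_lnc + members_mrna
        label = f"PLANTED_M{m + 1}"
        module_members[label] = set(members)
        latent_t = _latent_trajectory(
            trait_vals, t_idx, config.planted_trait_correlation, rng
        )
        module_latents[label] = latent_t
        for g in members:
            amp = config.module_amplitude * rng.uniform(0.8, 1.2)
            noise = rng.normal(0.0, config.noise_sigma, len(samples))
            log_expr[row[g]] = baseline[row[g]] + amp * latent_t + noise

    # --- planted ceRNA triplets (drawn from the first planted module) ----
    triplets: list[tuple[str, str, str]] = []
    pair_rows: list[tuple[str, str, str]] = []
    if config.n_planted_triplets:
        label = "PLANTED_M1"
        members = sorted(module_members[label])
        lncs = [g for g in members if biotype[g] == "lncRNA"]
        mrnas = [g for g in members if biotype[g] == "mRNA"]
        latent_t = module_latents[label]
        jitter_sd = config.triplet_jitter_frac * config.noise_sigma
        for i in range(config.n_planted_triplets):
            L, M, mi = lncs[i], mrnas[i], mir_ids[i]
            triplets.append((L, mi, M))
            pair_rows += [
                (L, M, EDGE_LNC_MRNA),
                (L, mi, EDGE_LNC_MIRNA),
                (mi, M, EDGE_MIRNA_MRNA),
            ]
            # the pair shares its sample-level fluctuations: competing
            # endogenous partners are buffered by the same miRNA pool
            amp = config.module_amplitude * rng.uniform(0.8, 1.2)
            shared = latent_t + rng.normal(0.0, config.noise_sigma, len(samples))
            for g in (L, M):
                log_expr[row[g]] = (
                    baseline[row[g]] + amp * shared
                    + rng.normal(0.0, jitter_sd, len(samples))
                )

    # --- planted model-profile followers ---------------------------------
    planted_profiles: dict[str, tuple[int, ...]] = {}
    if config.n_planted_profile_genes:
        templates = []
        for diffs in PLANTED_PROFILE_DIFFS:
            d = diffs[: T - 1] if len(diffs) >= T - 1 else (
                diffs + (0,) * (T - 1 - len(diffs))
            )
            templates.append((0, *itertools.accumulate(d)))
        n_lnc = config.n_planted_profile_genes // 4
        genes = list(itertools.islice(free_lnc, n_lnc)) + list(
            itertools.islice(free_mrna, config.n_planted_profile_genes - n_lnc)
        )
        for j, g in enumerate(genes):
            vec = templates[j % len(templates)]
            planted_profiles[g] = tuple(vec)
            scale = config.profile_scale * rng.uniform(0.8, 1.2)
            signal = scale * np.array(vec, dtype=float)[t_idx]
            noise = rng.normal(0.0, config.noise_sigma, len(samples))
            log_expr[row[g]] = baseline[row[g]] + signal + noise

    values = pd.DataFrame(np.exp(log_expr), index=pd.Index(gene_ids),
                          columns=samples)
    expr = ExpressionMatrix(values=values, biotype=biotype,
                            sample_meta=sample_meta)

    # --- pair files: planted triplet edges + random background -----------
    def _sample_pairs(src_pool, tgt_pool, n, etype):
        for _ in range(n):
            s = src_pool[rng.integers(len(src_pool))]
            t = tgt_pool[rng.integers(len(tgt_pool))]
            pair_rows.append((s, t, etype))

    _sample_pairs(lnc_ids, mrna_ids, config.n_candidate_lnc_mrna, EDGE_LNC_MRNA)
    if mir_ids:
        _sample_pairs(lnc_ids, mir_ids, config.n_lnc_mirna_pairs, EDGE_LNC_MIRNA)
        _sample_pairs(mir_ids, mrna_ids, config.n_mirna_mrna_pairs, EDGE_MIRNA_MRNA)
    pairs = TargetPairSet(edges=pd.DataFrame(
        pair_rows, columns=["source", "target", "type"]
    ))

    # --- annotations: a stress-response term on two planted mRNAs --------
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    if config.n_planted_triplets >= 2:
        stress_genes = frozenset({triplets[0][2], triplets[1][2]})
    elif module_members:
        mrnas = sorted(g for g in module_members["PLANTED_M1"]
                       if biotype[g] == "mRNA")
        stress_genes = frozenset(mrnas[:2])
    else:
        stress_genes = frozenset(mrna_ids[:2])
    terms[STRESS_TERM_ID] = (STRESS_TERM_NAME, stress_genes)
    for j in range(config.n_background_terms):
        size = int(rng.integers(10, 31))
        members = frozenset(rng.choice(mrna_ids, size=size, replace=False))
        terms[f"TERM:{j + 2:04d}"] = (f"background process {j + 1}", members)
    annot = AnnotationMap(terms=terms, universe=frozenset(gene_ids))

    truth = GroundTruth(
        planted_module_members=module_members,
        planted_profiles=planted_profiles,
        planted_triplets=triplets,
        trait=trait,
    )
    _check_truth(truth, expr, pairs)
    return expr, pairs, annot, trait, truth


def _check_truth(truth: GroundTruth, expr: ExpressionMatrix,
                 pairs: TargetPairSet) -> None:
    """Ground-truth invariants: planted ids exist, triplet biotypes consistent."""
    genes = set(expr.gene_ids)
    for members in truth.planted_module_members.values():
        if not members <= genes:
            raise ValidationError("planted module member missing from matrix")
    if not set(truth.planted_profiles) <= genes:
        raise ValidationError("planted profile gene missing from matrix")
    tuples = pairs.as_tuples()
    for L, mi, M in truth.planted_triplets:
        if expr.biotype[L] != "lncRNA" or expr.biotype[M] != "mRNA":
            raise ValidationError(f"triplet ({L}, {mi}, {M}) has inconsistent biotypes")
        for e in [(L, M, EDGE_LNC_MRNA), (L, mi, EDGE_LNC_MIRNA),
                  (mi, M, EDGE_MIRNA_MRNA)]:
            if e not in tuples:
                raise ValidationError(f"planted triplet edge missing from pairs: {e}")


# ---------------------------------------------------------------------------
# hand-checkable toy fixture
# ---------------------------------------------------------------------------

def toy_fixture() -> tuple[ExpressionMatrix, TargetPairSet, AnnotationMap, TraitVector]:
    """A hard-coded 12-gene, 2-patient x 5-time-point dataset.

    Contains a constant gene (``flat1``, CV = 0), a hand-computable ramp
    (``ramp1``: 1,2,3,4,10 per patient, CV = 0.8839 to 4 d.p.), an obvious
    4-gene co-expression module and two planted ceRNA triplets whose
    lncRNA/mRNA partners have identical value vectors (r = 1).
    """
    times = (0, 2, 12, 24, 72)

    def per_patient(vals):  # same series in both patients
        return list(vals) * 2

    data = {
        "flat1":   per_patient([5, 5, 5, 5, 5]),
        "ramp1":   per_patient([1, 2, 3, 4, 10]),
        # obvious module: shared rise-and-fall trajectory, scaled
        "MRNA_A1": per_patient([1, 4, 16, 4, 1]),
        "MRNA_A2": per_patient([2, 8, 32, 8, 2]),
        "MRNA_A3": per_patient([1, 5, 20, 5, 1]),
        "LNC_A4":  per_patient([3, 12, 50, 12, 3]),
        # ceRNA triplet partners: identical vectors -> r exactly 1
        "LNC_T1":  per_patient([1, 5, 25, 5, 1]),
        "MRNA_T1": per_patient([1, 5, 25, 5, 1]),
        "LNC_T2":  per_patient([10, 8, 6, 4, 2]),
        "MRNA_T2": per_patient([10, 8, 6, 4, 2]),
        # background
        "MRNA_B1": per_patient([7, 6, 8, 7, 6]),
        "LNC_B2":  per_patient([2, 3, 2, 3, 2]),
    }
    samples = [f"P{p}_t{t:g}" for p in (1, 2) for t in times]
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples,
                                    dtype=float)
    biotype = pd.Series(
        {"flat1": "mRNA", "ramp1": "mRNA", "MRNA_A1": "mRNA", "MRNA_A2": "mRNA",
         "MRNA_A3": "mRNA", "LNC_A4": "lncRNA", "LNC_T1": "lncRNA",
         "MRNA_T1": "mRNA", "LNC_T2": "lncRNA", "MRNA_T2": "mRNA",
         "MRNA_B1": "mRNA", "LNC_B2": "lncRNA"},
    ).loc[values.index]
    sample_meta = pd.DataFrame(
        {"patient": [s.split("_t")[0] for s in samples],
         "time_hours": [float(s.split("_t")[1]) for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    expr = ExpressionMatrix(values=values, biotype=biotype,
                            sample_meta=sample_meta)
    pairs = TargetPairSet(edges=pd.DataFrame(
        [("LNC_T1", "MRNA_T1", EDGE_LNC_MRNA),
         ("LNC_T1", "MIR_T1", EDGE_LNC_MIRNA),
         ("MIR_T1", "MRNA_T1", EDGE_MIRNA_MRNA),
         ("LNC_T2", "MRNA_T2", EDGE_LNC_MRNA),
         ("MIR_T2", "MRNA_T2", EDGE_MIRNA_MRNA),
         ("LNC_T2", "MIR_T2", EDGE_LNC_MIRNA)],
        columns=["source", "target", "type"],
    ))
    annot = AnnotationMap(
        terms={STRESS_TERM_ID: (STRESS_TERM_NAME,
                                frozenset({"MRNA_T1", "MRNA_T2"})),
               "TERM:0002": ("background process",
                             frozenset({"MRNA_B1", "MRNA_A1", "MRNA_A2"}))},
        universe=frozenset(values.index),
    )
    trait = make_trait(sample_meta, "binary")
    return expr, pairs, annot, trait


# ---------------------------------------------------------------------------
# ground-truth sidecar serialization
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, directory) -> None:
    """Serialize the planted structure as tabular sidecar files."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(label, g) for label, members in truth.planted_module_members.items()
         for g in sorted(members)],
        columns=["module", "gene"],
    ).to_csv(d / "planted_modules.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, ",".join(map(str, v)))
         for g, v in sorted(truth.planted_profiles.items())],
        columns=["gene", "profile"],
    ).to_csv(d / "planted_profiles.tsv", sep="\t", index=False)
    pd.DataFrame(truth.planted_triplets,
                 columns=["lncRNA", "miRNA", "mRNA"]
                 ).to_csv(d / "planted_triplets.tsv", sep="\t", index=False)
    t = truth.trait.values.rename("trait").to_frame()
    t.index.name = "sample"
    t.to_csv(d / "trait.tsv", sep="\t")
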