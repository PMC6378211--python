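"""Stage 1: coefficient-of-variation screening of the time course, per patient.

For each patient, every gene's CV (sample standard deviation over that
patient's time-ordered abundances, divided by their mean) is computed on the
raw, untransformed values — CV is scale-free there, which is the point of the
statistic. Genes exceeding the threshold (strictly) in *every* enrolled
patient form the shared candidate set, split by biotype into DELs (lncRNAs)
and DEMs (mRNAs). A sample-level correlation QC mirrors the usual pairwise
R-squared check on log abundances.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ValidationError

logger = logging.getLogger("cerna_ti")


@dataclass
class CVReport:
    """Per-patient CVs and retained gene sets from one screening run."""

    threshold: float
    cv: dict[str, pd.Series]              # patient -> gene_id -> CV
    retained: dict[str, set[str]]         # patient -> genes with CV > threshold
    dropped_zero_mean: dict[str, int]     # patient -> count of undefined-CV genes
    biotype: pd.Series = field(repr=False)

    def retained_by_biotype(self, patient: str) -> tuple[set[str], set[str]]:
        """(DELs, DEMs) for one patient."""
        kept = self.retained[patient]
        is_lnc = self.biotype.loc[list(kept)] == "lncRNA"
        dels = set(is_lnc.index[is_lnc])
        dems = {g for g in kept if self.biotype[g] == "mRNA"}
        return dels, dems


def compute_cv(expr: ExpressionMatrix, patient_id: str) -> pd.Series:
    """CV per gene for one patient's time course.

    Uses the sample (n-1 denominator) standard deviation. Genes whose mean
    over the patient's time points is zero have no defined CV and are omitted
    from the returned Series (a count is logged).
    """
    samples = expr.samples_of_patient(patient_id)
    if len(samples) < 2:
        raise ValidationError(
            f"patient {patient_id!r} has {len(samples)} time point(s); need >= 2"
        )
    vals = expr.values[samples].to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    defined = mean > 0
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info(
            "patient %s: %d gene(s) with zero mean dropped (undefined CV)",
            patient_id, n_dropped,
        )
    cv = pd.Series(sd[defined] / mean[defined],
                   index=expr.values.index[defined], name=patient_id)
    return cv


def screen_by_cv(expr: ExpressionMatrix, threshold: float = 0.6) -> CVReport:
    """Screen every patient's time course for high-CV genes (strict ``CV > threshold``)."""
    if threshold < 0:
        raise ValidationError(f"CV threshold must be >= 0, got {threshold}")
    patients = expr.patients
    if not patients:
        raise ValidationError("expression matrix has no patients")
    cv: dict[str, pd.Series] = {}
    retained: dict[str, set[str]] = {}
    dropped: dict[str, int] = {}
    n_genes = len(expr.gene_ids)
    for p in patients:
        s = compute_cv(expr, p)
        cv[p] = s
        retained[p] = set(s.index[s > threshold])
        dropped[p] = n_genes - len(s)
        logger.info("patient %s: %d/%d genes retained at CV > %g",
                    p, len(retained[p]), n_genes, threshold)
    return CVReport(threshold=threshold, cv=cv, retained=retained,
                    dropped_zero_mean=dropped, biotype=expr.biotype)


def intersect_patients(report: CVReport) -> tuple[set[str], set[str]]:
    """Genes retained by *every* patient, split as (shared DELs, shared DEMs)."""
    patients = list(report.retained)
    if len(patients) < 2:
        raise ValidationError(
            "intersection needs >= 2 patients; skip this step for single-patient data"
        )
    shared = set.intersection(*(report.retained[p] for p in patients))
    dels = {g for g in shared if report.biotype[g] == "lncRNA"}
    dems = {g for g in shared if report.biotype[g] == "mRNA"}
    logger.info("shared across %d patients: %d DELs, %d DEMs",
                len(patients), len(dels), len(dems))
    return dels, dems


def sample_correlation_qc(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise squared Pearson correlation between samples on log(x+1) values.

    Symmetric with unit diagonal; entries involving a zero-variance sample
    are NaN (flagged undefined).
    """
    if len(expr.samples) < 2:
        raise ValidationError("sample correlation QC needs >= 2 samples")
    logged = np.log1p(expr.values.to_numpy(dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(logged, rowvar=False)
    r2 = r ** 2
    np.fill_diagonal(r2, 1.0)
    sd = logged.std(axis=0)
    r2[sd == 0, :] = np.nan
    r2[:, sd == 0] = np.nan
    return pd.DataFrame(r2, index=expr.samples, columns=expr.samples)
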