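"""Threshold phenotype classifiers and the stratified complication analysis.

The complication analyses (chronic kidney disease, diabetic retinopathy)
are run separately in subjects with and without type-2 diabetes, because
complication prevalence differs sharply between the strata.  Per-cohort
logistic fits within each stratum are combined across cohorts by
fixed-effect inverse-variance meta-analysis of the log odds ratios; the
"combined" row is the IVW combination of the two stratum-level results.

Classifier boundaries follow the clinical definitions exactly:

* T2D case: HbA1c >= 6.5% or self-reported diabetic history.
* T2D control: HbA1c < 6% and no history (for fasting-glucose cohorts:
  fasting glucose <= 6 mmol/L and no history).  Subjects in the
  6.0 <= HbA1c < 6.5 band without history fall in neither class.
* CKD case: 0 <= eGFR < 60; control: eGFR >= 60.
* DR (modified Airlie House grade): moderate/severe case grade >= 30,
  any-DR case grade >= 14; controls grade < 14 under both definitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import AssocResult, logistic_assoc
from .io_formats import IndexSnp
from .meta import ivw_meta

__all__ = [
    "StratifiedResult",
    "classify_t2d",
    "classify_ckd",
    "classify_dr",
    "exclude_diabetes_for_gwas",
    "stratified_assoc_meta",
    "bonferroni_threshold",
]


@dataclass
class StratifiedResult:
    snp_id: str
    stratum: str  # T2D-cases | T2D-controls | combined
    or_: float
    ci95: tuple[float, float]
    p: float
    n_cases: int
    n_controls: int


def classify_t2d(record, cohort_kind: str = "eye-study") -> str:
    """Three-way T2D label ('case' / 'control' / 'excluded') for one subject.

    ``record`` is a mapping or Series with fields ``hba1c``,
    ``diabetes_history`` and, for ``cohort_kind="SP2"``,
    ``fasting_glucose``.
    """
    if cohort_kind not in ("eye-study", "SP2"):
        raise ValueError(f"unknown cohort kind {cohort_kind!r}")
    hba1c = record.get("hba1c")
    history = record.get("diabetes_history")
    history = bool(history) if history is not None and not _isna(history) else None
    if hba1c is not None and _isna(hba1c):
        hba1c = None
    if hba1c is None and history is None:
        return "excluded"  # missing-data
    if history or (hba1c is not None and hba1c >= 6.5):
        return "case"
    if cohort_kind == "SP2":
        fg = record.get("fasting_glucose")
        if fg is None or _isna(fg):
            return "excluded"
        if fg <= 6.0 and not history:
            return "control"
        return "excluded"
    if hba1c is not None and hba1c < 6.0 and not history:
        return "control"
    return "excluded"


def _isna(x) -> bool:
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


def classify_ckd(egfr: float) -> str:
    """'case' iff 0 <= eGFR < 60 mL/min/1.73m^2, else 'control'."""
    if egfr < 0:
        raise ValueError(f"negative eGFR {egfr}")
    return "case" if egfr < 60.0 else "control"


def classify_dr(grade: int, definition: str = "moderate-severe") -> str:
    """Retinopathy label from the modified Airlie House grade."""
    if grade < 0:
        raise ValueError("grade must be non-negative")
    if definition == "moderate-severe":
        if grade >= 30:
            return "case"
        return "control" if grade < 14 else "excluded"
    if definition == "any":
        return "case" if grade >= 14 else "control"
    raise ValueError(f"unknown DR definition {definition!r}")


def exclude_diabetes_for_gwas(record, cohort_kind: str = "eye-study") -> bool:
    """True when a subject must be excluded from the quantitative HbA1c
    analysis: diabetic history, glucose-lowering medication, HbA1c >=
    6.5%, or (fasting-glucose cohorts) fasting glucose >= 7 mmol/L."""
    if record.get("diabetes_history") or record.get("on_diabetes_meds"):
        return True
    hba1c = record.get("hba1c")
    if hba1c is not None and not _isna(hba1c) and hba1c >= 6.5:
        return True
    if cohort_kind == "SP2":
        fg = record.get("fasting_glucose")
        if fg is not None and not _isna(fg) and fg >= 7.0:
            return True
    return False


def _outcome_labels(pheno: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "ckd":
        return pheno["egfr"].map(classify_ckd)
    if outcome == "dr-moderate":
        return pheno["dr_grade"].map(lambda g: classify_dr(g, "moderate-severe"))
    if outcome == "dr-any":
        return pheno["dr_grade"].map(lambda g: classify_dr(g, "any"))
    raise ValueError(f"unknown outcome {outcome!r}")


def stratified_assoc_meta(
    cohorts: Sequence[tuple[np.ndarray | pd.DataFrame, pd.DataFrame]],
    snps: Sequence[IndexSnp] | Sequence[str],
    outcome: str = "ckd",
    cohort_kinds: Sequence[str] | None = None,
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Stratified case-control association of index SNPs with a complication.

    ``cohorts`` is a sequence of (dosages, phenotypes) pairs; ``dosages``
    is a 1-D array (single SNP) or a DataFrame with one column per SNP id.
    Within each cohort, subjects are stratified by T2D status; the
    complication outcome is regressed on dosage by logistic regression
    within each stratum, results are IVW-combined across cohorts within
    stratum, and the combined row is the IVW of the two stratum results.
    Stratum-by-cohort cells with a single outcome class (or a separated
    fit) are dropped with a diagnostic.

    Returns a tidy DataFrame with one row per SNP x stratum.
    """
    snp_ids = [s.snp_id if isinstance(s, IndexSnp) else str(s) for s in snps]
    kinds = list(cohort_kinds) if cohort_kinds else ["eye-study"] * len(cohorts)
    out_rows = []
    for snp_id in snp_ids:
        stratum_meta: dict[str, tuple] = {}
        for stratum in ("case", "control"):
            per_cohort: list[tuple[float, float]] = []
            n_cases = n_controls = 0
            for (dos, pheno), kind in zip(cohorts, kinds):
                d = _dosage_vector(dos, snp_id)
                t2d = pheno.apply(lambda r: classify_t2d(r, kind), axis=1)
                labels = _outcome_labels(pheno, outcome)
                mask = (t2d == stratum) & labels.isin(["case", "control"])
                y = (labels[mask] == "case").to_numpy(dtype=float)
                if y.size == 0 or len(np.unique(y)) < 2:
                    warnings.warn(
                        f"{snp_id}: stratum {stratum!r} in one cohort has a single "
                        "outcome class; dropped"
                    )
                    continue
                covs = pheno.loc[mask, list(covariates)] if covariates else None
                try:
                    res = logistic_assoc(d[mask.to_numpy()], y, covs, snp_id=snp_id)
                except ValueError:
                    continue
                if res.separation:
                    warnings.warn(f"{snp_id}: separated fit in stratum {stratum!r}; dropped")
                    continue
                per_cohort.append((res.beta, res.se))
                n_cases += int(y.sum())
                n_controls += int((1 - y).sum())
            if per_cohort:
                m = ivw_meta(per_cohort, snp_id=snp_id)
                stratum_meta[stratum] = (m, n_cases, n_controls)
        strata_rows = []
        for stratum, key in (("T2D-cases", "case"), ("T2D-controls", "control")):
            if key not in stratum_meta:
                continue
            m, nc, nn = stratum_meta[key]
            lo, hi = m.ci95
            strata_rows.append({
                "snp_id": snp_id, "stratum": stratum,
                "or_": math.exp(m.beta_meta), "ci_low": math.exp(lo),
                "ci_high": math.exp(hi), "p": m.p,
                "n_cases": nc, "n_controls": nn,
            })
        if len(stratum_meta) == 2:
            pair = [
                (stratum_meta["case"][0].beta_meta, stratum_meta["case"][0].se_meta),
                (stratum_meta["control"][0].beta_meta, stratum_meta["control"][0].se_meta),
            ]
            comb = ivw_meta(pair, snp_id=snp_id)
            lo, hi = comb.ci95
            out_rows.append({
                "snp_id": snp_id, "stratum": "combined",
                "or_": math.exp(comb.beta_meta), "ci_low": math.exp(lo),
                "ci_high": math.exp(hi), "p": comb.p,
                "n_cases": stratum_meta["case"][1] + stratum_meta["control"][1],
                "n_controls": stratum_meta["case"][2] + stratum_meta["control"][2],
            })
        out_rows.extend(strata_rows)
    return pd.DataFrame(out_rows)


def _dosage_vector(dos, snp_id: str) -> np.ndarray:
    if isinstance(dos, pd.DataFrame):
        if snp_id not in dos.columns:
            raise KeyError(f"dosage table has no column {snp_id!r}")
        return dos[snp_id].to_numpy(dtype=float)
    return np.asarray(dos, dtype=float)


def bonferroni_threshold(
    alpha: float = 0.05,
    n_snps: int = 15,
    n_phenotypes: int = 4,
) -> float:
    """Family-wise significance level alpha / (n_snps * n_phenotypes)."""
    if alpha <= 0 or n_snps <= 0 or n_phenotypes <= 0:
        raise ValueError("all arguments must be positive")
    return alpha / (n_snps * n_phenotypes)
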