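"""Per-SNP association tests and SNP-level quality-control filters.

Dosages are real numbers in [0, 2] (post-imputation expected allele
counts) and are treated as continuous predictors.  Rows with missing
values in the dosage, trait/outcome or any covariate are deleted
list-wise; the subject count actually used is reported in the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_formats import SummaryStatRecord

__all__ = [
    "AssocResult",
    "DegeneratePredictorError",
    "linear_assoc",
    "logistic_assoc",
    "hwe_test",
    "snp_qc_filter",
]


class DegeneratePredictorError(ValueError):
    """The dosage vector carries no variation."""


@dataclass
class AssocResult:
    """One SNP's association fit.

    For the logistic test, ``beta`` is the log odds ratio; ``or_`` and
    ``ci95`` expose the odds-ratio scale.  When complete separation is
    detected the estimates are absent (NaN) and ``separation`` is set.
    """

    snp_id: str
    beta: float
    se: float
    p: float
    n: int
    test: str
    covariates_used: list[str] = field(default_factory=list)
    separation: bool = False

    @property
    def or_(self) -> float:
        if self.test != "logistic":
            raise ValueError("odds ratio defined for logistic results only")
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        lo = self.beta - 1.959963984540054 * self.se
        hi = self.beta + 1.959963984540054 * self.se
        if self.test == "logistic":
            return math.exp(lo), math.exp(hi)
        return lo, hi


def _design(dosage, covariates) -> tuple[np.ndarray, list[str], np.ndarray]:
    dosage = np.asarray(dosage, dtype=float)
    cols = [dosage]
    names: list[str] = []
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            names = list(covariates.columns)
            for c in names:
                cols.append(covariates[c].to_numpy(dtype=float))
        else:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] == dosage.size and covariates.ndim == 2:
                covariates = covariates.T
            for i, row in enumerate(covariates):
                cols.append(np.asarray(row, dtype=float))
                names.append(f"cov{i + 1}")
    X = np.column_stack(cols)
    return X, names, dosage


def linear_assoc(
    dosage,
    trait,
    covariates=None,
    snp_id: str = "snp",
) -> AssocResult:
    """Ordinary least squares of a quantitative trait on allele dosage.

    The model is trait ~ intercept + dosage + covariates; the reported P
    is the two-sided Wald test on the dosage coefficient against the t
    reference distribution.
    """
    X, names, dosage = _design(dosage, covariates)
    y = np.asarray(trait, dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    if X.shape[0] <= X.shape[1] + 2:
        raise ValueError("too few complete observations for the requested model")
    if np.ptp(X[:, 0]) == 0:
        raise DegeneratePredictorError(f"{snp_id}: dosage is constant")
    fit = sm.OLS(y, sm.add_constant(X, prepend=True)).fit()
    return AssocResult(
        snp_id=snp_id,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(max(fit.pvalues[1], np.finfo(float).tiny)),
        n=int(X.shape[0]),
        test="linear",
        covariates_used=names,
    )


def logistic_assoc(
    dosage,
    outcome,
    covariates=None,
    snp_id: str = "snp",
) -> AssocResult:
    """Maximum-likelihood logistic regression of a binary outcome on dosage.

    Complete (or quasi-complete) separation is flagged rather than raised:
    the result carries NaN estimates and ``separation=True``.
    """
    X, names, dosage = _design(dosage, covariates)
    y = np.asarray(outcome, dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    if np.ptp(X[:, 0]) == 0:
        raise DegeneratePredictorError(f"{snp_id}: dosage is constant")
    Xc = sm.add_constant(X, prepend=True)
    sep = AssocResult(snp_id, float("nan"), float("nan"), float("nan"),
                      int(X.shape[0]), "logistic", names, separation=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
        except Exception:
            return sep
    se = float(fit.bse[1])
    if not fit.mle_retvals.get("converged", False) or not np.isfinite(se) or se > 50:
        return sep
    return AssocResult(
        snp_id=snp_id,
        beta=float(fit.params[1]),
        se=se,
        p=float(max(fit.pvalues[1], np.finfo(float).tiny)),
        n=int(X.shape[0]),
        test="logistic",
        covariates_used=names,
    )


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the conditional probabilities no larger than that of
    the observed configuration.  Symmetric in the allele labels;
    monomorphic sites return P = 1.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab  # minor/major labels are irrelevant by symmetry
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    # log-probability of each heterozygote count with the observed parity
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rr = (rare - hets) // 2
    n_cc = n - n_rr - hets
    from scipy.special import gammaln

    logp = (
        hets * math.log(2.0)
        + gammaln(n + 1) - gammaln(n_rr + 1) - gammaln(hets + 1) - gammaln(n_cc + 1)
        - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = np.nonzero(hets == n_ab)[0]
    if obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = prob[obs[0]]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def snp_qc_filter(
    records: list[SummaryStatRecord],
    maf_min: float = 0.01,
    miss_max: float = 0.05,
    hwe_min: float = 1e-6,
    info_min: float = 0.5,
) -> tuple[list[SummaryStatRecord], dict[str, int]]:
    """Apply the standard SNP inclusion rules to summary records.

    A SNP survives iff MAF >= ``maf_min``, missingness <= ``miss_max``,
    HWE P > ``hwe_min`` and (INFO absent, i.e. genotyped, or INFO >=
    ``info_min``).  Absent missingness or HWE fields pass their rules
    vacuously.  Returns the survivors plus per-rule removal counts (a SNP
    violating several rules is counted under each).
    """
    counts = {"maf": 0, "missing": 0, "hwe": 0, "info": 0}
    kept: list[SummaryStatRecord] = []
    for r in records:
        bad = False
        if r.maf < maf_min:
            counts["maf"] += 1
            bad = True
        if r.missing_rate is not None and r.missing_rate > miss_max:
            counts["missing"] += 1
            bad = True
        if r.hwe_p is not None and r.hwe_p <= hwe_min:
            counts["hwe"] += 1
            bad = True
        if r.info is not None and r.info < info_min:
            counts["info"] += 1
            bad = True
        if not bad:
            kept.append(r)
    return kept, counts
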