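"""Replication assessment of established index SNPs in target cohorts.

A literature-reported (European-established) index SNP is called
replicated in a target cohort when its association P is at or below the
nominal level (0.05 by default).  Because modest cohorts are often
underpowered for small glycaemic effects, replication is read alongside
two further quantities: the direction concordance of the target effect
with the reported European effect, and the analytic power of the target
cohort to detect the European effect size at its own allele frequency.

Power uses the 1-df chi-square non-centrality of the dosage Wald test in
a linear model:  NCP = n * 2p(1-p) * beta^2 / sd^2,  where 2p(1-p) is the
dosage variance under Hardy-Weinberg proportions.
"""

from __future__ import annotations

import warnings
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HarmonisationError, IndexSnp, SummaryStatRecord, harmonise
from .meta import MetaResult, ivw_meta

__all__ = [
    "Concordance",
    "classify_replication",
    "direction_concordance",
    "analytic_power",
    "analytic_power_meta",
    "build_transfer_report",
]

DEFAULT_SD_TRAIT = 0.4  # per-cohort HbA1c SD (%)


class Concordance(NamedTuple):
    """Direction agreement of a target effect with the reported one.

    Truth-tests as the boolean verdict; ``zero_effect`` flags an exactly
    zero target estimate (discordant by convention).
    """

    concordant: bool
    zero_effect: bool

    def __bool__(self) -> bool:  # noqa: D105
        return self.concordant


def classify_replication(p: float, alpha: float = 0.05) -> bool:
    """True iff P <= alpha (boundary inclusive)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return p <= alpha


def direction_concordance(beta_target: float, beta_eur: float) -> Concordance:
    """Sign agreement between target and reported effect estimates."""
    if not np.isfinite(beta_target) or not np.isfinite(beta_eur):
        raise ValueError("both effect estimates must be finite")
    if beta_eur == 0:
        raise ValueError("reference effect must be nonzero")
    if beta_target == 0.0:
        return Concordance(False, True)
    return Concordance(float(np.sign(beta_target) * np.sign(beta_eur)) > 0, False)


def analytic_power(
    n: int,
    eaf: float,
    beta: float,
    sd_trait: float = DEFAULT_SD_TRAIT,
    alpha: float = 0.05,
) -> float:
    """Power of the two-sided dosage Wald test at level alpha.

    Computed as P(chi2_1(NCP) > chi2 critical value), with NCP =
    n * 2*eaf*(1-eaf) * beta^2 / sd_trait^2.  beta = 0 returns alpha.
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError("eaf must lie strictly in (0, 1)")
    if sd_trait <= 0:
        raise ValueError("sd_trait must be positive")
    ncp = n * 2.0 * eaf * (1.0 - eaf) * beta ** 2 / sd_trait ** 2
    crit = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else float(alpha)


def analytic_power_meta(
    cohorts: Sequence[tuple[int, float]],
    beta: float,
    sd_trait: float = DEFAULT_SD_TRAIT,
    alpha: float = 0.05,
) -> float:
    """Meta-analysis power: non-centralities add across cohorts.

    ``cohorts`` is a sequence of (n, eaf) pairs; each contributes
    n_i * 2*p_i*(1-p_i) * beta^2 / sd^2 to the pooled NCP.
    """
    ncp = sum(
        n * 2.0 * p * (1.0 - p) for n, p in cohorts
    ) * beta ** 2 / sd_trait ** 2
    crit = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else float(alpha)


def _harmonised(rec: SummaryStatRecord, index: IndexSnp) -> tuple[float, float]:
    beta, eaf, _ = harmonise(
        rec.beta, rec.eaf, rec.effect_allele, rec.other_allele,
        index.effect_allele,
    )
    return beta, eaf


def build_transfer_report(
    index_snps: Sequence[IndexSnp],
    cohort_results: Mapping[str, Mapping[str, SummaryStatRecord]],
    meta_results: Mapping[str, MetaResult] | None = None,
    alpha: float = 0.05,
    sd_trait: float = DEFAULT_SD_TRAIT,
) -> pd.DataFrame:
    """Assemble the per-index-SNP transferability table.

    ``cohort_results`` maps population label -> {snp_id -> record}; records
    are harmonised onto each index SNP's effect allele before
    classification (a flipped cohort file therefore cannot flip a
    conclusion).  When ``meta_results`` is omitted, the meta column is the
    IVW combination of the available per-population results.

    Index SNPs absent from every cohort, or with unresolvable alleles
    everywhere, are excluded from the summary counts; the exclusion is
    visible in the ``n_populations`` column and a warning.

    Returns a DataFrame with, per population and for the meta analysis:
    beta, p, replication flag, direction concordance with the European
    effect, and analytic power to detect the European effect.
    """
    pops = list(cohort_results.keys())
    rows = []
    for snp in index_snps:
        row: dict = {
            "snp_id": snp.snp_id, "locus": snp.locus_name,
            "beta_eur": snp.beta_eur, "eaf_eur": snp.eaf_eur,
        }
        per_pop: list[tuple[float, float]] = []
        power_cohorts: list[tuple[int, float]] = []
        n_present = 0
        for pop in pops:
            rec = cohort_results[pop].get(snp.snp_id)
            if rec is None:
                for k in ("beta", "p", "replicated", "concordant", "power"):
                    row[f"{pop}_{k}"] = np.nan
                continue
            try:
                beta, eaf = _harmonised(rec, snp)
            except HarmonisationError as exc:
                warnings.warn(f"{snp.snp_id}/{pop}: {exc}; population skipped")
                for k in ("beta", "p", "replicated", "concordant", "power"):
                    row[f"{pop}_{k}"] = np.nan
                continue
            n_present += 1
            se = rec.se if rec.se is not None else None
            if se is None:
                from .meta import recover_se

                se = recover_se(beta, rec.p) if beta != 0 and rec.p < 1 else None
            if se is not None:
                per_pop.append((beta, se))
            power_cohorts.append((rec.n, eaf))
            row[f"{pop}_beta"] = beta
            row[f"{pop}_p"] = rec.p
            row[f"{pop}_replicated"] = classify_replication(rec.p, alpha)
            row[f"{pop}_concordant"] = bool(direction_concordance(beta, snp.beta_eur))
            # power at the effect estimated in this population (not the
            # reported European effect): the question is whether the cohort
            # could detect the association at the size it shows locally
            row[f"{pop}_power"] = (
                analytic_power(rec.n, eaf, beta, sd_trait, alpha)
                if beta != 0.0 else alpha
            )
        row["n_populations"] = n_present
        meta = (meta_results or {}).get(snp.snp_id)
        if meta is None and len(per_pop) >= 1 and n_present == len(pops):
            meta = ivw_meta(per_pop, snp_id=snp.snp_id)
        if meta is not None:
            row["meta_beta"] = meta.beta_meta
            row["meta_p"] = meta.p
            row["meta_replicated"] = classify_replication(meta.p, alpha)
            row["meta_concordant"] = bool(direction_concordance(meta.beta_meta, snp.beta_eur))
            row["meta_power"] = analytic_power_meta(power_cohorts, meta.beta_meta, sd_trait, alpha)
        else:
            for k in ("beta", "p", "replicated", "concordant", "power"):
                row[f"meta_{k}"] = np.nan
        if n_present == 0:
            warnings.warn(f"{snp.snp_id}: absent from every cohort; excluded from counts")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_replicated_meta"] = int(
        df.loc[df["n_populations"] > 0, "meta_replicated"].fillna(False).sum()
    )
    df.attrs["n_discordant_meta"] = int(
        (df.loc[df["n_populations"] > 0, "meta_concordant"] == False).sum()  # noqa: E712
    )
    return df
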