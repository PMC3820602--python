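"""Synthetic multi-population cohorts with the structure the analysis assumes.

The generators emulate the study design the pipeline targets: several
ancestry groups measured for a quantitative glycaemic trait (HbA1c, %),
genotyped at biallelic SNPs, with binary microvascular-complication
phenotypes derived from threshold rules on HbA1c, eGFR and retinopathy
grade.

Population structure follows the Balding-Nichols model: each population's
allele frequency at a site is a Beta draw with mean equal to the shared
ancestral frequency p and variance F*p*(1-p), so the divergence parameter
F is also the expected SNP-level F_ST between two populations — which
gives the differentiation estimators an analytic recovery target.

Linkage is produced by founder-mosaic copying: a small founder set is
drawn per population and each haplotype copies founder segments in blocks
of ``block_length`` bp.  A small founder count yields shared multi-site
haplotypes (as needed by the haplotype-entropy metrics); when
``n_founders`` equals ``n_haplotypes`` the copy assignment is a per-block
permutation, so site frequencies are exactly binomial around the drawn
population frequencies.

Every generator takes an integer seed, is deterministic under it, and
records it in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HaplotypePanel, SummaryStatRecord

__all__ = [
    "PopulationModel",
    "draw_population_freqs",
    "simulate_panel",
    "simulate_quantitative_cohort",
    "simulate_complication_cohort",
    "simulate_summary_stats",
    "PHENOTYPE_COLUMNS",
]

#: columns of a phenotype table (one row per subject)
PHENOTYPE_COLUMNS = [
    "subject_id", "hba1c", "fasting_glucose", "egfr", "dr_grade",
    "diabetes_history", "on_diabetes_meds", "age", "sex",
]

# Defaults mirror the study conditions the pipeline targets: mean HbA1c
# ~5.7% with SD 0.4 in non-diabetic adults of mean age ~52 (SD ~11).
HBA1C_MEAN = 5.71
HBA1C_SD = 0.4
AGE_MEAN, AGE_SD = 52.0, 11.0
# modest covariate effects so "adjusted for age and gender" is non-vacuous
AGE_EFFECT = 0.004   # % HbA1c per year
SEX_EFFECT = 0.05    # % HbA1c, male vs female


@dataclass
class PopulationModel:
    """Balding-Nichols population with founder-mosaic linkage."""

    label: str
    ancestral_freqs: np.ndarray
    divergence_F: float
    block_length: int = 5_000
    n_haplotypes: int = 200
    n_founders: int | None = None

    def __post_init__(self) -> None:
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        if not 0.0 < self.divergence_F < 1.0:
            raise ValueError(f"divergence_F {self.divergence_F} outside (0, 1)")
        if np.any(self.ancestral_freqs <= 0) or np.any(self.ancestral_freqs >= 1):
            raise ValueError("ancestral_freqs must lie strictly in (0, 1)")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (diploid phasing)")


def draw_population_freqs(
    ancestral_freqs: np.ndarray,
    divergence_F: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Per-population site frequencies under Balding-Nichols.

    Each site's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F): mean p,
    variance F*p*(1-p).
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if not 0.0 < divergence_F < 1.0:
        raise ValueError(f"divergence_F {divergence_F} outside (0, 1)")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scale = (1.0 - divergence_F) / divergence_F
    draws = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(draws, 1e-12, 1.0 - 1e-12)


def simulate_panel(
    model: PopulationModel,
    region: tuple[int, int],
    n_sites: int,
    seed: int,
    positions: np.ndarray | None = None,
) -> HaplotypePanel:
    """Simulate a phased haplotype panel for one population.

    Site positions are drawn uniformly in ``region`` (inclusive, 1-based)
    unless given explicitly — panels meant to be compared share a site
    map, so pairs should pass the same ``positions`` (or use
    :func:`simulate_panel_pair`).  Population frequencies come from
    :func:`draw_population_freqs`; haplotypes are founder mosaics with
    switch points on a ``model.block_length`` grid.
    """
    start, end = region
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if end - start + 1 < model.block_length:
        raise ValueError(
            f"region of {end - start + 1} bp is shorter than one block "
            f"({model.block_length} bp)"
        )
    if model.ancestral_freqs.size != n_sites:
        raise ValueError("model.ancestral_freqs must have one entry per site")
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = np.sort(
            rng.choice(np.arange(start, end + 1), size=n_sites, replace=False)
        )
    else:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size != n_sites:
            raise ValueError("positions must have one entry per site")
    freqs = draw_population_freqs(model.ancestral_freqs, model.divergence_F, rng)

    K = model.n_founders or model.n_haplotypes
    n = model.n_haplotypes
    founders = (rng.random((K, n_sites)) < freqs).astype(np.uint8)

    block_of_site = (positions - start) // model.block_length
    n_blocks = int(block_of_site.max()) + 1
    if K == n:
        # permutation copying: panel frequencies equal founder frequencies
        assign = np.empty((n, n_blocks), dtype=np.int64)
        for b in range(n_blocks):
            assign[:, b] = rng.permutation(K)
    else:
        assign = rng.integers(0, K, size=(n, n_blocks))

    matrix = founders[assign[:, block_of_site], np.arange(n_sites)[None, :]]
    alleles = [("A", "G")] * n_sites
    return HaplotypePanel(
        population_label=model.label,
        positions=positions,
        alleles=alleles,
        matrix=matrix,
        meta={
            "seed": seed,
            "divergence_F": model.divergence_F,
            "population_freqs": freqs,
            "n_founders": K,
        },
    )


def simulate_panel_pair(
    model_a: PopulationModel,
    model_b: PopulationModel,
    region: tuple[int, int],
    n_sites: int,
    seed: int,
    shared_founders: bool = False,
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Two population panels over a common site map.

    The site positions are drawn once and shared.  In the default mode
    each population draws its own Balding-Nichols frequencies and an
    independent founder set, so SNP-level differentiation follows the
    analytic F_ST target exactly but the populations share no multi-site
    haplotypes — appropriate for allele-frequency metrics.

    With ``shared_founders=True`` both populations copy from one common
    founder pool (drawn at the ancestral frequencies) but use it with
    population-specific Dirichlet(alpha) weights, alpha = (1-F)/(K*F) for
    K founders, so each founder haplotype's usage frequency has mean 1/K
    and Balding-Nichols variance F*(1/K)*(1-1/K).  Populations then share
    haplotypes to a degree that shrinks as F grows — the structure the
    haplotype-entropy metric measures.  Both models must set
    ``n_founders`` and agree on it in this mode.

    The two models are expected to share ``ancestral_freqs`` so the pair
    diverges by their F parameters alone.
    """
    rng = np.random.default_rng(seed)
    start, end = region
    positions = np.sort(rng.choice(np.arange(start, end + 1), size=n_sites, replace=False))
    if not shared_founders:
        sub = rng.integers(0, 2**31 - 1, size=2)
        pa = simulate_panel(model_a, region, n_sites, int(sub[0]), positions=positions)
        pb = simulate_panel(model_b, region, n_sites, int(sub[1]), positions=positions)
        return pa, pb

    K = model_a.n_founders
    if not K or model_b.n_founders != K:
        raise ValueError("shared_founders mode requires both models to set the same n_founders")
    founders = (rng.random((K, n_sites)) < model_a.ancestral_freqs).astype(np.uint8)
    block_of_site = (positions - start) // model_a.block_length
    n_blocks = int(block_of_site.max()) + 1
    panels = []
    for model in (model_a, model_b):
        F = model.divergence_F
        alpha = (1.0 - F) / (K * F)
        w = rng.dirichlet(np.full(K, alpha))
        assign = rng.choice(K, size=(model.n_haplotypes, n_blocks), p=w)
        matrix = founders[assign[:, block_of_site], np.arange(n_sites)[None, :]]
        panels.append(HaplotypePanel(
            population_label=model.label,
            positions=positions,
            alleles=[("A", "G")] * n_sites,
            matrix=matrix,
            meta={"seed": seed, "divergence_F": F, "n_founders": K,
                  "founder_weights": w},
        ))
    return panels[0], panels[1]


def _base_phenotypes(n: int, rng: np.random.Generator, n_pcs: int = 0) -> pd.DataFrame:
    df = pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "fasting_glucose": np.round(rng.normal(5.0, 0.5, n), 2),
        "egfr": np.full(n, 90.0),
        "dr_grade": np.zeros(n, dtype=int),
        "diabetes_history": np.zeros(n, dtype=bool),
        "on_diabetes_meds": np.zeros(n, dtype=bool),
        "age": np.round(rng.normal(AGE_MEAN, AGE_SD, n), 1),
        "sex": rng.integers(0, 2, n),
    })
    for k in range(n_pcs):
        df[f"PC{k + 1}"] = rng.normal(0.0, 1.0, n)
    return df


def simulate_quantitative_cohort(
    n: int,
    eaf: float,
    beta: float,
    sd_trait: float = HBA1C_SD,
    covariate_spec: dict[str, float] | None = None,
    seed: int = 0,
    intercept: float = HBA1C_MEAN,
    n_pcs: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Quantitative-trait cohort: HbA1c linear in allele dosage.

    hba1c = intercept + beta*dosage + covariate effects + N(0, sd_trait),
    with dosage ~ Binomial(2, eaf).  ``covariate_spec`` maps covariate
    column names to trait effects; the default applies small age and sex
    effects so covariate adjustment is exercised.
    """
    if sd_trait <= 0:
        raise ValueError("sd_trait must be positive")
    if not 0.0 < eaf < 1.0:
        raise ValueError("eaf must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, eaf, n).astype(float)
    pheno = _base_phenotypes(n, rng, n_pcs=n_pcs)
    effects = {"age": AGE_EFFECT, "sex": SEX_EFFECT} if covariate_spec is None else covariate_spec
    trait = intercept + beta * dosage + rng.normal(0.0, sd_trait, n)
    for name, eff in effects.items():
        centred = pheno[name] - pheno[name].mean()
        trait = trait + eff * centred.to_numpy(dtype=float)
    pheno["hba1c"] = trait
    pheno.attrs["seed"] = seed
    return dosage, pheno


def simulate_complication_cohort(
    n: int,
    eaf: float,
    or_effect: float,
    baseline_prevalence: float,
    t2d_mixture: float = 0.3,
    seed: int = 0,
    outcome: str = "ckd",
    n_pcs: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Case-control cohort for a diabetic complication.

    The binary complication is drawn from logit(pi) = alpha +
    log(or_effect)*dosage, with alpha set so the dosage-averaged
    prevalence is ``baseline_prevalence``.  Phenotype fields are then
    populated so the threshold classifiers reproduce the drawn labels:
    CKD cases get eGFR in [15, 60), controls in [60, 120]; retinopathy
    cases get grade >= 30 (moderate/severe) and controls grade < 14.

    ``t2d_mixture`` is the fraction of subjects meeting the T2D-case
    definition (HbA1c >= 6.5% or diabetic history); the remainder are
    clean controls (HbA1c < 6%, no history, fasting glucose <= 6).
    """
    if not 0.0 < baseline_prevalence < 1.0:
        raise ValueError("baseline_prevalence must lie in (0, 1)")
    if or_effect <= 0:
        raise ValueError("or_effect must be positive")
    if not 0.0 <= t2d_mixture <= 1.0:
        raise ValueError("t2d_mixture must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, eaf, n).astype(float)
    pheno = _base_phenotypes(n, rng, n_pcs=n_pcs)

    log_or = np.log(or_effect)
    alpha = _solve_intercept(baseline_prevalence, log_or, eaf)
    pi = 1.0 / (1.0 + np.exp(-(alpha + log_or * dosage)))
    case = rng.random(n) < pi

    if outcome == "ckd":
        egfr = np.where(case, rng.uniform(15.0, 59.9, n), rng.uniform(60.0, 120.0, n))
        pheno["egfr"] = egfr
    elif outcome in ("dr-moderate", "dr-any"):
        grade = np.where(case, rng.integers(30, 66, n), rng.integers(0, 14, n))
        pheno["dr_grade"] = grade
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    t2d = rng.random(n) < t2d_mixture
    hba1c = np.where(t2d, rng.uniform(6.5, 9.5, n), rng.uniform(4.8, 5.99, n))
    history = t2d & (rng.random(n) < 0.5)
    pheno["hba1c"] = np.round(hba1c, 2)
    pheno["diabetes_history"] = history
    pheno["on_diabetes_meds"] = history & (rng.random(n) < 0.7)
    pheno["fasting_glucose"] = np.where(t2d, rng.uniform(7.0, 12.0, n),
                                        rng.uniform(4.0, 6.0, n)).round(2)
    pheno.attrs["seed"] = seed
    return dosage, pheno


def _solve_intercept(prevalence: float, log_or: float, eaf: float) -> float:
    """Intercept alpha with E_dosage[expit(alpha + log_or*d)] = prevalence."""
    from scipy.optimize import brentq

    q = 1.0 - eaf
    wts = np.array([q * q, 2 * eaf * q, eaf * eaf])
    dos = np.array([0.0, 1.0, 2.0])

    def f(a: float) -> float:
        return float(wts @ (1.0 / (1.0 + np.exp(-(a + log_or * dos)))) - prevalence)

    return brentq(f, -30.0, 30.0)


def simulate_summary_stats(
    m_snps: int,
    n: int,
    null_fraction: float = 1.0,
    effect_distribution=None,
    seed: int = 0,
    sd_trait: float = HBA1C_SD,
    eaf_range: tuple[float, float] = (0.05, 0.95),
) -> list[SummaryStatRecord]:
    """Summary statistics for a mixture of null and effect SNPs.

    Null SNPs have z ~ N(0, 1); the SE follows the linear-model formula
    SE = sd_trait / sqrt(2*n*p*(1-p)) and beta = z*SE.  Non-null SNPs draw
    a true beta from ``effect_distribution`` (a callable
    ``rng, size -> array``; default N(0, 0.03)) and observe beta_hat =
    beta + N(0, SE).
    """
    if m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(*eaf_range, m_snps)
    se = sd_trait / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
    is_null = rng.random(m_snps) < null_fraction
    beta_true = np.zeros(m_snps)
    if not is_null.all():
        k = int((~is_null).sum())
        if effect_distribution is None:
            beta_true[~is_null] = rng.normal(0.0, 0.03, k)
        else:
            beta_true[~is_null] = effect_distribution(rng, k)
    beta_hat = beta_true + rng.normal(0.0, 1.0, m_snps) * se
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    records = []
    for i in range(m_snps):
        records.append(SummaryStatRecord(
            snp_id=f"snp{i:06d}",
            chrom="1",
            pos=1_000_000 + 1_000 * i,
            effect_allele="A",
            other_allele="G",
            eaf=float(eaf[i]),
            beta=float(beta_hat[i]),
            se=float(se[i]),
            p=float(p[i]),
            n=n,
        ))
    return records
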