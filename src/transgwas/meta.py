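"""Genomic control and fixed-effect inverse-variance meta-analysis.

The combination rule is the classical fixed-effect scheme: with study
estimates beta_i and standard errors se_i, weights w_i = se_i^-2 give

    beta_meta = sum(w_i * beta_i) / sum(w_i),   se_meta = sum(w_i)^-1/2,

and the meta P comes from the normal reference (large-sample Wald).

Published tables often print only (beta, P); :func:`recover_se` inverts
the two-sided normal test, se = |beta| / Phi^-1(1 - P/2), so such tables
can be re-combined.

Genomic control estimates the inflation factor lambda as the ratio of the
observed median 1-df association chi-square to its null median (0.4549)
and, when lambda > 1, deflates the statistics.  Because meta-analysis
consumes (beta, se), the adjustment is applied as SE inflation by
sqrt(lambda) — algebraically identical to dividing chi-square by lambda.
lambda < 1 is reported as a diagnostic but never used to deflate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MetaResult",
    "GcReport",
    "recover_se",
    "ivw_meta",
    "genomic_control",
    "gc_adjust_se",
    "hierarchical_meta",
    "count_significant",
]

#: median of the 1-df chi-square distribution, at 4-decimal precision
CHI2_1DF_NULL_MEDIAN = 0.4549


@dataclass
class MetaResult:
    snp_id: str
    beta_meta: float
    se_meta: float
    z: float
    p: float
    k_studies: int
    direction: str  # METAL-style, one of +/-/? per study

    @property
    def or_(self) -> float:
        return math.exp(self.beta_meta)

    @property
    def ci95(self) -> tuple[float, float]:
        lo = self.beta_meta - 1.959963984540054 * self.se_meta
        hi = self.beta_meta + 1.959963984540054 * self.se_meta
        return lo, hi


@dataclass
class GcReport:
    lambda_gc: float
    n_tests: int


def recover_se(beta: float, p: float) -> float:
    """Standard error implied by (beta, P) under the two-sided normal test."""
    if beta == 0:
        raise ValueError("se is undefined for beta = 0")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    z = stats.norm.isf(p / 2.0)
    return abs(beta) / z


def ivw_meta(
    studies: Sequence[tuple[float, float]],
    snp_id: str = "snp",
) -> MetaResult:
    """Fixed-effect inverse-variance combination of (beta, se) pairs."""
    if len(studies) == 0:
        raise ValueError("at least one study is required")
    beta = np.array([b for b, _ in studies], dtype=float)
    se = np.array([s for _, s in studies], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = se ** -2.0
    beta_meta = float(np.sum(w * beta) / np.sum(w))
    se_meta = float(np.sum(w) ** -0.5)
    z = beta_meta / se_meta
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    direction = "".join("+" if b > 0 else "-" if b < 0 else "?" for b in beta)
    return MetaResult(snp_id, beta_meta, se_meta, z, p, len(studies), direction)


def genomic_control(
    p_values: Sequence[float] | None = None,
    chisq: Sequence[float] | None = None,
    adjust: bool = True,
) -> tuple[GcReport, np.ndarray]:
    """Estimate lambda_GC and return GC-adjusted P values.

    Provide either two-sided P values (inverted to 1-df chi-squares) or
    the chi-square statistics themselves.  The adjusted statistics are
    chisq / max(lambda, 1); with ``adjust=False`` only the diagnostic is
    wanted and the input P values are returned unchanged.
    """
    if (p_values is None) == (chisq is None):
        raise ValueError("provide exactly one of p_values or chisq")
    if p_values is not None:
        p_arr = np.asarray(p_values, dtype=float)
        x = stats.chi2.isf(p_arr, df=1)
    else:
        x = np.asarray(chisq, dtype=float)
    if x.size < 2:
        raise ValueError("at least 2 tests are required")
    lam = float(np.median(x) / CHI2_1DF_NULL_MEDIAN)
    report = GcReport(lambda_gc=lam, n_tests=int(x.size))
    if not adjust:
        if p_values is not None:
            return report, np.asarray(p_values, dtype=float)
        return report, x
    adj = x / max(lam, 1.0)
    p_adj = stats.chi2.sf(adj, df=1)
    return report, p_adj


def gc_adjust_se(se, lambda_gc: float):
    """Apply genomic control on the (beta, se) scale: se * sqrt(max(lambda, 1))."""
    return np.asarray(se, dtype=float) * math.sqrt(max(lambda_gc, 1.0))


def hierarchical_meta(
    stage1: dict[str, Sequence[tuple[float, float]]],
    group_lambdas: dict[str, float] | None = None,
    snp_id: str = "snp",
) -> MetaResult:
    """Two-stage IVW: combine studies within each named group, then combine
    the group-level results.

    ``group_lambdas`` optionally applies genomic control between the
    stages, inflating each group's SE by sqrt(max(lambda, 1)).  Without
    inter-stage GC the result is algebraically identical to a flat
    single-stage IVW over all studies.
    """
    if not stage1:
        raise ValueError("at least one group is required")
    stage2: list[tuple[float, float]] = []
    directions = []
    for name, studies in stage1.items():
        res = ivw_meta(studies, snp_id=snp_id)
        se = res.se_meta
        if group_lambdas and name in group_lambdas:
            se = float(gc_adjust_se(se, group_lambdas[name]))
        stage2.append((res.beta_meta, se))
        directions.append(res.direction)
    out = ivw_meta(stage2, snp_id=snp_id)
    out.direction = "".join(directions)
    out.k_studies = sum(len(v) for v in stage1.values())
    return out


def count_significant(results: Iterable, alpha: float = 0.05) -> int:
    """Number of results with P <= alpha (inclusive).

    Accepts raw P values or any objects with a ``p`` attribute; absent
    (None/NaN) P values do not count.
    """
    count = 0
    for r in results:
        p = getattr(r, "p", r)
        if p is None:
            continue
        p = float(p)
        if math.isfinite(p) and p <= alpha:
            count += 1
    return count
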