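"""Population-differentiation metrics around index SNPs.

Two complementary regional metrics are computed over a window (by default
+/- 50 kb, inclusive) centred on an index SNP, for a pair of populations:

* **Regional F_ST** — the mean of SNP-level F_ST over the sites shared by
  the two panels in the window.  The SNP-level estimator is Hudson's,

      F_ST = [(p_a - p_b)^2 - p_a(1-p_a)/(n_a-1) - p_b(1-p_b)/(n_b-1)]
             / [p_a(1-p_b) + p_b(1-p_a)],

  which is unbiased in the numerator/denominator and may be negative on
  finite samples.  Weir-Cockerham is available behind a flag.  Regional
  aggregation defaults to the mean of per-site ratios; the ratio-of-sums
  form (sum of numerators over sum of denominators), which is the
  recommended multi-SNP combination because the mean of per-site ratios
  is downward-biased at strong differentiation, is available via
  ``method="ratio"``.

* **Haplotype entropy** — haplotypes are enumerated over the window's
  shared polymorphic sites; for haplotype i with frequencies f_iA, f_iB
  the relative mutual information is

      RMI(i) = 1 + (F_iA log F_iA + F_iB log F_iB) / log 2,
      F_ij = f_ij / (f_iA + f_iB),

  0 for a haplotype equally frequent in both populations, 1 for a private
  one.  The regional entropy is the overall-frequency weighted mean
  sum_i f_i. * RMI(i) / sum_i f_i., bounded in [0, 1]; whether f_i. is
  the sum or the mean of the pair provably does not change the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HaplotypePanel

__all__ = [
    "HaplotypeFreqTable",
    "DiffMetrics",
    "snp_fst",
    "regional_fst",
    "enumerate_haplotypes",
    "rmi",
    "haplotype_entropy",
    "diff_metrics",
    "compare_groups",
]

LN2 = math.log(2.0)


@dataclass
class HaplotypeFreqTable:
    """Windowed haplotype frequencies for a pair of populations.

    ``rows`` has columns ``haplotype`` (0/1 string over the window's
    shared polymorphic sites), ``f_a`` and ``f_b``.
    """

    window: tuple[str, int, int]
    pair: tuple[str, str]
    rows: pd.DataFrame


@dataclass
class DiffMetrics:
    index_snp_id: str
    regional_fst: float
    haplotype_entropy: float
    n_snps_in_window: int
    n_haplotypes: int


def snp_fst(
    p_a: float,
    p_b: float,
    n_a: int,
    n_b: int,
    estimator: str = "hudson",
) -> float:
    """SNP-level F_ST between two populations from allele frequencies and
    haplotype sample sizes.

    Returns NaN when the denominator vanishes (both populations fixed for
    the same allele); callers skip such sites.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("at least 2 haplotypes per population are required")
    if estimator == "hudson":
        num = (p_a - p_b) ** 2 - p_a * (1 - p_a) / (n_a - 1) - p_b * (1 - p_b) / (n_b - 1)
        den = p_a * (1 - p_b) + p_b * (1 - p_a)
        return num / den if den > 0 else float("nan")
    if estimator == "weir-cockerham":
        return _weir_cockerham(p_a, p_b, n_a, n_b)
    raise ValueError(f"unknown estimator {estimator!r}")


def _weir_cockerham(p_a: float, p_b: float, n_a: int, n_b: int) -> float:
    # two-population haploid-sample form of the variance-components estimator
    r = 2.0
    n_bar = (n_a + n_b) / r
    nc = (n_a + n_b - (n_a ** 2 + n_b ** 2) / (n_a + n_b)) / (r - 1)
    p_bar = (n_a * p_a + n_b * p_b) / (n_a + n_b)
    s2 = (n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2) / ((r - 1) * n_bar)
    a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
    den = a + b
    return a / den if den > 0 else float("nan")


def _hudson_components(fa, fb, n_a, n_b):
    num = (fa - fb) ** 2 - fa * (1 - fa) / (n_a - 1) - fb * (1 - fb) / (n_b - 1)
    den = fa * (1 - fb) + fb * (1 - fa)
    return num, den


def _shared_site_indices(panel_a: HaplotypePanel, panel_b: HaplotypePanel):
    common, ia, ib = np.intersect1d(
        panel_a.positions, panel_b.positions, return_indices=True
    )
    return common, ia, ib


def regional_fst(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    index_pos: int,
    flank: int = 50_000,
    method: str = "mean",
    estimator: str = "hudson",
) -> tuple[float, int]:
    """Regional F_ST over shared sites within ``index_pos`` +/- ``flank``.

    ``method="mean"`` averages per-site estimates (sites with an undefined
    estimate are excluded from numerator and count); ``method="ratio"``
    forms the ratio of summed numerator and denominator components
    (Hudson estimator only).  Returns (value, number of sites used);
    (NaN, 0) with a warning when no usable shared site exists.
    """
    pos, ia, ib = _shared_site_indices(panel_a, panel_b)
    in_win = (pos >= index_pos - flank) & (pos <= index_pos + flank)
    ia, ib = ia[in_win], ib[in_win]
    if ia.size == 0:
        warnings.warn("no shared sites in window; regional F_ST undefined")
        return float("nan"), 0
    fa = panel_a.matrix[:, ia].mean(axis=0)
    fb = panel_b.matrix[:, ib].mean(axis=0)
    n_a, n_b = panel_a.n_haplotypes, panel_b.n_haplotypes
    if method == "ratio":
        if estimator != "hudson":
            raise ValueError("ratio-of-sums aggregation is defined for the Hudson estimator")
        num, den = _hudson_components(fa, fb, n_a, n_b)
        ok = den > 0
        if not ok.any():
            warnings.warn("all shared window sites are fixed; regional F_ST undefined")
            return float("nan"), 0
        return float(num[ok].sum() / den[ok].sum()), int(ok.sum())
    if method != "mean":
        raise ValueError(f"unknown method {method!r}")
    vals = np.array([
        snp_fst(a, b, n_a, n_b, estimator=estimator) for a, b in zip(fa, fb)
    ])
    ok = np.isfinite(vals)
    if not ok.any():
        warnings.warn("all shared window sites are fixed; regional F_ST undefined")
        return float("nan"), 0
    return float(vals[ok].mean()), int(ok.sum())


def enumerate_haplotypes(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    window: tuple[int, int],
    min_freq: float = 0.02,
    rule: str = "union",
) -> HaplotypeFreqTable:
    """Windowed haplotype frequency table over shared polymorphic sites.

    Haplotypes are strings over the sites present in both panels within
    ``window`` (inclusive) that are polymorphic in at least one of the
    two populations.  A haplotype is retained when its frequency reaches
    ``min_freq`` in at least one population (``rule="union"``, default) or
    in both (``rule="intersection"``).  Frequencies are reported
    unnormalised (they need not sum to 1 after filtering).
    """
    start, end = window
    pos, ia, ib = _shared_site_indices(panel_a, panel_b)
    in_win = (pos >= start) & (pos <= end)
    ia, ib = ia[in_win], ib[in_win]
    if ia.size == 0:
        raise ValueError("window contains no site shared by the two panels")
    sub_a = panel_a.matrix[:, ia]
    sub_b = panel_b.matrix[:, ib]
    both = np.vstack([sub_a, sub_b])
    poly = (both.min(axis=0) != both.max(axis=0))
    sub_a, sub_b = sub_a[:, poly], sub_b[:, poly]
    if sub_a.shape[1] == 0:
        # window monomorphic in both populations: one shared haplotype
        rows = pd.DataFrame({"haplotype": [""], "f_a": [1.0], "f_b": [1.0]})
        return HaplotypeFreqTable((_chrom(panel_a), start, end),
                                  (panel_a.population_label, panel_b.population_label), rows)

    def counts(mat: np.ndarray) -> dict[str, int]:
        out: dict[str, int] = {}
        for row in mat:
            key = "".join(map(str, row))
            out[key] = out.get(key, 0) + 1
        return out

    ca, cb = counts(sub_a), counts(sub_b)
    haps = sorted(set(ca) | set(cb))
    f_a = np.array([ca.get(h, 0) / panel_a.n_haplotypes for h in haps])
    f_b = np.array([cb.get(h, 0) / panel_b.n_haplotypes for h in haps])
    if rule == "union":
        keep = (f_a >= min_freq) | (f_b >= min_freq)
    elif rule == "intersection":
        keep = (f_a >= min_freq) & (f_b >= min_freq)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    rows = pd.DataFrame({
        "haplotype": [h for h, k in zip(haps, keep) if k],
        "f_a": f_a[keep],
        "f_b": f_b[keep],
    })
    return HaplotypeFreqTable(
        (_chrom(panel_a), start, end),
        (panel_a.population_label, panel_b.population_label),
        rows,
    )


def _chrom(panel: HaplotypePanel) -> str:
    return str(panel.meta.get("chrom", "?"))


def rmi(f_a: float, f_b: float) -> float:
    """Relative mutual information of one haplotype's frequency pair.

    0 when the haplotype is equally frequent in the two populations, 1
    when private to one; 0*log 0 is taken as 0.
    """
    if f_a < 0 or f_b < 0:
        raise ValueError("frequencies must be non-negative")
    tot = f_a + f_b
    if tot == 0:
        raise ValueError("both frequencies are zero")
    Fa, Fb = f_a / tot, f_b / tot
    acc = 0.0
    for F in (Fa, Fb):
        if F > 0:
            acc += F * math.log(F)
    return 1.0 + acc / LN2


def haplotype_entropy(table: HaplotypeFreqTable, combine: str = "mean") -> float:
    """Overall-frequency weighted mean RMI over a window's haplotypes.

    ``combine`` sets whether a haplotype's overall frequency f_i. is the
    mean or the sum of its two population frequencies; the weighting
    normalises, so both give the identical entropy.
    """
    rows = table.rows
    if len(rows) == 0:
        raise ValueError("haplotype table is empty")
    f_a = rows["f_a"].to_numpy(dtype=float)
    f_b = rows["f_b"].to_numpy(dtype=float)
    if combine == "mean":
        w = (f_a + f_b) / 2.0
    elif combine == "sum":
        w = f_a + f_b
    else:
        raise ValueError(f"unknown combine {combine!r}")
    vals = np.array([rmi(a, b) for a, b in zip(f_a, f_b)])
    return float(np.sum(w * vals) / np.sum(w))


def diff_metrics(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    index_snp_id: str,
    index_pos: int,
    flank: int = 50_000,
    min_freq: float = 0.02,
) -> DiffMetrics:
    """Regional F_ST and haplotype entropy around one index SNP."""
    fst, n_snps = regional_fst(panel_a, panel_b, index_pos, flank)
    table = enumerate_haplotypes(
        panel_a, panel_b, (index_pos - flank, index_pos + flank), min_freq
    )
    return DiffMetrics(
        index_snp_id=index_snp_id,
        regional_fst=fst,
        haplotype_entropy=haplotype_entropy(table),
        n_snps_in_window=n_snps,
        n_haplotypes=len(table.rows),
    )


def compare_groups(
    values_replicated,
    values_failed,
) -> tuple[float, float]:
    """Pooled-variance two-sample t test of replicated vs failed loci.

    One-tailed, for the alternative mean(replicated) < mean(failed) — the
    hypothesis that transferable loci are the less differentiated ones.
    Returns (t statistic, one-tail P).
    """
    a = np.asarray(values_replicated, dtype=float)
    b = np.asarray(values_failed, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        warnings.warn("zero pooled variance; degenerate comparison")
        if a.mean() == b.mean():
            return 0.0, 0.5
        return (-math.inf, 0.0) if a.mean() < b.mean() else (math.inf, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative="less")
    return float(t), float(p)
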