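"""Readers and writers for the pipeline's external representations.

Three kinds of files are handled: per-cohort GWAS summary statistics
(tab-delimited), phased haplotype panels (phased VCF or IMPUTE-style
hap/legend/sample), and index-SNP tables listing literature-reported
variants with their European effect estimates.

Conventions
-----------
* Coordinates are 1-based base pairs throughout; windows are inclusive on
  both ends.
* ``NA`` and the empty string parse as "absent"; any other non-numeric
  token is a format error carrying the offending row number.
* Alleles are taken as written.  Harmonising a cohort record against an
  index SNP flips the sign of beta and maps eaf to 1-eaf when the
  effect/other alleles are swapped; strand-ambiguous (A/T, C/G) mismatches
  are rejected rather than guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "HaplotypePanel",
    "IndexSnp",
    "FormatError",
    "ValidationError",
    "HarmonisationError",
    "read_summary_stats",
    "write_summary_stats",
    "read_phased_panel",
    "read_index_snps",
    "load_table2",
    "table2_index_snps",
    "table2_cohort_records",
    "table2_meta_results",
    "TABLE2_N",
    "harmonise",
    "write_report",
    "read_report",
    "DEFAULT_DIALECT",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


class HarmonisationError(ValueError):
    """Alleles of two records cannot be reconciled."""


COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_strand_ambiguous(a: str, b: str) -> bool:
    return COMPLEMENT.get(a.upper()) == b.upper()


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association summary in one cohort.

    ``beta`` is in trait units per copy of the effect allele (HbA1c in %
    for the glycaemic analyses).  ``se`` and ``info`` may be absent:
    printed tables often carry only (beta, P), and only imputed SNPs have
    an imputation information score.  ``missing_rate`` and ``hwe_p`` are
    optional per-SNP QC metrics consumed by :func:`transgwas.assoc.snp_qc_filter`.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    p: float
    n: int
    se: float | None = None
    info: float | None = None
    missing_rate: float | None = None
    hwe_p: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"{self.snp_id}: p {self.p} outside (0, 1]")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if self.se is not None and not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se {self.se} must be positive")
        if self.info is not None and not 0.0 <= self.info <= 1.0:
            raise ValidationError(f"{self.snp_id}: info {self.info} outside [0, 1]")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix for one population.

    ``matrix`` is haplotypes x sites with entries in {0, 1} (0 = reference
    allele, 1 = alternate).  ``positions`` are strictly increasing 1-based
    coordinates; ``alleles`` holds the per-site (ref, alt) pair.
    """

    population_label: str
    positions: np.ndarray
    alleles: list[tuple[str, str]]
    matrix: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.positions.ndim != 1 or self.matrix.ndim != 2:
            raise ValidationError("positions must be 1-D and matrix 2-D")
        if self.matrix.shape[1] != self.positions.size:
            raise ValidationError("matrix column count must match number of positions")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValidationError("positions must be strictly increasing")
        if self.matrix.size and self.matrix.max() > 1:
            raise ValidationError("haplotype matrix entries must be 0/1")
        if len(self.alleles) != self.positions.size:
            raise ValidationError("one (ref, alt) pair required per site")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def frequencies(self) -> np.ndarray:
        """Alternate-allele frequency at each site."""
        return self.matrix.mean(axis=0)

    def window(self, start: int, end: int) -> "HaplotypePanel":
        """Sub-panel of sites with start <= position <= end (inclusive)."""
        keep = (self.positions >= start) & (self.positions <= end)
        idx = np.nonzero(keep)[0]
        return HaplotypePanel(
            population_label=self.population_label,
            positions=self.positions[idx],
            alleles=[self.alleles[i] for i in idx],
            matrix=self.matrix[:, idx],
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class IndexSnp:
    """A literature-reported lead variant with its European effect."""

    snp_id: str
    chrom: str
    pos: int
    locus_name: str
    effect_allele: str
    eaf_eur: float
    beta_eur: float
    source: str = "literature"

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta_eur) or self.beta_eur == 0.0:
            raise ValidationError(f"{self.snp_id}: beta_eur must be finite and nonzero")


#: canonical column names of the summary-statistic TSV dialect
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
    "info": "INFO",
    "missing_rate": "MISS",
    "hwe_p": "HWE_P",
}

_OPTIONAL_FIELDS = {"se", "info", "missing_rate", "hwe_p"}
_MANDATORY_FIELDS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "p", "n",
]


def _parse_float(token: str, *, row: int, col: str, optional: bool) -> float | None:
    token = token.strip()
    if token in ("", "NA"):
        if optional:
            return None
        raise FormatError(f"row {row}: mandatory column {col} is missing")
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"row {row}: column {col} has non-numeric value {token!r}") from None


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Read a tab-delimited summary-statistics file.

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`)
    to the file's column headers; unmapped optional fields are skipped.
    Malformed numeric fields raise :class:`FormatError` naming the data-row
    number (1-based, header excluded); out-of-range values raise
    :class:`ValidationError` naming the row.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fld in _MANDATORY_FIELDS:
        if colmap[fld] not in df.columns:
            raise FormatError(f"missing mandatory column {colmap[fld]!r}")
    records: list[SummaryStatRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        kwargs: dict = {}
        for fld in _MANDATORY_FIELDS + sorted(_OPTIONAL_FIELDS):
            col = colmap.get(fld)
            if col is None or col not in df.columns:
                continue
            token = str(row_d[col])
            if fld in ("snp_id", "chrom", "effect_allele", "other_allele"):
                kwargs[fld] = token.strip()
            elif fld in ("pos", "n"):
                val = _parse_float(token, row=i, col=col, optional=False)
                kwargs[fld] = int(val)
            else:
                val = _parse_float(token, row=i, col=col, optional=fld in _OPTIONAL_FIELDS)
                if val is not None:
                    kwargs[fld] = val
        try:
            records.append(SummaryStatRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    """Write records in the default TSV dialect (absent values as NA)."""
    rows = []
    for r in records:
        rows.append({
            "SNP": r.snp_id, "CHR": r.chrom, "BP": r.pos,
            "EA": r.effect_allele, "OA": r.other_allele,
            "EAF": _fmt(r.eaf), "BETA": _fmt(r.beta), "SE": _fmt(r.se),
            "P": _fmt(r.p), "N": r.n, "INFO": _fmt(r.info),
            "MISS": _fmt(r.missing_rate), "HWE_P": _fmt(r.hwe_p),
        })
    pd.DataFrame(rows, columns=list(DEFAULT_DIALECT.values())).to_csv(
        path, sep="\t", index=False
    )


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.6g}"


# ---------------------------------------------------------------------------
# phased haplotype panels


def read_phased_panel(
    path: str | Path,
    format: str | None = None,
    population_label: str | None = None,
) -> HaplotypePanel:
    """Read a phased panel from a VCF or an IMPUTE hap/legend pair.

    ``format`` is ``"vcf"`` or ``"hap-legend-sample"``; when omitted it is
    inferred from the file suffix (``.vcf``/``.vcf.gz`` vs ``.hap``).  For
    hap/legend input, ``path`` names the ``.hap`` file and the matching
    ``.legend`` is looked up beside it.

    Unphased genotypes (``/`` separator) and multiallelic sites are
    rejected: the differentiation metrics downstream are defined on
    biallelic phased data.
    """
    path = Path(path)
    if format is None:
        if path.suffix == ".hap":
            format = "hap-legend-sample"
        elif ".vcf" in path.suffixes or path.suffix == ".vcf":
            format = "vcf"
        else:
            raise FormatError(f"cannot infer panel format from {path.name!r}")
    if format == "vcf":
        return _read_vcf_panel(path, population_label)
    if format == "hap-legend-sample":
        return _read_hls_panel(path, population_label)
    raise FormatError(f"unknown panel format {format!r}")


def _read_vcf_panel(path: Path, label: str | None) -> HaplotypePanel:
    from cyvcf2 import VCF

    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    vcf = VCF(str(path))
    n_samples = len(vcf.samples)
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise FormatError(
                f"{variant.CHROM}:{variant.POS}: multiallelic site; metrics are biallelic"
            )
        gts = variant.genotypes  # [a0, a1, phased] per sample
        col = np.empty(2 * n_samples, dtype=np.uint8)
        for s, gt in enumerate(gts):
            if not gt[-1]:
                raise FormatError(
                    f"{variant.CHROM}:{variant.POS}: unphased genotype; "
                    "phasing ('|') is required"
                )
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                raise FormatError(f"{variant.CHROM}:{variant.POS}: missing genotype")
            col[2 * s] = a0
            col[2 * s + 1] = a1
        positions.append(variant.POS)
        alleles.append((variant.REF, variant.ALT[0]))
        columns.append(col)
    matrix = np.column_stack(columns) if columns else np.empty((2 * n_samples, 0), np.uint8)
    return HaplotypePanel(label or path.stem, np.array(positions, dtype=np.int64),
                          alleles, matrix)


def _read_hls_panel(path: Path, label: str | None) -> HaplotypePanel:
    legend_path = path.with_suffix(".legend")
    if not legend_path.exists():
        raise FormatError(f"legend file {legend_path.name!r} not found beside {path.name!r}")
    legend = pd.read_csv(legend_path, sep=r"\s+")
    for col in ("id", "position", "a0", "a1"):
        if col not in legend.columns:
            raise FormatError(f"legend is missing column {col!r}")
    hap = np.loadtxt(path, dtype=np.uint8, ndmin=2)
    # .hap convention: one row per site, one column per haplotype
    if hap.shape[0] != len(legend):
        raise FormatError(
            f"hap has {hap.shape[0]} rows but legend lists {len(legend)} sites"
        )
    if hap.size and hap.max() > 1:
        raise FormatError("hap entries must be 0/1")
    alleles = list(zip(legend["a0"].astype(str), legend["a1"].astype(str)))
    return HaplotypePanel(
        label or path.stem,
        legend["position"].to_numpy(dtype=np.int64),
        alleles,
        hap.T,
    )


# ---------------------------------------------------------------------------
# index SNPs and the packaged worked-example table


def read_index_snps(path: str | Path) -> list[IndexSnp]:
    """Read an index-SNP TSV (columns SNP CHR BP GENE EA EAF_EUR BETA_EUR [SOURCE])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["SNP", "CHR", "BP", "GENE", "EA", "EAF_EUR", "BETA_EUR"]
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    out = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        out.append(IndexSnp(
            snp_id=row["SNP"],
            chrom=row["CHR"],
            pos=int(row["BP"]),
            locus_name=row["GENE"],
            effect_allele=row["EA"],
            eaf_eur=float(_parse_float(row["EAF_EUR"], row=i, col="EAF_EUR", optional=False)),
            beta_eur=float(_parse_float(row["BETA_EUR"], row=i, col="BETA_EUR", optional=False)),
            source=row.get("SOURCE", "literature"),
        ))
    return out


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_table2() -> pd.DataFrame:
    """Packaged fixture: the published per-population and meta summary of
    the European-established HbA1c index SNPs (beta in % HbA1c per effect
    allele; ``NA`` where a SNP failed QC or was absent in a population)."""
    df = pd.read_csv(_data_path("table2.tsv"), sep="\t", na_values=["NA"])
    return df


def table2_index_snps() -> list[IndexSnp]:
    """Index-SNP objects for the packaged worked-example table."""
    return read_index_snps(_data_path("table2.tsv"))


#: per-population sample sizes of the cohorts behind the worked-example table
TABLE2_N = {"Chinese": 3427, "Malay": 1735, "Indian": 1520}


def table2_cohort_records() -> dict[str, dict[str, SummaryStatRecord]]:
    """Per-population summary records from the packaged worked-example table.

    The published table prints EAF, beta and P per population (no SE and
    no other allele); the other allele is filled with a non-ambiguous
    placeholder and SE is left absent for downstream reconstruction.
    SNPs absent from a population (printed NA) are omitted from that
    population's mapping.
    """
    df = load_table2()
    out: dict[str, dict[str, SummaryStatRecord]] = {}
    for pop, n in TABLE2_N.items():
        key = pop.upper()
        recs: dict[str, SummaryStatRecord] = {}
        for _, row in df.iterrows():
            if pd.isna(row[f"BETA_{key}"]) or pd.isna(row[f"P_{key}"]):
                continue
            ea = str(row["EA"])
            oa = "C" if ea != "C" else "A"
            recs[row["SNP"]] = SummaryStatRecord(
                snp_id=row["SNP"],
                chrom=str(row["CHR"]),
                pos=int(row["BP"]),
                effect_allele=ea,
                other_allele=oa,
                eaf=float(row[f"EAF_{key}"]),
                beta=float(row[f"BETA_{key}"]),
                p=float(row[f"P_{key}"]),
                n=n,
            )
        out[pop] = recs
    return out


def table2_meta_results():
    """Published meta-analysis rows of the worked-example table as
    :class:`transgwas.meta.MetaResult` objects (SE reconstructed by
    normal inversion of the printed P; zero-beta rows carry a nominal SE)."""
    from .meta import MetaResult, recover_se

    df = load_table2()
    out = {}
    for _, row in df.iterrows():
        beta, p = row["BETA_META"], row["P_META"]
        if pd.isna(beta) or pd.isna(p):
            continue
        beta, p = float(beta), float(p)
        if beta != 0.0 and p < 1.0:
            se = recover_se(beta, p)
            z = beta / se
        else:
            se, z = float("nan"), 0.0
        out[row["SNP"]] = MetaResult(
            snp_id=row["SNP"], beta_meta=beta, se_meta=se, z=z, p=p,
            k_studies=3, direction="???",
        )
    return out


# ---------------------------------------------------------------------------
# allele harmonisation


def harmonise(
    beta: float,
    eaf: float,
    effect_allele: str,
    other_allele: str,
    target_effect_allele: str,
    target_other_allele: str | None = None,
) -> tuple[float, float, bool]:
    """Express (beta, eaf) on the target's effect allele.

    Returns ``(beta, eaf, flipped)``.  If the record's effect allele already
    matches the target, values pass through.  If effect/other are swapped,
    beta changes sign and eaf maps to 1-eaf.  A mismatch that could be a
    strand flip of an ambiguous pair (A/T or C/G) raises
    :class:`HarmonisationError`, as does any unresolvable allele pair.
    """
    ea, oa = effect_allele.upper(), other_allele.upper()
    tea = target_effect_allele.upper()
    toa = target_other_allele.upper() if target_other_allele else None
    if ea == tea and (toa is None or oa == toa):
        return beta, eaf, False
    if _is_strand_ambiguous(ea, oa):
        # a swap cannot be told apart from a strand flip for A/T and C/G
        raise HarmonisationError(
            f"strand-ambiguous pair {ea}/{oa} cannot be reconciled with {tea}"
        )
    if oa == tea and (toa is None or ea == toa):
        return -beta, 1.0 - eaf, True
    # try the complementary strand
    cea, coa = COMPLEMENT.get(ea), COMPLEMENT.get(oa)
    if cea == tea and (toa is None or coa == toa):
        return beta, eaf, False
    if coa == tea and (toa is None or cea == toa):
        return -beta, 1.0 - eaf, True
    raise HarmonisationError(f"alleles {ea}/{oa} cannot be matched to {tea}/{toa or '?'}")


# ---------------------------------------------------------------------------
# transfer reports


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV; floats at 6 significant digits, absent
    values encoded as NA.  Round-trips through :func:`read_report`."""
    out = report.copy()
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, out.columns)) + "\n")
        for _, row in out.iterrows():
            cells = []
            for v in row:
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    cells.append("NA")
                elif isinstance(v, (float, np.floating)):
                    cells.append(f"{v:.6g}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_report` (NA -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
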