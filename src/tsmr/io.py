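"""Reading, validating and writing GWAS summary-statistic tables and LD matrices.

This module is the pipeline's only contact with files.  Tables are delimited
text (TSV by default) with one header row; the column layout is configurable
through a column map whose defaults follow common summary-statistic exports
(``SNP``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
``pval``, ``samplesize``).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Default mapping from record field -> column name in delimited files.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "chromosome": "chr",
    "position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "samplesize",
}

#: Fields that must be present in any readable table.
REQUIRED_FIELDS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
)

#: Smallest positive normal double; substituted for p-values of exactly 0.
TINY_PVALUE = sys.float_info.min


class ColumnMappingError(KeyError):
    """A mapped column is missing from the file header."""


class LDFormatError(ValueError):
    """An LD matrix file violates the symmetric/[0,1]/unit-diagonal contract."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association statistics in one GWAS.

    ``beta`` is the per-(effect-)allele effect; for binary outcomes it is a
    log odds ratio.  Optional fields use ``None`` when absent.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None
    chromosome: str | None = None
    position: int | None = None


def validate_record(rec: SummaryStatRecord) -> str | None:
    """Return a short reason string if ``rec`` violates an invariant, else None.

    Only single-base biallelic SNPs are accepted: indels and multi-allelic
    codes cannot be strand-resolved by the palindrome logic downstream.
    """
    if not rec.variant_id:
        return "missing_id"
    ea, oa = rec.effect_allele, rec.other_allele
    if ea not in VALID_BASES or oa not in VALID_BASES:
        return "invalid_allele"
    if ea == oa:
        return "identical_alleles"
    if not np.isfinite(rec.beta):
        return "invalid_beta"
    if not (np.isfinite(rec.se) and rec.se > 0):
        return "invalid_se"
    if not (0 < rec.pvalue <= 1):
        return "invalid_pvalue"
    if rec.eaf is not None and not (0 < rec.eaf < 1):
        return "invalid_eaf"
    if rec.n is not None and rec.n <= 0:
        return "invalid_n"
    return None


@dataclass
class ReadReport:
    """Tally of rows dropped during validation, keyed by reason."""

    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def _coerce_record(row: Mapping[str, object]) -> SummaryStatRecord:
    def opt_float(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return float(v)

    def opt_int(v):
        f = opt_float(v)
        return None if f is None else int(f)

    def opt_str(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return str(v)

    pvalue = float(row["pvalue"])
    if pvalue == 0.0:
        logger.warning("p-value of exactly 0 replaced by %.3e", TINY_PVALUE)
        pvalue = TINY_PVALUE
    return SummaryStatRecord(
        variant_id=str(row["variant_id"]),
        effect_allele=str(row["effect_allele"]).upper(),
        other_allele=str(row["other_allele"]).upper(),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pvalue=pvalue,
        eaf=opt_float(row.get("eaf")),
        n=opt_int(row.get("n")),
        chromosome=opt_str(row.get("chromosome")),
        position=opt_int(row.get("position")),
    )


def records_from_frame(
    df: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> tuple[list[SummaryStatRecord], ReadReport]:
    """Convert a DataFrame to validated records, dropping and tallying bad rows."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    missing = [cmap[f] for f in REQUIRED_FIELDS if cmap[f] not in df.columns]
    if missing:
        raise ColumnMappingError(
            f"mapped column(s) {missing} not found in header {list(df.columns)}"
        )
    present = {f: c for f, c in cmap.items() if c in df.columns}
    report = ReadReport(n_read=len(df))
    records: list[SummaryStatRecord] = []
    for _, row in df.iterrows():
        try:
            rec = _coerce_record({f: row[c] for f, c in present.items()})
        except (ValueError, TypeError):
            report.dropped["unparseable"] = report.dropped.get("unparseable", 0) + 1
            continue
        reason = validate_record(rec)
        if reason is None:
            records.append(rec)
        else:
            report.dropped[reason] = report.dropped.get(reason, 0) + 1
    report.n_kept = len(records)
    return records, report


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> tuple[list[SummaryStatRecord], ReadReport]:
    """Read a delimited summary-statistic table.

    Rows violating the record invariants are dropped and counted in the
    returned :class:`ReadReport`; row order is preserved.  An empty file
    yields an empty list with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.empty:
        logger.warning("summary table %s is empty", path)
        # header must still be checked for mapping errors
    return records_from_frame(df, column_map)


def records_to_frame(
    records: Sequence[SummaryStatRecord],
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    field_names = [f.name for f in fields(SummaryStatRecord)]
    data = {cmap[f]: [getattr(r, f) for r in records] for f in field_names}
    df = pd.DataFrame(data, columns=[cmap[f] for f in field_names])
    return df


def write_summary_table(
    records: Sequence[SummaryStatRecord],
    path: str | Path,
    delimiter: str = "\t",
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write records so that reading the file back reproduces them exactly.

    Absent optional fields are written as empty cells and re-read as absent.
    """
    df = records_to_frame(records, column_map)
    df.to_csv(path, sep=delimiter, index=False, na_rep="")


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over an ordered set of variants."""

    variant_ids: tuple[str, ...]
    r2: np.ndarray  # (J, J), symmetric, unit diagonal, values in [0, 1]

    def __post_init__(self):
        object.__setattr__(self, "r2", np.asarray(self.r2, dtype=float))
        self._check()

    def _check(self) -> None:
        J = len(self.variant_ids)
        if self.r2.shape != (J, J):
            raise LDFormatError(f"r2 shape {self.r2.shape} != ({J}, {J})")
        if np.nanmax(np.abs(self.r2 - self.r2.T)) > 1e-8:
            raise LDFormatError("r2 matrix is not symmetric")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise LDFormatError("r2 values outside [0, 1]")
        if np.max(np.abs(np.diag(self.r2) - 1.0)) > 1e-8:
            raise LDFormatError("r2 diagonal differs from 1")

    def lookup(self, id_a: str, id_b: str) -> float:
        idx = {v: i for i, v in enumerate(self.variant_ids)}
        return float(self.r2[idx[id_a], idx[id_b]])


def read_ld_matrix(path: str | Path, delimiter: str = "\t") -> LDMatrix:
    """Read an LD matrix written as TSV with a leading id column and id header.

    Input asymmetric beyond 1e-8 is rejected; smaller asymmetry is averaged
    away.  Diagonal entries must equal 1 to within 1e-8.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise LDFormatError("row ids do not match column ids")
    m = df.to_numpy(dtype=float)
    if np.nanmax(np.abs(m - m.T)) >= 1e-8:
        raise LDFormatError("asymmetry exceeds 1e-8")
    m = 0.5 * (m + m.T)
    return LDMatrix(variant_ids=tuple(ids), r2=m)


def write_ld_matrix(ld: LDMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(ld.r2, index=list(ld.variant_ids), columns=list(ld.variant_ids))
    df.to_csv(path, sep=delimiter)


def drop_duplicate_ids(
    records: Sequence[SummaryStatRecord],
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord]]:
    """Keep the smallest-p instance of each duplicated variant_id.

    Returns (kept-in-original-order, dropped duplicates).
    """
    best: dict[str, SummaryStatRecord] = {}
    for rec in records:
        cur = best.get(rec.variant_id)
        if cur is None or rec.pvalue < cur.pvalue:
            best[rec.variant_id] = rec
    kept, dropped, taken = [], [], set()
    for rec in records:
        if rec is best[rec.variant_id] and rec.variant_id not in taken:
            kept.append(rec)
            taken.add(rec.variant_id)
        else:
            dropped.append(rec)
    return kept, dropped


__all__ = [
    "SummaryStatRecord",
    "LDMatrix",
    "ReadReport",
    "ColumnMappingError",
    "LDFormatError",
    "DEFAULT_COLUMN_MAP",
    "TINY_PVALUE",
    "read_summary_table",
    "write_summary_table",
    "records_from_frame",
    "records_to_frame",
    "read_ld_matrix",
    "write_ld_matrix",
    "validate_record",
    "drop_duplicate_ids",
]
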