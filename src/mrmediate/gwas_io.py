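"""Summary-statistic data model and delimited-text I/O.

Every stage of the pipeline consumes GWAS summary associations through the
two containers defined here: :class:`AssociationRecord` (one SNP-trait
association) and :class:`SummaryTable` (one trait).  The on-disk format is
a delimited text table (tab canonical, comma accepted on read) with the
header ``snp, effect_allele, other_allele, beta, se, pvalue, eaf, n``;
``eaf`` and ``n`` are optional and serialized as ``NA`` when missing.

Validation is total: a file is either fully valid or the read fails with
every offending row enumerated.  Nothing is silently dropped or coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "AssociationRecord",
    "SummaryTable",
    "SummaryTableFormatError",
    "SummaryTableValidationError",
    "read_summary_table",
    "write_summary_table",
]

VALID_BASES = frozenset("ACGT")
MANDATORY_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pvalue")
OPTIONAL_COLUMNS = ("eaf", "n")
CANONICAL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS
TRAIT_TYPES = ("binary", "quantitative")


class SummaryTableFormatError(ValueError):
    """File-level problem: missing column, unreadable structure."""


class SummaryTableValidationError(ValueError):
    """Row-level invariant violations; the message enumerates every bad row."""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait summary association.

    ``beta`` is the additive effect per copy of ``effect_allele``
    (log-odds for a binary trait, trait-SD units for a quantitative one);
    ``se`` is its standard error on the same scale.  ``eaf`` is the
    effect-allele frequency and ``n`` the GWAS sample size; both may be
    missing (``None``).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    n: Optional[int] = None

    def validation_errors(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errors = []
        if not self.snp_id:
            errors.append("snp id is empty")
        if self.effect_allele not in VALID_BASES:
            errors.append(
                f"effect_allele {self.effect_allele!r} is not a single base in A/C/G/T"
            )
        if self.other_allele not in VALID_BASES:
            errors.append(
                f"other_allele {self.other_allele!r} is not a single base in A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            errors.append(f"effect and other allele are identical ({self.effect_allele})")
        if not math.isfinite(self.beta):
            errors.append(f"beta is not finite ({self.beta})")
        if not (math.isfinite(self.se) and self.se > 0):
            errors.append(f"se must be finite and > 0, got {self.se}")
        if not (0.0 < self.pvalue <= 1.0):
            errors.append(f"pvalue must lie in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            errors.append(f"eaf must lie in [0, 1], got {self.eaf}")
        if self.n is not None and self.n <= 0:
            errors.append(f"n must be a positive integer, got {self.n}")
        return errors


@dataclass
class SummaryTable:
    """An ordered collection of :class:`AssociationRecord` for one trait.

    ``trait_type`` (``binary`` or ``quantitative``) determines downstream
    reporting: binary-trait effects are exponentiated to odds ratios.
    """

    trait_name: str
    trait_type: str
    records: list[AssociationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(
                f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> AssociationRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def subset(self, snp_ids: Iterable[str]) -> "SummaryTable":
        """Records restricted to ``snp_ids``, original order preserved."""
        keep = set(snp_ids)
        return replace(self, records=[r for r in self.records if r.snp_id in keep])

    def validate(self) -> None:
        """Raise :class:`SummaryTableValidationError` listing every bad row."""
        messages = []
        for i, rec in enumerate(self.records, start=1):
            for err in rec.validation_errors():
                messages.append(f"row {i} ({rec.snp_id or '<no id>'}): {err}")
        seen: dict[str, int] = {}
        dupes = []
        for i, rec in enumerate(self.records, start=1):
            if rec.snp_id in seen:
                dupes.append(f"duplicate snp id {rec.snp_id!r} at rows {seen[rec.snp_id]} and {i}")
            else:
                seen[rec.snp_id] = i
        messages.extend(dupes)
        if messages:
            raise SummaryTableValidationError(
                f"summary table {self.trait_name!r} failed validation:\n  "
                + "\n  ".join(messages)
            )

    def to_frame(self) -> pd.DataFrame:
        """Canonical-layout DataFrame (missing eaf/n as NaN)."""
        return pd.DataFrame(
            {
                "snp": [r.snp_id for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pvalue": [r.pvalue for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _parse_optional_float(token, row: int, column: str, errors: list[str]):
    if token is None:
        return None
    text = str(token).strip()
    if text == "" or text.upper() == "NA":
        return None
    try:
        return float(text)
    except ValueError:
        errors.append(f"row {row}: column {column!r} has unparsable value {text!r}")
        return None


def _parse_float(token, row: int, column: str, errors: list[str]) -> float:
    text = "" if token is None else str(token).strip()
    if text == "" or text.upper() == "NA":
        errors.append(f"row {row}: column {column!r} is missing but mandatory")
        return math.nan
    try:
        return float(text)
    except ValueError:
        errors.append(f"row {row}: column {column!r} has non-numeric value {text!r}")
        return math.nan


def read_summary_table(path, trait_name: str, trait_type: str) -> SummaryTable:
    """Read and fully validate a delimited summary-statistics file.

    The delimiter (tab or comma) is sniffed from the header line and column
    order is irrelevant.  Missing ``eaf``/``n`` are written ``NA`` (any case)
    or left empty; any other unparsable token is an error, never a missing
    value.  On any failure the raised error enumerates all offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SummaryTableFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )

    errors: list[str] = []
    records: list[AssociationRecord] = []
    has_eaf = "eaf" in frame.columns
    has_n = "n" in frame.columns
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        n_val = _parse_optional_float(row["n"], i, "n", errors) if has_n else None
        if n_val is not None:
            if n_val != int(n_val):
                errors.append(f"row {i}: column 'n' must be an integer, got {n_val}")
                n_val = None
            else:
                n_val = int(n_val)
        rec = AssociationRecord(
            snp_id=str(row["snp"]).strip(),
            effect_allele=str(row["effect_allele"]).strip().upper(),
            other_allele=str(row["other_allele"]).strip().upper(),
            beta=_parse_float(row["beta"], i, "beta", errors),
            se=_parse_float(row["se"], i, "se", errors),
            pvalue=_parse_float(row["pvalue"], i, "pvalue", errors),
            eaf=_parse_optional_float(row["eaf"], i, "eaf", errors) if has_eaf else None,
            n=n_val,
        )
        records.append(rec)
    if errors:
        raise SummaryTableValidationError(
            f"{path}: failed to parse:\n  " + "\n  ".join(errors)
        )
    table = SummaryTable(trait_name=trait_name, trait_type=trait_type, records=records)
    table.validate()
    return table


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, int):
        return str(value)
    # shortest exact representation (>= 10 significant digits when needed):
    # read(write(T)) round-trips bit-for-bit
    return repr(float(value))


def write_summary_table(table: SummaryTable, path) -> None:
    """Write ``table`` as canonical tab-delimited text (see module docstring)."""
    table.validate()
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for r in table.records:
        lines.append(
            "\t".join(
                [
                    r.snp_id,
                    r.effect_allele,
                    r.other_allele,
                    _fmt(r.beta),
                    _fmt(r.se),
                    _fmt(r.pvalue),
                    _fmt(r.eaf),
                    _fmt(r.n),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
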