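"""Reading MAF / micro-MAF somatic mutation tables and cohort summaries.

MAF (Mutation Annotation Format) is the tab-separated per-variant table used
by TCGA: one row per called somatic mutation, carrying at least the gene
symbol, tumor sample barcode, genomic coordinates, alleles, and a variant
classification (Missense_Mutation, Silent, ...). The micro-MAF dialect is a
reduced table carrying only the three columns the downstream consensus
pipeline actually consumes: Hugo_Symbol, Tumor_Sample_Barcode and
Variant_Classification; positional columns are optional and filled with
sentinels when absent.

Cohort summaries report the number of distinct tumor samples, the number of
retained mutation records, and the mean mutation burden per sample. Every
data row counts toward the totals regardless of variant classification
(silent mutations included); means are rounded half-up to two decimals, the
precision at which such pan-cancer cohort tables are conventionally printed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence, TextIO

__all__ = [
    "MafRecord",
    "CohortSummary",
    "read_maf",
    "write_micro_maf",
    "summarize_cohort",
    "gene_mutation_counts",
]

#: Columns required in a full MAF header (TCGA MAF specification names).
MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)

#: Columns required in a micro-MAF header.
MICRO_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
)


@dataclass(frozen=True)
class MafRecord:
    """One somatic mutation call.

    Positions are 1-based inclusive; ``start_position``/``end_position`` of 0
    and alleles of ``"-"`` are the sentinels used when a micro-MAF omits the
    positional columns.
    """

    hugo_symbol: str
    sample_barcode: str
    variant_classification: str
    chromosome: str = ""
    start_position: int = 0
    end_position: int = 0
    reference_allele: str = "-"
    tumor_allele: str = "-"

    def __post_init__(self) -> None:
        if not self.hugo_symbol.strip():
            raise ValueError("MafRecord.hugo_symbol must be non-empty")
        if not self.sample_barcode.strip():
            raise ValueError("MafRecord.sample_barcode must be non-empty")
        if self.start_position < 0 or self.end_position < 0:
            raise ValueError("MAF positions must be non-negative")
        if self.end_position and self.start_position and self.end_position < self.start_position:
            raise ValueError(
                f"end_position {self.end_position} < start_position {self.start_position}"
            )


@dataclass(frozen=True)
class CohortSummary:
    """Per-cohort mutation statistics (samples, mutations, mean burden)."""

    cancer_type: str
    n_samples: int
    n_mutations: int
    mean_mutations_per_sample: float

    def to_tsv_row(self) -> str:
        return "\t".join(
            [
                self.cancer_type,
                str(self.n_samples),
                str(self.n_mutations),
                f"{self.mean_mutations_per_sample:.2f}",
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "cancer_type": self.cancer_type,
                "n_samples": self.n_samples,
                "n_mutations": self.n_mutations,
                "mean_mutations_per_sample": self.mean_mutations_per_sample,
            }
        )


def _open_text(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_maf(source: str | Path | TextIO, dialect: str = "maf") -> list[MafRecord]:
    """Parse a MAF or micro-MAF stream into records, preserving input order.

    Parameters
    ----------
    source
        Path or readable text stream; tab-separated with a header row.
        Lines beginning with ``#`` are comments and skipped.
    dialect
        ``"maf"`` requires the full TCGA column set; ``"micro"`` requires only
        Hugo_Symbol, Tumor_Sample_Barcode and Variant_Classification and fills
        missing positional fields with sentinels.

    Raises
    ------
    ValueError
        If a required column is missing (the message names it) or an integer
        position fails to parse (the message cites the 1-based line number).
    """
    if dialect not in ("maf", "micro"):
        raise ValueError(f"unknown MAF dialect {dialect!r}; expected 'maf' or 'micro'")
    required = MAF_REQUIRED_COLUMNS if dialect == "maf" else MICRO_REQUIRED_COLUMNS

    handle, owned = _open_text(source)
    try:
        lines = enumerate(handle, start=1)
        header: list[str] | None = None
        for _, raw in lines:
            if raw.startswith("#"):
                continue
            header = raw.rstrip("\n").rstrip("\r").split("\t")
            break
        if header is None:
            raise ValueError("empty MAF input: no header row found")
        col = {name: i for i, name in enumerate(header)}
        for name in required:
            if name not in col:
                raise ValueError(f"MAF input is missing required column {name!r}")

        def field(parts: list[str], name: str, default: str) -> str:
            idx = col.get(name)
            if idx is None or idx >= len(parts):
                return default
            return parts[idx].strip()

        records: list[MafRecord] = []
        for lineno, raw in lines:
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")

            def int_field(name: str) -> int:
                text = field(parts, name, "0")
                if text in ("", "0"):
                    return 0
                try:
                    return int(text)
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: malformed integer in column {name!r}: {text!r}"
                    ) from None

            records.append(
                MafRecord(
                    hugo_symbol=field(parts, "Hugo_Symbol", ""),
                    sample_barcode=field(parts, "Tumor_Sample_Barcode", ""),
                    variant_classification=field(parts, "Variant_Classification", ""),
                    chromosome=field(parts, "Chromosome", ""),
                    start_position=int_field("Start_Position"),
                    end_position=int_field("End_Position"),
                    reference_allele=field(parts, "Reference_Allele", "-") or "-",
                    tumor_allele=field(parts, "Tumor_Seq_Allele2", "-") or "-",
                )
            )
        return records
    finally:
        if owned:
            handle.close()


def write_micro_maf(records: Iterable[MafRecord], destination: str | Path | TextIO) -> None:
    """Write records as a micro-MAF (the three mandatory columns only)."""
    handle, owned = (
        (open(destination, "w", encoding="utf-8"), True)
        if isinstance(destination, (str, Path))
        else (destination, False)
    )
    try:
        handle.write("Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n")
        for rec in records:
            handle.write(
                f"{rec.hugo_symbol}\t{rec.sample_barcode}\t{rec.variant_classification}\n"
            )
    finally:
        if owned:
            handle.close()


def _round_half_up(value: float | Decimal, places: int = 2) -> float:
    quantum = Decimal(1).scaleb(-places)
    return float(Decimal(value).quantize(quantum, rounding=ROUND_HALF_UP))


def summarize_cohort(records: Sequence[MafRecord], cancer_type: str) -> CohortSummary:
    """Summarize a cohort: distinct samples, record count, mean burden.

    The mean is n_mutations / n_samples rounded half-up to 2 decimals
    (0 when the cohort is empty). All variant classifications count.
    """
    n_mutations = len(records)
    n_samples = len({r.sample_barcode for r in records})
    if n_samples == 0:
        mean = 0.0
    else:
        mean = _round_half_up(Decimal(n_mutations) / Decimal(n_samples))
    return CohortSummary(
        cancer_type=cancer_type,
        n_samples=n_samples,
        n_mutations=n_mutations,
        mean_mutations_per_sample=mean,
    )


def gene_mutation_counts(records: Sequence[MafRecord]) -> dict[str, int]:
    """Count mutation records per gene symbol.

    Genes with no records are absent from the result; the counts sum to the
    number of records.
    """
    return dict(Counter(r.hugo_symbol for r in records))
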