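"""Read-level quality filtering.

Implements the three discard rules applied to raw libraries before any
downstream step: reads containing the sequencing adaptor, reads with more
than 10% unknown bases (N), and low-quality reads with more than 50% of
bases at Phred quality <= 5.  Rules use strict inequalities and are applied
in the fixed order adaptor -> N-fraction -> low-quality; the first failing
rule is recorded as the reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

REASONS = ("adaptor", "N-fraction", "low-quality")


@dataclass(frozen=True)
class QCThresholds:
    adaptor: str | None = None
    max_n_frac: float = 0.10
    low_q: int = 5
    max_lowq_frac: float = 0.50

    def __post_init__(self) -> None:
        if not (0 <= self.max_n_frac <= 1 and 0 <= self.max_lowq_frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.low_q < 0:
            raise ValueError("low_q must be >= 0")


@dataclass
class QCReport:
    n_raw: int = 0
    n_clean: int = 0
    failures: dict[str, int] = field(default_factory=lambda: dict.fromkeys(REASONS, 0))

    @property
    def clean_percent(self) -> float | None:
        if self.n_raw == 0:
            return None
        return 100.0 * self.n_clean / self.n_raw

    def to_tsv(self) -> str:
        lines = [f"n_raw\t{self.n_raw}", f"n_clean\t{self.n_clean}"]
        if self.clean_percent is not None:
            lines.append(f"clean_percent\t{self.clean_percent:.2f}")
        lines += [f"fail_{r}\t{n}" for r, n in self.failures.items()]
        return "\n".join(lines) + "\n"


class FastqFormatError(ValueError):
    pass


def check_read(seq: str, quals: list[int], thresholds: QCThresholds) -> str | None:
    """Return the failure reason for one read, or None if it passes."""
    n = len(seq)
    if thresholds.adaptor and thresholds.adaptor in seq.upper():
        return "adaptor"
    if seq.upper().count("N") / n > thresholds.max_n_frac:
        return "N-fraction"
    if sum(q <= thresholds.low_q for q in quals) / n > thresholds.max_lowq_frac:
        return "low-quality"
    return None


def filter_reads(
    records: Iterable, thresholds: QCThresholds
) -> tuple[list, QCReport]:
    """Partition FASTQ records (Biopython SeqRecords) into clean reads and a tally.

    Every input read lands either in the clean list or in exactly one
    failure count; clean output preserves input order.
    """
    report = QCReport()
    clean = []
    for idx, rec in enumerate(records):
        seq = str(rec.seq)
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(seq):
            raise FastqFormatError(f"record {idx}: sequence/quality length mismatch")
        report.n_raw += 1
        reason = check_read(seq, quals, thresholds)
        if reason is None:
            report.n_clean += 1
            clean.append(rec)
        else:
            report.failures[reason] += 1
    return clean, report


def filter_fastq(
    in_path, out_path, thresholds: QCThresholds
) -> QCReport:
    """Filter a Phred+33 FASTQ file on disk; write clean reads to out_path."""
    records = SeqIO.parse(str(in_path), "fastq")
    clean, report = filter_reads(records, thresholds)
    with open(out_path, "w") as fh:
        SeqIO.write(clean, fh, "fastq")
    return report
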