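"""Genomic intervals, transcript models, GTF/FASTA I/O and transcript classification.

Coordinates are 0-based half-open internally; the GTF boundary converts to
and from the format's 1-based inclusive convention.  Transcript-vs-reference
classification implements the five class codes the novel-lncRNA cascade
needs ('=', 'i', 'x', 'o', 'u'); every other situation with same-strand
exonic overlap collapses to 'o'.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

BIOTYPES = {
    "protein_coding",
    "lncRNA",
    "rRNA",
    "tRNA",
    "miRNA",
    "pseudogene",
    "unknown",
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """An exon-structured transcript; the unit the cascade classifies and filters."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = "unknown"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.sequence is not None and len(self.sequence) != self.spliced_length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= spliced length {self.spliced_length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]

    def splice(self, genome: dict[str, str]) -> str:
        """Extract the spliced sequence from a genome dict, reverse-complementing on '-'."""
        seq = "".join(genome[self.chrom][e.start : e.end] for e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass(frozen=True)
class ClassCode:
    """Result of comparing one assembled transcript against the reference annotation."""

    code: str
    ref_id: str | None = None

    def __post_init__(self) -> None:
        if self.code not in {"=", "i", "x", "o", "u"}:
            raise ValueError(f"unknown class code {self.code!r}")
        if (self.code == "u") != (self.ref_id is None):
            raise ValueError("ref_id must be present iff code != 'u'")


# ---------------------------------------------------------------------------
# GTF / FASTA I/O


class GTFParseError(ValueError):
    pass


def read_gtf(path) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    Exon rows are grouped per transcript_id; other feature types are ignored
    (counted in a log line).  GTF 1-based inclusive coordinates become
    0-based half-open.
    """
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    n_ignored = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed row
                raise GTFParseError(f"line {lineno}: cannot parse GTF row: {exc}")
            if feat.featuretype != "exon":
                n_ignored += 1
                continue
            if feat.end < feat.start:
                raise GTFParseError(f"line {lineno}: end < start")
            attrs = feat.attributes
            if "transcript_id" not in attrs:
                raise GTFParseError(f"line {lineno}: missing transcript_id attribute")
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0] if "gene_id" in attrs else tid
            biotype = attrs["biotype"][0] if "biotype" in attrs else "unknown"
            if tid not in meta:
                order.append(tid)
            meta[tid] = (gid, biotype)
            exons[tid].append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
    if n_ignored:
        logger.info("read_gtf: ignored %d non-exon rows", n_ignored)
    return [
        TranscriptModel(tid, meta[tid][0], exons[tid], biotype=meta[tid][1])
        for tid in order
    ]


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write exon rows, one per exon, with gene_id/transcript_id/biotype attributes."""
    with open(path, "w") as fh:
        for m in models:
            for e in m.exons:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'biotype "{m.biotype}";'
                )
                fh.write(
                    f"{e.chrom}\tlncweave\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Classification


class ReferenceIndex:
    """Reference transcripts indexed by chromosome for overlap queries."""

    def __init__(self, models: Iterable[TranscriptModel]):
        self.by_chrom: dict[str, list[TranscriptModel]] = defaultdict(list)
        for m in models:
            self.by_chrom[m.chrom].append(m)
        for lst in self.by_chrom.values():
            lst.sort(key=lambda m: m.start)

    def candidates(self, chrom: str) -> Sequence[TranscriptModel]:
        return self.by_chrom.get(chrom, ())


def _exonic_overlap(query: TranscriptModel, ref: TranscriptModel) -> bool:
    return any(qe.overlaps(re) for qe in query.exons for re in ref.exons)


def _same_intron_chain(query: TranscriptModel, ref: TranscriptModel, tol: int) -> bool:
    if query.strand != ref.strand:
        return False
    if len(query.exons) == 1 and len(ref.exons) == 1:
        e, r = query.exons[0], ref.exons[0]
        return abs(e.start - r.start) <= tol and abs(e.end - r.end) <= tol
    return len(query.exons) > 1 and query.introns == ref.introns


def _inside_intron(query: TranscriptModel, ref: TranscriptModel) -> bool:
    if query.strand != ref.strand:
        return False
    return any(
        i_start <= query.start and query.end <= i_end
        for i_start, i_end in ref.introns
    )


def classify_transcript(
    query: TranscriptModel,
    reference: ReferenceIndex,
    single_exon_tolerance: int = 0,
) -> ClassCode:
    """Assign one of the class codes '=', 'o', 'i', 'x', 'u' to a query transcript.

    Priority: identical intron chain on the same strand ('='), any remaining
    same-strand exonic overlap ('o'), fully intronic within a same-strand
    reference with no exonic overlap on either strand ('i'), exonic overlap
    only on the opposite strand ('x'), else intergenic ('u').
    """
    cands = reference.candidates(query.chrom)
    if not cands and query.chrom not in reference.by_chrom:
        logger.warning(
            "classify_transcript: %s on chromosome %s absent from reference",
            query.transcript_id,
            query.chrom,
        )
    same_overlap: str | None = None
    anti_overlap: str | None = None
    intronic: str | None = None
    for ref in cands:
        if ref.end <= query.start or query.end <= ref.start:
            continue
        if _same_intron_chain(query, ref, single_exon_tolerance):
            return ClassCode("=", ref.transcript_id)
        if _exonic_overlap(query, ref):
            if query.strand == ref.strand:
                same_overlap = same_overlap or ref.transcript_id
            else:
                anti_overlap = anti_overlap or ref.transcript_id
        elif _inside_intron(query, ref):
            intronic = intronic or ref.transcript_id
    if same_overlap:
        return ClassCode("o", same_overlap)
    if intronic and not anti_overlap:
        return ClassCode("i", intronic)
    if anti_overlap:
        return ClassCode("x", anti_overlap)
    return ClassCode("u", None)


# ---------------------------------------------------------------------------
# Assembly summary


@dataclass
class AssemblySummary:
    n_sequences: int
    n_genes: int
    total_bases: int
    max_len: int
    min_len: int
    mean_len: float
    median_len: float
    n50: int
    gc_percent: float


def n50(lengths: Sequence[int]) -> int:
    """Length L such that sequences of length >= L cover half the total bases."""
    if not lengths:
        raise ValueError("n50 of empty input")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def gc_percent(seqs: Iterable[str]) -> float:
    """GC percentage over unambiguous A/C/G/T bases only."""
    gc = acgt = 0
    for s in seqs:
        u = s.upper()
        gc += u.count("G") + u.count("C")
        acgt += sum(u.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * gc / acgt


def transcript_stats(
    models: Sequence[TranscriptModel] | None = None,
    sequences: dict[str, str] | None = None,
    n_genes: int | None = None,
) -> AssemblySummary:
    """Summary statistics (length distribution, N50, GC%) for an assembly.

    Accepts transcript models carrying sequences, a plain id->sequence dict,
    or both; at least one is required and must be non-empty.
    """
    seqs: list[str] = []
    genes: set[str] = set()
    if models:
        for m in models:
            if m.sequence is None:
                raise ValueError(f"{m.transcript_id}: no sequence for stats")
            seqs.append(m.sequence)
            genes.add(m.gene_id)
    if sequences:
        seqs.extend(sequences.values())
    if not seqs:
        raise ValueError("transcript_stats: empty input")
    lengths = [len(s) for s in seqs]
    return AssemblySummary(
        n_sequences=len(seqs),
        n_genes=n_genes if n_genes is not None else (len(genes) or len(seqs)),
        total_bases=int(sum(lengths)),
        max_len=int(max(lengths)),
        min_len=int(min(lengths)),
        mean_len=float(np.mean(lengths)),
        median_len=float(np.median(lengths)),
        n50=n50(lengths),
        gc_percent=gc_percent(seqs),
    )
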