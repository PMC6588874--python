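"""Novel-lncRNA discovery: the six-step filter cascade.

Candidates from a transcriptome assembly are reduced to novel lncRNAs by a
conjunction of filters: (0) transcripts identical to excluded reference
biotypes (protein-coding, pseudogene, rRNA/tRNA/miRNA) are removed; (a)
transcripts hitting the known-lncRNA database at E <= 1e-10 are assigned
known-lncRNA status; then, in order, (1) only intergenic ('u') transcripts
survive, (2) transcripts < 200 nt are removed, (3) transcripts with exonic
overlap to known lncRNA loci are removed, (4) transcripts whose longest ORF
exceeds 300 bp (~100 aa) are removed, (5) transcripts with a protein-database
hit at E <= 1e-5 are removed, (6) transcripts whose combined coding-potential
score S is >= 0 are removed.  Survivors are novel lncRNAs.

The coding-potential score is a deterministic linear combination of ORF
length, ORF coverage, the Fickett TESTCODE statistic and an in-frame hexamer
log-likelihood ratio, with the noncoding decision rule "S < 0".
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .annotation import ReferenceIndex, TranscriptModel, classify_transcript

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

# ---------------------------------------------------------------------------
# ORF scanning


@dataclass(frozen=True)
class ORFRecord:
    """An ATG..stop open reading frame located in a transcript sequence.

    Coordinates are 0-based offsets into the given (forward) sequence; for
    minus-strand ORFs they are offsets into the reverse complement.
    length_nt includes the stop codon.
    """

    start: int
    end: int
    strand: str
    frame: int
    length_nt: int


def _scan_frame(seq: str, frame: int, strand: str) -> list[ORFRecord]:
    orfs = []
    i = frame
    n = len(seq)
    while i + 3 <= n:
        if seq[i : i + 3] == "ATG":
            j = i + 3
            while j + 3 <= n:
                codon = seq[j : j + 3]
                if codon in STOP_CODONS:
                    orfs.append(ORFRecord(i, j + 3, strand, frame, j + 3 - i))
                    break
                j += 3
            # skip to after this ATG; nested ATGs give shorter ORFs only
        i += 3
    return orfs


def longest_orf(sequence: str) -> ORFRecord | None:
    """Longest ATG..stop ORF over all 3 frames on both strands.

    Ties resolve to the + strand first, then to the smallest start offset.
    Codons containing N never match ATG or a stop codon (string comparison
    guarantees this).  Returns None when no complete ORF exists; stop-less
    partial ORFs at transcript ends are not counted.
    """
    seq = sequence.upper()
    candidates: list[ORFRecord] = []
    for frame in range(3):
        candidates.extend(_scan_frame(seq, frame, "+"))
    rc = str(Seq(seq).reverse_complement())
    for frame in range(3):
        candidates.extend(_scan_frame(rc, frame, "-"))
    if not candidates:
        return None
    return max(
        candidates,
        key=lambda o: (o.length_nt, o.strand == "+", -o.start),
    )


# ---------------------------------------------------------------------------
# Fickett TESTCODE

# Published TESTCODE lookup tables: probability of coding given the position
# or composition parameter, with the standard per-base weights.  Position
# thresholds run 0, 1.1, ..., 1.9; content thresholds 0, 0.17, ..., 0.33.
_POSITION_THRESHOLDS = [0.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9]
_CONTENT_THRESHOLDS = [0.0, 0.17, 0.19, 0.21, 0.23, 0.25, 0.27, 0.29, 0.31, 0.33]

_POSITION_PROB = {
    "A": [0.22, 0.20, 0.34, 0.45, 0.68, 0.58, 0.93, 0.84, 0.68, 0.94],
    "C": [0.23, 0.30, 0.33, 0.51, 0.48, 0.66, 0.81, 0.70, 0.70, 0.80],
    "G": [0.08, 0.08, 0.16, 0.27, 0.48, 0.53, 0.64, 0.74, 0.88, 0.90],
    "T": [0.09, 0.09, 0.20, 0.54, 0.44, 0.69, 0.68, 0.91, 0.97, 0.97],
}
_CONTENT_PROB = {
    "A": [0.21, 0.81, 0.65, 0.67, 0.49, 0.62, 0.55, 0.44, 0.49, 0.28],
    "C": [0.31, 0.39, 0.44, 0.43, 0.59, 0.59, 0.64, 0.51, 0.64, 0.82],
    "G": [0.29, 0.33, 0.41, 0.41, 0.73, 0.64, 0.64, 0.47, 0.54, 0.40],
    "T": [0.58, 0.51, 0.69, 0.56, 0.75, 0.55, 0.40, 0.39, 0.24, 0.28],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, thresholds: list[float], probs: list[float]) -> float:
    idx = 0
    for i, t in enumerate(thresholds):
        if value >= t:
            idx = i
    return probs[idx]


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic from base positional bias and composition.

    For each base B the position parameter is max/ (min+1) of the counts of B
    in the three codon positions; the content parameter is the overall
    fraction of B.  Each parameter indexes a published probability-of-coding
    table; the statistic is the weighted sum of the eight looked-up values.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        return 0.0
    score = 0.0
    for base in "ACGT":
        pos_counts = [seq[i::3].count(base) for i in range(3)]
        position = max(pos_counts) / (min(pos_counts) + 1.0)
        content = seq.count(base) / len(seq)
        score += (
            _lookup(position, _POSITION_THRESHOLDS, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        score += (
            _lookup(content, _CONTENT_THRESHOLDS, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer usage


def hexamer_table(
    coding_seqs: Iterable[str], noncoding_seqs: Iterable[str], pseudocount: float = 1.0
) -> dict[str, float]:
    """Log-ratio of in-frame hexamer frequency in coding vs noncoding training sequences.

    Coding sequences are read in frame 0 with step 3 (codon pairs); noncoding
    sequences contribute hexamers at every offset.  Laplace smoothing keeps
    unseen hexamers finite.
    """

    def count(seqs: Iterable[str], step: int) -> Counter:
        c: Counter = Counter()
        for s in seqs:
            s = s.upper()
            for i in range(0, len(s) - 5, step):
                h = s[i : i + 6]
                if set(h) <= set("ACGT"):
                    c[h] += 1
        return c

    cod = count(coding_seqs, 3)
    non = count(noncoding_seqs, 1)
    n_cod = sum(cod.values()) + pseudocount * 4096
    n_non = sum(non.values()) + pseudocount * 4096
    table = {}
    bases = "ACGT"
    for i in range(4096):
        h = "".join(bases[(i >> (2 * k)) & 3] for k in range(5, -1, -1))
        f_c = (cod[h] + pseudocount) / n_cod
        f_n = (non[h] + pseudocount) / n_non
        table[h] = float(np.log(f_c / f_n))
    return table


def hexamer_llr(sequence: str, table: dict[str, float]) -> float:
    """Mean in-frame hexamer log-ratio over the longest ORF; 0 with no ORF."""
    seq = sequence.upper()
    if len(seq) < 6:
        logger.info("hexamer_llr: sequence shorter than 6 nt, returning 0")
        return 0.0
    orf = longest_orf(seq)
    if orf is None:
        return 0.0
    sub = seq if orf.strand == "+" else str(Seq(seq).reverse_complement())
    sub = sub[orf.start : orf.end]
    vals = [
        table[sub[i : i + 6]]
        for i in range(0, len(sub) - 5, 3)
        if sub[i : i + 6] in table
    ]
    return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# Combined coding potential


@dataclass(frozen=True)
class ScoreWeights:
    """Weights and standardization constants for the combined score S.

    S = w_orf * (orf_len - orf_center)/orf_scale
      + w_cov * (orf_coverage - cov_center)
      + w_fickett * (fickett - fickett_center)
      + w_hexamer * hexamer_llr

    Defaults center the ORF term at the 300 bp cascade cutoff, coverage at
    0.5 and the Fickett statistic at 0.95 (the classical coding threshold),
    so a transcript that is neutral on every axis scores S = 0 and the
    noncoding call is "S < 0".
    """

    w_orf: float = 1.0
    w_cov: float = 1.0
    w_fickett: float = 1.0
    w_hexamer: float = 1.0
    orf_center: float = 300.0
    orf_scale: float = 300.0
    cov_center: float = 0.5
    fickett_center: float = 0.95


@dataclass(frozen=True)
class CodingPotential:
    orf_len: int
    orf_coverage: float
    fickett: float
    hexamer_llr: float
    S: float


def coding_potential(
    sequence: str,
    table: dict[str, float],
    weights: ScoreWeights = ScoreWeights(),
) -> CodingPotential:
    """Combined coding-potential record for one transcript sequence."""
    orf = longest_orf(sequence)
    orf_len = orf.length_nt if orf else 0
    coverage = orf_len / len(sequence) if sequence else 0.0
    fick = fickett_score(sequence)
    hex_llr = hexamer_llr(sequence, table)
    s = (
        weights.w_orf * (orf_len - weights.orf_center) / weights.orf_scale
        + weights.w_cov * (coverage - weights.cov_center)
        + weights.w_fickett * (fick - weights.fickett_center)
        + weights.w_hexamer * hex_llr
    )
    return CodingPotential(orf_len, coverage, fick, hex_llr, float(s))


# ---------------------------------------------------------------------------
# Similarity hit tables (BLAST tabular outfmt-6 dialect)


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_len: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity must lie in [0, 100]")


def read_hit_table(path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                hits.append(
                    HitRecord(
                        parts[0],
                        parts[1],
                        float(parts[2]),
                        int(parts[3]),
                        float(parts[10]),
                        float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}")
    return hits


def write_hit_table(hits: Sequence[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_len}\t0\t0\t1\t{h.alignment_len}\t1\t"
                f"{h.alignment_len}\t{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )


def apply_hit_filter(
    ids: Iterable[str], hits: Sequence[HitRecord], e_max: float
) -> tuple[set[str], set[str]]:
    """Partition ids into (hit, no-hit) by best E-value, inclusive at e_max."""
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    ids = set(ids)
    hit_ids = {h.query_id for h in hits if h.e_value <= e_max} & ids
    return hit_ids, ids - hit_ids


# ---------------------------------------------------------------------------
# The cascade


@dataclass(frozen=True)
class CascadeParams:
    min_len: int = 200
    max_orf: int = 300
    protein_evalue_max: float = 1e-5
    known_lnc_evalue_max: float = 1e-10
    cpc_threshold: float = 0.0
    excluded_biotypes: frozenset[str] = frozenset(
        {"protein_coding", "pseudogene", "rRNA", "tRNA", "miRNA"}
    )

    def __post_init__(self) -> None:
        if self.min_len <= 0:
            raise ValueError("min_len must be > 0")
        if self.protein_evalue_max <= 0 or self.known_lnc_evalue_max <= 0:
            raise ValueError("e-value cutoffs must be > 0")


REJECTION_REASONS = (
    "biotype",
    "not_u",
    "too_short",
    "known_lnc_overlap",
    "long_orf",
    "protein_hit",
    "coding_score",
)


@dataclass
class CatalogEntry:
    transcript_id: str
    status: str  # known_lncRNA | novel_lncRNA | rejected
    reason: str | None = None
    class_code: str | None = None
    potential: CodingPotential | None = None


@dataclass
class LncRNACatalog:
    entries: dict[str, CatalogEntry] = field(default_factory=dict)

    @property
    def novel_ids(self) -> set[str]:
        return {t for t, e in self.entries.items() if e.status == "novel_lncRNA"}

    @property
    def known_ids(self) -> set[str]:
        return {t for t, e in self.entries.items() if e.status == "known_lncRNA"}

    def rejected_by_reason(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {r: set() for r in REJECTION_REASONS}
        for t, e in self.entries.items():
            if e.status == "rejected":
                out[e.reason].add(t)
        return out

    def counts(self) -> dict[str, int]:
        c = {"known_lncRNA": len(self.known_ids), "novel_lncRNA": len(self.novel_ids)}
        for r, ids in self.rejected_by_reason().items():
            c[f"rejected_{r}"] = len(ids)
        return c

    def to_tsv(self, path) -> None:
        cols = "transcript_id\tstatus\treason\torf_len\tfickett\thexamer_llr\tS\n"
        with open(path, "w") as fh:
            fh.write(cols)
            for t in sorted(self.entries):
                e = self.entries[t]
                p = e.potential
                fh.write(
                    f"{t}\t{e.status}\t{e.reason or '.'}\t"
                    f"{p.orf_len if p else '.'}\t"
                    f"{f'{p.fickett:.4f}' if p else '.'}\t"
                    f"{f'{p.hexamer_llr:.4f}' if p else '.'}\t"
                    f"{f'{p.S:.4f}' if p else '.'}\n"
                )


def _exonic_overlap_any(
    query: TranscriptModel, index: ReferenceIndex
) -> bool:
    for ref in index.candidates(query.chrom):
        if ref.end <= query.start or query.end <= ref.start:
            continue
        if any(qe.overlaps(re) for qe in query.exons for re in ref.exons):
            return True
    return False


def discover_lncrnas(
    assembly: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    known_lnc_hits: Sequence[HitRecord],
    protein_hits: Sequence[HitRecord],
    params: CascadeParams = CascadeParams(),
    hexamer_tab: dict[str, float] | None = None,
    weights: ScoreWeights = ScoreWeights(),
) -> LncRNACatalog:
    """Run the full discovery cascade and return a per-transcript catalog.

    The positional comparison (class codes) is computed against the
    reference EXCLUDING lncRNA-biotype transcripts, mirroring a reference
    annotation without lncRNA entries; overlap with the known-lncRNA loci is
    then a separate filter (step 3).  Every transcript receives exactly one
    status; rejected transcripts carry the first failing step as reason.
    """
    non_lnc_ref = [m for m in reference if m.biotype != "lncRNA"]
    lnc_ref = [m for m in reference if m.biotype == "lncRNA"]
    class_index = ReferenceIndex(non_lnc_ref)
    lnc_index = ReferenceIndex(lnc_ref)
    hexamer_tab = hexamer_tab if hexamer_tab is not None else {}

    all_ids = [m.transcript_id for m in assembly]
    known_hit_ids, _ = apply_hit_filter(all_ids, known_lnc_hits, params.known_lnc_evalue_max)
    protein_hit_ids, _ = apply_hit_filter(all_ids, protein_hits, params.protein_evalue_max)

    catalog = LncRNACatalog()
    for m in assembly:
        tid = m.transcript_id
        code = classify_transcript(m, class_index)
        entry = CatalogEntry(tid, "rejected", class_code=code.code)
        # step 0: excluded biotypes, identified positionally by an exact
        # ('=') match to an excluded-biotype reference transcript
        if code.code == "=":
            ref_biotype = next(
                (r.biotype for r in non_lnc_ref if r.transcript_id == code.ref_id),
                None,
            )
            if ref_biotype in params.excluded_biotypes:
                entry.reason = "biotype"
                catalog.entries[tid] = entry
                continue
        # step a: known-lncRNA assignment by database similarity
        if tid in known_hit_ids:
            entry.status = "known_lncRNA"
            catalog.entries[tid] = entry
            continue
        # step 1: intergenic only
        if code.code != "u":
            entry.reason = "not_u"
            catalog.entries[tid] = entry
            continue
        # step 2: length
        if m.spliced_length < params.min_len:
            entry.reason = "too_short"
            catalog.entries[tid] = entry
            continue
        # step 3: known-lncRNA locus overlap
        if _exonic_overlap_any(m, lnc_index):
            entry.reason = "known_lnc_overlap"
            catalog.entries[tid] = entry
            continue
        if m.sequence is None:
            raise ValueError(f"{tid}: sequence required for ORF/coding-potential steps")
        # step 4: long ORF
        orf = longest_orf(m.sequence)
        if orf is not None and orf.length_nt > params.max_orf:
            entry.reason = "long_orf"
            catalog.entries[tid] = entry
            continue
        # step 5: protein similarity
        if tid in protein_hit_ids:
            entry.reason = "protein_hit"
            catalog.entries[tid] = entry
            continue
        # step 6: coding-potential score
        pot = coding_potential(m.sequence, hexamer_tab, weights)
        entry.potential = pot
        if pot.S >= params.cpc_threshold:
            entry.reason = "coding_score"
            catalog.entries[tid] = entry
            continue
        entry.status = "novel_lncRNA"
        entry.reason = None
        catalog.entries[tid] = entry
    return catalog
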