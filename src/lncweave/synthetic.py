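"""Synthetic study generator with planted ground truth.

Emulates the inputs of a three-condition skin transcriptome study — black
(BS), white (WS) and red (RS) groups with three replicate libraries each —
so every pipeline stage can be tested against known truth:

* a toy genome and reference annotation with multi-exon coding genes and
  known lncRNAs, plus coding genes planted at fixed offsets from designated
  lncRNA loci (cis-target positives);
* an assembled transcript set containing planted novel lncRNAs (intergenic,
  >= 200 nt, longest ORF <= 300 bp, coding-potential score designed < 0)
  and one decoy class per cascade filter;
* negative-binomial count matrices with planted differential expression at
  a fixed log2 fold change and lncRNA-mRNA pairs driven by a shared latent
  profile (trans-target positives);
* FASTQ reads violating exactly one QC rule each, with truth labels;
* a term-to-gene map with terms biased toward planted DE genes, and a qPCR
  Ct table with stable reference genes.

All generators are deterministic functions of the configuration (including
its seed): the same config yields byte-identical output files.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GenomicInterval, TranscriptModel
from .discovery import (
    HitRecord,
    ScoreWeights,
    coding_potential,
    hexamer_table,
    longest_orf,
)
from .expression import CountMatrix

BASES = "ACGT"

# codon bias used for synthetic coding sequence (optimal-codon set carrying
# most of the probability mass) — gives coding hexamer usage a clear
# signature against uniform-random noncoding sequence
_PREFERRED_CODONS = ["GCC", "GAG", "AAG", "CTG", "GAC", "TTC", "ATC", "GGC", "CAG", "GTG"]
_STOPS = {"TAA", "TAG", "TGA"}
_OTHER_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOPS and a + b + c not in _PREFERRED_CODONS
]


class SizingError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic generator (defaults mirror
    the emulated nine-library, three-group design)."""

    n_chroms: int = 4
    chrom_len: int = 1_500_000
    gc_content: float = 0.44
    n_coding_genes: int = 80
    n_known_lncs: int = 40
    n_novel_lncs: int = 200
    n_decoys_short: int = 30
    n_decoys_coding: int = 30
    n_decoys_overlap: int = 30
    n_decoys_lnc_overlap: int = 30
    n_decoys_protein: int = 30
    n_decoys_cpc: int = 30
    n_coding_copies: int = 60
    n_known_copies: int = 40
    groups: tuple[str, ...] = ("BS", "WS", "RS")
    reps_per_group: int = 3
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.10
    base_mean_log_mu: float = 5.0
    base_mean_log_sd: float = 1.0
    base_mean_min: float = 10.0
    lib_size_spread: float = 0.0
    n_trans_pairs: int = 20
    target_r: float = 0.99
    trans_latent_sd: float = 1.5
    trans_dispersion: float = 0.01
    trans_base_mean: float = 500.0
    cis_offsets: tuple[int, ...] = (20_000, 50_000)
    cis_pairs_per_offset: int = 3
    n_reads_pass: int = 480
    n_reads_fail_adaptor: int = 7
    n_reads_fail_n: int = 6
    n_reads_fail_lowq: int = 7
    read_len: int = 100
    adaptor: str = "AGATCGGAAGAGC"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_chroms, self.chrom_len, self.n_coding_genes, self.n_known_lncs,
            self.n_novel_lncs, self.n_decoys_short, self.n_decoys_coding,
            self.n_decoys_overlap, self.n_decoys_lnc_overlap, self.n_decoys_protein,
            self.n_decoys_cpc, self.n_coding_copies, self.n_known_copies,
            self.reps_per_group, self.n_trans_pairs, self.cis_pairs_per_offset,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.de_log2fc < 0:
            raise ValueError("de_log2fc must be >= 0")
        if not (0 < self.target_r <= 1):
            raise ValueError("target_r must lie in (0, 1]")
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must lie in [0, 1]")
        n_cis = len(self.cis_offsets) * self.cis_pairs_per_offset
        if self.n_known_lncs < n_cis or self.n_coding_genes < n_cis:
            raise ValueError("cis pairs exceed available lncRNAs or coding genes")
        if self.n_coding_copies > self.n_coding_genes:
            raise ValueError("n_coding_copies exceeds n_coding_genes")
        if self.n_known_copies > self.n_known_lncs:
            raise ValueError("n_known_copies exceeds n_known_lncs")
        if self.n_decoys_overlap > 0 and self.n_coding_genes == 0:
            raise ValueError("overlap decoys need coding genes")
        if self.n_decoys_lnc_overlap > 0 and self.n_known_lncs == 0:
            raise ValueError("lnc-overlap decoys need known lncRNAs")


@dataclass
class GroundTruth:
    """Planted truth for every stage; ids are a subset of emitted ids."""

    novel_ids: set[str] = field(default_factory=set)
    known_ids: set[str] = field(default_factory=set)
    rejected_ids_by_reason: dict[str, set[str]] = field(default_factory=dict)
    de_ids_by_comparison: dict[str, dict[str, str]] = field(default_factory=dict)
    trans_pairs: set[tuple[str, str]] = field(default_factory=set)
    cis_pairs: set[tuple[str, str, int]] = field(default_factory=set)
    read_labels: dict[str, str] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    reference: list[TranscriptModel]
    genome: dict[str, str]
    truth: GroundTruth
    assembly: list[TranscriptModel]
    hexamer_tab: dict[str, float]
    known_lnc_hits: list[HitRecord]
    protein_hits: list[HitRecord]

    def gene_table(self) -> pd.DataFrame:
        """Gene-level table (gene_id, length, kind) for count simulation."""
        rows = []
        seen = set()
        for m in self.reference:
            if m.gene_id in seen:
                continue
            seen.add(m.gene_id)
            kind = "coding" if m.biotype == "protein_coding" else "lnc"
            rows.append((m.gene_id, m.spliced_length, kind))
        for m in self.assembly:
            if m.transcript_id in self.truth.novel_ids:
                rows.append((m.transcript_id, m.spliced_length, "lnc"))
        return pd.DataFrame(rows, columns=["gene_id", "length", "kind"])


# ---------------------------------------------------------------------------
# sequence design helpers


def _rand_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _biased_codons(rng: np.random.Generator, n: int) -> str:
    picks = []
    for _ in range(n):
        if rng.random() < 0.7:
            picks.append(_PREFERRED_CODONS[rng.integers(len(_PREFERRED_CODONS))])
        else:
            picks.append(_OTHER_CODONS[rng.integers(len(_OTHER_CODONS))])
    return "".join(picks)


def _cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + biased codons + stop; ORF length 3*(n_codons + 2) bp."""
    return "ATG" + _biased_codons(rng, n_codons) + "TAA"


def _no_atg(rng: np.random.Generator, length: int) -> str:
    # pyrimidine-rich filler that cannot contain ATG on either strand
    return "".join(rng.choice(["C", "T"], size=length))


def _cap_orfs(seq: str, cap: int) -> str:
    """Break every ORF longer than cap by a mid-ORF stop codon."""
    for _ in range(200):
        orf = longest_orf(seq)
        if orf is None or orf.length_nt <= cap:
            return seq
        if orf.strand == "+":
            k = orf.start + 3 * ((orf.length_nt // 3) // 2)
            seq = seq[:k] + "TAA" + seq[k + 3 :]
        else:
            rc = _revcomp(seq)
            k = orf.start + 3 * ((orf.length_nt // 3) // 2)
            rc = rc[:k] + "TAA" + rc[k + 3 :]
            seq = _revcomp(rc)
    raise RuntimeError("ORF capping did not converge")


def _noncoding_seq(
    rng: np.random.Generator,
    length: int,
    gc: float,
    max_orf: int,
    table: dict[str, float] | None = None,
    require_negative_score: bool = False,
) -> str:
    """Random sequence with all ORFs <= max_orf, optionally with a verified
    negative coding-potential score."""
    for _ in range(50):
        seq = _cap_orfs(_rand_seq(rng, length, gc), max_orf)
        if not require_negative_score:
            return seq
        if coding_potential(seq, table or {}).S < 0:
            return seq
    raise RuntimeError("could not design a noncoding sequence with S < 0")


def default_hexamer_table(seed: int) -> dict[str, float]:
    """Hexamer log-ratio table trained on synthetic coding vs noncoding sequence."""
    rng = np.random.default_rng([seed, 1])
    coding = [_cds(rng, 300) for _ in range(60)]
    noncoding = [_rand_seq(rng, 900, 0.44) for _ in range(60)]
    return hexamer_table(coding, noncoding)


# ---------------------------------------------------------------------------
# layout engine


class _Cursor:
    def __init__(self, config: SyntheticConfig):
        self.config = config
        self.chrom_idx = 0
        self.pos = 0

    def place(self, span: int, gap: int, feature_id: str) -> tuple[str, int]:
        while True:
            if self.chrom_idx >= self.config.n_chroms:
                raise SizingError(
                    f"cannot place feature {feature_id!r}: genome exhausted "
                    f"({self.config.n_chroms} x {self.config.chrom_len} bp)"
                )
            start = self.pos + gap
            if start + span <= self.config.chrom_len:
                self.pos = start + span
                return f"chr{self.chrom_idx + 1}", start
            self.chrom_idx += 1
            self.pos = 0


def _split_exons(
    rng: np.random.Generator, chrom: str, start: int, strand: str, spliced_len: int,
    n_exons: int,
) -> tuple[list[GenomicInterval], int]:
    """Cut a spliced length into n_exons genomic exons with random introns."""
    if n_exons == 1:
        return [GenomicInterval(chrom, start, start + spliced_len, strand)], spliced_len
    cuts = np.sort(rng.choice(np.arange(1, spliced_len), size=n_exons - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [spliced_len]])).astype(int)
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append(GenomicInterval(chrom, pos, pos + int(size), strand))
        pos += int(size)
        if i < len(sizes) - 1:
            pos += int(rng.integers(100, 400))
    return exons, pos - start


def _paste(genome: dict[str, bytearray], model: TranscriptModel, spliced: str) -> None:
    """Write a designed spliced sequence into the genome at the model's exons."""
    seq = _revcomp(spliced) if model.strand == "-" else spliced
    # on '-' the genomic order of exon chunks is the reverse of transcript order
    offset = 0
    for e in model.exons:
        chunk = seq[offset : offset + len(e)]
        genome[e.chrom][e.start : e.end] = chunk.encode()
        offset += len(e)


@lru_cache(maxsize=4)
def _layout(config: SyntheticConfig):
    rng = np.random.default_rng([config.seed, 0])
    table = default_hexamer_table(config.seed)
    gc = config.gc_content

    genome: dict[str, bytearray] = {}
    for c in range(config.n_chroms):
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.chrom_len, p=p)
        genome[f"chr{c + 1}"] = bytearray(arr.tobytes())

    cursor = _Cursor(config)
    reference: list[TranscriptModel] = []
    planted: list[TranscriptModel] = []  # assembly-only features with designed seqs
    truth = GroundTruth(
        rejected_ids_by_reason={
            r: set()
            for r in (
                "biotype", "not_u", "too_short", "known_lnc_overlap",
                "long_orf", "protein_hit", "coding_score",
            )
        }
    )

    def make_coding(gene_idx: int, chrom=None, start=None) -> TranscriptModel:
        gid = f"GENE{gene_idx:04d}"
        n_codons = int(rng.integers(110, 160))
        utr5 = _noncoding_seq(rng, int(rng.integers(20, 60)), gc, 120)
        utr3 = _noncoding_seq(rng, int(rng.integers(20, 60)), gc, 120)
        spliced = utr5 + _cds(rng, n_codons) + utr3
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 4))
        if chrom is None:
            span_guess = len(spliced) + 400 * n_exons
            chrom, start = cursor.place(span_guess, int(rng.integers(400, 1500)), gid)
        exons, genomic_span = _split_exons(rng, chrom, start, strand, len(spliced), n_exons)
        m = TranscriptModel(f"T{gid}", gid, exons, biotype="protein_coding", sequence=spliced)
        _paste(genome, m, spliced)
        return m

    def make_lnc_like(tid: str, gid: str, biotype: str, min_len=300, max_len=1200,
                      require_neg=True) -> TranscriptModel:
        length = int(rng.integers(min_len, max_len))
        spliced = _noncoding_seq(rng, length, gc, 300, table, require_neg)
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 3))
        span_guess = length + 400 * n_exons
        chrom, start = cursor.place(span_guess, int(rng.integers(400, 1500)), tid)
        exons, _ = _split_exons(rng, chrom, start, strand, length, n_exons)
        m = TranscriptModel(tid, gid, exons, biotype=biotype, sequence=spliced)
        _paste(genome, m, spliced)
        return m

    # --- cis pairs: known lncRNA anchors with a coding neighbor at an exact offset
    n_cis_lnc = 0
    n_cis_gene = 0
    coding_genes: list[TranscriptModel] = []
    known_lncs: list[TranscriptModel] = []
    for offset in config.cis_offsets:
        for _ in range(config.cis_pairs_per_offset):
            lnc_id = f"KLNC{n_cis_lnc:04d}"
            lnc = make_lnc_like(f"T{lnc_id}", lnc_id, "lncRNA")
            n_cis_lnc += 1
            # neighbor gene: gap between lnc end and gene start is exactly `offset`
            gid_idx = n_cis_gene
            gene_start = lnc.end + offset
            # reserve the region: advance the cursor past the neighbor
            gene = make_coding(gid_idx, chrom=lnc.chrom, start=gene_start)
            if gene.end > config.chrom_len:
                raise SizingError(f"cannot place cis neighbor GENE{gid_idx:04d}")
            cursor.pos = max(cursor.pos, gene.end)
            n_cis_gene += 1
            coding_genes.append(gene)
            known_lncs.append(lnc)
            truth.cis_pairs.add((lnc.gene_id, gene.gene_id, offset))

    # --- remaining reference features
    for i in range(n_cis_gene, config.n_coding_genes):
        coding_genes.append(make_coding(i))
    for i in range(n_cis_lnc, config.n_known_lncs):
        known_lncs.append(make_lnc_like(f"TKLNC{i:04d}", f"KLNC{i:04d}", "lncRNA"))
    reference = coding_genes + known_lncs

    # --- planted novel lncRNAs
    for i in range(config.n_novel_lncs):
        tid = f"asm_novel_{i:04d}"
        m = make_lnc_like(tid, tid, "unknown", min_len=250)
        planted.append(m)
        truth.novel_ids.add(tid)

    # --- decoy classes, one per cascade filter
    for i in range(config.n_decoys_short):
        tid = f"asm_short_{i:04d}"
        length = int(rng.integers(100, 180))
        spliced = _noncoding_seq(rng, length, gc, 300)
        chrom, start = cursor.place(length, int(rng.integers(400, 1500)), tid)
        m = TranscriptModel(
            tid, tid, [GenomicInterval(chrom, start, start + length, "+")],
            sequence=spliced,
        )
        _paste(genome, m, spliced)
        planted.append(m)
        truth.rejected_ids_by_reason["too_short"].add(tid)

    for i in range(config.n_decoys_coding):
        tid = f"asm_longorf_{i:04d}"
        n_codons = int(rng.integers(110, 160))
        spliced = (
            _noncoding_seq(rng, 30, gc, 120) + _cds(rng, n_codons)
            + _noncoding_seq(rng, 30, gc, 120)
        )
        chrom, start = cursor.place(len(spliced), int(rng.integers(400, 1500)), tid)
        m = TranscriptModel(
            tid, tid, [GenomicInterval(chrom, start, start + len(spliced), "+")],
            sequence=spliced,
        )
        _paste(genome, m, spliced)
        planted.append(m)
        truth.rejected_ids_by_reason["long_orf"].add(tid)

    for i in range(config.n_decoys_protein):
        tid = f"asm_prot_{i:04d}"
        m = make_lnc_like(tid, tid, "unknown", min_len=250, require_neg=True)
        planted.append(m)
        truth.rejected_ids_by_reason["protein_hit"].add(tid)

    for i in range(config.n_decoys_cpc):
        tid = f"asm_cpc_{i:04d}"
        for _ in range(50):
            spliced = _no_atg(rng, 15) + "ATG" + _biased_codons(rng, 98) + "TAA" + _no_atg(rng, 15)
            orf = longest_orf(spliced)
            if (
                orf is not None
                and orf.length_nt <= 300
                and coding_potential(spliced, table).S >= 0
            ):
                break
        else:
            raise RuntimeError("could not design coding-score decoy")
        chrom, start = cursor.place(len(spliced), int(rng.integers(400, 1500)), tid)
        m = TranscriptModel(
            tid, tid, [GenomicInterval(chrom, start, start + len(spliced), "+")],
            sequence=spliced,
        )
        _paste(genome, m, spliced)
        planted.append(m)
        truth.rejected_ids_by_reason["coding_score"].add(tid)

    # overlap decoys: single-exon transcripts straddling a reference exon
    genome_str_cache: dict[str, str] = {}

    def _splice_from_genome(m: TranscriptModel) -> str:
        for e in m.exons:
            if e.chrom not in genome_str_cache:
                genome_str_cache[e.chrom] = genome[e.chrom].decode()
        return m.splice(genome_str_cache)

    for i in range(config.n_decoys_overlap):
        tid = f"asm_refoverlap_{i:04d}"
        host = coding_genes[int(rng.integers(len(coding_genes)))]
        exon = host.exons[0]
        start = exon.start + int(rng.integers(0, max(1, len(exon) // 2)))
        length = int(rng.integers(220, 400))
        m = TranscriptModel(
            tid, tid,
            [GenomicInterval(exon.chrom, start, start + length, exon.strand)],
        )
        m.sequence = _splice_from_genome(m)
        planted.append(m)
        truth.rejected_ids_by_reason["not_u"].add(tid)

    for i in range(config.n_decoys_lnc_overlap):
        tid = f"asm_lncoverlap_{i:04d}"
        host = known_lncs[int(rng.integers(len(known_lncs)))]
        exon = host.exons[0]
        start = exon.start + int(rng.integers(0, max(1, len(exon) // 2)))
        length = int(rng.integers(220, 400))
        m = TranscriptModel(
            tid, tid,
            [GenomicInterval(exon.chrom, start, start + length, exon.strand)],
        )
        m.sequence = _splice_from_genome(m)
        planted.append(m)
        truth.rejected_ids_by_reason["known_lnc_overlap"].add(tid)

    # --- assembly re-emission of reference transcripts
    known_lnc_hits: list[HitRecord] = []
    protein_hits: list[HitRecord] = []
    copies: list[TranscriptModel] = []
    for i in range(config.n_coding_copies):
        src = coding_genes[i]
        tid = f"asm_cod_{i:04d}"
        m = TranscriptModel(tid, tid, list(src.exons), sequence=src.sequence)
        copies.append(m)
        truth.rejected_ids_by_reason["biotype"].add(tid)
        protein_hits.append(HitRecord(tid, f"NR_PROT_{i:05d}", 99.0, 300, 1e-30, 600.0))
    for i in range(config.n_known_copies):
        src = known_lncs[i]
        tid = f"asm_known_{i:04d}"
        m = TranscriptModel(tid, tid, list(src.exons), sequence=src.sequence)
        copies.append(m)
        truth.known_ids.add(tid)
        known_lnc_hits.append(
            HitRecord(tid, f"NONCODE_DR_{i:05d}", 98.0, 250, 1e-12, 420.0)
        )
    for i, tid in enumerate(sorted(truth.rejected_ids_by_reason["protein_hit"])):
        protein_hits.append(HitRecord(tid, f"NR_PROT_D{i:05d}", 85.0, 80, 1e-6, 120.0))

    assembly = copies + planted
    genome_final = {c: b.decode() for c, b in genome.items()}
    return reference, genome_final, truth, assembly, table, known_lnc_hits, protein_hits


# ---------------------------------------------------------------------------
# public operations


def gen_annotation(
    config: SyntheticConfig,
) -> tuple[list[TranscriptModel], dict[str, str], GroundTruth]:
    """Reference annotation, genome and ground truth for a configuration."""
    reference, genome, truth, *_ = _layout(config)
    return list(reference), dict(genome), copy.deepcopy(truth)


def gen_assembly(
    config: SyntheticConfig,
    reference: list[TranscriptModel],
    truth: GroundTruth,
) -> list[TranscriptModel]:
    """Assembled transcript set (with spliced sequences) matching the truth."""
    ref2, _, truth2, assembly, *_ = _layout(config)
    if [(m.transcript_id, m.exons) for m in ref2] != [
        (m.transcript_id, m.exons) for m in reference
    ]:
        raise ConsistencyError("reference does not match this configuration")
    if truth2.novel_ids != truth.novel_ids or truth2.cis_pairs != truth.cis_pairs:
        raise ConsistencyError("truth does not match this configuration")
    return assembly


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the complete synthetic study in one call."""
    reference, genome, truth, assembly, table, lnc_hits, prot_hits = _layout(config)
    return SyntheticDataset(
        config, list(reference), dict(genome), copy.deepcopy(truth), list(assembly),
        table, list(lnc_hits), list(prot_hits),
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def standard_comparisons(groups: tuple[str, ...]) -> list[tuple[str, str]]:
    """The three pairwise comparisons of a three-group design (A_vs_B,
    C_vs_A, C_vs_B for groups (A, B, C))."""
    if len(groups) != 3:
        return [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    a, b, c = groups
    return [(a, b), (c, a), (c, b)]


def gen_counts(
    config: SyntheticConfig,
    genes: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix over `genes` (columns gene_id, length, kind).

    Plants DE genes whose configured group means differ by exactly
    2**de_log2fc, and lncRNA-mRNA trans pairs sharing a latent per-sample
    profile so their expected correlation exceeds target_r.  Returns the
    counts and the matrix of expected means; updates `truth` in place.
    """
    rng = np.random.default_rng([config.seed, 2])
    if truth is None:
        truth = GroundTruth()
    samples = [f"{g}_{r + 1}" for g in config.groups for r in range(config.reps_per_group)]
    groups = {f"{g}_{r + 1}": g for g in config.groups for r in range(config.reps_per_group)}
    gene_ids = genes["gene_id"].tolist()
    n_genes = len(gene_ids)
    if n_genes == 0:
        raise ValueError("empty gene set")

    base = np.exp(rng.normal(config.base_mean_log_mu, config.base_mean_log_sd, n_genes))
    base = np.maximum(base, config.base_mean_min)

    kinds = genes["kind"].tolist()
    lnc_idx = [i for i, k in enumerate(kinds) if k == "lnc"]
    cod_idx = [i for i, k in enumerate(kinds) if k == "coding"]

    # trans pairs first (excluded from DE planting)
    n_pairs = min(config.n_trans_pairs, len(lnc_idx), len(cod_idx))
    pair_lnc = rng.choice(lnc_idx, size=n_pairs, replace=False) if n_pairs else np.array([], int)
    pair_cod = rng.choice(cod_idx, size=n_pairs, replace=False) if n_pairs else np.array([], int)
    trans_members = set(pair_lnc) | set(pair_cod)

    # planted DE
    mult = np.ones((n_genes, len(config.groups)))
    eligible = [i for i in range(n_genes) if i not in trans_members]
    n_de = int(round(config.de_fraction * n_genes))
    de_idx = rng.choice(eligible, size=min(n_de, len(eligible)), replace=False)
    de_group = rng.integers(0, len(config.groups), size=len(de_idx))
    for i, g in zip(de_idx, de_group):
        mult[i, g] = 2.0**config.de_log2fc
    for a, b in standard_comparisons(config.groups):
        ia, ib = config.groups.index(a), config.groups.index(b)
        comp = {}
        for i, g in zip(de_idx, de_group):
            if g == ia:
                comp[gene_ids[i]] = "up"
            elif g == ib:
                comp[gene_ids[i]] = "down"
        truth.de_ids_by_comparison[f"{a}_vs_{b}"] = comp

    # per-sample library scale
    lib_factor = (
        np.exp(rng.normal(0.0, config.lib_size_spread, len(samples)))
        if config.lib_size_spread > 0
        else np.ones(len(samples))
    )
    if np.any(lib_factor <= 0):
        raise ValueError("non-positive library size target")

    group_of = np.array([config.groups.index(groups[s]) for s in samples])
    means = base[:, None] * mult[:, group_of] * lib_factor[None, :]

    # shared latent profile for trans pairs
    phi = np.full(n_genes, config.nb_dispersion)
    for li, ci in zip(pair_lnc, pair_cod):
        z = rng.normal(0.0, config.trans_latent_sd, len(samples))
        profile = config.trans_base_mean * 2.0**z
        means[li, :] = profile * lib_factor
        means[ci, :] = profile * lib_factor
        phi[li] = phi[ci] = config.trans_dispersion
        truth.trans_pairs.add((gene_ids[li], gene_ids[ci]))

    counts = np.vstack(
        [_nb_draw(rng, means[i], float(phi[i])) for i in range(n_genes)]
    )
    cdf = pd.DataFrame(counts, index=gene_ids, columns=samples, dtype=float)
    lengths = pd.Series(genes["length"].to_numpy(float), index=gene_ids)
    cm = CountMatrix(cdf, groups, lengths)
    mean_df = pd.DataFrame(means, index=gene_ids, columns=samples)
    return cm, mean_df


def gen_reads(config: SyntheticConfig) -> tuple[list[SeqRecord], GroundTruth]:
    """FASTQ records violating exactly the QC rule each is labeled with."""
    rng = np.random.default_rng([config.seed, 3])
    truth = GroundTruth()
    records: list[tuple[str, str, list[int], str]] = []
    L = config.read_len

    def clean_seq() -> str:
        while True:
            s = _rand_seq(rng, L, 0.5)
            if config.adaptor not in s:
                return s

    def good_quals() -> list[int]:
        return list(rng.integers(30, 41, L))

    for i in range(config.n_reads_pass):
        records.append((f"read_pass_{i:05d}", clean_seq(), good_quals(), "pass"))
    for i in range(config.n_reads_fail_adaptor):
        s = clean_seq()
        pos = int(rng.integers(0, L - len(config.adaptor)))
        s = s[:pos] + config.adaptor + s[pos + len(config.adaptor) :]
        records.append((f"read_adaptor_{i:05d}", s, good_quals(), "fail:adaptor"))
    for i in range(config.n_reads_fail_n):
        s = list(clean_seq())
        n_n = int(rng.integers(int(0.10 * L) + 1, int(0.30 * L)))
        for k in rng.choice(L, size=n_n, replace=False):
            s[k] = "N"
        records.append((f"read_n_{i:05d}", "".join(s), good_quals(), "fail:N-fraction"))
    for i in range(config.n_reads_fail_lowq):
        q = good_quals()
        n_low = int(rng.integers(int(0.50 * L) + 1, int(0.80 * L)))
        for k in rng.choice(L, size=n_low, replace=False):
            q[k] = int(rng.integers(0, 6))
        records.append((f"read_lowq_{i:05d}", clean_seq(), q, "fail:low-quality"))

    order = rng.permutation(len(records))
    out = []
    for idx in order:
        rid, seq, quals, label = records[idx]
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = quals
        out.append(rec)
        truth.read_labels[rid] = label
    return out, truth


def gen_term_map(
    config: SyntheticConfig, genes: pd.DataFrame, truth: GroundTruth,
    terms_per_namespace: int = 8, term_size: int = 15, n_biased: int = 2,
) -> pd.DataFrame:
    """Term-to-gene map with a few terms biased toward planted DE genes."""
    rng = np.random.default_rng([config.seed, 4])
    gene_ids = genes["gene_id"].tolist()
    coding = set(genes.loc[genes["kind"] == "coding", "gene_id"])
    de_all = sorted(
        {g for comp in truth.de_ids_by_comparison.values() for g in comp} & coding
    ) or sorted({g for comp in truth.de_ids_by_comparison.values() for g in comp})
    rows = []
    for ns in ("biological_process", "cellular_component", "molecular_function", "pathway"):
        for t in range(terms_per_namespace):
            term_id = f"{ns[:2].upper()}:{t:04d}"
            name = f"{ns} term {t}"
            if t < n_biased and de_all:
                n_from_de = min(term_size // 2, len(de_all))
                members = set(rng.choice(de_all, size=n_from_de, replace=False))
                rest = [g for g in gene_ids if g not in members]
                members |= set(rng.choice(rest, size=term_size - n_from_de, replace=False))
            else:
                members = set(rng.choice(gene_ids, size=min(term_size, len(gene_ids)), replace=False))
            for g in sorted(members):
                rows.append((g, term_id, name, ns))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "namespace"])


def gen_ct_table(
    config: SyntheticConfig,
    stages: tuple[str, ...] = ("Zy", "Cl", "BL", "Ga"),
    reps: int = 3,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Triplicate Ct table for one target and two reference genes across stages."""
    rng = np.random.default_rng([config.seed, 5])
    shifts = {s: float(rng.uniform(-2.0, 2.0)) for s in stages}
    rows = []
    for s_i, stage in enumerate(stages):
        for r in range(reps):
            sample = f"{stage}_{r + 1}"
            for k in range(3):
                rows.append((sample, stage, "lnc_target", "target",
                             20.0 + shifts[stage] + rng.normal(0, noise_sd)))
                rows.append((sample, stage, "GAPDH", "reference",
                             15.0 + rng.normal(0, noise_sd)))
                rows.append((sample, stage, "beta_actin", "reference",
                             17.0 + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "role", "ct"])
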