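import numpy as np
import pytest

from lncweave.annotation import GenomicInterval, TranscriptModel
from lncweave.synthetic import SyntheticConfig, simulate

STOPS = {"TAA", "TAG", "TGA"}


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study, shared across tests (deterministic)."""
    return simulate(SyntheticConfig(seed=1))


def brute_force_orf(seq: str):
    """Exhaustive ORF scan over all (strand, start) pairs; independent oracle.

    Returns (length_nt, strand, start) of the longest ORF with the
    tie-break + strand first, then smallest start, or None.
    """
    from Bio.Seq import Seq

    seq = seq.upper()
    best = None
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for start in range(len(s) - 2):
            if s[start : start + 3] != "ATG":
                continue
            end = start + 3
            while end + 3 <= len(s):
                if s[end : end + 3] in STOPS:
                    cand = (end + 3 - start, strand, start)
                    if best is None or (
                        cand[0],
                        cand[1] == "+",
                        -cand[2],
                    ) > (best[0], best[1] == "+", -best[2]):
                        best = cand
                    break
                end += 3
    return best


def brute_force_classify(query: TranscriptModel, refs: list[TranscriptModel], tol=0):
    """Base-set implementation of the class-code definitions; independent oracle."""

    def bases(m):
        out = set()
        for e in m.exons:
            out.update(range(e.start, e.end))
        return out

    qb = bases(query)
    same_refs = [r for r in refs if r.chrom == query.chrom]
    equal = overlap_same = overlap_anti = intronic = False
    for r in same_refs:
        rb = bases(r)
        hit = bool(qb & rb)
        if hit and r.strand == query.strand:
            overlap_same = True
        if hit and r.strand != query.strand:
            overlap_anti = True
        if r.strand == query.strand:
            if len(query.exons) == 1 and len(r.exons) == 1:
                if (
                    abs(query.exons[0].start - r.exons[0].start) <= tol
                    and abs(query.exons[0].end - r.exons[0].end) <= tol
                ):
                    equal = True
            elif len(query.exons) > 1 and query.introns == r.introns:
                equal = True
            span_bases = set(range(r.start, r.end))
            if not (qb & rb) and qb <= (span_bases - rb):
                intronic = True
    if equal:
        return "="
    if overlap_same:
        return "o"
    if intronic and not overlap_anti:
        return "i"
    if overlap_anti:
        return "x"
    return "u"


def random_transcript(rng: np.random.Generator, chrom="chr1", max_pos=10_000, tid="q"):
    n_exons = int(rng.integers(1, 4))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(0, max_pos - 2000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(30, 300))
    return TranscriptModel(tid, tid, exons)
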