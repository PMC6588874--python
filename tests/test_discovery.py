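import numpy as np
import pytest

from lncweave.annotation import GenomicInterval, TranscriptModel
from lncweave.discovery import (
    CascadeParams,
    HitRecord,
    ScoreWeights,
    apply_hit_filter,
    coding_potential,
    discover_lncrnas,
    fickett_score,
    hexamer_llr,
    hexamer_table,
    longest_orf,
    read_hit_table,
)
from lncweave.synthetic import default_hexamer_table

from conftest import brute_force_orf


class TestLongestORF:
    def test_minimal_orf(self):
        orf = longest_orf("ATGAAATAG")
        assert (orf.length_nt, orf.strand, orf.frame) == (9, "+", 0)

    def test_no_atg_means_no_orf(self):
        assert longest_orf("CCCCCCCCC") is None

    def test_no_stop_means_no_orf(self):
        assert longest_orf("ATGAAAAAAAAA") is None

    def test_codons_with_n_never_match(self):
        assert longest_orf("ATNAAATAG") is None

    def test_reverse_strand_found(self):
        # revcomp of ATGAAATAG
        orf = longest_orf("CTATTTCAT")
        assert orf.length_nt == 9 and orf.strand == "-"

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for trial in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(9, 400))))
            got = longest_orf(seq)
            want = brute_force_orf(seq)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (got.length_nt, got.strand, got.start) == want, f"trial {trial}"


class TestCodingPotential:
    def test_zero_weights_give_zero_score(self):
        w = ScoreWeights(w_orf=0, w_cov=0, w_fickett=0, w_hexamer=0)
        assert coding_potential("ATGAAATAGTTT", {}, w).S == 0.0

    def test_no_orf_gives_zero_hexamer_llr(self):
        assert hexamer_llr("CCCCCCCCCCCC", {"CCCCCC": 5.0}) == 0.0

    def test_short_sequence_gives_zero_hexamer_llr(self):
        assert hexamer_llr("ACG", {"ACGACG": 1.0}) == 0.0

    def test_coding_biased_orf_outscores_its_shuffle(self):
        rng = np.random.default_rng(5)
        table = default_hexamer_table(seed=5)
        best = max(table, key=table.get)
        core = (best * 60)[: 59 * 3]
        seq = "ATG" + core + "TAA"
        shuffled = "".join(rng.permutation(list(seq)))
        assert coding_potential(seq, table).S > coding_potential(shuffled, table).S

    def test_fickett_separates_coding_from_random(self):
        rng = np.random.default_rng(9)
        from lncweave.synthetic import _cds, _rand_seq

        coding = [fickett_score(_cds(rng, 150)) for _ in range(20)]
        random_ = [fickett_score(_rand_seq(rng, 450, 0.44)) for _ in range(20)]
        assert np.mean(coding) > np.mean(random_)

    def test_hexamer_table_sign_convention(self):
        table = hexamer_table(["ATGGCCGAGAAG" * 20], ["ACGTACGTACGT" * 20])
        assert table["GCCGAG"] > 0  # coding-enriched hexamer
        assert table["CGTACG"] < 0  # noncoding-enriched hexamer


class TestHitFilter:
    def test_empty_table_all_no_hit(self):
        hit, no_hit = apply_hit_filter(["a", "b"], [], 1e-5)
        assert hit == set() and no_hit == {"a", "b"}

    def test_boundary_evalue_is_inclusive(self):
        hits = [HitRecord("a", "s", 90.0, 100, 1e-5, 50.0)]
        hit, _ = apply_hit_filter(["a"], hits, 1e-5)
        assert hit == {"a"}

    def test_matches_per_id_minimum_evalue_check(self):
        rng = np.random.default_rng(13)
        ids = [f"t{i}" for i in range(50)]
        hits = [
            HitRecord(ids[int(rng.integers(50))], "s", 90.0, 100,
                      float(10.0 ** rng.uniform(-12, 0)), 50.0)
            for _ in range(200)
        ]
        e_max = 1e-5
        hit, no_hit = apply_hit_filter(ids, hits, e_max)
        for i in ids:
            evals = [h.e_value for h in hits if h.query_id == i]
            want_hit = bool(evals) and min(evals) <= e_max
            assert (i in hit) == want_hit
        assert hit | no_hit == set(ids) and not (hit & no_hit)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match="line 1"):
            read_hit_table(p)


def _intergenic(tid, start, length, seq=None, chrom="chr9"):
    return TranscriptModel(
        tid, tid, [GenomicInterval(chrom, start, start + length, "+")], sequence=seq
    )


class TestCascade:
    def test_recovers_planted_truth(self, dataset):
        catalog = discover_lncrnas(
            dataset.assembly, dataset.reference, dataset.known_lnc_hits,
            dataset.protein_hits, hexamer_tab=dataset.hexamer_tab,
        )
        assert catalog.novel_ids == dataset.truth.novel_ids
        assert catalog.known_ids == dataset.truth.known_ids
        assert catalog.rejected_by_reason() == dataset.truth.rejected_ids_by_reason

    def test_count_conservation(self, dataset):
        catalog = discover_lncrnas(
            dataset.assembly, dataset.reference, dataset.known_lnc_hits,
            dataset.protein_hits, hexamer_tab=dataset.hexamer_tab,
        )
        assert sum(catalog.counts().values()) == len(dataset.assembly)

    def test_empty_assembly_gives_empty_catalog(self, dataset):
        catalog = discover_lncrnas([], dataset.reference, [], [])
        assert catalog.entries == {} and sum(catalog.counts().values()) == 0

    def test_first_failing_step_is_the_reason(self, dataset):
        """A short transcript overlapping a known lncRNA is rejected as
        too_short: the length filter precedes the lncRNA-overlap filter."""
        lnc = next(m for m in dataset.reference if m.biotype == "lncRNA")
        exon = lnc.exons[0]
        q = TranscriptModel(
            "q_short_overlap", "q",
            [GenomicInterval(exon.chrom, exon.start, exon.start + 150, exon.strand)],
            sequence="A" * 150,
        )
        catalog = discover_lncrnas([q], dataset.reference, [], [])
        assert catalog.entries["q_short_overlap"].reason == "too_short"

    def test_relaxing_thresholds_never_shrinks_novel_set(self, dataset):
        base = discover_lncrnas(
            dataset.assembly, dataset.reference, dataset.known_lnc_hits,
            dataset.protein_hits, CascadeParams(), dataset.hexamer_tab,
        ).novel_ids
        relaxed = discover_lncrnas(
            dataset.assembly, dataset.reference, dataset.known_lnc_hits,
            dataset.protein_hits,
            CascadeParams(min_len=150, max_orf=450), dataset.hexamer_tab,
        ).novel_ids
        assert base <= relaxed

    def test_missing_sequence_raises_naming_transcript(self, dataset):
        q = _intergenic("q_noseq", 5000, 400)
        with pytest.raises(ValueError, match="q_noseq"):
            discover_lncrnas([q], dataset.reference, [], [])
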