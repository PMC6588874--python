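import numpy as np
import pandas as pd
import pytest

from lncweave.annotation import read_gtf, write_gtf
from lncweave.synthetic import (
    GroundTruth,
    SizingError,
    SyntheticConfig,
    gen_annotation,
    gen_assembly,
    gen_counts,
    gen_reads,
    simulate,
)

from conftest import brute_force_orf

SMALL = SyntheticConfig(
    n_chroms=2, chrom_len=800_000, n_coding_genes=20, n_known_lncs=10,
    n_novel_lncs=30, n_decoys_short=5, n_decoys_coding=5, n_decoys_overlap=5,
    n_decoys_lnc_overlap=5, n_decoys_protein=5, n_decoys_cpc=5,
    n_coding_copies=10, n_known_copies=10, cis_offsets=(50_000,),
    cis_pairs_per_offset=2, n_trans_pairs=5, seed=7,
)


class TestDeterminism:
    def test_same_config_gives_identical_gtf_text(self, tmp_path):
        ref1, _, _ = gen_annotation(SMALL)
        ref2, _, _ = gen_annotation(SyntheticConfig(**vars(SMALL)))
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(ref1, p1)
        write_gtf(ref2, p2)
        assert p1.read_text() == p2.read_text()

    def test_counts_reproducible(self):
        ds = simulate(SMALL)
        genes = ds.gene_table()
        cm1, _ = gen_counts(SMALL, genes, GroundTruth())
        cm2, _ = gen_counts(SMALL, genes, GroundTruth())
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)

    def test_reads_reproducible(self):
        r1, t1 = gen_reads(SMALL)
        r2, t2 = gen_reads(SMALL)
        assert [str(x.seq) for x in r1] == [str(x.seq) for x in r2]
        assert t1.read_labels == t2.read_labels


class TestAnnotation:
    def test_no_coding_genes_when_zero(self):
        cfg = SyntheticConfig(
            n_chroms=1, chrom_len=600_000, n_coding_genes=0, n_known_lncs=5,
            n_novel_lncs=5, n_decoys_short=0, n_decoys_coding=0,
            n_decoys_overlap=0, n_decoys_lnc_overlap=2, n_decoys_protein=0,
            n_decoys_cpc=0, n_coding_copies=0, n_known_copies=2,
            cis_offsets=(), n_trans_pairs=0, seed=1,
        )
        ref, _, _ = gen_annotation(cfg)
        assert all(m.biotype != "protein_coding" for m in ref)

    def test_cis_offsets_verified_from_emitted_gtf(self, tmp_path):
        """Planted neighbor gene start sits exactly `offset` bp from the lnc
        end, recomputed from the written GTF with an independent scan."""
        ref, _, truth = gen_annotation(SMALL)
        p = tmp_path / "ref.gtf"
        write_gtf(ref, p)
        back = read_gtf(p)
        span = {}
        for m in back:
            lo, hi = span.get(m.gene_id, (m.start, m.end))
            span[m.gene_id] = (min(lo, m.start), max(hi, m.end))
        assert truth.cis_pairs
        for lnc_gid, gene_gid, offset in truth.cis_pairs:
            lnc_lo, lnc_hi = span[lnc_gid]
            gene_lo, gene_hi = span[gene_gid]
            assert gene_lo - lnc_hi == offset

    def test_sizing_error_names_feature(self):
        cfg = SyntheticConfig(
            n_chroms=1, chrom_len=30_000, n_coding_genes=20, n_known_lncs=10,
            n_novel_lncs=10, cis_offsets=(), n_coding_copies=0, n_known_copies=0,
            n_decoys_short=0, n_decoys_coding=0, n_decoys_overlap=0,
            n_decoys_lnc_overlap=0, n_decoys_protein=0, n_decoys_cpc=0, seed=1,
        )
        with pytest.raises(SizingError, match="cannot place"):
            gen_annotation(cfg)

    def test_genome_gc_near_target(self):
        _, genome, _ = gen_annotation(SMALL)
        seq = "".join(genome.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - SMALL.gc_content) < 0.02


@pytest.fixture(scope="module")
def ds():
    return simulate(SMALL)


class TestAssembly:

    def test_novel_transcripts_have_no_reference_exon_overlap(self, ds):
        ref_exons = [
            (e.chrom, e.start, e.end) for m in ds.reference for e in m.exons
        ]
        novel = [m for m in ds.assembly if m.transcript_id in ds.truth.novel_ids]
        for m in novel:
            for qe in m.exons:
                for chrom, s, e in ref_exons:
                    assert not (qe.chrom == chrom and qe.start < e and s < qe.end), (
                        m.transcript_id
                    )

    def test_short_decoys_under_200(self, ds):
        for tid in ds.truth.rejected_ids_by_reason["too_short"]:
            m = next(x for x in ds.assembly if x.transcript_id == tid)
            assert m.spliced_length < 200

    def test_coding_decoys_have_long_orf_by_brute_force(self, ds):
        for tid in ds.truth.rejected_ids_by_reason["long_orf"]:
            m = next(x for x in ds.assembly if x.transcript_id == tid)
            length, _, _ = brute_force_orf(m.sequence)
            assert length > 300

    def test_novel_orfs_capped_by_brute_force(self, ds):
        novel = [m for m in ds.assembly if m.transcript_id in ds.truth.novel_ids]
        for m in novel[:10]:
            best = brute_force_orf(m.sequence)
            assert best is None or best[0] <= 300

    def test_sequences_match_genome_splice(self, ds):
        for m in ds.assembly[:20]:
            assert m.sequence == m.splice(ds.genome)

    def test_truth_ids_subset_of_emitted(self, ds):
        emitted = {m.transcript_id for m in ds.assembly}
        planted = set(ds.truth.novel_ids) | set(ds.truth.known_ids)
        for ids in ds.truth.rejected_ids_by_reason.values():
            planted |= ids
        assert planted <= emitted

    def test_mismatched_truth_rejected(self, ds):
        from lncweave.synthetic import ConsistencyError

        tampered = simulate(SMALL).truth
        tampered.novel_ids.pop()
        with pytest.raises(ConsistencyError):
            gen_assembly(SMALL, ds.reference, tampered)

    def test_mismatched_reference_rejected(self, ds):
        from lncweave.synthetic import ConsistencyError

        other = simulate(SyntheticConfig(**{**vars(SMALL), "seed": 8}))
        with pytest.raises(ConsistencyError):
            gen_assembly(SMALL, other.reference, ds.truth)


class TestCounts:
    def _genes(self, n=300):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "length": 1000,
            "kind": ["coding"] * (n // 2) + ["lnc"] * (n - n // 2),
        })

    def test_null_config_has_equal_group_means(self):
        cfg = SyntheticConfig(seed=2, de_fraction=0.0, n_trans_pairs=0)
        _, means = gen_counts(cfg, self._genes(), GroundTruth())
        bs = means[[c for c in means.columns if c.startswith("BS")]].mean(axis=1)
        ws = means[[c for c in means.columns if c.startswith("WS")]].mean(axis=1)
        assert np.allclose(bs, ws)

    def test_planted_de_ratio_is_2_to_log2fc(self):
        cfg = SyntheticConfig(seed=2, de_fraction=0.2, de_log2fc=2.0, n_trans_pairs=0)
        truth = GroundTruth()
        _, means = gen_counts(cfg, self._genes(), truth)
        comp = truth.de_ids_by_comparison["BS_vs_WS"]
        assert comp
        for gene, direction in comp.items():
            bs = means.loc[gene, [c for c in means.columns if c.startswith("BS")]].mean()
            ws = means.loc[gene, [c for c in means.columns if c.startswith("WS")]].mean()
            ratio = bs / ws if direction == "up" else ws / bs
            assert ratio == pytest.approx(2.0**2.0)

    def test_planted_trans_pairs_reach_target_correlation(self):
        cfg = SyntheticConfig(seed=2, de_fraction=0.0, n_trans_pairs=15, target_r=0.99)
        truth = GroundTruth()
        cm, _ = gen_counts(cfg, self._genes(), truth)
        log_expr = np.log2(cm.counts + 1)
        rs = [
            np.corrcoef(log_expr.loc[l], log_expr.loc[g])[0, 1]
            for l, g in truth.trans_pairs
        ]
        assert np.median(rs) >= 0.95

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            gen_counts(SMALL, pd.DataFrame(columns=["gene_id", "length", "kind"]), GroundTruth())


class TestReads:
    def test_labels_consistent_with_rules_by_recomputation(self):
        cfg = SyntheticConfig(seed=4)
        reads, truth = gen_reads(cfg)
        for rec in reads:
            seq = str(rec.seq)
            quals = rec.letter_annotations["phred_quality"]
            label = truth.read_labels[rec.id]
            has_adaptor = cfg.adaptor in seq
            n_frac = seq.count("N") / len(seq)
            lowq_frac = sum(q <= 5 for q in quals) / len(quals)
            if label == "pass":
                assert not has_adaptor and n_frac <= 0.10 and lowq_frac <= 0.50
            elif label == "fail:adaptor":
                assert has_adaptor
            elif label == "fail:N-fraction":
                assert not has_adaptor and n_frac > 0.10
            else:
                assert not has_adaptor and n_frac <= 0.10 and lowq_frac > 0.50
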