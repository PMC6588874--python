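"""End-to-end orchestration: simulate -> qc -> discover -> fpkm/de -> targets -> enrich.

The pipeline runs the stages in the order of the study workflow on a
synthetic dataset (or on files supplied via config), writes every stage
output under an output directory, and assembles a summary report whose
percentages are always recomputed from its counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import annotation, discovery, enrichment, expression, qc, synthetic, targets

logger = logging.getLogger(__name__)


def percentages(counts: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Percentage of each count in the total, rounded; pure function of counts."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


def catalog_split(known: int, novel: int) -> dict[str, float | int]:
    """Worked-example arithmetic: known/novel lncRNA counts to percentages."""
    pct = percentages({"known": known, "novel": novel}, decimals=1)
    return {
        "total": known + novel,
        "known": known,
        "novel": novel,
        "known_percent": pct["known"],
        "novel_percent": pct["novel"],
    }


@dataclass
class SummaryReport:
    """Per-stage counts; every percentage is derived, never stored."""

    n_raw_reads: int = 0
    n_clean_reads: int = 0
    n_transcripts: int = 0
    n_known_lnc: int = 0
    n_novel_lnc: int = 0
    rejected_by_reason: dict[str, int] = field(default_factory=dict)
    de_up_down: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_de_lnc: int = 0
    n_de_mrna: int = 0
    n_de_lnc_known: int = 0
    n_de_lnc_novel: int = 0
    n_cis_pairs: int = 0
    n_cis_lnc: int = 0
    n_trans_pairs: int = 0
    n_trans_lnc: int = 0
    enrichment_namespaces: dict[str, int] = field(default_factory=dict)

    @property
    def clean_percent(self) -> float | None:
        if self.n_raw_reads == 0:
            return None
        return round(100.0 * self.n_clean_reads / self.n_raw_reads, 2)

    @property
    def known_percent(self) -> float:
        return catalog_split(self.n_known_lnc, self.n_novel_lnc)["known_percent"]

    @property
    def novel_percent(self) -> float:
        return catalog_split(self.n_known_lnc, self.n_novel_lnc)["novel_percent"]

    def to_dict(self) -> dict:
        d = {
            "n_raw_reads": self.n_raw_reads,
            "n_clean_reads": self.n_clean_reads,
            "clean_percent": self.clean_percent,
            "n_transcripts": self.n_transcripts,
            "n_known_lnc": self.n_known_lnc,
            "n_novel_lnc": self.n_novel_lnc,
            "known_percent": self.known_percent,
            "novel_percent": self.novel_percent,
            "rejected_by_reason": dict(sorted(self.rejected_by_reason.items())),
            "de_up_down": {k: list(v) for k, v in sorted(self.de_up_down.items())},
            "n_de_lnc": self.n_de_lnc,
            "n_de_mrna": self.n_de_mrna,
            "n_de_lnc_known": self.n_de_lnc_known,
            "n_de_lnc_novel": self.n_de_lnc_novel,
            "n_cis_pairs": self.n_cis_pairs,
            "n_cis_lnc": self.n_cis_lnc,
            "n_trans_pairs": self.n_trans_pairs,
            "n_trans_lnc": self.n_trans_lnc,
            "enrichment_namespaces": dict(sorted(self.enrichment_namespaces.items())),
        }
        return d

    def to_text(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def summarize_de(
    de_tables: dict[str, list[expression.DERecord]],
    catalog: discovery.LncRNACatalog | None = None,
) -> dict:
    """Distinct DE gene tallies across comparisons, with Venn intersections
    and (when a catalog is supplied) the known/novel lncRNA split."""
    sig_sets = {
        comp: {r.gene_id for r in recs if r.call != "ns"}
        for comp, recs in de_tables.items()
    }
    per_comp = {
        comp: (
            sum(r.call == "up" for r in recs),
            sum(r.call == "down" for r in recs),
        )
        for comp, recs in de_tables.items()
    }
    distinct = set().union(*sig_sets.values()) if sig_sets else set()
    out = {
        "per_comparison_up_down": per_comp,
        "distinct_total": len(distinct),
        "distinct_ids": distinct,
    }
    comps = sorted(sig_sets)
    if len(comps) == 3:
        a, b, c = (sig_sets[k] for k in comps)
        out["intersections"] = {
            f"{comps[0]}&{comps[1]}": len(a & b),
            f"{comps[0]}&{comps[2]}": len(a & c),
            f"{comps[1]}&{comps[2]}": len(b & c),
            "all_three": len(a & b & c),
        }
    if catalog is not None:
        known = distinct & catalog.known_ids
        novel = distinct & catalog.novel_ids
        out["de_lnc_known"] = len(known)
        out["de_lnc_novel"] = len(novel)
        out["de_lnc_total"] = len(known | novel)
        out["de_mrna_total"] = len(distinct - known - novel)
    return out


@dataclass
class PipelineConfig:
    out_dir: str = "lncweave_out"
    seed: int = 0
    synthetic: synthetic.SyntheticConfig | None = None
    cascade: discovery.CascadeParams = field(default_factory=discovery.CascadeParams)
    de_thresholds: expression.DEThresholds = field(default_factory=expression.DEThresholds)
    cis_min: int = 10_000
    cis_max: int = 100_000
    trans_r_min: float = 0.95
    trans_p_max: float = 0.05
    enrich_p_max: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        cfg.seed = raw.get("seed", cfg.seed)
        syn = raw.get("synthetic", {})
        cfg.synthetic = synthetic.SyntheticConfig(seed=cfg.seed, **syn)
        if "cascade" in raw:
            cfg.cascade = discovery.CascadeParams(**raw["cascade"])
        if "de" in raw:
            cfg.de_thresholds = expression.DEThresholds(**raw["de"])
        for key in ("cis_min", "cis_max", "trans_r_min", "trans_p_max", "enrich_p_max"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Run every stage on the configured synthetic study and write outputs.

    Stage order: read QC -> discovery cascade -> FPKM -> pairwise DE ->
    cis/trans targets -> network -> enrichment.  All randomness flows from
    the single seed in the synthetic configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn_cfg = config.synthetic or synthetic.SyntheticConfig(seed=config.seed)
    report = SummaryReport()

    logger.info("stage simulate: seed %d", syn_cfg.seed)
    ds = synthetic.simulate(syn_cfg)
    annotation.write_gtf(ds.reference, out / "reference.gtf")
    annotation.write_fasta(ds.genome, out / "genome.fa")
    annotation.write_gtf(ds.assembly, out / "assembly.gtf")
    annotation.write_fasta(
        {m.transcript_id: m.sequence for m in ds.assembly}, out / "assembly.fa"
    )
    discovery.write_hit_table(ds.known_lnc_hits, out / "known_lnc_hits.tsv")
    discovery.write_hit_table(ds.protein_hits, out / "protein_hits.tsv")

    logger.info("stage qc")
    reads, _read_truth = synthetic.gen_reads(syn_cfg)
    with open(out / "raw.fastq", "w") as fh:
        SeqIO.write(reads, fh, "fastq")
    qc_report = qc.filter_fastq(
        out / "raw.fastq", out / "clean.fastq",
        qc.QCThresholds(adaptor=syn_cfg.adaptor),
    )
    (out / "qc_report.tsv").write_text(qc_report.to_tsv())
    report.n_raw_reads = qc_report.n_raw
    report.n_clean_reads = qc_report.n_clean

    logger.info("stage discover")
    catalog = discovery.discover_lncrnas(
        ds.assembly, ds.reference, ds.known_lnc_hits, ds.protein_hits,
        config.cascade, ds.hexamer_tab,
    )
    catalog.to_tsv(out / "catalog.tsv")
    report.n_transcripts = len(ds.assembly)
    report.n_known_lnc = len(catalog.known_ids)
    report.n_novel_lnc = len(catalog.novel_ids)
    report.rejected_by_reason = {
        r: len(ids) for r, ids in catalog.rejected_by_reason().items()
    }

    logger.info("stage expression")
    genes = ds.gene_table()
    cm, _means = synthetic.gen_counts(syn_cfg, genes, ds.truth)
    cm.to_tsv(out / "counts.tsv", out / "groups.tsv", out / "lengths.tsv")
    fpkm_mat = expression.fpkm(cm)
    fpkm_mat.to_csv(out / "fpkm.tsv", sep="\t", index_label="gene_id")
    comparisons = synthetic.standard_comparisons(syn_cfg.groups)
    de = expression.call_de(cm, comparisons, config.de_thresholds)
    expression.de_table(de).to_csv(out / "de.tsv", sep="\t", index=False)
    for comp, recs in de.items():
        report.de_up_down[comp] = (
            sum(r.call == "up" for r in recs),
            sum(r.call == "down" for r in recs),
        )
    de_summary = summarize_de(de, catalog)
    lnc_gene_ids = set(genes.loc[genes["kind"] == "lnc", "gene_id"])
    known_lnc_gene_ids = {m.gene_id for m in ds.reference if m.biotype == "lncRNA"}
    distinct = de_summary["distinct_ids"]
    de_lnc = distinct & lnc_gene_ids
    report.n_de_lnc = len(de_lnc)
    report.n_de_mrna = len(distinct - lnc_gene_ids)
    report.n_de_lnc_known = len(de_lnc & known_lnc_gene_ids)
    report.n_de_lnc_novel = len(de_lnc & catalog.novel_ids)

    logger.info("stage targets")
    novel_models = {m.transcript_id: m for m in ds.assembly}
    lnc_loci = [m for m in ds.reference if m.biotype == "lncRNA"] + [
        novel_models[t] for t in sorted(catalog.novel_ids)
    ]
    coding_loci = [m for m in ds.reference if m.biotype == "protein_coding"]
    cis = targets.cis_targets(lnc_loci, coding_loci, config.cis_min, config.cis_max)
    # cis loci carry transcript ids; report pairs at gene level
    cis_gene_pairs = [
        targets.TargetPair(novel_models[p.lnc_id].gene_id if p.lnc_id in novel_models
                           else next(m.gene_id for m in lnc_loci if m.transcript_id == p.lnc_id),
                           next(m.gene_id for m in coding_loci if m.transcript_id == p.gene_id),
                           "cis", distance=p.distance)
        for p in cis
    ]
    trans = targets.trans_targets(
        fpkm_mat, sorted(lnc_gene_ids), sorted(set(genes["gene_id"]) - lnc_gene_ids),
        config.trans_r_min, config.trans_p_max,
    )
    all_pairs = cis_gene_pairs + trans
    targets.pairs_table(all_pairs).to_csv(out / "target_pairs.tsv", sep="\t", index=False)
    net = targets.build_network(all_pairs)
    targets.export_network(net, out / "network.sif", "sif")
    targets.export_network(net, out / "network.graphml", "graphml")
    report.n_cis_pairs = len(cis_gene_pairs)
    report.n_cis_lnc = len({p.lnc_id for p in cis_gene_pairs})
    report.n_trans_pairs = len(trans)
    report.n_trans_lnc = len({p.lnc_id for p in trans})

    logger.info("stage enrichment")
    term_map = synthetic.gen_term_map(syn_cfg, genes, ds.truth)
    term_map.to_csv(out / "terms.tsv", sep="\t", index=False)
    background = set(genes["gene_id"])
    study = (distinct - lnc_gene_ids) or background
    records = enrichment.enrich(study & background, background, term_map)
    enrichment.records_table(records).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    ns_summary, _total = enrichment.namespace_summary(records, p_max=config.enrich_p_max)
    report.enrichment_namespaces = {ns: c for ns, (c, _pct) in ns_summary.items()}

    (out / "report.json").write_text(report.to_text())
    return report
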