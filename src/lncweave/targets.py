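"""Cis/trans lncRNA target prediction and co-expression network construction.

Cis targets are protein-coding genes whose locus lies 10-100 kb from a
lncRNA locus (gap between nearest feature ends; overlap counts as distance
0).  Trans targets are genes whose expression across samples correlates
with the lncRNA at Pearson r >= 0.95 with p < 0.05 (two-sided t test on
r).  Pairs assemble into a bipartite lncRNA-gene network exportable as SIF
or GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetPair:
    lnc_id: str
    gene_id: str
    mode: str  # cis | trans
    distance: int | None = None  # signed bp; negative = gene upstream of lnc
    r: float | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "cis" and (self.distance is None or self.r is not None):
            raise ValueError("cis pairs carry distance and no (r, p)")
        if self.mode == "trans" and (self.r is None or self.distance is not None):
            raise ValueError("trans pairs carry (r, p) and no distance")
        if self.r is not None and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _span(m: TranscriptModel) -> tuple[str, int, int]:
    return m.chrom, m.start, m.end


def gap_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp between nearest ends of two intervals; 0 when they overlap."""
    if a_start < b_end and b_start < a_end:
        return 0
    return b_start - a_end if b_start >= a_end else a_start - b_end


def cis_targets(
    lnc_loci: Sequence[TranscriptModel],
    gene_loci: Sequence[TranscriptModel],
    min_dist: int = 10_000,
    max_dist: int = 100_000,
) -> list[TargetPair]:
    """All (lncRNA, gene) pairs whose genomic gap lies within [min_dist, max_dist].

    The signed distance reports the gene's position on the reference strand:
    negative when the gene is upstream (left) of the lncRNA.  Output is
    sorted by lnc_id then distance.
    """
    if min_dist >= max_dist:
        raise ValueError("min_dist must be < max_dist")
    pairs = []
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in gene_loci:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lnc in lnc_loci:
        for gene in by_chrom.get(lnc.chrom, ()):
            d = gap_distance(lnc.start, lnc.end, gene.start, gene.end)
            if min_dist <= d <= max_dist:
                signed = -d if gene.end <= lnc.start else d
                pairs.append(
                    TargetPair(lnc.transcript_id, gene.transcript_id, "cis", distance=signed)
                )
    pairs.sort(key=lambda p: (p.lnc_id, p.distance, p.gene_id))
    return pairs


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value from the t statistic with n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def trans_targets(
    expr: pd.DataFrame,
    lnc_ids: Iterable[str],
    gene_ids: Iterable[str],
    r_min: float = 0.95,
    p_max: float = 0.05,
    use_absolute: bool = False,
    log_transform: bool = True,
) -> list[TargetPair]:
    """Correlated (lncRNA, gene) pairs across samples.

    Expression defaults to log2(FPKM + 1).  A pair is emitted iff
    r >= r_min (or |r| >= r_min with use_absolute) AND p < p_max (strict).
    Zero-variance rows are skipped with a logged count.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    lnc_ids = [i for i in lnc_ids if i in expr.index]
    gene_ids = [i for i in gene_ids if i in expr.index]
    mat = np.log2(expr + 1.0) if log_transform else expr
    n = mat.shape[1]
    lm = mat.loc[lnc_ids].to_numpy(float)
    gm = mat.loc[gene_ids].to_numpy(float)
    ls = lm.std(axis=1)
    gs = gm.std(axis=1)
    n_skipped = int((ls == 0).sum() + (gs == 0).sum())
    if n_skipped:
        logger.info("trans_targets: %d zero-variance rows skipped", n_skipped)
    lz = (lm - lm.mean(axis=1, keepdims=True))
    gz = (gm - gm.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        rmat = (lz @ gz.T) / (n * np.outer(ls, gs))
    rmat = np.clip(rmat, -1.0, 1.0)
    pairs = []
    for i, lnc in enumerate(lnc_ids):
        if ls[i] == 0:
            continue
        for j, gene in enumerate(gene_ids):
            if gs[j] == 0 or lnc == gene:
                continue
            r = float(rmat[i, j])
            crit = abs(r) if use_absolute else r
            if crit < r_min:
                continue
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1 - r * r))
                p = float(2 * stats.t.sf(abs(t), n - 2))
            if p < p_max:
                pairs.append(TargetPair(lnc, gene, "trans", r=r, p=p))
    pairs.sort(key=lambda p: (p.lnc_id, -p.r, p.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# Network


def build_network(pairs: Sequence[TargetPair]) -> nx.Graph:
    """Bipartite lncRNA-gene graph with edge attributes (mode, r, p, distance)."""
    g = nx.Graph()
    for p in pairs:
        if p.lnc_id == p.gene_id:
            raise ValueError(f"self-loop: {p.lnc_id}")
        g.add_node(p.lnc_id, node_type="lncRNA", bipartite=0)
        g.add_node(p.gene_id, node_type="gene", bipartite=1)
        attrs = {"mode": p.mode}
        if p.distance is not None:
            attrs["distance"] = p.distance
        if p.r is not None:
            attrs["r"] = p.r
            attrs["p"] = p.p
        g.add_edge(p.lnc_id, p.gene_id, **attrs)
    return g


def export_network(network: nx.Graph, path, fmt: str = "sif") -> None:
    """Write the network as SIF (lnc <tab> interacts <tab> gene) or GraphML."""
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(network.edges()):
                if network.nodes[u].get("node_type") != "lncRNA":
                    u, v = v, u
                fh.write(f"{u}\tinteracts\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: sif, graphml")


def read_sif(path) -> set[tuple[str, str]]:
    edges = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 3:
                edges.add((parts[0], parts[2]))
    return edges


def hub_report(network: nx.Graph, top_k: int = 10) -> list[tuple[str, str, int]]:
    """Top-k nodes by degree as (node, node_type, degree)."""
    ranked = sorted(network.degree(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return [(n, network.nodes[n].get("node_type", "?"), d) for n, d in ranked]


def pairs_table(pairs: Sequence[TargetPair]) -> pd.DataFrame:
    rows = [
        (p.lnc_id, p.gene_id, p.mode, p.distance, p.r, p.p) for p in pairs
    ]
    return pd.DataFrame(
        rows, columns=["lnc_id", "gene_id", "mode", "distance", "r", "p"]
    )
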