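"""Over-representation analysis for GO/KEGG-style term maps.

For each term with K background genes, a study set of n genes out of N
background genes containing k term members is scored with the upper
hypergeometric tail P(X >= k); BH adjustment runs across all tested terms.
An EASE-style conservative variant (scoring k-1) is available behind a
flag.  Namespace tallies summarize the significant records.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .expression import bh_adjust


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    namespace: str
    k: int  # study hits
    K: int  # term size in background
    n: int  # study size
    N: int  # background size
    p: float
    q: float = 1.0


def read_term_map(path) -> pd.DataFrame:
    """Term map TSV with columns gene_id, term_id, term_name, namespace."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "term_id", "term_name", "namespace"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"term map missing columns: {sorted(missing)}")
    return df


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: set[str],
    background: set[str],
    term_map: pd.DataFrame,
    p_max: float = 0.05,
    ease: bool = False,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of each term in the study set.

    Terms are restricted to background genes.  Records are sorted by p then
    term id; q is BH-adjusted across all tested terms.  With ease=True the
    tail is evaluated at k-1 (never below 0), the DAVID-style conservative
    score.
    """
    offenders = study - background
    if offenders:
        raise ValueError(f"study genes absent from background: {sorted(offenders)[:5]}")
    tm = term_map[term_map["gene_id"].isin(background)]
    N, n = len(background), len(study)
    records = []
    for (term_id, term_name, namespace), sub in tm.groupby(
        ["term_id", "term_name", "namespace"], sort=True
    ):
        members = set(sub["gene_id"])
        K = len(members)
        k = len(members & study)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_tail(k_eff, N, K, n)
        records.append(EnrichmentRecord(term_id, term_name, namespace, k, K, n, N, p))
    if records:
        qvals = bh_adjust([r.p for r in records])
        records = [
            EnrichmentRecord(r.term_id, r.term_name, r.namespace, r.k, r.K, r.n, r.N, r.p, float(q))
            for r, q in zip(records, qvals)
        ]
    records.sort(key=lambda r: (r.p, r.term_id))
    return records


def namespace_summary(
    records: list[EnrichmentRecord],
    significant_only: bool = True,
    p_max: float = 0.05,
) -> tuple[dict[str, tuple[int, float]], int]:
    """Per-namespace (count, percentage) over the reported terms, plus the total.

    Percentages are 100*count/total rounded to 2 decimals; an empty record
    set yields an empty summary with total 0.
    """
    kept = [r for r in records if not significant_only or r.p <= p_max]
    total = len(kept)
    out: dict[str, tuple[int, float]] = {}
    if total == 0:
        return out, 0
    counts: dict[str, int] = {}
    for r in kept:
        counts[r.namespace] = counts.get(r.namespace, 0) + 1
    for ns in sorted(counts):
        out[ns] = (counts[ns], round(100.0 * counts[ns] / total, 2))
    return out, total


def namespace_percentages(counts: dict[str, int]) -> tuple[dict[str, float], int]:
    """Percentage per namespace from plain counts (worked-example arithmetic)."""
    total = sum(counts.values())
    if total == 0:
        return {}, 0
    return {ns: round(100.0 * c / total, 2) for ns, c in counts.items()}, total


def records_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term_id, r.term_name, r.namespace, r.k, r.K, r.n, r.N, r.p, r.q)
            for r in records
        ],
        columns=["term_id", "term_name", "namespace", "k", "K", "n", "N", "p", "q"],
    )
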