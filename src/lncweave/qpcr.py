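"""qPCR relative quantification (2^-ddCt) with dual reference genes, plus one-way ANOVA.

Each sample's reference Ct is the arithmetic mean over reference genes of
replicate-mean Cts (equivalent to the geometric mean of reference
expression levels); dCt = mean target Ct - reference Ct.  The calibrator
is aggregated on the linear scale: ddCt = dCt + log2(mean over calibrator
samples of 2^-dCt), so the calibrator group's arithmetic-mean relative
expression is exactly 1.  With a single calibrator sample (or identical
calibrator replicates) this coincides with the textbook
ddCt = dCt - mean dCt(calibrator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def read_ct_table(path) -> pd.DataFrame:
    """Ct TSV with columns sample, group, gene, role (target|reference), ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "gene", "role", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    if not set(df["role"]) <= {"target", "reference"}:
        raise ValueError("role must be target or reference")
    return df


@dataclass
class RelativeExpression:
    sample: str
    group: str
    gene: str
    dct: float
    ddct: float
    fold_change: float


def ddct(
    ct: pd.DataFrame, calibrator: str, target: str | None = None
) -> list[RelativeExpression]:
    """Per-sample relative expression 2^-ddCt against a calibrator group.

    Samples missing reference measurements are skipped with a warning.  With
    multiple target genes, each is quantified independently (pass `target`
    to restrict).
    """
    groups = set(ct["group"])
    if calibrator not in groups:
        raise ValueError(f"calibrator group {calibrator!r} not present")
    targets = sorted(set(ct.loc[ct["role"] == "target", "gene"]))
    if target is not None:
        targets = [t for t in targets if t == target]
    ref_ct: dict[str, float] = {}
    for sample, sub in ct[ct["role"] == "reference"].groupby("sample"):
        ref_ct[sample] = float(sub.groupby("gene")["ct"].mean().mean())
    out: list[RelativeExpression] = []
    for gene in targets:
        tsub = ct[(ct["role"] == "target") & (ct["gene"] == gene)]
        dcts: dict[str, tuple[str, float]] = {}
        for sample, ssub in tsub.groupby("sample"):
            if sample not in ref_ct:
                logger.warning("ddct: sample %s lacks reference Cts; skipped", sample)
                continue
            group = ssub["group"].iloc[0]
            dcts[sample] = (group, float(ssub["ct"].mean()) - ref_ct[sample])
        cal = [d for g, d in dcts.values() if g == calibrator]
        if not cal:
            raise ValueError(f"{gene}: no calibrator samples with complete data")
        # linear-scale calibrator aggregate: calibrator mean expression == 1
        cal_log2 = float(np.log2(np.mean([2.0**-d for d in cal])))
        for sample, (group, d) in sorted(dcts.items()):
            dd = d + cal_log2
            out.append(RelativeExpression(sample, group, gene, d, dd, float(2.0**-dd)))
    return out


def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across >= 2 groups.

    Degenerate inputs: all values identical -> (0, 1); zero within-group
    variance with differing means -> (inf, 0) with a log note.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if not any(a.size >= 2 for a in arrays):
        raise ValueError("need >= 2 values in some group")
    allv = np.concatenate(arrays)
    if np.allclose(allv, allv[0]):
        return 0.0, 1.0
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = allv.size - len(arrays)
    if ss_within == 0:
        logger.info("anova_oneway: zero within-group variance; p -> 0 limit")
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def expression_table(results: list[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample, r.group, r.gene, r.dct, r.ddct, r.fold_change) for r in results],
        columns=["sample", "group", "gene", "dCt", "ddCt", "fold_change"],
    )
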