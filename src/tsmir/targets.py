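"""Consensus miRNA-target selection and tumor-upregulation intersection.

Target-prediction algorithms disagree widely, so a gene is accepted as
a target of a miRNA only when at least half (configurable fraction) of
the algorithms *available for that miRNA* call it. Availability is a
mask, not a negative call: aggregation databases expose different
algorithm panels per miRNA, and an algorithm that does not cover a
miRNA contributes to neither numerator nor denominator. The threshold
is the exact rational ``rule_fraction * n_available`` compared with
``>=`` (4 of 7 passes at one half; 3 of 7 does not).

The pooled target union is then intersected with genes upregulated in
tumor versus normal expression (linear fold change of group means plus
a two-sample t-test on log2 values with Benjamini-Hochberg adjustment).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DEResult, ExprMatrix, PredictionTensor, TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "consensus_targets",
    "union_target_genes",
    "differential_upregulation",
    "intersect_targets_with_upregulated",
]


def consensus_targets(
    tensor: PredictionTensor,
    rule_fraction: float = 0.5,
    global_denominator: bool = False,
) -> TargetSet:
    """Majority-style voting over prediction algorithms.

    Gene g is a consensus target of miRNA m iff the number of available
    algorithms calling (m, g) is >= ``rule_fraction`` times the number
    of algorithms available for m (or times the global algorithm count
    when ``global_denominator``). miRNAs with zero available algorithms
    are excluded with a warning.
    """
    if not (0 < rule_fraction <= 1):
        raise ValueError("rule_fraction must be in (0, 1]")
    votes = tensor.calls.sum(axis=0)  # (miRNA, gene)
    n_avail = tensor.available.sum(axis=0)  # (miRNA,)
    per_mirna: dict[str, set[str]] = {}
    genes = np.asarray(tensor.genes, dtype=object)
    for i, mirna in enumerate(tensor.mirnas):
        denom = len(tensor.algorithms) if global_denominator else int(n_avail[i])
        if denom == 0 or n_avail[i] == 0:
            logger.warning("miRNA %s has no available algorithms; excluded", mirna)
            continue
        hits = votes[i] >= rule_fraction * denom
        per_mirna[mirna] = set(genes[hits])
    return TargetSet(per_mirna)


def union_target_genes(targets: TargetSet) -> list[str]:
    """Sorted deduplicated union of per-miRNA target sets."""
    return targets.union


def differential_upregulation(
    expr: ExprMatrix,
    fold_cutoff: float = 1.5,
    adj_p_cutoff: float = 0.005,
    adjust_method: str = "fdr_bh",
) -> DEResult:
    """Per-gene tumor-vs-normal upregulation at joint fold and
    adjusted-p cutoffs.

    Fold change is the linear ratio of group means; the test is a
    pooled-variance two-sample t on log2 values, adjusted across genes
    (Benjamini-Hochberg by default). A gene is flagged upregulated iff
    fold >= ``fold_cutoff`` (inclusive) and adjusted p < ``adj_p_cutoff``
    (strict). Zero-variance genes get p = 1 when group means agree and
    p = 0 otherwise.
    """
    meta = expr.sample_meta.loc[expr.sample_ids]
    tumor = meta.index[meta["group"] == "tumor"]
    normal = meta.index[meta["group"] == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need >= 2 samples per group")
    lin = expr.to_linear()
    lt = np.log2(lin.values[tumor].to_numpy(dtype=float) + 1e-12)
    ln = np.log2(lin.values[normal].to_numpy(dtype=float) + 1e-12)

    mt = lin.values[tumor].mean(axis=1).to_numpy()
    mn = lin.values[normal].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mt / mn

    stat, p = stats.ttest_ind(lt, ln, axis=1, equal_var=True)
    degenerate = (lt.var(axis=1) == 0.0) & (ln.var(axis=1) == 0.0)
    p = np.where(
        degenerate, np.where(np.isclose(lt.mean(1), ln.mean(1)), 1.0, 0.0), p
    )
    p = np.nan_to_num(p, nan=1.0)
    p_adj = multipletests(p, method=adjust_method)[1]
    up = (fold >= fold_cutoff) & (p_adj < adj_p_cutoff)
    table = pd.DataFrame(
        {
            "gene": lin.feature_ids,
            "fold_change": fold,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(fold >= 1.0, "up", "down"),
            "upregulated": up,
        }
    )
    logger.info(
        "differential upregulation: %d of %d genes pass (fold >= %g, adj p < %g)",
        int(up.sum()), len(table), fold_cutoff, adj_p_cutoff,
    )
    return DEResult(table, fold_cutoff, adj_p_cutoff)


def intersect_targets_with_upregulated(
    targets: list[str], de: DEResult
) -> list[str]:
    """Sorted intersection of the consensus target union with genes
    flagged upregulated. Duplicate identifiers in ``targets`` are a
    hard error (they would silently double-count downstream)."""
    tser = pd.Series(targets)
    if tser.duplicated().any():
        raise ValueError(
            f"duplicate gene identifiers: {sorted(tser[tser.duplicated()])[:5]}"
        )
    return sorted(set(targets) & set(de.upregulated_genes))
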