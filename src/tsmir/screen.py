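"""Pharmacologic-unmasking screen.

Myeloma cell lines treated with the DNA-methyltransferase inhibitor
5'azacytidine re-express miRNAs whose promoters were silenced by
hypermethylation. The screen computes a per-(miRNA, cell line) linear
fold change of treated over control intensity, then selects miRNAs
upregulated at least ``fold_threshold``-fold in at least ``min_lines``
cell lines. A feature whose intensity falls below the detection floor
on either arm is "n.d." (not detected) for that cell line; n.d. entries
are neutral — they neither qualify nor disqualify a miRNA.

Also provides the comparative-Ct (2^-ddCt) helper used for qPCR
validation data, and a loader for the bundled published fold-change
table of the nine leading candidates across four myeloma lines.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .containers import (
    REGULATION_DOWN,
    REGULATION_ND,
    REGULATION_UP,
    CandidateSet,
    ExprMatrix,
    FoldChangeTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "compute_fold_changes",
    "select_unmasked",
    "ddct_relative_quantity",
    "load_candidate_fold_changes",
    "quantile_normalize_samples",
]


def quantile_normalize_samples(expr: ExprMatrix, q: float = 0.75) -> ExprMatrix:
    """Scale each sample so its ``q``-th intensity quantile is equal
    across samples (single-channel array convention; default upper
    quartile). Only ratios matter downstream, so this is optional."""
    if expr.log2:
        raise ValueError("quantile scaling expects linear intensities")
    quantiles = expr.values.quantile(q, axis=0)
    target = float(np.median(quantiles))
    scaled = expr.values.div(quantiles, axis=1) * target
    return ExprMatrix(scaled, expr.sample_meta, log2=False)


def _arm_by_line(expr: ExprMatrix, condition: str) -> pd.DataFrame:
    """Collapse samples of one condition to one column per cell line
    (mean over replicates)."""
    meta = expr.sample_meta.loc[expr.sample_ids]
    mask = meta["condition"] == condition
    if not mask.any():
        raise ValueError(f"no samples with condition '{condition}'")
    cols = meta.index[mask]
    sub = expr.values[cols]
    lines = meta.loc[cols, "cell_line"]
    return sub.T.groupby(lines.values).mean().T


def compute_fold_changes(
    treated: ExprMatrix,
    control: ExprMatrix,
    detection_floor: float = 0.0,
) -> FoldChangeTable:
    """Linear fold change treated/control per (miRNA, cell line).

    Both matrices must cover the same features and the same cell lines
    (replicates within an arm are averaged). An intensity below
    ``detection_floor`` makes that arm "not detected"; when either arm
    is undetected the row is n.d. and carries no numeric fold change.
    A detected control intensity of exactly zero cannot form a ratio
    and is demoted to n.d. with a warning.
    """
    if list(treated.feature_ids) != list(control.feature_ids):
        if set(treated.feature_ids) != set(control.feature_ids):
            raise ValueError("treated and control feature sets differ")
    t_lin, c_lin = treated.to_linear(), control.to_linear()
    t = _arm_by_line(t_lin, "treated")
    c = _arm_by_line(c_lin, "control").loc[t_lin.feature_ids]
    t = t.loc[t_lin.feature_ids]
    if set(t.columns) != set(c.columns):
        raise ValueError(
            f"cell lines differ between arms: {sorted(set(t.columns) ^ set(c.columns))}"
        )
    c = c[t.columns]

    rows = []
    for line in t.columns:
        tv = t[line].to_numpy(dtype=float)
        cv = c[line].to_numpy(dtype=float)
        det_t = tv >= detection_floor
        det_c = cv >= detection_floor
        for i, mirna in enumerate(t.index):
            detected = det_t[i] and det_c[i]
            if detected and cv[i] == 0.0:
                warnings.warn(
                    f"control intensity 0 for {mirna}/{line}; reported as n.d.",
                    RuntimeWarning,
                    stacklevel=2,
                )
                detected = False
            if not detected:
                rows.append((mirna, line, np.nan, REGULATION_ND, det_t[i], det_c[i]))
                continue
            fc = tv[i] / cv[i]
            reg = REGULATION_UP if fc > 1 else REGULATION_DOWN
            rows.append((mirna, line, fc, reg, True, True))
    table = pd.DataFrame(
        rows, columns=list(FoldChangeTable.REQUIRED)
    ).sort_values(["mirna", "cell_line"], kind="mergesort", ignore_index=True)
    return FoldChangeTable(table)


def select_unmasked(
    fc: FoldChangeTable,
    fold_threshold: float = 1.5,
    min_lines: int = 2,
) -> CandidateSet:
    """Select miRNAs upregulated >= ``fold_threshold``-fold (inclusive)
    in at least ``min_lines`` cell lines.

    Only rows with regulation "up" can qualify; n.d. rows never count
    toward or against selection. An empty table yields an empty set.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if min_lines < 1:
        raise ValueError("min_lines must be at least 1")
    tab = fc.table
    ok = (tab["regulation"] == REGULATION_UP) & (tab["fold_change"] >= fold_threshold)
    evidence: dict[str, list[tuple[str, float]]] = {}
    for _, row in tab.loc[ok].iterrows():
        evidence.setdefault(row["mirna"], []).append(
            (row["cell_line"], float(row["fold_change"]))
        )
    selected = sorted(m for m, ev in evidence.items() if len(ev) >= min_lines)
    evidence = {m: evidence[m] for m in selected}
    logger.info(
        "unmasking selection: %d of %d miRNAs pass (fold >= %g in >= %d lines)",
        len(selected), tab["mirna"].nunique(), fold_threshold, min_lines,
    )
    return CandidateSet(selected, evidence, fold_threshold, min_lines)


def ddct_relative_quantity(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Comparative-Ct relative quantification.

    Returns 2^-ddCt where ddCt = (Ct_target - Ct_ref) in the sample
    minus the same difference in the calibrator. One PCR cycle is one
    doubling, so a sample dCt one cycle below the calibrator's means a
    two-fold relative quantity.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(cts)):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))


def load_candidate_fold_changes() -> FoldChangeTable:
    """Published fold changes of the nine leading candidate miRNAs in
    four myeloma cell lines after 5'azacytidine treatment (bundled)."""
    with resources.files("tsmir.data").joinpath(
        "aza_candidate_foldchanges.tsv"
    ).open() as fh:
        tab = pd.read_csv(fh, sep="\t")
    tab["fold_change"] = pd.to_numeric(tab["fold_change"], errors="coerce")
    nd = tab["regulation"] == REGULATION_ND
    tab["detected_treated"] = ~nd
    tab["detected_control"] = ~nd
    return FoldChangeTable(tab)
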