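"""Tumor-vs-normal CpG methylation comparison.

CpG probes are linked to miRNA / host-gene transcription start sites
within a configurable window (hypermethylation near a TSS — in the
island, its shores, or intragenic sites — is associated with
transcriptional silencing). Beta values (fraction methylated, 0..1)
are then compared between tumor and normal groups per probe, or per
feature after averaging a feature's linked probes within each sample.

The two-group tests offered are the classic pooled-variance Student's
t-test (Welch optional) and the two-sided Mann-Whitney U rank-sum
test. Degenerate inputs follow an explicit rule: zero variance in both
groups gives p = 1 when the means agree and p = 0 when they differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "annotate_probes_to_features",
    "group_test",
    "compare_methylation",
    "summarize_beta_distribution",
    "GroupTestRow",
]


@dataclass
class GroupTestRow:
    """One two-group comparison: group means, difference, test."""

    mean_a: float
    mean_b: float
    delta: float  # mean_a - mean_b
    statistic: float
    p_value: float
    test_name: str
    degenerate: bool = False


def annotate_probes_to_features(
    probes: pd.DataFrame,
    features: pd.DataFrame,
    window: int = 2000,
) -> ProbeAnnotation:
    """Link CpG probes to features whose TSS lies within ``window`` bp.

    ``probes``: columns probe_id, chrom, pos (1-based); optional
    region_class. ``features``: columns feature_id, chrom, tss
    (1-based), strand ('+'/'-'). A probe links to every feature with
    |pos - tss| <= window on the same chromosome; the reported distance
    is signed relative to the feature strand, negative upstream of the
    TSS. Probes on chromosomes absent from the feature table are
    skipped with a warning; probes linking to no feature are kept with
    a null feature so downstream stages can report coverage.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    known = set(features["chrom"])
    rows = []
    n_skipped = 0
    for probe in probes.itertuples(index=False):
        region = getattr(probe, "region_class", "intergenic")
        if probe.chrom not in known:
            n_skipped += 1
            continue
        feats = features.loc[features["chrom"] == probe.chrom]
        hit = False
        for f in feats.itertuples(index=False):
            d = probe.pos - f.tss
            if abs(d) <= window:
                signed = d if f.strand == "+" else -d
                rows.append(
                    (probe.probe_id, probe.chrom, probe.pos, f.feature_id,
                     signed, region)
                )
                hit = True
        if not hit:
            rows.append((probe.probe_id, probe.chrom, probe.pos, None, np.nan, region))
    if n_skipped:
        logger.warning("skipped %d probes on unknown chromosomes", n_skipped)
    table = pd.DataFrame(rows, columns=list(ProbeAnnotation.REQUIRED))
    return ProbeAnnotation(table)


def _degenerate_p(mean_a: float, mean_b: float) -> tuple[float, bool]:
    return (1.0, True) if np.isclose(mean_a, mean_b) else (0.0, True)


def group_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    method: str = "student_t",
) -> GroupTestRow:
    """Two-sided two-group test of location.

    ``student_t`` is the pooled-variance two-sample t-test ("Student's"
    proper); ``welch_t`` drops the equal-variance assumption;
    ``mann_whitney_u`` is the exact / normal-approximate rank-sum test.
    ``delta`` is mean(a) - mean(b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method in ("student_t", "welch_t") and (len(a) < 2 or len(b) < 2):
        raise ValueError("t-test needs at least 2 values per group")
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least 1 value")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    delta = mean_a - mean_b

    if method in ("student_t", "welch_t"):
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            p, degen = _degenerate_p(mean_a, mean_b)
            return GroupTestRow(mean_a, mean_b, delta, np.nan, p, method, degen)
        stat, p = stats.ttest_ind(a, b, equal_var=(method == "student_t"))
        return GroupTestRow(mean_a, mean_b, delta, float(stat), float(p), method)
    if method == "mann_whitney_u":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("rank-sum test needs at least 1 value per group")
        if np.ptp(np.concatenate([a, b])) == 0.0:
            return GroupTestRow(mean_a, mean_b, delta, np.nan, 1.0, method, True)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupTestRow(mean_a, mean_b, delta, float(stat), float(p), method)
    raise ValueError(f"unknown test method '{method}'")


def compare_methylation(
    betas: BetaMatrix,
    annotation: ProbeAnnotation,
    level: str = "probe",
    method: str = "student_t",
    adjust: bool = False,
) -> pd.DataFrame:
    """Tumor-vs-normal beta comparison per linked probe or per feature.

    ``level='probe'`` tests each (probe, feature) link separately;
    ``level='region'`` first averages a feature's linked probes within
    each sample, then tests one row per feature. Output is sorted by
    feature then position and reports mean_beta_tumor, mean_beta_normal,
    delta (tumor - normal), statistic, p_value and test_name. Raw
    p-values are reported by default; ``adjust=True`` adds a
    Benjamini-Hochberg ``p_adj`` column.
    """
    if level not in ("probe", "region"):
        raise ValueError("level must be 'probe' or 'region'")
    tumor = betas.group_samples("tumor")
    normal = betas.group_samples("normal")
    if method.endswith("_t") and (len(tumor) < 2 or len(normal) < 2):
        raise ValueError("need >= 2 samples per group for t-testing")

    links = annotation.table.dropna(subset=["feature"])
    rows = []
    if level == "probe":
        for link in links.itertuples(index=False):
            if link.probe_id not in betas.betas.index:
                continue
            vals = betas.betas.loc[link.probe_id]
            r = group_test(vals[tumor].to_numpy(), vals[normal].to_numpy(), method)
            rows.append((link.feature, link.probe_id, link.pos, r))
    else:
        for feature, sub in links.groupby("feature", sort=True):
            probe_ids = [p for p in sub["probe_id"] if p in betas.betas.index]
            if not probe_ids:
                logger.warning("feature %s has no linked probes with data", feature)
                continue
            region = betas.betas.loc[probe_ids].mean(axis=0)
            r = group_test(
                region[tumor].to_numpy(), region[normal].to_numpy(), method
            )
            rows.append((feature, None, int(sub["pos"].min()), r))
    if not rows:
        logger.warning("no testable probe-feature links")
    out = pd.DataFrame(
        [
            {
                "feature": feat,
                "probe_id": pid,
                "pos": pos,
                "mean_beta_tumor": r.mean_a,
                "mean_beta_normal": r.mean_b,
                "delta": r.delta,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "test_name": r.test_name,
            }
            for feat, pid, pos, r in rows
        ]
    )
    if len(out):
        out = out.sort_values(["feature", "pos"], kind="mergesort", ignore_index=True)
        if adjust:
            out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def summarize_beta_distribution(values: np.ndarray) -> tuple[float, ...]:
    """Five-number summary (min, Q1, median, Q3, max) with whiskers at
    the extremes (not 1.5 IQR). Quartiles use linear interpolation
    between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty vector")
    q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return tuple(float(x) for x in q)
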