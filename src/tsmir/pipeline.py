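"""End-to-end pipeline orchestration with a declarative config.

The four analysis stages (unmasking screen, methylation comparison,
target consensus, survival signature) run in order from TSV inputs,
each writing its outputs and contributing counts to a machine-readable
JSON summary, so filter-by-filter numbers can be read off one file.
Every stage is equally runnable standalone from its own inputs; the
orchestrated run is just the concatenation on intermediate files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .methylation import annotate_probes_to_features, compare_methylation
from .screen import compute_fold_changes, select_unmasked
from .survival import (
    bin_risk_levels,
    build_signature,
    compute_risk_scores,
    cox_screen,
    km_curves,
    survival_association,
)
from .targets import (
    consensus_targets,
    differential_upregulation,
    intersect_targets_with_upregulated,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "simulate_fixture"]

STAGES = ("screen", "methylation", "targets", "signature")


@dataclass
class PipelineConfig:
    """All stage toggles, thresholds and file paths of one run."""

    # stage toggles
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # unmasking screen
    fold_threshold: float = 1.5
    min_lines: int = 2
    detection_floor: float = 0.0
    # methylation comparison
    tss_window: int = 2000
    meth_level: str = "probe"
    meth_test: str = "student_t"
    # target consensus + differential upregulation
    rule_fraction: float = 0.5
    fold_cutoff: float = 1.5
    adj_p_cutoff: float = 0.005
    # survival signature
    alpha: float = 0.05
    n_levels: int = 4
    # misc
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)
    out_dir: str = "tsmir_run"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.fold_threshold <= 1 or self.fold_cutoff <= 1:
            raise ValueError("fold thresholds must exceed 1")
        if not (0 < self.rule_fraction <= 1):
            raise ValueError("rule_fraction must be in (0, 1]")
        if not (0 < self.alpha < 1) or not (0 < self.adj_p_cutoff < 1):
            raise ValueError("significance cutoffs must be in (0, 1)")
        if self.n_levels < 2 or self.min_lines < 1 or self.tss_window <= 0:
            raise ValueError("count parameters out of range")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _require(config: PipelineConfig, keys: list[str], stage: str) -> list[str]:
    paths = []
    for key in keys:
        if key not in config.inputs:
            raise ValueError(f"stage '{stage}' needs input '{key}'")
        path = config.inputs[key]
        if not Path(path).exists():
            raise FileNotFoundError(f"input '{key}' not found: {path}")
        paths.append(path)
    return paths


def _run_screen(config: PipelineConfig, out: Path, summary: dict) -> list[str]:
    expr_p, sheet_p = _require(config, ["screen_matrix", "screen_samples"], "screen")
    expr = tio.read_expr_matrix(expr_p, sheet_p)
    meta = expr.sample_meta
    treated_ids = meta.index[meta["condition"] == "treated"]
    control_ids = meta.index[meta["condition"] == "control"]
    from .containers import ExprMatrix

    treated = ExprMatrix(expr.values[treated_ids], meta.loc[treated_ids])
    control = ExprMatrix(expr.values[control_ids], meta.loc[control_ids])
    fc = compute_fold_changes(treated, control, config.detection_floor)
    candidates = select_unmasked(fc, config.fold_threshold, config.min_lines)
    tio.write_fold_changes(fc, out / "fold_changes.tsv")
    pd.DataFrame({"mirna": candidates.selected}).to_csv(
        out / "candidates.tsv", sep="\t", index=False
    )
    summary["screen"] = {
        "n_mirnas": int(fc.table["mirna"].nunique()),
        "n_candidates": len(candidates),
        "fold_threshold": config.fold_threshold,
        "min_lines": config.min_lines,
    }
    return candidates.selected


def _run_methylation(config: PipelineConfig, out: Path, summary: dict) -> None:
    betas_p, sheet_p, bed_p, tss_p = _require(
        config,
        ["meth_matrix", "meth_samples", "probe_bed", "feature_tss"],
        "methylation",
    )
    betas = tio.read_beta_matrix(betas_p, sheet_p)
    annotation = annotate_probes_to_features(
        tio.read_probe_bed(bed_p), tio.read_feature_tss(tss_p), config.tss_window
    )
    probe_res = compare_methylation(betas, annotation, "probe", config.meth_test)
    region_res = compare_methylation(betas, annotation, "region", config.meth_test)
    probe_res.to_csv(out / "methylation_probe.tsv", sep="\t", index=False)
    region_res.to_csv(out / "methylation_region.tsv", sep="\t", index=False)
    summary["methylation"] = {
        "n_linked_probes": int(len(probe_res)),
        "n_features": int(len(region_res)),
        "n_hyper_features_p05": int(
            ((region_res["delta"] > 0) & (region_res["p_value"] < 0.05)).sum()
        ),
        "tss_window": config.tss_window,
    }


def _run_targets(
    config: PipelineConfig, out: Path, summary: dict, candidates: list[str] | None
) -> list[str]:
    calls_p, avail_p, expr_p, sheet_p = _require(
        config,
        ["pred_calls", "pred_availability", "de_matrix", "de_samples"],
        "targets",
    )
    tensor = tio.read_prediction_tensor(calls_p, avail_p)
    targets = consensus_targets(tensor, config.rule_fraction)
    if candidates is not None:
        targets.per_mirna = {
            m: g for m, g in targets.per_mirna.items() if m in set(candidates)
        }
    union = targets.union
    de = differential_upregulation(
        tio.read_expr_matrix(expr_p, sheet_p),
        config.fold_cutoff,
        config.adj_p_cutoff,
    )
    intersected = intersect_targets_with_upregulated(union, de)
    rows = [(m, g) for m, genes in sorted(targets.per_mirna.items())
            for g in sorted(genes)]
    pd.DataFrame(rows, columns=["mirna", "gene"]).to_csv(
        out / "targets_per_mirna.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene": union}).to_csv(out / "targets_union.tsv", sep="\t",
                                         index=False)
    de.table.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": intersected}).to_csv(
        out / "targets_upregulated.tsv", sep="\t", index=False
    )
    summary["targets"] = {
        "n_mirnas_scored": len(targets.per_mirna),
        "n_union_targets": len(union),
        "n_upregulated": len(de.upregulated_genes),
        "n_intersection": len(intersected),
        "rule_fraction": config.rule_fraction,
        "fold_cutoff": config.fold_cutoff,
        "adj_p_cutoff": config.adj_p_cutoff,
    }
    return intersected


def _run_signature(
    config: PipelineConfig, out: Path, summary: dict, gene_list: list[str] | None
) -> None:
    expr_p, sheet_p, surv_p = _require(
        config, ["surv_matrix", "surv_samples", "survival"], "signature"
    )
    expr = tio.read_expr_matrix(expr_p, sheet_p, log2=True)
    surv = tio.read_survival_table(surv_p)
    if gene_list is not None:
        keep = [g for g in expr.feature_ids if g in set(gene_list)]
        from .containers import ExprMatrix

        expr = ExprMatrix(expr.values.loc[keep], expr.sample_meta, log2=True)
    fits = cox_screen(expr, surv)
    sig = build_signature(fits, config.alpha)
    fit_rows = [
        {
            "gene": g,
            "coef": f.coef,
            "se": f.se,
            "hazard_ratio": f.hazard_ratio,
            "ci_low": f.ci_low,
            "ci_high": f.ci_high,
            "p": f.p,
            "n_events": f.n_events,
        }
        for g, f in sorted(fits.items())
    ]
    pd.DataFrame(fit_rows).to_csv(out / "cox_per_gene.tsv", sep="\t", index=False)
    tio.write_signature(sig, out / "signature.tsv")
    summary["signature"] = {
        "n_genes_tested": len(fits),
        "n_c_plus": len(sig.c_plus),
        "n_c_minus": len(sig.c_minus),
        "alpha": config.alpha,
    }
    if len(sig) == 0:
        logger.warning("empty signature; skipping risk scoring")
        return
    scores = bin_risk_levels(compute_risk_scores(expr, sig), config.n_levels)
    tio.write_risk_scores(scores, out / "risk_scores.tsv")
    assoc = survival_association(scores.levels, surv)
    pd.DataFrame(
        [
            {
                "coef": assoc.coef,
                "hazard_ratio": assoc.hazard_ratio,
                "ci_low": assoc.ci_low,
                "ci_high": assoc.ci_high,
                "p": assoc.p,
                "n": assoc.n,
                "n_events": assoc.n_events,
            }
        ]
    ).to_csv(out / "association.tsv", sep="\t", index=False)
    km = km_curves(scores.levels, surv)
    pd.concat(
        [curve.assign(level=lev) for lev, curve in km.items()], ignore_index=True
    ).to_csv(out / "km_coordinates.tsv", sep="\t", index=False)
    summary["signature"].update(
        {
            "n_levels": config.n_levels,
            "hazard_ratio_per_level": round(assoc.hazard_ratio, 6),
            "log_hr_per_level": round(assoc.coef, 6),
            "p_value": float(f"{assoc.p:.6g}"),
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the summary dict
    (also written to ``<out_dir>/summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    candidates = None
    intersected = None
    if "screen" in config.stages:
        candidates = _run_screen(config, out, summary)
    if "methylation" in config.stages:
        _run_methylation(config, out, summary)
    if "targets" in config.stages:
        intersected = _run_targets(config, out, summary, candidates)
    if "signature" in config.stages:
        _run_signature(config, out, summary, intersected)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema conformance report (list of human-readable violations);
    never mutates inputs. Checks headers, identifier uniqueness, beta
    range and survival positivity for whichever roles are provided."""
    report: list[str] = []

    def _check_matrix(path: str, role: str, lo=None, hi=None):
        try:
            mat = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            report.append(f"{role}: unreadable ({exc})")
            return
        if mat.index.has_duplicates:
            dupes = mat.index[mat.index.duplicated()].unique()
            report.append(f"{role}: duplicate row ids {list(dupes)[:3]}")
        if mat.columns.has_duplicates:
            report.append(f"{role}: duplicate sample ids")
        vals = mat.apply(pd.to_numeric, errors="coerce")
        if lo is not None:
            bad = vals.lt(lo) | vals.gt(hi)
            if bad.any().any():
                for probe in mat.index[bad.any(axis=1)][:5]:
                    report.append(
                        f"{role}: value outside [{lo}, {hi}] at row '{probe}'"
                    )

    for role, path in paths.items():
        if not Path(path).exists():
            report.append(f"{role}: file not found ({path})")
            continue
        if role in ("screen_matrix", "de_matrix", "surv_matrix"):
            _check_matrix(path, role)
        elif role == "meth_matrix":
            _check_matrix(path, role, lo=0.0, hi=1.0)
        elif role == "survival":
            tab = pd.read_csv(path, sep="\t")
            if "sample_id" not in tab.columns or "time" not in tab.columns:
                report.append(f"{role}: missing required header columns")
                continue
            if tab["sample_id"].duplicated().any():
                report.append(f"{role}: duplicate sample ids")
            bad = tab.loc[pd.to_numeric(tab["time"], errors="coerce").le(0).fillna(True)]
            for sid in bad["sample_id"][:5]:
                report.append(f"{role}: non-positive time for sample '{sid}'")
            if "event" in tab.columns and not tab["event"].isin((0, 1)).all():
                report.append(f"{role}: event indicator not in {{0,1}}")
        elif role.endswith("_samples"):
            tab = pd.read_csv(path, sep="\t")
            if "sample_id" not in tab.columns:
                report.append(f"{role}: missing 'sample_id' column")
            elif tab["sample_id"].duplicated().any():
                report.append(f"{role}: duplicate sample ids")
    return report


def simulate_fixture(out_dir: str | Path, seed: int = 0, **kw) -> dict[str, str]:
    """Emit a complete synthetic fixture directory (all pipeline inputs)
    plus a ground-truth manifest; returns the input-path mapping ready
    to drop into :class:`PipelineConfig`."""
    from . import simulate as sim
    from .io import write_beta_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_mirna = kw.get("n_mirna", 150)
    n_silenced = kw.get("n_silenced", 9)
    treated, control, truth = sim.gen_unmasking_experiment(
        n_mirna=n_mirna,
        n_silenced=n_silenced,
        noise_sd=kw.get("noise_sd", 0.15),
        seed=int(rng.integers(2**31)),
    )
    combined = pd.concat([treated.values, control.values], axis=1)
    meta = pd.concat([treated.sample_meta, control.sample_meta])
    tio.write_expr_matrix(
        type(treated)(combined, meta),
        out / "screen_matrix.tsv",
        out / "screen_samples.tsv",
    )

    betas, annotation, candidate_probes = sim.gen_methylation_cohort(
        seed=int(rng.integers(2**31))
    )
    write_beta_matrix(betas, out / "meth_matrix.tsv", out / "meth_samples.tsv")
    ann = annotation.table
    pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "start": ann["pos"] - 1,
            "end": ann["pos"],
            "probe_id": ann["probe_id"],
            "region_class": ann["region_class"],
        }
    ).to_csv(out / "probe_bed.tsv", sep="\t", index=False)
    tss = (
        ann.groupby("feature")
        .apply(lambda g: int((g["pos"] - g["distance"]).iloc[0]),
               include_groups=False)
        .reset_index(name="tss")
    )
    tss["chrom"] = "chrSim"
    tss["strand"] = "+"
    tss.rename(columns={"feature": "feature_id"}).to_csv(
        out / "feature_tss.tsv", sep="\t", index=False
    )

    silenced = sorted(truth.silenced_mirnas)
    genes = [f"GENE{i:04d}" for i in range(kw.get("n_genes", 120))]
    true_targets = {
        m: set(rng.choice(genes, size=8, replace=False)) for m in silenced
    }
    tensor, _ = sim.gen_prediction_tensor(
        silenced, genes, true_targets, seed=int(rng.integers(2**31))
    )
    tio.write_prediction_tensor(
        tensor, out / "pred_calls.tsv", out / "pred_availability.tsv"
    )

    # plant the survival signature inside the target union so the
    # orchestrated run (targets -> signature) has signal to find
    union_pool = sorted(set().union(*true_targets.values()))
    struth = sim.SurvivalCohortTruth(
        planted_cpos=union_pool[:8], planted_cneg=union_pool[8:14]
    )
    expr, surv, struth = sim.gen_survival_cohort(
        n_samples=kw.get("n_samples", 400),
        n_genes=len(genes),
        truth=struth,
        seed=int(rng.integers(2**31)),
    )
    tio.write_expr_matrix(expr, out / "surv_matrix.tsv", out / "surv_samples.tsv")
    tio.write_survival_table(surv, out / "survival.tsv")
    # tumor-vs-normal DE cohort for the intersection step: upregulate the
    # planted targets' union in tumor samples
    union = sorted(set().union(*true_targets.values()))
    n_t, n_n = kw.get("de_tumor", 30), kw.get("de_normal", 30)
    rng2 = np.random.default_rng(int(rng.integers(2**31)))
    log2e = rng2.normal(6.0, 0.4, size=(len(genes), n_t + n_n))
    up_idx = [genes.index(g) for g in union]
    log2e[up_idx, :n_t] += 1.0  # 2-fold planted upregulation
    de_samples = [f"T{i:02d}" for i in range(n_t)] + [f"N{i:02d}" for i in range(n_n)]
    de_meta = pd.DataFrame(
        {"group": ["tumor"] * n_t + ["normal"] * n_n},
        index=pd.Index(de_samples, name="sample_id"),
    )
    de_expr = type(expr)(
        pd.DataFrame(np.exp2(log2e), index=genes, columns=de_samples), de_meta
    )
    tio.write_expr_matrix(de_expr, out / "de_matrix.tsv", out / "de_samples.tsv")

    tio.write_truth_manifest(
        {
            "screen.silenced": truth.silenced_mirnas,
            "screen.n_silenced": len(truth.silenced_mirnas),
            "methylation.candidate_probes": candidate_probes,
            "targets.union_size": len(union),
            "targets.union": union,
            "survival.c_plus": struth.planted_cpos,
            "survival.c_minus": struth.planted_cneg,
            "survival.beta_rs": struth.beta_rs,
            "seed": seed,
        },
        out / "truth_manifest.txt",
    )
    return {
        "screen_matrix": str(out / "screen_matrix.tsv"),
        "screen_samples": str(out / "screen_samples.tsv"),
        "meth_matrix": str(out / "meth_matrix.tsv"),
        "meth_samples": str(out / "meth_samples.tsv"),
        "probe_bed": str(out / "probe_bed.tsv"),
        "feature_tss": str(out / "feature_tss.tsv"),
        "pred_calls": str(out / "pred_calls.tsv"),
        "pred_availability": str(out / "pred_availability.tsv"),
        "de_matrix": str(out / "de_matrix.tsv"),
        "de_samples": str(out / "de_samples.tsv"),
        "surv_matrix": str(out / "surv_matrix.tsv"),
        "surv_samples": str(out / "surv_samples.tsv"),
        "survival": str(out / "survival.tsv"),
    }
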