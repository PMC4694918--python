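"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so each stage (and the
end-to-end run) is testable without any external download:

* a demethylation screen — log-normal miRNA intensities for
  treated/control pairs across cell lines with a planted subset of
  silenced miRNAs whose treated intensity is multiplied by a per-line
  fold effect in a random subset of at least two lines;
* a methylation cohort — beta values near a low baseline in normal
  plasma cells, with a planted additive hypermethylation shift on
  candidate probes in tumor samples (clipped to [0, 1]);
* a target-prediction tensor — Bernoulli calls per algorithm with a
  per-(algorithm, miRNA) availability mask;
* a survival cohort — standard-normal gene expression, a true
  median-difference risk score from planted C+/C- gene sets, and
  exponential event times with hazard proportional to exp(beta_rs * RS)
  under independent uniform censoring.

All generators are deterministic given a seed. Defaults mirror the
study design the pipeline was built for: four treated cell lines,
17 tumor vs 5 normal methylation samples, twelve prediction
algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import (
    BetaMatrix,
    ExprMatrix,
    PredictionTensor,
    ProbeAnnotation,
    SurvivalTable,
)
from .survival import compute_risk_scores
from .containers import Signature

__all__ = [
    "UnmaskingTruth",
    "SurvivalCohortTruth",
    "gen_unmasking_experiment",
    "gen_methylation_cohort",
    "gen_prediction_tensor",
    "gen_survival_cohort",
    "default_survival_truth",
    "DEFAULT_CELL_LINES",
]

DEFAULT_CELL_LINES = ("H929", "MM1S", "OPM2", "8226")


@dataclass
class UnmaskingTruth:
    """Ground truth of a simulated demethylation screen."""

    silenced_mirnas: set[str]
    per_line_effect: dict[tuple[str, str], float]
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be non-negative")
        for m in self.silenced_mirnas:
            effects = [v for (mm, _), v in self.per_line_effect.items() if mm == m]
            if not effects or max(effects) <= 1:
                raise ValueError(f"silenced miRNA {m} has no effect > 1 in any line")

    def affected_lines(self, mirna: str) -> list[str]:
        return sorted(
            line for (m, line), eff in self.per_line_effect.items()
            if m == mirna and eff > 1
        )


@dataclass
class SurvivalCohortTruth:
    """Planted survival-signature structure of a simulated cohort."""

    planted_cpos: list[str]
    planted_cneg: list[str]
    beta_rs: float = 0.7
    censor_rate: float = 0.3

    def __post_init__(self) -> None:
        if set(self.planted_cpos) & set(self.planted_cneg):
            raise ValueError("planted C+ and C- gene sets overlap")
        if not np.isfinite(self.beta_rs):
            raise ValueError("beta_rs must be finite")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must lie in [0, 1]")


def gen_unmasking_experiment(
    n_mirna: int = 1205,
    n_silenced: int = 74,
    n_lines: int = 4,
    effect_range: tuple[float, float] = (2.0, 8.0),
    noise_sd: float = 0.25,
    seed: int = 0,
    baseline_log2_mean: float = 7.0,
    baseline_log2_sd: float = 1.5,
    detection_floor: float = 0.0,
    min_affected_lines: int = 2,
) -> tuple[ExprMatrix, ExprMatrix, UnmaskingTruth]:
    """Simulate a treated/control miRNA array experiment.

    Baseline intensities are log-normal (log2 intensities normal with
    the given mean and sd, shared between arms per miRNA and line).
    Each planted silenced miRNA gets a fold effect drawn uniformly from
    ``effect_range`` independently per line, applied to the treated arm
    in a random subset of at least ``min_affected_lines`` lines.
    Measurement noise is normal on the log2 scale, independent per arm.
    """
    if n_mirna <= 0 or n_lines <= 0 or n_silenced < 0:
        raise ValueError("counts must be positive")
    if n_silenced > n_mirna:
        raise ValueError("n_silenced cannot exceed n_mirna")
    if effect_range[0] < 1 or effect_range[1] < effect_range[0]:
        raise ValueError("effect_range lower bound must be >= 1")
    if min_affected_lines > n_lines:
        raise ValueError("min_affected_lines cannot exceed n_lines")
    rng = np.random.default_rng(seed)

    mirnas = [f"sim-miR-{i:04d}" for i in range(n_mirna)]
    lines = (
        list(DEFAULT_CELL_LINES)
        if n_lines == len(DEFAULT_CELL_LINES)
        else [f"line{j + 1}" for j in range(n_lines)]
    )
    silenced = sorted(rng.choice(mirnas, size=n_silenced, replace=False))

    base = rng.normal(baseline_log2_mean, baseline_log2_sd, size=(n_mirna, n_lines))
    log_effect = np.zeros((n_mirna, n_lines))
    per_line_effect: dict[tuple[str, str], float] = {}
    idx = {m: i for i, m in enumerate(mirnas)}
    for m in silenced:
        k = int(rng.integers(min_affected_lines, n_lines + 1))
        affected = rng.choice(n_lines, size=k, replace=False)
        for j in affected:
            eff = float(rng.uniform(*effect_range))
            log_effect[idx[m], j] = np.log2(eff)
            per_line_effect[(m, lines[j])] = eff

    noise_c = rng.normal(0.0, noise_sd, size=(n_mirna, n_lines))
    noise_t = rng.normal(0.0, noise_sd, size=(n_mirna, n_lines))
    control = np.exp2(base + noise_c)
    treated = np.exp2(base + log_effect + noise_t)

    def _matrix(values: np.ndarray, condition: str) -> ExprMatrix:
        cols = [f"{line}_{condition}" for line in lines]
        meta = pd.DataFrame(
            {"cell_line": lines, "condition": condition},
            index=pd.Index(cols, name="sample_id"),
        )
        return ExprMatrix(
            pd.DataFrame(values, index=mirnas, columns=cols), meta, log2=False
        )

    truth = UnmaskingTruth(set(silenced), per_line_effect, detection_floor)
    return _matrix(treated, "treated"), _matrix(control, "control"), truth


def gen_methylation_cohort(
    n_probes: int = 400,
    n_candidate: int = 36,
    n_tumor: int = 17,
    n_normal: int = 5,
    delta_beta: float = 0.3,
    seed: int = 0,
    baseline_range: tuple[float, float] = (0.05, 0.2),
    noise_sd: float = 0.05,
    probes_per_feature: int = 4,
) -> tuple[BetaMatrix, ProbeAnnotation, set[str]]:
    """Simulate a tumor-vs-normal 450K-style methylation cohort.

    Probes are placed on one synthetic chromosome in feature-sized
    groups (``probes_per_feature`` probes within 2 kb of each feature's
    TSS). Per-probe baseline beta is uniform in ``baseline_range``;
    per-sample values add normal noise and are clipped to [0, 1]. The
    first ``n_candidate`` probes are hypermethylation candidates: tumor
    samples gain ``delta_beta`` before clipping. Returns the beta
    matrix, the probe annotation and the candidate probe id set.
    """
    if not (0.0 < delta_beta < 1.0):
        raise ValueError("delta_beta must lie in (0, 1)")
    if n_candidate > n_probes:
        raise ValueError("n_candidate cannot exceed n_probes")
    if min(n_probes, n_tumor, n_normal) <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)

    probes = [f"cg{i:07d}" for i in range(n_probes)]
    candidate = set(probes[:n_candidate])
    samples = [f"MM_{i + 1:02d}" for i in range(n_tumor)] + [
        f"NPC_{i + 1:02d}" for i in range(n_normal)
    ]
    groups = ["tumor"] * n_tumor + ["normal"] * n_normal

    base = rng.uniform(*baseline_range, size=n_probes)[:, None]
    vals = base + rng.normal(0.0, noise_sd, size=(n_probes, len(samples)))
    shift = np.zeros((n_probes, len(samples)))
    shift[:n_candidate, :n_tumor] = delta_beta
    betas = np.clip(vals + shift, 0.0, 1.0)

    meta = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    bm = BetaMatrix(pd.DataFrame(betas, index=probes, columns=samples), meta)

    n_features = int(np.ceil(n_probes / probes_per_feature))
    rows = []
    region_classes = ("island", "shore", "intragenic", "intergenic")
    for i, probe in enumerate(probes):
        fidx = i // probes_per_feature
        tss = 10_000 + fidx * 100_000
        offset = int(rng.integers(-1500, 1501))
        rows.append(
            {
                "probe_id": probe,
                "chrom": "chrSim",
                "pos": tss + offset,
                "feature": f"sim-miR-host-{fidx:03d}",
                "distance": offset,
                "region_class": region_classes[i % len(region_classes)],
            }
        )
    annotation = ProbeAnnotation(pd.DataFrame(rows))
    assert n_features == annotation.table["feature"].nunique()
    return bm, annotation, candidate


def gen_prediction_tensor(
    mirnas: list[str],
    genes: list[str],
    true_targets: dict[str, set[str]],
    n_algorithms: int = 12,
    sensitivity: float = 0.9,
    fpr: float = 0.05,
    availability: float = 0.8,
    seed: int = 0,
) -> tuple[PredictionTensor, dict[str, set[str]]]:
    """Simulate per-algorithm binary target calls with availability.

    Each (algorithm, miRNA) cell is available with probability
    ``availability`` (every miRNA is guaranteed at least one available
    algorithm). An available algorithm calls a true (miRNA, gene) pair
    with probability ``sensitivity`` and a false pair with probability
    ``fpr``. Returns the tensor and the truth mapping (echoed, with
    unknown genes dropped).
    """
    if not mirnas or not genes:
        raise ValueError("miRNA and gene lists must be non-empty")
    if n_algorithms < 1:
        raise ValueError("need at least one algorithm")
    for p, name in ((sensitivity, "sensitivity"), (fpr, "fpr"),
                    (availability, "availability")):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be a probability")
    rng = np.random.default_rng(seed)

    algorithms = [f"algo{a + 1:02d}" for a in range(n_algorithms)]
    gene_idx = {g: j for j, g in enumerate(genes)}
    truth_matrix = np.zeros((len(mirnas), len(genes)), dtype=bool)
    echoed: dict[str, set[str]] = {}
    for i, m in enumerate(mirnas):
        keep = {g for g in true_targets.get(m, set()) if g in gene_idx}
        echoed[m] = keep
        for g in keep:
            truth_matrix[i, gene_idx[g]] = True

    available = rng.random((n_algorithms, len(mirnas))) < availability
    for i in range(len(mirnas)):
        if not available[:, i].any():
            available[int(rng.integers(n_algorithms)), i] = True

    p_call = np.where(truth_matrix[None, :, :], sensitivity, fpr)
    calls = rng.random((n_algorithms, len(mirnas), len(genes))) < p_call
    calls &= available[:, :, None]
    tensor = PredictionTensor(algorithms, list(mirnas), list(genes), calls, available)
    return tensor, echoed


def default_survival_truth(
    n_genes: int = 120,
    n_cpos: int = 8,
    n_cneg: int = 6,
    beta_rs: float = 0.7,
    censor_rate: float = 0.3,
) -> SurvivalCohortTruth:
    """Default planted signature: a small C+/C- gene pair of sets at the
    front of the gene universe. The per-gene marginal hazard signal
    scales roughly as beta_rs / group size (each gene contributes 1/k
    of its group's median), so modest group sizes keep individual genes
    detectable by univariate screening at realistic cohort sizes."""
    if n_cpos + n_cneg > n_genes:
        raise ValueError("planted gene sets exceed gene universe")
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    return SurvivalCohortTruth(
        planted_cpos=genes[:n_cpos],
        planted_cneg=genes[n_cpos:n_cpos + n_cneg],
        beta_rs=beta_rs,
        censor_rate=censor_rate,
    )


def _censor_horizon(lam: np.ndarray, censor_rate: float) -> float:
    """Horizon c of a Uniform(0, c) censoring time giving the requested
    expected censoring fraction against exponential event times with
    per-sample rates ``lam``: P(censored_i) = (1 - exp(-lam_i c)) / (lam_i c)."""

    def frac(c: float) -> float:
        z = lam * c
        return float(np.mean((1.0 - np.exp(-z)) / z))

    lo, hi = 1e-9, 1.0
    while frac(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    return float(optimize.brentq(lambda c: frac(c) - censor_rate, lo, hi))


def gen_survival_cohort(
    n_samples: int = 559,
    n_genes: int = 120,
    truth: SurvivalCohortTruth | None = None,
    baseline_hazard: float = 0.015,
    seed: int = 0,
) -> tuple[ExprMatrix, SurvivalTable, SurvivalCohortTruth]:
    """Simulate an expression + overall-survival cohort.

    Gene expression is standard normal per gene. The true risk score of
    each sample is the median-difference score over the planted C+/C-
    sets; event times are exponential with hazard
    ``baseline_hazard * exp(beta_rs * RS)`` (time unit: months;
    baseline 0.015/month gives a realistic ~46-month median when
    RS = 0). Censoring times are independent Uniform(0, c) with c
    chosen so the expected censored fraction equals ``censor_rate``.
    """
    if truth is None:
        truth = default_survival_truth(n_genes=n_genes)
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if n_samples <= 0 or n_genes <= 0:
        raise ValueError("counts must be positive")
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    missing = (set(truth.planted_cpos) | set(truth.planted_cneg)) - set(genes)
    if missing:
        raise ValueError(f"planted genes outside gene universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)

    samples = [f"PT_{i + 1:04d}" for i in range(n_samples)]
    values = pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)), index=genes, columns=samples
    )
    meta = pd.DataFrame(
        {"group": "tumor"}, index=pd.Index(samples, name="sample_id")
    )
    expr = ExprMatrix(values, meta, log2=True)

    sig = Signature(list(truth.planted_cpos), list(truth.planted_cneg))
    rs = compute_risk_scores(expr, sig).rs
    lam = baseline_hazard * np.exp(truth.beta_rs * rs)
    t_event = rng.exponential(1.0 / lam)

    if truth.censor_rate > 0.0:
        c_max = _censor_horizon(lam, truth.censor_rate)
        t_cens = rng.uniform(0.0, c_max, size=n_samples)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n_samples, dtype=int)
    time = np.maximum(time, 1e-9)  # guard against an exact-zero draw

    surv = SurvivalTable(
        pd.DataFrame(
            {"time": time, "event": event},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return expr, surv, truth
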