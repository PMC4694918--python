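"""Core data containers shared across pipeline stages.

The pipeline operates on four kinds of data: expression matrices
(miRNA or gene intensities, features x samples), CpG methylation beta
matrices with probe annotations, binary target-prediction tensors, and
survival tables. Containers are thin validated wrappers around pandas /
numpy objects so that every stage can be used directly from Python
without going through the TSV interchange layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExprMatrix",
    "FoldChangeTable",
    "CandidateSet",
    "BetaMatrix",
    "ProbeAnnotation",
    "PredictionTensor",
    "TargetSet",
    "DEResult",
    "SurvivalTable",
    "CoxFit",
    "Signature",
    "RiskScores",
]

REGULATION_UP = "up"
REGULATION_DOWN = "down"
REGULATION_ND = "n.d."


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass
class ExprMatrix:
    """Expression matrix: features in rows, samples in columns.

    ``values`` holds linear intensities unless ``log2=True``, in which
    case values are log2 intensities and may be negative. ``sample_meta``
    is indexed by sample id; recognised columns are ``cell_line``,
    ``condition`` (``treated`` / ``control`` / ``none``) and ``group``
    (e.g. ``tumor`` / ``normal``).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    log2: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if not self.log2 and (vals < 0).any():
            raise ValueError("linear intensities must be non-negative")
        missing = self.values.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples missing from sample_meta: {list(missing)[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_linear(self) -> "ExprMatrix":
        if not self.log2:
            return self
        return ExprMatrix(np.exp2(self.values), self.sample_meta, log2=False)

    def to_log2(self, pseudocount: float = 0.0) -> "ExprMatrix":
        if self.log2:
            return self
        return ExprMatrix(
            np.log2(self.values + pseudocount), self.sample_meta, log2=True
        )


@dataclass
class FoldChangeTable:
    """Per (miRNA, cell line) linear fold changes with detection calls.

    ``table`` columns: mirna, cell_line, fold_change (NaN when not
    detected), regulation (up / down / n.d.), detected_treated,
    detected_control.
    """

    table: pd.DataFrame

    REQUIRED = (
        "mirna",
        "cell_line",
        "fold_change",
        "regulation",
        "detected_treated",
        "detected_control",
    )

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"fold-change table missing columns: {sorted(missing)}")
        nd = self.table["regulation"] == REGULATION_ND
        if self.table.loc[nd, "fold_change"].notna().any():
            raise ValueError("n.d. rows must not carry a numeric fold change")
        numeric = self.table.loc[~nd, "fold_change"]
        if (numeric <= 0).any():
            raise ValueError("fold changes must be positive ratios")

    @property
    def mirnas(self) -> list[str]:
        return list(pd.unique(self.table["mirna"]))

    @property
    def cell_lines(self) -> list[str]:
        return list(pd.unique(self.table["cell_line"]))


@dataclass
class CandidateSet:
    """miRNAs passing the unmasking selection rule, with evidence.

    ``evidence`` maps each selected miRNA to the (cell_line, fold_change)
    pairs that satisfied the rule.
    """

    selected: list[str]
    evidence: dict[str, list[tuple[str, float]]]
    fold_threshold: float
    min_lines: int

    def __post_init__(self) -> None:
        for m in self.selected:
            if len(self.evidence.get(m, [])) < self.min_lines:
                raise ValueError(f"{m} selected with insufficient qualifying lines")

    def __len__(self) -> int:
        return len(self.selected)

    def __contains__(self, mirna: str) -> bool:
        return mirna in set(self.selected)


@dataclass
class BetaMatrix:
    """CpG methylation beta values (probes x samples), all in [0, 1].

    ``sample_meta`` must carry a ``group`` column labelling each sample
    ``tumor`` or ``normal``.
    """

    betas: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.betas.index, "probe")
        _check_unique(self.betas.columns, "sample")
        vals = self.betas.to_numpy(dtype=float)
        if np.isnan(vals).all():
            raise ValueError("beta matrix is empty")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("beta values must lie in [0, 1]")
        if "group" not in self.sample_meta.columns:
            raise ValueError("sample_meta must have a 'group' column")
        missing = self.betas.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples missing group labels: {list(missing)[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.betas.index)

    def group_samples(self, group: str) -> list[str]:
        mask = self.sample_meta["group"] == group
        ids = self.sample_meta.index[mask]
        return [s for s in self.betas.columns if s in set(ids)]


@dataclass
class ProbeAnnotation:
    """Probe-to-feature links with signed TSS distances.

    One row per (probe, feature) link; a probe may recur when it lies
    within the window of several features. ``distance`` is signed
    relative to the feature strand: negative means upstream of the TSS.
    ``region_class`` is one of island / shore / intragenic / intergenic.
    """

    table: pd.DataFrame

    REQUIRED = ("probe_id", "chrom", "pos", "feature", "distance", "region_class")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"probe annotation missing columns: {sorted(missing)}")
        if (self.table["pos"] <= 0).any():
            raise ValueError("positions must be 1-based and positive")

    @property
    def features(self) -> list[str]:
        return list(pd.unique(self.table["feature"].dropna()))

    def probes_for(self, feature: str) -> list[str]:
        return list(self.table.loc[self.table["feature"] == feature, "probe_id"])


@dataclass
class PredictionTensor:
    """Binary miRNA->gene calls per prediction algorithm.

    ``calls[a, m, g]`` is True when algorithm ``a`` predicts gene ``g``
    as a target of miRNA ``m``. ``available[a, m]`` marks whether the
    algorithm covers that miRNA at all; unavailable cells are masked out
    of both numerator and denominator of any voting rule, they are not
    negative calls.
    """

    algorithms: list[str]
    mirnas: list[str]
    genes: list[str]
    calls: np.ndarray
    available: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        self.available = np.asarray(self.available, dtype=bool)
        shape = (len(self.algorithms), len(self.mirnas), len(self.genes))
        if self.calls.shape != shape:
            raise ValueError(f"calls shape {self.calls.shape} != {shape}")
        if self.available.shape != shape[:2]:
            raise ValueError(
                f"available shape {self.available.shape} != {shape[:2]}"
            )
        if (self.calls & ~self.available[:, :, None]).any():
            raise ValueError("calls present where algorithm is unavailable")


@dataclass
class TargetSet:
    """Consensus-predicted target genes per miRNA."""

    per_mirna: dict[str, set[str]]

    @property
    def union(self) -> list[str]:
        out: set[str] = set()
        for genes in self.per_mirna.values():
            out |= genes
        return sorted(out)


@dataclass
class DEResult:
    """Per-gene tumor-vs-normal differential expression.

    ``table`` columns: gene, fold_change (linear, tumor/normal), p,
    p_adj, direction, upregulated.
    """

    table: pd.DataFrame
    fold_cutoff: float
    adj_p_cutoff: float

    REQUIRED = ("gene", "fold_change", "p", "p_adj", "direction", "upregulated")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        _check_unique(pd.Index(self.table["gene"]), "gene")

    @property
    def upregulated_genes(self) -> list[str]:
        return sorted(self.table.loc[self.table["upregulated"], "gene"])


@dataclass
class SurvivalTable:
    """Per-sample follow-up time and event indicator.

    ``table`` is indexed by sample id with columns ``time`` (> 0, any
    consistent unit) and ``event`` (1 = death, 0 = censored).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.table.columns:
                raise ValueError(f"survival table missing '{col}' column")
        _check_unique(self.table.index, "sample")
        t = self.table["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or (t <= 0).any():
            raise ValueError("survival times must be positive and finite")
        e = self.table["event"].to_numpy()
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class CoxFit:
    """Single-covariate proportional-hazards fit summary."""

    coef: float
    se: float
    p: float
    n: int
    n_events: int
    converged: bool = True

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.coef))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.coef - 1.959964 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.coef + 1.959964 * self.se))


@dataclass
class Signature:
    """Survival signature: genes with positive (C+) and negative (C-)
    hazard association. Higher expression of a C+ gene implies higher
    risk of death; C- is the reverse."""

    c_plus: list[str] = field(default_factory=list)
    c_minus: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.c_plus) & set(self.c_minus)
        if overlap:
            raise ValueError(f"genes in both C+ and C-: {sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.c_plus) + len(self.c_minus)


@dataclass
class RiskScores:
    """Per-sample median-difference risk scores.

    ``table`` is indexed by sample id with columns ``u`` (median of C+
    gene expression), ``d`` (median of C- gene expression), ``rs``
    (= u - d) and, after binning, ``level`` (1-based equal-width bin).
    """

    table: pd.DataFrame
    n_levels: int | None = None

    def __post_init__(self) -> None:
        for col in ("u", "d", "rs"):
            if col not in self.table.columns:
                raise ValueError(f"risk-score table missing '{col}' column")
        resid = self.table["rs"] - (self.table["u"] - self.table["d"])
        if not np.allclose(resid, 0.0, atol=1e-12):
            raise ValueError("rs must equal u - d")

    @property
    def rs(self) -> np.ndarray:
        return self.table["rs"].to_numpy(dtype=float)

    @property
    def levels(self) -> np.ndarray:
        if "level" not in self.table.columns:
            raise ValueError("risk scores have not been binned into levels")
        return self.table["level"].to_numpy(dtype=int)
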