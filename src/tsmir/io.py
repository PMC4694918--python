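"""TSV interchange readers and writers.

Everything on disk is tab-separated UTF-8 text with a header row and
'.' decimals. Expression and beta matrices carry features in rows and
samples in columns, with a separate sample sheet (sample_id plus
metadata columns). Probe files may be BED-like (0-based, half-open
start/end) and are converted to 1-based positions on read; feature TSS
tables are 1-based already.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    ExprMatrix,
    FoldChangeTable,
    PredictionTensor,
    RiskScores,
    Signature,
    SurvivalTable,
)

__all__ = [
    "read_expr_matrix",
    "write_expr_matrix",
    "read_beta_matrix",
    "read_probe_bed",
    "read_feature_tss",
    "read_prediction_tensor",
    "read_survival_table",
    "write_survival_table",
    "read_signature",
    "write_signature",
    "write_fold_changes",
    "read_fold_changes",
    "write_risk_scores",
    "write_truth_manifest",
    "read_truth_manifest",
]


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    mat = _read_tsv(path, index_col=0)
    mat.index = mat.index.astype(str)
    return mat


def read_expr_matrix(
    matrix_path: str | Path, sample_sheet_path: str | Path, log2: bool = False
) -> ExprMatrix:
    values = _read_matrix(matrix_path)
    meta = _read_tsv(sample_sheet_path, index_col="sample_id")
    return ExprMatrix(values, meta, log2=log2)


def write_expr_matrix(
    expr: ExprMatrix, matrix_path: str | Path, sample_sheet_path: str | Path
) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="feature_id")
    expr.sample_meta.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


def read_beta_matrix(
    matrix_path: str | Path, sample_sheet_path: str | Path
) -> BetaMatrix:
    betas = _read_matrix(matrix_path)
    meta = _read_tsv(sample_sheet_path, index_col="sample_id")
    return BetaMatrix(betas, meta)


def write_beta_matrix(
    bm: BetaMatrix, matrix_path: str | Path, sample_sheet_path: str | Path
) -> None:
    bm.betas.to_csv(matrix_path, sep="\t", index_label="probe_id")
    bm.sample_meta.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


def read_probe_bed(path: str | Path) -> pd.DataFrame:
    """BED-like probe file: chrom, start (0-based), end (half-open),
    probe_id, optional region_class. Returns 1-based probe midpoint
    positions (for a single-CpG probe start+1 == end, so pos == end)."""
    bed = _read_tsv(path)
    required = {"chrom", "start", "end", "probe_id"}
    missing = required - set(bed.columns)
    if missing:
        raise ValueError(f"probe BED missing columns: {sorted(missing)}")
    pos = (bed["start"] + 1 + bed["end"]) // 2
    out = pd.DataFrame(
        {"probe_id": bed["probe_id"].astype(str), "chrom": bed["chrom"], "pos": pos}
    )
    if "region_class" in bed.columns:
        out["region_class"] = bed["region_class"]
    return out


def read_feature_tss(path: str | Path) -> pd.DataFrame:
    """Feature TSS table: feature_id, chrom, tss (1-based), strand."""
    tab = _read_tsv(path)
    missing = {"feature_id", "chrom", "tss", "strand"} - set(tab.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return tab


def read_prediction_tensor(
    calls_path: str | Path, availability_path: str | Path
) -> PredictionTensor:
    """Long-format calls (algorithm, mirna, gene, call) plus an
    availability table (algorithm, mirna, available)."""
    calls = _read_tsv(calls_path)
    avail = _read_tsv(availability_path)
    algorithms = sorted(set(avail["algorithm"]) | set(calls["algorithm"]))
    mirnas = sorted(set(avail["mirna"]) | set(calls["mirna"]))
    genes = sorted(set(calls["gene"]))
    ai = {a: i for i, a in enumerate(algorithms)}
    mi = {m: i for i, m in enumerate(mirnas)}
    gi = {g: i for i, g in enumerate(genes)}
    call_arr = np.zeros((len(algorithms), len(mirnas), len(genes)), dtype=bool)
    avail_arr = np.zeros((len(algorithms), len(mirnas)), dtype=bool)
    for row in avail.itertuples(index=False):
        avail_arr[ai[row.algorithm], mi[row.mirna]] = bool(int(row.available))
    for row in calls.itertuples(index=False):
        if int(row.call):
            call_arr[ai[row.algorithm], mi[row.mirna], gi[row.gene]] = True
    return PredictionTensor(algorithms, mirnas, genes, call_arr, avail_arr)


def write_prediction_tensor(
    tensor: PredictionTensor, calls_path: str | Path, availability_path: str | Path
) -> None:
    a_idx, m_idx, g_idx = np.nonzero(tensor.calls)
    pd.DataFrame(
        {
            "algorithm": [tensor.algorithms[a] for a in a_idx],
            "mirna": [tensor.mirnas[m] for m in m_idx],
            "gene": [tensor.genes[g] for g in g_idx],
            "call": 1,
        }
    ).to_csv(calls_path, sep="\t", index=False)
    rows = [
        (a, m, int(tensor.available[i, j]))
        for i, a in enumerate(tensor.algorithms)
        for j, m in enumerate(tensor.mirnas)
    ]
    pd.DataFrame(rows, columns=["algorithm", "mirna", "available"]).to_csv(
        availability_path, sep="\t", index=False
    )


def read_survival_table(path: str | Path) -> SurvivalTable:
    tab = _read_tsv(path, index_col="sample_id")
    return SurvivalTable(tab[["time", "event"]])


def write_survival_table(surv: SurvivalTable, path: str | Path) -> None:
    surv.table.to_csv(path, sep="\t", index_label="sample_id")


def read_signature(path: str | Path) -> Signature:
    tab = _read_tsv(path)
    cp = list(tab.loc[tab["group"] == "C+", "gene"])
    cm = list(tab.loc[tab["group"] == "C-", "gene"])
    return Signature(cp, cm)


def write_signature(sig: Signature, path: str | Path) -> None:
    rows = [(g, "C+") for g in sig.c_plus] + [(g, "C-") for g in sig.c_minus]
    pd.DataFrame(rows, columns=["gene", "group"]).to_csv(path, sep="\t", index=False)


def write_fold_changes(fc: FoldChangeTable, path: str | Path) -> None:
    fc.table.to_csv(path, sep="\t", index=False)


def read_fold_changes(path: str | Path) -> FoldChangeTable:
    tab = _read_tsv(path)
    tab["fold_change"] = pd.to_numeric(tab["fold_change"], errors="coerce")
    for col in ("detected_treated", "detected_control"):
        if col not in tab.columns:
            tab[col] = tab["regulation"] != "n.d."
    return FoldChangeTable(tab)


def write_risk_scores(scores: RiskScores, path: str | Path) -> None:
    scores.table.to_csv(path, sep="\t", index_label="sample_id")


def write_truth_manifest(manifest: dict[str, object], path: str | Path) -> None:
    """Flat key=value text manifest describing planted ground truth."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(manifest):
            value = manifest[key]
            if isinstance(value, (set, frozenset)):
                value = ",".join(sorted(value))
            elif isinstance(value, (list, tuple)):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key}={value}\n")


def read_truth_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, value = line.split("=", 1)
                out[key] = value
    return out
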