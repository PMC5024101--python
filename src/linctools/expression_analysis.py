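"""Expression-pattern analysis of lincRNAs across a tissue panel.

Works on an FPKM matrix (rows = transcripts, columns = tissues; the study
panel has 11 tissues: GS, YL, SAM, FB1-FB4, FL1-FL4).  Provides
expression-level classes, the tissue-specificity index tau
(TSI = sum_i (1 - x_i / x_max) / (N - 1)), tissue- and stage-specific
calls, and rank (Spearman) co-expression between lincRNAs and mRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

TISSUE_LABELS = ["GS", "YL", "SAM", "FB1", "FB2", "FB3", "FB4", "FL1", "FL2", "FL3", "FL4"]

EXPRESSION_CLASSES = ("very_low", "low", "moderate", "high", "very_high")

__all__ = [
    "TISSUE_LABELS",
    "EXPRESSION_CLASSES",
    "TsiResult",
    "CoexpressionResult",
    "read_fpkm",
    "classify_expression",
    "expression_class_counts",
    "compute_tsi",
    "compute_tsi_table",
    "call_tissue_specific",
    "call_stage_specific",
    "zscore_rows",
    "spearman_coexpression",
    "top_coexpressed",
    "count_expressed_per_tissue",
]


def read_fpkm(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited FPKM matrix (first column = transcript id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_matrix(df)
    return df


def validate_matrix(df: pd.DataFrame) -> None:
    if df.isna().any().any():
        raise ValueError("FPKM matrix contains missing cells")
    if (df.values < 0).any():
        raise ValueError("FPKM matrix contains negative values")
    if df.columns.duplicated().any():
        raise ValueError("duplicate tissue labels")


def classify_expression(fpkm: float) -> str:
    """Five-level expression class for one FPKM value.

    Bins: very_low [0,2), low [2,5), moderate [5,10), high [10,20],
    very_high (20,inf).  Only the outer bounds (<2 and >20) are fixed by
    the scheme; the intermediate boundaries follow standard FPKM binning.
    """
    if fpkm < 0:
        raise ValueError(f"negative FPKM: {fpkm}")
    if fpkm < 2:
        return "very_low"
    if fpkm < 5:
        return "low"
    if fpkm < 10:
        return "moderate"
    if fpkm <= 20:
        return "high"
    return "very_high"


def expression_class_counts(df: pd.DataFrame, statistic: str = "max") -> pd.Series:
    """Count transcripts per expression class, by max (default) or mean FPKM."""
    values = df.max(axis=1) if statistic == "max" else df.mean(axis=1)
    classes = values.map(classify_expression)
    return classes.value_counts().reindex(EXPRESSION_CLASSES, fill_value=0)


# ---------------------------------------------------------------------------
# Tissue-specificity index (tau)
# ---------------------------------------------------------------------------

@dataclass
class TsiResult:
    transcript_id: str
    tsi: float | None          # None when undefined (all-zero expression)
    max_tissue: str | None

    @property
    def defined(self) -> bool:
        return self.tsi is not None


def compute_tsi(x, tissues: list[str] | None = None, transcript_id: str = "") -> TsiResult:
    """Tissue-specificity index tau of one expression vector.

    TSI = sum_i (1 - x_i / x_max) / (N - 1): 0 for perfectly uniform
    (housekeeping) profiles, 1 for strict single-tissue expression.
    Undefined (flagged, excluded from specificity calls) when the vector
    is all zero.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expression vector must be 1-D with at least 2 tissues")
    if (x < 0).any():
        raise ValueError("negative expression values")
    xmax = x.max()
    if xmax == 0:
        return TsiResult(transcript_id, None, None)
    tsi = float(np.sum(1.0 - x / xmax) / (x.size - 1))
    imax = int(np.argmax(x))  # ties -> first in column order
    max_tissue = tissues[imax] if tissues is not None else str(imax)
    return TsiResult(transcript_id, tsi, max_tissue)


def compute_tsi_table(df: pd.DataFrame) -> pd.DataFrame:
    """TSI for every row of an FPKM matrix (columns: tsi, max_tissue, defined)."""
    tissues = list(df.columns)
    rows = []
    for tid, x in zip(df.index, df.values):
        r = compute_tsi(x, tissues, str(tid))
        rows.append({"transcript_id": r.transcript_id, "tsi": r.tsi,
                     "max_tissue": r.max_tissue, "defined": r.defined})
    return pd.DataFrame(rows).set_index("transcript_id")


def zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score across tissues (constant rows map to 0)."""
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0).replace(0, np.nan)
    return df.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)


def call_tissue_specific(
    df: pd.DataFrame, tsi_threshold: float = 0.9
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Assign each transcript with TSI >= threshold to its maximal tissue.

    Returns (per-tissue lists, heatmap-ready z-scored matrix of the
    specific set).  Transcripts with undefined TSI are never called.
    """
    table = compute_tsi_table(df)
    specific = table[table["defined"] & (table["tsi"] >= tsi_threshold)]
    per_tissue: dict[str, list[str]] = {t: [] for t in df.columns}
    for tid, row in specific.iterrows():
        per_tissue[row["max_tissue"]].append(tid)
    heat = zscore_rows(df.loc[specific.index])
    return per_tissue, heat


def call_stage_specific(
    df: pd.DataFrame,
    target_tissues: list[str],
    on_min: float = 3.0,
    off_max: float = 0.1,
) -> list[str]:
    """Transcripts expressed only in the target tissues.

    Called iff max FPKM over the targets >= on_min and max over every
    other tissue <= off_max.
    """
    if not target_tissues:
        raise ValueError("empty target tissue set")
    missing = set(target_tissues) - set(df.columns)
    if missing:
        raise ValueError(f"unknown tissues: {sorted(missing)}")
    others = [c for c in df.columns if c not in set(target_tissues)]
    on = df[list(target_tissues)].max(axis=1) >= on_min
    off = df[others].max(axis=1) <= off_max if others else pd.Series(True, index=df.index)
    return list(df.index[on & off])


# ---------------------------------------------------------------------------
# Co-expression
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionResult:
    """Spearman rho between lincRNA rows (index) and mRNA rows (columns)."""

    rho: pd.DataFrame
    flagged: set[str] = field(default_factory=set)  # zero-variance rows (rho forced to 0)

    def to_edge_frame(self) -> pd.DataFrame:
        stacked = self.rho.stack()
        stacked.index.names = ["linc_id", "mrna_id"]
        long = stacked.rename("rho").reset_index()
        return long


def _ranked(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks per row, centred; returns (ranks, zero-variance mask)."""
    ranks = np.apply_along_axis(rankdata, 1, values)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    flat = norms == 0
    norms[flat] = 1.0
    return ranks / norms[:, None], flat


def spearman_coexpression(linc_df: pd.DataFrame, mrna_df: pd.DataFrame) -> CoexpressionResult:
    """All-pairs Spearman correlation (average-rank, tie-corrected).

    Zero-variance rows have undefined rho; they are reported as 0 and the
    row/column id is flagged rather than dropped silently.
    """
    if list(linc_df.columns) != list(mrna_df.columns):
        raise ValueError("tissue columns differ between the two matrices")
    if linc_df.shape[1] < 3:
        raise ValueError("need at least 3 tissues for rank correlation")
    ra, fa = _ranked(linc_df.values.astype(float))
    rb, fb = _ranked(mrna_df.values.astype(float))
    rho = ra @ rb.T
    rho[fa, :] = 0.0
    rho[:, fb] = 0.0
    np.clip(rho, -1.0, 1.0, out=rho)
    flagged = set(np.asarray(linc_df.index)[fa]) | set(np.asarray(mrna_df.index)[fb])
    return CoexpressionResult(
        rho=pd.DataFrame(rho, index=linc_df.index, columns=mrna_df.index),
        flagged=flagged,
    )


def top_coexpressed(coexpr: CoexpressionResult, linc_id: str, k: int = 10) -> list[tuple[str, float]]:
    """The k mRNAs with highest rho for one lincRNA (ties by mRNA id)."""
    if linc_id not in coexpr.rho.index:
        raise KeyError(f"unknown lincRNA id: {linc_id}")
    row = coexpr.rho.loc[linc_id]
    ordered = sorted(row.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [(str(m), float(r)) for m, r in ordered[:k]]


def count_expressed_per_tissue(df: pd.DataFrame, min_fpkm: float = 1.0) -> pd.Series:
    """Number of transcripts with FPKM >= min_fpkm in each tissue."""
    if min_fpkm < 0:
        raise ValueError("min_fpkm must be >= 0")
    return (df >= min_fpkm).sum(axis=0)
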