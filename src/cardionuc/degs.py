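"""DEG thresholding and per-chromosome summaries.

A differential-expression table (DESeq2-style: gene, chromosome, log2
fold-change, adjusted p) is filtered with the conventional thresholds
``padj < 0.05`` and ``|log2FC| > 0.5`` and summarized per chromosome:
DEG percentage of the chromosome's genes, share of all DEGs, and the
ECM-related DEG tally.  An exact binomial enrichment test against the
genome-wide DEG fraction makes per-chromosome enrichment assertable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_PADJ_MAX",
    "DEFAULT_LFC_MIN",
    "FilterResult",
    "filter_degs",
    "summarize_by_chromosome",
    "enrichment_test",
    "read_deg_table",
]

DEFAULT_PADJ_MAX = 0.05
DEFAULT_LFC_MIN = 0.5

ALLOWED_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X", "Y"}

#: accepted aliases for DESeq2-style column names
COLUMN_ALIASES = {
    "log2FoldChange": "log2fc",
    "log2fc": "log2fc",
    "padj": "padj",
    "gene": "gene_id",
    "gene_id": "gene_id",
    "chromosome": "chromosome",
    "chr": "chromosome",
    "is_ecm": "is_ecm",
}


@dataclass
class FilterResult:
    """DEG subset plus the thresholds applied and rows rejected."""

    subset: pd.DataFrame
    padj_max: float
    lfc_min: float
    n_input: int
    n_missing_dropped: int


def read_deg_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a DE table (TSV/CSV), mapping DESeq2 column names to canonical ones."""
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns={c: COLUMN_ALIASES[c] for c in df.columns if c in COLUMN_ALIASES})
    return validate_deg_table(df)


def validate_deg_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, chromosome codes, unique gene ids, padj range."""
    required = {"gene_id", "chromosome", "log2fc", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    table = table.copy()
    table["chromosome"] = table["chromosome"].astype(str).str.removeprefix("chr")
    bad = set(table["chromosome"].unique()) - ALLOWED_CHROMOSOMES
    if bad:
        raise ValueError(f"unknown chromosomes: {sorted(bad)}")
    if table["gene_id"].duplicated().any():
        raise ValueError("gene_id values must be unique")
    padj = table["padj"].dropna()
    if ((padj < 0) | (padj > 1)).any():
        raise ValueError("padj must lie in [0, 1]")
    if "is_ecm" not in table.columns:
        table["is_ecm"] = False
    return table


def filter_degs(
    table: pd.DataFrame,
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> FilterResult:
    """Select DEGs with ``padj < padj_max`` and ``|log2fc| > lfc_min`` (strict).

    Rows with missing ``padj`` or ``log2fc`` are rejected and counted in
    ``n_missing_dropped``.  The filter is idempotent and monotone: loosening
    either threshold can only grow the subset.
    """
    table = validate_deg_table(table)
    missing = table["padj"].isna() | table["log2fc"].isna()
    clean = table.loc[~missing]
    keep = (clean["padj"] < padj_max) & (clean["log2fc"].abs() > lfc_min)
    return FilterResult(
        subset=clean.loc[keep].reset_index(drop=True),
        padj_max=padj_max,
        lfc_min=lfc_min,
        n_input=len(table),
        n_missing_dropped=int(missing.sum()),
    )


def summarize_by_chromosome(subset: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome DEG counts, percentages and ECM-related DEG tally.

    ``deg_percent`` normalizes by the chromosome's gene count (the default
    reading of a per-chromosome DEG percentage); ``share_of_degs`` normalizes
    by the total DEG count.  Chromosomes without genes in the table are
    absent from the output rather than reported as zero.
    """
    table = validate_deg_table(table)
    if not set(subset["gene_id"]).issubset(set(table["gene_id"])):
        raise ValueError("subset contains genes absent from the full table")
    n_genes = table.groupby("chromosome")["gene_id"].size().rename("n_genes")
    n_deg = subset.groupby("chromosome")["gene_id"].size().rename("n_deg")
    n_ecm = subset.loc[subset["is_ecm"]].groupby("chromosome")["gene_id"].size().rename("n_ecm_deg")
    out = pd.concat([n_genes, n_deg, n_ecm], axis=1).fillna(0)
    out[["n_deg", "n_ecm_deg"]] = out[["n_deg", "n_ecm_deg"]].astype(int)
    out["deg_percent"] = 100.0 * out["n_deg"] / out["n_genes"]
    total_deg = out["n_deg"].sum()
    out["share_of_degs"] = 100.0 * out["n_deg"] / total_deg if total_deg else 0.0
    order = [str(i) for i in range(1, 23)] + ["X", "Y"]
    out = out.reindex([c for c in order if c in out.index])
    return out.reset_index().rename(columns={"index": "chromosome"})


def enrichment_test(summary: pd.DataFrame, method: str = "fdr_bh") -> pd.DataFrame:
    """Exact two-sided binomial test of each chromosome's DEG fraction.

    The null rate is the genome-wide DEG fraction computed from the summary
    totals; p-values are adjusted across chromosomes (Benjamini-Hochberg by
    default).  A chromosome whose DEG count equals its expectation exactly
    gets p = 1 under the two-sided exact convention.
    """
    total_genes = int(summary["n_genes"].sum())
    total_deg = int(summary["n_deg"].sum())
    if total_genes == 0:
        raise ValueError("summary has no genes")
    p0 = total_deg / total_genes
    pvals = [
        binomtest(int(row.n_deg), int(row.n_genes), p0, alternative="two-sided").pvalue
        for row in summary.itertuples()
    ]
    out = summary[["chromosome", "n_genes", "n_deg", "deg_percent"]].copy()
    out["pval"] = pvals
    out["padj"] = multipletests(pvals, method=method)[1]
    out["genomewide_fraction"] = p0
    return out
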