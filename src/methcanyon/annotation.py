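"""Gene models and genomic interval sets (BED I/O, promoter windows).

Gene models are strand-aware: the TSS of a + strand gene is its interval
start, and of a - strand gene its interval end.  Promoters are TSS +/- 2 kb
windows.  All coordinates 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PROMOTER_FLANK = 2_000

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tts", "biotype"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def make_genes(gene_id, chrom, start, end, strand) -> pd.DataFrame:
    """Build a gene-model table from parallel arrays (start < end, half-open)."""
    df = pd.DataFrame({"gene_id": gene_id, "chrom": chrom,
                       "start": np.asarray(start, dtype=np.int64),
                       "end": np.asarray(end, dtype=np.int64),
                       "strand": strand})
    if (df["end"] <= df["start"]).any():
        raise ValueError("gene end must exceed start")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return add_tss(df)


def add_tss(genes: pd.DataFrame) -> pd.DataFrame:
    genes = genes.copy()
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    genes["tts"] = np.where(genes["strand"] == "+", genes["end"], genes["start"])
    return genes


def promoter_windows(genes: pd.DataFrame, flank: int = PROMOTER_FLANK) -> pd.DataFrame:
    """TSS +/- flank windows, clipped at 0 (one row per gene)."""
    return pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "chrom": genes["chrom"].to_numpy(),
        "start": np.maximum(genes["tss"].to_numpy() - flank, 0),
        "end": genes["tss"].to_numpy() + flank,
    })


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    if "biotype" not in out:
        out["biotype"] = "protein_coding"
    out[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"gene model file missing columns: {sorted(missing)}")
    df["start"] = np.where(df["strand"] == "+", df["tss"], df["tts"])
    df["end"] = np.where(df["strand"] == "+", df["tts"], df["tss"])
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write intervals (chrom,start,end[,name...]) as BED6."""
    out = intervals.copy()
    if "name" not in out:
        out["name"] = [f"region_{i}" for i in range(len(out))]
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "."
    out[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df
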