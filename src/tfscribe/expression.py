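"""RNA-seq counts -> filtered, replicate-averaged FPKM response vectors.

The counts table has one row per gene with its length and one column per
sample named ``<condition>.<replicate>``.  Processing: (1) drop genes not
detected with at least ``min_reads`` in *every* sample, (2) convert counts to
FPKM per sample using the post-filter column sums as library sizes,
(3) average replicates within each condition.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd


def read_counts_table(path) -> pd.DataFrame:
    """Read a counts TSV (gene_id, length_bp, then `condition.replicate` columns)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length_bp" not in df.columns:
        raise ValueError("counts table must have a length_bp column")
    return df


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "length_bp"]


def condition_of(sample: str) -> str:
    return sample.rsplit(".", 1)[0]


def filter_min_count(table: pd.DataFrame, min_reads: int = 1) -> pd.DataFrame:
    """Keep genes with count >= min_reads in every sample (all conditions/replicates)."""
    samples = sample_columns(table)
    keep = (table[samples] >= min_reads).all(axis=1)
    return table.loc[keep].copy()


def compute_fpkm(table: pd.DataFrame, library_sizes: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Per-condition FPKM: count * 1e9 / (library_size * length), replicate-averaged.

    Library size defaults to the per-sample sum of counts over the genes
    present in ``table`` (i.e. after filtering); pass ``library_sizes`` to
    override, e.g. when reprocessing simulated counts generated at a known
    sequencing depth.
    """
    samples = sample_columns(table)
    lengths = table["length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    per_sample = {}
    for s in samples:
        libsize = float(library_sizes[s]) if library_sizes else float(table[s].sum())
        if libsize == 0:
            raise ValueError(f"zero library size in sample {s}")
        per_sample[s] = table[s].to_numpy(dtype=float) * 1e9 / (libsize * lengths)
    fpkm_samples = pd.DataFrame(per_sample, index=table.index)
    # conditions in first-appearance order
    seen: list[str] = []
    for s in samples:
        c = condition_of(s)
        if c not in seen:
            seen.append(c)
    out = pd.DataFrame(
        {c: fpkm_samples[[s for s in samples if condition_of(s) == c]].mean(axis=1) for c in seen},
        index=table.index,
    )
    return out


def sum_of_squares_normalize(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene's cross-condition vector to unit Euclidean norm.

    All-zero rows cannot be normalized and are dropped with a warning.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("need at least two conditions to normalize across")
    vals = fpkm.to_numpy(dtype=float)
    norms = np.sqrt((vals**2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} all-zero gene rows")
    out = fpkm.loc[~zero].div(pd.Series(norms[~zero], index=fpkm.index[~zero]), axis=0)
    return out


def log2_transform(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Optional log2(FPKM + 1) transform (off by default in all pipelines)."""
    return np.log2(fpkm + 1.0)
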