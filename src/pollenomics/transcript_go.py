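"""Transcript-level aggregation statistics.

These are the bulk-RNA-seq summary computations downstream of read counting:
a counts-per-million (CPM) detection filter (> 0.5 CPM in at least 2
libraries), RPKM, a GO-term statistic that sums RPKM values of all detected
genes within a term per sample and compares the per-sample sums between two
conditions (log2 fold change of condition means, Student's t test), and
gene-set tallies of externally supplied differential-expression flags
(|log2FC| > 1, FDR < 0.005; DE model fitting itself is an upstream tool
and not reimplemented here).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import two_sample_t

__all__ = [
    "CPM_THRESHOLD",
    "CPM_MIN_LIBS",
    "DE_FC_THRESHOLD",
    "DE_FDR_THRESHOLD",
    "library_sizes",
    "cpm",
    "cpm_filter",
    "rpkm",
    "go_quant",
    "gene_set_tally",
]

CPM_THRESHOLD = 0.5
CPM_MIN_LIBS = 2
DE_FC_THRESHOLD = 1.0
DE_FDR_THRESHOLD = 0.005


def library_sizes(
    counts: pd.DataFrame, sizes: Optional[pd.Series] = None
) -> pd.Series:
    """Column sums of the counts matrix unless explicit sizes are given."""
    if sizes is None:
        sizes = counts.sum(axis=0)
    sizes = sizes.astype(float)
    if (sizes <= 0).any():
        bad = sizes.index[sizes <= 0].tolist()
        raise ValueError(f"zero/negative library size for {bad}")
    return sizes


def cpm(counts: pd.DataFrame, sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    """Counts per million mapped reads (gene × sample)."""
    sizes = library_sizes(counts, sizes)
    return counts.div(sizes, axis=1) * 1e6


def cpm_filter(
    counts: pd.DataFrame,
    min_cpm: float = CPM_THRESHOLD,
    min_libs: int = CPM_MIN_LIBS,
    sizes: Optional[pd.Series] = None,
) -> pd.Index:
    """Genes with CPM strictly above ``min_cpm`` in at least ``min_libs`` libraries."""
    c = cpm(counts, sizes)
    keep = (c > min_cpm).sum(axis=1) >= min_libs
    return counts.index[keep]


def rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    ``RPKM = count / (length/1000) / (library_size/1e6)`` with gene lengths
    in bp (> 0 required).
    """
    sizes = library_sizes(counts, sizes)
    lengths = lengths.reindex(counts.index).astype(float)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    per_kb = counts.div(lengths / 1e3, axis=0)
    return per_kb.div(sizes / 1e6, axis=1)


def _go_long(go_map: Mapping[str, Sequence[str]] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a gene→GO multimap to a two-column frame (gene, go_id)."""
    if isinstance(go_map, pd.DataFrame):
        cols = list(go_map.columns[:2])
        out = go_map.rename(columns=dict(zip(cols, ["gene", "go_id"])))
        return out[["gene", "go_id"]]
    records = [
        {"gene": gene, "go_id": term}
        for gene, terms in go_map.items()
        for term in terms
    ]
    return pd.DataFrame.from_records(records, columns=["gene", "go_id"])


def go_quant(
    rpkm_matrix: pd.DataFrame,
    go_map,
    sheet: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    de_table: Optional[pd.DataFrame] = None,
    fc_threshold: float = DE_FC_THRESHOLD,
    fdr_threshold: float = DE_FDR_THRESHOLD,
) -> pd.DataFrame:
    """GO-term summed-RPKM fold change between two conditions.

    Per sample, a term's score is the sum of RPKM over its member genes that
    are present in the matrix.  ``log2FC = log2(mean_b / mean_a)`` with a as
    the earlier condition; the p-value is a two-sample Student's t test on
    the per-sample scores (n per condition from the sheet).  If a DE table
    (index gene, columns log2FC and FDR) is given, DEGs within the term are
    tallied with strict thresholds.

    Returns one row per GO term: summed RPKM means, log2FC, p, n_genes and
    DEG counts.  Terms with a zero denominator mean get NaN log2FC.
    """
    long = _go_long(go_map)
    long = long.loc[long["gene"].isin(rpkm_matrix.index)]

    cond = sheet.set_index("sample_id")["condition"]
    samples_a = cond.index[(cond == condition_a) & cond.index.isin(rpkm_matrix.columns)]
    samples_b = cond.index[(cond == condition_b) & cond.index.isin(rpkm_matrix.columns)]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each condition needs >= 2 samples in the matrix")

    de_up = de_down = None
    if de_table is not None:
        de_up = set(
            de_table.index[
                (de_table["log2FC"] > fc_threshold)
                & (de_table["FDR"] < fdr_threshold)
            ]
        )
        de_down = set(
            de_table.index[
                (de_table["log2FC"] < -fc_threshold)
                & (de_table["FDR"] < fdr_threshold)
            ]
        )

    records = []
    for go_id, genes in long.groupby("go_id")["gene"]:
        members = genes.unique()
        sub = rpkm_matrix.loc[members]
        score_a = sub[samples_a].sum(axis=0).to_numpy()
        score_b = sub[samples_b].sum(axis=0).to_numpy()
        mean_a, mean_b = float(score_a.mean()), float(score_b.mean())
        if mean_a > 0 and mean_b > 0:
            log2fc = float(np.log2(mean_b / mean_a))
        else:
            log2fc = float("nan")
        if score_a.std(ddof=1) == 0 and score_b.std(ddof=1) == 0 and mean_a == mean_b:
            p = 1.0
        else:
            _, p = two_sample_t(score_a, score_b)
        rec = {
            "go_id": go_id,
            "n_genes": len(members),
            "mean_sum_rpkm_a": mean_a,
            "mean_sum_rpkm_b": mean_b,
            "log2FC": log2fc,
            "p_value": p,
        }
        if de_up is not None:
            rec["deg_up"] = len(set(members) & de_up)
            rec["deg_down"] = len(set(members) & de_down)
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("go_id")


def gene_set_tally(
    de_table: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    fc_threshold: float = DE_FC_THRESHOLD,
    fdr_threshold: float = DE_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Per-set counts of detected genes and up/down DEGs.

    ``up``: log2FC > fc_threshold and FDR < fdr_threshold (strict);
    ``down`` symmetric with log2FC < -fc_threshold.  Genes of a set absent
    from the DE table are not counted as detected; their ids are collected
    in ``result.attrs["absent"]``.
    """
    detected = set(de_table.index)
    up_set = set(
        de_table.index[
            (de_table["log2FC"] > fc_threshold) & (de_table["FDR"] < fdr_threshold)
        ]
    )
    down_set = set(
        de_table.index[
            (de_table["log2FC"] < -fc_threshold) & (de_table["FDR"] < fdr_threshold)
        ]
    )
    records = []
    absent: dict[str, list] = {}
    for name, genes in sets.items():
        genes = set(genes)
        miss = sorted(genes - detected)
        if miss:
            absent[name] = miss
        records.append(
            {
                "set": name,
                "detected": len(genes & detected),
                "up": len(genes & up_set),
                "down": len(genes & down_set),
            }
        )
    out = pd.DataFrame.from_records(
        records, columns=["set", "detected", "up", "down"]
    ).set_index("set")
    out.attrs["absent"] = absent
    return out
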