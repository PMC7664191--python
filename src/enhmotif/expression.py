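"""Selection of highly expressed, upregulated genes and the TF subset.

Mirrors the standard RNA-seq shortlist step for a two-timepoint comparison:
keep genes abundant in the later condition (FPKM >= 10 in condition B by
default) that are significantly upregulated relative to the earlier one
(linear fold >= 2, q-value <= 0.05, thresholds inclusive), then intersect
with a transcription-factor catalog to obtain candidate regulators.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


def filter_upregulated(
    records: pd.DataFrame,
    fpkm_min: float = 10.0,
    fold_min: float = 2.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Genes with fpkm_b >= fpkm_min, fold >= fold_min and q_value <= q_max.

    Rows with missing q-values cannot assert significance and are dropped
    (their count is logged). Output is sorted by gene_id for stability.
    """
    if fpkm_min <= 0 or fold_min <= 0 or q_max <= 0:
        raise ValueError("thresholds must be positive")
    n_na = int(records["q_value"].isna().sum())
    if n_na:
        logger.warning("%d records with missing q_value excluded", n_na)
    df = records.dropna(subset=["q_value"])
    keep = (
        (df["fpkm_b"] >= fpkm_min)
        & (df["fold"] >= fold_min)
        & (df["q_value"] <= q_max)
    )
    out = df[keep].sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    logger.info(
        "expression filter (FPKM>=%g, fold>=%g, q<=%g): %d of %d genes kept",
        fpkm_min, fold_min, q_max, len(out), len(records),
    )
    return out


def read_tf_catalog(path) -> set[str]:
    """One TF gene symbol per line (e.g. an AnimalTFDB species export)."""
    genes = {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return genes


def restrict_to_tfs(records: pd.DataFrame, catalog: set[str], strict: bool = True) -> pd.DataFrame:
    """Subset records whose gene_id is in the TF catalog (case-insensitive)."""
    if not catalog:
        if strict:
            raise ValueError("TF catalog is empty")
        logger.warning("TF catalog is empty; returning no genes")
        return records.iloc[0:0].reset_index(drop=True)
    upper = {g.upper() for g in catalog}
    keep = records["gene_id"].str.upper().isin(upper)
    out = records[keep].reset_index(drop=True)
    logger.info("TF catalog intersection: %d of %d genes are TFs", len(out), len(records))
    return out
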