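"""miRNA–target confidence tiering and signature annotation.

Predicted miRNA–mRNA pairs are tiered purely by their prediction score:
> 80 high-confidence, < 60 cautious, everything between intermediate.
Signature genes are then annotated with their high-tier regulators and a
per-subtype up/down pattern from the sign of the gene's log2 fold change;
no inverse-correlation requirement is imposed, since miRNA-mediated
regulation need not appear as a linear inverse relationship at the
transcript level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

HIGH_THRESHOLD = 80
CAUTIOUS_THRESHOLD = 60


def tier_of(score: int | float) -> str:
    if not 0 <= score <= 100:
        raise ValueError(f"target score outside [0, 100]: {score}")
    if score > HIGH_THRESHOLD:
        return "high"
    if score < CAUTIOUS_THRESHOLD:
        return "cautious"
    return "intermediate"


def tier_targets(pairs: pd.DataFrame) -> pd.DataFrame:
    """Add a ``tier`` column to a (gene_symbol, mirna_id, target_score)
    table; tiering is a pure function of the score and hence idempotent."""
    out = pairs.copy()
    out["tier"] = out["target_score"].map(tier_of)
    return out


def join_signature_targets(
    pairs: pd.DataFrame, gene_fc: pd.DataFrame
) -> pd.DataFrame:
    """Annotate each gene with its high-tier regulators and per-subtype
    expression pattern.

    ``gene_fc`` is genes × subtypes (gene-level log2FC).  Output has one row
    per (gene, high-tier miRNA) with ``pattern_<subtype>`` ∈ {up, down}
    columns.  An empty join is allowed and warned about.
    """
    tiered = tier_targets(pairs)
    high = tiered[tiered["tier"] == "high"]
    joined = high[high["gene_symbol"].isin(gene_fc.index)]
    if joined.empty:
        warnings.warn("no high-tier regulators overlap the signature genes")
        cols = ["gene_symbol", "mirna_id", "target_score", "tier"] + [
            f"pattern_{s}" for s in gene_fc.columns
        ]
        return pd.DataFrame(columns=cols)
    out = joined.copy()
    for s in gene_fc.columns:
        out[f"pattern_{s}"] = np.where(
            gene_fc.loc[out["gene_symbol"], s].to_numpy() >= 0, "up", "down"
        )
    return out.reset_index(drop=True)


def regulators_of(annotated: pd.DataFrame, gene: str) -> set[str]:
    """High-tier miRNAs predicted to regulate ``gene``."""
    return set(annotated.loc[annotated["gene_symbol"] == gene, "mirna_id"])
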