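"""Pyroptosis Index (PI) and Inflammasome Activation Score (IAS).

Two PI variants are provided.  The "published" variant — the default and
the one that reproduces the reported per-subtype index values — is the
difference between the mean gene-level log2 fold change of the six
pro-pyroptotic genes and that of the three anti-pyroptotic genes, with
gene-level values taken from the first listed probe per gene.  The "stated"
variant follows the index's verbal definition instead: a signed
log2(1+|FC|) transform per gene, Z-score standardization across samples,
then the same mean difference per sample.  The stated variant is bounded by
the Z-scale (order ±√n) and cannot reach the published subtype values; both
are kept because they answer different questions (cohort-relative ranking
vs absolute fold-change contrast).

The IAS is the arithmetic mean of the log2 fold changes of a ten-gene
inflammasome panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import registry
from .registry import ANTI_PYROPTOTIC, CORE9, INFLAMMASOME_PANEL, PRO_PYROPTOTIC


@dataclass(frozen=True)
class SignatureScore:
    scope: str  # subtype or sample id
    score_type: str  # "PI_published", "PI_stated" or "IAS"
    value: float
    pro_mean: float | None = None
    anti_mean: float | None = None
    aggregation_rule: str | None = None


def aggregate_probes(
    table: pd.DataFrame, rule: str = "first", value_cols: list[str] | None = None
) -> pd.DataFrame:
    """Collapse probe-level fold changes to one value per gene.

    ``table`` needs ``gene_symbol`` and ``list_rank`` columns (probe order
    within each gene's block); ``rule`` is ``first`` (probe with list_rank
    1), ``mean`` or ``median``.
    """
    if rule not in {"first", "mean", "median"}:
        raise ValueError(f"unknown aggregation rule: {rule!r}")
    if value_cols is None:
        value_cols = [
            c for c in table.columns
            if c not in {"probe_id", "gene_symbol", "list_rank"}
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    if not value_cols:
        raise ValueError("no value columns to aggregate")
    tbl = table.copy()
    tbl["gene_symbol"] = tbl["gene_symbol"].map(registry.canonical_symbol)
    if rule == "first":
        if "list_rank" not in tbl.columns:
            raise ValueError("rule='first' requires a list_rank column")
        out = (
            tbl.sort_values("list_rank")
            .groupby("gene_symbol", sort=False)[value_cols]
            .first()
        )
    else:
        out = tbl.groupby("gene_symbol", sort=False)[value_cols].agg(rule)
    empty = out.index[out[value_cols].isna().all(axis=1)]
    if len(empty):
        raise ValueError(f"gene(s) with no probes: {', '.join(empty)}")
    return out.sort_index()


def _check_genes(index, needed: frozenset[str], what: str) -> None:
    missing = needed - set(index)
    if missing:
        raise ValueError(f"missing {what} gene(s): {', '.join(sorted(missing))}")


def pyroptosis_index_published(gene_fc: pd.Series, scope: str = "") -> SignatureScore:
    """PI = mean(log2FC over pro-pyroptotic) − mean(log2FC over
    anti-pyroptotic) for one subtype's gene-level fold changes."""
    gene_fc = gene_fc.rename(index=registry.canonical_symbol)
    _check_genes(gene_fc.index, CORE9, "core signature")
    pro = float(gene_fc[list(PRO_PYROPTOTIC)].mean())
    anti = float(gene_fc[list(ANTI_PYROPTOTIC)].mean())
    return SignatureScore(
        scope=scope,
        score_type="PI_published",
        value=pro - anti,
        pro_mean=pro,
        anti_mean=anti,
    )


def _signed_log2_1p(x: np.ndarray) -> np.ndarray:
    # log2(1+FC) is undefined for FC <= -1; the signed extension keeps the
    # transform odd and monotone over the whole real line
    return np.sign(x) * np.log2(1.0 + np.abs(x))


def pyroptosis_index_stated(values: pd.DataFrame) -> pd.Series:
    """Per-sample PI from the verbal definition: signed log2(1+|FC|)
    transform, per-gene Z-score across samples (SD 0 maps to Z = 0), then
    mean Z(pro) − mean Z(anti) per sample.

    ``values`` is genes × samples over the nine core genes; needs ≥2
    samples for the Z-scores to exist.
    """
    values = values.rename(index=registry.canonical_symbol)
    _check_genes(values.index, CORE9, "core signature")
    if values.shape[1] < 2:
        raise ValueError("Z-score standardization requires at least 2 samples")
    t = _signed_log2_1p(values.loc[sorted(CORE9)].to_numpy(dtype=float))
    mu = t.mean(axis=1, keepdims=True)
    sd = t.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (t - mu) / sd, 0.0)
    zdf = pd.DataFrame(z, index=sorted(CORE9), columns=values.columns)
    pi = zdf.loc[list(PRO_PYROPTOTIC)].mean() - zdf.loc[list(ANTI_PYROPTOTIC)].mean()
    pi.name = "PI_stated"
    return pi


def inflammasome_activation_score(gene_fc: pd.Series, scope: str = "") -> SignatureScore:
    """IAS = arithmetic mean of the ten inflammasome-panel log2FC values."""
    gene_fc = gene_fc.rename(index=registry.canonical_symbol)
    _check_genes(gene_fc.index, INFLAMMASOME_PANEL, "inflammasome panel")
    return SignatureScore(
        scope=scope,
        score_type="IAS",
        value=float(gene_fc[list(INFLAMMASOME_PANEL)].mean()),
    )


def subtype_pi_table(
    fc_table: pd.DataFrame, rule: str = "first", subtypes: list[str] | None = None
) -> pd.DataFrame:
    """PI per subtype from a probe-level fold-change table (one numeric
    column per subtype, e.g. the packaged fold-change fixture)."""
    gene_fc = aggregate_probes(fc_table, rule=rule)
    if subtypes is None:
        subtypes = list(gene_fc.columns)
    rows = []
    for s in subtypes:
        score = pyroptosis_index_published(gene_fc[s], scope=s)
        rows.append((s, score.value, score.pro_mean, score.anti_mean))
    return pd.DataFrame(rows, columns=["subtype", "PI", "pro_mean", "anti_mean"])
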