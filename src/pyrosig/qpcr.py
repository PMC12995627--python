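"""Relative qPCR quantification by the 2^−ΔΔCt method.

Each sample's target Ct is normalized to the reference gene (ΔCt), then to
the mean ΔCt of the calibrator group (ΔΔCt); the fold change is 2^−ΔΔCt,
so FC = 1 marks the calibrator level, > 1 upregulation, < 1 downregulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCE = "ACTB"


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "gene_symbol", "group", "Ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if (table["Ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table.pivot_table(index=["sample_id", "group"], columns="gene_symbol", values="Ct")


def ddct_fold_change(
    table: pd.DataFrame,
    gene: str,
    group: str,
    reference: str = DEFAULT_REFERENCE,
    calibrator: str = "control",
) -> pd.Series:
    """Per-sample 2^−ΔΔCt fold change of ``gene`` in ``group`` relative to
    the calibrator group's mean ΔCt."""
    wide = _pivot(table)
    for g in (gene, reference):
        if g not in wide.columns:
            raise ValueError(f"gene {g!r} absent from Ct table")
    if wide[reference].isna().any():
        bad = wide.index[wide[reference].isna()][0][0]
        raise ValueError(f"missing reference Ct for sample {bad!r}")
    dct = wide[gene] - wide[reference]
    groups = wide.index.get_level_values("group")
    cal = dct[groups == calibrator].dropna()
    if cal.empty:
        raise ValueError(f"empty calibrator group {calibrator!r}")
    ddct = dct[groups == group].dropna() - cal.mean()
    fc = np.power(2.0, -ddct)
    fc.name = f"FC_{gene}"
    return fc.droplevel("group")


def summarize_fc(fc: pd.Series | np.ndarray, alpha: float = 0.05) -> dict:
    """Mean ± SD of per-sample fold changes plus a two-sided one-sample
    t-test of log2(FC) against 0 (i.e. FC against baseline 1)."""
    values = np.asarray(fc, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples to summarize")
    log_fc = np.log2(values)
    if np.allclose(log_fc, log_fc[0]):
        p = 1.0 if np.allclose(log_fc, 0.0) else 0.0
        # zero variance: degenerate t-test; exact equality to baseline is
        # "no evidence", any constant offset is unambiguous change
    else:
        p = float(stats.ttest_1samp(log_fc, 0.0).pvalue)
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "n": int(values.size),
        "p": p,
        "significant": p < alpha,
    }
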