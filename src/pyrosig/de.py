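"""Differential-expression screen with subtype intersection.

The screen runs a classical one-way ANOVA per probe across the six tissue
classes (pooled control plus the five tumor subtypes), corrects the ANOVA
p-values across probes with Benjamini–Hochberg within each subtype-contrast
family, confirms each subtype-vs-control contrast with Tukey's HSD, applies
the effect-size filter (|log2FC| > 3, strict), and intersects the five
per-subtype significant gene sets.  Genes in all five sets form the
subtype-independent ("universal") signature; the direction of change is NOT
required to agree across subtypes — the criterion is magnitude per
comparison.

ANOVA and the Tukey decision are vectorized over probes so full synthetic
cohorts screen in milliseconds; the Tukey flag compares the studentized
range statistic q against the α critical value, which is equivalent to
thresholding its p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

CONTROL_LABEL = "control"


def estimate_log2fc(matrix: ExpressionMatrix, subtype: str) -> pd.Series:
    """Per-probe mean(log2 tumor) − mean(log2 control) for one subtype."""
    meta = matrix.sample_meta
    tum = meta.index[(meta["subtype"] == subtype) & (meta["group"] == "tumor")]
    ctl = meta.index[(meta["subtype"] == subtype) & (meta["group"] == "control")]
    if len(tum) < 2 or len(ctl) < 2:
        raise ValueError(
            f"subtype {subtype!r}: need >=2 tumor and >=2 control samples"
        )
    return matrix.values[list(tum)].mean(axis=1) - matrix.values[list(ctl)].mean(axis=1)


def _tissue_groups(matrix: ExpressionMatrix) -> dict[str, list[str]]:
    """Six tissue classes: all controls pooled, tumors split by subtype."""
    meta = matrix.sample_meta
    groups: dict[str, list[str]] = {
        CONTROL_LABEL: list(meta.index[meta["group"] == "control"])
    }
    for s in sorted(meta.loc[meta["group"] == "tumor", "subtype"].unique()):
        groups[s] = list(meta.index[(meta["subtype"] == s) & (meta["group"] == "tumor")])
    return groups


def _anova_components(matrix: ExpressionMatrix):
    groups = _tissue_groups(matrix)
    for name, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    X = matrix.values
    n_g = np.array([len(cols) for cols in groups.values()])
    means = np.column_stack([X[cols].mean(axis=1).to_numpy() for cols in groups.values()])
    grand = (means * n_g).sum(axis=1) / n_g.sum()
    ssb = ((means - grand[:, None]) ** 2 * n_g).sum(axis=1)
    ssw = np.zeros(X.shape[0])
    for j, cols in enumerate(groups.values()):
        ssw += ((X[cols].to_numpy() - means[:, j][:, None]) ** 2).sum(axis=1)
    df_b = k - 1
    df_w = int(n_g.sum()) - k
    return groups, means, n_g, ssb / df_b, ssw / df_w, df_b, df_w


def anova_screen(matrix: ExpressionMatrix) -> pd.DataFrame:
    """One-way F statistic and upper-tail p per probe across tissue classes.

    Probes with zero within-group variance everywhere get NaN p and are
    flagged ``degenerate`` for downstream exclusion.
    """
    _, _, _, msb, msw, df_b, df_w = _anova_components(matrix)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    p = stats.f.sf(F, df_b, df_w)
    degenerate = msw == 0
    F = np.where(degenerate, np.nan, F)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {"F_stat": F, "p_raw": p, "degenerate": degenerate}, index=matrix.values.index
    )


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    p_adj(i) = min over j >= rank(i) of p(j)·m/j, capped at 1.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


@lru_cache(maxsize=64)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_hsd(groups: list[np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Tukey HSD comparisons.

    q = |mean_i − mean_j| / sqrt(MSW/2 · (1/n_i + 1/n_j)); p from the
    studentized range distribution with k groups and N−k degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    n = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_w = int(n.sum()) - k
    msw = ssw / df_w
    if msw == 0:
        raise ValueError("zero within-group variance: Tukey q undefined")
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(msw / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
        q = abs(means[i] - means[j]) / se
        p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append((i, j, q, p, p < alpha))
    return pd.DataFrame(rows, columns=["group_i", "group_j", "q", "p", "significant"])


def screen(matrix: ExpressionMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Build the per-(probe, subtype) fold-change table.

    Columns: gene_symbol (when a probe→gene map is attached), subtype,
    log2FC, F_stat, p_raw (ANOVA), p_adj (BH across probes within the
    subtype family), tukey_significant (subtype-vs-control HSD at α).
    """
    groups, means, n_g, msb, msw, df_b, df_w = _anova_components(matrix)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    p = stats.f.sf(F, df_b, df_w)
    degenerate = msw == 0
    p = np.where(degenerate, np.nan, p)

    names = list(groups)
    k = len(names)
    ctrl_idx = names.index(CONTROL_LABEL)
    qc = _q_crit(alpha, k, df_w)
    subtypes = [s for s in names if s != CONTROL_LABEL]

    frames = []
    for s in subtypes:
        j = names.index(s)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(msw / 2.0 * (1.0 / n_g[j] + 1.0 / n_g[ctrl_idx]))
            q = np.abs(means[:, j] - means[:, ctrl_idx]) / se
        ok = ~degenerate & ~np.isnan(p)
        p_adj = np.full_like(p, np.nan)
        if ok.any():
            p_adj[ok] = adjust_bh(p[ok])
        frame = pd.DataFrame(
            {
                "probe_id": matrix.values.index,
                "subtype": s,
                "log2FC": estimate_log2fc(matrix, s).to_numpy(),
                "F_stat": np.where(degenerate, np.nan, F),
                "p_raw": p,
                "p_adj": p_adj,
                "tukey_significant": ok & (q > qc),
            }
        )
        if matrix.probe_genes is not None:
            frame.insert(1, "gene_symbol", matrix.probe_genes.to_numpy())
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def filter_de(
    table: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 3.0
) -> dict[str, set[str]]:
    """Per-subtype significant gene sets.

    A probe passes for a subtype iff p_adj < α AND |log2FC| > threshold AND
    the Tukey subtype-vs-control contrast is significant (all strict); a
    gene passes iff at least one of its probes passes.
    """
    key = "gene_symbol" if "gene_symbol" in table.columns else "probe_id"
    passing = table[
        (table["p_adj"] < alpha)
        & (table["log2FC"].abs() > fc_threshold)
        & table["tukey_significant"].astype(bool)
    ]
    return {
        s: set(passing.loc[passing["subtype"] == s, key])
        for s in table["subtype"].unique()
    }


@dataclass(frozen=True)
class VennPartition:
    """Membership of each gene across the five per-subtype sets."""

    membership: pd.DataFrame  # genes × subtypes, boolean
    universal_set: frozenset[str]

    def cell_counts(self) -> dict[tuple[str, ...], int]:
        """Counts of the disjoint partition cells, keyed by the sorted tuple
        of subtypes a gene is significant in (empty tuple excluded)."""
        counts: dict[tuple[str, ...], int] = {}
        for _, row in self.membership.iterrows():
            key = tuple(c for c in self.membership.columns if row[c])
            if key:
                counts[key] = counts.get(key, 0) + 1
        return counts


def intersect_subtypes(sets: dict[str, set[str]]) -> VennPartition:
    """Five-way intersection of per-subtype significant gene sets."""
    if len(sets) < 5:
        raise ValueError(f"need 5 per-subtype sets, got {len(sets)}")
    universe = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {name: [g in genes for g in universe] for name, genes in sets.items()},
        index=pd.Index(universe, name="gene_symbol"),
    )
    universal = frozenset.intersection(*(frozenset(v) for v in sets.values()))
    return VennPartition(membership=membership, universal_set=universal)


def run_screen(
    matrix: ExpressionMatrix, alpha: float = 0.05, fc_threshold: float = 3.0
) -> tuple[pd.DataFrame, dict[str, set[str]], VennPartition]:
    """Full screen: fold-change table, per-subtype sets, Venn partition."""
    table = screen(matrix, alpha=alpha)
    sets = filter_de(table, alpha=alpha, fc_threshold=fc_threshold)
    return table, sets, intersect_subtypes(sets)
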