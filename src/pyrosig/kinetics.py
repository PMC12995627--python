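"""Post-cryoablation longitudinal dynamics.

Blood-borne analytes sampled on the fixed grid T0 (pre-procedure) through
T6 (3 months) show a pulse-shaped response: a rapid rise, a peak around
8–12 h (T2) and a slow return toward baseline.  This module locates the
peak, finds the earliest durable return to a baseline band, and recomputes
per-time-point significance from replicate-level values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: nominal hour coordinate of each sampling point; T1–T6 use the midpoint
#: of the protocol window (30–60 min, 8–12 h, 48–72 h, 7 d, 1 mo, 3 mo)
TIME_GRID: dict[str, float] = {
    "T0": 0.0,
    "T1": 0.75,
    "T2": 10.0,
    "T3": 60.0,
    "T4": 168.0,
    "T5": 720.0,
    "T6": 2160.0,
}

TIME_POINTS: tuple[str, ...] = tuple(TIME_GRID)


@dataclass
class LongitudinalSeries:
    """One analyte's ordered time course of means ± SD.

    ``level`` distinguishes mRNA fold changes (baseline 1.0, T0 implicit)
    from protein concentrations (baseline = T0 mean).  ``replicates``
    optionally holds per-subject values per time point for significance
    recomputation.
    """

    analyte: str
    level: str  # "mrna_fc" or "protein"
    means: pd.Series  # indexed by time point label
    sds: pd.Series
    significant: pd.Series | None = None
    replicates: pd.DataFrame | None = field(default=None)  # subjects × time points

    def __post_init__(self) -> None:
        order = [t for t in TIME_POINTS if t in self.means.index]
        if list(self.means.index) != order:
            raise ValueError("time points out of order")
        if (self.sds < 0).any():
            raise ValueError("negative SD")

    @property
    def baseline(self) -> float:
        if self.level == "mrna_fc":
            return 1.0
        if "T0" not in self.means.index:
            raise ValueError("protein series requires a T0 baseline point")
        return float(self.means["T0"])


def series_from_fixture(fixture, level: str) -> list[LongitudinalSeries]:
    """Convert a loaded longitudinal fixture table (mRNA fold changes or
    protein concentrations) into LongitudinalSeries objects."""
    out = []
    points = [t for t in TIME_POINTS if t in fixture.table.columns]
    for _, row in fixture.table.iterrows():
        name = row.get("gene_symbol", row.get("protein"))
        out.append(
            LongitudinalSeries(
                analyte=str(name),
                level=level,
                means=pd.Series({t: row[t] for t in points}),
                sds=pd.Series({t: row[f"{t}_sd"] for t in points}),
                significant=pd.Series({t: row[f"{t}_sig"] for t in points}),
            )
        )
    return out


def detect_peak(series: LongitudinalSeries) -> tuple[str, float]:
    """Argmax of the mean over post-baseline points, earliest point on ties."""
    post = series.means.drop(index="T0", errors="ignore")
    if len(post) < 2:
        raise ValueError("need at least two post-baseline points")
    best = post.idxmax()  # first occurrence wins ties
    return str(best), float(post[best])


def time_to_baseline(series: LongitudinalSeries, band: float = 0.15) -> str | None:
    """Earliest post-peak time point whose mean sits within ``band`` relative
    tolerance of baseline, with all later points also inside the band."""
    if band <= 0:
        raise ValueError("band must be positive")
    base = series.baseline
    peak_time, _ = detect_peak(series)
    post = series.means.drop(index="T0", errors="ignore")
    labels = list(post.index)
    start = labels.index(peak_time)
    within = np.abs(post.to_numpy() / base - 1.0) <= band
    for i in range(start, len(labels)):
        if within[i:].all():
            return labels[i]
    return None


def paired_vs_baseline(t0: np.ndarray, tk: np.ndarray) -> float:
    """Two-sided paired t-test of log values at Tk against T0.

    Returns 1.0 when all paired differences vanish (degenerate but
    unambiguous: no change)."""
    t0 = np.asarray(t0, dtype=float)
    tk = np.asarray(tk, dtype=float)
    if t0.shape != tk.shape:
        raise ValueError("unpaired input: T0 and Tk lengths differ")
    if t0.size < 2:
        raise ValueError("need n >= 2 paired subjects")
    diffs = np.log(tk) - np.log(t0)
    if np.allclose(diffs, 0.0):
        return 1.0
    return float(stats.ttest_rel(np.log(tk), np.log(t0)).pvalue)


def significance_profile(series: LongitudinalSeries, alpha: float = 0.05) -> pd.Series:
    """Per-time-point p-values vs T0 from replicate-level values."""
    if series.replicates is None or "T0" not in series.replicates.columns:
        raise ValueError("replicate-level values with a T0 column are required")
    reps = series.replicates
    pvals = {}
    for t in reps.columns:
        if t == "T0":
            continue
        pvals[t] = paired_vs_baseline(reps["T0"].to_numpy(), reps[t].to_numpy())
    return pd.Series(pvals)
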