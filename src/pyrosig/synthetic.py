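"""Synthetic cohort generation.

Generates inputs with the statistical structure the analysis assumes — a
five-subtype paired tumor/control expression matrix with planted
subtype-independent ("universal"), subtype-specific and null genes, qPCR Ct
tables whose implied 2^−ΔΔCt fold changes match the planted effects,
pulse-shaped post-cryoablation time courses peaking near 8–12 h, and
miRNA–target score tables — so every pipeline stage is testable without the
original arrays.

Default cohort sizes scale the study's 130/100/96/36/43 subjects per
subtype down by a factor of five; expression noise is additive on the log2
scale (SD 0.8), the microarray convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .kinetics import TIME_GRID, LongitudinalSeries
from .registry import SUBTYPES

#: study sizes 130/100/96/36/43 scaled down 5x
DEFAULT_PAIRS: dict[str, int] = {
    "LumA": 26,
    "LumB_HER2neg": 20,
    "LumB_HER2pos": 19,
    "NonLum_HER2pos": 7,
    "TNBC": 9,
}

#: pulse amplitudes matching the observed mRNA peak fold changes at T2
DEFAULT_AMPLITUDES: dict[str, float] = {
    "CXCL8": 1.10,
    "BCL2": 0.10,
    "BAX": 0.80,
    "CASP1": 0.95,
    "CASP9": 0.70,
    "TP53": 0.55,
    "CDKN1A": 0.35,
    "CDKN1B": 0.25,
    "MMP9": 1.00,
}


@dataclass
class KineticsConfig:
    amplitudes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    tau: float = 10.0  # peak time in hours (the T2 grid coordinate)
    baseline: float = 1.0
    noise_sd: float = 0.15
    n_replicates: int = 34


@dataclass
class SyntheticConfig:
    """Knobs for all generators; ``seed`` makes every output reproducible."""

    seed: int = 0
    n_pairs_per_subtype: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PAIRS))
    n_universal: int = 9
    n_subtype_specific: int = 40
    n_null: int = 500
    universal_effects: dict[str, float] | None = None  # gene -> signed log2FC, |v|>3
    specific_effects: dict[str, dict[str, float]] | None = None  # gene -> subtype -> log2FC
    noise_sd: float = 0.8
    probes_per_gene: int = 1
    ct_noise_sd: float = 0.2
    reference_gene: str = "ACTB"
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for s, n in self.n_pairs_per_subtype.items():
            if n < 2:
                raise ValueError(f"n_pairs_per_subtype[{s!r}] < 2: variance undefined")
        if self.universal_effects is not None:
            for g, v in self.universal_effects.items():
                if abs(v) <= 3:
                    raise ValueError(f"universal effect for {g} must exceed |3|, got {v}")


def _default_effects(config: SyntheticConfig, rng: np.random.Generator):
    """Per-gene planted log2FC: universal genes get one signed magnitude in
    [4, 6] applied to every subtype; specific genes one subtype each."""
    universal = config.universal_effects
    if universal is None:
        universal = {}
        for i in range(config.n_universal):
            mag = rng.uniform(4.0, 6.0)
            sign = rng.choice([-1.0, 1.0])
            universal[f"UNIV{i + 1:03d}"] = sign * mag
    specific = config.specific_effects
    if specific is None:
        specific = {}
        subtypes = list(config.n_pairs_per_subtype)
        for i in range(config.n_subtype_specific):
            mag = rng.uniform(4.0, 6.0)
            sign = rng.choice([-1.0, 1.0])
            specific[f"SPEC{i + 1:03d}"] = {subtypes[i % len(subtypes)]: sign * mag}
    return universal, specific


def generate_cohort(config: SyntheticConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a paired tumor/control cohort.

    Control expression per probe is a gene baseline plus N(0, noise_sd) on
    the log2 scale; tumor expression adds the planted log2FC.  Returns the
    matrix and a truth table with one row per gene (class and planted
    per-subtype log2FC), the ground truth for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    universal, specific = _default_effects(config, rng)

    genes = list(universal) + list(specific) + [
        f"NULL{i + 1:04d}" for i in range(config.n_null)
    ]
    subtypes = list(config.n_pairs_per_subtype)
    effect = pd.DataFrame(0.0, index=genes, columns=subtypes)
    for g, v in universal.items():
        effect.loc[g, :] = v
    for g, per_sub in specific.items():
        for s, v in per_sub.items():
            effect.loc[g, s] = v

    truth = pd.DataFrame(
        {
            "gene_symbol": genes,
            "class": (
                ["universal"] * len(universal)
                + ["subtype_specific"] * len(specific)
                + ["null"] * config.n_null
            ),
        }
    )
    for s in subtypes:
        truth[f"fc_{s}"] = effect[s].to_numpy()

    baseline = rng.uniform(6.0, 12.0, size=len(genes))
    k = config.probes_per_gene
    probe_offsets = rng.normal(0.0, 0.1, size=(len(genes), k)) if k > 1 else np.zeros((len(genes), 1))

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for s in subtypes:
        n = config.n_pairs_per_subtype[s]
        for i in range(n):
            subj = f"{s}_subj{i + 1:03d}"
            pair = f"{s}_pair{i + 1:03d}"
            ctrl = baseline[:, None] + probe_offsets + rng.normal(
                0.0, config.noise_sd, size=(len(genes), k)
            )
            tum = baseline[:, None] + probe_offsets + effect[s].to_numpy()[:, None] + rng.normal(
                0.0, config.noise_sd, size=(len(genes), k)
            )
            columns[f"{pair}_T"] = tum.ravel()
            columns[f"{pair}_C"] = ctrl.ravel()
            meta_rows.append((f"{pair}_T", subj, s, "tumor", pair))
            meta_rows.append((f"{pair}_C", subj, s, "control", pair))

    probe_ids = [f"{g}_p{j + 1}_at" for g in genes for j in range(k)]
    probe_genes = pd.Series(
        [g for g in genes for _ in range(k)], index=probe_ids, name="gene_symbol"
    )
    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "subtype", "group", "pair_id"]
    ).set_index("sample_id")
    matrix = ExpressionMatrix(values=values, sample_meta=meta, probe_genes=probe_genes)
    return matrix, truth


def generate_ct_table(
    config: SyntheticConfig,
    planted_fc: dict[str, float] | None = None,
    n_per_group: int = 20,
) -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table (sample, gene, group, Ct).

    The planted linear fold change of each target gene is encoded in the
    tumor-group ΔCt (ΔΔCt = −log2 FC); the reference gene's Ct is constant
    across groups up to noise, so 2^−ΔΔCt recovers the planted effects.
    """
    config.validate()
    if not config.reference_gene:
        raise ValueError("missing reference gene")
    if planted_fc is None:
        planted_fc = {"CXCL8": 4.0}
    rng = np.random.default_rng(config.seed + 1)
    sd = config.ct_noise_sd
    rows = []
    base_dct = {g: rng.uniform(4.0, 8.0) for g in planted_fc}
    for group, shift in (("control", {g: 0.0 for g in planted_fc}),
                         ("tumor", {g: -np.log2(fc) for g, fc in planted_fc.items()})):
        for i in range(n_per_group):
            sample = f"{group}_{i + 1:03d}"
            ct_ref = 15.0 + rng.normal(0.0, sd)
            rows.append((sample, config.reference_gene, group, ct_ref))
            for g in planted_fc:
                ct = ct_ref + base_dct[g] + shift[g] + rng.normal(0.0, sd)
                rows.append((sample, g, group, ct))
    return pd.DataFrame(rows, columns=["sample_id", "gene_symbol", "group", "Ct"])


def pulse(t: np.ndarray | float, amplitude: float, tau: float, baseline: float = 1.0):
    """Gamma-like pulse ``baseline + A·(t/τ)·exp(1 − t/τ)``: value =
    baseline at t=0, maximum baseline + A exactly at t=τ."""
    t = np.asarray(t, dtype=float)
    return baseline + amplitude * (t / tau) * np.exp(1.0 - t / tau)


def generate_longitudinal_panel(config: SyntheticConfig) -> list[LongitudinalSeries]:
    """Simulate replicate-level fold-change trajectories on the T0–T6 grid."""
    config.validate()
    kin = config.kinetics
    rng = np.random.default_rng(config.seed + 2)
    hours = np.array(list(TIME_GRID.values()))
    labels = list(TIME_GRID)
    out = []
    for analyte, amp in kin.amplitudes.items():
        if amp < 0:
            raise ValueError(f"amplitude for {analyte} must be non-negative")
        traj = pulse(hours, amp, kin.tau, kin.baseline)
        reps = traj[None, :] + rng.normal(0.0, kin.noise_sd, size=(kin.n_replicates, len(hours)))
        reps_df = pd.DataFrame(reps, columns=labels)
        out.append(
            LongitudinalSeries(
                analyte=analyte,
                level="mrna_fc",
                means=reps_df.mean(),
                sds=reps_df.std(ddof=1),
                replicates=reps_df,
            )
        )
    return out


def generate_protein_panel(
    config: SyntheticConfig,
    base_conc: dict[str, float] | None = None,
    beta: float = 1.0,
) -> list[LongitudinalSeries]:
    """Protein time courses derived from the mRNA pulse through a monotone
    power link conc = base·FC^β with lognormal noise."""
    if base_conc is None:
        base_conc = {a: 1.0 for a in config.kinetics.amplitudes}
    kin = config.kinetics
    rng = np.random.default_rng(config.seed + 3)
    hours = np.array(list(TIME_GRID.values()))
    labels = list(TIME_GRID)
    out = []
    for analyte, amp in kin.amplitudes.items():
        fc = pulse(hours, amp, kin.tau, kin.baseline)
        conc = base_conc.get(analyte, 1.0) * fc**beta
        reps = conc[None, :] * np.exp(
            rng.normal(0.0, kin.noise_sd / 2, size=(kin.n_replicates, len(hours)))
        )
        reps_df = pd.DataFrame(reps, columns=labels)
        out.append(
            LongitudinalSeries(
                analyte=analyte,
                level="protein",
                means=reps_df.mean(),
                sds=reps_df.std(ddof=1),
                replicates=reps_df,
            )
        )
    return out


def generate_target_pairs(
    config: SyntheticConfig,
    genes: list[str],
    mirnas_per_gene: int = 2,
    fixture_pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Random miRNA–target pairs with integer scores uniform on [50, 99];
    rows of ``fixture_pairs`` (gene, miRNA, score) are appended verbatim."""
    if not genes:
        raise ValueError("empty gene list")
    rng = np.random.default_rng(config.seed + 4)
    rows = []
    for g in genes:
        for j in range(mirnas_per_gene):
            score = int(rng.integers(50, 100))
            rows.append((g, f"hsa-miR-sim-{g}-{j + 1}", score))
    df = pd.DataFrame(rows, columns=["gene_symbol", "mirna_id", "target_score"])
    if fixture_pairs is not None:
        df = pd.concat(
            [fixture_pairs[["gene_symbol", "mirna_id", "target_score"]], df],
            ignore_index=True,
        )
    return df
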