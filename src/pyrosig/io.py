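"""Tabular I/O and packaged reference tables.

Everything the pipeline reads or writes is plain text: expression matrices
as TSV/CSV with a ``#meta`` header block carrying per-sample metadata,
interaction graphs as two-column edge lists, and reports as TSV.  The
printed summary tables of the source study (primer sequences, fold-change
tables, protein panels, longitudinal panels, signature scores) ship as
versioned fixtures inside the package and are exposed through
:func:`load_paper_fixture`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

FIXTURE_NAMES = tuple(f"table{i}" for i in range(1, 9))

#: tables whose cells are printed as "mean ± SD" with a significance star
_MEASUREMENT_TABLES = {"table3", "table4", "table5", "table6"}

_CELL_RE = re.compile(r"^(-?\d+(?:\.\d+)?)\s*±\s*(\d+(?:\.\d+)?)(\**)$")


class FixtureError(KeyError):
    """Raised for an unknown fixture name."""


@dataclass(frozen=True)
class PaperFixture:
    """A packaged printed table, parsed into a typed DataFrame."""

    name: str
    table: pd.DataFrame


@dataclass
class ExpressionMatrix:
    """Probe × sample log2-intensity matrix with per-sample metadata.

    ``values`` is indexed by probe id with one column per sample;
    ``sample_meta`` is indexed by sample id with columns
    ``subject_id, subtype, group, pair_id``.  ``probe_genes`` optionally
    maps probe ids to gene symbols (needed by gene-level aggregation).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    probe_genes: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe id(s): {', '.join(map(str, dupes))}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("sample columns and metadata rows do not match")
        required = {"subject_id", "subtype", "group", "pair_id"}
        missing_cols = required - set(self.sample_meta.columns)
        if missing_cols:
            raise ValueError(f"sample metadata lacks columns: {sorted(missing_cols)}")
        if self.sample_meta[["subtype", "group"]].isna().any().any():
            raise ValueError("every sample must carry subtype and group")
        bad_group = set(self.sample_meta["group"]) - {"tumor", "control"}
        if bad_group:
            raise ValueError(f"unknown group label(s): {sorted(bad_group)}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ValueError("non-numeric expression cell")
        if np.isnan(self.values.to_numpy()).any():
            raise ValueError("missing expression values are not allowed")
        # each pair id must pair exactly one tumor with one control sample
        counts = self.sample_meta.groupby("pair_id")["group"].agg(
            lambda g: tuple(sorted(g))
        )
        bad = counts[counts != ("control", "tumor")]
        if len(bad):
            raise ValueError(f"unbalanced pair id(s): {', '.join(map(str, bad.index))}")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _normalize_minus(text: str) -> str:
    return text.replace("−", "-")


def _parse_measurement_cell(cell: str) -> tuple[float, float, bool]:
    m = _CELL_RE.match(_normalize_minus(cell).strip())
    if m is None:
        raise ValueError(f"unparseable measurement cell: {cell!r}")
    return float(m.group(1)), float(m.group(2)), bool(m.group(3))


def load_paper_fixture(name: str) -> PaperFixture:
    """Load one of the packaged printed tables (``table1`` … ``table8``).

    Measurement tables (3–6) are expanded so a printed ``m ± s*`` cell
    becomes three typed columns ``<col>``, ``<col>_sd`` and ``<col>_sig``.
    Repeated calls return identical content.
    """
    if name not in FIXTURE_NAMES:
        raise FixtureError(f"no such fixture: {name!r}")
    ref = resources.files("pyrosig.fixtures").joinpath(f"{name}.tsv")
    raw = _normalize_minus(ref.read_text(encoding="utf-8"))
    from io import StringIO

    df = pd.read_csv(StringIO(raw), sep="\t", dtype=str)
    out: dict[str, object] = {}
    for col in df.columns:
        series = df[col]
        if name in _MEASUREMENT_TABLES and series.str.contains("±").all():
            parsed = series.map(_parse_measurement_cell)
            out[col] = [p[0] for p in parsed]
            out[f"{col}_sd"] = [p[1] for p in parsed]
            out[f"{col}_sig"] = [p[2] for p in parsed]
        else:
            try:
                out[col] = pd.to_numeric(series)
            except (ValueError, TypeError):
                out[col] = series
    return PaperFixture(name=name, table=pd.DataFrame(out))


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    meta_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a probe × sample matrix with its ``#meta`` header block.

    Metadata rows are ``#meta<sep>sample<sep>subject<sep>subtype<sep>group
    <sep>pair_id`` and precede the probe table; a side-car metadata file may
    be supplied instead via ``meta_path``.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    path = Path(path)
    meta_rows: list[list[str]] = []
    data_lines: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#meta"):
            meta_rows.append(line.split(sep)[1:])
        elif line and not line.startswith("#"):
            data_lines.append(line)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep=sep, dtype=str).set_index("sample_id")
    elif meta_rows:
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "subject_id", "subtype", "group", "pair_id"]
        ).set_index("sample_id")
    else:
        raise ValueError("no sample metadata found (#meta block or side-car file)")

    from io import StringIO

    df = pd.read_csv(
        StringIO("\n".join(data_lines)), sep=sep, dtype=str, keep_default_na=False
    )
    probe_col = df.columns[0]
    if df[probe_col].duplicated().any():
        dup = df.loc[df[probe_col].duplicated(), probe_col].iloc[0]
        raise ValueError(f"duplicate probe: {dup}")
    df = df.set_index(probe_col)
    gene_col = None
    if "gene_symbol" in df.columns:
        gene_col = df.pop("gene_symbol")
    try:
        # float() round-trips repr() exactly, preserving write→read identity
        values = df.map(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric expression cell: {exc}") from exc
    missing = set(values.columns) - set(meta.index)
    if missing:
        raise ValueError(f"sample(s) without metadata: {sorted(missing)}")
    meta = meta.loc[list(values.columns)]
    return ExpressionMatrix(values=values, sample_meta=meta, probe_genes=gene_col)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the single-file TSV layout read back by
    :func:`read_expression_matrix` (exact round-trip)."""
    path = Path(path)
    lines = []
    for sample, row in matrix.sample_meta.iterrows():
        lines.append(
            "\t".join(
                ["#meta", str(sample), str(row["subject_id"]), str(row["subtype"]),
                 str(row["group"]), str(row["pair_id"])]
            )
        )
    header = ["probe_id"]
    if matrix.probe_genes is not None:
        header.append("gene_symbol")
    header += list(matrix.values.columns)
    lines.append("\t".join(header))
    for probe, row in matrix.values.iterrows():
        cells = [str(probe)]
        if matrix.probe_genes is not None:
            cells.append(str(matrix.probe_genes.loc[probe]))
        cells += [repr(float(v)) for v in row]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column whitespace-separated edge list into a simple
    undirected graph; duplicate and reversed duplicate pairs collapse."""
    g = nx.Graph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected two columns, got {len(parts)}")
        a, b = parts
        if a == b:
            raise ValueError(f"line {lineno}: self-loop on node {a!r}")
        g.add_edge(a, b)
    return g


def _format_cell(col: str, value: object) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        name = col.lower()
        if name.startswith("p_") or name in {"p", "p_value", "pvalue"}:
            return f"{value:.3e}"
        return f"{value:.2f}"
    return str(value)


def write_report(results: dict[str, pd.DataFrame], path: str | Path) -> list[Path]:
    """Write each result table as ``<name>.tsv`` under ``path``.

    Column order is preserved as given; scores render with 2 decimals and
    p-value columns in scientific notation, so re-runs on identical inputs
    produce byte-identical files.
    """
    if not results:
        raise ValueError("nothing to write")
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for name, df in results.items():
        if df.empty:
            raise ValueError(f"nothing to write for {name!r}")
        dest = out_dir / f"{name}.tsv"
        lines = ["\t".join(map(str, df.columns))]
        for _, row in df.iterrows():
            lines.append("\t".join(_format_cell(c, row[c]) for c in df.columns))
        dest.write_text("\n".join(lines) + "\n")
        manifest.append(dest)
    return manifest
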