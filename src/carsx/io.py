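"""Readers and writers for the package's on-disk formats.

Expression travels as TSV/CSV (rows = genes, header = sample IDs) or as a
MatrixMarket triplet (``X.mtx`` plus ``X.rows.txt`` / ``X.cols.txt``
sidecars); annotations as two-column TSV (sample, group); gene sets as GMT;
network edges as a fixed-column TSV. Every writer's output is re-readable by
the corresponding reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix, GeneSet, Interactome

EDGE_COLUMNS = ["source", "target", "mi", "spearman", "sign", "support"]


def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return stem.with_suffix(".rows.txt"), stem.with_suffix(".cols.txt")


def read_expression(path, fmt: str | None = None, normalization: str = "log2cpm",
                    species: str = "") -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV, or MatrixMarket.

    ``fmt`` is inferred from the suffix when omitted. MTX input requires the
    ``.rows.txt`` / ``.cols.txt`` sidecars next to the matrix file.
    """
    path = Path(path)
    fmt = fmt or {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
                  ".mtx": "mtx"}.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format from {path.name!r}; pass fmt=")
    if fmt == "mtx":
        rows_p, cols_p = _sidecar_paths(path)
        for p in (rows_p, cols_p):
            if not p.exists():
                raise FileNotFoundError(f"missing MTX sidecar file: {p}")
        m = spio.mmread(path)
        genes = rows_p.read_text().split()
        samples = cols_p.read_text().split()
        dense = m.toarray() if sparse.issparse(m) else np.asarray(m)
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as err:
            raise ValueError(f"malformed expression file {path}: {err}") from err
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dups[:5]}")
    return ExpressionMatrix(df.astype(float), normalization, species)


def write_expression(expr: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write an expression matrix as TSV/CSV or MatrixMarket with sidecars."""
    path = Path(path)
    fmt = fmt or {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
                  ".mtx": "mtx"}.get(path.suffix.lower(), "tsv")
    if fmt == "mtx":
        rows_p, cols_p = _sidecar_paths(path)
        spio.mmwrite(path, sparse.csr_matrix(expr.values.to_numpy(dtype=float)))
        rows_p.write_text("\n".join(map(str, expr.genes)) + "\n")
        cols_p.write_text("\n".join(map(str, expr.samples)) + "\n")
    else:
        # default float repr is shortest-round-trip, so read(write(x)) == x
        sep = "\t" if fmt == "tsv" else ","
        out = expr.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep=sep)


def read_annotation(path) -> pd.Series:
    """Read a two-column (sample, group) TSV into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"annotation file {path} needs two columns (sample, group)")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="group")
    if s.index.has_duplicates:
        raise ValueError(f"duplicate sample IDs in annotation {path}")
    return s


def write_annotation(groups, path) -> None:
    s = pd.Series(groups, name="group")
    s.rename_axis("sample").to_frame().to_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    """Read a DE/DA, ranking, or hidden-driver table (gene-indexed TSV).

    Accepts any table carrying at least one Z-statistic column
    (``z``, ``combined_z``, or ``z_da``).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not {"z", "combined_z", "z_da"} & set(df.columns):
        raise ValueError(f"{path} lacks a Z-statistic column")
    return df


def write_de_table(de: pd.DataFrame, path) -> None:
    out = de.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members...)."""
    sets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description, "
                             "and at least one gene")
        sets.append(GeneSet(parts[0], [g for g in parts[2:] if g],
                            description=parts[1]))
    return sets


def write_gmt(sets, path) -> None:
    lines = []
    for gs in sets:
        lines.append("\t".join([gs.name, gs.description or "na", *gs.members]))
    Path(path).write_text("\n".join(lines) + "\n")


def regulons_to_gmt(interactome: Interactome, path) -> None:
    """Export regulons as GMT, one ``_pos``/``_neg`` set per driver and sign."""
    sets = []
    for driver, reg in interactome.regulons.items():
        if reg.positive_targets:
            sets.append(GeneSet(f"{driver}_pos", reg.positive_targets,
                                description=f"positive targets of {driver}"))
        if reg.negative_targets:
            sets.append(GeneSet(f"{driver}_neg", reg.negative_targets,
                                description=f"negative targets of {driver}"))
    write_gmt(sets, path)


def read_network(path) -> Interactome:
    """Read an edge TSV (source target mi spearman sign support)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("source", "target", "mi", "sign") if c not in df.columns]
    if missing:
        raise ValueError(f"network file {path} lacks columns: {missing}")
    return Interactome.from_frame(df)


def write_network(interactome: Interactome, path) -> None:
    interactome.to_frame().to_csv(path, sep="\t", index=False,
                                  float_format="%.10g")


def read_ranking(path) -> pd.Series:
    """Read a two-column (gene, statistic) ranked list."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=df.iloc[:, 0], name="statistic")


def write_ranking(ranked: pd.Series, path) -> None:
    out = pd.Series(ranked, name="statistic").rename_axis("gene")
    out.to_frame().to_csv(path, sep="\t", float_format="%.10g")
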