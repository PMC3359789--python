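"""Readers and writers for network samples and motif tables.

Two plain-text network formats are supported:

* **edge list** — one ``tail head`` pair per whitespace-separated line,
  ``#`` comments allowed; the full label set is declared either in a header
  line ``#labels: F3,Fz,...`` or passed explicitly (required so that
  isolated vertices are representable).
* **labeled adjacency CSV** — label header row and label first column,
  entries 0/1.  Orientation is fixed as row = tail, column = head
  (A[i, j] = 1 ⇔ u_i → u_j); transposing an input silently reverses every
  motif, so the convention is checked wherever possible and documented here
  prominently.

Motif tables are written as TSV with ``#``-comment metadata (n, ν, q, α,
family mode, family size, tool version).  Floats are printed at six
significant digits; p-values are carried in log space so that extreme
values are printed in scientific notation rather than flushed to zero.
Reading a table and re-writing it is byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    GraphValidationError,
    LabeledDigraph,
    LabelError,
    LoopError,
    MotifTestResult,
    NetworkSample,
    SubnetworkKey,
    validate_network,
)
from .stats import MotifTable

__all__ = [
    "FormatError",
    "read_edgelist",
    "read_adjacency_csv",
    "read_sample",
    "write_edgelist",
    "write_adjacency_csv",
    "write_sample",
    "write_motif_table",
    "read_motif_table",
]


class FormatError(GraphValidationError):
    """A file does not conform to its declared format."""


_LABEL_HEADER = "#labels:"


def read_edgelist(
    path: str | Path, labels: Optional[Sequence[str]] = None
) -> LabeledDigraph:
    """Read one network from a plain-text edge list.

    ``labels`` may be passed explicitly; otherwise a ``#labels:`` header
    line must declare the full vertex set.  Duplicate edge lines are an
    error (the graphs are simple), as are ``u u`` loop lines.
    """
    path = Path(path)
    declared: Optional[tuple[str, ...]] = tuple(labels) if labels else None
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.lower().startswith(_LABEL_HEADER):
                header = tuple(
                    lab.strip()
                    for lab in line[len(_LABEL_HEADER):].split(",")
                    if lab.strip()
                )
                if declared is not None and set(declared) != set(header):
                    raise FormatError(
                        f"{path}:{lineno}: header labels disagree with "
                        "explicitly passed labels"
                    )
                declared = header
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 'tail head', got {raw!r}"
            )
        u, v = fields
        if u == v:
            raise LoopError(f"{path}:{lineno}: self-loop {u!r} -> {v!r}")
        if (u, v) in seen:
            raise FormatError(
                f"{path}:{lineno}: duplicate edge {u!r} -> {v!r} "
                "(multi-edges are not allowed)"
            )
        seen.add((u, v))
        edges.append((u, v))
    if declared is None:
        raise LabelError(
            f"{path}: no '#labels:' header and no explicit label set; "
            "isolated vertices would be unrepresentable"
        )
    return LabeledDigraph(declared, edges)


def read_adjacency_csv(path: str | Path) -> LabeledDigraph:
    """Read one network from a labeled 0/1 adjacency CSV.

    Row label = tail, column label = head.  Row and column label sets must
    agree.
    """
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    row_labels = tuple(str(lab) for lab in frame.index)
    col_labels = tuple(str(lab) for lab in frame.columns)
    if sorted(row_labels) != sorted(col_labels):
        raise FormatError(
            f"{path}: row labels {row_labels!r} and column labels "
            f"{col_labels!r} disagree"
        )
    # align columns to row order so A[i, j] is tail=row i, head=row j
    matrix = frame.loc[list(row_labels), list(row_labels)].to_numpy()
    if not np.isin(matrix, (0, 1)).all():
        raise FormatError(f"{path}: adjacency entries must be 0 or 1")
    return validate_network(row_labels, matrix)


def write_edgelist(network: LabeledDigraph, path: str | Path) -> None:
    path = Path(path)
    lines = [f"{_LABEL_HEADER} {','.join(network.labels)}"]
    lines += [f"{u}\t{v}" for u, v in sorted(network.edges)]
    path.write_text("\n".join(lines) + "\n")


def write_adjacency_csv(network: LabeledDigraph, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        network.adjacency, index=network.labels, columns=network.labels
    )
    frame.to_csv(path)


def read_sample(
    source: str | Path,
    format: str = "edgelist",
    labels: Optional[Sequence[str]] = None,
) -> NetworkSample:
    """Read a whole sample from a directory or a manifest file.

    A directory is globbed (sorted) for ``*.edges``/``*.edgelist``/``*.txt``
    in edge-list mode or ``*.csv`` in adjacency mode.  A manifest is a text
    file listing one network file path per line (relative paths resolve
    against the manifest's directory; ``#`` comments allowed).  The shared
    label set is validated across all files before any counting.
    """
    source = Path(source)
    if format not in ("edgelist", "adjacency"):
        raise FormatError(f"unknown sample format {format!r}")
    if source.is_dir():
        patterns = ("*.edges", "*.edgelist", "*.txt") if format == "edgelist" else ("*.csv",)
        paths = sorted(p for pat in patterns for p in source.glob(pat))
        if not paths:
            raise FormatError(f"no {format} files found in directory {source}")
    elif source.is_file():
        paths = []
        for raw in source.read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            p = Path(line)
            paths.append(p if p.is_absolute() else source.parent / p)
    else:
        raise FormatError(f"input {source} is neither a directory nor a file")
    reader = (
        (lambda p: read_edgelist(p, labels=labels))
        if format == "edgelist"
        else read_adjacency_csv
    )
    return NetworkSample([reader(p) for p in paths])


def write_sample(
    sample: NetworkSample, outdir: str | Path, format: str = "edgelist"
) -> list[Path]:
    """Write each member to ``outdir`` as net_<i>.edges or net_<i>.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = max(2, len(str(sample.n - 1)))
    paths = []
    for i, network in enumerate(sample):
        if format == "edgelist":
            path = outdir / f"net_{i:0{width}d}.edges"
            write_edgelist(network, path)
        elif format == "adjacency":
            path = outdir / f"net_{i:0{width}d}.csv"
            write_adjacency_csv(network, path)
        else:
            raise FormatError(f"unknown sample format {format!r}")
        paths.append(path)
    return paths


def _fmt(value: float) -> str:
    return f"{value:.6g}"


def _fmt_p(p: float, log10_p: float) -> str:
    """Six-significant-digit p-value; falls back to the log-space value
    when the float underflowed, so nothing is ever printed as a bare 0."""
    if p > 0.0 or not math.isfinite(log10_p):
        return _fmt(p)
    exponent = math.floor(log10_p)
    mantissa = 10.0 ** (log10_p - exponent)
    return f"{mantissa:.5f}e{exponent:+03d}"


_COLUMNS = (
    "subnetwork", "size", "eta", "count", "mean_count",
    "p_null", "p_value", "p_holm", "is_motif",
)


def write_motif_table(table: MotifTable, path: str | Path) -> None:
    """Write a motif table as TSV with metadata comment headers.

    Rows are sorted by ascending p-value, ties by canonical key string
    (already the table's order).  Re-reading and re-writing the file is
    byte-identical.
    """
    path = Path(path)
    lines = [
        "# labmotif motif table",
        f"# version: {__version__}",
        f"# n: {table.n}",
        f"# num_labels: {table.num_labels}",
        f"# size: {table.size}",
        f"# q: {_fmt(table.q)}",
        f"# alpha: {_fmt(table.alpha)}",
        f"# family_mode: {table.family_mode}",
        f"# family: {table.family}",
        "\t".join(_COLUMNS),
    ]
    for r in table.results:
        lines.append(
            "\t".join(
                (
                    r.key.key_string,
                    str(r.key.size),
                    str(r.key.eta),
                    str(r.count),
                    _fmt(r.mean_count),
                    _fmt_p(r.p_null, math.log10(r.p_null) if r.p_null > 0 else -math.inf),
                    _fmt_p(r.p_value, r.log10_p_value),
                    _fmt_p(r.p_holm, r.log10_p_holm),
                    str(int(r.is_motif)),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_motif_table(path: str | Path) -> MotifTable:
    """Read a motif table TSV written by :func:`write_motif_table`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header_seen = False
    for raw in path.read_text().splitlines():
        line = raw.rstrip("\n")
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != _COLUMNS:
                raise FormatError(f"{path}: unexpected column header {fields!r}")
            header_seen = True
            continue
        rows.append(fields)
    if not header_seen:
        raise FormatError(f"{path}: missing column header line")
    try:
        n = int(meta["n"])
        num_labels = int(meta["num_labels"])
        size = int(meta["size"])
        q = float(meta["q"])
        alpha = float(meta["alpha"])
        family_mode = meta["family_mode"]
        family = int(meta["family"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing metadata field {exc}") from exc
    results = []
    for fields in rows:
        if len(fields) != len(_COLUMNS):
            raise FormatError(f"{path}: malformed row {fields!r}")
        key = SubnetworkKey.from_string(fields[0])
        p_value = float(fields[6])
        p_holm = float(fields[7])
        results.append(
            MotifTestResult(
                key=key,
                count=int(fields[3]),
                n=n,
                p_null=float(fields[5]),
                p_value=p_value,
                p_holm=p_holm,
                is_motif=bool(int(fields[8])),
                log10_p_value=math.log10(p_value) if p_value > 0 else -math.inf,
                log10_p_holm=math.log10(p_holm) if p_holm > 0 else -math.inf,
            )
        )
    return MotifTable(
        results=tuple(results),
        alpha=alpha,
        family=family,
        family_mode=family_mode,
        q=q,
        n=n,
        num_labels=num_labels,
        size=size,
    )
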