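"""Readers and writers for the pipeline's plain-text interchange formats.

Formats
-------
- guide library: CSV with header ``guide_id,gene,spacer,is_ntc``
- count matrices: TSV, first column the row id (``guide_id`` / ``clone_id``),
  remaining columns sample ids; integer cells
- sample sheets: TSV with ``sample_id,timepoint,replicate[,is_plasmid]``
- clone map: CSV with header ``clone_id,construct``
- repertoire reads: FASTA; annotations: AIRR-style TSV
- graphs: GraphML (via networkx); trees: newick

All TSVs are tab-separated UTF-8 without quoting; lines starting with ``#``
are ignored. Readers reject malformed input (ragged rows, duplicate ids,
negative or non-integer counts) with the offending line number rather than
coercing it. Writers emit deterministic, stably ordered output.

AIRR-style coordinates (``v_end``) are 0-based half-open; ``read_airr`` can
convert 1-based inclusive (IMGT-style) input via ``one_based=True``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "v_end",
    "junction",
    "junction_length",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# count matrices and sample sheets


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and '#'."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_counts_tsv(path: str | Path, id_column: str | None = None) -> pd.DataFrame:
    """Read a row-id x sample integer count matrix from TSV.

    Returns a DataFrame indexed by the first column with int64 values.
    Raises :class:`ParseError` on ragged rows, duplicate row ids, or
    negative / non-integer cells, naming the line.
    """
    rows: list[list[int]] = []
    ids: list[str] = []
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: header must name >=1 sample")
            header = fields
            if id_column is not None and header[0] != id_column:
                raise ParseError(
                    f"{path}:{lineno}: expected first column {id_column!r}, "
                    f"got {header[0]!r}"
                )
            continue
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        row_id, cells = fields[0], fields[1:]
        values: list[int] = []
        for cell in cells:
            try:
                value = int(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer count {cell!r}"
                ) from None
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative count {value}")
            values.append(value)
        ids.append(row_id)
        rows.append(values)
    if header is None:
        raise ParseError(f"{path}: empty file")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicate row ids: {', '.join(dupes)}")
    frame = pd.DataFrame(rows, index=pd.Index(ids, name=header[0]), columns=header[1:])
    return frame.astype("int64")


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path, with_plasmid: bool = False) -> pd.DataFrame:
    """Read a sample sheet TSV; ``with_plasmid`` requires an is_plasmid column."""
    required = ["sample_id", "timepoint", "replicate"] + (
        ["is_plasmid"] if with_plasmid else []
    )
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns: {', '.join(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id in sample sheet")
    if with_plasmid:
        sheet["is_plasmid"] = sheet["is_plasmid"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
        if sheet["is_plasmid"].isna().any():
            raise ParseError(f"{path}: is_plasmid must be True/False or 1/0")
    return sheet.set_index("sample_id", drop=False)


def read_clone_map(path: str | Path) -> pd.Series:
    """clone_id -> construct mapping from a two-column CSV."""
    frame = pd.read_csv(path, comment="#", dtype=str)
    for col in ("clone_id", "construct"):
        if col not in frame.columns:
            raise ParseError(f"{path}: clone map missing column {col!r}")
    if frame["clone_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate clone_id in clone map")
    return frame.set_index("clone_id")["construct"]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, uppercased sequence) records; rejects non-ACGTN letters,
    empty files and header-only records."""
    records: list[tuple[str, str]] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {record.id!r} has no sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"{path}: record {record.id!r} contains invalid characters "
                f"{sorted(bad)}"
            )
        records.append((record.id, seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# AIRR-style annotation tables


def read_airr(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """AIRR-style rearrangement table.

    ``one_based=True`` converts a 1-based inclusive ``v_end`` (IMGT
    convention) to the 0-based half-open coordinate used internally (the two
    encodings are numerically identical for an end coordinate, so this is a
    declaration of intent rather than an offset).
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in AIRR_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: AIRR table missing columns: {', '.join(missing)}")
    table["v_end"] = table["v_end"].astype(int)
    table["junction_length"] = table["junction_length"].astype(int)
    table["sequence"] = table["sequence"].str.upper()
    if table["sequence_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sequence_id in AIRR table")
    return table


def write_airr(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=AIRR_COLUMNS)


# ---------------------------------------------------------------------------
# graphs and trees


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_newick(tree: nx.Graph, path: str | Path | None = None) -> str:
    """Serialize an unrooted tree (edge attr ``length``) to newick.

    The tree is rooted at the lexicographically smallest leaf for output
    (newick requires a root); a 2-leaf tree with branch length d becomes
    ``(A:d,B:0);`` by convention. Leaf names come from the node attribute
    ``label`` (falling back to the node id); internal nodes are unnamed.
    """
    if tree.number_of_nodes() == 0:
        raise ValueError("empty tree")

    def label(node) -> str:
        return str(tree.nodes[node].get("label", node))

    leaves = sorted(
        (n for n in tree.nodes if tree.degree(n) <= 1), key=label
    )
    if not leaves:
        raise ValueError("tree has no leaves")
    root = leaves[0]

    def render(node, parent) -> str:
        children = [n for n in tree.neighbors(node) if n != parent]
        name = label(node) if tree.degree(node) <= 1 else ""
        if not children:
            return name
        inner = ",".join(
            f"{render(child, node)}:{tree.edges[node, child].get('length', 0):g}"
            for child in children
        )
        return f"({inner}){name}"

    if tree.number_of_nodes() == 1:
        newick = f"{label(root)};"
    else:
        children = list(tree.neighbors(root))
        inner = ",".join(
            f"{render(child, root)}:{tree.edges[root, child].get('length', 0):g}"
            for child in children
        )
        newick = f"({inner},{label(root)}:0);"
    if path is not None:
        Path(path).write_text(newick + "\n", encoding="utf-8")
    return newick


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
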