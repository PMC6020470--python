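"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ and aligned FASTA go through Biopython, Newick through
dendropy, tab-separated tables through pandas, and jplace is plain JSON.
Sequences are normalized on input: uppercase, '.' gaps rewritten to '-'.
"""

from __future__ import annotations

import io
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

GAP = "-"
ALPHABET = "ACGT"

#: assignment-table column order (consensus coordinates are 1-based inclusive)
ASSIGNMENT_COLUMNS = [
    "id",
    "cs_start",
    "cs_end",
    "aligned",
    "branch_id",
    "taxonomy",
    "loglik",
    "q_score",
    "flags",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence, optionally with per-base qualities."""

    id: str
    seq: str
    description: str = ""
    qual: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_sequences(path, format: str = "fasta") -> list[SeqRecord]:
    """Read FASTA or FASTQ records, preserving file order.

    Symbols are uppercased and '.' is normalized to '-'. An empty file
    yields an empty list.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    out: list[SeqRecord] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            qual = rec.letter_annotations.get("phred_quality")
            out.append(
                SeqRecord(
                    id=rec.id,
                    seq=_normalize(str(rec.seq)),
                    description=rec.description,
                    qual=list(qual) if qual is not None else None,
                )
            )
    except ValueError as exc:  # Biopython parse failure
        raise FormatError(f"{path}: {exc}") from exc
    return out


def write_sequences(records: Iterable[SeqRecord], path, format: str = "fasta") -> None:
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                header = rec.id if not rec.description or rec.description == rec.id \
                    else f"{rec.id} {rec.description}"
                fh.write(f">{header}\n{rec.seq}\n")
            elif format == "fastq":
                qual = rec.qual if rec.qual is not None else [40] * len(rec.seq)
                qline = "".join(chr(q + 33) for q in qual)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qline}\n")
            else:
                raise ValueError(f"unsupported format {format!r}")


@dataclass
class Msa:
    """An aligned set of sequences with consensus and column statistics.

    The consensus at column j is the modal non-gap symbol (alphabetical
    tie-break), or '-' when more than half of the column is gaps.
    """

    records: list[SeqRecord]
    consensus: str = field(default="")
    col_gap_frac: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("empty alignment")
        L = len(self.records[0].seq)
        for rec in self.records:
            if len(rec.seq) != L:
                raise FormatError(
                    f"ragged alignment: {rec.id!r} has length {len(rec.seq)}, "
                    f"expected {L}"
                )
        if not self.consensus:
            self.consensus, self.col_gap_frac = _column_stats(self.records)

    @property
    def L(self) -> int:
        return len(self.records[0].seq)

    @property
    def nseq(self) -> int:
        return len(self.records)

    def match_columns(self, max_gap_frac: float = 0.5) -> list[int]:
        """Columns whose gap fraction is <= max_gap_frac (profile match states)."""
        return [j for j, g in enumerate(self.col_gap_frac) if g <= max_gap_frac]


def _column_stats(records: Sequence[SeqRecord]) -> tuple[str, list[float]]:
    n = len(records)
    consensus = []
    gap_frac = []
    L = len(records[0].seq)
    for j in range(L):
        col = [rec.seq[j] for rec in records]
        ngap = sum(1 for c in col if c == GAP)
        frac = ngap / n
        gap_frac.append(frac)
        if frac > 0.5:
            consensus.append(GAP)
        else:
            counts = Counter(c for c in col if c != GAP)
            best = min(counts, key=lambda c: (-counts[c], c))
            consensus.append(best)
    return "".join(consensus), gap_frac


def read_msa(path) -> Msa:
    records = read_sequences(path, "fasta")
    return Msa(records=records)


def write_msa(msa: Msa, path) -> None:
    write_sequences(msa.records, path, "fasta")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNodeSpec:
    name: str
    parent: int  # -1 for root
    children: list[int]
    length: float


@dataclass
class TreeSpec:
    """Flattened parsed tree: node 0 is the root; lengths are >= 0."""

    nodes: list[TreeNodeSpec]
    rooted: bool = True

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if not n.children)


def parse_newick(text: str) -> TreeSpec:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:
        raise FormatError(f"newick parse error: {exc}") from exc
    nodes: list[TreeNodeSpec] = []
    index: dict = {}
    for nd in tree.preorder_node_iter():
        name = ""
        if nd.taxon is not None and nd.taxon.label:
            name = nd.taxon.label
        elif nd.label:
            name = nd.label
        length = nd.edge.length if nd.edge.length is not None else 0.0
        if length < 0:
            raise FormatError(f"negative branch length at node {name!r}")
        parent = index[id(nd.parent_node)] if nd.parent_node is not None else -1
        idx = len(nodes)
        index[id(nd)] = idx
        nodes.append(TreeNodeSpec(name=name, parent=parent, children=[], length=length))
        if parent >= 0:
            nodes[parent].children.append(idx)
    return TreeSpec(nodes=nodes)


def write_newick(spec: TreeSpec) -> str:
    def fmt(i: int) -> str:
        node = spec.nodes[i]
        label = node.name
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner}){label}"
        else:
            s = label
        if node.parent >= 0:
            s += f":{node.length:.10g}"
        return s

    return fmt(0) + ";"


# ---------------------------------------------------------------------------
# Assignment TSV and jplace
# ---------------------------------------------------------------------------

def placements_to_frame(placements) -> pd.DataFrame:
    rows = []
    for p in placements:
        rows.append(
            {
                "id": p.read_id,
                "cs_start": p.cs_start,
                "cs_end": p.cs_end,
                "aligned": p.aligned,
                "branch_id": p.branch_id,
                "taxonomy": p.taxonomy,
                "loglik": p.loglik,
                "q_score": p.q_score,
                "flags": p.flags,
            }
        )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def write_assignment_tsv(placements, path) -> None:
    """One row per read; '#'-prefixed comment lines allowed on re-read."""
    frame = placements_to_frame(placements)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_assignment_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _edge_numbered_newick(tree) -> str:
    """Newick with jplace {edge_num} tags; edge_num = child node id."""

    def fmt(i: int) -> str:
        node = tree.nodes[i]
        label = node.name or ""
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner}){label}"
        else:
            s = label or f"n{i}"
        if node.parent >= 0:
            s += f":{node.length:.10g}{{{i}}}"
        return s

    return fmt(0) + ";"


def write_jplace(placements, tree) -> str:
    """Serialize placements in jplace (version 3) JSON on an edge-numbered tree.

    Edge numbers are the child-node ids of the reference tree, so any
    placement can be mapped back to its branch. Raises on a placement
    whose branch id is not a valid non-root node.
    """
    n_nodes = len(tree.nodes)
    entries = []
    for p in placements:
        if not (0 < p.branch_id < n_nodes):
            raise FormatError(f"placement {p.read_id!r}: unknown branch {p.branch_id}")
        lwr = 10 ** (-p.q_score / 10.0)
        entries.append(
            {
                "p": [[int(p.branch_id), float(p.loglik), float(1.0 - lwr),
                       float(p.distal_length), float(p.pendant_length)]],
                "n": [p.read_id],
            }
        )
    doc = {
        "version": 3,
        "tree": _edge_numbered_newick(tree),
        "placements": entries,
        "fields": [
            "edge_num",
            "likelihood",
            "like_weight_ratio",
            "distal_length",
            "pendant_length",
        ],
        "metadata": {"invocation": "phylotu"},
    }
    return json.dumps(doc, indent=1)


def read_taxonomy_tsv(path) -> dict[str, str]:
    """Read an id -> taxonomy-string table (2 columns, optional header)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"taxonomy line lacks 2 columns: {line!r}")
            if parts[0] in ("id", "node_id") and not table:
                continue
            table[parts[0]] = parts[1]
    return table


def write_taxonomy_tsv(table: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\ttaxonomy\n")
        for key, val in table.items():
            fh.write(f"{key}\t{val}\n")
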