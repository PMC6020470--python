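"""Phylogeny-based OTU summarization.

Any reference-tree node with more than a preset number of placed reads
(across all samples) becomes an OTU. The representative sequence of an
OTU is a per-site Dirichlet posterior consensus of its member reads'
aligned bases, with a prior proportional to the node's pre-evaluated
base posterior (concentration 2 == two background pseudo-reads); a gap
is emitted where gap observations outnumber base observations. The OTU
tree is the reference tree pruned to the OTU nodes plus the minimal
connecting nodes, with pass-through nodes collapsed so pairwise path
lengths between OTU nodes are preserved.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import formats
from .formats import SeqRecord, TreeNodeSpec, TreeSpec
from .ref_phylogeny import PhyloTree, encode_states
from .sep_placement import Placement

BASES = "ACGT"


@dataclass
class Otu:
    node: int
    counts: dict[str, int]              # per-sample read counts
    members: list[Placement]
    taxonomy: str = ""
    repseq: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def cluster_placements(placements: Sequence[Placement],
                       otu_min_reads: int = 1
                       ) -> tuple[list[Otu], list[Placement]]:
    """Group placements by assigned node; nodes with more than
    `otu_min_reads` total reads become OTUs, the rest are rejects.

    Returns (otus, rejects); read counts are conserved:
    sum(otu totals) + len(rejects) == len(placements).
    """
    by_node: dict[int, list[Placement]] = {}
    for p in placements:
        by_node.setdefault(p.assigned_node, []).append(p)
    otus: list[Otu] = []
    rejects: list[Placement] = []
    for node in sorted(by_node):
        members = by_node[node]
        if node < 0 or len(members) < otu_min_reads:
            rejects.extend(members)
            continue
        counts: dict[str, int] = {}
        for p in members:
            counts[p.sample] = counts.get(p.sample, 0) + 1
        otus.append(Otu(node=node, counts=counts, members=members,
                        taxonomy=members[0].taxonomy))
    return otus, rejects


def consensus_repseq(otu: Otu, tree: PhyloTree, concentration: float = 2.0,
                     use_prior: bool = True, aligned: bool = False) -> str:
    """Dirichlet-posterior consensus sequence of an OTU's member reads.

    Per site, base counts from the aligned members are combined with a
    Dirichlet prior alpha_b = concentration * (node posterior of b); the
    emitted base maximizes the posterior mean, unless gap observations
    outnumber base observations, in which case a gap is emitted. The
    output covers the OTU's observed consensus span, gap-stripped unless
    `aligned` is set.
    """
    if not otu.members:
        raise ValueError("empty OTU")
    S = tree.S
    counts = np.zeros((S, 4))
    gaps = np.zeros(S)
    covered = np.zeros(S, dtype=bool)
    for p in otu.members:
        states = encode_states(p.aligned)
        lo = p.cs_start - 1
        for off, b in enumerate(states):
            covered[lo + off] = True
            if b < 4:
                counts[lo + off, b] += 1
            else:
                gaps[lo + off] += 1
    if use_prior and concentration > 0:
        node_logpost = tree.marginal_log_posterior(otu.node)  # (4, S)
        alpha = concentration * np.exp(node_logpost).T        # (S, 4)
    else:
        alpha = np.zeros((S, 4))
    post = counts + alpha
    lo = int(np.argmax(covered))
    hi = S - int(np.argmax(covered[::-1])) - 1
    out = []
    for s in range(lo, hi + 1):
        nbase = counts[s].sum()
        if gaps[s] > nbase or (nbase == 0 and post[s].sum() == 0):
            out.append("-")
        else:
            out.append(BASES[int(np.argmax(post[s]))])
    seq = "".join(out)
    return seq if aligned else seq.replace("-", "")


def prune_otu_tree(tree: PhyloTree, otus: Sequence[Otu]) -> TreeSpec:
    """Prune to the OTU nodes plus minimal connectors; collapse
    pass-through nodes, summing branch lengths, so pairwise distances
    between OTU nodes are preserved."""
    keep = set(o.node for o in otus)
    if not keep:
        return TreeSpec(nodes=[TreeNodeSpec(name="root", parent=-1,
                                            children=[], length=0.0)])
    # mark ancestors of kept nodes
    needed = set()
    for v in keep:
        while v >= 0 and v not in needed:
            needed.add(v)
            v = tree.nodes[v].parent

    def build(v: int, extra_len: float, parent_idx: int,
              out: list[TreeNodeSpec]) -> None:
        node = tree.nodes[v]
        kids = [c for c in node.children if c in needed]
        length = node.length + extra_len
        if v not in keep and len(kids) == 1 and parent_idx >= 0:
            build(kids[0], length, parent_idx, out)  # collapse pass-through
            return
        idx = len(out)
        name = node.name or f"node{v}"
        out.append(TreeNodeSpec(name=name, parent=parent_idx, children=[],
                                length=length if parent_idx >= 0 else 0.0))
        if parent_idx >= 0:
            out[parent_idx].children.append(idx)
        for c in kids:
            build(c, 0.0, idx, out)

    # find the top: walk down from the root through single-child connectors
    top = 0
    while top not in keep:
        kids = [c for c in tree.nodes[top].children if c in needed]
        if len(kids) != 1:
            break
        top = kids[0]
    out: list[TreeNodeSpec] = []
    build(top, 0.0, -1, out)
    return TreeSpec(nodes=out)


def otu_table(otus: Sequence[Otu], samples: Optional[Sequence[str]] = None
              ) -> pd.DataFrame:
    if samples is None:
        samples = sorted({s for o in otus for s in o.counts})
    rows = []
    for o in otus:
        row = {"otu_id": f"node{o.node}"}
        for s in samples:
            row[s] = o.counts.get(s, 0)
        row["taxonomy"] = o.taxonomy
        rows.append(row)
    return pd.DataFrame(rows, columns=["otu_id", *samples, "taxonomy"])


def write_otu_artifacts(otus: Sequence[Otu], tree: PhyloTree, outdir,
                        samples: Optional[Sequence[str]] = None,
                        concentration: float = 2.0,
                        use_prior: bool = True) -> dict[str, str]:
    """Write the OTU table (TSV), representative sequences (FASTA) and
    the pruned OTU tree (Newick); returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    table_path = os.path.join(outdir, "otu_table.tsv")
    fasta_path = os.path.join(outdir, "otu_repseqs.fasta")
    tree_path = os.path.join(outdir, "otu_tree.nwk")
    otu_table(otus, samples).to_csv(table_path, sep="\t", index=False)
    recs = []
    for o in otus:
        if not o.repseq:
            o.repseq = consensus_repseq(o, tree, concentration=concentration,
                                        use_prior=use_prior)
        recs.append(SeqRecord(id=f"node{o.node}", seq=o.repseq or "N",
                              description=o.taxonomy))
    with open(fasta_path, "w") as fh:
        for r in recs:
            fh.write(f">{r.id} {r.description}\n{r.seq}\n")
    spec = prune_otu_tree(tree, otus)
    with open(tree_path, "w") as fh:
        fh.write(formats.write_newick(spec) + "\n")
    return {"table": table_path, "repseqs": fasta_path, "tree": tree_path}
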