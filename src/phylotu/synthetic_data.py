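"""Toy reference packages, read and chimera simulators, and benchmark
metrics.

The read simulator mirrors a marker-gene library construction: a tree
branch is drawn uniformly, a branching point uniformly along it, an
amplicon locus fixed or uniform, amplicon length fixed or truncated-
Gaussian, and each base sampled from the conditional posterior of the
four bases at the branching point (gap sites are skipped, so simulated
reads are gap-free). The chimera simulator splices pairs of reference
sequences whose p-distance falls in preset bins at a uniform consensus
breakpoint; a splice only counts as a chimera when the breakpoint lands
in the central half [0.25, 0.75) of the alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .evo_models import SubstModel, transition_matrix
from .formats import Msa, SeqRecord, TreeNodeSpec, TreeSpec
from .ref_phylogeny import (PhyloTree, ReferencePackage,
                            build_reference_package, encode_states)

BASES = "ACGT"
RANKS = ["k", "p", "c", "o", "f", "g", "s"]

DEFAULT_CHIMERA_BINS = [(0.01, 0.03), (0.03, 0.05), (0.05, 0.10), (0.10, 0.15)]


@dataclass
class SimRead:
    read_id: str
    seq: str
    branch: int              # child-node id of the true branch
    fraction: float          # 0 = at parent end, 1 = at child end
    cs_start: int            # 1-based inclusive true locus
    cs_end: int
    taxonomy: str
    sample: str = ""


@dataclass
class ChimeraSimRecord:
    read_id: str
    seq: str
    parent1: str
    parent2: str
    p_dist: float
    bin: tuple[float, float]
    breakpoint_fraction: float
    label: str               # "chimera" | "non-chimera"


# ---------------------------------------------------------------------------
# Toy reference
# ---------------------------------------------------------------------------

def _random_yule_tree(n_leaves: int, rng: np.random.Generator,
                      mean_branch: float = 0.08) -> TreeSpec:
    """Random bifurcating tree grown by repeatedly splitting a random leaf."""
    nodes = [TreeNodeSpec(name="", parent=-1, children=[], length=0.0)]
    leaves = [0]
    while len(leaves) < n_leaves:
        pick = int(rng.integers(len(leaves)))
        v = leaves.pop(pick)
        for _ in range(2):
            idx = len(nodes)
            nodes.append(TreeNodeSpec(
                name="", parent=v, children=[],
                length=float(rng.exponential(mean_branch)) + 1e-3,
            ))
            nodes[v].children.append(idx)
            leaves.append(idx)
    leaf_no = 0
    for n in nodes:
        if not n.children:
            n.name = f"L{leaf_no:03d}"
            leaf_no += 1
    return TreeSpec(nodes=nodes)


def _assign_taxonomy(spec: TreeSpec) -> dict[str, str]:
    """Full 7-rank taxonomy strings assigned by depth quantiles.

    The root is the kingdom; each node's rank deepens with its edge
    depth so that every leaf carries a complete
    k__;p__;c__;o__;f__;g__;s__ string and internal nodes stop at the
    rank matching their depth.
    """
    n = len(spec.nodes)
    depth = [0] * n
    maxd = 1
    for i in range(1, n):
        depth[i] = depth[spec.nodes[i].parent] + 1
        maxd = max(maxd, depth[i])
    if not spec.nodes[0].name:
        spec.nodes[0].name = "root"
    labels = [""] * n
    names: dict[str, str] = {}
    for i in range(n):  # spec nodes are in preorder: parents precede children
        node = spec.nodes[i]
        p = node.parent
        parts = labels[p].split(";") if p >= 0 else []
        if p < 0:
            level = 0
        elif not node.children:
            level = 6
        else:
            level = min(6, max(1, round(depth[i] / maxd * 6)))
        level = max(level, len(parts) - 1)
        while len(parts) <= level:
            parts.append(f"{RANKS[len(parts)]}__T{i}")
        labels[i] = ";".join(parts)
        if not node.name:
            node.name = f"N{i}"
        names[node.name] = labels[i]
    return names


def _evolve_sequences(spec: TreeSpec, S: int, model: SubstModel,
                      rng: np.random.Generator) -> dict[str, str]:
    seqs_enc: dict[int, np.ndarray] = {}
    root_seq = rng.choice(4, size=S, p=model.pi)
    seqs_enc[0] = root_seq
    for i in range(1, len(spec.nodes)):
        node = spec.nodes[i]
        P = transition_matrix(model, node.length)
        parent = seqs_enc[node.parent]
        child = np.empty(S, dtype=np.int64)
        for b in range(4):
            mask = parent == b
            if mask.any():
                child[mask] = rng.choice(4, size=int(mask.sum()), p=P[b])
        seqs_enc[i] = child
    out = {}
    for i, node in enumerate(spec.nodes):
        if not node.children:
            out[node.name] = "".join(BASES[b] for b in seqs_enc[i])
    return out


def make_toy_reference(n_leaves: int = 20, S: int = 200,
                       model: Optional[SubstModel] = None,
                       model_name: str = "GTR", seed: int = 0,
                       mean_branch: float = 0.08
                       ) -> tuple[ReferencePackage, dict]:
    """Generate a small reference package with known ground truth.

    A random bifurcating tree is grown, sequences are evolved from a
    random root under the model, taxonomy is assigned by clade depth,
    and the package is assembled exactly as for real references. The
    returned truth dict carries the generating model and tree spec.
    """
    if n_leaves < 4 or S < 50:
        raise ValueError("toy reference needs n_leaves >= 4 and S >= 50")
    rng = np.random.default_rng(seed)
    if model is None:
        R = np.array([
            [0.0, 1.0, 2.5, 0.8],
            [1.0, 0.0, 0.9, 2.2],
            [2.5, 0.9, 0.0, 1.1],
            [0.8, 2.2, 1.1, 0.0],
        ])
        pi = np.array([0.3, 0.2, 0.25, 0.25])
        model = SubstModel(name=model_name, pi=pi, R=_constrain(R, model_name, pi))
    spec = _random_yule_tree(n_leaves, rng, mean_branch)
    taxonomy = _assign_taxonomy(spec)
    leaf_seqs = _evolve_sequences(spec, S, model, rng)
    records = [SeqRecord(id=name, seq=seq) for name, seq in leaf_seqs.items()]
    msa = Msa(records=records)
    pkg = build_reference_package(msa, spec, taxonomy, model=model, seed=seed)
    truth = {"model": model, "treespec": spec, "taxonomy": taxonomy,
             "seed": seed}
    return pkg, truth


def _constrain(R: np.ndarray, model_name: str, pi: np.ndarray) -> np.ndarray:
    if model_name == "GTR":
        return R
    out = R.copy()
    tv = np.mean([R[0, 1], R[0, 3], R[1, 2], R[2, 3]])
    for i, j in [(0, 1), (0, 3), (1, 2), (2, 3)]:
        out[i, j] = out[j, i] = tv
    if model_name == "HKY85":
        ts = (R[0, 2] + R[1, 3]) / 2
        out[0, 2] = out[2, 0] = ts
        out[1, 3] = out[3, 1] = ts
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _branch_point_posterior(tree: PhyloTree, branch: int, fraction: float
                            ) -> np.ndarray:
    """(4, S) base probabilities at a point along a branch.

    The point posterior combines the upward message transported from the
    parent end and the downward message from the child end.
    """
    node = tree.nodes[branch]
    w0 = node.length
    w_u = fraction * w0
    w_v = w0 - w_u
    U = tree.up_excl[branch]
    D = tree.down[branch]
    L = (tree._conv_all(U, tree.branch_P(w_u))
         + tree._conv_all(D, tree.branch_P(w_v)))
    logpi = np.log(tree.model.pi)
    joint = logsumexp(logpi[None, :, None] + L, axis=0)
    joint -= logsumexp(joint, axis=0, keepdims=True)
    return np.exp(joint)


def simulate_reads(pkg: ReferencePackage, n_samples: int = 1,
                   reads_per_sample: int = 100,
                   locus_mode: str = "random",
                   fixed_locus: Optional[tuple[int, int]] = None,
                   amplicon: str = "gaussian",
                   amplicon_len: int = 150,
                   amplicon_mu: float = 150, amplicon_sd: float = 30,
                   amplicon_min: int = 75, amplicon_max: int = 300,
                   seed: int = 0,
                   leaf_fraction_min: float = 0.0,
                   leaf_branches_only: bool = False) -> list[SimRead]:
    """Simulate amplicon reads from the reference tree.

    Per read: a branch is drawn uniformly, a branching point uniformly
    along it (optionally restricted toward the child end via
    `leaf_fraction_min`), a locus fixed or uniform, the length fixed or
    truncated-Gaussian, and each base sampled from the branch-point
    conditional posterior. Gap-majority consensus sites of the nearest
    node are skipped, so reads contain no gaps.
    """
    tree = pkg.tree
    S = tree.S
    rng = np.random.default_rng(seed)
    branches = tree.branches()
    if leaf_branches_only:
        branches = [b for b in branches if tree.nodes[b].is_leaf]
    reads: list[SimRead] = []
    for si in range(n_samples):
        sample = f"S{si:02d}"
        for ri in range(reads_per_sample):
            branch = int(branches[rng.integers(len(branches))])
            frac = float(rng.uniform(leaf_fraction_min, 1.0))
            if amplicon == "fixed_len":
                length = amplicon_len
            else:
                length = int(np.clip(round(rng.normal(amplicon_mu, amplicon_sd)),
                                     amplicon_min, amplicon_max))
            length = min(length, S)
            if length > S:
                raise ValueError("amplicon longer than the consensus")
            if locus_mode == "fixed":
                lo, hi = fixed_locus if fixed_locus else (1, length)
            else:
                lo = int(rng.integers(1, S - length + 2))
                hi = lo + length - 1
            post = _branch_point_posterior(tree, branch, frac)
            node_states = encode_states(tree.node_seq(branch))
            bases = []
            for s in range(lo - 1, hi):
                if node_states[s] == 4:
                    continue  # gap site: skipped, reads carry no gaps
                bases.append(BASES[int(rng.choice(4, p=post[:, s]))])
            taxonomy = tree.nodes[branch].taxonomy
            reads.append(SimRead(
                read_id=f"{sample}_r{ri:05d}", seq="".join(bases),
                branch=branch, fraction=frac, cs_start=lo, cs_end=hi,
                taxonomy=taxonomy, sample=sample,
            ))
    return reads


# ---------------------------------------------------------------------------
# Chimera simulation
# ---------------------------------------------------------------------------

def _pairwise_pdist(a: np.ndarray, b: np.ndarray) -> float:
    both = (a < 4) & (b < 4)
    n = int(both.sum())
    if n == 0:
        return 1.0
    return float(np.sum(a[both] != b[both]) / n)


def simulate_chimeras(msa: Msa, bins: Sequence[tuple[float, float]] = None,
                      n_per_bin: int = 25, seed: int = 0,
                      max_pair_draws: int = 200_000) -> list[ChimeraSimRecord]:
    """Simulate chimeric and non-chimeric amplicons from reference pairs.

    Pairs whose aligned p-distance falls in a requested bin are spliced
    at a uniformly drawn consensus breakpoint; the product is labeled a
    chimera only when the breakpoint fraction lies in [0.25, 0.75),
    otherwise the first parent is kept unchanged. Alignment gaps are
    removed from the emitted sequences.
    """
    if bins is None:
        bins = DEFAULT_CHIMERA_BINS
    rng = np.random.default_rng(seed)
    enc = [encode_states(r.seq) for r in msa.records]
    n = len(enc)
    L = msa.L
    # pre-bin all pairs
    bin_pairs: dict[tuple[float, float], list[tuple[int, int]]] = {
        tuple(b): [] for b in bins
    }
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairwise_pdist(enc[i], enc[j])
            for b in bins:
                if b[0] <= d < b[1]:
                    bin_pairs[tuple(b)].append((i, j))
                    break
    out: list[ChimeraSimRecord] = []
    for b in bins:
        pairs = bin_pairs[tuple(b)]
        if not pairs:
            raise ValueError(f"no reference pair with p-distance in {b}")
        for t in range(n_per_bin):
            i, j = pairs[int(rng.integers(len(pairs)))]
            bp = int(rng.integers(1, L))
            frac = bp / L
            s1, s2 = msa.records[i].seq, msa.records[j].seq
            if 0.25 <= frac < 0.75:
                seq = s1[:bp] + s2[bp:]
                label = "chimera"
            else:
                seq = s1
                label = "non-chimera"
            out.append(ChimeraSimRecord(
                read_id=f"chim_{b[0]}_{t:04d}",
                seq=seq.replace("-", ""),
                parent1=msa.records[i].id, parent2=msa.records[j].id,
                p_dist=_pairwise_pdist(enc[i], enc[j]),
                bin=tuple(b), breakpoint_fraction=frac, label=label,
            ))
    return out


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def eval_alignment(alignments, truths: Sequence[SimRead],
                   min_overlap: float = 0.9) -> float:
    """Fraction of reads whose aligned consensus locus overlaps at least
    `min_overlap` of the true locus."""
    by_id = {t.read_id: t for t in truths}
    correct = 0
    total = 0
    for aln in alignments:
        t = by_id.get(aln.read_id)
        if t is None:
            continue
        total += 1
        lo = max(aln.cs_start, t.cs_start)
        hi = min(aln.cs_end, t.cs_end)
        inter = max(0, hi - lo + 1)
        true_len = t.cs_end - t.cs_start + 1
        if true_len > 0 and inter / true_len >= min_overlap:
            correct += 1
    return correct / total if total else 0.0


def parse_ranks(taxonomy: str) -> dict[str, str]:
    out = {}
    for part in taxonomy.split(";"):
        part = part.strip()
        if "__" in part:
            r, name = part.split("__", 1)
            out[r] = name
    return out


def eval_taxonomy(assigned: dict[str, str], truth: dict[str, str],
                  levels: Sequence[str] = RANKS) -> dict[str, dict[str, float]]:
    """Per-rank TPR/TNR/PPV/ACC.

    TP: both truth and assignment annotate the rank and the names match;
    TN: both lack the rank; FP: assignment annotates it but the truth
    lacks it, or both annotate it and the names differ (also an FN);
    FN: the truth annotates it but the assignment lacks it.
    """
    results = {}
    for level in levels:
        tp = tn = fp = fn = 0
        for rid, ttax in truth.items():
            atax = assigned.get(rid, "")
            tranks = parse_ranks(ttax)
            aranks = parse_ranks(atax)
            thas = bool(tranks.get(level))
            ahas = bool(aranks.get(level))
            if thas and ahas:
                if tranks[level] == aranks[level]:
                    tp += 1
                else:
                    fp += 1
                    fn += 1
            elif thas and not ahas:
                fn += 1
            elif ahas and not thas:
                fp += 1
            else:
                tn += 1
        results[level] = {
            "TPR": tp / (tp + fn) if tp + fn else float("nan"),
            "TNR": tn / (tn + fp) if tn + fp else float("nan"),
            "PPV": tp / (tp + fp) if tp + fp else float("nan"),
            "ACC": (tp + tn) / max(tp + tn + fp + fn, 1),
        }
    return results


def placement_emd(mass_a: dict[int, float], mass_b: dict[int, float],
                  tree: PhyloTree) -> float:
    """Earth-mover (weighted-UniFrac-style) distance between two
    placement mass distributions on the same tree.

    Masses are normalized to 1; the transport cost is the sum over
    branches of branch length times the absolute net mass below it.
    """
    ta = sum(mass_a.values())
    tb = sum(mass_b.values())
    if ta <= 0 or tb <= 0:
        raise ValueError("both placement sets must carry positive mass")
    n = len(tree.nodes)
    net = np.zeros(n)
    for node, m in mass_a.items():
        net[node] += m / ta
    for node, m in mass_b.items():
        net[node] -= m / tb
    dist = 0.0
    for v in tree._postorder:
        node = tree.nodes[v]
        for c in node.children:
            net[v] += net[c]
        if node.parent >= 0:
            dist += node.length * abs(net[v])
    return float(dist)
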