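"""Seed-Estimate-Place: local maximum-likelihood phylogenetic placement.

A read aligned to the profile consensus coordinates is placed on the
reference tree in three steps. Seed: candidate nodes are ranked by
observed p-distance between the read and each node's observed or
inferred sequence over the read's consensus interval. Estimate: for
every branch adjacent to a seed node, the attachment point and pendant
branch length are estimated from p-distances and the placement
likelihood is computed from the branch's cached directional conditional
log-likelihoods — the global tree is never modified. Place: the top
estimates are refined by iterated one-dimensional likelihood
optimization of the attachment point and pendant length; by the Pulley
Principle (time-reversible model) the optimized two-node subtree
likelihood equals the whole-tree likelihood with the read grafted.

Confidence is summarized as a Q-score: with softmax ("likelihood
weight") w of the chosen placement among all optimized candidates,
q = min(250, -10*log10(1 - w)).

Chimeras are screened by placing the 5' and 3' halves of the alignment
independently; when their best branches differ and the joint log-odds
LOD = (loglik5_best - loglik5_alt) + (loglik3_best - loglik3_alt)
exceeds the cutoff, the read is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .profile_hmm import HmmAlignment
from .ref_phylogeny import NEG_INF, PhyloTree, TreeError, encode_states, leaf_loglik

Q_MAX = 250.0


@dataclass
class PlacementConfig:
    max_seeds: int = 5
    top_n: int = 5
    tol: float = 1e-6
    max_iter: int = 100
    min_branch: float = 1e-6
    max_pendant: float = 5.0
    prior: str = "uniform"      # or "height": node-height weighted
    prior_tau: float = 1.0
    chimera_segments: int = 2
    min_segment: int = 30
    lod_cutoff: float = 50.0


@dataclass
class SeedCandidate:
    node: int
    p_dist: float


@dataclass
class PlacementEstimate:
    branch: int                  # child-node id of the branch
    w0: float
    w_ur: float
    w_rv: float
    w_nr: float
    loglik: float


@dataclass
class Placement:
    read_id: str
    branch_id: int
    w_ur: float
    w_rv: float
    w_nr: float
    loglik: float
    assigned_node: int
    taxonomy: str
    q_score: float
    cs_start: int = 0
    cs_end: int = 0
    aligned: str = ""
    sample: str = ""
    flags: str = ""

    @property
    def distal_length(self) -> float:
        return self.w_ur

    @property
    def pendant_length(self) -> float:
        return self.w_nr


@dataclass
class ChimeraResult:
    is_chimera: bool
    lod: float
    best5: int
    best3: int
    loglik5best: float
    loglik5alt: float
    loglik3best: float
    loglik3alt: float
    flags: str = ""


# ---------------------------------------------------------------------------
# read encoding helpers
# ---------------------------------------------------------------------------

def read_site_states(aln: HmmAlignment, S: int) -> np.ndarray:
    """Encode the aligned read over all S consensus sites (4 = unobserved)."""
    states = np.full(S, 4, dtype=np.int8)
    seg = encode_states(aln.aligned)
    states[aln.cs_start - 1: aln.cs_end] = seg
    return states


def read_loglik_matrix(states: np.ndarray, ncat: int) -> np.ndarray:
    L = leaf_loglik(states)
    return np.repeat(L[None, :, :], ncat, axis=0)


def _states_matrix(tree: PhyloTree) -> np.ndarray:
    cached = getattr(tree, "_states_mat", None)
    if cached is not None:
        return cached
    if tree.node_states is None:
        raise TreeError("ancestral sequences not inferred")
    mat = np.stack([encode_states(s) for s in tree.node_states])
    tree._states_mat = mat
    return mat


def p_distance(tree: PhyloTree, node: int, read_states: np.ndarray) -> float:
    """Observed mismatch fraction over shared non-gap sites."""
    ref = _states_matrix(tree)[node]
    both = (ref < 4) & (read_states < 4)
    n = int(both.sum())
    if n == 0:
        return 1.0
    return float(np.sum(ref[both] != read_states[both]) / n)


# ---------------------------------------------------------------------------
# Seed
# ---------------------------------------------------------------------------

def find_seed_nodes(tree: PhyloTree, read_states: np.ndarray,
                    max_seeds: int = 5) -> list[SeedCandidate]:
    """Rank all tree nodes by p-distance to the read; keep the best."""
    if not np.any(read_states < 4):
        raise TreeError("read has no observed consensus sites (unplaceable)")
    mat = _states_matrix(tree)
    both = (mat < 4) & (read_states[None, :] < 4)
    overlap = both.sum(axis=1)
    mism = ((mat != read_states[None, :]) & both).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pd = np.where(overlap > 0, mism / np.maximum(overlap, 1), 1.0)
    order = sorted(range(len(tree.nodes)), key=lambda i: (pd[i], i))
    return [SeedCandidate(node=i, p_dist=float(pd[i]))
            for i in order[:max_seeds]]


def candidate_branches(tree: PhyloTree, seeds: Sequence[SeedCandidate]
                       ) -> list[int]:
    """Branches incident to the seed nodes (branch id = child node id)."""
    out: list[int] = []
    seen = set()
    for s in seeds:
        node = tree.nodes[s.node]
        incident = list(node.children)
        if node.parent >= 0:
            incident.append(s.node)
        for b in incident:
            if b not in seen:
                seen.add(b)
                out.append(b)
    return out


# ---------------------------------------------------------------------------
# Estimate
# ---------------------------------------------------------------------------

def _branch_messages(tree: PhyloTree, branch: int):
    if tree.down[branch] is None:
        raise TreeError("tree not evaluated")
    U = tree.up_excl[branch]   # conditional at the parent end
    D = tree.down[branch]      # conditional at the child end
    return U, D


def _placement_loglik(tree: PhyloTree, U, D, R, w_ur: float, w_rv: float,
                      w_nr: float) -> float:
    Lr = (tree._conv_all(U, tree.branch_P(w_ur))
          + tree._conv_all(D, tree.branch_P(w_rv))
          + tree._conv_all(R, tree.branch_P(w_nr)))
    return tree._total_from(Lr, np.zeros_like(Lr))


def estimate_place(tree: PhyloTree, read_states: np.ndarray, branch: int,
                   config: PlacementConfig = PlacementConfig()
                   ) -> PlacementEstimate:
    """Fast placement estimate on one branch from p-distances.

    The attachment splits the branch proportionally to the read's
    p-distances to the two endpoints, and the pendant length is the
    excess of the nearer p-distance over the nearer half-branch.
    """
    node = tree.nodes[branch]
    u = node.parent
    if u < 0:
        raise ValueError("cannot place on the root pseudo-branch")
    w0 = node.length
    d_u = p_distance(tree, u, read_states)
    d_v = p_distance(tree, branch, read_states)
    total = d_u + d_v
    ratio = 0.5 if total == 0 else min(max(d_u / total, 0.0), 1.0)
    w_ur = ratio * w0
    w_rv = w0 - w_ur
    w_nr = max(min(d_u, d_v) - min(w_ur, w_rv), config.min_branch)
    U, D = _branch_messages(tree, branch)
    R = read_loglik_matrix(read_states, len(tree.rates))
    ll = _placement_loglik(tree, U, D, R, w_ur, w_rv, w_nr)
    return PlacementEstimate(branch=branch, w0=w0, w_ur=w_ur, w_rv=w_rv,
                             w_nr=w_nr, loglik=ll)


# ---------------------------------------------------------------------------
# Place (joint optimization)
# ---------------------------------------------------------------------------

def joint_opt_place(tree: PhyloTree, read_states: np.ndarray,
                    estimate: PlacementEstimate,
                    config: PlacementConfig = PlacementConfig()
                    ) -> PlacementEstimate:
    """Iterated 1-D likelihood maximization of attachment and pendant.

    Alternates bounded scalar optimization of the attachment point
    (w_ur in [0, w0]) and the pendant length (w_nr) until the placement
    log-likelihood improves by less than `tol` or `max_iter` is hit.
    Requires a reversible model (all supported models are).
    """
    U, D = _branch_messages(tree, estimate.branch)
    R = read_loglik_matrix(read_states, len(tree.rates))
    w0 = estimate.w0
    w_ur, w_nr = estimate.w_ur, estimate.w_nr
    best = _placement_loglik(tree, U, D, R, w_ur, w0 - w_ur, w_nr)
    flags = ""
    converged = False
    for _ in range(config.max_iter):
        if w0 > 0:
            res = minimize_scalar(
                lambda w: -_placement_loglik(tree, U, D, R, w, w0 - w, w_nr),
                bounds=(0.0, w0), method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun >= best:
                w_ur, best = float(res.x), -res.fun
        res = minimize_scalar(
            lambda w: -_placement_loglik(tree, U, D, R, w_ur, w0 - w_ur, w),
            bounds=(config.min_branch, config.max_pendant), method="bounded",
            options={"xatol": 1e-6},
        )
        new = -res.fun
        if new >= best:
            w_nr, improvement = float(res.x), new - best
            best = new
        else:
            improvement = 0.0
        if improvement < config.tol:
            converged = True
            break
    if not converged:
        flags = "nonconverged"
    out = PlacementEstimate(branch=estimate.branch, w0=w0, w_ur=w_ur,
                            w_rv=w0 - w_ur, w_nr=w_nr, loglik=best)
    out.flags = flags  # type: ignore[attr-defined]
    return out


def _assigned_node(tree: PhyloTree, est: PlacementEstimate,
                   min_branch: float) -> int:
    v = est.branch
    u = tree.nodes[v].parent
    if est.w_ur <= min_branch:
        return u
    if est.w_rv <= min_branch:
        return v
    return v  # taxonomy lives on nodes; interior points map to the child


def _q_score(weights: np.ndarray, chosen: int) -> float:
    w = float(weights[chosen])
    if w >= 1.0 - 1e-300:
        return Q_MAX
    return min(Q_MAX, -10.0 * math.log10(1.0 - w))


def place_read(tree: PhyloTree, aln: HmmAlignment,
               config: PlacementConfig = PlacementConfig(),
               sample: str = "") -> Placement:
    """Full SEP placement of one aligned read, with taxonomy and Q-score."""
    try:
        read_states = read_site_states(aln, tree.S)
        seeds = find_seed_nodes(tree, read_states, config.max_seeds)
    except TreeError:
        return Placement(read_id=aln.read_id, branch_id=-1, w_ur=0, w_rv=0,
                         w_nr=0, loglik=NEG_INF, assigned_node=-1, taxonomy="",
                         q_score=0.0, cs_start=aln.cs_start, cs_end=aln.cs_end,
                         aligned=aln.aligned, sample=sample, flags="unplaced")
    branches = candidate_branches(tree, seeds)
    estimates = [estimate_place(tree, read_states, b, config) for b in branches]
    estimates.sort(key=lambda e: (-e.loglik, e.branch))
    optimized = [joint_opt_place(tree, read_states, e, config)
                 for e in estimates[: config.top_n]]

    def score(est: PlacementEstimate) -> float:
        if config.prior == "height":
            node = _assigned_node(tree, est, config.min_branch)
            return est.loglik - tree.node_height(node) / config.prior_tau
        return est.loglik

    scores = np.array([score(e) for e in optimized])
    lw = scores - logsumexp(scores)
    weights = np.exp(lw)
    chosen = int(np.argmax(scores))
    best = optimized[chosen]
    node = _assigned_node(tree, best, config.min_branch)
    flags = getattr(best, "flags", "")
    return Placement(
        read_id=aln.read_id, branch_id=best.branch, w_ur=best.w_ur,
        w_rv=best.w_rv, w_nr=best.w_nr, loglik=best.loglik,
        assigned_node=node, taxonomy=tree.nodes[node].taxonomy,
        q_score=_q_score(weights, chosen),
        cs_start=aln.cs_start, cs_end=aln.cs_end, aligned=aln.aligned,
        sample=sample, flags=flags,
    )


# ---------------------------------------------------------------------------
# Chimera detection by segment placement comparison
# ---------------------------------------------------------------------------

def _segment_alignment(aln: HmmAlignment, lo_col: int, hi_col: int
                       ) -> HmmAlignment:
    """Sub-alignment over consensus columns [lo_col, hi_col] (1-based)."""
    off = aln.cs_start
    seg = aln.aligned[lo_col - off: hi_col - off + 1]
    return HmmAlignment(read_id=aln.read_id, cs_start=lo_col, cs_end=hi_col,
                        aligned=seg, vpath=[], score=0.0, banded=aln.banded)


def _best_for_segment(tree: PhyloTree, states: np.ndarray,
                      branches: Sequence[int], config: PlacementConfig
                      ) -> PlacementEstimate:
    estimates = [estimate_place(tree, states, b, config) for b in branches]
    estimates.sort(key=lambda e: (-e.loglik, e.branch))
    optimized = [joint_opt_place(tree, states, e, config)
                 for e in estimates[: config.top_n]]
    return max(optimized, key=lambda e: e.loglik)


def detect_chimera(tree: PhyloTree, aln: HmmAlignment,
                   config: PlacementConfig = PlacementConfig(),
                   lod_cutoff: Optional[float] = None) -> ChimeraResult:
    """Flag a read whose 5' and 3' halves place on different branches
    with joint LOD above the cutoff.

    Both segments are placed with the common candidate-branch set found
    by seeding on the whole read; the alternatives re-place each segment
    at the other segment's best branch.
    """
    cutoff = config.lod_cutoff if lod_cutoff is None else lod_cutoff
    width = aln.cs_end - aln.cs_start + 1
    nseg = config.chimera_segments
    if nseg % 2 != 0:
        raise ValueError("segment count must be even")
    if width < nseg * config.min_segment:
        return ChimeraResult(is_chimera=False, lod=0.0, best5=-1, best3=-1,
                             loglik5best=0, loglik5alt=0, loglik3best=0,
                             loglik3alt=0, flags="unknown:too_short")
    mid = aln.cs_start + width // 2 - 1
    seg5 = _segment_alignment(aln, aln.cs_start, mid)
    seg3 = _segment_alignment(aln, mid + 1, aln.cs_end)
    full_states = read_site_states(aln, tree.S)
    seeds = find_seed_nodes(tree, full_states, config.max_seeds)
    branches = candidate_branches(tree, seeds)
    s5 = read_site_states(seg5, tree.S)
    s3 = read_site_states(seg3, tree.S)
    best5 = _best_for_segment(tree, s5, branches, config)
    best3 = _best_for_segment(tree, s3, branches, config)
    # alternative: each segment re-placed at the other segment's branch
    alt5 = joint_opt_place(tree, s5,
                           estimate_place(tree, s5, best3.branch, config),
                           config)
    alt3 = joint_opt_place(tree, s3,
                           estimate_place(tree, s3, best5.branch, config),
                           config)
    lod = (best5.loglik - alt5.loglik) + (best3.loglik - alt3.loglik)
    node5 = _assigned_node(tree, best5, config.min_branch)
    node3 = _assigned_node(tree, best3, config.min_branch)
    flagged = (node5 != node3) and (lod >= cutoff)
    return ChimeraResult(is_chimera=bool(flagged), lod=float(lod),
                         best5=best5.branch, best3=best3.branch,
                         loglik5best=best5.loglik, loglik5alt=alt5.loglik,
                         loglik3best=best3.loglik, loglik3alt=alt3.loglik)


# ---------------------------------------------------------------------------
# test/oracle helper: graft the read as a real leaf and re-evaluate
# ---------------------------------------------------------------------------

def graft_read_tree(tree: PhyloTree, placement: Placement,
                    read_string: str) -> PhyloTree:
    """Build a new tree with the read attached at the placement and the
    caches re-evaluated; its total log-likelihood should match the
    placement's (Pulley Principle)."""
    from .ref_phylogeny import TreeNode

    nodes = [TreeNode(id=n.id, name=n.name, taxonomy=n.taxonomy,
                      parent=n.parent, children=list(n.children),
                      length=n.length) for n in tree.nodes]
    v = placement.branch_id
    u = nodes[v].parent
    r_id, n_id = len(nodes), len(nodes) + 1
    nodes.append(TreeNode(id=r_id, name="", parent=u,
                          children=[v, n_id], length=placement.w_ur))
    nodes.append(TreeNode(id=n_id, name="__query__", parent=r_id,
                          children=[], length=placement.w_nr))
    nodes[u].children = [r_id if c == v else c for c in nodes[u].children]
    nodes[v].parent = r_id
    nodes[v].length = placement.w_rv
    leaf_seqs = dict(tree.leaf_seqs)
    leaf_seqs["__query__"] = read_string
    grafted = PhyloTree(nodes, leaf_seqs, model=tree.model, dgamma=tree.dgamma)
    grafted.evaluate()
    return grafted
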