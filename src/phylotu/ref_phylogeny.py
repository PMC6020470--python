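"""Reference-tree engine: pruning likelihoods with directional caches.

Every branch of the rooted bifurcating reference tree carries two
conditional log-likelihood matrices after evaluation: the downward
message (likelihood of the subtree below the branch, conditioned on the
state at its child end) and the upward message (likelihood of everything
outside the subtree, conditioned on the state at its parent end). With a
time-reversible substitution model this makes any branch usable as a
local root — the Pulley Principle — which is what lets read placement
work on a two-node subtree without touching the global tree.

Conventions: leaf states A/C/G/T are certain (log-likelihood 0 for the
observed base, -inf otherwise); gaps and N are fully ambiguous
(likelihood 1 for every base). All matrices are (ncat, 4, S) where ncat
is the number of discrete-Gamma rate categories (1 for fixed-rate).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from . import evo_models, formats, profile_hmm
from .csfm_index import CsfmIndex, build_index
from .evo_models import DiscreteGamma, SubstModel, transition_matrix
from .formats import Msa, TreeSpec
from .profile_hmm import P7Profile, build_profile

NEG_INF = -np.inf
REFPKG_MAGIC = "PHYLOTU-REFPKG"
REFPKG_VERSION = 1

_IDX = {b: i for i, b in enumerate("ACGT")}


class TreeError(ValueError):
    pass


def encode_states(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int8)
    for i, c in enumerate(seq):
        if c in _IDX:
            out[i] = _IDX[c]
    return out


def leaf_loglik(states: np.ndarray) -> np.ndarray:
    """(4, S) leaf conditional log-likelihoods (Leaf-LogLik)."""
    S = len(states)
    L = np.full((4, S), NEG_INF)
    obs = states < 4
    L[states[obs], np.nonzero(obs)[0]] = 0.0
    L[:, ~obs] = 0.0  # gap/N: every base equally compatible
    return L


def convolute(L: np.ndarray, P: np.ndarray) -> np.ndarray:
    """out[i, s] = log sum_j P[i, j] * exp(L[j, s]), underflow-free.

    Transports a conditional log-likelihood matrix across a branch with
    transition matrix P (row-stochastic).
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (4, 4) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix must be 4x4 row-stochastic")
    # per-column max shift keeps exp() in range for entries down to -1e4+
    m = L.max(axis=0)
    with np.errstate(divide="ignore"):
        out = np.log(P @ np.exp(L - m[None, :])) + m[None, :]
    return out


@dataclass
class TreeNode:
    id: int
    name: str = ""
    taxonomy: str = ""
    parent: int = -1
    children: list[int] = field(default_factory=list)
    length: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted bifurcating tree with cached directional likelihoods."""

    def __init__(self, nodes: list[TreeNode], leaf_seqs: dict[str, str],
                 model: Optional[SubstModel] = None,
                 dgamma: Optional[DiscreteGamma] = None):
        self.nodes = nodes
        self.model = model
        self.dgamma = dgamma
        self.leaf_seqs = dict(leaf_seqs)
        self.S = len(next(iter(leaf_seqs.values()))) if leaf_seqs else 0
        self.leaf_states: dict[int, np.ndarray] = {}
        for node in nodes:
            if node.is_leaf:
                if node.name not in leaf_seqs:
                    raise TreeError(f"no sequence for leaf {node.name!r}")
                states = encode_states(leaf_seqs[node.name])
                if len(states) != self.S:
                    raise TreeError(f"leaf {node.name!r}: wrong sequence length")
                self.leaf_states[node.id] = states
        self.down: list[Optional[np.ndarray]] = [None] * len(nodes)
        self.up_excl: list[Optional[np.ndarray]] = [None] * len(nodes)
        self.node_states: Optional[list[str]] = None
        self.loglik: Optional[float] = None
        self._postorder = self._compute_postorder()

    # -- construction -------------------------------------------------

    @classmethod
    def from_treespec(cls, spec: TreeSpec, leaf_seqs: dict[str, str],
                      model: Optional[SubstModel] = None,
                      dgamma: Optional[DiscreteGamma] = None) -> "PhyloTree":
        nodes = [TreeNode(id=i, name=n.name, parent=n.parent,
                          children=list(n.children), length=n.length)
                 for i, n in enumerate(spec.nodes)]
        _canonicalize_bifurcating(nodes)
        return cls(nodes, leaf_seqs, model=model, dgamma=dgamma)

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(0, False)]
        while stack:
            idx, done = stack.pop()
            if done:
                order.append(idx)
            else:
                stack.append((idx, True))
                for c in self.nodes[idx].children:
                    stack.append((c, False))
        return order

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if n.is_leaf)

    def branches(self) -> list[int]:
        """Branch ids == non-root node ids (branch to the parent)."""
        return [n.id for n in self.nodes if n.parent >= 0]

    # -- likelihood machinery -----------------------------------------

    @property
    def rates(self) -> np.ndarray:
        if self.dgamma is None:
            return np.array([1.0])
        return self.dgamma.category_rates

    def branch_P(self, length: float) -> np.ndarray:
        """(ncat, 4, 4) per-category transition matrices for a branch."""
        return np.stack([transition_matrix(self.model, length, rate=r)
                         for r in self.rates])

    def _conv_all(self, L: np.ndarray, Ps: np.ndarray) -> np.ndarray:
        return np.stack([convolute(L[c], Ps[c]) for c in range(len(Ps))])

    def evaluate(self) -> float:
        """Felsenstein pruning: fill both directional caches, return loglik."""
        if self.model is None:
            raise TreeError("tree has no substitution model")
        ncat = len(self.rates)
        Pcache = {v: self.branch_P(self.nodes[v].length)
                  for v in self.branches()}
        # downward (postorder)
        for v in self._postorder:
            node = self.nodes[v]
            if node.is_leaf:
                L = leaf_loglik(self.leaf_states[v])
                self.down[v] = np.repeat(L[None, :, :], ncat, axis=0)
            else:
                acc = np.zeros((ncat, 4, self.S))
                for c in node.children:
                    acc += self._conv_all(self.down[c], Pcache[c])
                self.down[v] = acc
        # upward (preorder): up_excl[v] lives at v's parent end
        self.up_excl[0] = None
        for v in self._postorder[::-1]:
            node = self.nodes[v]
            if node.parent < 0:
                outside = np.zeros((len(self.rates), 4, self.S))
            else:
                outside = self._conv_all(self.up_excl[v], Pcache[v])
            for c in node.children:
                acc = outside.copy()
                for sib in node.children:
                    if sib != c:
                        acc += self._conv_all(self.down[sib], Pcache[sib])
                self.up_excl[c] = acc
        self.loglik = self._total_from(self.down[0],
                                       np.zeros((ncat, 4, self.S)))
        return self.loglik

    def _total_from(self, down: np.ndarray, up: np.ndarray) -> float:
        ncat = down.shape[0]
        logpi = np.log(self.model.pi)
        site = logsumexp(
            logpi[None, :, None] + down + up - math.log(ncat),
            axis=(0, 1),
        )
        return float(site.sum())

    def loglik_at(self, v: int) -> float:
        """Total log-likelihood recomputed with node v as local root."""
        if self.down[v] is None:
            raise TreeError("tree not evaluated")
        if v == 0:
            up = np.zeros_like(self.down[0])
        else:
            Ps = self.branch_P(self.nodes[v].length)
            up = self._conv_all(self.up_excl[v], Ps)
        return self._total_from(self.down[v], up)

    def marginal_log_posterior(self, v: int) -> np.ndarray:
        """(4, S) log posterior of states at node v (category-averaged)."""
        if self.down[v] is None:
            raise TreeError("tree not evaluated")
        if v == 0:
            up = np.zeros_like(self.down[0])
        else:
            Ps = self.branch_P(self.nodes[v].length)
            up = self._conv_all(self.up_excl[v], Ps)
        logpi = np.log(self.model.pi)
        joint = logsumexp(logpi[None, :, None] + self.down[v] + up, axis=0)
        return joint - logsumexp(joint, axis=0, keepdims=True)

    # -- ancestral states and taxonomy --------------------------------

    def infer_ancestral_sequences(self) -> None:
        """ML marginal states at internal nodes; gap where the node's
        descendant leaves are gap-majority at a site."""
        if self.down[0] is None:
            raise TreeError("tree not evaluated")
        n = len(self.nodes)
        gap_leaf = np.zeros((n, self.S))
        tot_leaf = np.zeros(n)
        for v in self._postorder:
            node = self.nodes[v]
            if node.is_leaf:
                gap_leaf[v] = (self.leaf_states[v] == 4)
                tot_leaf[v] = 1
            else:
                for c in node.children:
                    gap_leaf[v] += gap_leaf[c]
                    tot_leaf[v] += tot_leaf[c]
        states: list[str] = [""] * n
        for v in range(n):
            node = self.nodes[v]
            if node.is_leaf:
                states[v] = self.leaf_seqs[node.name]
                continue
            post = self.marginal_log_posterior(v)
            best = np.argmax(post, axis=0)
            chars = np.array(list("ACGT"))[best]
            gap_mask = gap_leaf[v] / tot_leaf[v] > 0.5
            chars[gap_mask] = "-"
            states[v] = "".join(chars)
        self.node_states = states

    def propagate_taxonomy(self, annotations: dict[str, str]) -> None:
        """Assign every unnamed node the nearest annotated ancestor's
        taxonomy. The root must be annotated (at least kingdom)."""
        by_name = dict(annotations)
        for node in self.nodes:
            node.taxonomy = by_name.get(node.name, "")
        if not self.nodes[0].taxonomy:
            raise TreeError("root has no taxonomy annotation")
        for v in self._postorder[::-1]:  # preorder
            node = self.nodes[v]
            if not node.taxonomy and node.parent >= 0:
                node.taxonomy = self.nodes[node.parent].taxonomy

    # -- convenience ---------------------------------------------------

    def node_seq(self, v: int) -> str:
        """Observed (leaf) or ML-inferred (internal) sequence of node v."""
        if self.node_states is None:
            raise TreeError("ancestral sequences not inferred")
        return self.node_states[v]

    def path_lengths_from(self, v: int) -> np.ndarray:
        """Branch-length distance from node v to every node."""
        n = len(self.nodes)
        dist = np.full(n, np.inf)
        dist[v] = 0.0
        # undirected BFS over the tree
        stack = [v]
        while stack:
            u = stack.pop()
            nbrs = list(self.nodes[u].children)
            if self.nodes[u].parent >= 0:
                nbrs.append(self.nodes[u].parent)
            for w in nbrs:
                edge = self.nodes[w].length if self.nodes[w].parent == u \
                    else self.nodes[u].length
                if dist[u] + edge < dist[w]:
                    dist[w] = dist[u] + edge
                    stack.append(w)
        return dist

    def node_height(self, v: int) -> float:
        """Maximal branch-length path from v down to a descendant leaf."""
        node = self.nodes[v]
        if node.is_leaf:
            return 0.0
        return max(self.node_height(c) + self.nodes[c].length
                   for c in node.children)

    def to_treespec(self) -> TreeSpec:
        return TreeSpec(nodes=[
            formats.TreeNodeSpec(name=n.name, parent=n.parent,
                                 children=list(n.children), length=n.length)
            for n in self.nodes
        ])


def _canonicalize_bifurcating(nodes: list[TreeNode]) -> None:
    """Split multifurcations by inserting zero-length internal branches."""
    i = 0
    while i < len(nodes):
        node = nodes[i]
        while len(node.children) > 2:
            keep = node.children[0]
            rest = node.children[1:]
            newid = len(nodes)
            newnode = TreeNode(id=newid, name="", parent=node.id,
                               children=rest, length=0.0)
            nodes.append(newnode)
            for c in rest:
                nodes[c].parent = newid
            node.children = [keep, newid]
            node = newnode  # continue splitting if still > 2
        i += 1


# ---------------------------------------------------------------------------
# Reference package
# ---------------------------------------------------------------------------

@dataclass
class ReferencePackage:
    msa: Msa
    index: CsfmIndex
    profile: P7Profile
    tree: PhyloTree
    taxonomy: dict[str, str]
    metadata: dict

    @property
    def S(self) -> int:
        return self.tree.S


def build_reference_package(msa: Msa, treespec: TreeSpec,
                            taxonomy: dict[str, str],
                            model_name: str = "GTR",
                            dgamma: bool = False,
                            model: Optional[SubstModel] = None,
                            seed: int = 0) -> ReferencePackage:
    """Assemble all components of a reference database.

    Builds the consensus FM-index and the plan7 profile from the MSA,
    attaches the MSA leaf sequences (restricted to match columns) to the
    tree, trains the substitution model from the alignment if one is not
    supplied, evaluates the tree, infers ancestral sequences, and
    propagates taxonomy. With `dgamma`, the discrete-Gamma shape is
    estimated from per-site mutation counts and the tree re-evaluated.
    """
    leaf_names = {n.name for n in treespec.nodes if not n.children}
    msa_ids = {rec.id for rec in msa.records}
    orphans = sorted(leaf_names - msa_ids)
    if orphans:
        raise TreeError(f"tree leaves missing from alignment: {orphans}")

    match_cols = msa.match_columns()
    consensus = "".join(msa.consensus[j] for j in match_cols)
    index = build_index(consensus)
    profile = build_profile(msa)
    leaf_seqs = {
        rec.id: "".join(rec.seq[j] for j in match_cols)
        for rec in msa.records if rec.id in leaf_names
    }
    if model is None:
        model = evo_models.train_subst_model(
            [leaf_seqs[n] for n in sorted(leaf_seqs)],
            method="gojobori3", model_name=model_name, seed=seed,
        )
    tree = PhyloTree.from_treespec(treespec, leaf_seqs, model=model)
    tree.evaluate()
    tree.infer_ancestral_sequences()
    meta = {"model": model.name, "dgamma": bool(dgamma), "seed": seed,
            "version": REFPKG_VERSION}
    if dgamma:
        counts = evo_models.count_site_mutations(tree)
        alpha = evo_models.estimate_gamma_shape(counts)
        if alpha is not None:
            tree.dgamma = evo_models.discretize_gamma(alpha, 4)
            tree.evaluate()
            tree.infer_ancestral_sequences()
            meta["gamma_shape"] = alpha
    tree.propagate_taxonomy(taxonomy)
    return ReferencePackage(msa=msa, index=index, profile=profile, tree=tree,
                            taxonomy=dict(taxonomy), metadata=meta)


def save_reference_package(pkg: ReferencePackage, path) -> None:
    """Write the package as a single self-describing JSON container."""
    msa_text = "".join(f">{r.id}\n{r.seq}\n" for r in pkg.msa.records)
    doc = {
        "magic": REFPKG_MAGIC,
        "version": REFPKG_VERSION,
        "msa": msa_text,
        "newick": formats.write_newick(pkg.tree.to_treespec()),
        "taxonomy": pkg.taxonomy,
        "model": evo_models.write_model_text(pkg.tree.model),
        "gamma_shape": pkg.metadata.get("gamma_shape"),
        "metadata": pkg.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_reference_package(path) -> ReferencePackage:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("magic") != REFPKG_MAGIC:
        raise TreeError(f"{path}: not a reference package")
    records = []
    cur_id, cur_seq = None, []
    for line in doc["msa"].splitlines():
        if line.startswith(">"):
            if cur_id is not None:
                records.append(formats.SeqRecord(id=cur_id, seq="".join(cur_seq)))
            cur_id, cur_seq = line[1:].split()[0], []
        else:
            cur_seq.append(line)
    if cur_id is not None:
        records.append(formats.SeqRecord(id=cur_id, seq="".join(cur_seq)))
    msa = Msa(records=records)
    spec = formats.parse_newick(doc["newick"])
    model = evo_models.read_model_text(doc["model"])
    pkg = build_reference_package(
        msa, spec, doc["taxonomy"],
        model_name=model.name, dgamma=False, model=model,
        seed=doc["metadata"].get("seed", 0),
    )
    if doc.get("gamma_shape"):
        pkg.tree.dgamma = evo_models.discretize_gamma(doc["gamma_shape"], 4)
        pkg.tree.evaluate()
        pkg.tree.infer_ancestral_sequences()
        pkg.metadata["gamma_shape"] = doc["gamma_shape"]
    pkg.metadata.update(doc["metadata"])
    return pkg
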