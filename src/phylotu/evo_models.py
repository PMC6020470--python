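"""Time-reversible DNA substitution models and among-site rate variation.

Models: GTR (6 free exchangeabilities), TN93 (two transition rates, one
transversion rate) and HKY85 (one transition/transversion ratio), all
parameterized by equilibrium frequencies pi and a symmetric
exchangeability matrix R, with the rate matrix Q scaled to one expected
substitution per unit time. Reversibility (pi_i Q_ij = pi_j Q_ji) lets
P(t) = exp(Qt) be computed through a symmetric eigendecomposition, which
is numerically stable and gives a real spectrum for all three models.

Among-site rate variation uses the discrete-Gamma approximation with k
equal-probability categories; the shape parameter is estimated from
per-site mutation counts by negative-binomial moment matching.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
# transitions: A<->G (purines), C<->T (pyrimidines)
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}

MODEL_NAMES = ("GTR", "TN93", "HKY85")


class ModelError(ValueError):
    pass


@dataclass
class SubstModel:
    """A reversible DNA model: Q_ij = R_ij * pi_j (i != j), mean rate 1."""

    name: str
    pi: np.ndarray           # (4,) equilibrium frequencies, sum 1
    R: np.ndarray            # (4,4) symmetric exchangeabilities, zero diagonal
    Q: np.ndarray = field(init=False)
    _eig: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ModelError(f"unknown model {self.name!r}")
        self.pi = np.asarray(self.pi, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.pi.shape != (4,) or not np.isclose(self.pi.sum(), 1.0):
            raise ModelError("pi must be 4 frequencies summing to 1")
        if not np.allclose(self.R, self.R.T):
            raise ModelError("exchangeability matrix must be symmetric")
        Q = self.R * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(self.pi @ np.diag(Q))
        if mu <= 0:
            raise ModelError("degenerate rate matrix (zero mean rate)")
        self.Q = Q / mu
        # symmetrized decomposition: B = D^{1/2} Q D^{-1/2} is symmetric
        sq = np.sqrt(self.pi)
        B = (self.Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self._eig = (lam, V, sq)


def transition_matrix(model: SubstModel, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q * rate * t); rows sum to 1."""
    if t < 0:
        raise ValueError("negative evolutionary time")
    lam, V, sq = model._eig
    E = V * np.exp(lam * rate * t)[None, :]
    P = (E @ V.T) * sq[None, :] / sq[:, None]
    # clip tiny negative round-off and renormalize rows
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _fit_exchangeabilities(name: str, counts: np.ndarray, pi: np.ndarray
                           ) -> np.ndarray:
    """Exchangeabilities from a symmetrized substitution-count matrix.

    For GTR each off-diagonal pair gets its own parameter
    R_ij ~ F_ij / (pi_i pi_j); TN93 pools the two transition classes
    separately and all transversions together; HKY85 pools all
    transitions. Scale is irrelevant (Q is renormalized).
    """
    F = (counts + counts.T) / 2.0
    rate = np.zeros((4, 4))
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    raw = {}
    for i, j in pairs:
        denom = pi[i] * pi[j]
        raw[(i, j)] = F[i, j] / denom if denom > 0 else 0.0
    if name == "GTR":
        for (i, j), v in raw.items():
            rate[i, j] = rate[j, i] = v
    else:
        ts_ag = raw[(0, 2)]
        ts_ct = raw[(1, 3)]
        tv_pairs = [p for p in pairs if p not in ((0, 2), (1, 3))]
        tv = np.mean([raw[p] for p in tv_pairs])
        if name == "HKY85":
            ts_ag = ts_ct = (raw[(0, 2)] * pi[0] * pi[2] + raw[(1, 3)] * pi[1] * pi[3]) \
                / max(pi[0] * pi[2] + pi[1] * pi[3], 1e-300)
        for i, j in pairs:
            v = tv
            if (i, j) == (0, 2):
                v = ts_ag
            elif (i, j) == (1, 3):
                v = ts_ct
            rate[i, j] = rate[j, i] = v
    if not np.any(rate > 0):
        raise ModelError("no informative substitutions observed")
    return rate


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _IDX.items():
        out[arr == ord(b)] = i
    return out


def train_subst_model(seqs: Sequence[str], tree=None, method: str = "gojobori3",
                      model_name: str = "GTR", max_triplets: int = 50_000,
                      seed: int = 0) -> SubstModel:
    """Train a DNA model from aligned sequences.

    gojobori3: ancestral states of sequence pairs are resolved by a third
    (outgroup) sequence — at sites where the outgroup agrees with one of
    the pair, that state is taken as ancestral and a substitution toward
    the other member is counted. goldman2: substitutions are counted
    symmetrically over sequence pairs. Triplet/pair enumeration is capped
    at `max_triplets`, subsampled deterministically from `seed`.
    """
    seqs = list(seqs)
    need = 3 if method == "gojobori3" else 2
    if len(seqs) < need:
        raise ModelError(f"{method} needs at least {need} sequences")
    enc = [_encode(s) for s in seqs]
    L = len(enc[0])
    if any(len(e) != L for e in enc):
        raise ModelError("sequences must be aligned to equal length")

    base_counts = np.zeros(4)
    for e in enc:
        for b in range(4):
            base_counts[b] += int(np.sum(e == b))
    if base_counts.sum() == 0:
        raise ModelError("no unambiguous bases")
    pi = base_counts / base_counts.sum()

    counts = np.zeros((4, 4))
    rng = np.random.default_rng(seed)
    n = len(seqs)
    if method == "gojobori3":
        combos = list(itertools.permutations(range(n), 3))
        # (a, b, o): o is the outgroup resolving the a/b ancestor
        if len(combos) > max_triplets:
            pick = rng.choice(len(combos), size=max_triplets, replace=False)
            combos = [combos[i] for i in sorted(pick)]
        for a, b, o in combos:
            ea, eb, eo = enc[a], enc[b], enc[o]
            valid = (ea < 4) & (eb < 4) & (eo < 4) & (ea != eb)
            anc_is_a = valid & (eo == ea)
            anc_is_b = valid & (eo == eb)
            for anc, der, mask in ((ea, eb, anc_is_a), (eb, ea, anc_is_b)):
                if not mask.any():
                    continue
                np.add.at(counts, (anc[mask], der[mask]), 1.0)
    elif method == "goldman2":
        combos = list(itertools.combinations(range(n), 2))
        if len(combos) > max_triplets:
            pick = rng.choice(len(combos), size=max_triplets, replace=False)
            combos = [combos[i] for i in sorted(pick)]
        for a, b in combos:
            ea, eb = enc[a], enc[b]
            valid = (ea < 4) & (eb < 4) & (ea != eb)
            if valid.any():
                np.add.at(counts, (ea[valid], eb[valid]), 0.5)
                np.add.at(counts, (eb[valid], ea[valid]), 0.5)
    else:
        raise ValueError(f"unknown training method {method!r}")

    if not np.any(counts > 0):
        raise ModelError("no informative sites (sequences are identical)")
    R = _fit_exchangeabilities(model_name, counts, pi)
    return SubstModel(name=model_name, pi=pi, R=R)


# ---------------------------------------------------------------------------
# Discrete-Gamma rate variation
# ---------------------------------------------------------------------------

RATE_HOMOGENEOUS = None  # sentinel returned when counts show no over-dispersion


@dataclass
class DiscreteGamma:
    alpha: float
    k: int
    category_rates: np.ndarray

    def __post_init__(self) -> None:
        self.category_rates = np.asarray(self.category_rates, dtype=float)
        if not np.isclose(self.category_rates.mean(), 1.0, atol=1e-9):
            raise ModelError("category rates must average 1")


def estimate_gamma_shape(site_mutation_counts: Sequence[int]) -> Optional[float]:
    """Moment-matching shape estimate: alpha = m^2 / (v - m).

    Per-site mutation counts under Gamma-distributed rates follow a
    negative-binomial law whose over-dispersion identifies the shape.
    Returns None (rate-homogeneous sentinel) when variance <= mean.
    """
    counts = np.asarray(site_mutation_counts, dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("counts must be non-negative and non-empty")
    m = counts.mean()
    v = counts.var()
    if v <= m or m == 0:
        return RATE_HOMOGENEOUS
    return float(m * m / (v - m))


def discretize_gamma(alpha: float, k: int = 4) -> DiscreteGamma:
    """k equal-probability categories with the category-mean rates.

    Rates are the conditional means of Gamma(alpha, scale=1/alpha) within
    each inter-quantile slice, renormalized to average exactly 1.
    """
    if k < 1:
        raise ValueError("need at least one rate category")
    if alpha <= 0:
        raise ValueError("shape must be positive")
    if k == 1:
        return DiscreteGamma(alpha=alpha, k=1, category_rates=np.array([1.0]))
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X; a<X<b] = mean * (F_{alpha+1}(b) - F_{alpha+1}(a)), mean = 1
    upper_cdf = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(upper_cdf)
    rates = rates / rates.mean()
    return DiscreteGamma(alpha=alpha, k=k, category_rates=rates)


def count_site_mutations(tree) -> np.ndarray:
    """Per-site count of branches whose parent/child states differ.

    `tree` must carry maximum-likelihood state strings on every node
    (leaves observed, internal nodes inferred); gap/ambiguous sites on
    either end of a branch are not counted.
    """
    seqs = getattr(tree, "node_states", None)
    if seqs is None:
        seqs = [getattr(n, "inferred_seq", None) for n in tree.nodes]
    if any(s is None for s in seqs):
        raise ValueError("tree has not been evaluated (missing node states)")
    S = len(seqs[0])
    counts = np.zeros(S, dtype=np.int64)
    for i, node in enumerate(tree.nodes):
        p = node.parent
        if p < 0:
            continue
        a = _encode(seqs[p])
        b = _encode(seqs[i])
        diff = (a < 4) & (b < 4) & (a != b)
        counts += diff.astype(np.int64)
    return counts


# ---------------------------------------------------------------------------
# Plain-text model files
# ---------------------------------------------------------------------------

def write_model_text(model: SubstModel) -> str:
    lines = [f"MODEL\t{model.name}"]
    lines.append("PI\t" + "\t".join(f"{x:.10g}" for x in model.pi))
    for i, b in enumerate(BASES):
        lines.append(f"R[{b}]\t" + "\t".join(f"{x:.10g}" for x in model.R[i]))
    for i, b in enumerate(BASES):
        lines.append(f"Q[{b}]\t" + "\t".join(f"{x:.10g}" for x in model.Q[i]))
    return "\n".join(lines) + "\n"


def read_model_text(text: str) -> SubstModel:
    name = None
    pi = None
    R = np.zeros((4, 4))
    for line in text.splitlines():
        parts = line.strip().split("\t")
        if not parts or not parts[0]:
            continue
        if parts[0] == "MODEL":
            name = parts[1]
        elif parts[0] == "PI":
            pi = np.array([float(x) for x in parts[1:5]])
        elif parts[0].startswith("R["):
            i = _IDX[parts[0][2]]
            R[i] = [float(x) for x in parts[1:5]]
    if name is None or pi is None:
        raise ModelError("incomplete model file")
    return SubstModel(name=name, pi=pi, R=R)
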