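"""plan7 profile-HMM: training from a reference alignment, and banded or
full Viterbi alignment of reads against it.

Architecture. K match states (one per alignment column with <= 50% gaps)
with insert and delete companions, plus the seven special states:
N (5' flank), B (begin), E (end), C (3' flank), and the terminal
flanking-insert states I_0/I_K for untemplated 5'/3' overhangs.
Alignment is global with respect to the read (every base is emitted by
N, M, I, or C) and local with respect to the profile through uniform
wing-retracted entries B->M_k and exits M_k->E, which also makes empty
match paths impossible by construction. All arithmetic is in natural-log
space; the Viterbi score is the maximum path log-likelihood.

Banding. When the consensus FM-index anchors one or both read ends, the
Viterbi recurrence is restricted to dynamic-programming cells within
`band_width` diagonals of the seed diagonals; the banded score can never
exceed the full score and equals it whenever the optimal path stays in
the band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, psi

from .csfm_index import CsfmIndex, SeedPath, find_seeds
from .formats import Msa

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
NEG_INF = -np.inf

# special-state constants (probabilities, not trained from data)
P_LOOP_FLANK = 0.9     # N->N and C->C self-loop
P_ENTRY_I0 = 0.02      # B->I_0 (5' overhang)
P_EXIT = 0.01          # M_k->E uniform local exit (k < K)
P_MK_IK = 0.05         # M_K->I_K (3' overhang); M_K->E gets the rest
P_LOOP_TAIL_INS = 0.9  # I_0/I_K self-loop


class HmmError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dirichlet priors
# ---------------------------------------------------------------------------

@dataclass
class DirichletDensity:
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet concentrations must be positive")

    def posterior_mean(self, counts: np.ndarray) -> np.ndarray:
        post = counts + self.alpha
        return post / post.sum()


@dataclass
class DirichletMixture:
    components: list[tuple[float, DirichletDensity]]

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components])
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must be positive and sum to 1")

    def posterior_mean(self, counts: np.ndarray) -> np.ndarray:
        logr = np.array(
            [math.log(w) + _dirmult_loglik(counts[None, :], d.alpha)
             for w, d in self.components]
        )
        logr -= logr.max()
        r = np.exp(logr)
        r /= r.sum()
        out = np.zeros_like(counts, dtype=float)
        for resp, (_, d) in zip(r, self.components):
            out += resp * d.posterior_mean(counts)
        return out


def _dirmult_loglik(rows: np.ndarray, alpha: np.ndarray,
                    weights: Optional[np.ndarray] = None) -> float:
    """Weighted Dirichlet-multinomial (Polya) marginal log-likelihood,
    dropping the alpha-free multinomial coefficient."""
    A = alpha.sum()
    n = rows.sum(axis=1)
    per_row = (
        gammaln(A) - gammaln(n + A)
        + (gammaln(rows + alpha[None, :]) - gammaln(alpha[None, :])).sum(axis=1)
    )
    if weights is None:
        return float(per_row.sum())
    return float(per_row @ weights)


def _fit_polya(rows: np.ndarray, weights: Optional[np.ndarray] = None,
               x0: Optional[np.ndarray] = None) -> DirichletDensity:
    """Maximum-likelihood Polya fit by L-BFGS on log-concentrations."""
    d = rows.shape[1]
    if x0 is None:
        x0 = np.ones(d)

    def objective(log_alpha):
        alpha = np.exp(log_alpha)
        A = alpha.sum()
        n = rows.sum(axis=1)
        w = weights if weights is not None else np.ones(len(rows))
        ll = (
            (gammaln(A) - gammaln(n + A)) * w
        ).sum() + (
            ((gammaln(rows + alpha[None, :]) - gammaln(alpha[None, :]))
             * w[:, None]).sum()
        )
        grad_alpha = (
            (psi(A) - psi(n + A)) @ w * np.ones(d)
            + ((psi(rows + alpha[None, :]) - psi(alpha[None, :]))
               * w[:, None]).sum(axis=0)
        )
        grad = -grad_alpha * alpha  # chain rule through exp
        return -ll, grad

    res = minimize(objective, np.log(x0), jac=True, method="L-BFGS-B")
    return DirichletDensity(alpha=np.exp(res.x))


def train_dirichlet(observations: np.ndarray, model_kind: str = "density",
                    ncomp: int = 1, seed: int = 0, n_iter: int = 50):
    """Fit a Dirichlet density or mixture to rows of event counts by
    (approximately) maximizing the Dirichlet-multinomial marginal
    likelihood. Mixtures are fit by EM over component responsibilities.
    """
    rows = np.asarray(observations, dtype=float)
    if rows.ndim != 2 or np.any(rows < 0) or not np.any(rows.sum(axis=1) > 0):
        raise ValueError("observations must be non-negative counts with "
                         "at least one positive row")
    rows = rows[rows.sum(axis=1) > 0]
    if model_kind == "density":
        return _fit_polya(rows)
    if model_kind != "mixture":
        raise ValueError(f"unknown model kind {model_kind!r}")

    rng = np.random.default_rng(seed)
    d = rows.shape[1]
    # start every component at the pooled density fit (perturbed after the
    # first) so a 1-component mixture reduces exactly to the density model
    pooled = _fit_polya(rows)
    comps = [DirichletDensity(alpha=pooled.alpha *
                              np.exp(rng.normal(0, 0.3, size=d) if m else
                                     np.zeros(d)))
             for m in range(ncomp)]
    weights = np.full(ncomp, 1.0 / ncomp)
    if ncomp == 1:
        return DirichletMixture(components=[(1.0, pooled)])
    for _ in range(n_iter):
        # E-step
        logr = np.stack(
            [np.log(w) + _polya_rowwise(rows, c.alpha)
             for w, c in zip(weights, comps)], axis=1
        )
        logr -= logr.max(axis=1, keepdims=True)
        resp = np.exp(logr)
        resp /= resp.sum(axis=1, keepdims=True)
        # M-step
        weights = resp.mean(axis=0)
        weights = np.clip(weights, 1e-8, None)
        weights /= weights.sum()
        comps = [_fit_polya(rows, weights=resp[:, m], x0=comps[m].alpha)
                 for m in range(ncomp)]
    return DirichletMixture(components=list(zip(weights.tolist(), comps)))


def _polya_rowwise(rows: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    A = alpha.sum()
    n = rows.sum(axis=1)
    return (
        gammaln(A) - gammaln(n + A)
        + (gammaln(rows + alpha[None, :]) - gammaln(alpha[None, :])).sum(axis=1)
    )


def mixture_marginal_loglik(prior, rows: np.ndarray) -> float:
    """Marginal data log-likelihood under a density or mixture prior."""
    rows = np.asarray(rows, dtype=float)
    if isinstance(prior, DirichletDensity):
        return float(_polya_rowwise(rows, prior.alpha).sum())
    per = np.stack(
        [np.log(w) + _polya_rowwise(rows, c.alpha) for w, c in prior.components],
        axis=1,
    )
    m = per.max(axis=1, keepdims=True)
    return float((m[:, 0] + np.log(np.exp(per - m).sum(axis=1))).sum())


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

@dataclass
class P7Profile:
    K: int
    match_emis: np.ndarray    # (K+1, 4) log-probs, rows 1..K used
    ins_emis: np.ndarray      # (K+1, 4) log-probs, rows 0..K (I_0..I_K)
    # transitions, rows 1..K-1 meaningful unless noted
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    entry: np.ndarray         # (K+1,) log B->M_k
    exit_: np.ndarray         # (K+1,) log M_k->E
    cs_map: list[int] = field(default_factory=list)  # match index -> MSA column

    @property
    def log_bg(self) -> float:
        return math.log(0.25)


def position_specific_weights(msa: Msa) -> np.ndarray:
    """Henikoff position-based sequence weights, normalized to mean 1.

    Each residue contributes 1/(r * s) where r is the number of distinct
    symbols in its column and s the count of its own symbol; summing over
    columns rewards sequences carrying rare states.
    """
    n = msa.nseq
    w = np.zeros(n)
    for j in range(msa.L):
        col = [rec.seq[j] for rec in msa.records]
        symbols = [c for c in col if c != "-"]
        if not symbols:
            continue
        from collections import Counter

        counts = Counter(symbols)
        r = len(counts)
        for i, c in enumerate(col):
            if c != "-":
                w[i] += 1.0 / (r * counts[c])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def _posterior(counts: np.ndarray, prior) -> np.ndarray:
    if prior is None:
        prior = DirichletDensity(alpha=np.ones_like(counts, dtype=float))
    return prior.posterior_mean(counts)


def build_profile(msa: Msa, dd_transition_prior: Optional[DirichletDensity] = None,
                  dd_insert_prior: Optional[DirichletDensity] = None,
                  dm_match_prior=None, max_gap_frac: float = 0.5) -> P7Profile:
    """Train the plan7 profile from an alignment under Dirichlet priors.

    Match states are columns with gap fraction <= `max_gap_frac`;
    emissions and transitions are posterior means of position-specific
    weighted counts under the supplied priors (symmetric Dirichlet(1)
    when a prior is omitted).
    """
    match_cols = msa.match_columns(max_gap_frac)
    if not match_cols:
        raise HmmError("alignment has no match columns")
    K = len(match_cols)
    col_state = {}  # MSA column -> (kind, k)
    k = 0
    last_match = 0
    for j in range(msa.L):
        if j in set(match_cols):
            k += 1
            col_state[j] = ("M", k)
            last_match = k
        else:
            col_state[j] = ("I", last_match)

    weights = position_specific_weights(msa)
    mcounts = np.zeros((K + 1, 4))
    icounts = np.zeros((K + 1, 4))
    # transition counts per source position: rows of [MM, MI, MD, IM, II, DM, DD]
    tcounts = np.zeros((K + 1, 7))
    for rec, w in zip(msa.records, weights):
        path = []  # (state_kind, k) for emitting/deleting columns
        for j in range(msa.L):
            kind, kk = col_state[j]
            c = rec.seq[j]
            if kind == "M":
                if c == "-":
                    path.append(("D", kk))
                else:
                    path.append(("M", kk))
                    if c in _IDX:
                        mcounts[kk, _IDX[c]] += w
            else:
                if c != "-":
                    path.append(("I", kk))
                    if c in _IDX:
                        icounts[kk, _IDX[c]] += w
        # transition walk (interior of the alignment path)
        for (k1, p1), (k2, p2) in zip(path, path[1:]):
            key = k1 + k2  # e.g. "MM", "MI"...
            col = {"MM": 0, "MI": 1, "MD": 2, "IM": 3, "II": 4,
                   "DM": 5, "DD": 6}.get(key)
            if col is None:  # I->D / D->I not representable in plan7
                continue
            tcounts[p1, col] += w

    match_emis = np.full((K + 1, 4), NEG_INF)
    ins_emis = np.full((K + 1, 4), NEG_INF)
    for kk in range(1, K + 1):
        prior = dm_match_prior
        probs = (prior.posterior_mean(mcounts[kk]) if prior is not None
                 else _posterior(mcounts[kk], None))
        match_emis[kk] = np.log(probs)
    for kk in range(0, K + 1):
        probs = (dd_insert_prior.posterior_mean(icounts[kk])
                 if dd_insert_prior is not None
                 else _posterior(icounts[kk], None))
        ins_emis[kk] = np.log(probs)

    t_mm = np.full(K + 1, NEG_INF)
    t_mi = np.full(K + 1, NEG_INF)
    t_md = np.full(K + 1, NEG_INF)
    t_im = np.full(K + 1, NEG_INF)
    t_ii = np.full(K + 1, NEG_INF)
    t_dm = np.full(K + 1, NEG_INF)
    t_dd = np.full(K + 1, NEG_INF)
    tp = dd_transition_prior
    for kk in range(1, K):
        m = tcounts[kk, 0:3]
        probs = (tp.posterior_mean(m) if tp is not None and len(tp.alpha) == 3
                 else _posterior(m, None))
        t_mm[kk], t_mi[kk], t_md[kk] = np.log(probs)
        i2 = _posterior(tcounts[kk, 3:5], None)
        t_im[kk], t_ii[kk] = np.log(i2)
        d2 = _posterior(tcounts[kk, 5:7], None)
        t_dm[kk], t_dd[kk] = np.log(d2)

    entry, exit_ = _entry_exit(K)
    return P7Profile(
        K=K, match_emis=match_emis, ins_emis=ins_emis,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd, entry=entry, exit_=exit_,
        cs_map=match_cols,
    )


def _entry_exit(K: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform wing-retracted entries; uniform exits except M_K, whose
    remaining mass goes to the 3' tail insert I_K."""
    entry = np.full(K + 1, NEG_INF)
    entry[1:] = math.log((1.0 - P_ENTRY_I0) / K)
    exit_ = np.full(K + 1, NEG_INF)
    exit_[1:] = math.log(P_EXIT)
    exit_[K] = math.log(1.0 - P_MK_IK)
    return entry, exit_


# ---------------------------------------------------------------------------
# Viterbi alignment
# ---------------------------------------------------------------------------

@dataclass
class HmmAlignment:
    read_id: str
    cs_start: int
    cs_end: int
    aligned: str
    vpath: list[str]
    score: float
    banded: bool
    strand: str = "+"
    flags: str = ""


def _encode_read(read: str) -> np.ndarray:
    out = np.empty(len(read), dtype=np.int8)
    for i, c in enumerate(read):
        if c in _IDX:
            out[i] = _IDX[c]
        elif c == "N":
            out[i] = 4
        else:
            raise HmmError(f"invalid read symbol {c!r}")
    return out


def _emission_rows(emis: np.ndarray, sym: int) -> np.ndarray:
    """Per-state log emission of read symbol `sym`; 'N' (sym 4) scores 0."""
    if sym == 4:
        return np.zeros(emis.shape[0])
    return emis[:, sym]


def _viterbi_dp(profile: P7Profile, read: str,
                band: Optional[tuple[np.ndarray, np.ndarray]] = None):
    """Run the plan7 Viterbi DP; returns the value matrices and score.

    `band` optionally gives per-read-position inclusive match-state
    bounds (klo[i], khi[i]); cells outside are forced to -inf.
    """
    if not read:
        raise HmmError("empty read")
    K = profile.K
    x = _encode_read(read)
    n = len(x)
    log_bg = profile.log_bg
    log_nn = math.log(P_LOOP_FLANK)
    log_nb = math.log(1 - P_LOOP_FLANK)
    log_bi0 = math.log(P_ENTRY_I0)
    log_i0loop = math.log(P_LOOP_TAIL_INS)
    log_i0m = math.log(1 - P_LOOP_TAIL_INS)
    # M_k emits then leaves: scale trained M transitions by the survival
    # probability (1 - P_EXIT) so every outgoing distribution sums to 1
    log_surv = math.log(1 - P_EXIT)

    VM = np.full((n + 1, K + 1), NEG_INF)
    VI = np.full((n + 1, K + 1), NEG_INF)   # I_1..I_{K-1} and I_K at col K
    VD = np.full((n + 1, K + 1), NEG_INF)
    VI0 = np.full(n + 1, NEG_INF)
    VN = np.full(n + 1, NEG_INF)
    VB = np.full(n + 1, NEG_INF)
    VE = np.full(n + 1, NEG_INF)
    VC = np.full(n + 1, NEG_INF)

    VN[0] = 0.0
    VB[0] = VN[0] + log_nb
    tmm = profile.t_mm + log_surv
    tmi = profile.t_mi + log_surv
    tmd = profile.t_md + log_surv
    ks = np.arange(K + 1)
    for i in range(1, n + 1):
        sym = int(x[i - 1])
        e_bg = 0.0 if sym == 4 else log_bg
        VN[i] = VN[i - 1] + e_bg + log_nn
        VB[i] = VN[i] + log_nb
        VI0[i] = (0.0 if sym == 4 else profile.ins_emis[0, sym]) + max(
            VB[i - 1] + log_bi0, VI0[i - 1] + log_i0loop
        )
        em = _emission_rows(profile.match_emis, sym)
        # predecessors at i-1, k-1 (shift right by one state)
        prev_m = np.concatenate(([NEG_INF], VM[i - 1, :-1] + tmm[:-1]))
        prev_i = np.concatenate(([NEG_INF], VI[i - 1, :-1] + profile.t_im[:-1]))
        prev_d = np.concatenate(([NEG_INF], VD[i - 1, :-1] + profile.t_dm[:-1]))
        prev_b = VB[i - 1] + profile.entry
        cand = np.maximum.reduce([prev_m, prev_i, prev_d, prev_b])
        if K >= 1:
            cand[1] = max(cand[1], VI0[i - 1] + log_i0m)
        VM[i] = em + cand
        VM[i, 0] = NEG_INF
        ei = _emission_rows(profile.ins_emis, sym)
        VI[i] = ei + np.maximum(VM[i - 1] + tmi, VI[i - 1] + profile.t_ii)
        VI[i, 0] = NEG_INF
        # I_K: entered from M_K, loops, exits to E
        VI[i, K] = (0.0 if sym == 4 else profile.ins_emis[K, sym]) + max(
            VM[i - 1, K] + math.log(P_MK_IK),
            VI[i - 1, K] + log_i0loop,
        )
        if band is not None:
            klo, khi = band[0][i], band[1][i]
            mask = (ks < klo) | (ks > khi)
            VM[i, mask] = NEG_INF
            VI[i, mask & (ks != K)] = NEG_INF
        # delete chain along k: VD[i,k] = max(VM[i,k-1]+tMD, VD[i,k-1]+tDD)
        # solved as a prefix max over the M entry points
        tdd = profile.t_dd
        cum = np.zeros(K + 1)
        cum[2:] = np.cumsum(tdd[1:K])  # cum[k] = sum of tDD(1..k-1) offsets
        a = VM[i, :K] + tmd[:K] - cum[1:]
        a[0] = NEG_INF  # no D_1 via M_0
        best = np.maximum.accumulate(a)
        VD[i, 1:] = NEG_INF
        VD[i, 2:] = best[:-1] + cum[2:]
        if band is not None:
            klo, khi = band[0][i], band[1][i]
            VD[i, (ks < klo) | (ks > khi)] = NEG_INF
        # E from any match (and the 3' tail insert)
        VE[i] = max(float(np.max(VM[i] + profile.exit_)),
                    VI[i, K] + log_i0m)
        VC[i] = max(VE[i], VC[i - 1] + e_bg + math.log(P_LOOP_FLANK))
    score = VC[n] + math.log(1 - P_LOOP_FLANK)
    return x, VM, VI, VD, VI0, VN, VB, VE, VC, score


def _traceback(profile: P7Profile, x, VM, VI, VD, VI0, VN, VB, VE, VC):
    """Recover the Viterbi path by recomputing argmaxes over stored values."""
    K = profile.K
    n = len(x)
    log_nn = math.log(P_LOOP_FLANK)
    log_nb = math.log(1 - P_LOOP_FLANK)
    log_bi0 = math.log(P_ENTRY_I0)
    log_i0loop = math.log(P_LOOP_TAIL_INS)
    log_i0m = math.log(1 - P_LOOP_TAIL_INS)
    log_surv = math.log(1 - P_EXIT)

    def close(a, b):
        return abs(a - b) < 1e-9 or (a == b)

    path: list[str] = []
    # walk back from C at position n
    i = n
    state = "C"
    path.append("C")
    while state == "C":
        e_bg = 0.0 if (i >= 1 and x[i - 1] == 4) else profile.log_bg
        if i >= 1 and VC[i] == VC[i - 1] + e_bg + log_nn and VC[i] != VE[i]:
            path.append("C")
            i -= 1
        else:
            state = "E"
            path.append("E")
    # E at position i: from which match (or I_K)?
    if close(VE[i], VI[i, K] + log_i0m):
        state, k = "IK", K
    else:
        k = int(np.argmax(VM[i] + profile.exit_))
        state = "M"
    while True:
        if state == "IK":
            path.append(f"I{K}")
            sym = int(x[i - 1])
            e = 0.0 if sym == 4 else profile.ins_emis[K, sym]
            if close(VI[i, K], e + VI[i - 1, K] + log_i0loop):
                i -= 1
                continue
            i -= 1
            state, k = "M", K
            continue
        if state == "M":
            path.append(f"M{k}")
            sym = int(x[i - 1])
            e = 0.0 if sym == 4 else profile.match_emis[k, sym]
            tgt = VM[i, k] - e
            if k == 1 and close(tgt, VI0[i - 1] + log_i0m):
                state = "I0"
                i -= 1
                continue
            if close(tgt, VB[i - 1] + profile.entry[k]):
                state = "B"
                i -= 1
                continue
            if close(tgt, VM[i - 1, k - 1] + profile.t_mm[k - 1] + log_surv):
                i -= 1
                k -= 1
                continue
            if close(tgt, VI[i - 1, k - 1] + profile.t_im[k - 1]):
                state = "I"
                i -= 1
                k -= 1
                continue
            if close(tgt, VD[i - 1, k - 1] + profile.t_dm[k - 1]):
                state = "D"
                i -= 1
                k -= 1
                continue
            state = "B"  # numerical fallback
            i -= 1
            continue
        if state == "I":
            path.append(f"I{k}")
            sym = int(x[i - 1])
            e = 0.0 if sym == 4 else profile.ins_emis[k, sym]
            tgt = VI[i, k] - e
            if close(tgt, VI[i - 1, k] + profile.t_ii[k]):
                i -= 1
                continue
            state = "M"
            i -= 1
            continue
        if state == "D":
            path.append(f"D{k}")
            if close(VD[i, k], VD[i, k - 1] + profile.t_dd[k - 1]):
                k -= 1
                continue
            state = "M"
            k -= 1
            continue
        if state == "I0":
            path.append("I0")
            sym = int(x[i - 1])
            e = 0.0 if sym == 4 else profile.ins_emis[0, sym]
            if close(VI0[i], e + VI0[i - 1] + log_i0loop):
                i -= 1
                continue
            state = "B"
            i -= 1
            continue
        if state == "B":
            path.append("B")
            path.append("N")
            while i > 0:
                path.append("N")
                i -= 1
            break
    path.reverse()
    return path


def _alignment_from_path(profile: P7Profile, read: str, vpath: list[str],
                         score: float, banded: bool) -> HmmAlignment:
    ms = [int(s[1:]) for s in vpath if s[0] == "M" or s[0] == "D"]
    if not ms:
        raise HmmError("alignment path has no match states")
    cs_start, cs_end = min(ms), max(ms)
    cols = {}
    ri = 0
    prev = ""
    for s in vpath:
        if s in ("B", "E"):
            prev = s
            continue
        if s in ("N", "C"):
            # the first N / first C of a run is entered without emission;
            # each self-loop emits one flanking read base
            if prev == s:
                ri += 1
        elif s[0] == "M":
            cols[int(s[1:])] = read[ri]
            ri += 1
        elif s[0] == "I":
            # insert emissions are excluded from the profile projection
            ri += 1
        elif s[0] == "D":
            cols[int(s[1:])] = "-"
        prev = s
    aligned = "".join(cols.get(k, "-") for k in range(cs_start, cs_end + 1))
    return HmmAlignment(read_id="", cs_start=cs_start, cs_end=cs_end,
                        aligned=aligned, vpath=vpath, score=score, banded=banded)


def full_viterbi(profile: P7Profile, read: str, read_id: str = "") -> HmmAlignment:
    """Optimal plan7 alignment over all legal paths (no banding)."""
    x, VM, VI, VD, VI0, VN, VB, VE, VC, score = _viterbi_dp(profile, read)
    vpath = _traceback(profile, x, VM, VI, VD, VI0, VN, VB, VE, VC)
    aln = _alignment_from_path(profile, read, vpath, score, banded=False)
    aln.read_id = read_id
    return aln


def _band_from_seeds(profile: P7Profile, read: str, seeds: Sequence[SeedPath],
                     band_width: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(read)
    diags = []
    for s in seeds:
        # at read position i (1-based) the seed path visits match state
        # k = cs_from + (i - read_from - 1)
        diags.append(s.cs_from - s.read_from - 1)
    dmin, dmax = min(diags), max(diags)
    i_arr = np.arange(n + 1)
    klo = np.clip(i_arr + dmin - band_width, 1, profile.K)
    khi = np.clip(i_arr + dmax + band_width, 1, profile.K)
    klo[0], khi[0] = 1, profile.K
    return klo, khi


def banded_viterbi(profile: P7Profile, read: str, seeds: Sequence[SeedPath],
                   band_width: int = 100, read_id: str = "") -> HmmAlignment:
    """Viterbi restricted to a diagonal band through the seed paths.

    The recurrence is identical to `full_viterbi`; cells farther than
    `band_width` diagonals from every seed diagonal are excluded, so the
    banded score never exceeds the full score. Mutually inconsistent
    seeds (3' locus before 5' locus) raise, signalling the non-banded
    fallback.
    """
    if not seeds:
        raise HmmError("banded alignment needs at least one seed")
    five = [s for s in seeds if s.end == "five_prime"]
    three = [s for s in seeds if s.end == "three_prime"]
    if five and three:
        if max(s.cs_from for s in three) < min(s.cs_from for s in five):
            raise HmmError("inconsistent seeds: 3' locus precedes 5' locus")
    if math.isinf(band_width):
        band = None
    else:
        band = _band_from_seeds(profile, read, seeds, int(band_width))
    x, VM, VI, VD, VI0, VN, VB, VE, VC, score = _viterbi_dp(profile, read, band)
    if not np.isfinite(score):
        raise HmmError("no path within the band")
    vpath = _traceback(profile, x, VM, VI, VD, VI0, VN, VB, VE, VC)
    aln = _alignment_from_path(profile, read, vpath, score, banded=band is not None)
    aln.read_id = read_id
    return aln


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def align_read(profile: P7Profile, index: CsfmIndex, read,
               read_id: str = "", band_width: int = 100,
               min_seed_len: int = 20, seed_window: int = 40,
               max_seed_hits: int = 10, try_revcomp: bool = True
               ) -> HmmAlignment:
    """Seed-then-band orchestration for a single read or a mate pair.

    A pair is given as a (forward, reverse) tuple; the reverse mate is
    reverse-complemented, both mates aligned independently, and the
    alignments merged as if a single assembled read, with profile
    columns between non-overlapping mates treated as unobserved ('-').
    """
    if isinstance(read, tuple):
        fwd, rev = read
        a1 = align_read(profile, index, fwd, read_id=read_id,
                        band_width=band_width, min_seed_len=min_seed_len,
                        seed_window=seed_window, max_seed_hits=max_seed_hits,
                        try_revcomp=False)
        a2 = align_read(profile, index, reverse_complement(rev),
                        read_id=read_id, band_width=band_width,
                        min_seed_len=min_seed_len, seed_window=seed_window,
                        max_seed_hits=max_seed_hits, try_revcomp=False)
        return merge_pair(a1, a2)

    def _try(seq: str, strand: str) -> Optional[HmmAlignment]:
        seeds = find_seeds(index, seq, "both", min_seed_len=min_seed_len,
                           window=seed_window, max_seed_hits=max_seed_hits)
        if not seeds:
            return None
        try:
            aln = banded_viterbi(profile, seq, seeds, band_width=band_width,
                                 read_id=read_id)
        except HmmError:
            return None
        aln.strand = strand
        return aln

    aln = _try(read, "+")
    if aln is None and try_revcomp:
        aln = _try(reverse_complement(read), "-")
    if aln is None:
        aln = full_viterbi(profile, read, read_id=read_id)
        aln.strand = "+"
    return aln


def merge_pair(a1: HmmAlignment, a2: HmmAlignment) -> HmmAlignment:
    """Merge two mate alignments into one assembled-read alignment."""
    lo_aln, hi_aln = (a1, a2) if a1.cs_start <= a2.cs_start else (a2, a1)
    if hi_aln.cs_end < lo_aln.cs_end and hi_aln.cs_start > lo_aln.cs_start:
        pass  # nested: fall through, the union below handles it
    if hi_aln.cs_start > lo_aln.cs_end + 1 and hi_aln.cs_end < lo_aln.cs_start:
        raise HmmError("inverted mate intervals")
    cs_start = min(a1.cs_start, a2.cs_start)
    cs_end = max(a1.cs_end, a2.cs_end)
    if cs_end < cs_start:
        raise HmmError("inverted mate intervals")
    cols = {}
    for aln in (hi_aln, lo_aln):  # forward/low mate wins overlapping columns
        for off, c in enumerate(aln.aligned):
            cols[aln.cs_start + off] = c
    aligned = "".join(cols.get(k, "-") for k in range(cs_start, cs_end + 1))
    return HmmAlignment(
        read_id=a1.read_id, cs_start=cs_start, cs_end=cs_end, aligned=aligned,
        vpath=a1.vpath + a2.vpath, score=a1.score + a2.score,
        banded=a1.banded and a2.banded, strand="+",
        flags="paired" + ("" if a1.banded and a2.banded else ",fallback"),
    )


# ---------------------------------------------------------------------------
# HMMER3-style text export
# ---------------------------------------------------------------------------

def export_hmmer_text(profile: P7Profile, name: str = "profile") -> str:
    """Emit the profile as HMMER3-style text (negative natural-log probs)."""
    lines = [
        "HMMER3/f [phylotu]",
        f"NAME  {name}",
        f"LENG  {profile.K}",
        "ALPH  DNA",
        "HMM          A        C        G        T",
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d",
    ]

    def row(vals):
        out = []
        for v in vals:
            out.append("  *      " if not np.isfinite(v) else f"{-v:8.5f} ")
        return " ".join(out)

    lines.append("  COMPO " + row(profile.ins_emis[0]))
    lines.append("        " + row(profile.ins_emis[0]))
    lines.append("        " + row([0.0] * 7))
    for k in range(1, profile.K + 1):
        lines.append(f"{k:7d} " + row(profile.match_emis[k]) +
                     f" {profile.cs_map[k-1]+1 if profile.cs_map else k}")
        lines.append("        " + row(profile.ins_emis[k]))
        lines.append("        " + row([
            profile.t_mm[k], profile.t_mi[k], profile.t_md[k],
            profile.t_im[k], profile.t_ii[k],
            profile.t_dm[k], profile.t_dd[k],
        ]))
    lines.append("//")
    return "\n".join(lines) + "\n"


def parse_hmmer_text(text: str) -> P7Profile:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    K = 0
    for ln in lines:
        if ln.startswith("LENG"):
            K = int(ln.split()[1])
    if K == 0:
        raise HmmError("missing LENG header")

    def parse_row(ln: str, n: int) -> np.ndarray:
        vals = []
        for tok in ln.split()[:n]:
            vals.append(NEG_INF if tok == "*" else -float(tok))
        return np.array(vals)

    match_emis = np.full((K + 1, 4), NEG_INF)
    ins_emis = np.full((K + 1, 4), NEG_INF)
    trans = np.full((K + 1, 7), NEG_INF)
    cs_map = []
    i = next(j for j, ln in enumerate(lines) if ln.strip().startswith("COMPO"))
    ins_emis[0] = parse_row(lines[i].split("COMPO")[1], 4)
    i += 3  # skip the node-0 insert/transition rows
    for k in range(1, K + 1):
        toks = lines[i].split()
        assert int(toks[0]) == k
        match_emis[k] = parse_row(" ".join(toks[1:5]), 4)
        if len(toks) > 5:
            cs_map.append(int(toks[5]) - 1)
        ins_emis[k] = parse_row(lines[i + 1], 4)
        trans[k] = parse_row(lines[i + 2], 7)
        i += 3
    entry, exit_ = _entry_exit(K)
    return P7Profile(
        K=K, match_emis=match_emis, ins_emis=ins_emis,
        t_mm=trans[:, 0], t_mi=trans[:, 1], t_md=trans[:, 2],
        t_im=trans[:, 3], t_ii=trans[:, 4], t_dm=trans[:, 5], t_dd=trans[:, 6],
        entry=entry, exit_=exit_, cs_map=cs_map,
    )
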