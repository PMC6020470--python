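"""Consensus-sequence FM-index: BWT backward search with position lookup.

The index is built over the gap-free consensus sequence of the reference
alignment. It supports exact backward search and maps suffix-array rows
back to 1-based consensus positions, which is what seed finding needs:
anchoring the 5' and 3' ends of an amplicon read on the profile before
running banded Viterbi.

The rank structure here is a plain checkpointed occurrence table; any
structure with the same contract (e.g. a wavelet tree) is equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SENTINEL = "$"
_ORDER = SENTINEL + "ACGT"  # sentinel sorts first
_CODE = {c: i for i, c in enumerate(_ORDER)}


@dataclass
class SeedPath:
    """An exact match between a read interval and a consensus interval.

    read coordinates are 0-based half-open; consensus coordinates are
    1-based inclusive, matching profile match-state numbering.
    """

    read_from: int
    read_to: int
    cs_from: int
    cs_to: int
    end: str  # "five_prime" | "three_prime"

    def __post_init__(self) -> None:
        if self.read_to - self.read_from != self.cs_to - self.cs_from + 1:
            raise ValueError("seed read/consensus interval lengths differ")

    @property
    def length(self) -> int:
        return self.read_to - self.read_from


@dataclass
class CsfmIndex:
    text: str                      # consensus, gap-free
    bwt: str
    counts: np.ndarray             # C array over _ORDER, len 6 (cumulative)
    occ: np.ndarray                # (len+1, 5) occurrence prefix counts
    sa_samples: dict[int, int]     # sampled SA: row -> text offset
    sa_stride: int

    @property
    def n(self) -> int:
        return len(self.text)


def build_index(consensus: str, sa_stride: int = 8) -> CsfmIndex:
    """Build the BWT/FM structures over a gap-free consensus string."""
    if not consensus:
        raise ValueError("empty consensus")
    if SENTINEL in consensus:
        raise ValueError("consensus contains the sentinel character '$'")
    bad = set(consensus) - set("ACGT")
    if bad:
        raise ValueError(f"consensus contains non-ACGT symbols: {sorted(bad)}")
    text = consensus + SENTINEL
    n = len(text)
    # suffix array by direct sort; reference consensus sequences are short
    # enough (<= a few kb at test scale) that O(n^2 log n) is immaterial
    sa = sorted(range(n), key=lambda i: text[i:])
    bwt = "".join(text[i - 1] for i in sa)
    codes = np.fromiter((_CODE[c] for c in bwt), dtype=np.int8, count=n)
    occ = np.zeros((n + 1, len(_ORDER)), dtype=np.int64)
    for sym in range(len(_ORDER)):
        occ[1:, sym] = np.cumsum(codes == sym)
    tot = occ[-1]
    counts = np.zeros(len(_ORDER) + 1, dtype=np.int64)
    counts[1:] = np.cumsum(tot)
    sa_samples = {row: pos for row, pos in enumerate(sa) if row % sa_stride == 0
                  or pos == 0}
    return CsfmIndex(text=consensus, bwt=bwt, counts=counts, occ=occ,
                     sa_samples=sa_samples, sa_stride=sa_stride)


def _lf(index: CsfmIndex, row: int) -> int:
    sym = _CODE[index.bwt[row]]
    return int(index.counts[sym] + index.occ[row, sym])


def inverse_bwt(index: CsfmIndex) -> str:
    """Reconstruct the text by LF-walking from the sentinel row."""
    n = index.n + 1
    out = []
    row = 0  # row 0 is the '$...' rotation; its BWT char is the last text char
    for _ in range(n - 1):
        out.append(index.bwt[row])
        row = _lf(index, row)
    return "".join(reversed(out))


def locate(index: CsfmIndex, row: int) -> int:
    """Text offset (0-based) of the suffix in suffix-array row `row`."""
    if not (0 <= row <= index.n):
        raise IndexError(f"suffix-array row {row} out of range")
    steps = 0
    r = row
    while r not in index.sa_samples:
        r = _lf(index, r)
        steps += 1
    return (index.sa_samples[r] + steps) % (index.n + 1)


def locate_cs(index: CsfmIndex, row: int) -> int:
    """1-based consensus position of a suffix-array row.

    The sentinel suffix maps to position len(text)+1 by convention.
    """
    return locate(index, row) + 1


def backward_search(index: CsfmIndex, pattern: str) -> tuple[int, list[int]]:
    """Exact occurrences of `pattern`: (count, sorted 0-based start offsets)."""
    if not pattern:
        raise ValueError("empty pattern has an undefined search range")
    lo, hi = 0, index.n + 1
    for ch in reversed(pattern):
        sym = _CODE.get(ch)
        if sym is None:
            return 0, []
        lo = int(index.counts[sym] + index.occ[lo, sym])
        hi = int(index.counts[sym] + index.occ[hi, sym])
        if lo >= hi:
            return 0, []
    positions = sorted(locate(index, r) for r in range(lo, hi))
    return hi - lo, positions


def _longest_match_at(index: CsfmIndex, read: str, start: int, max_len: int
                      ) -> tuple[int, int, int]:
    """Longest exact match of read[start:start+L]; returns (L, lo, hi).

    Uses incremental backward search over the reversed window so each
    extension is O(1) rank queries.
    """
    # backward search extends the pattern leftward; to grow a match that is
    # anchored at `start` and extends rightward, search each prefix length
    # afresh (window lengths are tiny, so the quadratic cost is fine)
    best = (0, 0, 0)
    for L in range(1, max_len + 1):
        lo, hi = 0, index.n + 1
        ok = True
        for ch in reversed(read[start:start + L]):
            sym = _CODE.get(ch)
            if sym is None:
                ok = False
                break
            lo = int(index.counts[sym] + index.occ[lo, sym])
            hi = int(index.counts[sym] + index.occ[hi, sym])
            if lo >= hi:
                ok = False
                break
        if not ok:
            break
        best = (L, lo, hi)
    return best


def find_seeds(index: CsfmIndex, read: str, which_end: str = "both",
               min_seed_len: int = 20, window: int = 40,
               max_seed_hits: int = 10) -> list[SeedPath]:
    """Anchor the 5' and/or 3' ends of a read on the consensus.

    A seed is a maximal exact match of at least `min_seed_len` bases
    anchored within the first (5') or last (3') `window` bases of the
    read. Seeds hitting more than `max_seed_hits` consensus loci are
    rejected as ambiguous; an empty list is the no-seed signal.
    """
    seeds: list[SeedPath] = []
    n = len(read)
    if n < min_seed_len:
        return seeds
    ends = ["five_prime", "three_prime"] if which_end == "both" else [which_end]
    for end in ends:
        if end == "five_prime":
            starts = range(0, max(1, min(window, n) - min_seed_len + 1))
            candidates = []
            for s in starts:
                L, lo, hi = _longest_match_at(index, read, s, n - s)
                if L >= min_seed_len and 0 < hi - lo <= max_seed_hits:
                    candidates = [(s, L, lo, hi)]
                    break
        else:
            # anchor at the read's 3' end: try suffixes ending at n, n-1, ...
            candidates = []
            for e in range(n, max(min_seed_len - 1, n - window), -1):
                # longest match ending at e: grow leftward with backward search
                lo, hi = 0, index.n + 1
                L = 0
                best = None
                for i in range(e - 1, -1, -1):
                    sym = _CODE.get(read[i])
                    if sym is None:
                        break
                    nlo = int(index.counts[sym] + index.occ[lo, sym])
                    nhi = int(index.counts[sym] + index.occ[hi, sym])
                    if nlo >= nhi:
                        break
                    lo, hi, L = nlo, nhi, L + 1
                    best = (e - L, L, lo, hi)
                if best and best[1] >= min_seed_len and \
                        0 < best[3] - best[2] <= max_seed_hits:
                    candidates = [best]
                    break
        for s, L, lo, hi in candidates:
            for row in range(lo, hi):
                pos = locate(index, row)
                seeds.append(SeedPath(read_from=s, read_to=s + L,
                                      cs_from=pos + 1, cs_to=pos + L,
                                      end=end))
    return seeds
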