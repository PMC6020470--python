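import math

import numpy as np
import pytest

from phylotu import csfm_index as cs
from phylotu import profile_hmm as ph
from phylotu.formats import Msa, SeqRecord

BASES = "ACGT"


def toy_profile(seqs):
    msa = Msa(records=[SeqRecord(id=f"s{i}", seq=s)
                       for i, s in enumerate(seqs)])
    return ph.build_profile(msa)


def enumerate_viterbi(profile, read):
    """Independent oracle: explicit max over all legal plan7 paths.

    Recursion over (state, k, read position) mirrors the architecture's
    transition diagram rather than the DP recurrences.
    """
    K = profile.K
    x = [BASES.index(c) if c in BASES else 4 for c in read]
    n = len(x)
    bg = profile.log_bg
    l_nn, l_nb = math.log(ph.P_LOOP_FLANK), math.log(1 - ph.P_LOOP_FLANK)
    l_bi0 = math.log(ph.P_ENTRY_I0)
    l_loop = math.log(ph.P_LOOP_TAIL_INS)
    l_leave = math.log(1 - ph.P_LOOP_TAIL_INS)
    l_surv = math.log(1 - ph.P_EXIT)

    def e(mat, k, i):
        return 0.0 if x[i] == 4 else mat[k, x[i]]

    best = [-np.inf]

    def tail(i, acc):
        # E reached with i bases consumed; C loop emits the rest
        rest = acc
        for j in range(i, n):
            rest += (0.0 if x[j] == 4 else bg) + l_nn
        best[0] = max(best[0], rest + l_nb)

    def core(state, k, i, acc):
        if acc < best[0] - 60:  # prune hopeless branches
            return
        if state == "M":
            if i >= n:
                return
            acc = acc + e(profile.match_emis, k, i)
            i += 1
            if k == K:
                tail(i, acc + math.log(1 - ph.P_MK_IK))
                core("IK", K, i, acc + math.log(ph.P_MK_IK))
            else:
                tail(i, acc + math.log(ph.P_EXIT))
                core("M", k + 1, i, acc + profile.t_mm[k] + l_surv)
                core("I", k, i, acc + profile.t_mi[k] + l_surv)
                core("D", k + 1, i, acc + profile.t_md[k] + l_surv)
        elif state == "I":
            if i >= n:
                return
            acc = acc + e(profile.ins_emis, k, i)
            i += 1
            core("I", k, i, acc + profile.t_ii[k])
            core("M", k + 1, i, acc + profile.t_im[k])
        elif state == "IK":
            if i >= n:
                return
            acc = acc + e(profile.ins_emis, K, i)
            i += 1
            tail(i, acc + l_leave)
            core("IK", K, i, acc + l_loop)
        elif state == "D":
            if k < K:
                core("D", k + 1, i, acc + profile.t_dd[k])
                core("M", k + 1, i, acc + profile.t_dm[k])
        elif state == "I0":
            if i >= n:
                return
            acc = acc + e(profile.ins_emis, 0, i)
            i += 1
            core("I0", 0, i, acc + l_loop)
            core("M", 1, i, acc + l_leave)

    for a in range(n + 1):  # N emits the first a read bases
        acc = sum((0.0 if x[j] == 4 else bg) + l_nn for j in range(a)) + l_nb
        for k in range(1, K + 1):
            core("M", k, a, acc + profile.entry[k])
        core("I0", 0, a, acc + l_bi0)
    return best[0]


class TestDirichlet:
    def test_symmetric_counts_give_symmetric_alpha(self):
        rng = np.random.default_rng(0)
        rows = rng.multinomial(20, [0.25] * 4, size=400).astype(float)
        fit = ph.train_dirichlet(rows, "density")
        assert fit.alpha.max() / fit.alpha.min() < 1.2

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        true = np.array([10.0, 1.0, 1.0, 1.0])
        ps = rng.dirichlet(true, size=5000)
        rows = np.array([rng.multinomial(30, p) for p in ps], dtype=float)
        fit = ph.train_dirichlet(rows, "density")
        assert np.all(np.abs(fit.alpha - true) / true < 0.2)

    def test_mixture_ncomp1_equals_density(self):
        rng = np.random.default_rng(2)
        rows = rng.multinomial(15, [0.4, 0.3, 0.2, 0.1], size=200).astype(float)
        dens = ph.train_dirichlet(rows, "density")
        mix = ph.train_dirichlet(rows, "mixture", ncomp=1)
        ll_d = ph.mixture_marginal_loglik(dens, rows)
        ll_m = ph.mixture_marginal_loglik(mix, rows)
        assert ll_m == pytest.approx(ll_d, abs=1e-6)

    def test_all_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            ph.train_dirichlet(np.zeros((3, 4)), "density")


class TestBuildProfile:
    def test_match_emission_posterior_mean(self):
        # 3 observed A with a flat Dirichlet(1,1,1,1): P(A) = 4/7
        profile = toy_profile(["A", "A", "A"])
        assert math.exp(profile.match_emis[1, 0]) == pytest.approx(4 / 7)

    def test_majority_gap_column_not_match_state(self):
        profile = toy_profile(["A-C", "A-C", "AGC"])
        assert profile.K == 2

    def test_all_distributions_normalize(self, toy_pkg):
        pkg, _ = toy_pkg
        p = pkg.profile
        for k in range(1, p.K + 1):
            assert np.exp(p.match_emis[k]).sum() == pytest.approx(1, abs=1e-9)
        for k in range(0, p.K + 1):
            assert np.exp(p.ins_emis[k]).sum() == pytest.approx(1, abs=1e-9)
        for k in range(1, p.K):
            m = np.exp([p.t_mm[k], p.t_mi[k], p.t_md[k]]).sum() \
                * (1 - ph.P_EXIT) + ph.P_EXIT
            assert m == pytest.approx(1, abs=1e-9)
            assert np.exp([p.t_im[k], p.t_ii[k]]).sum() == \
                pytest.approx(1, abs=1e-9)
            assert np.exp([p.t_dm[k], p.t_dd[k]]).sum() == \
                pytest.approx(1, abs=1e-9)
        # wing-retracted entry and exit cover k = 1..K
        assert np.all(np.isfinite(p.entry[1:]))
        assert np.all(np.isfinite(p.exit_[1:]))
        assert np.exp(p.entry[1:]).sum() + ph.P_ENTRY_I0 == \
            pytest.approx(1, abs=1e-9)

    def test_no_match_columns_rejected(self):
        with pytest.raises(ph.HmmError):
            toy_profile(["--", "--", "A-"])


class TestFullViterbi:
    def test_perfect_read_path(self):
        profile = toy_profile(["ACG"] * 5)
        aln = ph.full_viterbi(profile, "ACG")
        assert aln.vpath == ["N", "B", "M1", "M2", "M3", "E", "C"]
        assert (aln.cs_start, aln.cs_end) == (1, 3)
        assert aln.aligned == "ACG"

    def test_mismatched_read_scores_worse(self):
        profile = toy_profile(["ACG"] * 5)
        good = ph.full_viterbi(profile, "ACG").score
        bad = ph.full_viterbi(profile, "TTTT").score
        assert bad < good

    def test_empty_read_rejected(self):
        profile = toy_profile(["ACG"] * 5)
        with pytest.raises(ph.HmmError):
            ph.full_viterbi(profile, "")

    def test_invalid_symbol_rejected(self):
        profile = toy_profile(["ACG"] * 5)
        with pytest.raises(ph.HmmError):
            ph.full_viterbi(profile, "AXG")

    @pytest.mark.parametrize("seqs,reads", [
        (["ACG", "ACG", "ATG"], ["ACG", "ATG", "A", "ACGTA", "TTTT"]),
        (["ACGT", "AC-T", "ACGT"], ["ACGT", "ACT", "GT", "CCCC", "ACGTN"]),
        (["AATT", "AGTT", "AATT"], ["AATT", "AGT", "TTAA", "N"]),
    ])
    def test_matches_exhaustive_path_enumeration(self, seqs, reads):
        """Viterbi DP equals explicit max over all paths (K<=4, len<=5)."""
        profile = toy_profile(seqs)
        for read in reads:
            dp = ph.full_viterbi(profile, read).score
            oracle = enumerate_viterbi(profile, read)
            assert dp == pytest.approx(oracle, abs=1e-9), read


@pytest.fixture(scope="module")
def banded_ref():
    rng = np.random.default_rng(31)
    consensus = "".join(rng.choice(list(BASES), 300))
    seqs = []
    for _ in range(6):
        s = list(consensus)
        for j in rng.choice(300, 15, replace=False):
            s[j] = BASES[int(rng.integers(4))]
        seqs.append("".join(s))
    profile = toy_profile(seqs)
    index = cs.build_index(consensus)
    return profile, index, consensus


class TestBandedViterbi:
    @pytest.fixture()
    def ref(self, banded_ref):
        return banded_ref

    def test_infinite_band_equals_full(self, ref):
        profile, index, consensus = ref
        rng = np.random.default_rng(32)
        for _ in range(20):
            lo = int(rng.integers(0, 150))
            read = consensus[lo:lo + 100]
            seeds = cs.find_seeds(index, read)
            if not seeds:
                continue
            b = ph.banded_viterbi(profile, read, seeds, band_width=math.inf)
            f = ph.full_viterbi(profile, read)
            assert b.score == pytest.approx(f.score, abs=1e-9)

    def test_banded_never_exceeds_full(self, ref):
        profile, index, consensus = ref
        rng = np.random.default_rng(33)
        for _ in range(20):
            lo = int(rng.integers(0, 150))
            read = list(consensus[lo:lo + 100])
            for j in rng.choice(100, 10, replace=False):
                read[j] = BASES[int(rng.integers(4))]
            read = "".join(read)
            seeds = cs.find_seeds(index, read)
            if not seeds:
                continue
            b = ph.banded_viterbi(profile, read, seeds, band_width=8)
            f = ph.full_viterbi(profile, read)
            assert b.score <= f.score + 1e-9

    def test_mutated_reads_mostly_equal_full(self, ref):
        profile, index, consensus = ref
        rng = np.random.default_rng(34)
        equal = total = 0
        for _ in range(60):
            lo = int(rng.integers(0, 150))
            read = list(consensus[lo:lo + 100])
            nmut = int(rng.integers(0, 11))
            for j in rng.choice(100, nmut, replace=False):
                read[j] = BASES[int(rng.integers(4))]
            read = "".join(read)
            seeds = cs.find_seeds(index, read)
            if not seeds:
                continue
            total += 1
            b = ph.banded_viterbi(profile, read, seeds)
            f = ph.full_viterbi(profile, read)
            equal += abs(b.score - f.score) < 1e-9
        assert total >= 40
        assert equal / total >= 0.95

    def test_inconsistent_seeds_signal_fallback(self, ref):
        profile, index, consensus = ref
        from phylotu.csfm_index import SeedPath

        seeds = [SeedPath(0, 20, 201, 220, "five_prime"),
                 SeedPath(80, 100, 51, 70, "three_prime")]
        with pytest.raises(ph.HmmError):
            ph.banded_viterbi(profile, consensus[:100], seeds)


class TestAlignRead:
    def test_fallback_to_full_without_seeds(self, ref_pkg=None):
        profile = toy_profile(["ACGTACGTACGTACGTACGTACGTA"] * 4)
        index = cs.build_index("ACGTACGTACGTACGTACGTACGTA")
        aln = ph.align_read(profile, index, "GGGGGGGG", try_revcomp=True)
        assert aln.banded is False

    def test_revcomp_retry(self):
        rng = np.random.default_rng(35)
        consensus = "".join(rng.choice(list(BASES), 200))
        profile = toy_profile([consensus] * 4)
        index = cs.build_index(consensus)
        read = ph.reverse_complement(consensus[50:150])
        aln = ph.align_read(profile, index, read)
        assert aln.strand == "-"
        assert (aln.cs_start, aln.cs_end) == (51, 150)

    def test_pair_merge_non_overlapping(self):
        rng = np.random.default_rng(36)
        consensus = "".join(rng.choice(list(BASES), 500))
        profile = toy_profile([consensus] * 4)
        index = cs.build_index(consensus)
        fwd = consensus[100:250]
        rev = ph.reverse_complement(consensus[300:450])
        aln = ph.align_read(profile, index, (fwd, rev))
        assert (aln.cs_start, aln.cs_end) == (101, 450)
        # unobserved middle is reported as '-'
        mid = aln.aligned[250 - 100: 300 - 100]
        assert set(mid) == {"-"}

    def test_pair_merge_overlapping_agreement(self):
        rng = np.random.default_rng(37)
        consensus = "".join(rng.choice(list(BASES), 400))
        profile = toy_profile([consensus] * 4)
        index = cs.build_index(consensus)
        fwd = consensus[100:220]
        rev = ph.reverse_complement(consensus[180:300])
        pair = ph.align_read(profile, index, (fwd, rev))
        merged = ph.align_read(profile, index, consensus[100:300])
        assert pair.aligned == merged.aligned


class TestHmmerText:
    def test_export_has_match_rows(self):
        profile = toy_profile(["ACG"] * 5)
        text = ph.export_hmmer_text(profile)
        assert "LENG  3" in text
        assert text.count("\n") > 9

    def test_round_trip(self, toy_pkg):
        pkg, _ = toy_pkg
        text1 = ph.export_hmmer_text(pkg.profile)
        back = ph.parse_hmmer_text(text1)
        text2 = ph.export_hmmer_text(back)
        assert text1 == text2
        assert np.allclose(back.match_emis[1:], pkg.profile.match_emis[1:],
                           atol=1e-4)

    def test_emissions_are_negative_log_probs(self):
        profile = toy_profile(["ACG"] * 5)
        text = ph.export_hmmer_text(profile)
        row = next(ln for ln in text.splitlines() if ln.strip().startswith("1 "))
        vals = [float(t) for t in row.split()[1:5]]
        assert all(v >= 0 for v in vals)  # -ln p >= 0
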