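import numpy as np
import pytest
from Bio.Data import CodonTable

from selpress.codon_model import (
    CodonModelParams,
    build_rate_matrix,
    estimate_codon_frequencies,
    genetic_code,
    site_opportunity,
    transition_matrix,
)
from selpress.seqio import codon_alignment_from_sequences


def random_params(rng):
    code = genetic_code(1)
    pi = rng.dirichlet(np.ones(code.n) * 5)
    return CodonModelParams(rng.uniform(0.5, 5), rng.uniform(0.05, 3), pi)


def enumerate_single_changes(transitions_only=False):
    """Independent enumeration of single-nucleotide sense-codon changes,
    classified synonymous/nonsynonymous straight from the Biopython table."""
    table = CodonTable.unambiguous_dna_by_id[1]
    sense = [c for c in (a + b + c2 for a in "TCAG" for b in "TCAG"
                         for c2 in "TCAG") if c not in table.stop_codons]
    ts_pairs = ({"A", "G"}, {"C", "T"})
    syn = nonsyn = 0
    for ci in sense:
        for cj in sense:
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            if transitions_only and {ci[diffs[0]], cj[diffs[0]]} not in ts_pairs:
                continue
            if table.forward_table[ci] == table.forward_table[cj]:
                syn += 1
            else:
                nonsyn += 1
    return syn, nonsyn


class TestFrequencies:
    def test_equal_scheme_uniform(self, code):
        aln = codon_alignment_from_sequences([("A", "AAAAAA"), ("B", "AAAAAA")])
        pi = estimate_codon_frequencies(aln, "equal")
        assert np.allclose(pi, 1.0 / code.n)

    def test_f61_concentrates_on_observed(self, code):
        aln = codon_alignment_from_sequences([("A", "AAAAAA")])
        pi = estimate_codon_frequencies(aln, "F61")
        # all observed mass on AAA (up to the 1e-6 floor on the others)
        assert pi[code.index["AAA"]] > 0.9999
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_f3x4_uniform_nucleotides_gives_equal_codons(self, code):
        # 4 sequences x 1 codon covering each nucleotide at every position
        seqs = [("s1", "TTT"), ("s2", "CCC"), ("s3", "AAA"), ("s4", "GGG")]
        aln = codon_alignment_from_sequences(seqs)
        pi = estimate_codon_frequencies(aln, "F3x4")
        # uniform position frequencies -> every sense codon (1/64)/(57/64... )
        # hand-derived: each codon product = (1/4)^3; renormalized over the
        # 61 sense codons -> exactly 1/61 each
        assert np.allclose(pi, 1.0 / code.n, atol=1e-12)

    def test_unknown_scheme_rejected(self):
        aln = codon_alignment_from_sequences([("A", "AAA")])
        with pytest.raises(ValueError):
            estimate_codon_frequencies(aln, "F5x5")


class TestRateMatrix:
    def test_neutral_symmetric_case(self, code):
        pi = np.full(code.n, 1.0 / code.n)
        rm = build_rate_matrix(CodonModelParams(1.0, 1.0, pi))
        offdiag = rm.Q[code.single_diff]
        assert np.allclose(offdiag, offdiag[0])
        assert -np.dot(pi, np.diag(rm.Q)) == pytest.approx(1.0, abs=1e-8)

    def test_omega_zero_kills_nonsynonymous_rates(self, code):
        pi = np.full(code.n, 1.0 / code.n)
        rm = build_rate_matrix(CodonModelParams(2.0, 0.0, pi))
        assert np.all(rm.Q[code.single_diff & ~code.is_synonymous] == 0)

    def test_multi_nucleotide_changes_forbidden(self, code):
        rng = np.random.default_rng(0)
        rm = build_rate_matrix(random_params(rng))
        off = ~code.single_diff & ~np.eye(code.n, dtype=bool)
        assert np.all(rm.Q[off] == 0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_detailed_balance(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng)
        rm = build_rate_matrix(params)
        flux = params.pi[:, None] * rm.Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_rows_sum_to_zero_and_normalized(self):
        rng = np.random.default_rng(4)
        params = random_params(rng)
        rm = build_rate_matrix(params)
        assert np.allclose(rm.Q.sum(axis=1), 0, atol=1e-8)
        assert -np.dot(params.pi, np.diag(rm.Q)) == pytest.approx(1.0, abs=1e-8)


class TestSiteOpportunity:
    def test_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            N, S = site_opportunity(random_params(rng))
            assert N + S == pytest.approx(3.0, abs=1e-12)
            assert 0 < S < N  # the standard code is mostly nonsynonymous

    def test_equal_pi_kappa_one_matches_enumeration(self, code):
        pi = np.full(code.n, 1.0 / code.n)
        N, S = site_opportunity(CodonModelParams(1.0, 1.0, pi))
        syn, nonsyn = enumerate_single_changes()
        assert S / 3.0 == pytest.approx(syn / (syn + nonsyn), abs=1e-12)

    def test_large_kappa_approaches_transition_only_fraction(self, code):
        pi = np.full(code.n, 1.0 / code.n)
        N, S = site_opportunity(CodonModelParams(1e7, 1.0, pi))
        syn_ts, nonsyn_ts = enumerate_single_changes(transitions_only=True)
        assert S / 3.0 == pytest.approx(syn_ts / (syn_ts + nonsyn_ts), abs=1e-4)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        rng = np.random.default_rng(6)
        rm = build_rate_matrix(random_params(rng))
        P = transition_matrix(rm, 0.0)
        assert np.allclose(P, np.eye(P.shape[0]), atol=1e-12)

    def test_long_time_converges_to_pi(self):
        rng = np.random.default_rng(7)
        params = random_params(rng)
        P = transition_matrix(build_rate_matrix(params), 50.0)
        assert np.allclose(P, np.tile(params.pi, (P.shape[0], 1)), atol=1e-6)

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(8)
        rm = build_rate_matrix(random_params(rng))
        a, b = rng.uniform(0.05, 1.5, size=2)
        Pab = transition_matrix(rm, a) @ transition_matrix(rm, b)
        assert np.allclose(Pab, transition_matrix(rm, a + b), atol=1e-8)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(9)
        rm = build_rate_matrix(random_params(rng))
        P = transition_matrix(rm, 0.3)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)

    def test_negative_time_rejected(self):
        rng = np.random.default_rng(10)
        rm = build_rate_matrix(random_params(rng))
        with pytest.raises(ValueError):
            transition_matrix(rm, -0.1)


class TestParamsValidation:
    def test_bad_pi_rejected(self, code):
        with pytest.raises(ValueError):
            CodonModelParams(2.0, 0.5, np.full(code.n, 1.0))  # sums to 61

    def test_negative_omega_rejected(self, code):
        with pytest.raises(ValueError):
            CodonModelParams(2.0, -0.5, np.full(code.n, 1.0 / code.n))
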