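import numpy as np
import pytest

import selpress as sp

from selpress.phylo_likelihood import fit_free_ratio
from selpress.seqio import (
    CodonAlignment,
    ValidationError,
    codon_alignment_from_sequences,
    read_tree,
)
from selpress.synthetic_data import (
    M0Regime,
    SimulationSpec,
    simulate_codon_alignment,
)

from oracles import brute_force_lnl


class TestLogLikelihood:
    def test_identical_sequences_zero_branches(self, code):
        """With no branch length there can be no substitutions: the site
        likelihood collapses to the root prior of the observed codon."""
        aln = codon_alignment_from_sequences([("A", "ATG"), ("B", "ATG")])
        tree = read_tree("(A:0,B:0);")
        pi = np.full(code.n, 1.0 / code.n)
        lnl = sp.log_likelihood(aln, tree, kappa=2.0, pi=pi, branch_omegas=0.5)
        assert lnl == pytest.approx(np.log(pi[code.index["ATG"]]), abs=1e-10)

    def test_matches_enumeration_oracle(self, code):
        rng = np.random.default_rng(21)
        nwk = "((A:0.2,B:0.15):0.1,C:0.3);"
        tree = read_tree(nwk)
        codes = rng.integers(0, code.n, size=(3, 4)).astype(np.int16)
        codes[1, 2] = -1  # one missing codon
        aln = CodonAlignment(["A", "B", "C"], codes)
        pi = rng.dirichlet(np.ones(code.n) * 5)
        kappa, omega = 2.3, 0.7
        expected = brute_force_lnl(aln, tree, kappa, omega, pi)
        got = sp.log_likelihood(aln, tree, kappa, pi, omega)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_duplicated_column_doubles_contribution(self, code):
        rng = np.random.default_rng(22)
        tree = read_tree("((A:0.2,B:0.15):0.1,C:0.3);")
        pi = np.full(code.n, 1.0 / code.n)
        col = rng.integers(0, code.n, size=(3, 1)).astype(np.int16)
        one = CodonAlignment(["A", "B", "C"], col)
        two = CodonAlignment(["A", "B", "C"], np.hstack([col, col]))
        l1 = sp.log_likelihood(one, tree, 2.0, pi, 0.5)
        l2 = sp.log_likelihood(two, tree, 2.0, pi, 0.5)
        assert l2 == pytest.approx(2 * l1, abs=1e-10)

    def test_invariant_to_taxon_and_column_order(self, code):
        rng = np.random.default_rng(23)
        tree = read_tree("((A:0.2,B:0.15):0.1,(C:0.3,D:0.05):0.1);")
        codes = rng.integers(0, code.n, size=(4, 6)).astype(np.int16)
        pi = rng.dirichlet(np.ones(code.n) * 5)
        base = CodonAlignment(["A", "B", "C", "D"], codes)
        shuffled_taxa = base.subset_taxa(["C", "A", "D", "B"])
        shuffled_cols = CodonAlignment(
            base.taxa, codes[:, rng.permutation(6)].copy()
        )
        l0 = sp.log_likelihood(base, tree, 2.0, pi, 0.5)
        assert sp.log_likelihood(shuffled_taxa, tree, 2.0, pi, 0.5) == \
            pytest.approx(l0, abs=1e-10)
        assert sp.log_likelihood(shuffled_cols, tree, 2.0, pi, 0.5) == \
            pytest.approx(l0, abs=1e-10)


class TestFitM0:
    def test_invariant_alignment_rejected(self, tree8):
        aln = codon_alignment_from_sequences(
            [(t, "ATGAAACGT") for t in tree8.tip_labels]
        )
        with pytest.raises(ValidationError, match="no information"):
            sp.fit_M0(aln, tree8)

    def test_deterministic(self, branch_sim):
        """Same data, same schedule: bit-stable log-likelihood."""
        refit = sp.fit_M0(branch_sim["aln"], branch_sim["tree"])
        assert refit.lnL == branch_sim["m0"].lnL
        assert refit.omega == branch_sim["m0"].omega

    def test_dn_ds_identity(self, branch_sim, code):
        from selpress.codon_model import CodonModelParams, site_opportunity

        m0 = branch_sim["m0"]
        N, S = site_opportunity(CodonModelParams(m0.kappa, m0.omega, m0.pi))
        for b in m0.per_branch:
            assert b.dN * N + b.dS * S == pytest.approx(b.t, abs=1e-10)


class TestBranchModels:
    def test_fixed_foreground_omega_is_one(self, branch_sim):
        assert branch_sim["mc_fixed"].omega_foreground == 1.0

    def test_nesting_chain(self, branch_sim):
        assert branch_sim["m0"].lnL <= branch_sim["mc"].lnL + 1e-8
        assert branch_sim["mc_fixed"].lnL <= branch_sim["mc"].lnL + 1e-8

    def test_unmarked_tree_rejected(self, branch_sim, tree8):
        with pytest.raises(ValidationError, match="foreground"):
            sp.fit_branch_model(branch_sim["aln"], tree8, False,
                                branch_sim["m0"])

    def test_two_ratio_separates_regimes(self, branch_sim):
        mc = branch_sim["mc"]
        assert mc.omega_foreground > 1.5  # true 3.0
        assert mc.omega_background < 0.7  # true 0.4


class TestFreeRatio:
    @pytest.fixture(scope="class")
    def free_fit(self, branch_sim):
        return fit_free_ratio(branch_sim["aln"], branch_sim["tree"],
                              branch_sim["m0"])

    def test_dominates_m0(self, branch_sim, free_fit):
        assert free_fit.lnL >= branch_sim["m0"].lnL - 1e-8

    def test_branch_length_identity(self, free_fit):
        """dN*N + dS*S recovers each branch's length exactly."""
        from selpress.codon_model import CodonModelParams, site_opportunity

        for b in free_fit.per_branch:
            if not np.isfinite(b.omega):
                continue
            N, S = site_opportunity(
                CodonModelParams(free_fit.kappa, b.omega, free_fit.pi)
            )
            assert b.dN * N + b.dS * S == pytest.approx(b.t, abs=1e-10)

    def test_near_zero_branch_has_zero_divergence(self, free_fit):
        tiny = [b for b in free_fit.per_branch if b.t < 1e-6]
        for b in tiny:
            assert b.dN < 1e-6 and b.dS < 1e-6
            assert b.flag == "zero_synonymous_change"
            assert np.isnan(b.omega)


class TestBranchSite:
    def test_mixture_proportion_identity(self, bs_sim):
        mix = bs_sim["bs"].mixture
        p2 = 1 - mix.p0 - mix.p1
        assert mix.p2a == pytest.approx(p2 * mix.p0 / (mix.p0 + mix.p1))
        assert mix.p2b == pytest.approx(p2 * mix.p1 / (mix.p0 + mix.p1))
        assert mix.proportions.sum() == pytest.approx(1.0, abs=1e-8)

    def test_null_constrains_omega2(self, bs_sim):
        assert bs_sim["bs_fixed"].mixture.omega2 == 1.0
        assert bs_sim["bs_fixed"].lnL <= bs_sim["bs"].lnL + 1e-8

    def test_posteriors_are_distributions(self, bs_sim):
        post = bs_sim["bs"].site_posteriors
        assert post.shape == (bs_sim["aln"].n_sites, 4)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(post >= 0)

    def test_planted_sites_get_higher_positive_posterior(self, bs_sim):
        cls = bs_sim["truth"]["site_class"]
        pos = bs_sim["bs"].site_posteriors[:, 2:].sum(axis=1)
        planted = pos[(cls == 2) | (cls == 3)].mean()
        background = pos[cls == 0].mean()
        assert planted > background


class TestReportingHelpers:
    def test_frequency_scheme_aic_table(self, code):
        from selpress.phylo_likelihood import compare_frequency_schemes
        from selpress.synthetic_data import random_yule_tree

        tree = random_yule_tree(5, seed=51, mean_branch_length=0.15)
        spec = SimulationSpec(tree=tree, n_codons=100, kappa=2.0,
                              regime=M0Regime(0.5), seed=52)
        aln, _ = simulate_codon_alignment(spec)
        table = compare_frequency_schemes(aln, tree)
        assert set(table["scheme"]) == {"equal", "F1x4", "F3x4", "F61"}
        assert (table["delta_AIC"] >= 0).all()
        assert table.loc[0, "delta_AIC"] == 0.0
        # data were generated with uniform codon frequencies: the equal
        # scheme (0 extra params) should not be far behind on AIC
        eq = table.set_index("scheme").loc["equal", "delta_AIC"]
        assert eq < 200

    def test_fit_report_round_readable(self, branch_sim, tmp_path):
        from selpress.phylo_likelihood import write_fit_report

        path = tmp_path / "m0.tsv"
        write_fit_report(branch_sim["m0"], path)
        text = path.read_text()
        assert "# model M0" in text
        header = [l for l in text.splitlines() if l.startswith("branch_id")]
        assert header == ["branch_id\tforeground\tt\tomega\tdN\tdS\tflag"]
        n_rows = sum(1 for l in text.splitlines()
                     if l and not l.startswith(("#", "branch_id")))
        assert n_rows == len(branch_sim["m0"].per_branch)


class TestScaleInvariance:
    def test_omega_unaffected_by_branch_length_scale(self, code):
        """Doubling every true branch length changes divergence, not the
        estimated omega (paired simulations, same seed)."""
        from selpress.synthetic_data import random_yule_tree

        base = random_yule_tree(6, seed=61, mean_branch_length=0.08)
        doubled = base.copy()
        for node in doubled.branches():
            node.length *= 2
        omegas = []
        for tree in (base, doubled):
            spec = SimulationSpec(tree=tree, n_codons=300, kappa=2.0,
                                  regime=M0Regime(0.5), seed=62)
            aln, _ = simulate_codon_alignment(spec)
            omegas.append(sp.fit_M0(aln, tree).omega)
        assert abs(omegas[0] - 0.5) < 0.15
        assert abs(omegas[1] - 0.5) < 0.15
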