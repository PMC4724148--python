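import numpy as np
import pytest
from scipy.stats import chi2

from selpress.codon_model import CodonModelParams, genetic_code
from selpress.phylo_likelihood import BranchEstimate, ModelFit
from selpress.selection_inference import (
    LRTResult,
    branch_dn_ds,
    classify_regime,
    classify_site_regime,
    detect_pss,
    lrt,
    root_to_tip_omega,
)
from selpress.seqio import ValidationError, read_tree


def uniform_params(kappa=2.0, omega=0.5):
    code = genetic_code(1)
    return CodonModelParams(kappa, omega, np.full(code.n, 1.0 / code.n))


class TestLRT:
    def test_equal_likelihoods(self):
        res = lrt(-100.0, -100.0, df=1)
        assert res.two_delta == 0.0 and res.p == 1.0

    def test_chi2_quantile(self):
        # 3.84 is the classical 5% critical value of chi2_1
        res = lrt(-100.0, -100.0 + 3.84 / 2, df=1)
        assert res.p == pytest.approx(0.05, abs=5e-4)

    def test_large_statistic_significant(self):
        res = lrt(-100.0, -100.0 + 25.86 / 2, df=1)
        assert res.p < 0.01

    def test_underoptimized_alternative_warns_and_clips(self):
        with pytest.warns(UserWarning, match="under-optimized"):
            res = lrt(-100.0, -100.5, df=1)
        assert res.two_delta == 0.0 and res.p == 1.0


def _lrt_from_stat(stat):
    return LRTResult(stat, 1, float(chi2.sf(stat, 1)))


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "sig1,sig2,omega_fg,omega_m0,expected",
        [
            (True, True, 3.12, 0.9, "positive"),
            (True, True, 0.53, 0.9, "conserved"),
            (True, False, 2.0, 0.9, "relaxed"),
            (True, False, 0.2, 0.9, "relaxed"),
            (False, True, 5.0, 0.54, "conserved"),   # effective omega is M0's
            (False, True, 5.0, 1.18, "positive"),
            (False, False, 2.0, 1.18, "relaxed"),
            (False, False, 0.3, 0.54, "relaxed"),
        ],
    )
    def test_decision_table(self, sig1, sig2, omega_fg, omega_m0, expected):
        l1 = _lrt_from_stat(10.0 if sig1 else 0.5)
        l2 = _lrt_from_stat(10.0 if sig2 else 0.5)
        call = classify_regime(l1, l2, omega_fg, omega_m0)
        assert call.label == expected
        assert call.omega_foreground == (omega_fg if sig1 else omega_m0)

    def test_pure_function(self):
        l1, l2 = _lrt_from_stat(4.2), _lrt_from_stat(0.1)
        a = classify_regime(l1, l2, 1.5, 0.8)
        b = classify_regime(l1, l2, 1.5, 0.8)
        assert a.label == b.label == "relaxed"

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            classify_regime(_lrt_from_stat(1), _lrt_from_stat(1), 1.0, 1.0,
                            alpha=1.5)

    def test_site_regime(self):
        assert classify_site_regime(_lrt_from_stat(10.0)) == "positive"
        assert classify_site_regime(_lrt_from_stat(0.5)) == "no_signal"


class TestBranchDnDs:
    def test_zero_branch(self):
        assert branch_dn_ds(0.0, uniform_params()) == (0.0, 0.0)

    def test_neutrality_equalizes_rates(self):
        dn, ds = branch_dn_ds(0.3, uniform_params(omega=1.0))
        assert dn == pytest.approx(ds, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_identity_and_omega(self, seed):
        from selpress.codon_model import site_opportunity

        rng = np.random.default_rng(seed)
        code = genetic_code(1)
        params = CodonModelParams(
            rng.uniform(0.5, 5), rng.uniform(0.05, 4),
            rng.dirichlet(np.ones(code.n) * 5),
        )
        t = rng.uniform(0.01, 1.0)
        dn, ds = branch_dn_ds(t, params)
        N, S = site_opportunity(params)
        assert dn * N + ds * S == pytest.approx(t, abs=1e-10)
        assert dn / ds == pytest.approx(params.omega, rel=1e-10)


def _fake_free_fit(tree, per_branch_dnds):
    code = genetic_code(1)
    pi = np.full(code.n, 1.0 / code.n)
    branches = []
    for node in tree.branches():
        dn, ds = per_branch_dnds[node.branch_id]
        branches.append(BranchEstimate(node.branch_id, node.length or 0.0,
                                       dn / ds if ds else float("nan"), dn, ds))
    return ModelFit(model_id="FREE", lnL=0.0, n_free_params=0, kappa=2.0,
                    pi=pi, freq_scheme="equal", per_branch=branches)


class TestRootToTipOmega:
    def test_single_branch_path(self):
        tree = read_tree("((A:1,B:1):1,C:1);")
        fit = _fake_free_fit(tree, {b.branch_id: (0.1, 0.2)
                                    for b in tree.branches()})
        # clade {A,B} rooted at the MRCA, stem excluded: path is just A
        w = root_to_tip_omega(fit, tree, "A", clade_root_tips={"A", "B"},
                              include_stem=False)
        assert w == pytest.approx(0.5)

    def test_worked_path_arithmetic(self):
        # chain of three branches with (dN,dS) = (0.1,0.2),(0.2,0.2),(0.1,0.4)
        tree = read_tree("(((A:1,B:1):1,C:1):1,D:1);")
        dnds = {b.branch_id: (0.0, 1.0) for b in tree.branches()}
        inner = tree.mrca({"A", "B"})
        outer = tree.mrca({"A", "B", "C"})
        dnds["A"] = (0.1, 0.2)
        dnds[inner.branch_id] = (0.2, 0.2)
        dnds[outer.branch_id] = (0.1, 0.4)
        fit = _fake_free_fit(tree, dnds)
        w = root_to_tip_omega(fit, tree, "A",
                              clade_root_tips={"A", "B", "C"},
                              include_stem=True)
        assert w == pytest.approx(0.4 / 0.8)

    def test_zero_synonymous_path_flagged_nan(self):
        tree = read_tree("((A:1,B:1):1,C:1);")
        fit = _fake_free_fit(tree, {b.branch_id: (0.1, 0.0)
                                    for b in tree.branches()})
        w = root_to_tip_omega(fit, tree, "A", clade_root_tips={"A", "B"})
        assert np.isnan(w)

    def test_subdivision_invariance(self):
        """Splitting a branch into two halves with the same per-unit rates
        leaves the statistic unchanged."""
        whole = read_tree("((A:1,B:1):1,C:1);")
        split = read_tree("(((A:0.5)x:0.5,B:1):1,C:1);")
        # the unifurcation survives parsing; its two halves carry half the
        # dN and dS of the original terminal branch
        d_whole = {b.branch_id: (0.12, 0.3) for b in whole.branches()}
        d_split = {}
        for b in split.branches():
            d_split[b.branch_id] = (0.06, 0.15) if b.branch_id in ("A", "x") \
                else (0.12, 0.3)
        w1 = root_to_tip_omega(_fake_free_fit(whole, d_whole), whole, "A",
                               clade_root_tips={"A", "B"})
        w2 = root_to_tip_omega(_fake_free_fit(split, d_split), split, "A",
                               clade_root_tips={"A", "B"})
        assert w1 == pytest.approx(w2, abs=1e-12)

    def test_tip_outside_clade_rejected(self):
        tree = read_tree("((A:1,B:1):1,C:1);")
        fit = _fake_free_fit(tree, {b.branch_id: (0.1, 0.2)
                                    for b in tree.branches()})
        with pytest.raises(ValidationError):
            root_to_tip_omega(fit, tree, "C", clade_root_tips={"A", "B"})


class TestDetectPSS:
    def test_null_fit_rejected(self, bs_sim):
        with pytest.raises(ValidationError, match="alternative"):
            detect_pss(bs_sim["bs_fixed"])

    def test_notation_format(self, bs_sim):
        records = detect_pss(bs_sim["bs"], threshold=0.5, method="neb")
        for rec in records:
            assert rec.notation == f"{rec.site}{rec.residue}"
            assert 1 <= rec.site <= bs_sim["aln"].n_sites
            assert 0.5 <= rec.posterior <= 1.0

    def test_beb_and_neb_agree_on_ranking(self, bs_sim):
        """Grid-integrated and MLE posteriors should broadly rank the same
        sites; check rank correlation is positive."""
        from selpress.selection_inference import (
            _beb_positive_posterior,
            _neb_positive_posterior,
        )

        neb = _neb_positive_posterior(bs_sim["bs"])
        beb = _beb_positive_posterior(bs_sim["bs"])
        assert beb.shape == neb.shape
        r = np.corrcoef(np.argsort(np.argsort(neb)),
                        np.argsort(np.argsort(beb)))[0, 1]
        assert r > 0.5
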