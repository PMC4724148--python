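import pytest

import selpress as sp
from oracles import clade_of_size
from selpress.codon_model import genetic_code
from selpress.synthetic_data import (
    BranchRegime,
    M0Regime,
    SimulationSpec,
    make_toy_study,
    random_yule_tree,
    simulate_codon_alignment,
)


@pytest.fixture(scope="session")
def code():
    return genetic_code(1)


@pytest.fixture(scope="session")
def tree8():
    return random_yule_tree(8, seed=7, mean_branch_length=0.12)


@pytest.fixture(scope="session")
def marked8(tree8):
    return tree8.mark_clade(clade_of_size(tree8, 3, 5))


@pytest.fixture(scope="session")
def branch_sim(marked8, tree8):
    """Two-ratio data (bg 0.4, fg 3.0) on the marked 8-taxon tree, with the
    M0 / MC / MCfixed ladder fitted once for reuse."""
    spec = SimulationSpec(tree=marked8, n_codons=300, kappa=2.0,
                          regime=BranchRegime(0.4, 3.0), seed=11)
    aln, truth = simulate_codon_alignment(spec)
    m0 = sp.fit_M0(aln, tree8)
    mc = sp.fit_branch_model(aln, marked8, False, m0)
    mc_fixed = sp.fit_branch_model(aln, marked8, True, m0)
    return {"aln": aln, "truth": truth, "m0": m0, "mc": mc,
            "mc_fixed": mc_fixed, "tree": tree8, "marked": marked8}


@pytest.fixture(scope="session")
def bs_sim(marked8, tree8):
    """Branch-site data (20% of sites at omega2=5 on the foreground) with
    the BSfixed/BS pair fitted once."""
    from selpress.synthetic_data import BranchSiteRegime

    spec = SimulationSpec(tree=marked8, n_codons=200, kappa=2.0,
                          regime=BranchSiteRegime(0.4, 0.4, 0.2, 5.0), seed=13)
    aln, truth = simulate_codon_alignment(spec)
    m0 = sp.fit_M0(aln, tree8)
    bs_fixed = sp.fit_branch_site(aln, marked8, True, m0)
    bs = sp.fit_branch_site(aln, marked8, False, m0, null_fit=bs_fixed)
    return {"aln": aln, "truth": truth, "m0": m0, "bs": bs,
            "bs_fixed": bs_fixed}


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """Reduced-scale toy study bundle with a RunConfig pointing at it."""
    from selpress.pipeline import RunConfig
    from selpress.synthetic_data import _write_bundle

    study = make_toy_study(seed=1, n_per_clade=6, n_cleaved=80, n_mature=150)
    d = tmp_path_factory.mktemp("toy")
    _write_bundle(study, d)
    config = RunConfig(
        alignments={"cleaved": str(d / "cleaved.fasta"),
                    "mature": str(d / "mature.fasta")},
        tree=str(d / "tree.nwk"),
        clades=study.clades,
        phenotypes=str(d / "phenotypes.tsv"),
        domain_annotation=str(d / "domains.tsv"),
        out_dir=str(d / "out"),
        seed=1,
    )
    return {"study": study, "dir": d, "config": config}
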