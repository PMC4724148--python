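"""Synthetic inputs with the statistical structure the analyses assume.

Two generators cover the two halves of the study design:

* codon alignments evolved along a tree under one-ratio, two-ratio
  (foreground/background) or branch-site (model-A site classes) regimes,
  with a truth sidecar recording per-branch and per-site generating values;
* continuous traits y = X beta + eps with eps ~ N(0, sigma^2 * C_lambda),
  i.e. lambda-scaled Brownian phylogenetic noise around a specified
  regression structure.

``make_toy_study`` bundles both into a small two-clade study — a conserved
N-terminal domain, a C-terminal domain with a positively selected
foreground clade and a neutrally drifting background clade, and a planted
association between the conserved domain's root-to-tip omega and relative
sperm head width — used for end-to-end tests and documentation.

All randomness flows from the single seed in the spec; the same seed gives
byte-identical bundles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_model import (
    CodonModelParams,
    TransitionKernel,
    build_rate_matrix,
    genetic_code,
)
from .pgls import apply_lambda, phylo_covariance
from .seqio import (
    CodonAlignment,
    DomainAnnotation,
    PhyloTree,
    TreeNode,
    write_codon_alignment,
    write_domain_annotation,
    write_tree,
)

__all__ = [
    "M0Regime",
    "BranchRegime",
    "BranchSiteRegime",
    "SimulationSpec",
    "random_yule_tree",
    "random_ultrametric_tree",
    "simulate_codon_alignment",
    "simulate_traits",
    "make_toy_study",
]


@dataclass
class M0Regime:
    omega: float


@dataclass
class BranchRegime:
    omega_background: float
    omega_foreground: float


@dataclass
class BranchSiteRegime:
    """Model-A generator: classes fixed per site at the root; omega switches
    to omega2 only on foreground branches (2a/2b semantics)."""

    p0: float
    p1: float
    omega0: float
    omega2: float

    @property
    def proportions(self) -> np.ndarray:
        p2 = 1.0 - self.p0 - self.p1
        frac = self.p0 / (self.p0 + self.p1)
        return np.array([self.p0, self.p1, p2 * frac, p2 * (1 - frac)])


@dataclass
class SimulationSpec:
    tree: PhyloTree
    n_codons: int
    kappa: float
    regime: M0Regime | BranchRegime | BranchSiteRegime
    seed: int
    pi: np.ndarray | None = None  # default: uniform over sense codons
    code_id: int = 1

    def resolved_pi(self) -> np.ndarray:
        if self.pi is not None:
            return np.asarray(self.pi, dtype=float)
        code = genetic_code(self.code_id)
        return np.full(code.n, 1.0 / code.n)


def random_yule_tree(
    n_tips: int,
    seed: int,
    mean_branch_length: float = 0.1,
    prefix: str = "T",
) -> PhyloTree:
    """Random bifurcating topology with exponential branch lengths."""
    rng = np.random.default_rng(seed)
    tips = [TreeNode(label=f"{prefix}{i + 1}") for i in range(n_tips)]
    lineages = list(tips)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        parent = TreeNode(children=[a, b])
        lineages.append(parent)
    root = lineages[0]
    tree = PhyloTree(root)
    for node in tree.branches():
        node.length = float(rng.exponential(mean_branch_length)) + 1e-3
    return tree


def random_ultrametric_tree(
    n_tips: int,
    seed: int,
    depth: float = 1.0,
    prefix: str = "T",
) -> PhyloTree:
    """Pure-birth (Yule) tree with a molecular clock: all tips equidistant
    from the root at ``depth``.  The natural shape for comparative trait
    analyses, where lambda = 0 collapses PGLS to ordinary least squares."""
    rng = np.random.default_rng(seed)
    # n-1 speciation events; waiting times exponential in the lineage count,
    # rescaled so the tree depth is exactly ``depth``
    events = [0.0]
    t = 0.0
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / k)
        events.append(t)
    total = t + rng.exponential(1.0 / n_tips)
    events = [x * depth / total for x in events]

    root = TreeNode()
    lineages = [(root, 0.0)]  # (node, birth time)
    for event_time in events:
        k = int(rng.integers(len(lineages)))
        node, birth = lineages.pop(k)
        node.length = event_time - birth
        left, right = TreeNode(), TreeNode()
        node.children = [left, right]
        lineages += [(left, event_time), (right, event_time)]
    for i, (node, birth) in enumerate(lineages):
        node.label = f"{prefix}{i + 1}"
        node.length = depth - birth
    root.length = None
    return PhyloTree(root)


def _sample_children(P: np.ndarray, parent_states: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw of child states given parent states."""
    out = np.empty_like(parent_states)
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    for s in np.unique(parent_states):
        mask = parent_states == s
        out[mask] = np.searchsorted(cum[s], u[mask])
    return np.clip(out, 0, P.shape[0] - 1)


def simulate_codon_alignment(
    spec: SimulationSpec,
) -> tuple[CodonAlignment, dict]:
    """Evolve codon states down the tree under the spec's regime.

    Returns the alignment and a truth sidecar with ``branches`` (DataFrame:
    branch_id, t, true omegas) and, for branch-site regimes, ``site_class``
    (per-site generating class 0/1/2a/2b).
    """
    rng = np.random.default_rng(spec.seed)
    pi = spec.resolved_pi()
    tree = spec.tree
    n = spec.n_codons
    regime = spec.regime

    # per-site (background omega, foreground omega)
    if isinstance(regime, M0Regime):
        site_bg = np.full(n, regime.omega)
        site_fg = site_bg
        site_class = None
    elif isinstance(regime, BranchRegime):
        site_bg = np.full(n, regime.omega_background)
        site_fg = np.full(n, regime.omega_foreground)
        site_class = None
    elif isinstance(regime, BranchSiteRegime):
        classes = rng.choice(4, size=n, p=regime.proportions)
        bg_by_class = np.array([regime.omega0, 1.0, regime.omega0, 1.0])
        fg_by_class = np.array([regime.omega0, 1.0, regime.omega2, regime.omega2])
        site_bg = bg_by_class[classes]
        site_fg = fg_by_class[classes]
        site_class = classes
    else:
        raise TypeError(f"unknown regime {regime!r}")

    kernels: dict[float, TransitionKernel] = {}

    def kernel(omega: float) -> TransitionKernel:
        if omega not in kernels:
            params = CodonModelParams(spec.kappa, omega, pi, spec.code_id)
            kernels[omega] = TransitionKernel(build_rate_matrix(params))
        return kernels[omega]

    root_states = rng.choice(len(pi), size=n, p=pi / pi.sum())
    states = {id(tree.root): root_states}
    branch_rows = []
    for node in reversed(tree.postorder()):  # preorder
        if node.parent is None:
            continue
        t = node.length if node.length is not None else 0.0
        site_omega = site_fg if node.foreground else site_bg
        parent_states = states[id(node.parent)]
        child = np.empty(n, dtype=np.int64)
        for w in np.unique(site_omega):
            mask = site_omega == w
            if t == 0:
                child[mask] = parent_states[mask]
            else:
                P = kernel(float(w)).probability_matrix(t)
                child[mask] = _sample_children(P, parent_states[mask], rng)
        states[id(node)] = child
        branch_rows.append({
            "branch_id": node.branch_id,
            "t": t,
            "foreground": node.foreground,
            "omega_background": site_bg[0] if site_class is None else regime.omega0,
            "omega_foreground": site_fg[0] if site_class is None else regime.omega2,
        })

    taxa = tree.tip_labels
    codes = np.vstack([states[id(tree.find_tip(t))] for t in taxa]).astype(np.int16)
    aln = CodonAlignment(taxa, codes, spec.code_id)
    truth = {"branches": pd.DataFrame(branch_rows)}
    if site_class is not None:
        truth["site_class"] = site_class
    truth["root_states"] = root_states
    return aln, truth


def simulate_traits(
    tree: PhyloTree,
    beta: np.ndarray,
    X: pd.DataFrame,
    lambda_true: float,
    sigma: float,
    seed: int,
    intercept: float = 0.0,
) -> pd.Series:
    """y = intercept + X beta + eps with eps ~ N(0, sigma^2 C_lambda).

    ``X`` is species-indexed; species order follows X.
    """
    species = list(X.index)
    C = phylo_covariance(tree, species).to_numpy()
    scale = np.mean(np.diag(C))
    Clam = apply_lambda(C / scale, lambda_true)
    rng = np.random.default_rng(seed)
    mean = intercept + X.to_numpy(dtype=float) @ np.asarray(beta, dtype=float)
    if sigma == 0:
        y = mean
    else:
        y = rng.multivariate_normal(mean, sigma**2 * Clam, method="cholesky")
    return pd.Series(y, index=species)


def simulate_brownian(tree: PhyloTree, sigma: float, seed: int,
                      mean: float = 0.0) -> pd.Series:
    """A single Brownian-motion trait (lambda = 1)."""
    species = tree.tip_labels
    X = pd.DataFrame(index=species)
    return simulate_traits(tree, np.zeros(0), X, 1.0, sigma, seed,
                           intercept=mean)


# ---------------------------------------------------------------------------
# bundled toy study
# ---------------------------------------------------------------------------


@dataclass
class ToyStudy:
    tree: PhyloTree
    cleaved: CodonAlignment
    mature: CodonAlignment
    precursor: CodonAlignment
    annotation: DomainAnnotation
    phenotypes: pd.DataFrame
    clades: dict[str, list[str]]
    truth: dict = field(default_factory=dict)


def _two_clade_tree(n_per_clade: int, seed: int) -> tuple[PhyloTree, dict]:
    # ultrametric (clock-like) overall shape, as comparative trait analyses
    # assume: two clades of equal depth joined by equal stem branches
    rng = np.random.default_rng(seed)
    a = random_ultrametric_tree(n_per_clade, seed + 1, depth=0.28,
                                prefix="A").root
    b = random_ultrametric_tree(n_per_clade, seed + 2, depth=0.28,
                                prefix="B").root
    stem = float(rng.uniform(0.05, 0.1))
    a.length = stem
    b.length = stem
    tree = PhyloTree(TreeNode(children=[a, b]))
    clades = {
        "cladeA": [t for t in tree.tip_labels if t.startswith("A")],
        "cladeB": [t for t in tree.tip_labels if t.startswith("B")],
    }
    return tree, clades


def make_toy_study(
    seed: int,
    out_dir: str | os.PathLike | None = None,
    n_per_clade: int = 8,
    n_cleaved: int = 100,
    n_mature: int = 200,
    kappa: float = 2.0,
    slope_hw: float = 0.14,
) -> ToyStudy:
    """Two-clade study with planted selection regimes and one planted
    trait association.

    * cleaved domain: purifying selection everywhere (omega 0.3), with mild
      lognormal branch-to-branch rate scatter so root-to-tip omega varies
      across species;
    * mature domain: neutral background (omega 1) with positive selection
      (omega 3) on clade A — so the branch test should call clade A
      "positive" and clade B "relaxed";
    * relative head width = 0.04 + ``slope_hw`` * true cleaved root-to-tip
      omega + Brownian noise; all other traits carry no planted signal.

    With ``out_dir`` the bundle is written as FASTA/Newick/TSV files
    (byte-identical for identical seeds).
    """
    from .selection_inference import branch_dn_ds

    tree, clades = _two_clade_tree(n_per_clade, seed)
    rng = np.random.default_rng(seed + 10)

    # cleaved: conserved on average, with substantial branch-to-branch rate
    # scatter (lognormal around 0.3) so root-to-tip omega varies enough
    # across species to carry the planted trait association through the
    # estimation noise of a ~100-codon domain
    cleaved_tree = tree.copy()
    branch_omegas = {}
    for node in cleaved_tree.branches():
        w = float(np.exp(np.log(0.3) + rng.normal(0, 0.8)))
        branch_omegas[node.branch_id] = min(w, 0.95)
    # simulate branch-by-branch by marking each branch foreground in turn is
    # wasteful; instead reuse the M0 machinery per branch via a custom walk
    pi = np.full(genetic_code(1).n, 1.0 / genetic_code(1).n)
    cleaved_aln, cleaved_truth = _simulate_heterogeneous(
        cleaved_tree, n_cleaved, kappa, branch_omegas, pi, seed + 20
    )

    mature_tree = tree.mark_clade(clades["cladeA"])
    mature_spec = SimulationSpec(
        tree=mature_tree, n_codons=n_mature, kappa=kappa,
        regime=BranchRegime(omega_background=1.0, omega_foreground=3.0),
        seed=seed + 30,
    )
    mature_aln, mature_truth = simulate_codon_alignment(mature_spec)

    taxa = tree.tip_labels
    precursor = CodonAlignment(
        taxa,
        np.hstack([
            cleaved_aln.subset_taxa(taxa).codes,
            mature_aln.subset_taxa(taxa).codes,
        ]),
        1,
    )
    annotation = DomainAnnotation({t: n_cleaved + 1 for t in taxa})

    # true root-to-tip omega of the cleaved domain per species (clade-rooted)
    params_of = {
        bid: CodonModelParams(kappa, w, pi) for bid, w in branch_omegas.items()
    }
    true_rtt = {}
    for clade, members in clades.items():
        root = cleaved_tree.mrca(members)
        for sp in members:
            node = cleaved_tree.find_tip(sp)
            dn = ds = 0.0
            path = []
            while node is not root:
                path.append(node)
                node = node.parent
            if root.parent is not None:
                path.append(root)
            for n_ in path:
                d_n, d_s = branch_dn_ds(n_.length or 0.0, params_of[n_.branch_id])
                dn, ds = dn + d_n, ds + d_s
            true_rtt[sp] = dn / ds if ds > 0 else float("nan")
    true_rtt = pd.Series(true_rtt, name="true_omega_rtt_cleaved").loc[taxa]

    # phenotypes: body/testes Brownian, no planted sexual-selection signal;
    # relative head width tracks the cleaved-domain rate
    log_body = simulate_brownian(tree, 0.5, seed + 40, mean=2.0)
    log_testes = (log_body - 2.0) * 0.7 + simulate_brownian(tree, 0.25, seed + 41)
    total_len = 90.0 + 25.0 * simulate_brownian(tree, 0.4, seed + 42)
    head_len = 7.0 + 1.5 * simulate_brownian(tree, 0.4, seed + 43)
    rel_hw = simulate_traits(
        tree, np.array([slope_hw]), true_rtt.to_frame(), lambda_true=1.0,
        sigma=0.008, seed=seed + 44, intercept=0.04,
    )
    rel_hw = rel_hw.clip(lower=0.01)

    phen = pd.DataFrame({
        "species": taxa,
        "clade": ["cladeA" if t.startswith("A") else "cladeB" for t in taxa],
        "body_mass_g": np.round(10.0 ** log_body.loc[taxa].to_numpy(), 4),
        "testes_mass_g": np.round(10.0 ** (log_testes.loc[taxa].to_numpy() - 1.0), 5),
        "head_length_um": np.round(head_len.loc[taxa].to_numpy(), 3),
        "head_width_um": np.round(
            (rel_hw.loc[taxa] * total_len.loc[taxa]).to_numpy(), 3
        ),
        "total_sperm_length_um": np.round(total_len.loc[taxa].to_numpy(), 3),
    })

    truth = {
        "cleaved_branch_omegas": branch_omegas,
        "cleaved_truth": cleaved_truth,
        "mature_truth": mature_truth,
        "true_omega_rtt_cleaved": true_rtt,
        "slope_hw": slope_hw,
        "mature_regime": mature_spec.regime,
    }
    study = ToyStudy(
        tree=mature_tree,  # carries the clade-A foreground marks
        cleaved=cleaved_aln, mature=mature_aln, precursor=precursor,
        annotation=annotation, phenotypes=phen, clades=clades, truth=truth,
    )
    if out_dir is not None:
        _write_bundle(study, out_dir)
    return study


def _simulate_heterogeneous(tree, n_codons, kappa, branch_omegas, pi, seed):
    """Evolve with an arbitrary fixed omega per branch (free-ratio truth)."""
    rng = np.random.default_rng(seed)
    kernels: dict[float, TransitionKernel] = {}

    def kernel(w):
        if w not in kernels:
            kernels[w] = TransitionKernel(
                build_rate_matrix(CodonModelParams(kappa, w, pi))
            )
        return kernels[w]

    root_states = rng.choice(len(pi), size=n_codons, p=pi / pi.sum())
    states = {id(tree.root): root_states}
    rows = []
    for node in reversed(tree.postorder()):
        if node.parent is None:
            continue
        t = node.length or 0.0
        w = branch_omegas[node.branch_id]
        P = kernel(w).probability_matrix(t)
        states[id(node)] = _sample_children(P, states[id(node.parent)], rng)
        rows.append({"branch_id": node.branch_id, "t": t, "omega": w})
    taxa = tree.tip_labels
    codes = np.vstack([states[id(tree.find_tip(x))] for x in taxa]).astype(np.int16)
    return CodonAlignment(taxa, codes, 1), {"branches": pd.DataFrame(rows)}


def _write_bundle(study: ToyStudy, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    j = lambda name: os.path.join(out_dir, name)  # noqa: E731
    write_codon_alignment(study.cleaved, j("cleaved.fasta"))
    write_codon_alignment(study.mature, j("mature.fasta"))
    write_codon_alignment(study.precursor, j("precursor.fasta"))
    write_tree(study.tree, j("tree.nwk"))
    write_domain_annotation(study.annotation, j("domains.tsv"))
    study.phenotypes.to_csv(j("phenotypes.tsv"), sep="\t", index=False)
    study.truth["true_omega_rtt_cleaved"].rename_axis("species").to_csv(
        j("truth_omega_rtt_cleaved.tsv"), sep="\t"
    )
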