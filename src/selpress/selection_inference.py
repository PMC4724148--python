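"""Likelihood-ratio tests, selection-regime classification, per-branch dN/dS,
root-to-tip omega and positively-selected-site (PSS) detection.

The regime decision combines two LRTs computed on the same foreground
marking:

* M0 vs MC     — does the foreground evolve at a different rate than the
                 background?
* MCfixed vs MC — is the foreground rate different from neutrality (omega=1)?

Decision table (alpha default 0.05; "effective omega" is the MC foreground
omega when M0-vs-MC is significant, the M0 omega otherwise, matching the
reporting rule used for branch tests):

====================  ====================  ============  =========
M0 vs MC              MCfixed vs MC         eff. omega    label
====================  ====================  ============  =========
significant           significant           > 1           positive
significant           significant           < 1           conserved
significant           not significant       any           relaxed
not significant       significant           < 1           conserved
not significant       significant           > 1           positive
not significant       not significant       any           relaxed
====================  ====================  ============  =========
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.stats import chi2

from .codon_model import CodonModelParams, flux_fractions, site_opportunity
from .phylo_likelihood import KernelCache, ModelFit, SiteClassMixture
from .seqio import PhyloTree, ValidationError

__all__ = [
    "LRTResult",
    "RegimeCall",
    "PSSRecord",
    "lrt",
    "classify_regime",
    "classify_site_regime",
    "branch_dn_ds",
    "root_to_tip_omega",
    "detect_pss",
]

#: optimizer slack below which lnL_alt < lnL_null is treated as ties
_OPT_TOL = 1e-6


@dataclass
class LRTResult:
    two_delta: float
    df: int
    p: float

    @property
    def significant(self) -> bool:  # at the conventional 0.05
        return self.p <= 0.05


@dataclass
class RegimeCall:
    label: str  # conserved | positive | relaxed | no_signal
    omega_foreground: float
    lrt_m0_mc: LRTResult | None = None
    lrt_mcfix_mc: LRTResult | None = None


@dataclass
class PSSRecord:
    site: int  # 1-based alignment codon coordinate
    residue: str  # reference taxon's residue at the site
    posterior: float  # P(class 2a or 2b)

    @property
    def notation(self) -> str:
        """Compact "64R"-style site+residue label."""
        return f"{self.site}{self.residue}"


def lrt(fit_null: ModelFit | float, fit_alt: ModelFit | float, df: int) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2*(lnL_alt - lnL_null) ~ chi2_df.

    Accepts ModelFit objects or raw log-likelihoods.  A negative difference
    beyond optimizer tolerance triggers an under-optimization warning; the
    statistic is clipped at 0 either way.
    """
    lnl_null = fit_null.lnL if isinstance(fit_null, ModelFit) else float(fit_null)
    lnl_alt = fit_alt.lnL if isinstance(fit_alt, ModelFit) else float(fit_alt)
    delta = 2.0 * (lnl_alt - lnl_null)
    if delta < -_OPT_TOL:
        warnings.warn(
            f"alternative under-optimized: lnL_alt - lnL_null = {delta / 2:.6g}",
            stacklevel=2,
        )
    two_delta = max(0.0, delta)
    p = float(chi2.sf(two_delta, df))
    return LRTResult(two_delta=two_delta, df=df, p=p)


def lrt_boundary_mixture(fit_null, fit_alt, df: int = 1) -> LRTResult:
    """LRT with the 50:50 point-mass/chi2_df null for boundary hypotheses."""
    base = lrt(fit_null, fit_alt, df)
    p = 1.0 if base.two_delta == 0 else float(0.5 * chi2.sf(base.two_delta, df))
    return LRTResult(base.two_delta, df, p)


def classify_regime(
    lrt_m0_mc: LRTResult,
    lrt_mcfix_mc: LRTResult,
    omega_fg: float,
    omega_m0: float,
    alpha: float = 0.05,
) -> RegimeCall:
    """Selection-regime label for a foreground clade from the two branch LRTs.

    When M0 vs MC is not significant the M0 omega is the effective
    (reported) foreground rate.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rate_differs = lrt_m0_mc.p <= alpha
    neutrality_rejected = lrt_mcfix_mc.p <= alpha
    effective_omega = omega_fg if rate_differs else omega_m0

    if neutrality_rejected:
        label = "positive" if effective_omega > 1 else "conserved"
    else:
        label = "relaxed"
    return RegimeCall(
        label=label,
        omega_foreground=effective_omega,
        lrt_m0_mc=lrt_m0_mc,
        lrt_mcfix_mc=lrt_mcfix_mc,
    )


def classify_site_regime(lrt_bsfix_bs: LRTResult, alpha: float = 0.05) -> str:
    """Branch-site interpretation: positive selection on sites, or no signal."""
    return "positive" if lrt_bsfix_bs.p <= alpha else "no_signal"


def branch_dn_ds(t: float, params: CodonModelParams) -> tuple[float, float]:
    """Per-branch (dN, dS) from the flux decomposition of branch length t.

    With opportunity sites (N, S) at omega=1 and flux fractions (rhoN, rhoS)
    under the branch's own omega: dN = t*rhoN/N, dS = t*rhoS/S, so that
    dN*N + dS*S = t and dN/dS = omega exactly.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    N, S = site_opportunity(params)
    if S <= 0:
        raise ValueError("degenerate code: S = 0")
    rho_n, rho_s = flux_fractions(params)
    return t * rho_n / N, t * rho_s / S


def root_to_tip_omega(
    free_fit: ModelFit,
    tree: PhyloTree,
    tip: str,
    clade_root_tips=None,
    include_stem: bool = True,
) -> float:
    """Sum dN and dS along the path from a clade's root to a tip; return the
    ratio of the sums.

    ``clade_root_tips`` names the clade (its MRCA is the clade root); when
    None, the path runs from the tree root.  ``include_stem`` includes the
    clade root's own stem branch in the path.  Returns NaN (flagged by the
    caller for exclusion from regressions) when the summed dS is zero.
    """
    by_id = {b.branch_id: b for b in free_fit.per_branch}
    # walk up from the tip to the clade root
    if clade_root_tips is not None:
        clade_root = tree.mrca(set(clade_root_tips))
    else:
        clade_root = tree.root
    node = tree.find_tip(tip)
    if not tree._is_descendant(node, clade_root):
        raise ValidationError(f"tip {tip!r} is not inside the clade")
    path = []
    while node is not clade_root:
        path.append(node)
        node = node.parent
        if node is None:
            raise ValidationError("tip is not below the clade root")
    if include_stem and clade_root.parent is not None:
        path.append(clade_root)
    dn = sum(by_id[n.branch_id].dN for n in path)
    ds = sum(by_id[n.branch_id].dS for n in path)
    if ds <= 0:
        return float("nan")
    return dn / ds


# ---------------------------------------------------------------------------
# positively selected sites
# ---------------------------------------------------------------------------


def _neb_positive_posterior(bs_fit: ModelFit) -> np.ndarray:
    """P(class 2a or 2b) per site at the MLE (naive empirical Bayes)."""
    post = bs_fit.site_posteriors  # (n_sites, 4)
    return post[:, 2] + post[:, 3]


def _beb_positive_posterior(bs_fit: ModelFit, n_grid: int = 8) -> np.ndarray:
    """Bayes-empirical-Bayes positive-class posterior per site.

    Integrates the model-A mixture over a uniform grid on (p0, p1, omega0,
    omega2) with kappa and branch lengths fixed at their MLEs, in the style
    of codeml's BEB: site class-conditional likelihoods are precomputed for
    each grid value of omega0 and omega2, then mixed under every grid
    combination of the proportions.
    """
    engine = bs_fit.engine
    if engine is None:
        raise ValidationError("fit carries no engine; refit to compute BEB")
    pi = bs_fit.pi
    cache = KernelCache(pi, engine.aln.genetic_code_id)
    t_of = {
        i: dict((b.branch_id, b.t) for b in bs_fit.per_branch)[engine.branch_ids[i]]
        for i in engine.branch_nodes
    }
    kappa = bs_fit.kappa

    w0_grid = (np.arange(n_grid) + 0.5) / n_grid  # omega0 in (0,1)
    w2_grid = 1.0 + 10.0 * (np.arange(n_grid) + 0.5) / n_grid  # omega2 in (1,11)

    def class_logliks(w_bg, w_fg):
        omega_of = {
            i: (w_fg if engine.foreground[i] else w_bg)
            for i in engine.branch_nodes
        }
        P = engine.build_P(cache, kappa, omega_of, t_of)
        return engine.pattern_logliks(P, pi)

    # conditional log-likelihood per pattern for each class/grid value
    ll_c1 = class_logliks(1.0, 1.0)
    ll_c0 = {w0: class_logliks(w0, w0) for w0 in w0_grid}
    ll_c2b = {w2: class_logliks(1.0, w2) for w2 in w2_grid}
    ll_c2a = {
        (w0, w2): class_logliks(w0, w2) for w0 in w0_grid for w2 in w2_grid
    }

    # proportion grid: p0, p1 from a uniform triangle discretization
    props = []
    for i in range(n_grid):
        for j in range(n_grid):
            p0 = (i + 0.5) / n_grid
            p1 = (j + 0.5) / n_grid * (1.0 - p0)
            props.append((p0, p1))

    n_pat = engine.n_patterns
    log_post_num = None  # log sum over grid of prior*L(data)*P(site in 2a/2b)
    log_marg = None
    counts = engine.counts

    def logaddexp_acc(acc, x):
        return x if acc is None else np.logaddexp(acc, x)

    for w0 in w0_grid:
        for w2 in w2_grid:
            lls = np.vstack([ll_c0[w0], ll_c1, ll_c2a[(w0, w2)], ll_c2b[w2]])
            for p0, p1 in props:
                mix = SiteClassMixture(p0, p1, w0, w2)
                wts = np.maximum(mix.proportions, 1e-300)
                m = lls.max(axis=0)
                site_like = np.log(wts @ np.exp(lls - m)) + m  # (n_pat,)
                log_data = float(counts @ site_like)  # log L(data | theta)
                pos = np.log(
                    np.maximum(
                        wts[2] * np.exp(lls[2] - m) + wts[3] * np.exp(lls[3] - m),
                        1e-300,
                    )
                ) + m
                log_post_num = logaddexp_acc(log_post_num, log_data + pos)
                log_marg = logaddexp_acc(log_marg, log_data + site_like)

    post_pat = np.exp(log_post_num - log_marg)
    return np.clip(post_pat[engine.site_to_pattern], 0.0, 1.0)


def detect_pss(
    bs_fit: ModelFit,
    threshold: float = 0.95,
    reference_taxon: str | None = None,
    method: str = "beb",
) -> list[PSSRecord]:
    """Sites with posterior probability >= threshold of the foreground
    positive-selection classes (2a + 2b), labelled "64R"-style with the
    reference taxon's residue.  Site numbers are 1-based alignment columns.

    ``method`` is "beb" (grid-integrated Bayes empirical Bayes, default) or
    "neb" (posteriors at the MLE).
    """
    if bs_fit.model_id != "BS":
        raise ValidationError(
            "PSS detection requires the alternative branch-site fit (BS); "
            f"got {bs_fit.model_id} (the null has no positive class)"
        )
    if method == "neb":
        pos = _neb_positive_posterior(bs_fit)
    elif method == "beb":
        pos = _beb_positive_posterior(bs_fit)
    else:
        raise ValueError(f"unknown method {method!r}")

    aln = bs_fit.engine.aln if bs_fit.engine is not None else None
    if reference_taxon is None and aln is not None:
        reference_taxon = aln.taxa[0]
    protein = aln.protein(reference_taxon) if aln is not None else None

    records = []
    for s in np.nonzero(pos >= threshold)[0]:
        residue = protein[s] if protein is not None else "?"
        records.append(PSSRecord(site=int(s) + 1, residue=residue,
                                 posterior=float(pos[s])))
    return records
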