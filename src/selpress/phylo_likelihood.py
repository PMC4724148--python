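"""Pruning likelihoods and maximum-likelihood fits of the branch/branch-site
model ladder: M0 (one ratio), MC (two ratio), MCfixed (foreground omega = 1),
free-ratio, branch-site model A (BS) and its null with omega2 = 1 (BSfixed).

The likelihood of a codon alignment on a rooted tree is computed by
Felsenstein pruning over the sense-codon state space, with alignment columns
compressed to unique site patterns.  The root is weighted by the equilibrium
frequencies; because the process is reversible the rooted likelihood equals
the unrooted one, with the two branches incident to a two-child root
identified only through their sum — those two branch lengths are therefore
tied to a single parameter during optimization (each reported as half).

Branch lengths are estimated once under M0 and held fixed for MC, MCfixed,
BS and BSfixed; the free-ratio model re-optimizes branch lengths jointly
with per-branch omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .codon_model import (
    CodonModelParams,
    TransitionKernel,
    build_rate_matrix,
    estimate_codon_frequencies,
    genetic_code,
)
from .seqio import CodonAlignment, PhyloTree, ValidationError

__all__ = [
    "ModelFit",
    "BranchEstimate",
    "SiteClassMixture",
    "LikelihoodEngine",
    "log_likelihood",
    "fit_M0",
    "fit_branch_model",
    "fit_free_ratio",
    "fit_branch_site",
]

LNL_TOL = 1e-8
OMEGA_MIN, OMEGA_MAX = 1e-4, 999.0
KAPPA_MIN, KAPPA_MAX = 1e-2, 100.0
T_MIN, T_MAX = 1e-7, 50.0


class LikelihoodError(RuntimeError):
    """Non-finite or zero likelihood."""


@dataclass
class BranchEstimate:
    branch_id: str
    t: float
    omega: float
    dN: float
    dS: float
    foreground: bool = False
    flag: str = ""


@dataclass
class SiteClassMixture:
    """Model-A site classes 0 / 1 / 2a / 2b.

    p2a and p2b are determined by (p0, p1):
    p2a = (1-p0-p1) * p0/(p0+p1), p2b = (1-p0-p1) * p1/(p0+p1).
    """

    p0: float
    p1: float
    omega0: float
    omega2: float
    omega1: float = 1.0

    @property
    def p2a(self) -> float:
        return (1.0 - self.p0 - self.p1) * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        return (1.0 - self.p0 - self.p1) * self.p1 / (self.p0 + self.p1)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])

    def class_omegas(self) -> list[tuple[float, float]]:
        """(background omega, foreground omega) per class 0,1,2a,2b."""
        return [
            (self.omega0, self.omega0),
            (self.omega1, self.omega1),
            (self.omega0, self.omega2),
            (self.omega1, self.omega2),
        ]


@dataclass
class ModelFit:
    model_id: str
    lnL: float
    n_free_params: int
    kappa: float
    pi: np.ndarray = field(repr=False)
    freq_scheme: str
    omega: float | None = None
    omega_background: float | None = None
    omega_foreground: float | None = None
    mixture: SiteClassMixture | None = None
    per_branch: list[BranchEstimate] = field(default_factory=list)
    site_posteriors: np.ndarray | None = field(default=None, repr=False)
    n_restarts: int = 0
    converged: bool = True
    diagnostics: str = ""
    # non-serialized handles used by downstream posterior computations
    engine: "LikelihoodEngine | None" = field(default=None, repr=False)

    def branch_lengths(self) -> dict[str, float]:
        return {b.branch_id: b.t for b in self.per_branch}


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


class KernelCache:
    """Transition kernels memoized by (kappa, omega) for a fixed pi."""

    def __init__(self, pi: np.ndarray, code_id: int = 1):
        self.pi = pi
        self.code_id = code_id
        self._cache: dict[tuple[float, float], TransitionKernel] = {}

    def kernel(self, kappa: float, omega: float) -> TransitionKernel:
        key = (kappa, omega)
        kern = self._cache.get(key)
        if kern is None:
            if len(self._cache) > 256:
                self._cache.clear()
            params = CodonModelParams(kappa, omega, self.pi, self.code_id)
            kern = TransitionKernel(build_rate_matrix(params))
            self._cache[key] = kern
        return kern


class LikelihoodEngine:
    """Pattern-compressed pruning on a tree matched to an alignment.

    Branch parameters follow postorder node indices; when the root has
    exactly two children their branch lengths share one optimization
    parameter (split half/half on report).
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree):
        if set(aln.taxa) - set(tree.tip_labels):
            raise ValidationError(
                "alignment taxa missing from tree: "
                f"{sorted(set(aln.taxa) - set(tree.tip_labels))}"
            )
        if set(tree.tip_labels) != set(aln.taxa):
            tree = tree.prune_to_taxa(aln.taxa)
        self.tree = tree
        self.aln = aln
        self.code = genetic_code(aln.genetic_code_id)
        self.n_states = self.code.n

        self.post = tree.postorder()
        index = {id(n): i for i, n in enumerate(self.post)}
        self.root_idx = index[id(tree.root)]
        self.children = [
            [index[id(c)] for c in n.children] for n in self.post
        ]
        self.is_tip = [n.is_tip for n in self.post]
        self.branch_ids = [n.branch_id for n in self.post]
        self.foreground = np.array([n.foreground for n in self.post])
        self.branch_nodes = [
            i for i, n in enumerate(self.post) if n.parent is not None
        ]

        # tie the two root-child branches to one length parameter
        root_children = self.children[self.root_idx]
        self.tied_pair = tuple(root_children) if len(root_children) == 2 else None

        # one length parameter per branch, minus one if a pair is tied
        self.length_param_of: dict[int, int] = {}
        self.length_factor: dict[int, float] = {}
        p = 0
        for i in self.branch_nodes:
            if self.tied_pair and i == self.tied_pair[1]:
                self.length_param_of[i] = self.length_param_of[self.tied_pair[0]]
                self.length_factor[i] = 0.5
            else:
                self.length_param_of[i] = p
                self.length_factor[i] = 0.5 if (
                    self.tied_pair and i == self.tied_pair[0]
                ) else 1.0
                p += 1
        self.n_length_params = p

        # pattern compression
        cols = aln.codes.T  # (n_sites, n_taxa)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_pat, n_taxa)
        self.site_to_pattern = inverse
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        self.n_sites = aln.n_sites

        row_of = {t: r for r, t in enumerate(aln.taxa)}
        self._tip_partial: dict[int, np.ndarray] = {}
        for i, node in enumerate(self.post):
            if not node.is_tip:
                continue
            states = patterns[:, row_of[node.label]]
            T = np.zeros((self.n_states, self.n_patterns))
            missing = states < 0
            T[:, missing] = 1.0
            obs = ~missing
            T[states[obs], np.nonzero(obs)[0]] = 1.0
            self._tip_partial[i] = T

    # -- core pruning -------------------------------------------------------

    def pattern_logliks(self, P: dict[int, np.ndarray], pi: np.ndarray) -> np.ndarray:
        """Log-likelihood per site pattern given per-branch P matrices."""
        partials: list[np.ndarray | None] = [None] * len(self.post)
        logscale = np.zeros(self.n_patterns)
        for i in range(len(self.post)):
            if self.is_tip[i]:
                partials[i] = self._tip_partial[i]
                continue
            L = np.ones((self.n_states, self.n_patterns))
            for c in self.children[i]:
                L *= P[c] @ partials[c]
                partials[c] = None
            m = L.max(axis=0)
            if not np.all(m > 0):
                bad = int(np.nonzero(m <= 0)[0][0])
                site = int(np.nonzero(self.site_to_pattern == bad)[0][0]) + 1
                raise LikelihoodError(
                    f"zero likelihood at codon site {site} (1-based)"
                )
            L /= m
            logscale += np.log(m)
            partials[i] = L
        site_like = pi @ partials[self.root_idx]
        if not np.all(np.isfinite(site_like)):
            raise LikelihoodError("non-finite site likelihood")
        return np.log(site_like) + logscale

    def lnL(self, P: dict[int, np.ndarray], pi: np.ndarray) -> float:
        return float(self.counts @ self.pattern_logliks(P, pi))

    def mixture_lnL(
        self,
        class_P: list[dict[int, np.ndarray]],
        weights: np.ndarray,
        pi: np.ndarray,
        return_class_logliks: bool = False,
    ):
        """Log-likelihood of a site-class mixture; classes share pi."""
        per_class = np.vstack(
            [self.pattern_logliks(P, pi) for P in class_P]
        )  # (n_class, n_pat)
        m = per_class.max(axis=0)
        mix = np.log(
            np.maximum(weights @ np.exp(per_class - m), 1e-300)
        ) + m
        lnl = float(self.counts @ mix)
        if return_class_logliks:
            return lnl, per_class
        return lnl

    # -- branch-length helpers ---------------------------------------------

    def lengths_from_tree(self, default: float = 0.1) -> np.ndarray:
        """Initial length-parameter vector from the tree's own lengths."""
        x = np.full(self.n_length_params, default)
        for i in self.branch_nodes:
            t = self.post[i].length
            if t is None:
                continue
            p = self.length_param_of[i]
            if self.length_factor[i] == 0.5:
                # tied pair: parameter is the pair's summed length
                if self.tied_pair and i == self.tied_pair[0]:
                    other = self.post[self.tied_pair[1]].length or 0.0
                    x[p] = np.clip(t + other, T_MIN, T_MAX)
            else:
                x[p] = np.clip(t, T_MIN, T_MAX)
        return x

    def branch_t(self, lengths: np.ndarray) -> dict[int, float]:
        return {
            i: self.length_factor[i] * lengths[self.length_param_of[i]]
            for i in self.branch_nodes
        }

    def lengths_from_fit(self, fit: ModelFit) -> np.ndarray:
        by_id = fit.branch_lengths()
        x = np.zeros(self.n_length_params)
        for i in self.branch_nodes:
            t = by_id[self.branch_ids[i]]
            p = self.length_param_of[i]
            if self.length_factor[i] == 0.5:
                x[p] += t  # tied root pair: halves sum to the parameter
            else:
                x[p] = t
        return np.clip(x, T_MIN, T_MAX)

    def build_P(
        self, cache: KernelCache, kappa: float, omega_of: dict[int, float],
        t_of: dict[int, float]
    ) -> dict[int, np.ndarray]:
        return {
            i: cache.kernel(kappa, omega_of[i]).probability_matrix(t_of[i])
            for i in self.branch_nodes
        }


def log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    pi: np.ndarray,
    branch_omegas: dict[str, float] | float,
    branch_lengths: dict[str, float] | None = None,
) -> float:
    """Plain pruning log-likelihood under fixed parameters.

    ``branch_omegas`` maps branch ids to omega (or one shared value);
    ``branch_lengths`` overrides the tree's own lengths if given.
    """
    engine = LikelihoodEngine(aln, tree)
    cache = KernelCache(pi, aln.genetic_code_id)
    t_of = {}
    for i in engine.branch_nodes:
        bid = engine.branch_ids[i]
        t = (branch_lengths or {}).get(bid, engine.post[i].length)
        if t is None:
            raise ValidationError(f"branch {bid} has no length")
        t_of[i] = t
    if isinstance(branch_omegas, dict):
        omega_of = {
            i: branch_omegas[engine.branch_ids[i]] for i in engine.branch_nodes
        }
    else:
        omega_of = {i: float(branch_omegas) for i in engine.branch_nodes}
    P = engine.build_P(cache, kappa, omega_of, t_of)
    return engine.lnL(P, pi)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _check_informative(aln: CodonAlignment) -> None:
    codes = aln.codes
    for col in codes.T:
        vals = col[col >= 0]
        if vals.size and np.unique(vals).size > 1:
            return
    raise ValidationError(
        "alignment is invariant: no information to estimate branch lengths"
    )


def _resolve_pi(aln, freq_scheme, pi):
    if pi is None:
        pi = estimate_codon_frequencies(aln, freq_scheme)
    return pi


def _dn_ds(t: float, kappa: float, omega: float, pi, code_id: int):
    from .selection_inference import branch_dn_ds

    return branch_dn_ds(t, CodonModelParams(kappa, omega, pi, code_id))


def _minimize(fun, x0, bounds):
    res = minimize(
        fun, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 1000},
    )
    return res


def fit_M0(
    aln: CodonAlignment,
    tree: PhyloTree,
    freq_scheme: str = "F3x4",
    pi: np.ndarray | None = None,
) -> ModelFit:
    """One-ratio model: joint ML of kappa, a single omega and branch lengths.

    The fitted branch lengths are the ones reused (held fixed) by the
    branch and branch-site models downstream.
    """
    if len(aln.taxa) < 3:
        raise ValidationError("need at least 3 taxa")
    _check_informative(aln)
    pi = _resolve_pi(aln, freq_scheme, pi)
    engine = LikelihoodEngine(aln, tree)
    cache = KernelCache(pi, aln.genetic_code_id)

    nb = engine.n_length_params
    x0 = np.concatenate(
        [[np.log(2.0), np.log(0.4)], np.log(engine.lengths_from_tree())]
    )
    bounds = (
        [(np.log(KAPPA_MIN), np.log(KAPPA_MAX)),
         (np.log(OMEGA_MIN), np.log(OMEGA_MAX))]
        + [(np.log(T_MIN), np.log(T_MAX))] * nb
    )

    def negll(x):
        kappa, omega = np.exp(x[0]), np.exp(x[1])
        t_of = engine.branch_t(np.exp(x[2:]))
        omega_of = {i: omega for i in engine.branch_nodes}
        return -engine.lnL(engine.build_P(cache, kappa, omega_of, t_of), pi)

    res = _minimize(negll, x0, bounds)
    kappa, omega = np.exp(res.x[0]), np.exp(res.x[1])
    t_of = engine.branch_t(np.exp(res.x[2:]))
    per_branch = []
    for i in engine.branch_nodes:
        dN, dS = _dn_ds(t_of[i], kappa, omega, pi, aln.genetic_code_id)
        per_branch.append(
            BranchEstimate(engine.branch_ids[i], t_of[i], omega, dN, dS,
                           bool(engine.foreground[i]))
        )
    return ModelFit(
        model_id="M0", lnL=-res.fun, n_free_params=2 + nb, kappa=kappa,
        pi=pi, freq_scheme=freq_scheme, omega=omega, per_branch=per_branch,
        converged=bool(res.success), engine=engine,
    )


def _require_marks(engine: LikelihoodEngine) -> None:
    fg = engine.foreground[engine.branch_nodes]
    if not fg.any():
        raise ValidationError("tree has no foreground marks")
    if fg.all():
        raise ValidationError("tree has no background branches")


def fit_branch_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    fix_foreground_omega: bool,
    m0_fit: ModelFit,
    freq_scheme: str | None = None,
    pi: np.ndarray | None = None,
) -> ModelFit:
    """Two-ratio model MC (or MCfixed with foreground omega pinned at 1).

    Branch lengths are held at the M0 estimates; kappa and the background
    (and, for MC, foreground) omega are optimized.
    """
    pi = pi if pi is not None else m0_fit.pi
    freq_scheme = freq_scheme or m0_fit.freq_scheme
    engine = LikelihoodEngine(aln, tree)
    _require_marks(engine)
    cache = KernelCache(pi, aln.genetic_code_id)
    t_by_id = m0_fit.branch_lengths()
    t_of = {i: t_by_id[engine.branch_ids[i]] for i in engine.branch_nodes}

    def omega_map(w_bg, w_fg):
        return {
            i: (w_fg if engine.foreground[i] else w_bg)
            for i in engine.branch_nodes
        }

    def negll(x):
        kappa = np.exp(x[0])
        w_bg = np.exp(x[1])
        w_fg = 1.0 if fix_foreground_omega else np.exp(x[2])
        P = engine.build_P(cache, kappa, omega_map(w_bg, w_fg), t_of)
        return -engine.lnL(P, pi)

    w0 = m0_fit.omega if m0_fit.omega else 0.4
    k0 = m0_fit.kappa
    obounds = (np.log(OMEGA_MIN), np.log(OMEGA_MAX))
    kbounds = (np.log(KAPPA_MIN), np.log(KAPPA_MAX))
    if fix_foreground_omega:
        starts = [np.log([k0, w0])]
        bounds = [kbounds, obounds]
    else:
        starts = [
            np.log([k0, w0, w0]),
            np.log([k0, w0, 1.0]),
            np.log([k0, w0, 3.0]),
        ]
        bounds = [kbounds, obounds, obounds]

    best = None
    for x0 in starts:
        res = _minimize(negll, x0, bounds)
        if best is None or res.fun < best.fun:
            best = res
    kappa = np.exp(best.x[0])
    w_bg = np.exp(best.x[1])
    w_fg = 1.0 if fix_foreground_omega else np.exp(best.x[2])

    per_branch = []
    for i in engine.branch_nodes:
        w = w_fg if engine.foreground[i] else w_bg
        dN, dS = _dn_ds(t_of[i], kappa, w, pi, aln.genetic_code_id)
        per_branch.append(
            BranchEstimate(engine.branch_ids[i], t_of[i], w, dN, dS,
                           bool(engine.foreground[i]))
        )
    model_id = "MCfixed" if fix_foreground_omega else "MC"
    return ModelFit(
        model_id=model_id, lnL=-best.fun,
        n_free_params=2 if fix_foreground_omega else 3,
        kappa=kappa, pi=pi, freq_scheme=freq_scheme,
        omega_background=w_bg, omega_foreground=w_fg,
        per_branch=per_branch, converged=bool(best.success), engine=engine,
    )


def fit_free_ratio(
    aln: CodonAlignment,
    tree: PhyloTree,
    m0_fit: ModelFit | None = None,
    freq_scheme: str = "F3x4",
    pi: np.ndarray | None = None,
) -> ModelFit:
    """Free-ratio model: an independent omega per branch, kappa shared,
    branch lengths re-optimized jointly (M0 estimates used as start).

    Branches with (numerically) zero synonymous change get omega = NaN and a
    flag; dN and dS are still reported.
    """
    if len(aln.taxa) < 3:
        raise ValidationError("need at least 3 taxa")
    _check_informative(aln)
    if pi is None:
        pi = m0_fit.pi if m0_fit is not None else _resolve_pi(aln, freq_scheme, None)
    if m0_fit is not None:
        freq_scheme = m0_fit.freq_scheme
    engine = LikelihoodEngine(aln, tree)
    cache = KernelCache(pi, aln.genetic_code_id)
    nb = engine.n_length_params

    if m0_fit is not None:
        t0 = engine.lengths_from_fit(m0_fit)
        k0, w0 = m0_fit.kappa, m0_fit.omega or 0.4
    else:
        t0 = engine.lengths_from_tree()
        k0, w0 = 2.0, 0.4

    # one omega parameter per length parameter (tied root pair shares omega)
    x0 = np.concatenate([[np.log(k0)], np.full(nb, np.log(w0)), np.log(t0)])
    bounds = (
        [(np.log(KAPPA_MIN), np.log(KAPPA_MAX))]
        + [(np.log(OMEGA_MIN), np.log(OMEGA_MAX))] * nb
        + [(np.log(T_MIN), np.log(T_MAX))] * nb
    )

    def unpack(x):
        kappa = np.exp(x[0])
        omegas = np.exp(x[1: 1 + nb])
        t_of = engine.branch_t(np.exp(x[1 + nb:]))
        omega_of = {
            i: omegas[engine.length_param_of[i]] for i in engine.branch_nodes
        }
        return kappa, omega_of, t_of

    def negll(x):
        kappa, omega_of, t_of = unpack(x)
        return -engine.lnL(engine.build_P(cache, kappa, omega_of, t_of), pi)

    res = _minimize(negll, x0, bounds)
    kappa, omega_of, t_of = unpack(res.x)

    per_branch = []
    for i in engine.branch_nodes:
        w, t = omega_of[i], t_of[i]
        dN, dS = _dn_ds(t, kappa, w, pi, aln.genetic_code_id)
        flag = ""
        omega_rep = w
        if dS < 1e-8:
            flag = "zero_synonymous_change"
            omega_rep = float("nan")
        per_branch.append(
            BranchEstimate(engine.branch_ids[i], t, omega_rep, dN, dS,
                           bool(engine.foreground[i]), flag)
        )
    return ModelFit(
        model_id="FREE", lnL=-res.fun, n_free_params=1 + 2 * nb,
        kappa=kappa, pi=pi, freq_scheme=freq_scheme, per_branch=per_branch,
        converged=bool(res.success), engine=engine,
    )


# -- branch-site model A ----------------------------------------------------


def _bs_class_P(engine, cache, kappa, mixture, t_of):
    class_P = []
    for w_bg, w_fg in mixture.class_omegas():
        omega_of = {
            i: (w_fg if engine.foreground[i] else w_bg)
            for i in engine.branch_nodes
        }
        class_P.append(engine.build_P(cache, kappa, omega_of, t_of))
    return class_P


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def fit_branch_site(
    aln: CodonAlignment,
    tree: PhyloTree,
    fix_omega2: bool,
    m0_fit: ModelFit,
    n_starts: int = 3,
    seed: int = 0,
    null_fit: ModelFit | None = None,
    pi: np.ndarray | None = None,
) -> ModelFit:
    """Branch-site model A (BS) or its null with omega2 = 1 (BSfixed).

    Site classes: 0 (omega0 everywhere), 1 (neutral everywhere),
    2a (omega0 background, omega2 foreground), 2b (1 background, omega2
    foreground).  Branch lengths held at M0 estimates; kappa, p0, p1,
    omega0 and (for BS) omega2 >= 1 optimized with a deterministic
    multi-start schedule.  Passing the fitted null as ``null_fit`` adds its
    optimum as an extra start of the alternative, which enforces the
    lnL(BSfixed) <= lnL(BS) nesting numerically.
    """
    pi = pi if pi is not None else m0_fit.pi
    engine = LikelihoodEngine(aln, tree)
    _require_marks(engine)
    cache = KernelCache(pi, aln.genetic_code_id)
    t_by_id = m0_fit.branch_lengths()
    t_of = {i: t_by_id[engine.branch_ids[i]] for i in engine.branch_nodes}

    # parameters: log kappa, logit(p0+p1), logit(p0/(p0+p1)), logit(omega0),
    # and for BS additionally log(omega2 - 1)
    def unpack(x):
        kappa = np.exp(x[0])
        psum = _expit(x[1])
        frac = _expit(x[2])
        p0, p1 = psum * frac, psum * (1 - frac)
        omega0 = _expit(x[3])
        omega2 = 1.0 if fix_omega2 else 1.0 + np.exp(x[4])
        return kappa, SiteClassMixture(p0, p1, omega0, omega2)

    def negll(x):
        kappa, mix = unpack(x)
        class_P = _bs_class_P(engine, cache, kappa, mix, t_of)
        return -engine.mixture_lnL(class_P, mix.proportions, pi)

    k0 = np.log(m0_fit.kappa)
    rng = np.random.default_rng(seed)
    starts = []
    base = [
        (0.7, 0.7, 0.3, 2.0),
        (0.9, 0.5, 0.1, 4.0),
        (0.5, 0.8, 0.5, 1.5),
    ]
    for psum, frac, w0, w2 in base[:n_starts]:
        x = [k0, _logit(psum), _logit(frac), _logit(w0)]
        if not fix_omega2:
            x.append(np.log(w2 - 1.0))
        starts.append(np.array(x))
    for _ in range(max(0, n_starts - len(base))):
        x = [
            k0,
            _logit(rng.uniform(0.3, 0.95)),
            _logit(rng.uniform(0.1, 0.9)),
            _logit(rng.uniform(0.05, 0.8)),
        ]
        if not fix_omega2:
            x.append(np.log(rng.uniform(1.2, 8.0) - 1.0))
        starts.append(np.array(x))
    if null_fit is not None and not fix_omega2 and null_fit.mixture is not None:
        # start the alternative at (a faithful image of) the null optimum so
        # the optimizer's monotone descent guarantees lnL(BS) >= lnL(BSfixed)
        nm = null_fit.mixture
        eps = 1e-10
        x = [
            np.log(null_fit.kappa),
            _logit(np.clip(nm.p0 + nm.p1, eps, 1 - eps)),
            _logit(np.clip(nm.p0 / max(nm.p0 + nm.p1, eps), eps, 1 - eps)),
            _logit(np.clip(nm.omega0, eps, 1 - eps)),
            np.log(1e-9),  # omega2 ~ 1
        ]
        starts.append(np.array(x))

    lim = 25.0  # logit bounds keep proportions (and omega0 < 1) off the boundary
    bounds = [
        (np.log(KAPPA_MIN), np.log(KAPPA_MAX)),
        (-lim, lim), (-lim, lim), (-lim, lim),
    ]
    if not fix_omega2:
        bounds.append((np.log(1e-7), np.log(OMEGA_MAX)))

    best = None
    for x0 in starts:
        res = _minimize(negll, x0, bounds)
        if best is None or res.fun < best.fun:
            best = res
    kappa, mix = unpack(best.x)
    lnl_best = -best.fun
    diagnostics = ""

    # omega2 = 1 lies on the closed boundary of the alternative's parameter
    # space but outside the open 1 + e^u parametrization; when the null fit
    # is the better optimum the MLE sits at that boundary
    if (null_fit is not None and not fix_omega2
            and null_fit.lnL > lnl_best):
        kappa = null_fit.kappa
        nm = null_fit.mixture
        mix = SiteClassMixture(nm.p0, nm.p1, nm.omega0, 1.0)
        lnl_best = null_fit.lnL
        diagnostics = "omega2 at boundary 1: alternative reduces to the null"
    if mix.p0 + mix.p1 > 1 - 1e-6:
        diagnostics = (diagnostics + "; " if diagnostics else "") + (
            f"proportion p0+p1 at boundary 1 after {len(starts)} starts; "
            "no mass in the foreground-selected classes"
        )

    # per-site class posteriors (naive empirical Bayes at the MLE)
    class_P = _bs_class_P(engine, cache, kappa, mix, t_of)
    lnl, per_class = engine.mixture_lnL(
        class_P, mix.proportions, pi, return_class_logliks=True
    )
    logw = np.log(np.maximum(mix.proportions, 1e-300))[:, None] + per_class
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    post_pat = w / w.sum(axis=0, keepdims=True)  # (4, n_pat)
    site_post = post_pat[:, engine.site_to_pattern].T  # (n_sites, 4)

    per_branch = [
        BranchEstimate(engine.branch_ids[i], t_of[i], float("nan"), float("nan"),
                       float("nan"), bool(engine.foreground[i]), "site_mixture")
        for i in engine.branch_nodes
    ]
    return ModelFit(
        model_id="BSfixed" if fix_omega2 else "BS",
        lnL=lnl_best,
        n_free_params=4 if fix_omega2 else 5,
        kappa=kappa, pi=pi, freq_scheme=m0_fit.freq_scheme,
        mixture=mix, per_branch=per_branch, site_posteriors=site_post,
        n_restarts=len(starts), converged=bool(best.success),
        diagnostics=diagnostics, engine=engine,
    )


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------


def compare_frequency_schemes(
    aln: CodonAlignment,
    tree: PhyloTree,
    schemes: tuple[str, ...] = ("equal", "F1x4", "F3x4", "F61"),
):
    """Fit M0 under each codon-frequency scheme and rank by AIC.

    Which frequency setting fits best is dataset specific, so the pipeline
    offers all four; AIC counts the fitted parameters plus the empirical
    frequency degrees of freedom (0, 3, 9, 60).
    """
    import pandas as pd

    freq_df = {"equal": 0, "F1x4": 3, "F3x4": 9, "F61": 60}
    rows = []
    for scheme in schemes:
        fit = fit_M0(aln, tree, scheme)
        k = fit.n_free_params + freq_df[scheme]
        rows.append({"scheme": scheme, "lnL": fit.lnL, "k": k,
                     "AIC": 2 * k - 2 * fit.lnL})
    out = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    out["delta_AIC"] = out["AIC"] - out["AIC"].min()
    return out


def write_fit_report(fit: ModelFit, path) -> None:
    """Plain-text fit report: header, parameter block, per-branch table
    (branch id, t, omega, dN, dS) and, for site models, the mixture table.
    Codon sites in reports are 1-based."""
    lines = [
        f"# model {fit.model_id}  lnL {fit.lnL:.6f}  "
        f"free_params {fit.n_free_params}",
        f"# kappa {fit.kappa:.6g}  freq_scheme {fit.freq_scheme}",
    ]
    if fit.omega is not None:
        lines.append(f"# omega {fit.omega:.6g}")
    if fit.omega_foreground is not None:
        lines.append(f"# omega_background {fit.omega_background:.6g}  "
                     f"omega_foreground {fit.omega_foreground:.6g}")
    if fit.mixture is not None:
        m = fit.mixture
        lines.append(
            f"# site classes: p0 {m.p0:.4f} p1 {m.p1:.4f} "
            f"p2a {m.p2a:.4f} p2b {m.p2b:.4f} "
            f"omega0 {m.omega0:.4f} omega2 {m.omega2:.4f}"
        )
    if fit.diagnostics:
        lines.append(f"# diagnostics: {fit.diagnostics}")
    lines.append("branch_id\tforeground\tt\tomega\tdN\tdS\tflag")
    for b in fit.per_branch:
        lines.append(
            f"{b.branch_id}\t{int(b.foreground)}\t{b.t:.8g}\t{b.omega:.8g}"
            f"\t{b.dN:.8g}\t{b.dS:.8g}\t{b.flag}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
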