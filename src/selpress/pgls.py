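"""Phylogenetic generalized least squares with ML/REML estimation of
Pagel's lambda.

Under Brownian motion on the tree, the error covariance between species i
and j is proportional to their shared root-to-MRCA path length C[i,j].
Pagel's lambda scales the off-diagonal entries: lambda=0 gives ordinary
(independent) least squares, lambda=1 the full Brownian structure.  The
fit profiles lambda over [0,1], reports per-coefficient t tests, an R^2
computed in the whitened space, and likelihood-ratio tests of lambda
against the boundaries 0 and 1 (50:50 point-mass/chi2_1 mixture null by
default, plain chi2_1 optionally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, t as t_dist

from .seqio import PhyloTree, ValidationError

__all__ = [
    "PGLSFit",
    "RegressionModel",
    "phylo_covariance",
    "apply_lambda",
    "pgls_fit",
    "run_regression_suite",
    "standard_models",
]


def phylo_covariance(tree: PhyloTree, species_subset=None) -> pd.DataFrame:
    """Brownian-motion covariance: C[i,j] = shared root-to-MRCA path length.

    Returned as a species-labelled DataFrame, restricted to
    ``species_subset`` if given.
    """
    tips = tree.tips()
    labels = [t.label for t in tips]
    if species_subset is not None:
        subset = list(species_subset)
        missing = set(subset) - set(labels)
        if missing:
            raise ValidationError(f"species not in tree: {sorted(missing)}")
    else:
        subset = labels

    # root-to-node depth for every node
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in reversed(tree.postorder()):  # preorder
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)

    # ancestor chains per tip
    chains: dict[str, list[int]] = {}
    for t in tips:
        chain = []
        n = t
        while n is not None:
            chain.append(id(n))
            n = n.parent
        chains[t.label] = chain

    n = len(subset)
    C = np.zeros((n, n))
    for i, a in enumerate(subset):
        seta = set(chains[a])
        for j, b in enumerate(subset):
            if j < i:
                continue
            if a == b:
                C[i, i] = depth[chains[a][0]]
                continue
            mrca = next(x for x in chains[b] if x in seta)
            C[i, j] = C[j, i] = depth[mrca]
    if np.all(C == 0):
        raise ValidationError("tree has zero total length")
    return pd.DataFrame(C, index=subset, columns=subset)


def apply_lambda(C: pd.DataFrame | np.ndarray, lam: float):
    """Multiply off-diagonal covariances by lambda, keep the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must be in [0, 1], got {lam}")
    arr = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C)
    out = lam * arr
    np.fill_diagonal(out, np.diag(arr))
    if isinstance(C, pd.DataFrame):
        return pd.DataFrame(out, index=C.index, columns=C.columns)
    return out


@dataclass
class PGLSFit:
    coef: pd.Series
    se: pd.Series
    t: pd.Series
    p_coef: pd.Series
    r2: float
    lam: float
    loglik: float
    p_lambda_vs_0: float
    p_lambda_vs_1: float
    n: int
    df_resid: int
    method: str
    species: list[str] = field(default_factory=list)


def _gls_core(y, X, Clam):
    """GLS estimates and the pieces of the profile likelihood."""
    cf = cho_factor(Clam, lower=True)
    Ci_X = cho_solve(cf, X)
    Ci_y = cho_solve(cf, y)
    XtCiX = X.T @ Ci_X
    try:
        beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    except np.linalg.LinAlgError:
        raise ValidationError("singular design matrix")
    resid = y - X @ beta
    rss = float(resid @ cho_solve(cf, resid))
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    sign, logdet_XtCiX = np.linalg.slogdet(XtCiX)
    if sign <= 0:
        raise ValidationError("singular design matrix")
    return beta, rss, logdet_C, XtCiX, logdet_XtCiX


def _profile_loglik(y, X, C, lam, method):
    n, p = X.shape
    Clam = apply_lambda(C, lam)
    _, rss, logdet_C, _, logdet_XtCiX = _gls_core(y, X, Clam)
    if method == "ML":
        s2 = rss / n
        return -0.5 * (n * np.log(2 * np.pi * s2) + logdet_C + n)
    s2 = rss / (n - p)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi * s2) + logdet_C + logdet_XtCiX + (n - p)
    )


def pgls_fit(
    y: pd.Series,
    X: pd.DataFrame,
    tree: PhyloTree | None = None,
    C: pd.DataFrame | None = None,
    lambda_mode: str | float = "REML",
    boundary_mixture: bool = True,
    add_intercept: bool = True,
) -> PGLSFit:
    """Fit y ~ X by PGLS with Pagel's lambda profiled over [0, 1].

    ``lambda_mode`` is "REML" (default), "ML", or a fixed value in [0, 1].
    Rows with missing y or X are dropped listwise.  At lambda = 0 the
    estimates equal ordinary least squares exactly.
    """
    df = pd.concat([y.rename("__y"), X], axis=1).dropna()
    species = list(df.index)
    n, p = len(species), X.shape[1] + int(add_intercept)
    if n < p + 2:
        raise ValidationError(
            f"insufficient data: n={n} rows for p={p} parameters"
        )
    if C is None:
        if tree is None:
            raise ValidationError("need a tree or a covariance matrix")
        C = phylo_covariance(tree, species)
    else:
        C = C.loc[species, species]
    Xm = df.drop(columns="__y").to_numpy(dtype=float)
    names = list(X.columns)
    if add_intercept:
        Xm = np.column_stack([np.ones(n), Xm])
        names = ["intercept"] + names
    # collinearity check with named columns
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        corr = np.corrcoef(Xm[:, 1:], rowvar=False) if Xm.shape[1] > 2 else None
        raise ValidationError(
            f"singular design: collinear columns among {names}"
            + (f" (corr=\n{corr})" if corr is not None else "")
        )
    yv = df["__y"].to_numpy(dtype=float)
    Ca = C.to_numpy()

    method = "fixed"
    if isinstance(lambda_mode, str):
        method = lambda_mode.upper()
        if method not in ("ML", "REML"):
            raise ValidationError(f"unknown lambda_mode {lambda_mode!r}")
        res = minimize_scalar(
            lambda lam: -_profile_loglik(yv, Xm, Ca, lam, method),
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        # the bounded optimizer can miss an exact-boundary optimum
        cands = {lam_hat, 0.0, 1.0}
        lam_hat = max(cands,
                      key=lambda l: _profile_loglik(yv, Xm, Ca, l, method))
        crit = method
    else:
        lam_hat = float(lambda_mode)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValidationError(f"lambda must be in [0, 1], got {lam_hat}")
        crit = "ML"

    ll_hat = _profile_loglik(yv, Xm, Ca, lam_hat, crit if crit != "fixed" else "ML")
    Clam = apply_lambda(Ca, lam_hat)
    beta, rss, _, XtCiX, _ = _gls_core(yv, Xm, Clam)
    s2 = rss / (n - Xm.shape[1])
    cov_beta = s2 * np.linalg.inv(XtCiX)
    se = np.sqrt(np.diag(cov_beta))
    tstat = beta / se
    df_resid = n - Xm.shape[1]
    p_coef = 2.0 * t_dist.sf(np.abs(tstat), df_resid)

    # R^2 against the intercept-only GLS model in the same whitened space
    ones = np.ones((n, 1))
    _, tss, _, _, _ = _gls_core(yv, ones, Clam)
    r2 = 1.0 - rss / tss

    def lam_test(fixed):
        ll_fixed = _profile_loglik(yv, Xm, Ca, fixed, crit if crit != "fixed" else "ML")
        two_delta = max(0.0, 2.0 * (ll_hat - ll_fixed))
        if two_delta == 0:
            return 1.0
        pval = float(chi2.sf(two_delta, 1))
        return 0.5 * pval if boundary_mixture else pval

    return PGLSFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        t=pd.Series(tstat, index=names),
        p_coef=pd.Series(p_coef, index=names),
        r2=float(r2),
        lam=lam_hat,
        loglik=float(ll_hat),
        p_lambda_vs_0=lam_test(0.0),
        p_lambda_vs_1=lam_test(1.0),
        n=n,
        df_resid=df_resid,
        method=str(lambda_mode),
        species=species,
    )


# ---------------------------------------------------------------------------
# regression suite
# ---------------------------------------------------------------------------


@dataclass
class RegressionModel:
    name: str
    response: str
    predictors: list[str]
    clade: str | None = None  # restrict to a named clade's species


def standard_models(domains: list[str], clades: list[str]) -> list[RegressionModel]:
    """The standard comparative battery, per clade and per domain:
    omega ~ log body + log testes; arginine% ~ log body + log testes;
    relative HL ~ omega; relative HW ~ omega; elongation ~ omega.
    """
    models = []
    for clade in clades:
        for dom in domains:
            w = f"omega_rtt_{dom}"
            models += [
                RegressionModel(f"{clade}:{dom}_omega~mass", w,
                                ["log_body_mass", "log_testes_mass"], clade),
                RegressionModel(f"{clade}:{dom}_arginine~mass",
                                f"arginine_pct_{dom}",
                                ["log_body_mass", "log_testes_mass"], clade),
                RegressionModel(f"{clade}:relative_hl~{dom}_omega",
                                "relative_hl", [w], clade),
                RegressionModel(f"{clade}:relative_hw~{dom}_omega",
                                "relative_hw", [w], clade),
                RegressionModel(f"{clade}:elongation~{dom}_omega",
                                "elongation", [w], clade),
            ]
    return models


def run_regression_suite(
    data: pd.DataFrame,
    tree: PhyloTree,
    models: list[RegressionModel],
    clade_members: dict[str, list[str]] | None = None,
    lambda_mode: str | float = "REML",
    alpha: float = 0.05,
    boundary_mixture: bool = True,
) -> pd.DataFrame:
    """Run every model; one report row per (model, predictor).

    ``data`` is indexed by species.  Models whose data are insufficient (or
    whose variables are absent) yield a skipped row with the reason; the
    suite never aborts on a single model.  Columns follow the
    (n, slope, t, R2, lambda, p) report order, with the lambda boundary-test
    significance as ns/* superscripts.
    """
    rows = []
    for model in models:
        sub = data
        if model.clade is not None:
            members = (clade_members or {}).get(model.clade)
            if members is None:
                rows.append(_skip_row(model, "unknown clade"))
                continue
            sub = data.loc[data.index.intersection(members)]
        missing_cols = [
            c for c in [model.response] + model.predictors if c not in sub.columns
        ]
        if missing_cols:
            rows.append(_skip_row(model, f"missing columns {missing_cols}"))
            continue
        y = sub[model.response]
        X = sub[model.predictors]
        try:
            fit = pgls_fit(y, X, tree=tree, lambda_mode=lambda_mode,
                           boundary_mixture=boundary_mixture)
        except ValidationError as exc:
            reason = "insufficient data" if "insufficient" in str(exc) else str(exc)
            rows.append(_skip_row(model, reason))
            continue
        sup0 = "*" if fit.p_lambda_vs_0 <= alpha else "ns"
        sup1 = "*" if fit.p_lambda_vs_1 <= alpha else "ns"
        for pred in model.predictors:
            rows.append({
                "model": model.name,
                "clade": model.clade or "",
                "response": model.response,
                "predictor": pred,
                "n": fit.n,
                "slope": fit.coef[pred],
                "t": fit.t[pred],
                "R2": fit.r2,
                "lambda": fit.lam,
                "lambda_sig": f"({sup0},{sup1})",
                "p": fit.p_coef[pred],
                "skipped": "",
            })
    return pd.DataFrame(rows)


def _skip_row(model: RegressionModel, reason: str) -> dict:
    return {
        "model": model.name, "clade": model.clade or "",
        "response": model.response, "predictor": "",
        "n": np.nan, "slope": np.nan, "t": np.nan, "R2": np.nan,
        "lambda": np.nan, "lambda_sig": "", "p": np.nan,
        "skipped": reason,
    }


def plot_regression(data: pd.DataFrame, x: str, y: str, fit: PGLSFit, path):
    """Scatter plot of a (significant) regression with the PGLS line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = data[[x, y]].dropna()
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(sub[x], sub[y], s=18, color="#2b6cb0")
    xs = np.linspace(sub[x].min(), sub[x].max(), 50)
    ax.plot(xs, fit.coef["intercept"] + fit.coef[x] * xs, color="#c05621")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
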