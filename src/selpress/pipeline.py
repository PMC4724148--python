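"""Study orchestration: the per-domain, per-clade model ladder with regime
calls and positively-selected sites (selection stage), and the root-to-tip
omega / sequence-statistics / PGLS battery (comparative stage).

Both stages are driven by a single declarative RunConfig (YAML on disk),
log to stderr, write TSV reports with atomic renames, and record a JSON
run manifest (config hash, seed, versions) so equal manifests imply
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import tempfile

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pgls import run_regression_suite, standard_models
from .phenotypes import derive_traits, read_phenotypes, normalize_species
from .phylo_likelihood import (
    ModelFit,
    fit_M0,
    fit_branch_model,
    fit_branch_site,
    fit_free_ratio,
)
from .selection_inference import (
    classify_regime,
    classify_site_regime,
    detect_pss,
    lrt,
    root_to_tip_omega,
)
from .seq_stats import arginine_percent, welch_t_test
from .seqio import read_codon_alignment, read_tree

log = logging.getLogger("selpress")


def configure_logging(debug: bool = False, logfile=None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if debug else logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclasses.dataclass
class RunConfig:
    alignments: dict[str, str]  # domain name -> FASTA path
    tree: str
    clades: dict[str, list[str]]  # clade name -> tip labels
    phenotypes: str | None = None
    domain_annotation: str | None = None
    alpha: float = 0.05
    freq_scheme: str = "F3x4"
    lambda_mode: str = "REML"
    boundary_mixture: bool = True
    pss_threshold: float = 0.95
    pss_method: str = "beb"
    bs_starts: int = 3
    seed: int = 0
    out_dir: str = "selpress_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        missing = [
            p for p in [cfg.tree, cfg.phenotypes, cfg.domain_annotation,
                        *cfg.alignments.values()]
            if p and not os.path.exists(p)
        ]
        if missing:
            raise FileNotFoundError(f"config references missing paths: {missing}")
        if len(set(cfg.clades)) != len(cfg.clades):
            raise ValueError("clade names must be unique")
        return cfg

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _atomic_write_df(df: pd.DataFrame, path: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def write_manifest(config: RunConfig, path: str) -> None:
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "selpress_version": __version__,
        "numpy_version": np.__version__,
    }
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(os.path.abspath(path)))
    with os.fdopen(fd, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def fmt_p(p: float, alpha: float = 0.05) -> str:
    """Mirror the significance reporting style: 'ns' above alpha, numeric
    (with a <0.01 floor) otherwise."""
    if np.isnan(p):
        return "NA"
    if p > alpha:
        return "ns"
    if p < 0.01:
        return "<0.01"
    return f"{p:.2f}"


# ---------------------------------------------------------------------------
# selection stage
# ---------------------------------------------------------------------------


def selection_ladder(
    aln, tree, clade_tips, *, freq_scheme="F3x4", alpha=0.05,
    pss_threshold=0.95, pss_method="beb", bs_starts=3, seed=0,
    m0_fit: ModelFit | None = None, pss_reference: str | None = None,
) -> dict:
    """Fit M0/MC/MCfixed/BS/BSfixed for one foreground clade and derive the
    LRTs, the regime call and the PSS list.  Returns a flat record dict."""
    marked = tree.mark_clade(clade_tips)
    if m0_fit is None:
        m0_fit = fit_M0(aln, tree, freq_scheme)
    mc_fix = fit_branch_model(aln, marked, True, m0_fit)
    mc = fit_branch_model(aln, marked, False, m0_fit)
    bs_fix = fit_branch_site(aln, marked, True, m0_fit,
                             n_starts=bs_starts, seed=seed)
    bs = fit_branch_site(aln, marked, False, m0_fit,
                         n_starts=bs_starts, seed=seed, null_fit=bs_fix)

    lrt_m0_mc = lrt(m0_fit, mc, df=1)
    lrt_mcfix_mc = lrt(mc_fix, mc, df=1)
    lrt_bs = lrt(bs_fix, bs, df=1)
    call = classify_regime(
        lrt_m0_mc, lrt_mcfix_mc, mc.omega_foreground, m0_fit.omega, alpha
    )
    site_call = classify_site_regime(lrt_bs, alpha)
    pss = []
    if site_call == "positive":
        pss = detect_pss(bs, threshold=pss_threshold, method=pss_method,
                         reference_taxon=pss_reference)
    mix = bs.mixture
    return {
        "m0": m0_fit, "mc": mc, "mc_fixed": mc_fix, "bs": bs, "bs_fixed": bs_fix,
        "record": {
            "two_delta_m0_mc": lrt_m0_mc.two_delta,
            "p_m0_mc": lrt_m0_mc.p,
            "two_delta_mcfix_mc": lrt_mcfix_mc.two_delta,
            "p_mcfix_mc": lrt_mcfix_mc.p,
            "m0_omega": m0_fit.omega,
            "mc_omega_background": mc.omega_background,
            "mc_omega_foreground": mc.omega_foreground,
            "omega_reported": call.omega_foreground,
            "two_delta_bsfix_bs": lrt_bs.two_delta,
            "p_bsfix_bs": lrt_bs.p,
            "p0": mix.p0, "p1": mix.p1, "p2a": mix.p2a, "p2b": mix.p2b,
            "bs_omega0": mix.omega0, "bs_omega2": mix.omega2,
            "pss": ",".join(r.notation for r in pss),
            "n_pss": len(pss),
            "interpretation_branch": call.label,
            "interpretation_sites": site_call,
        },
    }


def run_selection_stage(config: RunConfig) -> pd.DataFrame:
    """Model ladder for every (domain x foreground clade); a fit failure
    marks that row failed and the run continues."""
    tree = read_tree(config.tree)
    rows = []
    for domain, path in config.alignments.items():
        aln = read_codon_alignment(path)
        try:
            m0_fit = fit_M0(aln, tree, config.freq_scheme)
        except Exception as exc:  # noqa: BLE001 - row-level resilience
            log.error("M0 fit failed for %s: %s", domain, exc)
            for clade in config.clades:
                rows.append({"domain": domain, "clade": clade,
                             "failed": f"M0: {exc}"})
            continue
        for clade, tips in config.clades.items():
            log.info("selection ladder: domain=%s foreground=%s", domain, clade)
            try:
                out = selection_ladder(
                    aln, tree, tips,
                    freq_scheme=config.freq_scheme, alpha=config.alpha,
                    pss_threshold=config.pss_threshold,
                    pss_method=config.pss_method,
                    bs_starts=config.bs_starts, seed=config.seed,
                    m0_fit=m0_fit,
                )
            except Exception as exc:  # noqa: BLE001
                log.error("ladder failed for %s/%s: %s", domain, clade, exc)
                rows.append({"domain": domain, "clade": clade,
                             "failed": str(exc)})
                continue
            rec = {"domain": domain, "clade": clade, "failed": ""}
            rec.update(out["record"])
            rec["p_m0_mc_fmt"] = fmt_p(rec["p_m0_mc"], config.alpha)
            rec["p_mcfix_mc_fmt"] = fmt_p(rec["p_mcfix_mc"], config.alpha)
            rec["p_bsfix_bs_fmt"] = fmt_p(rec["p_bsfix_bs"], config.alpha)
            rows.append(rec)
    report = pd.DataFrame(rows)
    _atomic_write_df(report, os.path.join(config.out_dir, "selection_report.tsv"))
    write_manifest(config, os.path.join(config.out_dir, "manifest.json"))
    return report


# ---------------------------------------------------------------------------
# comparative stage
# ---------------------------------------------------------------------------


def species_statistics(config: RunConfig, free_fits: dict[str, ModelFit],
                       tree) -> pd.DataFrame:
    """Per-species table: clade, domain lengths, arginine %, root-to-tip
    omega per domain (clade-rooted paths)."""
    alns = {d: read_codon_alignment(p) for d, p in config.alignments.items()}
    clade_of = {}
    for clade, tips in config.clades.items():
        for t in tips:
            clade_of[t] = clade
    rows = []
    any_aln = next(iter(alns.values()))
    for sp in any_aln.taxa:
        row = {"species": sp, "clade": clade_of.get(sp, "")}
        for domain, aln in alns.items():
            prot = aln.protein(sp)
            row[f"length_{domain}"] = sum(c != "-" for c in prot)
            row[f"arginine_pct_{domain}"] = arginine_percent(prot)
            fit = free_fits[domain]
            clade = clade_of.get(sp)
            clade_tips = config.clades.get(clade) if clade else None
            try:
                w = root_to_tip_omega(fit, fit.engine.tree, sp,
                                      clade_root_tips=clade_tips)
            except Exception as exc:  # noqa: BLE001
                log.warning("omega_rtt failed for %s/%s: %s", sp, domain, exc)
                w = float("nan")
            if np.isnan(w):
                log.info(
                    "undefined root-to-tip omega for %s/%s "
                    "(zero synonymous path change); excluded from regressions",
                    sp, domain,
                )
            row[f"omega_rtt_{domain}"] = w
        rows.append(row)
    return pd.DataFrame(rows)


def clade_comparisons(stats: pd.DataFrame, clades: list[str],
                      domains: list[str]) -> pd.DataFrame:
    """Welch tests between the first two clades on domain lengths and
    arginine content."""
    if len(clades) < 2:
        return pd.DataFrame()
    a, b = clades[:2]
    rows = []
    for domain in domains:
        for var in (f"length_{domain}", f"arginine_pct_{domain}"):
            ga = stats.loc[stats["clade"] == a, var]
            gb = stats.loc[stats["clade"] == b, var]
            try:
                res = welch_t_test(ga, gb)
            except Exception as exc:  # noqa: BLE001
                rows.append({"variable": var, "clade_a": a, "clade_b": b,
                             "failed": str(exc)})
                continue
            rows.append({"variable": var, "clade_a": a, "clade_b": b,
                         "t": res.t, "df": res.df, "p": res.p, "failed": ""})
    return pd.DataFrame(rows)


def run_comparative_stage(
    config: RunConfig, free_fits: dict[str, ModelFit] | None = None
) -> dict[str, pd.DataFrame]:
    """Free-ratio fits per domain, per-species statistics, Welch clade
    comparisons, and the PGLS regression battery."""
    tree = read_tree(config.tree)
    if free_fits is None:
        free_fits = {}
        for domain, path in config.alignments.items():
            log.info("free-ratio fit: domain=%s", domain)
            aln = read_codon_alignment(path)
            m0 = fit_M0(aln, tree, config.freq_scheme)
            free_fits[domain] = fit_free_ratio(aln, tree, m0)

    stats = species_statistics(config, free_fits, tree)
    domains = list(config.alignments)
    welch = clade_comparisons(stats, list(config.clades), domains)

    if config.phenotypes:
        phen = derive_traits(read_phenotypes(config.phenotypes))
        phen["log_body_mass"] = np.log10(phen["body_mass_g"])
        phen["log_testes_mass"] = np.log10(phen["testes_mass_g"])
        stats["species"] = stats["species"].map(normalize_species)
        merged = stats.merge(phen, on="species", how="left",
                             suffixes=("", "_phen"))
        unmatched = merged.loc[merged["body_mass_g"].isna(), "species"]
        if len(unmatched):
            log.warning("species without phenotypes: %s", sorted(unmatched))
        data = merged.set_index("species")
        models = standard_models(domains, list(config.clades))
        regressions = run_regression_suite(
            data, tree, models, clade_members=config.clades,
            lambda_mode=config.lambda_mode, alpha=config.alpha,
            boundary_mixture=config.boundary_mixture,
        )
    else:
        data = stats.set_index("species")
        regressions = pd.DataFrame()

    out = {"species_stats": stats, "welch": welch, "regressions": regressions}
    for name, df in out.items():
        if len(df):
            _atomic_write_df(df, os.path.join(config.out_dir, f"{name}.tsv"))
    write_manifest(config, os.path.join(config.out_dir, "manifest.json"))
    return out
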