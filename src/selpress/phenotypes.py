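"""Phenotype-table ingestion and derived trait construction.

Input is a delimited table with one row per species: body mass (g), testes
mass (g), sperm head length and width (um) and total sperm length (um).
Derived traits:

* relative HL = head length / total sperm length
* relative HW = head width / total sperm length
* elongation  = head length / head width

Relative testes mass — the standard sperm-competition proxy — enters the
regressions as (log testes mass with log body mass as covariate); the
explicit residual from regressing log testes on log body mass is computed
only for plotting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .seqio import ValidationError

__all__ = ["read_phenotypes", "derive_traits", "residual_testes_mass",
           "normalize_species"]

REQUIRED_COLUMNS = ["species"]
MEASURE_COLUMNS = [
    "body_mass_g",
    "testes_mass_g",
    "head_length_um",
    "head_width_um",
    "total_sperm_length_um",
]


def normalize_species(name: str) -> str:
    """Whitespace/underscore-insensitive species key."""
    return "_".join(str(name).strip().split()).replace("__", "_")


def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Read a phenotype table (TSV/CSV inferred) and validate it.

    Missing values stay NaN; nonpositive masses or lengths are rejected.
    An optional ``clade`` column is carried through.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table lacks columns: {missing}")
    df["species"] = df["species"].map(normalize_species)
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"])
        raise ValidationError(f"duplicate species rows: {dupes}")
    for col in MEASURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df[col] <= 0
        if bad.any():
            raise ValidationError(
                f"nonpositive {col} for {sorted(df.loc[bad, 'species'])}"
            )
    return df


def derive_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Add relative_hl, relative_hw and elongation columns.

    Missing inputs propagate to missing outputs, never zeros.
    """
    out = df.copy()
    out["relative_hl"] = out["head_length_um"] / out["total_sperm_length_um"]
    out["relative_hw"] = out["head_width_um"] / out["total_sperm_length_um"]
    out["elongation"] = out["head_length_um"] / out["head_width_um"]
    return out


def residual_testes_mass(df: pd.DataFrame, log_base: float = 10.0) -> pd.Series:
    """OLS residuals of log testes mass on log body mass (for plotting only).

    Logs are base 10 by default (comparative-methods convention).
    """
    sub = df.dropna(subset=["body_mass_g", "testes_mass_g"])
    if len(sub) < 3:
        raise ValidationError(
            f"need >= 3 species with both masses, have {len(sub)}"
        )
    logb = np.log(sub["body_mass_g"].to_numpy()) / np.log(log_base)
    logt = np.log(sub["testes_mass_g"].to_numpy()) / np.log(log_base)
    model = sm.OLS(logt, sm.add_constant(logb)).fit()
    return pd.Series(model.resid, index=sub["species"].to_numpy(),
                     name="residual_testes_mass")
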