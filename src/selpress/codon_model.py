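"""Goldman–Yang-style codon substitution process.

The instantaneous rate between sense codons i and j is

    q_ij = 0                      if i and j differ at more than one position
    q_ij = pi_j                   synonymous transversion
    q_ij = kappa * pi_j           synonymous transition
    q_ij = omega * pi_j           nonsynonymous transversion
    q_ij = omega * kappa * pi_j   nonsynonymous transition

with the matrix scaled so one unit of branch length equals one expected
substitution per codon.  omega = dN/dS summarizes selective pressure at the
protein level: omega < 1 purifying, omega = 1 neutral, omega > 1 positive
selection.

Everything downstream (pruning likelihoods, per-branch dN/dS, simulation)
builds on the structures here.  Gap and ambiguous codons are missing data;
their likelihood sums over all sense codons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable
from scipy.linalg import eigh, expm

NUC = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUC)}
#: transitions are A<->G and C<->T
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}

FREQ_FLOOR = 1e-6


class CodonModelError(ValueError):
    """Invalid codon-model parameters or inputs."""


@lru_cache(maxsize=8)
def genetic_code(code_id: int = 1) -> "GeneticCode":
    """Return the (cached) genetic code tables for an NCBI translation table id."""
    return GeneticCode(code_id)


class GeneticCode:
    """Sense-codon indexing and single-nucleotide-change classification.

    Attributes
    ----------
    codons : list of str
        Sense codons in a fixed lexicographic (TCAG) order; for the standard
        code there are 61.
    single_diff, is_transition, is_synonymous : (n, n) bool arrays
        Pairwise classification of single-nucleotide codon changes.
    """

    def __init__(self, code_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[code_id]
        self.code_id = code_id
        self.stop_codons = set(table.stop_codons)
        all_codons = [a + b + c for a in NUC for b in NUC for c in NUC]
        self.codons = [c for c in all_codons if c not in self.stop_codons]
        self.n = len(self.codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.amino_acids = [table.forward_table[c] for c in self.codons]

        n = self.n
        diff = np.zeros((n, n), dtype=bool)
        ts = np.zeros((n, n), dtype=bool)
        syn = np.zeros((n, n), dtype=bool)
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                pos = [p for p in range(3) if ci[p] != cj[p]]
                if len(pos) != 1:
                    continue
                diff[i, j] = True
                p = pos[0]
                ts[i, j] = frozenset((ci[p], cj[p])) in _TRANSITION_PAIRS
                syn[i, j] = self.amino_acids[i] == self.amino_acids[j]
        self.single_diff = diff
        self.is_transition = ts
        self.is_synonymous = syn

    def translate(self, codon: str) -> str:
        return self.amino_acids[self.index[codon]]


@dataclass
class CodonModelParams:
    """kappa (ts/tv rate ratio), omega (dN/dS) and codon equilibrium frequencies."""

    kappa: float
    omega: float
    pi: np.ndarray
    code_id: int = 1

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        code = genetic_code(self.code_id)
        if self.kappa <= 0:
            raise CodonModelError(f"kappa must be > 0, got {self.kappa}")
        if self.omega < 0:
            raise CodonModelError(f"omega must be >= 0, got {self.omega}")
        if self.pi.shape != (code.n,):
            raise CodonModelError(
                f"pi must have length {code.n}, got {self.pi.shape}"
            )
        if np.any(self.pi < 0):
            raise CodonModelError("pi entries must be nonnegative")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise CodonModelError(f"pi must sum to 1, got {self.pi.sum()!r}")


@dataclass
class RateMatrix:
    """Normalized instantaneous rate matrix over sense codons.

    ``scale`` is the expected substitutions per codon per unit time of the
    unnormalized matrix; after division rows of ``Q`` satisfy
    -sum_i pi_i Q_ii = 1.
    """

    Q: np.ndarray
    scale: float
    params: CodonModelParams = field(repr=False, default=None)


def estimate_codon_frequencies(aln, scheme: str = "F3x4") -> np.ndarray:
    """Estimate codon equilibrium frequencies from an alignment.

    Parameters
    ----------
    aln : CodonAlignment
    scheme : {"equal", "F1x4", "F3x4", "F61"}
        ``equal``: uniform over sense codons.  ``F1x4``: products of overall
        nucleotide frequencies.  ``F3x4``: products of position-specific
        nucleotide frequencies.  ``F61``: observed codon frequencies.
        Stop-codon mass is renormalized over sense codons for F1x4/F3x4.

    Frequencies of zero for codons the scheme cannot support are floored at
    1e-6 (with a warning if an observed codon got zero mass) and
    renormalized so the likelihood stays finite.
    """
    code = genetic_code(aln.genetic_code_id)
    codes = aln.codes  # (n_taxa, n_sites) int, -1 for missing
    observed = codes[codes >= 0]
    if observed.size == 0:
        raise CodonModelError("alignment contains no unambiguous codons")

    if scheme == "equal":
        pi = np.full(code.n, 1.0 / code.n)
    elif scheme == "F61":
        counts = np.bincount(observed, minlength=code.n).astype(float)
        pi = counts / counts.sum()
    elif scheme in ("F1x4", "F3x4"):
        # nucleotide counts per codon position (3, 4)
        pos_counts = np.zeros((3, 4))
        for idx in observed:
            codon = code.codons[idx]
            for p in range(3):
                pos_counts[p, NUC_INDEX[codon[p]]] += 1
        if scheme == "F1x4":
            tot = pos_counts.sum(axis=0)
            pos_freq = np.tile(tot / tot.sum(), (3, 1))
        else:
            pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                pos_freq[0, NUC_INDEX[c[0]]]
                * pos_freq[1, NUC_INDEX[c[1]]]
                * pos_freq[2, NUC_INDEX[c[2]]]
                for c in code.codons
            ]
        )
        pi = pi / pi.sum()  # renormalize stop-codon mass over sense codons
    else:
        raise CodonModelError(f"unknown frequency scheme {scheme!r}")

    observed_set = np.unique(observed)
    if np.any(pi[observed_set] < FREQ_FLOOR):
        warnings.warn(
            f"{scheme} assigns ~zero frequency to observed codons; "
            f"flooring at {FREQ_FLOOR}",
            stacklevel=2,
        )
    pi = np.maximum(pi, FREQ_FLOOR)
    return pi / pi.sum()


def _unnormalized_rates(params: CodonModelParams) -> np.ndarray:
    code = genetic_code(params.code_id)
    factor = np.where(code.is_transition, params.kappa, 1.0) * np.where(
        code.is_synonymous, 1.0, params.omega
    )
    Q = np.where(code.single_diff, factor * params.pi[None, :], 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_rate_matrix(params: CodonModelParams) -> RateMatrix:
    """Build the normalized rate matrix for (kappa, omega, pi)."""
    Q = _unnormalized_rates(params)
    scale = -float(np.dot(params.pi, np.diag(Q)))
    if scale <= 0:
        raise CodonModelError("degenerate process: zero total substitution rate")
    return RateMatrix(Q=Q / scale, scale=scale, params=params)


def site_opportunity(params: CodonModelParams) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts per codon, (N, S) with N+S=3.

    Defined from the mutational-opportunity flux: with omega forced to 1, the
    fraction rhoN of total substitution flux that is nonsynonymous gives
    N = 3*rhoN and S = 3*(1 - rhoN).
    """
    neutral = CodonModelParams(params.kappa, 1.0, params.pi, params.code_id)
    code = genetic_code(params.code_id)
    Q1 = _unnormalized_rates(neutral)
    flux = params.pi[:, None] * Q1
    total = flux[code.single_diff].sum()
    nonsyn = flux[code.single_diff & ~code.is_synonymous].sum()
    if total - nonsyn <= 0:
        raise CodonModelError("degenerate code: no synonymous changes possible")
    rho_n1 = nonsyn / total
    return 3.0 * rho_n1, 3.0 * (1.0 - rho_n1)


def flux_fractions(params: CodonModelParams) -> tuple[float, float]:
    """Fractions (rhoN, rhoS) of substitution flux that are nonsynonymous /
    synonymous under the branch's own omega."""
    code = genetic_code(params.code_id)
    Q = _unnormalized_rates(params)
    flux = params.pi[:, None] * Q
    total = flux[code.single_diff].sum()
    nonsyn = flux[code.single_diff & ~code.is_synonymous].sum()
    return nonsyn / total, 1.0 - nonsyn / total


class TransitionKernel:
    """Cached spectral form of P(t) = exp(Qt) for one (kappa, omega, pi).

    Q for this reversible process symmetrizes as S = D Q D^-1 with
    D = diag(sqrt(pi)); eigh(S) then gives P(t) = A (exp(lam t) * B) with
    A = D^-1 U and B = U^T D, so each branch costs one 61x61 product.
    """

    def __init__(self, rate_matrix: RateMatrix):
        self.pi = rate_matrix.params.pi
        sqrt_pi = np.sqrt(self.pi)
        S = sqrt_pi[:, None] * rate_matrix.Q / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)  # symmetrize numerical noise
        lam, U = eigh(S)
        self.lam = lam
        self.A = U / sqrt_pi[:, None]
        self.B = U.T * sqrt_pi[None, :]
        self._Q = rate_matrix.Q

    def probability_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise CodonModelError(f"branch length must be >= 0, got {t}")
        P = (self.A * np.exp(self.lam * t)) @ self.B
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_matrix(rate_matrix: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries >= 0.

    Uses the spectral decomposition of the symmetrized generator; falls back
    to scipy's scaling-and-squaring expm if the spectral route misbehaves.
    """
    if t < 0:
        raise CodonModelError(f"branch length must be >= 0, got {t}")
    try:
        return TransitionKernel(rate_matrix).probability_matrix(t)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        P = expm(rate_matrix.Q * t)
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)
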