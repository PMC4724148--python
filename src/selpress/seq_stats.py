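"""Domain splitting, arginine content, and Welch two-sample comparisons.

The protamine precursor is proteolytically processed: the N-terminal
(cleaved) domain is removed during chromatin condensation while the
C-terminal (mature) domain stays DNA-bound.  The two domains are analysed
separately throughout; the split point is the per-species 1-based codon
index of the first mature-domain codon, supplied by a DomainAnnotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

from .seqio import DomainAnnotation, ValidationError

__all__ = ["DomainSeqs", "WelchResult", "split_domains", "arginine_percent",
           "welch_t_test"]


@dataclass
class DomainSeqs:
    cleaved: str
    mature: str

    @property
    def cleaved_length(self) -> int:
        return len(self.cleaved)

    @property
    def mature_length(self) -> int:
        return len(self.mature)


def split_domains(precursor: str, boundary: int, unit: int = 1) -> DomainSeqs:
    """Split a precursor at a 1-based boundary index.

    ``unit`` is 1 for residue strings and 3 for nucleotide strings (the
    boundary is always counted in codons/residues).  The cleaved domain is
    positions [1, boundary) and the mature domain [boundary, end]; their
    concatenation is the input.
    """
    length = len(precursor) // unit
    if not 1 < boundary <= length:
        raise ValidationError(
            f"boundary {boundary} outside (1, {length}] for this sequence"
        )
    cut = (boundary - 1) * unit
    return DomainSeqs(cleaved=precursor[:cut], mature=precursor[cut:])


def split_domains_annotated(
    precursor: str, annotation: DomainAnnotation, species: str, unit: int = 1
) -> DomainSeqs:
    return split_domains(precursor, annotation.boundary(species), unit)


def arginine_percent(protein_seq: str, include_gaps: bool = False) -> float:
    """Arginine content as a percentage of sequence length.

    Gaps ('-') are excluded from the denominator by default (content is a
    property of the unaligned sequence).
    """
    seq = protein_seq.upper()
    denom = len(seq) if include_gaps else sum(c != "-" for c in seq)
    if denom == 0:
        raise ValidationError("empty (or all-gap) sequence")
    return 100.0 * seq.count("R") / denom


@dataclass
class WelchResult:
    t: float
    df: float  # Welch–Satterthwaite, fractional
    p: float  # two-sided


def welch_t_test(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with the
    Welch–Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        raise ValidationError("zero variance in both groups")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1)
    )
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(p, 1.0))
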