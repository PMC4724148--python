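"""Shared test helpers: independent oracles and tree utilities."""

import itertools

import numpy as np

from selpress.codon_model import (
    CodonModelParams,
    build_rate_matrix,
    genetic_code,
    transition_matrix,
)


def brute_force_lnl(aln, tree, kappa, omega, pi):
    """Exhaustive enumeration over all internal-node codon assignments.

    Independent oracle for the pruning likelihood: for every site, sum
    pi(root) * prod_branches P(parent -> child) over every joint assignment
    of internal-node states; tips with missing data contribute factor 1
    (their transition probabilities sum out).
    """
    code = genetic_code(aln.genetic_code_id)
    Q = build_rate_matrix(CodonModelParams(kappa, omega, pi))
    nodes = tree.postorder()
    P = {
        id(n): transition_matrix(Q, n.length) for n in nodes if n.parent is not None
    }
    internal = [n for n in nodes if not n.is_tip]
    row = {t: aln.taxa.index(t) for t in aln.taxa}
    total = 0.0
    for s in range(aln.n_sites):
        site_like = 0.0
        for assign in itertools.product(range(code.n), repeat=len(internal)):
            amap = {id(n): a for n, a in zip(internal, assign)}
            pr = pi[amap[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                ps = amap[id(n.parent)]
                if n.is_tip:
                    obs = aln.codes[row[n.label], s]
                    if obs >= 0:
                        pr *= P[id(n)][ps, obs]
                else:
                    pr *= P[id(n)][ps, amap[id(n)]]
            site_like += pr
        total += np.log(site_like)
    return total


def clade_of_size(tree, lo=2, hi=None):
    """A monophyletic tip set of size in [lo, hi] (prefers the largest)."""
    hi = hi or len(tree.tip_labels) - 1
    best = None
    for node in tree.postorder():
        if node.parent is None:
            continue
        tips = tree.clade_tips(node)
        if lo <= len(tips) <= hi and (best is None or len(tips) > len(best)):
            best = sorted(tips)
    return best
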