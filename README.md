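# selpress

Selective-pressure analysis of protein-coding genes: codon-model maximum
likelihood (one-ratio, two-ratio, free-ratio and branch-site models),
likelihood-ratio classification of selection regimes, root-to-tip omega,
sequence-property statistics, and phylogenetically corrected regression —
built for comparative studies of rapidly evolving reproductive proteins
such as the sperm nuclear protein protamine 2 (PRM2).

## The scientific problem

Protamines condense sperm chromatin; their coding sequences sit in a
tug-of-war between functional constraint and post-copulatory sexual
selection (sperm competition).  The PRM2 precursor has two functionally
distinct parts: an N-terminal domain cleaved off during DNA condensation
and a C-terminal mature domain that stays DNA-bound.  Questions a study of
such a gene asks — and this package answers mechanically — include:

* Is a clade (say, primates or rodents) evolving under purifying selection,
  positive selection, or relaxed constraint, for each domain?
* Which codon sites are under positive selection on the foreground
  lineages?
* Does a species' evolutionary rate (root-to-tip dN/dS) covary with
  sperm-competition proxies (testes mass relative to body mass) or with
  sperm head dimensions, once phylogeny is accounted for?

## The models

The codon substitution process is the standard kappa/omega rate matrix
over the 61 sense codons, q_ij proportional to pi_j, multiplied by kappa
for transitions and by omega = dN/dS for nonsynonymous changes, normalized
to one expected substitution per codon per unit branch length.  Likelihoods
are computed by Felsenstein pruning; models are fitted by L-BFGS-B on
transformed parameters:

| model   | structure                                   | tested against |
|---------|---------------------------------------------|----------------|
| M0      | one omega, all branches                     | —              |
| MC      | foreground vs background omega              | M0, MCfixed    |
| MCfixed | foreground omega fixed at 1                 | MC             |
| FREE    | one omega per branch                        | —              |
| BS      | branch-site model A (classes 0/1/2a/2b)     | BSfixed        |
| BSfixed | model A with omega2 = 1                     | BS             |

Two LRTs classify each foreground clade: M0-vs-MC (rate differs from
background) and MCfixed-vs-MC (rate differs from neutrality) combine into
`conserved` / `positive` / `relaxed` labels; BSfixed-vs-BS detects
positive selection on individual sites, reported at Bayes-empirical-Bayes
posterior >= 0.95 in "64R" notation.  Root-to-tip omega sums free-ratio dN
and dS along the path from a clade's root to each tip and takes the ratio.
Trait associations use PGLS with Pagel's lambda profiled by REML over
[0, 1], with LRTs of lambda against 0 and 1.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

Everything below is reproducible — the bundle is generated from a seed:

```bash
selpress simulate --seed 2 --out toy/ --n-per-clade 6
selpress fit --alignment toy/mature.fasta --tree toy/tree.nwk --model M0
```

```
model=M0 lnL=-2751.328929 kappa=1.8017 omega=1.9740
branch_id	t	omega	dN	dS
A3	0.0874131	1.97398	0.0340664	0.0172577
A4	0.150079	1.97398	0.0584883	0.0296296
...
```

The toy study plants known truth: a conserved cleaved domain (omega ~ 0.3),
a mature domain with positive selection (omega = 3) on clade A and neutral
drift (omega = 1) on clade B, and a relative-head-width ~ omega association
with slope 0.14.  The M0 omega above (1.97) averages the mature domain's
mixed regimes into a single ratio.  Running the full ladder:

```python
from selpress.pipeline import RunConfig, run_selection_stage

cfg = RunConfig(
    alignments={"cleaved": "toy/cleaved.fasta", "mature": "toy/mature.fasta"},
    tree="toy/tree.nwk",
    clades={"cladeA": [f"A{i}" for i in range(1, 7)],
            "cladeB": [f"B{i}" for i in range(1, 7)]},
    phenotypes="toy/phenotypes.tsv",
    out_dir="toy/out", seed=2,
)
print(run_selection_stage(cfg)[
    ["domain", "clade", "omega_reported", "interpretation_branch"]
])
```

```
    domain   clade  omega_reported interpretation_branch
0  cleaved  cladeA        0.328961             conserved
1  cleaved  cladeB        0.328961             conserved
2   mature  cladeA        3.220931              positive
3   mature  cladeB        1.157318               relaxed
```

Each row gives the reported omega — the two-ratio foreground
estimate when the M0-vs-MC test is significant, the M0 estimate otherwise
— and the regime label derived from the two LRTs.  The comparative stage
(`run_comparative_stage`) adds per-species root-to-tip omega, arginine
content, Welch clade comparisons and the PGLS battery.

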