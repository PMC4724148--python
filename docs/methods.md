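# Methods

`selpress` implements a selection-constraint analysis for protein-coding
genes of the kind used to study sperm proteins such as protamine 2: codon
substitution models fitted by maximum likelihood on a species tree,
likelihood-ratio tests that classify the selective regime of marked clades,
a per-species root-to-tip omega statistic, sequence-property comparisons
between clades, and phylogenetically corrected regressions of evolutionary
rate against sperm-competition proxies and sperm head dimensions.

## Codon substitution model

The substitution process acts on the 61 sense codons of the standard
genetic code (any NCBI table can be injected).  Instantaneous rates follow
the standard kappa/omega parameterization:

    q_ij = 0                          more than one nucleotide changes
    q_ij = pi_j                       synonymous transversion
    q_ij = kappa * pi_j               synonymous transition
    q_ij = omega * pi_j               nonsynonymous transversion
    q_ij = omega * kappa * pi_j       nonsynonymous transition

Q is normalized so one unit of branch length equals one expected
substitution per codon.  omega = dN/dS measures selective pressure: < 1
purifying, = 1 neutral, > 1 positive selection.

Equilibrium frequencies come from one of four schemes — `equal`, `F1x4`,
`F3x4` (default; products of position-specific nucleotide frequencies with
stop-codon mass renormalized) and `F61` — with a floor of 1e-6 so codons
unobserved under F61 keep the likelihood finite.  All four are provided and
an AIC comparison is a one-liner, because which scheme is best is dataset
specific.

**Numerics.**  P(t) = exp(Qt) is computed from the spectral decomposition of
the pi^1/2-symmetrized generator (the process is reversible and the
frequency floor keeps pi strictly positive, so the symmetrization is always
well defined), with scipy's scaling-and-squaring `expm` as a fallback.  One
eigendecomposition per (kappa, omega) is reused across all branches, which
is what makes the iterative fits cheap.  Tiny negative entries from
round-off are clipped and rows renormalized.

Site opportunities are defined by flux: with omega forced to 1, the
fraction rhoN of substitution flux that is nonsynonymous gives N = 3 rhoN
nonsynonymous sites per codon and S = 3 - N.  A branch of length t under
its own omega then decomposes as dN = t rhoN(omega)/N, dS = t rhoS(omega)/S,
which satisfies dN*N + dS*S = t and dN/dS = omega exactly.

## Likelihood and the model ladder

Likelihoods are computed by Felsenstein pruning over unique site patterns;
gap and ambiguous codons are missing data whose tip partials are 1 for
every state.  Rooted trees are accepted; under reversibility only the sum
of the two branches joining at a two-child root is identified, so those two
lengths share one parameter (reported half/half) while the rooted form is
retained for root-to-tip paths.

The fitted ladder mirrors the branch and branch-site analyses used in
comparative selection studies:

* **M0** (one ratio): joint ML of kappa, a single omega and all branch
  lengths.  Its branch lengths are frozen and reused by all two-ratio and
  branch-site fits, as is conventional.
* **MC** (two ratio): separate foreground/background omega for a marked
  clade; **MCfixed** pins the foreground omega at 1.
* **free ratio**: an independent omega per branch, branch lengths
  re-optimized jointly; branches with numerically zero synonymous change
  report omega = NaN with a flag.
* **BS / BSfixed** (branch-site model A): site classes 0 (omega0 < 1
  everywhere), 1 (neutral), 2a/2b (omega2 on the foreground only), with
  p2a/p2b proportional to p0/p1.  BSfixed fixes omega2 = 1.

Optimization uses L-BFGS-B on transformed parameters (log kappa, log
omega, logit proportions; omega2 = 1 + e^u), bounds omega in [1e-4, 999],
kappa in [0.01, 100], t in [1e-7, 50], and an lnL tolerance of ~1e-8.
Branch-site fits use a deterministic 3-start schedule (these surfaces have
well-known local optima); the alternative additionally starts from the
fitted null's optimum, so its likelihood can never fall below the null's.
Because omega2 = 1 lies on the closed boundary of the alternative but
outside the open 1 + e^u parametrization, a null optimum that beats every
interior start is recognized as the boundary MLE and reported with
omega2 = 1 and a diagnostic.

Foreground marking follows the clade convention: a `#1` tag on a Newick
node marks the node's whole subtree *plus its stem branch*; `mark_clade`
enforces monophyly.  (Note this is deliberately a clade dialect: tools that
mark single branches with `#1` tag each branch individually.)

## Tests of selection and regime classification

Nested models are compared by LRT, 2*(lnL_alt - lnL_null) against
chi-square with df = 1 (each comparison frees exactly one omega); the
50:50 point-mass/chi2_1 mixture null appropriate for boundary hypotheses
is available as `lrt_boundary_mixture`.  The regime label for a foreground
clade combines M0-vs-MC (rate differs from background?) and MCfixed-vs-MC
(rate differs from neutrality?):

| M0 vs MC | MCfixed vs MC | effective omega | label     |
|----------|---------------|-----------------|-----------|
| sig      | sig           | > 1             | positive  |
| sig      | sig           | < 1             | conserved |
| sig      | ns            | any             | relaxed   |
| ns       | sig           | < 1             | conserved |
| ns       | sig           | > 1             | positive  |
| ns       | ns            | any             | relaxed   |

The "effective" omega is the MC foreground estimate when M0-vs-MC is
significant and the M0 estimate otherwise — the same rule used to decide
which omega a report prints.  The both-not-significant cell is labelled
relaxed: a clade indistinguishable from the background *and* from
neutrality carries no evidence of constraint.  (A stricter reading would
require a significant rate difference before calling relaxation; the table
above reproduces how such summaries are conventionally reported.)

Positively selected sites are reported from the alternative branch-site
fit at posterior >= 0.95 of the foreground-positive classes (2a + 2b).
The default posterior is a Bayes-empirical-Bayes grid integration over
(p0, p1, omega0, omega2) — 8 uniform categories per dimension, omega2 on
(1, 11), kappa and branch lengths fixed at the MLE — with naive empirical
Bayes (posteriors at the MLE) as a faster fallback (`method="neb"`).
Sites are labelled "64R"-style: 1-based alignment codon column plus the
reference taxon's residue; both coordinates are alignment columns, with the
reference projection provided because published site lists rarely say which
system they use.

Root-to-tip omega for a species sums dN and dS along the path from its
clade's root (including the stem branch by default, configurable) to the
terminal branch and takes the ratio of sums.  A path with zero synonymous
change yields NaN, which downstream regressions exclude pairwise with a
logged reason — never imputed.

## Sequence statistics and phenotypes

The precursor is split at a per-species 1-based boundary codon into the
N-terminal cleaved domain and the C-terminal mature domain; boundaries must
be supplied (no motif scanning is attempted, since cleavage sites come from
experimental literature).  Arginine content is 100 * (#R)/(non-gap length);
length statistics use residue counts.  Between-clade comparisons use
Welch's unequal-variance t test with Welch–Satterthwaite degrees of
freedom.

Phenotypes (body mass g, testes mass g, sperm head length/width um, total
sperm length um) load from delimited text with explicit missing values.
Derived traits: relative HL = HL/total, relative HW = HW/total, elongation
= HL/HW.  Sperm competition enters regressions as log testes mass with log
body mass as covariate (relative testes mass); the explicit OLS residual
of log testes on log body mass (base-10 logs, configurable) is computed
only for plotting.  Species keys are matched exactly after
whitespace/underscore normalization, and mismatches are listed, not
dropped silently.

## PGLS with Pagel's lambda

Under Brownian motion the error covariance of species i, j is proportional
to their shared root-to-MRCA path length; Pagel's lambda multiplies the
off-diagonal entries.  lambda is profiled over [0, 1] by bounded scalar
minimization of the REML criterion (ML available), with the endpoint
likelihoods checked explicitly so boundary optima are never missed.
Coefficients get t tests on n - p df; R^2 compares the whitened residual
sum of squares against the whitened intercept-only model; lambda is tested
against 0 and 1 by LRT with the 50:50 boundary mixture (plain chi2_1
switchable).  At lambda = 0 on a clock-like tree the fit reproduces OLS to
machine precision, which the tests assert against statsmodels.

The regression battery runs, per clade and per domain: omega ~ log body +
log testes; arginine% ~ log body + log testes; relative HL ~ omega;
relative HW ~ omega; elongation ~ omega.  Models drop incomplete species
listwise (so n varies by row); rows with n < p + 2 are reported as skipped
with the reason rather than aborting the suite.  No multiple-testing
correction is applied by default (a Benjamini–Hochberg switch exists).

## Synthetic data

`simulate_codon_alignment` draws root codons from pi and propagates states
down the tree with the exact transition matrices of the generating regime;
for branch-site regimes each site's class is fixed at the root and omega
switches to omega2 only on foreground branches (standard model-A
semantics).  `simulate_traits` draws y = X beta + eps with eps ~
N(0, sigma^2 C_lambda); C is normalized to unit mean diagonal so sigma is
in trait units.  Trees come from either a Yule topology with exponential
branch lengths (sequence work) or a clock-rescaled pure-birth process
(trait work — comparative analyses presume ultrametry, and lambda = 0 then
reduces exactly to OLS).

`make_toy_study` bundles a two-clade study (default 8 tips per clade):

* cleaved domain (100 codons): per-branch omega lognormal around 0.3
  (sd 0.8 on the log scale, capped at 0.95) — conserved on average but with
  real rate scatter, so root-to-tip omega varies across species;
* mature domain (200 codons): background omega 1, clade A foreground
  omega 3 — the branch ladder should call clade A positive and clade B
  relaxed;
* phenotypes: body and testes mass Brownian with no planted
  sexual-selection signal; relative head width = 0.04 + 0.14 * (true
  cleaved root-to-tip omega) + Brownian noise (sigma 0.008).

All randomness flows from the single seed; identical seeds produce
byte-identical bundles.

**What the toy data do not emulate:** indels and alignment error (domain
lengths are equal across species, so length t-tests on the bundle are
degenerate by construction), codon usage bias (uniform pi), rate variation
within domains beyond the planted structure, and measurement error in
phenotypes.  Passing tests therefore validate the inference machinery, not
robustness to alignment artefacts.

**Estimation noise and the planted association.**  With ~100-codon domains
and per-branch free omegas, root-to-tip omega estimates are noisy enough to
attenuate trait regressions substantially (classical regression dilution);
the recovery tests for the planted relative-HW slope therefore regress on
the generator's true path omega, while the estimated-omega route is
exercised structurally.  A real study of a short sperm-protein gene faces
the same attenuation — one reason published analyses lean on dozens of
species.

## Problem sizes used by the test suite and acceptance script

Chosen so the whole suite runs comfortably on a single CPU: pruning-oracle
sweeps at <= 4 tips x <= 5 codon sites; recovery at 8 taxa x 500 codons
(20 replicates in the tests, 10 in the acceptance script); LRT calibration
at 6 taxa x 200 codons (200 and 100 replicates respectively); branch-site
detection at 8 taxa x 150 codons (20/8 replicates) with 12/4 null
replicates; PGLS calibration at 16 species x 200 replicates; the end-to-end
study at 12 taxa x (80 + 150) codons, with the 16-taxon default reserved
for interactive use.

## Known limitations

* Site-only models (M1a/M2a/M7/M8), clade models C/D, gamma rate variation
  and empirical codon models are out of scope.
* The BEB grid is coarser (8 categories) than codeml's (10) and fixes
  kappa at the MLE; posteriors agree in ranking but can differ in the
  third decimal.
* Free-ratio fits re-optimize branch lengths jointly, so their per-branch
  omegas are not directly comparable to two-ratio fits with frozen M0
  lengths.
* PGLS assumes the supplied tree is ultrametric for the lambda = 0 = OLS
  identity; on non-clock trees lambda = 0 is weighted least squares with
  root-to-tip weights, which is reported as-is.
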