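# Methods

This note documents the statistical models implemented in `phylotherm`,
their assumptions, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Probit estimation of critical thermal limits

A critical limit is the 50% point of a binomial dose-response: at
temperature T the probability of death is Phi(a + bT), so the limit is
L50 = -a/b. The `direction` field records whether deaths rise with
temperature (upper limit, b > 0) or fall (lower limit, b < 0); the two
directions are related by negating the temperature axis, and the estimators
are exactly equivariant under affine transforms of temperature.

*Empirical probit* (the default) maps observed proportions to normal
quantiles — 0% and 100% tables first receive Finney's 1/(2n) correction —
and regresses the probits on temperature by ordinary least squares. This is
the classical hand-computation and is reported alongside the ML fit.

*ML probit* maximizes the binomial likelihood by Fisher-scoring IRLS.
Three numerical guards matter on small assays (3-4 temperatures, 8-10
animals each): the normal density in the working weights is floored at
1e-10 so the weight matrix stays full rank when fitted probabilities
saturate; each IRLS step is halved until the log-likelihood does not
decrease; and iteration stops at 50 rounds or a 1e-10 relative change in
parameters or log-likelihood. Quasi-separated tables (deaths jump from 0
to n across one step) then converge to a steep but finite slope whose L50
is still well determined. Tables that are all-dead or all-alive everywhere
raise an unidentifiability error; a slope below 1e-8 per degree raises a
no-dose-response error. The L50 standard error is the delta method applied
to -a/b with the IRLS information matrix (or the OLS covariance for the
empirical fit); Fieller intervals are a possible extension but are not
implemented.

The design checker reports whether mortality strictly exceeds 50% at some
temperature and falls strictly below it at another — the bracketing rule
the assay design is supposed to satisfy; fits are attempted either way.

## Trees, distances, covariance structures

Newick parsing and pruning are delegated to dendropy; the package adds
validation (unique non-empty tips, branch lengths present and
non-negative, at least one positive) and a deterministic tip order (input
encounter order). Pruning collapses unary nodes by summing branch lengths,
so patristic distances among retained tips are invariant — a property the
tests check against dendropy's own distance matrix as an independent
oracle.

Patristic distances and the Brownian-motion covariance are computed from a
tip-by-edge incidence matrix: an edge lies on the i-j path iff exactly one
of the two tips descends from it (distance = XOR), and contributes to
C_ij iff both descend from it (shared path = AND). The OU correlation uses
the Martins-Hansen tip-distance form exp(-alpha d_ij) with unit diagonal,
chosen because it needs only patristic distances and is the structure
conventionally profiled inside GLS; as alpha grows it tends elementwise to
the identity. Every structure is verified positive definite (smallest
eigenvalue > 1e-10) at construction; a BM structure over tips joined by
zero-length paths fails this check with a named error.

## Moran's I correlogram

Pairs of species are binned into patristic-distance classes (default 3,
matching standard practice for a dozen species). The default
`equal_frequency` scheme partitions the sorted unique pair distances into
contiguous blocks with near-equal cumulative pair counts; tied distances
are never split, and floating-point near-ties (relative gap < 1e-9, e.g.
from Newick round-tripping) are merged into one tie block first. An
`equal_width` scheme (uniform bins over the distance range) is available;
a star tree, where all pairs are equidistant, cannot form more than one
class and says so.

For each class, I = (n/S0) z'Wz / z'z with centred trait z and binary
symmetric weights W. Significance is by trait permutation across species —
999 permutations by default, the same permutation applied to every class
within an iteration — with the two-sided criterion
|I_perm - E[I]| >= |I_obs - E[I]|, E[I] = -1/(n-1), and the add-one
p-value (1 + #extreme)/(n_perm + 1). Permutation was preferred over the
analytic normal approximation because n = 12 is small; the analytic
variance is still reported for reference. The per-class error bars are
jackknife-over-species standard errors, and are labelled as such in the
output: they are a precision measure of I, not the permutation null's
spread.

## PGLS, alpha profiling, F tables

All fits are maximum likelihood (not REML) so that profile-alpha
likelihoods are comparable across fixed-effects designs. For fixed C the
model is whitened by the Cholesky factor:
beta = (X'C^-1X)^-1 X'C^-1 y, sigma2 = RSS_w/n, and
loglik = -[n log(2 pi sigma2) + log|C| + n]/2. Rank-deficient designs
raise an error naming an aliased column (QR with pivoting); a response
lying exactly in the design's column space raises a degeneracy error
rather than reporting an infinite likelihood. Standard errors and t tests
use the unbiased scale RSS_w/(n - p).

The OU selection strength is profiled on a 61-point log-spaced grid
(1e-4 to 1e3) followed by bounded scalar minimization between the best
grid point's neighbours (tolerance 1e-6 on log alpha). Three diagnostic
flags are kept honest: a maximum at a grid edge; a globally flat profile
(range < 1e-8, alpha unidentifiable); and an interior maximum whose
log-likelihood exceeds the upper grid end by less than 1e-6 — the identity
limit in disguise, common when the data carry no phylogenetic structure.
The results object also exposes the log-likelihood gap between alpha-hat
and the identity limit, so callers can judge (e.g. by a 1-df chi-square
criterion) whether the OU correlation earns its parameter. On simulated
independent data the fitted alpha frequently sits at a finite interior
value, but essentially never with a significant advantage over the
identity limit — which is why the flags, not the point estimate, are the
recommended summary of "no signal".

ANCOVA terms enter in the order province, MHT, province x MHT. The
sequential (type I) table takes each term's SS as the drop in whitened RSS
when it is added, against the full-model MSE; the marginal (drop-one)
table removes each term from the model, with interactions involving a main
effect dropped before that main effect is tested. Degrees of freedom come
from rank differences, so aliasing in submodels is handled correctly.

## Simulation-based phylogenetic ANOVA and post hoc tests

`phyl_anova` computes the ordinary between/within F — the phylogeny does
not change the statistic, only its reference distribution. The null is
built by simulating traits under Brownian motion on the tree, with the
rate set to the ML estimate from the residuals of the group-mean model
(the rate only scales the simulations and F is scale-free, so this choice
affects nothing but interpretability of the simulated traits), and
p = (1 + #{F_sim >= F_obs})/(n_sim + 1). On a star tree the BM null is
iid normal and the simulated p converges to the analytic F-test p, which
the tests verify.

Post hoc comparisons use classical t contrasts of group means from a
cell-means model — with a covariate added, the contrasts compare
covariate-adjusted means under parallel slopes — and the same BM
simulation null, per pair, followed by Holm-Bonferroni step-down
adjustment with enforced monotonicity. With two groups the adjustment is
the identity.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes,
under the published study's design: 12 species split 7/3/2 across the
Brazilian/Argentinian/Magellanic provinces; trait optima at the provinces'
adaptive peaks (LL50 13.5/8.5/-0.2 °C, UL50 37.4/37.4/26.0 °C, MHT
27/27/1.5 °C); mortality assays with 4 consecutive temperatures at
±1 and ±3 °C around the true limit, 10 animals per temperature, and a
probit slope of 0.8 per °C — values chosen so that simulated assays
bracket 50% mortality the way the protocol requires, and so simulated
trait tables have within-province spreads of the same order as the
packaged data (default OU with sigma2 = 2, alpha = 2 gives a stationary
SD of ~0.7 °C on a unit-depth tree). Pure-birth trees use exponential
waiting times with a random lineage chosen at each split and are rescaled
to unit depth; balanced and star shapes are deterministic. One master seed
is split into named substreams (tree / trait / mortality) so adding a
stage never perturbs another's draws, and identical seeds give bit-identical
outputs.

Not emulated: tidal emergence and acclimation effects, time-to-death
within the 6-h exposure, sex differences, measurement error in MHT, and —
most importantly — any real molecular tree. Passing tests on synthetic
data therefore demonstrate estimator correctness and calibration under
the model's own assumptions, not robustness to the ways field data violate
them.

## Packaged data and the surrogate tree

The trait table is the published 12-species comparative dataset (province,
substrate, MHT with SEM, LL50, UL50); GenBank 16S accessions for the focal
species are included as metadata only. The study's molecular tree was
never published, so the packaged tree is a SURROGATE: family-level
taxonomy with arbitrary small integer branch lengths. Pipeline reports
computed on it carry an explicit non-comparability banner for every
tree-dependent statistic (Moran's I values, alpha estimates, ANCOVA F
values). Tree-free quantities — province summaries and the classical
ANOVA F of MHT by province — do not depend on this choice at all.

Report display rounds half away from zero at one decimal. One fixture
quirk is worth naming: the Magellanic LL50 species mean is exactly
-0.15 °C (from -0.2 and -0.1), displayed as -0.2 under this convention;
the report calls this out rather than hiding it.

## Problem sizes and tolerances used in verification

Monte-Carlo checks use, as the package's own verification scale: 200
replicates for OU alpha recovery on a 64-tip pure-birth tree (median
alpha-hat within [1.5, 2.7] for true alpha = 2); 500 replicates for probit
L50 recovery at 50 animals per temperature (|bias| < 0.1 °C); 500
replicates each for the type-I error of the permutation correlogram and of
phyl_anova at nominal 0.05, judged against a central 99% binomial
acceptance interval; exact (1e-12) agreement between Moran's I and the
double-sum definition; and machine-precision agreement between
identity-structure GLS and OLS. Oracle cross-checks against statsmodels
(GLS, probit GLM, Holm) and dendropy (patristic distances) live in the
test suite, never in the implementation path.

## Known limitations

Single-optimum OU only (no regime painting); no Pagel-style branch-length
transforms; no measurement-error model for the MHT SEMs; the alpha profile
treats distances in the tree's own units, so alpha values are only
comparable across analyses that share a tree scaling; and with 12 species
the OU alpha is weakly identified — boundary and flatness flags should be
taken seriously rather than read as point estimates.
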