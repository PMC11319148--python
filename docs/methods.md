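# Methods

This note documents the models, algorithms and design choices behind
`germeval`: a pipeline for evaluating imported wheat germplasm from
multi-environment yield trials (METs) and for valuing its downstream
contribution to national production.

## The MET model

A MET observes plot yields across p environments (year-location
combinations) for m genotypes, with partial replication inside each trial.
The model is a linear mixed model on plot yield (t/ha):

    y = X tau + Z_b b + Z_a u_a + Z_i u_i + e

* `tau` — fixed environment means.
* `b` — random block effects, two resolvable blocks per environment, one
  common variance `sigma2_block`.  The minimal block structure matches how
  collaborating programs lay the trials out; the model is deliberately the
  smallest one that respects the randomization (no spatial row/column
  correlation is modelled at the MET stage).
* `u_a` — additive genetic GE effects with `var(u_a) = Ga ⊗ A`, where A is
  the pedigree numerator relationship matrix.  These are breeding values:
  the quantity a program selects parents on.
* `u_i` — non-additive (residual genetic) GE effects, `var(u_i) = Gi ⊗ I`.
* `e` — independent residuals with a separate variance per environment.

Both between-environment covariance matrices follow factor-analytic (FA)
structures `G = Lambda Lambda' + diag(psi)` of low order k.  The FA form is
the parsimonious standard for GE covariance: k common factors capture how
environments co-rank genotypes, `psi` holds what is specific to each
environment.  Order conventions in this package: `k >= 1` fits FA(k);
`k == 0` fits the diagonal (independent-variance) structure; `None` omits
the component.  When `k >= p` the specific variances are pinned at zero,
since an FA(p) loading matrix already spans every covariance — this also
makes the single-environment collapse (p=1, ka=1) well-posed.

### REML estimation

Variance parameters maximize the REML log-likelihood.  The likelihood is
evaluated through the mixed-model equations after whitening the additive
effects by a matrix square root of A, so the coefficient matrix stays
block-structured per environment and assembly is O(p m^2).  The optimizer is
L-BFGS-B over free loadings (upper-triangle-zero identification constraint)
and log variances, with analytic gradients obtained from the inverse of the
augmented coefficient matrix (the standard MME-inverse identities for REML
scores).  Starting values come from a two-stage pass: per-environment
genotype means, their between-environment covariance (noise-corrected on the
diagonal using replicate-pair residual variances), and a principal-component
factorization.

Numerical choices:

* variances are floored at 1e-10 (log-scale bounds); fits touching the floor
  are flagged `boundary`;
* `Ga`/`Gi` inversion adds a 1e-12 jitter, applied identically in the
  likelihood and its gradient so the objective stays self-consistent;
* convergence uses a relative function decrease of 1e-9 (a log-likelihood
  change well below 1e-6 at the problem scales used here); stalled
  line searches restart L-BFGS-B with fresh curvature memory up to 3 times;
* `reml_loglik_direct` re-evaluates the same likelihood by building the
  dense marginal covariance and applying the textbook residual-projection
  form — an independent oracle used by the tests, never by the fit path.

Model search increments the additive order first, then the non-additive
order, starting from the independent genetic-variance model (no pedigree
component, diagonal non-additive covariance).  Nested increments are
accepted when the likelihood-ratio test is significant at 5%; because the
null pins parameters at a boundary, the chi-square p-value is halved.  AIC
(`-2 loglik + 2 x #variance-parameters`) and the overall %vaf are reported
for every candidate.

### Single-trial screening

Before any MET fit, each trial is analysed alone: random genotype, block,
row and column effects over a fixed mean, dense REML at trial scale.
Reliability is `1 - mean(PEV)/sigma2_g`, the prediction-error-variance
generalization of line-mean heritability (they coincide for balanced
designs).  Outliers are plots whose conditional residual exceeds 3 residual
standard deviations.  When the true genotype variance is zero the REML
estimate collapses to the boundary in roughly half of the samples — the rate
at which the unconstrained estimator is negative — and stays small otherwise;
the tests assert that attainable behaviour.

## Selection tools

The FA fit is summarized per genotype after a principal-axis rotation
(SVD of Lambda, scores counter-rotated, each factor's sign set so its mean
loading is non-negative).  All measures are on the trait scale (t/ha):

* overall performance `OP_i = mean-loading_1 x score_i1` — the first factor
  carries the most genetic variance, so OP ranks genotypes by their common
  response across environments;
* total OP adds the non-additive component's OP from its own rotation
  (additive OP ranks parents; total OP ranks release candidates).  The
  combination rule — a straight sum of the two components' first-factor
  effects — is this package's choice of how to express "total genetic
  effect" on one scale;
* stability `RMSD_i = sqrt(mean_j (sum_{k>=2} lambda*_jk f*_ik)^2)` — the
  deviation of a genotype's fit from its factor-1 profile; 0 means fully
  stable;
* responsiveness per factor `k >= 2`: `mean-loading_k x score_ik`, signed.

Top-fraction summaries admit `ceil(fraction x m)` genotypes and include all
ties at the cutoff (a selection list should not drop tied candidates), with
counts reported per germplasm source.

## Pedigrees and the relationship matrix

Purdy cross strings are parsed by splitting at the highest-order operator
(`/` < `//` < `/n/`), rightmost occurrence first among ties — Purdy strings
are written in crossing order, so the last cross is the outermost.
Backcross multipliers bind to the adjacent parent: `A*2/B` reads
A/(A/B), each extra dose one more backcross on that side; `*k` is accepted
on input but never emitted by the generator, keeping generated strings
round-trip exact.  Intermediate crosses materialize as records whose ids are
content hashes of their subtree, so repeated sub-crosses unify.  Unknown or
unparseable parents become unrelated founders.

The numerator relationship matrix uses the tabular method (founders
unrelated with unit diagonal; `a_ij = (a_{j,p} + a_{j,q})/2`;
`a_ii = 1 + a_{pq}/2`); a memoized recursion over the same rules serves as
its entrywise oracle.  Expected ancestry shares (`pct_ancestry`) follow the
same halving recursion from a tagged source set, with a tagged genotype
contributing share 1 outright; a gene-dropping Monte Carlo is the test
oracle.  Whether published "percent program material" figures used expected
shares or discrete generation counting is not documented anywhere we know
of; expected share is the default here.

## p-rep designs

Packet allocation is rule-based: check varieties get two packets everywhere;
every test genotype gets one packet per location while capacity lasts;
second packets go to the key locations first, then round-robin.  Within a
location, genotypes are arranged on a rows x columns grid with two blocks in
the column direction, each duplicated genotype once per block
(near-resolvability implemented as hard resolvability — it is then a
testable invariant; a relaxation would need only the `validate` hook).
A pairwise within-block swap search improves an A-measure: the average
pairwise prediction variance of genotype contrasts under a working model
with fixed genotype means, random block/row/column effects at fixed variance
ratios (default 0.1 : 0.1 : 0.1 over a unit residual) and a generalized
inverse of the information matrix.  The published designs came from
dedicated design software whose exact criterion is not public; this
A-measure is a stand-in ranking criterion, and only its monotone improvement
and the layout invariants are asserted.

## Disease scales

Raw pathology scores on declared numeric schemes (1-9, 0-9, percent) map to
the nine-category ordinal reaction scale R … VS through equal-width
cutpoints (overridable per pathogen — published reports give no cutpoints,
so equal width is the neutral default).  Categorical input passes through
unchanged.  `pct_resistant` reports the share of scored genotypes in
{R, R-MR, MR}; including the intermediate R-MR class is a documented,
configurable choice.  Summaries exclude unscored genotypes from the
denominator.

## Economics

The benefit chain, season by season: classify cultivars by pedigree share of
program ancestry (threshold 1%, boundary inclusive); multiply a program
cultivar's tonnes by its share and by the 1.4% average yield advantage;
value at the grower price deflated to 2020 dollars by the December CPI and
reduced by the price flexibility (-0.025% price per % supply above the
period-mean tonnage — the reciprocal of the -39.93 demand elasticity,
applied only above the mean by default); deduct the 3% end-point royalty.
The observed series is projected with a linear trend to a peak 10 years
after the first benefit season and a linear decline to zero at 2034/35 (the
functional form between the stated anchor points is this package's choice).
Past flows inflate to the base season by CPI; future flows discount at 5%.

Summaries report the total column and a funder-attributed column (45.5%).
The attributed BCR divides attributed benefits by the TOTAL investment;
that convention is adopted deliberately, because an attributed-over-attributed
ratio just reproduces the total BCR and cannot match the published
attributed figure, which the total-denominator convention reproduces
exactly.  NPV is always the exact difference of the summed present values;
dollar outputs round to the nearest dollar and ratios to two decimals.
IRR is the smallest root of the NPV polynomial in (-0.99, 10), found by
bracketed root refinement to 1e-8; MIRR compounds inflows at the 5%
reinvestment rate and discounts outflows at the 3% finance rate.

## The synthetic-data generators

`synth` emulates the study conditions so every stage is testable offline:

* pedigrees of founders plus shallow crosses with round-trip-exact Purdy
  strings, sources cycling through Australian / CIMMYT / ICARDA;
* METs with FA-structured additive effects correlated by the pedigree NRM
  (factor scores drawn as `L_A z`, so `var = Ga ⊗ A` exactly), non-additive
  effects independent between genotypes, two block effects per environment,
  heterogeneous residuals.  Default ranges follow the published evaluation
  summary: environment means 0.6-6.6 t/ha, replication fractions 5-100%,
  residual variances giving reliabilities roughly 0.35-0.90.  First-factor
  loadings are log-uniform over [0.35, 2.8] x 0.35 t/ha so per-environment
  genetic variances span the published ~0.014-0.975 (t/ha)^2 range;
* every genotype appears in every environment (unbalance enters only through
  replication); real METs also drop genotypes between years, so
  between-year connectivity effects are *not* exercised by these data — a
  passing test suite says nothing about estimation under the very low
  connectivity of the real program;
* one 9-point severity draw per genotype-disease with disease-specific
  resistance prevalence;
* an economics ledger whose truth summary (benefit series, present values,
  BCR) is computed by an independent plain-arithmetic loop, so the pipeline
  must reproduce the configured BCR exactly when noise is off.

All generators draw from hierarchical streams (`default_rng([seed, k])`):
adding a generator never perturbs another's draws.

## Problem sizes used in the tests

The test suite and acceptance script run the estimators at desk scale,
chosen so each check is informative for its property: dense-oracle equality
at p=3/m=14; FA(1) recovery at p=6, m=200 over 20 seeds; order selection at
p=6, m=60; the FAST invariance check at p=8, m=80 where the REML optimum is
interior.  Recovery of loading structure at these sizes demonstrates the
estimator's correctness, not the precision attainable on the full
33-environment, 1,321-genotype program dataset.

## Known limitations

* No spatial (e.g. autoregressive row-column) residual modelling; the
  published single-trial pipeline may curate data with it.
* A single block variance across environments (per-environment block
  variances would add p-1 parameters the desk-scale data cannot support).
* The FA likelihood surface can be multimodal; the two-stage start plus
  restarts is a practical, not certified-global, optimum.
* `pct_ancestry` ignores selection and inbreeding when attributing genome
  shares (expected-share recursion).
* The economics model values yield only — disease-resistance cost savings
  and welfare-surplus measures are out of scope by design.
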