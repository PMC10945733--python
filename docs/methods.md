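# Methods

`phylotaste` implements a Bayesian phylogenetic generalised linear mixed
model (PGLMM) analysis linking chemosensory tasting-panel scores of
botanical drugs to their recorded therapeutic uses, together with the
domain metrics, phylogeny preparation, and a synthetic-data generator that
serves as the package's test surface.  This note records the model, its
assumptions, the defaults that matter, and the design choices made where
the design was genuinely open.

## Data model

A *botanical drug* is a specific plant part of a specific taxon.  A
*sensory trial* is one panellist's evaluation of one drug sample: 22
chemosensory qualities (bitter, sweet, astringent, ...) each scored on the
4-point ordinal scale absent (0) / weak (1) / medium (2) / strong (3).
Two trial-level metrics summarise a trial: **intensity**, the sum of the
22 scores (0–66), and **complexity**, the number of non-zero scores
(0–22).  Drug-level therapeutic information is a binary drug × use matrix
(46 uses in the full design) with a total map from uses into ≤ 25 broader
categories; **versatility** is the number of distinct categories a drug is
recommended for.  A *perception report* is one non-zero (trial, quality)
score; by definition the total number of perception reports equals the
summed per-trial complexity, which the validator checks.

Percentage conventions in the descriptive report: per-quality percentages
divide by the number of trials; weak/medium/strong percentages divide by
the number of perception reports.  Percentages ≥ 10 are printed as
integers, smaller ones with one decimal.

## Phylogeny preparation

Trees are rooted, ultrametric (relative tolerance 1e-8), with unique tip
labels.  Taxa missing from a source tree are grafted at the most recent
common ancestor of their genus (family as fallback) with pendant length =
tree height − attachment depth, so ultrametricity is preserved by
construction; a single-congener genus has no MRCA, so the new tip is hung
from the midpoint of the existing tip's pendant edge.  Grafts are
processed sequentially, so an early graft can anchor a later congener.
Small ultrametricity violations in a source tree can be repaired by
extending tips to the maximum depth, but only behind an explicit flag.

The phylogenetic correlation matrix **A** has entries
`A[i,j] = depth(MRCA(i,j)) / height` — shared root-to-MRCA path length on
the unit-height tree — giving a unit diagonal, entries in [0,1],
positive semi-definiteness, and invariance to branch-length rescaling.
Drugs map onto taxa by an incidence mapping, so multiple parts of one
species are phylogenetically identical and differ only through the
plant-part random effect.

## The PGLMM engine

For response `y` over rows (sensory trials by default), with linear
predictor

    eta_i = x_i' beta + z_phylo(i)' u_phylo + z_part(i)' u_part
            + z_pan(i)' u_pan  (+ e_i),

where `u_k ~ N(0, sigma2_k K_k)` (K = A for the phylogenetic term,
identity otherwise) and `e_i ~ N(0, sigma2_e)`:

* **gaussian** — identity link; fully conjugate Gibbs.
* **probit** — binary response via a latent liability `l_i = eta_i + e_i`,
  `y_i = 1 iff l_i > 0`; truncated-normal data augmentation with conjugate
  updates elsewhere.
* **zt_poisson** — counts `y_i >= 1` with
  `pmf(k; lam) = lam^k e^-lam / (k! (1 - e^-lam))`, log link, and an
  observation-level latent log-rate `l_i ~ N(eta_i, sigma2_e)`.  The
  latents are updated by vectorised per-site Metropolis steps; the global
  proposal scale adapts during burn-in towards ~30% acceptance and is
  frozen afterwards so the post-burn-in chain is a valid Markov chain.

Priors follow the published analysis: fixed effects N(0, 1e10) (an option
lowers this — see recovery below), residual variance inverse-gamma with
V = 1, nu = 0.002, and parameter-expanded priors on random-effect
variances: `u_k = xi_k * nu_k` with a working N(0, alpha_V) prior on the
scalar expansion factor, giving an approximately flat (half-Cauchy-like)
prior on the random-effect standard deviation.  The default
alpha_V = 25^2 matches common practice for response scales of order 10;
the assessments use alpha_V = 1 because probit liabilities and log-rates
are O(1) quantities.  The joint (beta, nu) update is a single
Cholesky-based multivariate normal draw; variances are conjugate
inverse-gamma draws; the expansion factors are a joint conjugate normal
draw.  Chains are bit-reproducible given the seed.

Run-length profiles: `paper` (500,000 post-burn-in iterations, thinning
5000 — the published setting, retaining 100 samples), `desk` (20,000 /
thin 20, retaining 1000) and `smoke` (2000 / 10, orchestration checks
only).  Burn-in defaults to 10% of the post-burn-in length.  Note the
published profile retains only 100 samples, so its attainable p_x floor is
0.01; the engine records the floor 1/N next to every p_x for this reason.

### Posterior summaries

* **p_x** — the share of retained samples on the opposite side of zero
  from the posterior mean, zeros counting as crossing; significance is
  declared at p_x < 0.05.  This is a one-sided crossing measure: for a
  true-zero coefficient it flags whenever the central 90% interval
  excludes zero, i.e. at roughly twice the nominal rate.  The doubled
  (two-sided) variant `min(1, 2 * smaller tail)` is reported alongside and
  is the quantity used by the calibration check.
* **modes** — kernel-density modes (Gaussian KDE on a 512-point grid;
  boundary reflection for quantities confined to [0,1]); the posterior
  mode is the reported per-coefficient statistic, matching the modal
  reporting convention, with the mean available.
* **h²** — per retained sample,
  `sigma2_phylo / (sigma2_phylo + sigma2_part + sigma2_pan + sigma2_e)`;
  the modal h² measures phylogenetic signal and reads like Pagel's
  lambda.
* **separation flags** — for binary responses, any fixed effect whose
  non-zero indicator crosses the response with an empty 2×2 cell is
  flagged as quasi-completely separated and its coefficient treated as
  poorly estimated.

### Design layout and its caveat

Rows are sensory trials; drug-level responses (versatility, use
indicators) repeat across a drug's trials.  This is the only layout in
which the panellist effect is estimable, but it is pseudo-replication on
the response side, with two measurable consequences at desk scale
(~5.7 trials per drug, 100 drugs):

* the latent residual variance collapses towards zero (repeated identical
  responses within a drug are best explained by near-identical latents),
  which pushes h² towards 1 and shrinks coefficients of trial-varying
  covariates;
* probit liabilities inflate — the systematic part must be large enough
  that ~6 independent per-row residual draws rarely flip the outcome — so
  liability-scale coefficients are comparable within a fit but not across
  dataset sizes.

Both effects also operate in the published design.  The collapse mechanism
means a model of this layout will report very high phylogenetic
heritability whenever drug-level variance of any origin dominates; the
generator therefore keeps non-phylogenetic drug-level response noise
small (it is unidentifiable against the phylogenetic term), and the
recovery target treats the generating phylogenetic share as the h²
reference.

An alternative drug-level design (one row per drug, drug-mean covariates,
no panellist term) is available in `build_design(level="drug")` and is
what the known-truth assessments fit, because it matches the generating
process exactly.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with full determinism from (scenario, seed):

* a pure-birth (Yule) tree, scaled to height 1, with genus/family labels
  assigned by clade blocks at relative depths 0.75 / 0.35 so grafting is
  exercisable;
* 22 latent quality traits per drug: baseline −0.6 plus phylogenetic
  (σ² = 1.0), plant-part (0.15), panellist (0.02) and trial residual
  (0.05) normal components, thresholded at cut-points 0.8 / 1.8 / 2.8
  into scores 0–3.  Phylogenetic draws are centred across taxa — deep
  shared branches otherwise shift whole traits out of the observable
  range; the model intercept absorbs the root state in any case;
* drug-level use indicators from probit liabilities driven by drug-mean
  observed scores through a sparse true 22 × n_uses effect matrix
  (defaults: 8 effects of ±0.8–1.0), plus phylogenetic (1.0), part (0.1)
  and residual (1.0, the identified-probit scale) liability components;
* a drug-level versatility count from a zero-truncated Poisson with
  log-rate linear in drug-mean scores (defaults: 4 effects of ±0.08–0.12)
  plus phylogenetic (0.9), part (0.05) and residual (0.05) components.

The default scenario is desk-sized: 80 taxa, 100 drugs (extra drugs are
additional parts of random taxa), 5 panellists, ~5.7 trials per drug
(normal, sd 1.3, minimum 1), 6 uses, days-since-collection uniform on
30–400 with no true effect.

What it does *not* emulate: real panel disagreement (within-drug noise is
deliberately small so that trial scores proxy the drug-level profile that
generates the responses — with realistic disagreement the trial-level
coefficient is an attenuated version of the drug-level truth and no exact
recovery target exists); the empirical score distribution (the default
scenario yields ~1.4 perception reports per trial against 2.6 in panel
data of this kind); correlations between qualities beyond those induced
by shared phylogeny; and any resemblance to the historical use
frequencies.  Passing recovery tests therefore demonstrates sampler and
pipeline correctness under the stated structure, not robustness to noisy
panels.

## Known-truth assessments

**Recovery** (`assess_recovery`): generates the default scenario, fits the
drug-level versatility model and a drug-level probit model for every use
carrying true effects, and scores the share of non-zero true effects
inside their central 95% intervals; the trial-level versatility model
supplies the modal h² compared against the generating phylogenetic share.
The probit fits fix the liability residual at its generating value (the
identified scale) and use a weakly informative N(0, 2.5²) coefficient
prior — the standard guard against quasi-complete separation, which is
otherwise near-certain with 22 predictors on 100 binary drug-level
responses and makes flat-prior magnitudes diverge (the sign remains
right; the magnitude does not).  The battery itself always keeps the
published flat prior.

**Calibration** (`assess_calibration`): regenerates datasets whose
responses are pure noise (all true effects zero, no response-level
phylogenetic structure) and counts doubled-p_x < 0.05 flags over the 22
quality coefficients across 10 replicates (~220 null tests).  The doubled
variant is used because it is the calibrated two-tailed quantity; the
one-sided rule flags true nulls at ~10% by construction.  A deliberately
confounded null — response noise phylogenetically structured like the
covariates — raises the empirical rate to ~0.10 at 100 drugs: the random
effect absorbs shared-ancestry confounding only partially at this sample
size.  That inflation is a finite-sample property of the method (and a
reason phylogenetic control matters at all), not of the significance
machinery, and is why the calibration null is generated unconfounded.

## Numerical choices

* Truncated-normal draws use inverse-CDF sampling in the survival scale,
  switching to the asymptotic tail inverse `sqrt(c² − 2 log(1−u))` when
  the standardised bound exceeds 8 (where `ndtri` would underflow); sign
  constraints are asserted in debug mode.
* The zero-truncated Poisson log-pmf uses `log(-expm1(-lam))`, stable to
  `lam -> 0+` (pmf(1) -> 1) and summing to 1 within 1e-12.
* Correlation matrices receive a 1e-10 diagonal jitter before Cholesky;
  a non-positive-definite covariance is a hard error.
* MRCA lookup during grafting walks parent chains directly rather than
  relying on cached bipartition encodings, which go stale under tree
  mutation.
* Constant fixed-effect columns are a hard error by default (a degenerate
  design); `drop_constant` drops and records them, for small or null
  datasets where rare qualities can vanish entirely.
* Battery seeds derive from a master seed via `SeedSequence.spawn` in a
  fixed label order, so results are independent of execution order and
  reruns are identical.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
the default 100-drug scenario, 12,000-iteration assessment chains
(600 retained samples), 10 calibration replicates, and the 14-model
battery (6 uses).  The full 94-model battery at the published 500,000 /
5000 profile is reached by the same code paths via the `paper` MCMC
profile and a 46-use dataset.

## Known limitations

* Real supplementary tables and the land-plant supertree are not bundled;
  on synthetic data the battery's published-prior probit magnitudes are
  separation-inflated (documented above), so the effect map's absolute
  scale is only meaningful within a run.
* The probit residual variance is estimated under its inverse-gamma prior
  by default for fidelity to the modelling convention; this scale is only
  weakly identified (p_x and signs are scale-invariant; magnitudes are
  not).  `fix_residual=1` gives the conventional identified probit.
* h² from trial-level fits saturates near 1 under the residual-collapse
  mechanism whenever drug-level structure dominates; treat it as evidence
  of strong drug-level (largely phylogenetic) signal rather than a
  precise variance decomposition.
* No multiple-testing correction is applied in the headline significance
  rule (by design); a Benjamini–Hochberg mask over the quality × use grid
  is emitted as a clearly labelled extension.
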