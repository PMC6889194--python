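# Methods

This note records the models implemented in `factorsig`, the defaults and
why they were chosen, the numerical decisions that affect results, what the
synthetic-data generators do and do not emulate, and known limitations.

## Feature encoding

Somatic single-base substitutions are encoded pyrimidine-centrically: when
the reference base is a purine, the substitution, both flanking-base pairs
and the transcription strand are reverse-complemented, so every feature has
a C or T reference base. A feature is the tuple (substitution type ∈ 6,
flank −2, −1, +1, +2 ∈ 4 each, strand ∈ 2 optional): 3072 combinations with
strand, 1536 without, and 96 at the trinucleotide resolution used by the
COSMIC SBS catalogs. Flanks are read from a user-supplied reference FASTA;
positions are 1-based inclusive throughout (MAF/VCF convention). Mutations
whose five-base window runs off a chromosome, contains a non-ACGT base, or
whose middle base disagrees with the stated reference allele are excluded
and counted, never imputed. Catalogs are restricted to autosomes 1–22 by
default (configurable), since sex chromosomes have sample-specific copy
number that distorts per-sample mutation loads.

Transcription strand is taken from an input column when present. The strand
factor enters the model only when **every** retained mutation carries a
strand; otherwise the model is fitted strandless. The alternative —
imputing or dropping only the strand-less mutations — would silently bias
the strand factor, so the all-or-nothing rule is deliberate. How strand
should be assigned to intergenic mutations is left to the upstream
annotation; the package does not guess.

## The factorized signature model

Signature k assigns each feature position an independent categorical
distribution θ_{k,j}; the probability of feature f is the product
Π_j θ_{k,j}(f_j). Sample d draws each mutation i.i.d. from the mixture
Σ_k q_{d,k} p_k(f) with exposures q_d on the simplex. Free parameters per
signature: 5 (substitution type) + 4×3 (flanks) + 1 (strand if present) =
17–18, versus 3071 for a saturated categorical over the same space — the
factorization is what makes five-base contexts estimable from hundreds of
mutations per sample.

Fitting is EM on the aggregated sample × unique-feature count table, which
is mathematically identical to per-mutation EM (a tested identity). The
E-step computes responsibilities over components per (sample, feature)
cell; the M-step re-estimates each factor from responsibility-weighted
marginal counts and each exposure row from responsibility totals. Defaults:

| parameter | default | rationale |
|---|---|---|
| `n_restarts` | 10 | symmetric Dirichlet(1) initializations; the best final log-likelihood wins, ties to the lowest restart index (deterministic given seed) |
| `max_iter` | 1000 | ample for the desk-scale problems tested; convergence typically < 200 iterations |
| `tol` | 1e-6 | relative log-likelihood change |
| background | off | an optional fixed component (e.g. genome context frequencies) whose factors are never updated and whose weight is estimated; off unless the caller supplies one |

A floor of 1e-10 is applied inside logarithms during iteration to avoid
−∞ from transiently zero mixture cells; the standalone `log_likelihood`
function applies no floor and returns −∞ when an observed feature has zero
probability, as its contract states. Samples with zero retained mutations
get uniform exposures and are flagged. After every M-step all factor
vectors and exposure rows are renormalized exactly; the suite checks sums
to 1e-9.

## Choosing K

BIC = −2·loglik + P·ln N with N the **total mutation count** — mutations,
not samples, are the observation unit of the multinomial likelihood — and
P = K·(5+12+[strand]) + n_samples·(K+[background]−1). Bootstrap standard
errors resample each sample's mutations with replacement (multinomial over
its observed features at the same total), refit warm-started at the point
estimate, align replicate signatures to the point estimate by greedy
best-cosine matching on expanded full vectors (ties to the lower index),
and take per-parameter standard deviations. Replicates whose refit fails
are dropped with a warning; more than 20% dropped is an error.

`select_k` chooses the BIC minimizer among scanned K whose maximum
bootstrap SE is ≤ 0.05 (default threshold; "low bootstrap error" has no
canonical numeric rule, so the threshold is exposed and documented). If no
K qualifies the overall BIC minimizer is returned with an explicit flag.
Defaults B = 20 replicates for interactive use; the selection study in the
acceptance checks uses B = 10.

## Cross-resolution comparison

Collapsing a five-base signature to 96 channels sums the expanded product
measure over the −2/+2 flanks and strand. Because the factors are
independent, this marginalization equals the product of the three shared
factors (substitution type, 5′ base, 3′ base); both routes are implemented
and their agreement to 1e-12 is a tested identity, which is what justifies
comparing models of different context lengths on their shared features
only. Channel order is canonical (substitution type, then 5′ base, then 3′
base, each alphabetical); COSMIC-format tables are reordered on read.
Matching uses cosine similarity on probability vectors; comparing two
factorized signatures at full resolution intersects their feature
structures, dropping strand when either side lacks it.

## Trunk/branch classification

Samples with tumor purity ≥ 0.70 are retained (inclusive cut); in retained
samples, mutations with VAF ≥ 0.25 are labelled trunk (clonal), the rest
branch (subclonal), both cuts inclusive. VAF is used as given — no
purity-adjustment is applied beyond the purity filter itself, and the
switch is documented because conventions differ. After labelling, any
sample in which either matched group has fewer than 10 mutations is
excluded entirely (both groups), since the paired exposure test needs both
sides. The per-sample trunk+branch partition is exhaustive and exclusive,
and raising the VAF threshold can only shrink trunk counts (tested
monotonicity).

## Hierarchical exposure test

With signatures fixed at their point estimates (two-stage approach), for
sample d and group g ∈ {trunk, branch} each mutation feature is i.i.d. from
the signature mixture with exposure q_{d,g}, and

  q_{d,g} ~ Dirichlet(α_g μ_g),  μ_g ~ Dirichlet(1,…,1),  α_g ~ half-normal(50).

Fixing the signatures keeps the test desk-scale and isolates the exposure
question; a fully joint treatment that also resamples signature factors is
a documented non-goal. The priors are weakly informative: uniform on the
mean simplex, and a concentration prior broad enough to cover both tight
(α ≈ 100) and loose (α ≈ 5) exposure clustering.

The posterior is sampled by Gibbs-within-Metropolis: latent per-mutation
component assignments and the q_{d,g} are conjugate Gibbs updates; μ_g uses
a Dirichlet proposal centered at the current value (+1 smoothing so the
proposal stays proper) with the exact Metropolis–Hastings correction; α_g
uses a log-scale random walk with the Jacobian term. Proposal scales adapt
only during warmup (doubling/halving on 50-iteration acceptance windows),
so the sampling phase is a valid fixed-kernel chain. Three μ and two α
sub-updates per sweep cost little next to the Gibbs steps and improve
mixing (split-chain R-hat ≈ 1.00–1.02 at 300 post-warmup draws in the
tested settings). Defaults: 4 chains × 1000 warmup + 1000 draws; chains are
seeded by spawning a NumPy SeedSequence, so a single-chain run is
bit-reproducible given its seed.

The reported quantity is Δ_k = μ_trunk,k − μ_branch,k: posterior mean and
central 95% credible interval from empirical quantiles, one interval per
signature with no multiplicity adjustment (signature-level reporting). Δ
draws sum to zero across signatures by construction. Convergence is judged
by split-chain R-hat ≤ 1.05 on each Δ_k; failure flags the result and
never suppresses it.

## Synthetic data

The generators provide ground truth for every stage without external
downloads; all are pure functions of their seed.

- **Signature sets.** `well_separated` anchors each signature on a distinct
  (substitution type, 5′ base) pair with 0.85 factor mass — the kind of
  concentrated pattern seen in real colon-cancer signatures, e.g. C>A with
  a 5′ C or C>T with a 5′ G in mismatch-repair-deficient tumors — keeping
  other positions near-uniform (Dirichlet(10)), which yields pairwise
  cosine ≤ 0.3 on expanded vectors. `random` draws all factors from
  Dirichlet(0.5).
- **Catalogs.** Per-sample totals are negative binomial with dispersion 5,
  mean 200 ("low", non-hypermutated) or 5000 ("hypermutated"), or an 80/20
  mixture — emulating the heavy-tailed burden spread between
  microsatellite-stable and MSI-H/Pol-ε tumors. An explicit uniform count
  range is also supported; the recovery and selection studies use 500–2000
  mutations per sample. Exposures are Dirichlet draws or caller-supplied.
- **Paired trunk/branch groups.** Group means are base_mu and
  base_mu + shift with shift summing to zero; the default places +0.096 on
  the first signature, the magnitude of exposure difference the test is
  designed to detect. Per sample-group exposures are Dirichlet around the
  group mean with concentration 50 — enough spread that samples are
  heterogeneous but the group mean is estimable from 40 pairs. Trunk VAFs
  are uniform on [0.25, purity/2] (a heterozygous clonal mutation in a
  diploid region cannot exceed half the purity), branch VAFs uniform on
  [0.02, 0.25). The VAF model is deliberately simple — it exercises the
  classifier's thresholds exactly, and claims no growth-model realism
  (no subclonal size distributions, no read-depth binomial noise).

What passing tests on these generators shows: the estimators recover the
parameters of data that actually follow the factorized model, at realistic
sample sizes. What they do not show: robustness to model misspecification
in real tumors — correlated flanking positions, sequencing artifacts,
caller-specific false negatives (which plausibly deplete subclonal calls
more than clonal ones), or copy-number-distorted VAFs.

## Problem sizes used in the checks

The automated checks run the recovery study at K=3, 60 samples, 500–2000
mutations/sample; the selection study scans K=2–5 with B=10 over 10 seeds
(5 in the acceptance script); the exposure-test calibration uses 40 pairs ×
500 mutations/group with a single chain of 250+250 iterations per run, 100
seeds per arm in the suite and 30 in the script. These sizes were chosen as
the smallest at which the statistical claims are stable across seeds.

## Known limitations

- The EM objective is non-convex; restarts mitigate but cannot guarantee
  the global optimum. Bootstrap SEs inherit the warm-start and can
  understate variability if the point estimate sits in a narrow local mode.
- The strand factor is all-or-nothing per catalog (see above).
- The two-stage exposure test ignores uncertainty in the fitted signatures;
  with few mutations per sample the resulting intervals can be mildly
  anti-conservative.
- The 0.05 bootstrap-SE threshold and the BIC observation-count convention
  (mutations) are defensible defaults, not universal standards; both are
  parameters.
- No liftover between genome builds, no remote data download, no
  NMF-style saturated 96-channel extraction, and no subclonal
  deconvolution beyond the VAF threshold rule.
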