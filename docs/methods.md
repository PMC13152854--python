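# Methods

## Problem setting

Chilling requirement (CR) is the cultivar-specific amount of winter chill a
dormant bud must accumulate before it can resume growth. In a multi-cultivar
dormancy series the dominant transcriptome axes are genotype background and
developmental stage; CR-associated signal is a second-order contrast that
appears as stage-dependent differences between the High-CR and Low-CR
cultivar groups. `budtraj` therefore works throughout on *within-cultivar
standardized trajectories* and on *group contrasts of cultivar-level means*,
never on raw cross-cultivar expression differences.

The reference design is 4 cultivars (2 per CR group) × 3 stages (S1
dormancy induction, S2 maintenance, S3 release) × 3 biological replicates
= 36 libraries; all dimensions are parameters.

## Pipeline model and statistics

**Working scale.** TPM on disk; log2(TPM+1) for every statistic except the
trajectory z-scores, which standardize TPM-scale replicate means (the means
of the measurement-scale values) — the log scale is used for group
contrasts, where differences are fold-change-like. `zscore_trajectories`
accepts either scale; closed-form identities (see below) hold exactly on
the log scale because log2(TPM+1) inverts the generator's 2^x − 1 map.

**Trajectory modules.** Per cultivar block, z = (x̄ − μ)/σ with σ computed
with denominator n−1; genes with zero variance in any cultivar are excluded
rather than zero-filled (zero-filling would fabricate a flat cluster). The
clustering feature vector concatenates all cultivar blocks (12 dimensions
in the reference design) so that modules reward cross-cultivar agreement in
shape; a pooled per-cultivar alternative would weight cultivars by profile
magnitude instead. Lloyd's k-means with k-means++ initialization, 10
restarts, fixed seed; clusters relabelled C1…Ck by decreasing size (the
ordering is otherwise arbitrary).

**Divergence.** d_s = mean over High-CR cultivars of the (cultivar, stage)
log-scale replicate mean, minus the Low-CR analogue — cultivars, not
libraries, are the units, so a single variable genotype cannot dominate.
Module divergence D(C, s) = mean |d_s| over the module's genes; peak stage
ties break toward the earliest stage. Discordance: the signs of
{d_s : |d_s| ≥ ε} are not all equal, ε = 0.05 log2 units (suppresses
replicate-scale sign flips). Concordance: per-cultivar trend sign
sign(x_S3 − x_S1) (0 below ε); the largest same-sign cultivar set must
reach k-of-n (default 3 of 4). Abundance gate: mean TPM ≥ 0.5 AND max
TPM ≥ 1, boundaries inclusive. Candidate = divergent-module member ∧
discordant ∧ concordant ∧ abundant ∧ plausible functional class
({TF, kinase-related, hormone-associated, chromatin/RNA}). Divergence here
is descriptive, not a significance test — with two cultivars per group
there is no useful within-group error model.

**Enrichment.** Hypergeometric upper tail P(X ≥ k) (log-gamma
implementation, stable to N ~ 1e6); BH step-up within each annotation
layer (different layers have incomparable term granularity); terms with
zero overlap are not tested, which shrinks the hypothesis count and hence
changes q-values; significance q < 0.05. The universe is the expressed
gene set.

**Networks.** Stage residualization subtracts per-stage sample means,
removing the dominant developmental signal. Two residual scopes are used:
*stage-only* (retains genotype differences; used for the pooled
correlation/hub network, threshold |r| ≥ 0.8) and *within-cultivar*
(additionally removes genotype baselines; used for per-cultivar networks
and for the WGCNA-style module layer). The module layer runs on
within-cultivar residuals deliberately: genotype baselines in related
germplasm are close to rank-one, and a stage-only residual would make
module detection recover relatedness rather than shared regulatory
covariation. Adjacency |r|^β with β = 6 (unsigned WGCNA default); TOM_ij =
(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); average-linkage
clustering of 1−TOM with a static cut at height 0.8 and minimum module
size 20 (a static cut is deterministic and sufficient for the few-module
structure expected of a pre-selected candidate set); size-ranked WGCNA
colour names, sub-threshold clusters grey. Eigengene = PC1 of the
gene-standardized module submatrix, unit variance, sign-aligned to
correlate positively with the module mean. Trait models: pairwise Pearson
r with the exact t-based two-sided p, plus OLS
ME ~ stage + cultivar + CR_group + ABA + GA3 + GA7; CR group is collinear
with cultivar dummies in the reference design, so the aliased term is
dropped and flagged rather than silently absorbed. Consensus edges require
the same correlation sign at |r| ≥ 0.5 in ≥ 3 of 4 per-cultivar networks
(9 samples each; the higher bar compensates for small n); the edge weight
is the signed minimum |r| among supporters, so raising either threshold
can only remove edges.

**Prioritization.** Components on [0,1]: div = max_s |d_s| / (99th
percentile over eligible genes, capped); hub = degree / max degree in the
candidate consensus network (0 off-network — genes can rank on divergence
alone); bridge = normalized betweenness; support = concordant cultivars /
n; abundance ∈ {0,1}. Score = weighted sum, default weights
0.4/0.2/0.1/0.2/0.1 — divergence is the primary evidence, topology and
reproducibility secondary, abundance a sanity weight. The functional class
gated candidacy upstream and is excluded from the score to avoid double
counting. Eligibility for ranking is membership in a flagged divergent
module plus the expression filter. Ties break lexicographically by gene id
so ranks are unique and reruns byte-identical.

## The synthetic-data generator

`generate_dataset` draws, per gene g in archetype a, the log2(TPM+1) value

    x(g,c,s,r) = m_g + β_g·t_c + j_{g,c} + A_g·arch_a(s)
                 + [c ∈ High, a divergent]·u_g·w_a(s)
                 + λ_g·f̃_b(c,s,r) + N(0, σ_noise)

with TPM = max(2^x − 1, 0). Parameters (defaults in brackets):

* **m_g** gene mean, N(5, 2) log2 units — spans silent to abundant genes so
  the expression filter has work to do.
* **β_g·t_c** rank-one cultivar baseline: gene loadings N(0, 1.5), cultivar
  scores ±0.5/±1.5 dealt as symmetric pairs per CR group. This produces the
  genotype-dominant PC1 (~65–69% of variance) with stage on PC2 (~15–18%),
  while each group's mean score is zero, so the background cancels exactly
  from High−Low contrasts — emulating a design where background is not
  confounded with CR. j_{g,c} ~ N(0, 0.3) adds idiosyncratic per-genotype
  offsets (these do *not* cancel, giving the realistic nonzero divergence
  floor of ~0.2 log2 units in non-divergent modules).
* **arch_a** eight unit archetypes: the circle spanned by the orthonormal
  linear and (negated) quadratic stage contrasts, at 45° spacing — monotone
  rise/fall, S2 peak/trough, and four intermediates; zero mean, unit sd
  (ddof=1) per archetype. Membership weights favour the two monotone shapes
  (0.2 each vs 0.1) so the linear stage contrast out-weighs the quadratic
  one and stage ordering lands on a single PC. Amplitudes A_g ~ U(0.5, 2).
* **Divergence windows** on archetypes 0, 1, 3 with peak stages S3, S2, S1:
  w = +0.8 at the peak, −0.2 elsewhere, scaled per gene by u_g ~
  U(0.35, 0.8) and added to High-CR cultivars only. The opposite-sign tail
  makes planted genes directionally discordant (sign reversal across
  stages), and the per-gene scaling puts module-level peak divergence near
  0.45–0.49 log2 units with off-peak values near the background floor.
* **Co-expression blocks**: genes of archetypes 1 and 3 load
  (λ_g ~ U(0.7, 1.1)) on one latent factor per block, drawn per sample and
  centred within each (cultivar, stage) cell — so the factors create
  replicate-level covariation that survives any residualization but leaves
  stage means (hence trajectories) untouched. The loading range is chosen
  so the block eigengene–ABA correlation sits near 0.5 and clears 0.4
  across seeds.
* **Hormones**: ABA = 40 × (mean log2(TPM+1) of archetype-1 genes) +
  N(0, 5) ng/g — archetype 1 peaks at S2, giving the rise-then-fall ABA
  trajectory, and the block-1 factor couples ABA to the planted module
  beyond the stage means. GA7 follows stage means (2, 3, 9.5) ng/g — a
  marked rise at release; GA3 varies moderately by stage; σ = 0.3 ng/g.
* **Annotations**: one planted term per archetype covering 80% of its
  genes, plus 4 uniformly random background terms; functional classes drawn
  at 8/8/8/6/70% (TF/kinase/hormone/chromatin-RNA/other).

All randomness derives from one integer seed through spawned generator
streams; zero-noise configurations are exact closed forms, assertable cell
by cell.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: count-level sampling noise (no negative
binomial; noise is Normal on the log scale), gene-length and library-size
artefacts, temporal autocorrelation beyond three stages, hub topology
inside co-expression blocks (blocks are exchangeable single-factor
structures), annotation incompleteness, and any relationship between CR and
actual chill accumulation. Recovery results certify that the pipeline's
inference is correct *under its own model assumptions* at realistic
signal-to-noise, not that those assumptions hold in any orchard.

## Numerical and testing choices

* Pearson statistics use denominator n−1 everywhere.
* Test problem sizes: unit tests run at 320–800 genes; recovery tests run
  the full pipeline at 2,000 genes × 36 samples over 20 seeds, which keeps
  the whole suite around half a minute while leaving every recovery margin
  wide (observed ARI ≥ 0.99 against a 0.8 bound, etc.).
* The exact-recovery claims (ARI = 1, centroids equal archetypes to 1e−6)
  are asserted on the fully deterministic configuration — no replicate
  noise, no latent factors, no divergence offsets, expression high enough
  that no TPM clips at zero — using log-scale trajectories, where
  standardization inverts the generator exactly. With planted divergence
  the High-CR blocks are intentionally displaced from the archetype, and on
  the TPM scale the convex 2^x − 1 map distorts z-profiles
  amplitude-dependently, so exactness is not expected there (recovery is
  then asserted statistically).
* Zero-variance genes are dropped with a warning wherever correlations are
  computed; empty networks, single-replicate s.e.m. (reported missing) and
  empty clusters are handled explicitly.
* Unknown configuration keys are rejected; every output TSV carries the
  package version, config hash and seed in its header, and a manifest
  records input checksums, so reruns are byte-identical and input drift is
  detectable.

## Known limitations

With two cultivars per CR group, group contrasts cannot be separated from
idiosyncratic genotype effects — the concordance and consensus filters
mitigate but cannot remove this, which is why outputs are ranked evidence,
not significance calls. The static tree cut cannot resolve nested module
structure (a dynamic cut would); the consensus network's |r| bar at n = 9
samples per cultivar is a blunt instrument against small-sample correlation
noise; and the priority weights, while exposed in configuration and echoed
into output headers, are a pragmatic default with no claim of optimality.
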