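# Methods

## The retention model

The package treats a TF's retention at a motif as a latent quantity r ∈ [0, 1]
that is never observed directly; what is observed is ChIP signal under a
series of increasingly stringent perturbation conditions.  The S-score is a
one-dimensional summary of that series: per-motif signal x_ic (motif i,
condition c, replicates pooled, RPM units) is transformed log2(1 + x),
each condition column centered and scaled to unit variance (ddof = 1), and
PC1 of the standardized matrix extracted by SVD.  Principal-component sign is
arbitrary, so the score is oriented by the convention that the loading on the
highest-stringency condition is positive — larger S-score = more retained.
The fitted `SScoreResults` records the preprocessing descriptor so the
transform choice is auditable.  Whether to log-transform before the PCA was a
genuinely open design point; log2(1 + x) was chosen because ChIP signal is
right-skewed and the transform makes the score insensitive to sequencing
depth; `log_transform=False` is exposed.

Degenerate inputs: a condition column with zero variance after transform has
no standardized direction and raises an error naming the condition (a
constant column carries no retention information and would otherwise poison
the standardization).  At least 3 motifs and 2 conditions are required.

## What the synthetic generator emulates

The generator produces every input the pipeline consumes, with the
statistical couplings the analyses are meant to detect.  Defaults are the
study conditions used throughout the tests; all were chosen on forward
(mechanistic) grounds:

- **Genome and motifs.** Two 400 kb chromosomes of uniform random sequence;
  2000 motifs ≥ 300 bp apart, strands random.  Exact core-motif (14 bp)
  instances are planted at motif coordinates, reverse-complemented on the
  minus strand, so PWM scanning can rediscover the catalog.
- **Latent truth.** Retention r ~ Uniform(0, 1) — a continuum, not clusters,
  so rank recovery is a meaningful test.  Transient-binding rate
  t ~ Exponential(mean 1/λ), λ = 2.  Auxiliary-motif presence
  P(has_U) = sigmoid(4·(r − 0.5)); the D-motif uses half that slope
  (the downstream association is the weaker one).  Planted auxiliary motifs
  sit 5 or 6 bp from the core motif on the motif strand.
- **Occupancy law.** Salt condition with threshold θ_c:
  p = sigmoid(a·(r − θ_c)), a = 10, θ = (0.2, 0.5, 0.8) standing in for
  75/150/225 mM NaCl.  This makes occupancy strictly monotone in salt for
  every motif, which is what produces nested peak sets.  X-ChIP:
  p = clip(r + β·t, 0, 1) with crosslink gain β = 1 — the additive
  transient-binding term is the simplest mechanism by which cumulative
  fixation compresses the retention spectrum.  DMSO uses the lowest-salt
  threshold; TPA (zinc depletion) shifts it by +0.3, so occupancy loss is
  inversely related to retention.  There is no quantitative model of
  crosslink accumulation to calibrate β and λ against; they are simulation
  knobs, not estimates.
- **Fragments.** The per-site footprint fragment count is
  Poisson(frags_per_site · p) with frags_per_site = 80: a sequencing library
  pools ~10^6 cells, so the count at a site is the ensemble average of
  per-cell occupancy, not a single Bernoulli draw (a Bernoulli draw would
  make per-library signal binary and no continuum would be recoverable from
  one library).  Protected fragments have length ~ Normal(35, 3) clipped to
  [25, 60], span a 35 bp footprint with uniform overhang and ±1 bp end
  jitter — emulating the 30–40 bp protected fragments of low-degree MNase
  digestion.  Remaining depth (150 000 fragments/library total) is uniform
  background with Normal(80, 25) lengths.  The model is strand-symmetric;
  orientation enters only via motif strand in downstream analyses.
- **Contact maps.** One matrix per condition on the first chromosome at 2 kb
  bins; expected counts N/(|i−j|+1) with N = 100, Poisson noise, symmetric.
  60 loops (factor 1 + s, s = 3) are planted over a 3×3 pixel neighborhood of
  the anchor pair — a point-loop would be diluted by the 3×3 APA center
  aggregation, so the loop footprint matches the measurement convention.
  24 boundaries divide crossing contacts by (1 + d), d = 2, but only within
  8 bins of the boundary: insulation is a local phenomenon, and letting
  attenuation compound across every boundary a long-range contact spans
  would extinguish distal loops.  Under TPA, loop strength and the depth of
  *motif-anchored* boundaries are scaled by min(1, r_anchor/0.8); control
  boundaries (not coupled to a motif) are perturbation-independent.  At 2 kb
  resolution essentially every bin contains some motif, so the with/without
  contrast is anchoring (whether the boundary's stability is driven by a
  motif), not literal motif presence in the bin.

What the generator does **not** emulate: nucleosome positioning,
sequence-dependent MNase bias, replicate-level overdispersion beyond Poisson,
matrix balancing artifacts, compartments, or trans contacts.  Passing tests
therefore demonstrate that the *analysis logic* is correct under the model's
assumptions — monotone occupancy loss, Poisson counting noise, local
insulation — not that real chromatin obeys them.

## Numerical conventions and tie-breaks

- Coordinates are 0-based, half-open everywhere; fragment midpoint of
  [s, e) is floor((s+e)/2) (even lengths round down).
- V-plot "inside-V" region: length ≥ 2·|offset| (the fragment spans the site
  center) and length ≤ L_v (default 120 bp).  The triangle is defined only
  graphically in the source experiments, so the bounds are configurable and
  the in-figure percentages are not reproduction targets.
- End pileups keep fragments ≤ 120 bp whose nearest motif center is within
  100 bp (ties toward the smaller coordinate); minus-strand motifs swap the
  5′/3′ roles and negate offsets; the 3′ end is the last covered base.
  After RPM normalization both profiles are divided by half the mean of
  their sum over the window, so mean(5′+3′) = 2 exactly after scaling.
- PWM p-values: per-position log2-odds (pseudocount 0.01 mixed in) are
  rounded to a 1e-3 lattice; the null distribution is the exact DP
  convolution over positions under the background model, and the reported
  p-value is the lattice tail probability.  On this lattice the DP equals
  exhaustive enumeration to < 1e-12 for the widths tested (≤ 6 exhaustively;
  the discretization error on the score itself is < w·5e-4 log-odds units).
  Windows containing N are skipped; overlapping same-strand hits within one
  motif width are resolved greedily by best p-value.  The genome-scan
  reporting threshold defaults to 1e-4.
- Peak caller: per-bin Poisson test against max(global mean, 10 kb local
  mean), BH correction, q ≤ 0.01 bins merged within 100 bp; an all-zero
  track yields an empty peak set, not an error.  Motif→peak membership uses
  the motif center point so adjacent peaks cannot double-claim a motif.
  Salt-nesting violations (present at higher salt, absent at lower) are
  counted in a report and classified by the highest salt reached.
- Differential sites: two-sided exact binomial test of condition-B counts
  against the library-size expectation, BH FDR, defaults FDR < 0.05 and
  |log2FC| ≥ 1 with a half-count continuity correction at zeros.  A
  depth-scaled Poisson/binomial test is used instead of a negative-binomial
  shrinkage fit because the synthetic data are Poisson by construction.
- Grouping: the matching signal is quantile-binned (default 20 bins;
  "same signal" has no stated tolerance, so shared quantile bin is the
  operational surrogate).  Within each stratum motifs are sorted by S-score
  descending (ties broken by the stable genomic input order) and dealt into
  k contiguous blocks; the remainder is trimmed symmetrically from both
  tails; strata with < k motifs are dropped with a warning.
- Cumulative-rank curves: descending sort, stable tie-break, x = rank/N,
  y = cumulative positive fraction, padded to (1, 1); AUC by trapezoid.
  For positives occupying the top ranks this gives exactly 1 − n_pos/(2N).
- Insulation score: mean over the diamond (b−w, b] × (b, b+w] (default
  w = 5 bins), log2 against the chromosome-wide mean diamond score.  Under
  this convention LOWER = stronger boundary, so weakening is a positive
  delta, and the one-sided paired t-test in `boundary_delta_test` targets
  Δ > 0.  Edge bins are reported as missing.  A zero-variance delta vector
  surfaces t = NaN explicitly rather than a fabricated p-value.
- APA: per-loop strength is the mean O/E over the center 3×3 pixels (the
  center-pixel-only variant is noisier; 3×3 is the documented choice);
  loops too close to the matrix edge are skipped and counted.  O/E replaces
  matrix balancing for synthetic matrices, whose coverage is uniform by
  construction; a balancing-weights slot is reserved on `ContactMatrix` for
  real data.
- Positional enrichment: domains scaled to 100 interior bins plus 10 pad
  bins each side (pad bins as wide as interior bins); counts are reported
  per 1000 domains; site position is the interval center.

## Problem sizes

The default synthetic experiment (2 × 400 kb genome, 2000 motifs, 150 000
fragments per library, 200-bin contact matrices) was sized so that every
statistical property of interest — rank recovery, nesting, AUC ordering,
APA monotonicity — is measured far from its noise floor while a full
pipeline run stays in the seconds range; the multi-seed analyses in the test
suite and acceptance script use 10–20 independent seeds.

## Known limitations

- The S-score is fit per TF; scores for different TFs (e.g. CTCF vs. MAZ
  series) are separate fits on different condition series and are not
  calibrated against each other.
- The peak caller is a deliberately transparent Poisson model validated by
  its type-I property; it is not a replacement for a model-based caller on
  real data.
- Variant (V-motif) discovery is out of scope; a variant motif can only be
  supplied as a user PWM.
- The exact-p-value DP is exact on its score lattice; for motifs much wider
  than ~20 bp the lattice range grows linearly and a coarser resolution may
  be preferable.
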