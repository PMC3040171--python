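# Methods

`chipmotif` implements the three core stages of a transcription-factor
ChIP-Seq analysis — binding-event detection, de novo motif discovery, and
motif annotation/validation — together with a synthetic-data module that
makes every stage testable against known ground truth. This note documents
the models, the defaults and why they were chosen, the numerical choices,
and what the synthetic data does and does not establish.

## Binding-event model (`peakcall`)

### Model

Within a candidate region, the 5′ coordinates of forward- and reverse-strand
reads are modeled jointly as a K-component mixture of shifted Student-t
densities sharing component weights w_k:

    forward:  x ~ Σ_k w_k · t_ν(μ_k − δ_k/2, σ²_{f,k})
    reverse:  x ~ Σ_k w_k · t_ν(μ_k + δ_k/2, σ²_{r,k})

μ_k is the binding-site position, δ_k the forward/reverse mode separation
(physically ≈ the mean immunoprecipitated-fragment length), and σ_{f,k},
σ_{r,k} the per-strand read spreads. Priors regularize the under-determined
geometry of sparse regions:

- δ_k ~ Normal(ξ, δ_sd²) with ξ = 175 bp, δ_sd = 50 bp. Sonication
  protocols target fragments around ~200 bp and sequencing starts at the
  fragment ends, so the separation of the two 5′-coordinate modes is close
  to the fragment length; the prior centers there and is weak enough to let
  well-populated regions override it.
- σ² ~ InvGamma(a = 2, b = 2·35²), a weak prior centered near read-scale
  spread (mode b/(a+1) ≈ 29² bp²).
- ν = 4 degrees of freedom, fixed: heavy-tailed enough to absorb stray reads,
  with finite variance. Estimating ν from a few hundred reads is unstable
  and buys nothing.

### Estimation

MAP-EM via the normal/gamma scale-mixture representation of the t
distribution (latent precision weights u = (ν+1)/(ν + z²)). The M-step for
(μ_k, δ_k) is an exact 2×2 linear solve of the penalized stationarity
conditions; σ updates are the inverse-gamma MAP. Convergence at relative
penalized log-likelihood change < 1e-6 or 500 iterations. A step-halving
safeguard re-tries any proposal that would decrease the penalized
log-likelihood (this can only occur in truncated fits, where the M-step is
not closed-form), so the trace is non-decreasing on every fit by
construction, and the tests assert it.

### Mappability truncation

Non-mappable stretches delete reads and bias naive location estimates. Each
component density is renormalized over the mappable subset of the region;
the normalizer is computed as Z = 1 − Σ_gaps pdf on a 1-bp grid over the
non-mappable gaps, so an all-mappable profile reduces bit-for-bit to the
uncorrected model. The M-step handles truncation by data augmentation:
per component and strand, the expected number of reads lost to the gaps is
imputed (mass m in the gaps contributes m/(1−m) ghost reads per observed
responsibility unit, with grid-resolved positions and t-precision weights),
which is the standard EM treatment of truncated samples and is what makes
the corrected estimate actually relocate the event rather than merely
re-weight the likelihood. On one-sided read deletion the corrected fit
roughly halves the mean location error relative to the uncorrected fit
(measured by `scripts/acceptance.py`).

### Segmentation, model selection, scoring, FDR

- Segmentation: 300-bp windows stepped by 50 bp; windows with ≥ 5 forward
  and ≥ 5 reverse 5′ positions are kept, merged, and extended by ξ on both
  sides. Permissive on purpose — downstream scoring filters.
- K is chosen by BIC over K = 1..Kmax (default 3) with 5K−1 free parameters;
  initialization is deterministic (quantiles plus 1-D Lloyd refinement of
  "implied centers" x ± ξ/2). Components closer than δ̂/4 are merged
  (weighted average) after selection.
- Enrichment score: n̂_frag = w_k · (reads in region)/2; with a control
  sample the score divides by the library-size-scaled control count within
  μ ± δ̂, floored at ε = 0.5 reads to avoid division by zero; without a
  control the score is n̂_frag itself.
- FDR(s) = #{swapped ≥ s} / max(#{treatment ≥ s}, 1) from a
  treatment/control exchange run, clipped to [0,1] and made monotone
  non-increasing by a cumulative minimum over ascending scores.
- 95% interval for μ from the observed-information (scale-mixture)
  approximation: μ ± 1.96 / sqrt(Σ z·u/σ²).

## Motif model and exact p-values (`pwm`)

PWMs are column-stochastic 4×w matrices (rows A,C,G,T), always strictly
positive via pseudocounts (0.25 per cell when normalizing count matrices —
uniform Laplace smoothing for a 4-letter alphabet). The scan statistic is
the log2 likelihood ratio against an i.i.d. background (uniform by default;
an observed-composition background is available).

The null distribution of the score is computed exactly on a discretized
grid: each matrix entry is rounded to a multiple of g = 1e-3 log2 units and
the word-score distribution is built by column-wise convolution (four
shifted adds per column). Every word's rounded score is within w·g of the
truth, so the tail probability at threshold T is bracketed by the exact
tails at T ± w·g; with g = 1e-3 this band is far below meaningful score
differences. Scanning uses the same rounded matrix, so reported p-values
and thresholding are exactly consistent with the distribution. Windows
containing N are skipped; both strands are scanned by default; the default
scan threshold is p ≤ 2e-4 (exposed in configuration).

Width adjustment is a trim: flanking columns with information content below
0.1 bits are removed from both ends (never below 4 columns), once, after EM
convergence — trimming inside the EM loop would couple the width to
transient parameter states.

## De novo discovery (`discover`)

Per discovery round: a population of spaced dyads (two 3–6-mers separated
by a 0–10-bp spacer, spanning compact monomer cores and spaced dimers) is
sampled with probability ∝ max(z, 0)², where z is the over-representation
z-score of a word (observed count vs background expectation). The squared
positive z-score concentrates the seed pool on genuinely enriched words
while leaving some mass on the background (sampling proportional to the
raw observed/expected ratio is dominated by the sheer number of unenriched
words and almost never seeds from the planted signal).

Each dyad becomes a letter-probability matrix (consensus letters at
probability 0.85, spacer columns uniform) refined by ZOOPS EM: per
sequence, a latent state over {no site} ∪ {offset × strand}, a positional
prior (uniform by default; optionally triangular, peaked at the sequence
center — useful when occurrences concentrate at peak centers, at the cost
of off-center secondary motifs), an optional per-sequence weight from
region enrichment, and a Dirichlet-pseudocount M-step. The penalized
observed-data log-likelihood is non-decreasing and is recorded.

The GA uses tournament selection (size 2), single-point crossover
exchanging (spacer, word2), point mutation (one letter, or spacer ± 1) with
probability 0.1, and elitism of 1, for n_gen generations over a population
of n_pop (defaults 5 and 100; the acceptance runs use 50×3, which is
already sufficient on the synthetic task). Fitness evaluation caches by
dyad and is order-independent, so a generation can be scored concurrently
with results identical to serial execution.

### Fitness and calibration

The fitness is a log E-value; lower is fitter, and motifs are reported
while logE ≤ 0 (fewer than one as good expected by chance). Two design
choices matter for calibration:

1. **Train/held-out split.** EM maximizes likelihood on the data it is
   given; scanning the same data overstates enrichment — on pure background
   a refined PWM can double its apparent site count. Discovery therefore
   refines on a random half of the sequences and evaluates fitness on the
   held-out half. Reported occurrences come from scanning all sequences.
2. **Selection-aware statistic.** Occurrences are by definition windows in
   the extreme score tail, so a statistic that compares their mean score to
   the *unconditional* background distribution is significant even under
   the null. The implemented statistic is

       logE = ln W + ln P(Binom(W, p*) ≥ n)
                   + ln P( mean site score ≥ observed | n sites, each ≥ T )

   where W is the number of scanned windows, p* the attained scan p-value,
   and the conditional term uses the threshold-truncated exact score
   distribution with a CLT tail (the exact n-fold convolution tail
   underflows double precision for realistic n; only the ordering matters
   to the GA). The ln W term plays the multiplicity role for the win-dow
   family being scanned. Together with the held-out evaluation this keeps
   the false-motif rate at roughly the cutoff's nominal level (~0.05 per
   run measured over background-only replicates) while planted motifs
   score logE in the hundreds of negative units.

Fold enrichment is reported as n / (W · p_threshold).

After each round the best motif's occurrences are masked with N (scan
skips N windows, so masking is sound by construction) and the search
repeats until no motif passes the cutoff or the motif budget is reached.
A motif whose best alignment to a previously reported motif (either
orientation) has mean column PCC ≥ 0.9 over ≥ 3/4 of the shorter width is
treated as a rediscovery and not reported again; the overlap requirement
stops two motifs that merely share a 4-mer from being collapsed. A motif
aligning to its own reverse complement above the same threshold is flagged
palindromic and reported once.

Seeded mode skips seeding and the GA entirely: the user PWM initializes a
single EM refinement (it is never used after initialization), then the
standard trim/fitness/scan. It is an order of magnitude faster than a de
novo run and is the tool of choice for re-finding a known motif.

## Annotation and distance statistics (`annotate`)

PWM similarity is the best ungapped alignment over all offsets with ≥ 4
aligned columns and both target orientations; the score is the mean
per-column similarity (Pearson correlation of probability columns by
default; ALLR available). Ties break toward smaller |offset|, then the +
orientation.

E-values are calibrated per width bucket (min of the two widths) from
simulated null profiles: alignment scores of column-shuffled database PWM
pairs (shuffling preserves the column IC composition). Scores are Fisher
z-transformed before a maximum-likelihood Gumbel fit — the raw mean-PCC
score is bounded at 1, which no unbounded extreme-value law can represent,
and the transform gives perfect matches E-values many orders of magnitude
below the 1e-4 reporting cutoff while leaving the score ordering intact.
E(score) = N_db · P_null(S ≥ score). Default 300 null samples per bucket
(Gumbel location/scale stabilize well below that); buckets that cannot be
filled are served by the nearest fitted bucket and flagged.

Filtering keeps motifs with at least one match passing an optional
case-insensitive name-substring filter and an optional E-value cutoff.
Combining is virtual: selected motifs share a label and pool their
occurrence lists; member PWMs are never modified (asserted bitwise in the
tests).

Distance statistics use occurrence midpoints (removing width asymmetry):

- distance-to-peak: signed distance to the nearest event center on the
  same chromosome (or a per-sequence center), histogrammed at 10-bp bins
  over ± 200 bp by default (matching 400-bp windows). Occurrences with no
  resolvable center and distances beyond the range are tallied separately
  so that binned + unmatched + out-of-range equals the input count.
- pairwise distances: all signed midpoint differences (B − A) within
  max_gap on sequences carrying both motifs; the co-occurrence fraction is
  #sequences with both / #sequences with the *rarer* motif, making the
  number read as "how often the rare motif travels with the common one".
  Self-pairs exclude zero-distance self-comparisons.

## Synthetic data (`simulate`)

`sim_reads` emulates the fragment-level geometry of a ChIP experiment:
per event, fragments of length ~ Normal(175, 35) truncated above the read
length (35 bp) are centered on the site; each emits one read — the + read's
5′ end at the fragment's left end or the − read's 5′ end at its rightmost
base, with equal probability — so the true mode separation is
δ* = frag_mean − 1. Uniform background noise goes into both treatment and
control; the control carries noise only; reads whose 5′ position falls in
a declared non-mappable gap are deleted from both samples. Defaults
(175/35 fragments, 35-bp reads, 100 fragments per event) reflect a typical
early-generation transcription-factor ChIP-Seq library.

`sim_sequences` plants PWM-sampled sites (random strand) into i.i.d.
background sequences at a configurable occupancy, with uniform, centered
(Normal around the midpoint), fixed, or lagged-relative-to-another-motif
placement; overlapping placements are re-drawn up to 10 times and then
recorded as skips, never silently dropped. Both generators are
deterministic given seed and configuration and serialize their ground
truth as JSON.

What the generators deliberately omit: PCR duplicates and amplification
bias, sequencing errors, chromatin-accessibility-driven background
structure, repeat families, and GC heterogeneity (a GC knob exists for the
background but defaults to uniform). Passing the synthetic acceptance
suite therefore demonstrates correctness of the estimators under the
model's own assumptions and the stated noise levels — not performance on
the pathologies of real libraries, where mappability profiles, control
samples and the distance-distribution diagnostics carry more of the load.

## Problem sizes and test design

The statistical acceptance tests run at the study scale the estimators are
designed for: 100 replicate single-event regions (100 fragments each),
100 two-event replicates at 300-bp separation, 100 one-sided-deletion
replicates, 100 discovery seeds at 500 sequences × 200 bp with 60%
occupancy of an ~11-bit motif, 60 background-only discovery runs, a
100-motif synthetic database for self-retrieval, and a 50-event
treatment/control pair for the FDR check. `scripts/acceptance.py`
recomputes the same quantities from scratch with freshly drawn seeds
(discovery metrics at 30 recall / 20 background replicates, recorded per
metric in its "n" field) and writes them as JSON.

## Known limitations

- The enrichment-score and log-E formulas are this package's own explicit
  constructions; they are monotone in the quantities practitioners rank by
  but are not numerically interchangeable with other tools' scores.
- BIC-based K selection with the δ̂/4 merge rule resolves events ≥ ~300 bp
  apart at typical coverage; closer events are reported as one.
- The truncated-fit ghost-imputation assumes gaps are declared in the
  mappability profile; reads missing for undeclared reasons (e.g. copy-
  number loss) are indistinguishable from true absence of signal.
- ZOOPS assumes at most one site per sequence per motif per round;
  multiple sites of the same motif on one sequence are picked up across
  rounds only if they survive masking, so dense homotypic clusters are
  undercounted within a round.
- The Gumbel null is fitted to column-shuffled database pairs; databases
  of highly redundant PWMs make the null conservative (higher E-values).
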