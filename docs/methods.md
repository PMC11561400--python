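# Methods

This note documents the statistical procedures, the defaults and why they
are what they are, the design decisions taken where the method left choices
open, and what the synthetic generator does and does not emulate.

## Data model and grid alignment

All temporal statistics assume an equidistant monthly grid with no missing
cells.  Sample dates are snapped to the nearest month midpoint (ties toward
the earlier month); two samples snapping to one month is an error rather
than an averaging rule, because it usually indicates a mislabelled date.
Grid months with no sample are filled by per-vOTU linear interpolation
between the neighbouring observations; the grid never extends beyond the
first and last observed months (no extrapolation).  An
`interpolated_mask` records the filled cells, and every statistic that does
not need equidistance — Bray–Curtis pair formation, medoid/environment
correlations — is restricted to observed months.  Interpolation acts on raw
RPKM before z-scoring; the per-vOTU G-test runs on the full interpolated
grid because the periodogram requires equidistance.

Environmental parameters are min–max scaled per parameter,
`X' = (x − min x)/(max x − min x)`; a constant parameter column is rejected
because its scaling is undefined.  Consecutive-month Euclidean distances are
computed on the scaled table so all parameters contribute on equal footing.

## Seasonality

The Fisher G-test is exact under Gaussian white noise: the statistic is the
maximum periodogram ordinate over the total, with the closed-form tail
probability given in the README.  Defaults: α = 0.05 per vOTU with no
cross-vOTU multiplicity correction (the conventional default of the
periodicity-testing packages this test comes from); the statistic uses the
global periodogram maximum, with an "annual" mode available that fixes the
tested ordinate to the one nearest a 12-month period and uses the exact
pre-specified-frequency tail `P = (1 − g)^{m−1}` (Beta(1, m−1)).

Abundance quartile fractions cut the vOTU ranking (by mean RPKM, ties broken
by id) at n/4 from each end, so 100 vOTUs split 25/50/25.

Time-decay curves average Bray–Curtis dissimilarity over all pairs of
observed samples at each month gap.  The harmonic regression is OLS of mean
dissimilarity on the first annual harmonic; amplitude significance is the
joint F-test of the sine and cosine coefficients.  At least 6 distinct lags
are required for the design to be well conditioned.

## Chronotype clustering

One bootstrap round: random subgroup partition (permutation over *sorted*
ids, so results are invariant to input row order; a trailing remainder
< 10 is merged into the previous subgroup) → per-subgroup agglomerative
clustering (complete linkage, Euclidean) with the cut k = 2..min(20, n−1)
maximizing mean silhouette → K-means (10 seeded restarts) over the pooled
subgroup centroids for every k = 1..n−1 → elbow pick → full-collection
clustering at that k.  The elbow rule: force the WSS curve non-increasing,
then take the smallest k whose drop to k+1 first falls to or below the mean
absolute slope of the whole curve, falling back to k = 2 when no drop
qualifies (a straight-line curve has no elbow).  An alternative
maximum-second-difference rule would pick the same k on well-separated data;
the tangent-line reading is the shipped one.

The "bootstrap" unit is the subgroup partition, not a with-replacement
resample of series: every round must cluster the *full* collection for the
co-occurrence accounting over all pairs to stay exact.  Co-occurrence is
co-membership count / B; the consensus dendrogram is average-linkage (UPGMA)
agglomeration of 1 − co-occurrence, cut into `k_final = max_b k_b` — the
finest granularity any round supported.

Linkage choices: subgroup clustering uses complete linkage (the silhouette
search makes the subgroup step robust to the linkage), but the
full-collection step defaults to Ward's minimum-variance criterion.  On
planted phase-group designs (120 series, 6 groups, amplitude 3, noise 0.3)
Ward recovers the planted partition with ARI 0.93–1.0 across seeds while
complete linkage ranges 0.65–0.98, and the consensus cannot repair a biased
base clustering because between-round variability enters only through k.
Complete and average linkage remain available via configuration.

Determinism: every random draw derives from the user seed (per-round
generators are seeded `[seed, round]`), K-means restarts are seeded from the
round generator, and all randomness is keyed to sorted ids — identical
inputs and seed give identical memberships, bit for bit.

## Medoids and environmental correlation

The medoid minimizes the summed Euclidean distance to the other members
(ties → lexicographically smallest id).  Spearman correlations use observed
months shared by the abundance and environment tables (≥ 4 required).  Holm
step-down is applied within each medoid's family of parameter tests —
the row-wise family used by standard correlation-matrix testing routines —
with an unadjusted mode available because heatmap significance colourings
are sometimes reported on raw p.  Significance threshold: adjusted p < 0.05.

## Gene-category enrichment

The unit of replication is the chronotype; the response is the category's
gene count divided by the chronotype's member count.  The default test is a
one-tailed Welch t-test in the pre-specified direction "enriched in
seasonal chronotypes", Bonferroni-multiplied by the number of categories
tested.  Welch rather than pooled-variance because seasonal and
non-seasonal chronotype ratio distributions have no reason to share a
variance (a pooled mode exists).  An exploratory `alternative="best"` mode
evaluates both one-sided tests and reports the smaller with its direction;
it is not the default because choosing the tail post hoc doubles the
per-test type-I error and voids family-wise control — with it, the expected
probability of at least one false Bonferroni hit at α = 0.05 over 100 null
categories roughly doubles from ~5% to ~10%.

## Polymorphism profiles

Variant records are kept iff QUAL ≥ 20 and DP ≥ 10 and alternate-allele
frequency > 1%; multi-allelic records are split per alternate.  A site is
(position, alternate allele) by default — allele-level sharing is the
stricter reading of "shared polymorphisms" — with a position-only mode.
Coverage eligibility (breadth-at-10× ≥ 0.9) comes in "all-samples"
(ubiquitous-and-abundant set) and "any-sample" flavours, consumed from a
precomputed coverage table so the package stays decoupled from alignment
tooling.

Sharing is anchored: `100·|A ∩ B|/|A|` with A the reference month's set,
because the natural question is "how much of *this* month's profile
persists".  The shift matrix collects these values by signed shift and pools
medians over vOTUs and reference months jointly.  Each side of shift zero is
summarized by nonlinear least squares of
`f(d) = c + A·e^{kd} / (1 + e^{(d−d0)/s})` — exponential change gated by a
sigmoid transition to a plateau `c`.  Fitting uses data-driven
initialization (plateau from the tail mean, rate from a log-linear fit of
the early segment, transition at the steepest drop) plus seeded random
multi-starts; non-convergence is reported, not raised.  This model is
*sloppy*: with a single noisy curve, near-equivalent (A, k, d0, s)
combinations fit almost equally well, so self-consistency checks summarize
parameter recovery as the median over noise replicates and use a truth
configuration in which every parameter is expressed inside the observation
window.

### Annual recurrence

Per vOTU, the mean shared percentage at each unordered month gap (averaging
the two directed comparisons; the trivial 100% at gap 0 is excluded) forms a
lag curve tested for an annual signal.  The raw curve cannot be fed to the
Fisher G-test: adjacent lag bins share month pairs, so even under pure
turnover the curve is a smooth decay plus slowly wandering (red) noise whose
low-frequency power the global G-test flags essentially always (measured
false-flag rate 86%).  The default screen therefore (1) removes the slow
component as the residual from a 7-lag centered moving average — wide enough
to absorb the decay trend and the coherent wander, narrow enough to pass a
12-month oscillation — and (2) tests the ordinate nearest a 12-month period
with the exact pre-specified-frequency tail.  Measured on the generator:
2–8% of pure-turnover vOTUs flagged across seeds, ~100% power at recurrence
weight 0.5.  Global-max testing and exponential/linear/no detrending remain
options for sensitivity analysis.

## Synthetic generator

Defaults mirror the study design: a 32-month grid with 5 interior months
dropped (27 samples), seasonal series as truncated annual sinusoids
`exp(N(0,1))·[1 + 3·sin(2π(t+φ_g)/12)]₊ + N(0, 0.3)` in 6 evenly spaced
phase groups, 20% non-seasonal series (single-spike or reflected random
walk), nine environmental parameters with temperature peaking in August and
nutrients in anti-phase, 20% monthly site turnover over 100 sites per vOTU,
an annual-recurrence pool (per month-of-year, sized 2× the monthly
recurrent draw) engaged at weight 0.5 where recurrence is planted, and 3 of
100 gene categories enriched at +0.4 ratio units over a Poisson(0.2)
background.  Generators are pure functions of (config, seed) and always
emit ground truth.

What the generator does **not** emulate — and therefore what passing tests
do not establish about field data: phylogenetic correlation between vOTUs,
compositionality of RPKM, bursty co-infection dynamics, depth-dependent
variant-calling error (decoy records failing the filters are planted, but
with simple uniform QUAL/DP/AF margins), overdispersed gene counts, and any
coupling between abundance, coverage and polymorphism density.  Recovery
rates measured here are upper bounds on what the same settings achieve on
real viromes.

## Numerical and reproducibility notes

- Tables are written with 17-significant-digit floats, so write→read
  round-trips are bit-exact and repeated runs are byte-identical.
- The run manifest records config, seed, input checksums and package
  version; a wall-clock timestamp is recorded only on request because it
  would break byte-level reproducibility of an output tree.
- Fisher G p-values are clamped to [0, 1]; the alternating series is
  evaluated directly (m ≤ ~50 ordinates in practice, no overflow).
- Z-scoring a constant series returns zeros with a degenerate flag;
  degenerate series are kept by default so collection partitions stay
  exhaustive.
- Problem sizes in the test and acceptance runs (e.g. 120 series × 20
  bootstrap rounds, 200 simulated vOTUs for decay checks, 50-replicate
  power estimates) are chosen so each check completes in seconds while the
  measured quantities sit well inside their tolerance; all scale linearly
  if enlarged.
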