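# Methods

This note documents the models and procedures implemented in mugakit, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used.

## Founder-discrimination window score

For F founder strains, the diplotype state space at any locus consists of
the F homozygous states plus C(F, 2) unordered heterozygous combinations —
36 states for F = 8. A window of w biallelic SNPs maps each state to a
vector of per-SNP unordered allele pairs (dosages 0/1/2); the window score
f is the number of *distinct* vectors, so 1 ≤ f ≤ F + C(F, 2). The
distinct-vector reading (rather than counting uniquely identified states)
is what makes the minimum 1: a fully monomorphic window collapses all
states onto one vector.

A missing founder allele is treated as a wildcard: the state's vector
becomes a set of consistent vectors, and states whose vector sets intersect
at every SNP are merged. f is then the number of connected components of
this collision graph — a conservative lower bound that reduces exactly to
the distinct-vector count on complete data. (Collision is not transitive,
so the component count is the natural conservative aggregate.)

## Beam-search marker selection

One SNP is chosen per target interval; intervals partition each
chromosome's candidate span into equal-cM bins (if some bin would be empty,
the bin count is decremented — never merged — so bins stay uniform in cM).
A path's score is the sum of f over all complete sliding w-windows.
The beam search extends every retained path by every candidate of the next
interval, adds the newly completed window's f, and prunes to the
`beam_width` best (default 10^5; ties keep insertion order). With a beam at
least as wide as the number of distinct paths the result is provably the
exhaustive optimum, which the test suite checks against a full-enumeration
oracle; width 1 degenerates to greedy and lower-bounds the optimum.
Optional suffix deduplication (keep the best path per (w−1)-suffix) is
exposed but off by default, since the historical behavior is unknown.
Chromosomes with fewer chosen SNPs than w have no complete window, score 0,
and are flagged rather than rejected.

Hotspot-local selection scores all runs of w = 4 consecutive candidates
whose span overlaps the central 100 bp of a hotspot, maximizing f with ties
broken by smaller span, then midpoint proximity; if no run overlaps, the
nearest run is returned flagged `off_center`.

Uniform-spacing selection is a greedy gap-halving loop: repeatedly pick the
candidate nearest the midpoint of the largest uncovered gap. It is not
globally optimal (tests bound it at 2× the exhaustive optimum's largest
gap) but is monotone, order-free and fast.

Wild-SNP placement fills three slots per 1-Mb window — one transition per
500-kb half and one transversion in the middle third — ranking candidates
by MAF with seeded random tie-breaks, and only violates the 100-kb minimum
spacing (flagged) when a slot has no compliant candidate.

## Quality control

d = √(x² + y²) is used for total intensity rather than R = x + y because R
overestimates intensity for heterozygous samples (triangle inequality).
The array-level flag compares the empirical distribution of d to
Normal(0.97, 0.42) — the reference distribution of a well-behaved array —
via the two-sided Kolmogorov–Smirnov statistic (right-continuous ECDF,
supremum over both one-sided deviations), flagging K > 0.1. At least 100
probes are required; the statistic is meaningless below that.

Call-rate bounds are strict inequalities (> 15,000 missing for
*M. musculus* groups, > 45,000 for other *Mus* species, > 2,000 heterozygous
for classical inbred strains only) quoted for a 143,259-marker array and
scaled by `markers_present / 143,259` on subsets. Sex inference counts good
(nonmissing, nonheterozygous) calls at Y-linked markers: ≤ 33 → F, ≥ 42 → M
(both scaled by `y_markers_present / 83`), and the ambiguous band is
resolved by the sample's mean d over X markers relative to the midpoint of
the batch's known-female and known-male means — females carry two X copies
and hybridize more strongly.

Quality tiers partition probes by reference-panel behavior: Tier 1 shows
all three genotype states with no-call rate strictly below 10%; Tier 2 both
homozygous states; Tier 3 anything else under the no-call bound; Tier 4 the
remainder. The 10% boundary is exclusive (a probe at exactly 10% is Tier 4).

## Normalization

θ = (2/π)·arctan(y/x) is 0 on the x-axis (A allele) and 1 on the y-axis.
Cluster centroids are per-marker trimmed means of θ and R over samples
called AA/AB/BB — 5% total trim, 2.5% per tail, θ and R trimmed
independently by rank (`scipy.stats.trim_mean`). BAF maps θ
piecewise-linearly through (θ_AA, 0), (θ_AB, 0.5), (θ_BB, 1), clipped
outside; LRR = log2(R / R_expected) with R_expected the linear
interpolation of centroid R at the observed θ (clamped beyond the terminal
centroids). Markers with a single observed cluster give BAF missing and
LRR against that cluster's R, and are marked low-confidence — the
transformations work best when all three genotype states are present.

The thresholded quantile normalization maps each channel of a sample onto
a reference batch's quantiles by rank and caps the per-probe adjustment
ratio at 1.5 (config-exposed). This is a simplification of published
thresholded-quantile schemes, documented as such, not claimed identical to
any particular pipeline's variant.

## Multiallelic clusters and construct calls

Cluster counting seeds one cluster per founder strain (its replicate
centroid), then iteratively merges pairs that are mutual nearest neighbors
with centroid distance within `merge_dist_factor` (default 2.0) times the
median within-cluster point spread. Each F1 class is then assigned to its
parents' cluster when they share one, else forms a candidate heterozygous
cluster, and the merge pass repeats. Distances are Euclidean in the
normalized (x, y) plane; labels are ordered by centroid angle for
reproducibility. The merge criterion and factor are this package's
choices — the cited style of trio-informed clustering does not pin them —
and are validated on calibration geometries (a biallelic probe → 3
clusters; three hybridization alleles with all F1s → 6).

Construct presence is called from *raw* intensity only, along each probe's
informative axis, summed within target and log10-transformed (floor 1.0
raw unit). A two-component univariate Gaussian mixture is fitted by EM
(means initialized at the 25th/75th percentiles, sds at the pooled sd,
weights 0.5; convergence at |ΔlogL| < 1e-8 or 500 iterations; the
log-likelihood trace is retained and is nondecreasing). A sample is present
when the posterior of the higher-mean component exceeds 0.5; if the two
means differ by less than 2 pooled sds the target is non-separable and all
calls are absent-with-warning. Percentile initialization makes the fit
deterministic, so no random seed is involved. Calls do not discriminate
heterozygous from homozygous construct carriers.

## Donor-mosaic HMM

Hidden states are candidate donor strains. Emissions: a genotype call
matching the donor's has probability 1 − ε, a mismatch ε (default
ε = 0.01); no-calls on either side are uninformative (uniform). Transition
between adjacent markers: switch probability 1 − exp(−Δ cM / L) split
evenly over the other donors, with L the expected segment length (default
10 cM); without a genetic map, 1 Mb counts as 1 cM. These parameters are
conventions, not estimates — they are validated by simulation recovery
(planted 20-cM blocks recovered within 2 markers in ≥ 95% of replicates at
ε = 0.01) and fully config-exposed. Heterozygous calls against homozygous
donors count as mismatches; a diploid two-donor state space is out of
scope. Viterbi gives the segmentation (boundaries at midpoints between
flanking markers of a state change, so segments tile the marker span);
forward–backward posteriors are attached. Per segment, any donor whose
emission log-likelihood over the segment is within `margin_delta` (default
2.0) of the decoded donor's joins an equivalence group — segments
consistent with several indistinguishable donors are labeled with the
group, not an arbitrary member.

## Copy number

Paralogous-SNP candidates require ≥ 2 bases each with > 3 supporting reads
and depth > 50, both strict as printed; flagged sites within 50 bp of a
previously flagged site are dropped left-to-right (the paper does not say
which of two close sites was kept; left-to-right greedy is deterministic).
Region screening averages LRR over a region's probes (≥ 3 required, else
withheld) and calls gain above +0.3 / loss below −0.3 — a screening default
of this package, not a calibrated caller; single-copy deletions sit near
log2(1/2) = −1 and duplications near log2(3/2) ≈ +0.58.

## Synthetic data

The generator's primary simulated quantity is d itself, reconstructed into
(x, y) from (d, θ) — this pins the QC-relevant marginal exactly. Good mode
draws d from Normal(0.97, 0.42) floored at 0; flooring (rather than
conditional truncation) keeps the mean at ≈ 0.9716, consistent with the
reference mean, and contributes a deterministic ≈ 0.0105 to K from the
atom at zero — far below the 0.1 flag. Failed mode is Gamma with mean 0.45
(shape 2), right-skewed, chosen so K > 0.1 holds with wide margin; failed
arrays additionally lose 20% of calls. Diverged mode mixes the good
distribution with a 20% near-zero spike (|Normal(0.05, 0.03)|), the
off-target-variant signature of genetically distant samples.

Founder alleles are i.i.d. Bernoulli(0.5) per marker; F1 genotypes derive
deterministically from parents; outbred genomes are two independent Markov
founder chains with switch probability 1 − exp(−g·ΔcM/100) for g
generations. Sexes alternate; females emit background intensity and
no-calls at Y markers; males are hemizygous on X with d halved there. The
default manifest keeps X probes at ~5% of the array, mirroring the real
platform's autosome-dominated composition — a disproportionate X fraction
would make hemizygous-male arrays fail the intensity check for purely
compositional reasons. CNV regions scale d by copy/2; VINO probes emit
near-zero intensity and no-calls for alternate-allele carriers.

Not emulated: linkage disequilibrium and realistic founder allele-sharing
structure, batch/plate effects, GC waves, probe-specific affinity
differences, and correlated per-probe noise. Passing tests therefore
demonstrate correctness of the algorithms under their stated models, not
performance on real arrays; in particular per-probe LRR under the
generator's independent heavy noise carries a small negative Jensen bias
(E log2 < log2 E), which region-level means inherit (≈ −0.15) — well
inside the ±0.3 screening band.

## Problem sizes

Tests and the acceptance script run at desk scale: the window-score bound
is checked over 100,000 random configurations; beam-vs-exhaustive over 200
instances of ≤ 3^8 paths; the QC distribution checks on one
141,090-probe array (the real platform's SNP-probe count); HMM recovery
over 100 replicates of 500 markers. These sizes were chosen so the full
suite completes in minutes while keeping every statistical check
well-powered.
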