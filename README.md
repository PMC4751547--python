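# mugakit

Design, quality control and downstream analytics for multi-founder mouse
genotyping arrays, built for platforms in the style of the MUGA family
(Illumina Infinium arrays genotyping the 8 Collaborative Cross / Diversity
Outbred founder strains and wild *Mus musculus*).

It is aimed at people who design SNP content for such arrays, run genotyping
cores, or analyze the resulting call/intensity tables: geneticists verifying
congenic backgrounds, CC/DO users needing founder-haplotype resolution, and
anyone screening arrays for failed hybridizations or copy-number change.

## What it implements

**Marker selection.** For F founder strains a window of consecutive SNPs can
distinguish at most F + C(F,2) diplotype states (36 for F = 8). The window
score *f* counts the genotype-state vectors distinguishable in a w-SNP window
(default w = 5); a chromosome's path score is

    S(path) = sum over sliding windows of f(window),

maximized by a beam search over one-SNP-per-interval paths that retains the
10^5 highest-scoring paths at each step (`markersel.beam_select`). Also:
candidate filtering (single-bead, unique flanks, ≥ 50 bp from neighbors),
equal-cM interval partitioning, hotspot-local 4-SNP selection, uniform-
spacing selection, and slotting of wild-mouse SNPs into 1-Mb windows.

**Quality control.** Per-probe total intensity d = √(x² + y²); an array is
flagged when the Kolmogorov–Smirnov statistic of d against the reference
N(0.97, 0.42) exceeds 0.1, when group-specific missing/heterozygous call
bounds are exceeded (> 15,000 / > 45,000 / > 2,000, scaled to the markers
present), or when Y-linked good-call counts contradict the known sex (the
33–42 ambiguous band is resolved by X-chromosome intensity). Probes are
assigned to four quality tiers from the genotype states they show in a
reference panel (`qc`).

**Normalization.** Polar transform R = x + y, θ = (2/π)·arctan(y/x);
per-marker trimmed-mean cluster centroids; B-allele frequency as the
piecewise-linear map of θ through the three centroids; log R ratio
LRR = log2(R / R_expected(θ)); thresholded quantile normalization across
arrays (`normalize`).

**Cluster analytics.** Trio-informed multiallelic cluster counting (founder
seeds, mutual-nearest-neighbor merging, F1 assignment) and presence/absence
calling for engineered constructs via a two-component Gaussian mixture on
log10 summed raw intensities (`cluster`).

**Strain informativeness.** Pairwise informative-marker counts, replicate
and F1 concordance, subspecies-diagnostic marker discovery (dom/mus/cas,
allowing up to two outside carriers), density augmentation to one diagnostic
marker per 300 kb, and recoding of Y/mitochondrial calls into four-state
character matrices for parsimony software (`inform`).

**Ancestry mosaics.** A hidden Markov model reconstructs a sample's genome
as a mosaic of donor-strain segments (Viterbi decoding, cM-scaled switch
probabilities, forward–backward posteriors), reporting indistinguishable
donors as equivalence groups — how congenic backgrounds are verified
(`ancestry`).

**Copy number.** Paralogous-SNP candidate filtering from pileup summaries
(> 3 reads for ≥ 2 bases, depth > 50, > 50 bp spacing) and region-level LRR
summaries for gain/loss screening (`cnv`).

**Synthetic data.** A generator producing all of the above inputs with
complete ground truth: founder haplotypes, all 28 F1 classes, outbred
mosaics, good/failed/diverged array modes, sexed samples, VINO probes, CNV
regions and construct carriers (`synthetic`).

## Worked example

```sh
python examples/01_simulate_and_qc.py
```

```
sample        mean d       K  miss   het  sex  status
AJ             0.926   0.045    83     0    F  PASS
B6             0.932   0.039     0     0    M  PASS
129S1          0.909   0.060    83     0    F  PASS
NOD            0.431   0.583   403     0    M  FAIL  (intensity_fail)
NZO            0.919   0.062    83     0    F  PASS
CAST           0.962   0.027     0     0    M  PASS
PWK            0.932   0.050    83     0    F  PASS
WSB            0.946   0.035     0     0    M  PASS
```

Good arrays show mean d near 0.97 and K well below the 0.1 threshold; the
planted failed array (NOD) has a low-mean, right-skewed d distribution
(K = 0.58) plus elevated missingness and is flagged. Females show 83 missing
calls — the Y-chromosome probes — and are sexed F. The other examples cover
marker selection, LRR/BAF, multiallelic/construct probes, informativeness,
congenic verification and CNV screening; each prints what it computes and
what the numbers mean.

A thin CLI wraps the pipeline-shaped steps:

```sh
mugakit simulate --seed 1 --out-dir demo/
mugakit qc --report demo/report.tsv --manifest demo/manifest.csv \
           --samples demo/samples.csv --out demo/qc.tsv
```

## Layout

```
src/mugakit/      library (datamodel, markersel, qc, normalize, cluster,
                  inform, ancestry, cnv, synthetic, cli)
examples/         one narrative script per capability
tests/            pytest suite
docs/methods.md   models, parameter choices, limitations
```
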