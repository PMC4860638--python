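# Methods

`wifaseq` detects recurrent *focal* somatic copy-number alterations (CNAs)
from tumor/normal whole-genome sequencing depth across a cohort. Focal
events (here ≤ 3 Mb, at most 25% of a chromosome arm) are the ones most
likely to pinpoint driver genes, but they are easily buried inside broad
arm-level alterations and, in WGS data, mimicked by mapping artifacts. The
method addresses both with a stationary Haar wavelet decomposition that
isolates each sample's *local* copy-number behavior before any cross-sample
aggregation.

## Signal model and preprocessing

Reads are counted at their leftmost mapped base (unmapped, secondary,
supplementary and duplicate reads are skipped), winsorized within a sliding
200-bp window at the 0.95 quantile, and summed into consecutive 100-bp bins;
the final partial bin of each chromosome is kept. For bin *i* on chromosome
*c* the observed signal is

    y_i = log2( (Tumor_i / Tumor_c) / (Normal_i / Normal_c) ),

the log-ratio of chromosome-normalized depths, which is invariant to
per-chromosome library size. We model `y_i = f(x_i) + e_i` with `f` the true
copy-number change and `e_i` noise. Bins with a zero tumor or normal count
have no defined ratio and are marked invalid (no pseudocounts: a pseudocount
would fabricate deletions exactly where the masking stage is supposed to act).

Winsorization detail: the cap is the window's `lower` order-statistic
quantile and the capping pass is iterated to a fixed point (typically two
passes), so the operation is idempotent and never increases a count.

## Masked concatenation

Reference 'N' gaps (centromeres, heterochromatin) and low-mapping regions are
excluded and the remaining bins concatenated in genome order before the
transform. Positions that become neighbors across a removed region are
recorded as junctions; clusters spanning one are flagged in reports rather
than silently split, since treating the flanks of a removed region as
neighbors is deliberate.

Low-mapping regions are found from the normal samples themselves: the same
high-frequency wavelet procedure is run on the median-centered normal count
signal, maximal nonzero segments are collected, and each segment's mean
mapped reads per bp is clustered with a deterministic 1-D 2-means (centers
initialized at the min and max, ties to the lower class). Segments in the
lower-coverage class at least 3 kb long are masked, the masks are unioned
across patients, and the analysis re-runs on the cleaned layout (two-pass
scheme). Masking is monotone: a masked bin is never unmasked.

## Stationary Haar transform and the high-frequency signal

The concatenated signal is mirror-extended to the next power of two
(`[1,2,3] → [1,2,3,3,2,1,1,2]`) and analysed with the undecimated (à trous)
Haar transform written with average / half-difference filters: at step *t*
with dilation `h = 2^(t−1)`, circular over the extended signal,

    s_t[i] = (s_{t−1}[i] + s_{t−1}[i+h]) / 2
    w_t[i] = (s_{t−1}[i] − s_{t−1}[i+h]) / 2 .

`s_t[i]` is the mean of `2^t` consecutive bins, `w_t[i]` half the difference
of two adjacent block means. With `J` the exponent of the extended length
and `M` the coarsest retained level, `J − M` steps are applied. Defaults
`J = 25, M = 10` come from the human genome: 3.2 Gbp at 100-bp bins is
32,000,000 bins (`J = ceil(log2) = 25`) and a 3 Mb neighbor scale is 30,000
bins (`ceil(log2) = 15` levels, `M = 25 − 15 = 10`). For smaller genomes the
signal is extended to its own next power of two and the *level count*
`J − M` is what is preserved (capped at the extended length), so the
physical neighborhood scale `2^(J−M)` bins (~3.3 Mb) is held fixed.

Each detail level is hard-thresholded with the universal (VisuShrink-style)
threshold

    λ_j = C · σ̂_j · sqrt(2 ln n_j),   σ̂_j = median(|w_j|) / 0.6745,

with `n_j` the number of coefficients on the extended signal (constant
across levels for a stationary transform) and non-strict comparison
(`|w| ≤ λ` is zeroed). `C` (default 2.0) is the operator's noise dial; the
level-wise MAD keeps the estimate robust to genuine structure.

`y_HIGH` is the branch-averaged inverse with the coarsest scaling
coefficients zeroed: each position's two synthesis branches are averaged
(the shift correction of the à trous inverse), the result is cropped to the
original range. The inverse is exact on untouched coefficients (tested to
1e−10, and in practice to machine epsilon). `y_HIGH` measures how a bin
differs from its neighborhood up to `2^(J−M)` bins — a focal event inside a
broad gain stands out while the broad plateau itself vanishes. Because a
step edge always throws an opposite-signed lobe onto its unaltered side,
positions whose `y_HIGH` sign disagrees with the raw log2 ratio are zeroed;
this sign-filtered signal is what all later stages consume.

A consequence worth knowing: around a real event the thresholded coarse
levels reconstruct a low-amplitude response *halo* up to one neighborhood
scale (~3.3 Mb) on each side, which the sign filter thins into many short
runs. This is expected behavior, mirrors the multi-megabase cluster widths
typical of this approach, and is why the permutation machinery is built for
thousands of runs per sample.

Performance: the analysis/threshold/inverse chain is implemented twice —
small, pure-numpy reference functions (`haar_swt`, `inverse_swt`, …) and
fused numba kernels used by the pipeline. A test asserts the two paths agree
bit-for-bit.

## Aggregation and clustering

Sign-filtered signals are summed bin-wise over patients (the recurrence
signal), together with per-bin patient support (number of samples
contributing a nonzero value). Maximal same-sign nonzero runs are extracted,
split at chromosome boundaries. Runs of the same sign on the same chromosome
merge into a *group* when the exclusive genomic gap between them is at most
`d` (default 0.3 Mb) and into *subgroups* at distance `r` (default 0.3 Mb);
a subgroup's score is the sum of the recurrence signal over its runs, and
each group's maximum-|score| subgroup is emitted as a cluster (leftmost wins
ties; non-winning subgroups are discarded). Opposite signs never share a
group. A cluster records 1-based inclusive coordinates at bin boundaries,
signed score, and its patient count as the maximum per-bin support inside it
(a conservative, reproducible reading of "patients with alterations in the
cluster"). High scores need many patients and/or large amplitude — the same
trade-off a GISTIC G-score encodes, computed without per-sample
segmentation.

## Significance: permutation null and the five FDC schemes

Under the null that patients alter independently, each patient's nonzero
runs are reallocated uniformly at random (order preserved, no overlap,
values intact) within their own chromosome's unmasked territory; the
reallocated cohort is summed and clustered with the same `d`, `r`, and this
is repeated `B` times (default 1000; tests and the bundled experiments use
200). Placement uses the gap method — the free territory is split by sorted
uniform draws into random inter-run gaps — which samples a uniformly random
non-overlapping arrangement in O(n) and stays exact when a sample carries
thousands of runs, where per-run rejection sampling degenerates. Placed runs
keep at least one empty bin between them whenever the territory allows, so
the multiset of run lengths and value sums is conserved exactly.

An observed cluster is compared against random clusters of its own sign, on
absolute score:

* **FDC1** — fraction of permutations whose maximum |score| reaches the
  observed one (permutations with no qualifying cluster count as
  non-exceedances);
* **FDC2** — as FDC1 over random clusters no longer than the observed;
* **FDC3** — as FDC2, additionally no more supporting patients;
* **FDC4** — residual exceedance after an ordinary least-squares fit of
  |score| on length over all pooled same-sign random clusters (undefined,
  NaN, below 3 random clusters);
* **FDC5** — as FDC4 with patient count as a second covariate.

FDC1 is the most conservative; the others discount score mass explicable by
length or recurrence and are increasingly permissive. Nesting
`p_FDC3 ≤ p_FDC2 ≤ p_FDC1` holds exactly by construction and is asserted on
seeded cohorts. For FDC2/3 the filtered maximum is taken per permutation
(consistent with FDC1); for FDC4/5 "compared to the regression estimate" is
read minimally as residual exceedance over the pooled random clusters. The
whole null is a pure function of (signals, d, r, B, seed). Significance
filtering uses `p ≤ α` with α = 0.1 by default. On small dense test genomes
FDC2/3 can degenerate to 0 when no random cluster is as short as the
observed one — visible in the bundled fixtures, and the reason FDC1 is the
default reporting mode.

## Synthetic cohorts

The generator emulates the data features the pipeline must survive, at
defaults chosen to mirror the GBM cohort the method was developed on:

* **Depth**: negative-binomial bin counts, `var = m + φ·m²` with dispersion
  φ = 0.05 (WGS depth is overdispersed; φ = 0 gives Poisson). Mean reads per
  100-bp bin default to 49.6 (tumor) and 43.7 (normal) — the cohort's mean
  genome-wide coverages, which for ~100-bp reads equal read starts per bin.
* **Events**: focal (≤ 3 Mb) and broad (> 25% of the chromosome) intervals
  with carrier sets; overlapping events compound multiplicatively, so a
  1 Mb Δlog2 = 1.0 focal gain inside a Δlog2 = 0.3 broad gain is the
  textbook nested scenario.
* **N-gaps**: zero counts in both samples.
* **Sparse-mapping stretches**: severely reduced mapping (defaults 30% of
  nominal normal depth, 3% tumor) rather than exact zeros — bins with no
  normal reads at all have an undefined ratio and are dropped before the
  transform, whereas the real artifact (and the false deletions it causes)
  comes from the few reads that do map.
* **Fractured tracks**: per-patient multiplicative depth jitter, log-normal
  (σ = 0.3) and piecewise-constant over ~50 kb blocks, reproducing the
  excessive read-depth-change artifact at the segment-count level.

Everything is a pure function of the spec's seed (per-patient child seeds
from a spawned `SeedSequence`). The generator does not emulate GC waves,
mappability structure, replication timing, subclonality or purity; passing
tests demonstrate the machinery's behavior under its stated model, not
performance on real tumor genomes.

## Bundled experiments and problem sizes

The test suite runs cohort-scale experiments at sizes chosen to exercise the
default neighborhood scale while staying desk-sized: a 3 × 30 Mb genome at
100-bp bins (900,000 bins) for the power study — 50 replicate cohorts of 20
patients with a 1 Mb focal gain (Δlog2 = 1.0, 6 carriers) and a broad-only
20 Mb gain on another chromosome, B = 200 permutations, FDC1 α = 0.1; a
1 × 10 Mb genome for the masking regression (5 kb sparse stretch, 20 seeds)
and the threshold sweep; 2 × 5 Mb cohorts for FDC nesting (20 seeds) and
pure-noise false-positive control (100 replicates, 10 patients). The
low-mapping screen is switched off in the power study (no mapping artifacts
are simulated there) and validated by the masking regression instead.

## Numerical and degenerate-input choices

* Invalid (zero-count) bins contribute 0 to the concatenated signal.
* An all-masked layout, an empty cohort, unknown reference names, or
  mismatched layouts are hard errors; a chromosome with zero total normal
  reads degrades to all-invalid bins with a warning.
* `σ̂_j = 0` (all-zero level) gives λ_j = 0; hard thresholding is non-strict.
* 2-means with fewer than two distinct segment coverages returns nothing
  (no bimodality to exploit) with a warning.
* Subgroup score ties break to the leftmost; cluster reports order by
  |score| descending.
* Gaps for grouping are genomic end-to-start distances (exclusive), so runs
  on different chromosomes never merge.

## Known limitations

* No GC or mappability correction, no allele-frequency signal, no
  purity/ploidy model — out of scope by design.
* The response halo means reported clusters are wider than the underlying
  focal event (megabase-scale localization, as in the original approach).
* FDC4/5 assume an adequate linear fit of |score| on its covariates; with
  few random clusters they are undefined.
* Arm-level events are deliberately suppressed, not called.
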