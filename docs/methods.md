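# Methods

`cnahier` detects copy-number alterations (CNAs) from the read-depth (RD)
signal of a single whole-genome sequencing sample, without a matched normal,
SNP data, or high coverage. It is built around three ideas: an **absolute
copy-number reference** fitted to the multimodal RD histogram of an
aneuploid genome, a **hierarchical segmentation** that separates Mb-scale
segmental aneuploidies (large-scale copy variations, LCVs) from the focal
amplifications/deletions (FAs) nested inside them, and **coverage-calibrated
amplitude thresholds** that keep focal calling honest when the data are
shallow and overdispersed.

## The RD signal

Reads are reduced to base-count frequency on fixed 1-kb bins: every aligned
reference base of a passing read (mapping quality ≥ 1 by default; duplicate,
secondary and supplementary alignments dropped) contributes 1/1000 to its
bin, so a genome at fold-coverage *c* has mean RD *c* over diploid
territory and RD maps linearly to copy number. GC bias is removed by
isochore-style stratified median matching: GC is computed over 100-kb
windows, bins inherit their window's GC, 1%-quantile GC strata are rescaled
to the global median (strata with fewer than 20 bins are left alone). Bins
in assembly gaps, blacklisted intervals, repeat-associated regions, or with
mappability below a threshold (default 0.5) are masked — set to missing,
never zeroed — and excluded from every downstream statistic. Masks only
grow along the correction chain.

The 100-kb isochore window, the 1% strata and the read filters are not
canonical values; they are exposed in `RunConfig` and the relevant function
signatures so they can be changed without touching code.

## Copy-number reference

The RD histogram of a cancer genome is a mixture of near-Gaussian peaks,
one per iso-copy-number population. The global median tracks the dominant
peak — in a triploid-dominant genome that is 3N, and calling it "2" breaks
every downstream copy-number estimate. Instead the density in copy-number
units is modelled as

    f(x) = Σ_{i=2..6} c · w_i · N(x; i, σ²),   c = 1 / Σ w_i ,

and a candidate 2N RD level *g* is scored by rescaling all RD values to
x = 2·rd/g, building the empirical density r̂(x) (normalised by the *total*
bin count, so mass pushed outside the modelled range [0, 6.5] is lost), and
computing the histogram intersection Σ min(r̂, f)·Δx on a Δx = 0.01 grid.
The candidate grid is 500 log-spaced points over [0.25, 2] × the global
median. Ploidy models set the weights: *free* is flat (w_i = 1);
*diploid/triploid/tetraploid* use w_i = 2^(−|i−n|) around the main state
n = 2/3/4, i.e. weight decays with distance from the dominant state. (The
increasing variant 2^(+|i−n|) is available as `weight_sign="printed"`, but
it contradicts the premise that most of the genome sits near the main
state, so the decaying form is the default.)

σ is re-fitted per candidate as 1.4826 × MAD of the residuals to the
nearest integer state (|residual| ≤ 0.25), clamped to [0.01, 0.5] CN. The
lower clamp matters: at 10x coverage a Poisson RD peak is only ~0.03 CN
wide, and a floor of 0.05 would make the model systematically wider than
the data, biasing the fit toward high-state interpretations whose implied σ
is larger.

Three numerical safeguards around the argmax:

* **Scale near-ties go to the larger candidate.** Under the free model a
  unimodal histogram scores almost identically wherever its mode is parked
  (every state has the same capped mass), so "ties toward larger rd_2n"
  (the lower-ploidy interpretation) is applied across *local maxima* of the
  score landscape within 15% (relative) of the best, not just on exact
  equality.
* **A refinement pass** (81 log-spaced points over ±2 coarse grid steps)
  removes the ~0.4% coarse-grid quantisation.
* **Mode-centering polish.** When the intersection saturates a state's cap
  the score is flat over a ~σ-wide band of scales. The final scale is
  therefore polished by up to three fixed-point steps of
  g ← g · median(x / round(x)) over bins within 0.25 CN of an integer state
  — an exact multiplicative correction for all states at once — and
  accepted only if the overlap stays within the tie tolerance. On clean
  genomes this pins the reference to the histogram's mode structure to well
  under 0.1%.

CN intervals are half-integer boundaries around each state, half-open
upward: continuous CN 2.5 belongs to state 3.

**Known limitation — the free model and extensive monosomy.** The mixture
has no state below 2, so a genome where monosomic (CN 1) territory is a
large fraction of the whole can genuinely score better under the
half-scale interpretation (CN 1 mass mapping to state 2) than under the
truth, whose CN 1 mass the model cannot explain. The *diploid* weighting
resolves this whenever the RD histogram has a prominent 2N peak — which is
exactly when it should be used — and is what the synthetic benchmarks use,
since their genomes are diploid backgrounds with planted LCVs. The free
model remains the default for genomes with broadly spread karyotypes and
for reference-model comparisons.

## Segmentation

The RD signal is smoothed with a Savitzky–Golay filter (window 51 bins,
order 3): a local least-squares polynomial smoother that flattens
short-term noise and low-frequency wave artifacts while preserving sharp
copy-number edges with no phase shift. Missing bins are bridged by linear
interpolation before filtering and re-masked after, so the kernel never
sees sentinels.

Change points are amplitude-shift points of the smoothed signal: at every
interior bin the means of the *w* bins to the left and right are compared,

    G(t) = | mean(s[t−w, t)) − mean(s[t, t+w)) | ,

and local maxima of G exceeding k·σ̂ are kept (coarse pass: w = 30, k = 4).
σ̂ is the robust per-bin noise scale, 1.4826 × MAD of the first differences
of the **pre-smoothing** signal divided by √2 — first differences cancel
piecewise-constant structure, and the pre-smoothing scale is the only choice
under which k keeps its meaning (the smoothed signal's differences are
~√window smaller than the noise the statistic must beat). Accepted points
are at least *w* bins apart (higher score wins, ties leftward), and
secondary maxima within 2w of an accepted point at under 10% of its score
are suppressed as smoothing sidelobes — the Gibbs-like overshoot of a
polynomial smoother at a large step otherwise yields spurious, tiny change
points, while true neighbouring steps need a ≥ 2-window plateau to be
resolvable at all. Masked runs of ≥ 100 bins (assembly gaps, centromeres)
act as hard boundaries and are emitted as excluded segments.

## Block assembly

Primary segments are merged into iso-copy-number blocks (IBs) by CN state.
Segmentation alone both under- and over-cuts: adjacent segments often share
a state (false segmentation), and focal events fragment the aneuploid
region that contains them (oversegmentation). The assembly is a single
deterministic pass per gap-free run:

1. **Anchors.** Segments at least `min_ib_size` (default 1 Mb) wide are
   anchors; their states are taken as certain.
2. **Gaps.** Each stretch of sub-minimum segments between anchors is
   resolved as a whole. Leading/trailing items matching a flank's state are
   bridged into it outright. The remainder is (a) promoted to a block of
   its own if its median bin CN matches neither flank and it is at least
   `min_ib_size` wide — the rescue path for an aneuploid region so dense
   with focal events that no single backbone segment reaches the minimum;
   (b) bridged into same-state flanks; or (c) split between different-state
   flanks at the cut minimising the width-weighted CN misassignment cost.
3. **Merge.** Adjacent same-state blocks merge; absorbed segments whose
   state differs from their final block are retained as embedded
   focal-alteration candidates.

Throughout, a block's copy number is the **median** bin CN over its
territory. At realistic focal densities (the shipped benchmark plants 40
focal events of 50–100 kb per 20-Mb chromosome — roughly 30% of the LCV
territory) a mean would be dragged substantially by the embedded events; a
median is unmoved until contamination exceeds half the block. The same
median is the **local reference** for focal amplitude shifts. Blocks whose
state differs from 2 are reported as LCVs.

This anchor-and-bridge formulation replaces an earlier iterative
absorb-the-narrowest cascade: with dense focal clusters at block edges the
cascade could snowball focal territory into spurious ≥ 1-Mb pseudo-blocks
or hand Mb-scale backbone fragments to tiny transitional segments,
truncating real LCVs. The single-pass form preserves all the merging
semantics (equal-state merging, sub-minimum absorption with candidate
retention, idempotence, oversegmentation repair) and is immune to cascade
order.

## Focal alterations

Each block with ≥ 100 usable bins is searched at fine scale: its own signal
is smoothed (window 11, order 3) and the amplitude detector re-run with
w = 10, k = 3; regions between consecutive fine change points, plus the
runs absorbed during assembly, are the candidates. Two call classes:

* **Class 1 (statistically significant):** Welch's two-sample t-test of
  the candidate's bins against the block's other bins (candidates with
  fewer than 5 bins are not tested), Benjamini–Hochberg corrected across
  all candidates genome-wide, significant at q < 0.05. BH is one of three
  selectable schemes (`none`, `bonferroni`, `fdr_bh`); a 5% level alone
  does not fix a correction, and BH is the standard choice for a discovery
  screen.
* **Class 2 (high confidence):** the amplitude shift
  Δcn = candidate mean CN − parent-block median CN reaches the
  coverage-calibrated amplification (Δcn ≥ th_amp) or deletion
  (−Δcn ≥ th_del) threshold. At high coverage both thresholds are 0.5 CN —
  the smallest shift that lands in a different CN interval.

The default report is class-2 calls annotated with their class-1 status
(the high-confidence emphasis appropriate at low coverage); every evaluated
candidate appears in an audit table with its flags and filter failures.
Calls are filtered by width (below the coverage-dependent resolution), by
> 50% overlap with blacklist/gap/repeat masks, and — deletions only — by a
low-mappability bin fraction above 0.5, since poor-mappability troughs
mimic focal losses.

## Coverage calibration

RD dispersion rises as coverage falls, so the class-2 thresholds and the
minimum callable width (*resolution*, the narrowest event callable at
FDR < 5%) must rise too. Each parameter is modelled as a negative
exponential in fold-coverage, p(cov) = a·exp(−b·cov) + c with a ≥ 0, b > 0,
c ≥ 0, fitted by constrained least squares from a deterministic initialiser
(a = value range, b = 1/mean coverage, c = minimum value); the asymptote c
is the high-coverage value (0.5 CN for thresholds, the 2-bin floor for
resolution).

The shipped default coefficients come from
`calibration.sweep_default_curves` (fixed seed): CN-neutral genomes with
**negative-binomial** bin counts at variance = 12 × mean are swept over
coverages 0.5–30x; the thresholds are the 75th percentile across replicates
of the per-genome extreme mean-CN shift over 3-bin windows (floored at
0.5), i.e. the smallest amplitude that noise alone reaches about once per
100k-bin genome, and the resolution is the smallest width at which fewer
than 5% of replicate genomes contain any window beyond threshold. The
overdispersed null is deliberate: real shallow-WGS read depth carries
residual mappability/GC structure and wave artifacts that inflate 1-kb bin
variance an order of magnitude beyond Poisson, and under a pure Poisson
null a 0.5-CN shift over even two bins is a many-sigma event at any
practical coverage, which would flatten every curve onto its floor. The
12× factor is a fixed package choice in the range reported for ~1x WGS;
users with their own high-coverage data should refit via binomial thinning
(`subsample_profile`) and `fit_negexp`, which is the better-grounded path.
`estimate_resolution_by_simulation` (the user-facing resolution estimator)
runs the actual candidate pipeline on Poisson profiles and is accordingly
conservative.

Coverage itself is estimated from the profile (mean unmasked RD), not read
from headers.

## Simulation and ground truth

Two generators back the tests and benchmarks.

**Read spike-in** edits a read set: to move region R from copy number C1 to
C2 it adds or removes round(X·(C2/C1 − 1)) reads (half-away-from-zero
rounding; X = reads starting in R). Added reads are copies of randomly
chosen originals with starts shifted by a uniform offset of ±[10, 500] bp,
clipped to stay inside R, so local coverage texture is preserved; removals
are uniform without replacement; reads outside R are untouched. Focal
regions are placed inside LCVs, mask-clean, non-overlapping, and accepted
only if their read count is within 5% of the chromosome's typical count at
that width. The same logic runs on lightweight interval records or pysam
alignments.

**Synthetic profiles** draw per-bin base counts from
Poisson(coverage · cn/2 · bin_size) over a planted piecewise-constant copy
number, optionally modulated by a multiplicative sinusoid (wave artifact)
and a GC-bias field assigned at the 100-kb isochore scale. The benchmark
layout mirrors the spike-in study design: per chromosome, 1–4 LCVs (target
CN drawn from {1, 3, 4}) alternating with diploid background, segment
lengths from a Dirichlet draw that gives LCVs three times the background
weight (so they can host the focal load) with a hard 1-Mb minimum, and 40
focal events of 50–100 kb placed uniformly over the LCV territory
(width-weighted across hosts) with a target state differing from the
parent by at least one. LCV partitions use exact slack-space sampling
(uniform cuts conditional on the minimum width), not rejection.

What the generator does **not** emulate: overdispersion beyond Poisson (it
enters only the calibration null), correlated bin noise, sequencing error,
fragment-size structure, subclonality/tumour purity, and real mappability/
blacklist geometry (masks are synthetic when tests need them). Passing the
synthetic benchmark therefore demonstrates the algorithmic contracts —
reference placement, boundary recovery, nested-event separation, CN
accuracy — under the caller's assumed noise model, not performance on any
particular real dataset.

**Evaluation** follows the benchmark's matching rules: a focal event counts
as detected when a single call covers > 75% of it; an LCV when a single
block covers ≥ 90% of it and carries the planted integer state. Precision
counts *false amplifications* only (deletion false positives are dominated
by mappability artifacts that vary between tools); an unmatched
amplification call is counted false only if less than half its width lies
in truth territory, so fragmented or duplicate calls over a real event are
not penalised as hallucinations. With zero calls precision is reported as
1.0 with an explicit `no_calls` flag.

## Default parameters

| parameter | default | units | role |
|---|---|---|---|
| `bin_size` | 1000 | bp | RD grid |
| `min_mapq` | 1 | — | read filter |
| `mappability_threshold` | 0.5 | — | bin mask |
| isochore window | 100,000 | bp | GC normalisation scale |
| `ploidy` | free | — | mixture weights (diploid recommended when a clear 2N peak exists) |
| `sg_window`, `sg_order` | 51, 3 | bins, — | smoothing |
| `varri_w`, `varri_k` | 30, 4 | bins, σ̂ | coarse change points |
| `fine_w`, `fine_k` | 10, 3 | bins, σ̂ | in-block candidate pass |
| `min_ib_size` | 1,000,000 | bp | block minimum |
| `amp/del_threshold` | AUTO | CN | class-2 amplitudes from the calibration curves |
| `resolution_bp` | AUTO | bp | minimum call width |
| `alpha`, `fdr_method` | 0.05, BH | — | class-1 testing |
| `low_map_frac_limit` | 0.5 | — | deletion screen |

## Problem sizes

The shipped benchmark uses three genomes of 5 chromosomes × 20 Mb at 1.5x
coverage (300k bins per genome) — large enough that each chromosome hosts
the full 40-event focal load inside Mb-scale LCVs, small enough that the
whole benchmark runs in well under a minute. Reference-estimation checks
use ≥ 50k bins, the scale at which histogram noise stops mattering.
Monte-Carlo properties (false-positive rates, FDR control) use 20–40
seeded replicates.
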