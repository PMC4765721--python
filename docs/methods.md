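# Methods

## Model

A sequenced tumour sample is treated as a two-component mixture: a
fraction *C* (cellularity) of tumour cells sharing one clonal
copy-number profile, and 1 − *C* normal diploid cells.  Reads at a locus
come from 2(1 − *C*) normal copies plus (*n₁* + *n₂*)·*C* tumour copies,
giving the expected depth *D*·[2(1 − *C*) + (*n₁* + *n₂*)·*C*], where
*D* is the depth per single chromosomal copy.  At a germline-heterozygous
locus the allele present on the *n₂* tumour copies is carried by
*C·n₂* + (1 − *C*) copy-equivalents out of *C*(*n₁* + *n₂*) + 2(1 − *C*),
which is the predicted minor-allele fraction written in the README.  The
model assumes one clonal population (no sub-clonal states — off-lattice
mass is the *signal* the tool exists to reveal, not something it fits),
integer allele-specific copy numbers, and no coverage biases (no GC or
mappability correction; such corrections would sharpen the depth axis but
are deliberately out of scope).

### Folding

The recorded quantity at each locus is the fraction of the *less
frequent* allele, chosen after observation.  If *X* ~ Binomial(*d*, *f*)
reads carry the true minor allele, the recorded value is
min(*X*, *d* − *X*)/*d*, whose expectation is strictly below *f* whenever
*P*(*X* > *d*/2) > 0.  We compute this folded expectation exactly by
enumerating *k* = 0..*d*; at *f* = 0.5 it is 0.376953125 for *d* = 10 and
approaches 0.5 as *d* grows.  Grid nodes therefore plot the folded value,
evaluated at the node's predicted depth rounded to the nearest integer
(clamped to ≥ 1); rounding rather than interpolating between adjacent
integer depths is a simplicity choice whose error is far below a pixel.
The binomial read model is the canonical minimal choice; overdispersed
(beta-binomial) alternatives are a non-goal.

The state lattice enumerates all (*n₁*, *n₂*) with *n₂* ≤ *n₁* and
*n₁* + *n₂* ≤ 8 by default — figures rarely need totals beyond ~5, and 8
gives headroom without clutter.  The single degenerate state, homozygous
deletion (0,0) in a *pure* tumour, has no defined fraction and is omitted
from grids with a log notice; at *C* < 1 its fraction is the (normal
contamination) value 0.5 and it is kept.

## Scanning alignments

Candidate heterozygous sites come from a user-supplied TSV (in practice a
common-SNP catalogue for the reference in use; a small synthetic example
list ships with the package).  Counting uses pysam: reads flagged
duplicate/secondary/supplementary/QC-fail are skipped, as are reads below
`min_mapq` (default 30) and bases below `min_baseq` (default 20); loci
with filtered depth below `min_depth` (default 15) are dropped.  These
are conventional values, exposed as options — published heterozygous-site
yields depend on unstated filters, so ours make no claim beyond being
sensible defaults.  A site is called heterozygous in the matched normal
when the second-most-frequent base holds 30–70% of filtered depth.  The
minor fraction is computed over the two most frequent bases only (the
model is biallelic; third-allele reads would otherwise deflate fractions
relative to the predictions).  Chromosome-name dialects (`chr1` vs `1`)
are never translated silently; a mismatch raises an error naming both
spellings, because silent renaming hides genuine reference mismatches.

Without a matched normal (cell lines), loss-of-heterozygosity sites are
indistinguishable per-locus from germline-homozygous ones and would
swamp the density plot; sites with minor fraction below `loh_threshold`
(default 0.1) are retained at rate `loh_keep_fraction` (default 0.05)
using a seeded generator, so runs are reproducible.  Both rates are
logged.  Near the threshold this down-sampling can leave a faint
artefactual cloud at low depth; it should be read as an artefact, not
sub-clonality.

## Smoothing and rendering

Depths and fractions are smoothed along each chromosome independently
with a running median (default) or mean over a `window` of loci (default
51); at chromosome ends the window shrinks symmetrically, so every locus
keeps an output and no locus leaks across a chromosome boundary.  Window
choice is a noise/resolution trade-off: a window spanning an appreciable
fraction of a segment averages across distinct states and merges their
clusters (this is a tested property), so the window should stay small
relative to the loci-per-segment count — with tens of thousands of loci,
51 is comfortable; near a thousand loci, ~11 is more appropriate.

Smoothed observations are binned into a depth × fraction histogram over
the axis limits (defaults: depth 0–100, fraction 0–0.5, the full range of
minor fractions) at plot-region resolution — an 800×800 px image with a
60 px margin by default — optionally Gaussian-blurred.  The PNG is always
accompanied by a plain-text `key=value` sidecar recording the geometry,
and the data↔pixel mapping is a single shared affine transform, so
overlays land on exactly the pixels the density renderer used (verified
to within one pixel).  Images produced elsewhere can be loaded too: with
no sidecar the defaults are assumed with a warning, mirroring the
metadata-editing workflow of the interactive view.

## Scoring solutions

For a candidate (*C*, *D*), each smoothed observation gets the distance
to its nearest grid node in normalised coordinates: depth differences in
units of `depth_scale` (default *D*/2, half a copy) and fraction
differences in units of `fraction_scale` (default 0.05).  The summary is
a trimmed mean (default trim 0.05) plus `fraction_explained`, the share
of observations within unit distance of some node.  The trim is applied
to the *upper* tail only: distances are bounded below by zero, and the
tail the score must resist — off-grid sub-clonal or boundary-mixed mass —
only inflates the top; that mass stays visible through
`fraction_explained`.  Scores operate on smoothed observations because
that is the object the eye compares.

`grid_search` evaluates an exhaustive (C, D) grid, ranked by mean
distance with a deterministic (lower C, lower D) tie-break, and returns
the *full* ranking: purity/ploidy aliasing — notably genome-halved or
-doubled solutions — produces genuine near-ties that must be surfaced for
human adjudication, not collapsed.  Node coordinates are cached per
solution, so scanning ~5,000 candidate pairs over thousands of loci takes
seconds per sample.  The score is a comparison aid, not an estimator with
stated uncertainty; likelihood-based or sub-clonal mixture fitting is a
non-goal.

## Synthetic data

The generator draws, per locus, a total depth (Poisson around the model
mean, or fixed) and a Binomial(depth, *p*) count for one *phased* allele,
with *p* the mixture-implied phased fraction; the recorded minor fraction
is min(*b*, *d* − *b*)/*d*.  Folding therefore *emerges* from the
generator rather than being injected, which makes the folded-expectation
correction a tested prediction.  Poisson depth is the minimal coverage
model: real coverage is overdispersed and locally biased (GC,
mappability), so passing tests demonstrate correctness of the machinery
under the stated model, not robustness to those artefacts.  Matched
normals are simulated as pure diploid at every candidate locus —
definitionally what germline-heterozygous means here.

SAM fixtures realise the same draws as reads (configurable length,
default 50 bp; qualities above the default filters), sorted by
coordinate with a proper header, plus the matching loci TSV.  Adjacent
loci must be at least one read length apart so each read covers exactly
one candidate site; this is what makes the scan ↔ simulation round-trip
exact, read for read.  Fixtures are capped at 10⁵ reads.

## Study designs used by the test suite

* **Phased balance**: 10,000 loci, state (1,1), pure sample, fixed depth
  40; the fixed-allele mean fraction is compared to 0.5 within three
  Monte-Carlo standard errors.
* **Parameter recovery**: 20 samples, each five segments of 1,000 loci
  with states (1,0), (1,1), (2,1), (2,2), (3,1); truths drawn on the
  search grid with *C* ∈ [0.3, 0.9], *D* ∈ [8, 20]; search over
  *C* ∈ [0.3, 0.95] step 0.01, *D* ∈ [5, 40] step 0.5.  The running
  *mean* (window 51) is used here because the score compares observations
  to expectation nodes, for which the mean is the unbiased smoother; the
  1,000-loci segments keep the share of state-mixing windows (~4%) within
  the score's 5% trim, preserving the window-to-segment ratio of the
  real-data regime the window-51 default was designed for.  With
  median smoothing or much shorter segments, recovery degrades toward
  low-cellularity dense-lattice solutions — a known limitation noted
  below.
* **Tetraploid vs impostor**: states (2,0), (2,1), (2,2), (3,1), (4,2) at
  *C* = 0.68, *D* = 15; the impostor (*C* = 0.81, *D* = 25.2) is the
  diploid reading forced by matching the balanced tetraploid row.  The
  generating solution must explain a larger share of observations and
  the impostor must leave at least two state modes uncovered (the
  odd-total states fall between its grid rows).

## Known limitations

* The score's chamfer-style distance intrinsically favours solutions with
  densely packed lattices (low *C* packs normalised depth rows at spacing
  2*C*); with noisy, short-segment inputs this can outrank the truth.
  The full ranking plus `fraction_explained` exposes such cases, and the
  interactive view exists precisely because automated ranking cannot be
  trusted blindly here.
* Median smoothing estimates the folded *median*, which sits slightly
  above the folded mean near balance at low depth; scoring pipelines
  should prefer mean smoothing.
* No GC/mappability/normal-polyploidy corrections; no indel handling; no
  genome-wide het discovery; no CRAM reference management beyond passing
  a path through; chromosome-level colouring and gene annotation are out
  of scope.
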