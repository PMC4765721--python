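# bafgrid

Visual and quantitative comparison of competing tumour purity/ploidy
solutions from whole-genome sequencing.

## The problem

Estimating the cellularity (tumour purity) and mean ploidy of a sequenced
tumour sample is a prerequisite for copy-number and sub-clonality
analyses, yet different estimators routinely return conflicting answers —
not because one is buggy, but because the problem is genuinely
under-determined: a hypo-diploid genome at high purity and a tetraploid
genome at lower purity can place their clonal copy-number states on very
similar positions in the data. `bafgrid` puts the data and the competing
explanations in one picture (and one score) so the conflict can be
adjudicated with biological knowledge of the tumour.

## The model

A sample is a mixture of tumour cells (fraction *C*) and normal diploid
cells.  For a region with *n₁* copies of one parental allele and *n₂* of
the other (*n₂* ≤ *n₁*), with *D* the sequencing depth contributed by a
single chromosomal copy:

```
depth                 = D · [2·(1 − C) + (n₁ + n₂)·C]
minor allele fraction = (1 + C·(n₂ − 1)) / (2 + C·(n₁ + n₂ − 2))
```

At germline-heterozygous loci the *minor* allele is chosen per locus
after observation, so sampled fractions above 0.5 reflect ("fold") below
it and the recorded mean drops beneath the prediction — most strongly at
low depth and near allelic balance.  `bafgrid` corrects each predicted
grid node by the exact folded expectation `E[min(X, d−X)]/d` with
`X ~ Binomial(d, f)`, computed by enumeration.

Each candidate (*C*, *D*) solution therefore predicts a lattice of
(depth, folded fraction) nodes.  The data — per-locus depth and minor
fraction at heterozygous sites, smoothed along the genome and rendered as
a 2D density — either sits on that lattice or leaves modes uncovered.

## Worked example

Simulate a broadly tetraploid genome (states 2+0, 2+1, 2+2, 3+1, 4+2;
1,000 loci each) at 68% cellularity and single-copy depth 15, render it,
and compare the generating solution with its classic "diploid impostor"
(the higher-purity reading that interprets the balanced tetraploid row as
diploid):

```bash
bafgrid simulate --profile prof.tsv --cellularity 0.68 --single-copy-depth 15 \
    --seed 7 --out obs.tsv
bafgrid plot --obs obs.tsv --window 51 --stat mean --out sample.png
bafgrid overlay --image sample.png --cellularity 0.68 --single-copy-depth 15 \
    --out overlay_truth.png
bafgrid score --obs obs.tsv --cellularity 0.68 --single-copy-depth 15
bafgrid score --obs obs.tsv --cellularity 0.81 --single-copy-depth 25.2
```

The scores print:

```
# C=0.68, D=15 (generating solution)
mean_distance       0.2640
fraction_explained  0.9888

# C=0.81, D=25.2 (diploid impostor)
mean_distance       0.7769
fraction_explained  0.6020
```

`mean_distance` is the trimmed mean distance of smoothed observations to
the nearest predicted node (in units of half a copy of depth and 5
fraction points); `fraction_explained` is the share of observations
within unit distance of some node.  The generating solution explains
~99% of the data; the impostor accounts for only ~60% — its grid has no
rows for the odd-total states — which is exactly the visual signature of
the purity/ploidy ambiguity.  An exhaustive search,

```bash
bafgrid search --obs obs.tsv --c-grid 0.5:0.9:0.02 --d-grid 10:30:0.5 \
    --out ranked.tsv
```

ranks (C=0.68, D=15.0) first.  `bafgrid app --image sample.png` opens the
same overlay with live sliders for *C* and *D*.

For real data, start from alignments instead:

```bash
bafgrid scan --tumour tumour.bam --normal normal.bam --loci loci.tsv --out obs.tsv
bafgrid scan-cellline --tumour cellline.bam --loci loci.tsv --out obs.tsv  # no normal
```

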