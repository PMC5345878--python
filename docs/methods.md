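# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic-data generator does and does not
emulate.

## Coordinates, anchors, conventions

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
and BED12 are converted at I/O only.  One canonical transcript
represents each gene: the transcript with the largest summed exon
length, ties broken by lexicographically smallest transcript id (the
annotation sources the analyses target say "canonical" without a rule,
so the package fixes one deterministically).

Splice-boundary anchors exist only at internal exon edges.  An
`intron_exon` (acceptor) anchor's position is the first exonic base in
transcript orientation — on the − strand that is the genomic *end* of
the exon — and an `exon_intron` (donor) anchor's position is the first
intronic base.  Profile matrices are strand-corrected so positive
offsets always point 5′→3′; off-chromosome positions are missing (NaN)
and excluded from means rather than zero-filled, which would bias genes
near contig edges.

Exon inclusion (PSI) classes are right-closed bins (0, 0.2], (0.2, 0.4],
(0.4, 0.6], (0.6, 1.0], with PSI = 0 folded into the lowest class.
Expression classes are: repressed (TPM < 0.1) plus rank tertiles of the
expressed genes; the sources name four classes without cutoffs, so the
0.1-TPM floor and tertile split are package choices, recorded in output
metadata by virtue of being deterministic defaults.  Signal-level
classes are rank quartiles of mean coverage in a scoring window: −75..−25
for TSS-level (the same window used for the TSS mean comparison) and
0..+150 into the exon for gene-body level (covering the 50–200 bp exon
range).  All rankings break ties by gene id, then input order, so every
partition is reproducible.

## Coverage and normalisation

Paired mates collapse to single spanning fragments (leftmost start to
rightmost end; discordant pairs skipped and counted; single-end
libraries fall back to a fixed 150-bp extension in read orientation).
Coverage at a base counts fragments containing it; fragments overhanging
a chromosome end are clipped, not dropped.  RPM = value × 10⁶ /
library size, where the library size is the number of fragments counted
(one pair = one unit).  Normalisation is a recorded state: re-applying
it, or normalising an empty library, is an error.  Tracks are dense
per-chromosome arrays — the intended genomes (toy, simulated, or small
model organisms' subsets) make density the simpler and faster choice;
the bedGraph interface leaves sparse backing open.

## The slope model

For each boundary *i* and offset *d*,

    r_i(d) = (ChIP window mean + ε) / (input window mean + ε)

with a 20-bp sliding window centred at *d* (truncated, not padded, at
matrix edges) and pseudocount ε = 0.1 RPM guarding zeros (the ratio's
zero-handling is otherwise undefined; 0.1 RPM is far below any signal of
interest).  At each offset, ordinary least squares fits
r = a + b·log₂(TPM + 1) across boundaries; the package reports b and its
OLS standard error, vectorised over offsets via the normal equations and
cross-checked against statsmodels on the same ratios.  Log base 2 is
used for expression and coverage throughout; the +1 keeps repressed
genes (TPM = 0) in the regression, at the cost of exact
scale-equivariance (which is recovered in the TPM ≫ 1 regime).

Positional correlation follows the same windowing logic: per 50-bp
window (non-overlapping by default), per-boundary mean coverage of each
track is log₂(x + ε)-transformed and Pearson-correlated across
boundaries; constant vectors give a missing value rather than a spurious
r.

The TSS-versus-boundary window comparison uses per-region mean coverage
and a two-sided Welch t-test by default (the comparison's source reports
a p-value without naming a test; Welch is the safe default for unequal
variances, and a Wilcoxon rank-sum alternative is available behind a
flag).

Positional gene-set enrichment ranks genes by mean coverage in 50-bp
windows stepped across the flank and applies a one-sided Wilcoxon
rank-sum per set (is the in-set rank distribution shifted upward?),
Benjamini–Hochberg corrected across all (window, set) pairs.  A
rank-based test was chosen over a permutation enrichment score because
the ranking statistic is the whole method here; sets with fewer than 5
joined genes are skipped.

Expression-matched subsampling bins the target set's log₂(TPM+1) into 20
quantile bins and draws, without replacement and under an explicit seed,
the same per-bin counts from the pool; a sparse bin borrows its
shortfall from the nearest bins with a warning.  The subset size always
equals the target size.

## RNA-IP processing

Control subtraction is per-base max(signal − control, 0) on RPM tracks;
clipping at zero keeps the result a valid coverage track (the
alternative, signed residuals, breaks every downstream profile
operation).  The ChIP-overlap statistic takes *raw* RNA-IP counts — the
≥ 30 reads-per-base cutoff is read support, not a rate — and measures,
within gene bodies plus 1-kb promoters, the base-level fraction of ChIP
fragment mass lying over qualifying bases.  Whether the analogous
published quantity counted reads or bases is ambiguous; base mode is the
default and a fragment-midpoint mode is available behind a flag.  The
statistic is monotone non-increasing in the cutoff in both modes.

## qChIP

2^(−ΔΔCt) with ΔCt = Ct_IP − Ct_input for the target amplicon minus the
same difference for a same-sample reference amplicon; enrichment is the
mean over replicate-level fold changes, with a standard deviation
reported from three replicates up.  The contract requires an explicit
reference amplicon per assay (equal-concentration library adjustment
alone does not pin down the reference; a same-sample amplicon is the
reproducible choice).

## The synthetic-data generator

The generator is the package's study system: it produces gene models,
expression, fragment libraries and CLIP reads with exactly the
statistical couplings the analyses are designed to detect, plus a truth
record sufficient to predict every expected profile.

**Genome.**  Genes with 3–7 exons; exon lengths lognormal with median
140 bp and σ = 0.2 (96% of exons fall in the 50–200 bp range typical of
mammalian internal exons), floored at 60 bp; introns lognormal median
650 bp, floored at 300 bp; 2-kb intergenic gaps on one toy chromosome.
Expression is a mixture: 20% repressed at TPM 0, the rest
TPM = 2^N(3, 1.5).  13.4% of internal exons are cassette, with inclusion
~ Beta(2, 2).

**Occupancy.**  Per track, per base:
λ(b) = exon-nucleosome kernels + intron plateaus (+ TSS kernel), with
every amplitude of the form max(intercept + slope·log₂(TPM+1), 0).  The
exonic nucleosome is a Gaussian (σ = 45 bp) centred at 60% of the exon
length from the acceptor — nearer the donor — so the acceptor-side
depleted region is the wider one; explicit multiplicative dips at both
splice sites (depth 0.6 acceptor / 0.3 donor, σ = 30 bp) sharpen the
depletion.  The activation-coupled variant track additionally carries a
TSS nucleosome at −50 bp and a multiplicative exclusion dip at +225 bp
(the +1 nucleosome it is kept out of).  Cassette-exon variant amplitude
can be multiplied by 1 + κ·(PSI − 0.5) to couple inclusion to occupancy
(κ = 0 by default: inclusion independent of chromatin).  Default
intercepts/slopes make the variant gain occupancy with expression (exon
0.5 + 0.4x, intron 0.3 + 0.1x) while input and the control variant lose
it (e.g. input exon 2.5 − 0.15x), with the negative slopes sized so
occupancy stays positive across the realistic x = log₂(TPM+1) range
(~0–9): transcription depletes nucleosomes, it does not eliminate them.
The small additive background (0.05) applies to intergenic bases only;
within genes the intron plateau is the baseline, which keeps the exonic
ChIP/input ratio an exact linear function of log expression.

**Sampling.**  Fragment centres are Poisson per base with intensity
λ·depth/mean length, so expected coverage ≈ λ·depth (default depth 60,
a deep MNase-ChIP-like coverage that keeps Monte-Carlo error small at
desk scale); centres jittered N(0, 20 bp), lengths N(147, 15) —
nucleosomal.  CLIP reads land on internal exons at rates ∝ TPM, centres
65 bp from the acceptor (σ = 15), footprints N(50, 8) truncated at the
exon edges (the captured RNA is spliced, so it maps exonically); the
control library is uniform background at 30% of the signal depth.
Everything is deterministic under the config seed, with independent
streams per track.

**What it does not emulate.**  Sequence content and mappability, PCR
duplicates, nucleosome phasing beyond the single exonic/TSS kernels,
isoform structure beyond one canonical transcript, chromatin-state
heterogeneity between cells, and any coupling between inclusion and
expression.  Passing recovery tests therefore demonstrates the
*statistical machinery* — that each estimator recovers the generating
parameter under its assumptions at realistic noise — not robustness to
alignment artefacts or biological confounds absent from the model.

## Recovery experiment design

The fitted ratio slope equals the generative exon/intron gain only under
three conditions, so the calibration experiments (`recovery_config`) set
them explicitly: an expression-flat unit input (otherwise the estimand
is a quotient of two expression couplings); plateau occupancy
(nucleosome width ≫ exon length, otherwise the kernel shape enters the
windowed ratio); and compartment-pure evaluation offsets.  The last
point is quantitative: coverage at offset *d* integrates fragments
centred within ±(length/2 + jitter) ≈ ±165 bp, so an offset must sit at
least that far inside its compartment.  With recovery exons of median
500 bp (min 420) and introns of median 900 bp (min 600), offsets
+180..+250 are purely exonic and −350..−200 purely intronic for every
boundary.  Under the default geometry (140-bp exons) the same fit
recovers ≈ 0.29 for a generative 0.4 — not an estimator error but
compartment mixing by the fragment footprint, the same attenuation a
real experiment with nucleosomal fragments and short exons would show.

Remaining small biases at the chosen depth: the Poisson denominator
gives the ratio a Jensen bias of order 1/(depth·occupancy) ≈ +2–3%, and
the ε-pseudocount an attenuation of order ε/depth ≈ −0.2%; both are well
inside the reported standard errors and vanish as depth grows.

Problem sizes used by the test suite and acceptance script — 300–800
genes, 60× coverage, 10⁵ CLIP reads, 5–20 seeds per experiment — were
chosen so each recovery statistic's Monte-Carlo error is several times
smaller than its acceptance tolerance.

## Numerical details and degenerate inputs

* Sliding windows truncate at matrix edges (never pad), and all-missing
  windows stay missing.
* 95% bands are pointwise normal approximations (mean ± 1.96·SEM); with
  hundreds of rows per profile the normal and bootstrap bands are
  indistinguishable and the former is deterministic.
* Metagene bins weight partial bases by fractional overlap via the
  interval's cumulative integral — exact for per-base-constant tracks —
  so a 50-bp and a 500-bp exon contribute identically.
* Heat-map rank groups differ in size by at most one, earlier groups
  taking the remainder; ranking is by decreasing key.
* Pearson r over a constant vector, OLS through fewer than 3 points or
  zero-variance expression, empty anchor/region/gene-set inputs, and
  double RPM normalisation are all errors or missing values, never
  silent numbers.
* Expression ratios use ε = 0.01 TPM, so two silent genes give exactly
  1.0 rather than 0/0.

## Known limitations

Dense tracks bound the practical genome size (a few hundred Mb per
process).  The slope model assumes a common pseudocount scale for ChIP
and input; strongly unbalanced library sizes shift the ratio's units
(not its sign or ordering).  The GSEA stage tests location shift only,
not redundancy among overlapping sets.  Boundary profiles pool both
strands after orientation; strand-specific effects would need a split
the interface already permits but no operation performs.
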