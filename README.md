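# metachrom

Landmark-anchored chromatin profile analysis for histone-variant
ChIP-seq, written for the question: *how does a variant's occupancy
around transcription start sites and splice boundaries relate to
expression and exon inclusion?*  The motivating system is a short H2A
variant (H2A.B-class) that is gained on active genes — fastest on exons
— while a repression-associated variant (H2A.Z-class) is lost, and that
additionally binds spliced RNA near intron–exon boundaries.  The package
is aimed at computational genomicists who want these analyses as tested,
reusable functions rather than one-off notebook code, and every stage can
be exercised against a built-in synthetic-data generator with known
ground truth, so nothing requires downloading sequencing data.

## What it computes

Given gene models (GTF/BED12), paired-end-derived fragment intervals
(BED) for ChIP, input and RNA-IP/CLIP libraries, a per-gene expression
table (TPM) and cassette-exon calls (PSI):

* **Coverage** — per-base fragment coverage tracks, RPM-normalised
  (value × 10⁶ / library size), read/written as bedGraph.
* **Anchored profiles** — strand-oriented signal matrices around the
  TSS, intron–exon (splice acceptor) or exon–intron (donor) boundaries;
  mean profiles with pointwise 95% bands; expression / signal-level /
  PSI stratification; 0–1 scaled exon metagenes; 100-group rank
  heat-map matrices.
* **Slope model** — at every offset *d* from the boundary, the OLS fit

  r_i(d) = a(d) + b(d) · log₂(TPM_i + 1)

  where r_i(d) is the ChIP/input ratio of 20-bp sliding-window mean
  coverage (pseudocount ε = 0.1) for boundary *i*.  b(d) > 0 on exons and
  smaller on introns means exons gain the variant faster upon activation.
* **Positional correlation** — Pearson r of log₂ window-mean coverage
  (50-bp windows) between two tracks, per position.
* **Matched subsampling** — a constitutive-exon subset matching the
  cassette set's log-expression distribution (20 quantile bins, seeded,
  without replacement), for confound-free class comparisons.
* **RNA-IP tools** — per-base control subtraction max(signal − control, 0)
  on RPM tracks, boundary-anchored RNA profiles with peak offsets, and
  the fraction of ChIP signal over gene bodies + promoters (−1000 bp)
  lying under RNA-IP coverage ≥ 30 raw reads per base.
* **Positional gene-set enrichment** — genes ranked by mean coverage in
  50-bp windows stepped across ±1 kb of the TSS, one-sided Wilcoxon
  rank-sum per set, BH-corrected over (window × set).
* **Expression utilities** — TPM, gene-family pool fractions (e.g. what
  percent of the H2A transcript pool a subtype holds), tissue expression
  ratios, and the qChIP 2^(−ΔΔCt) fold-enrichment calculator.
* **Synthetic data** — toy genomes with positioned exonic nucleosomes,
  occupancy linearly coupled to log₂(TPM+1) per track, splice-site
  depletion, a −50 bp TSS nucleosome with +1 exclusion, Poisson fragment
  sampling, and exon-restricted CLIP reads peaking 65 bp inside the
  exon.  See `docs/methods.md` for the model.

## Worked example

Simulate a small study and fit the slope model, entirely from the shell:

```sh
cat > sim.yaml <<EOF
seed: 4
n_genes: 80
depth: 30.0
clip_reads: 20000
EOF
metachrom simulate --config sim.yaml --out .
metachrom coverage --fragments variant.bed --chrom-sizes chrom.sizes --rpm --out variant.bedgraph
metachrom coverage --fragments input.bed   --chrom-sizes chrom.sizes --rpm --out input.bedgraph
metachrom slope --chip variant.bedgraph --input input.bedgraph \
    --chrom-sizes chrom.sizes --genes genes.bed12 --expression expression.tsv \
    --upstream 300 --downstream 200 --out slope.tsv
```

Selected rows of `slope.tsv` (offset 0 is the first exonic base of each
intron–exon boundary; 327 boundaries fitted):

```text
offset  slope   stderr  n
-150    0.2529  0.0101  327
-50     0.2513  0.0111  327
0       0.3144  0.0119  327
30      0.3655  0.0119  327
100     0.3935  0.0157  327
```

The slope rises from ~0.25 in the intron to ~0.39 over the exon body:
per unit log₂ expression, exons gain variant signal (relative to input)
faster than flanking introns — the generator's exon/intron gains are
0.4/0.1, attenuated at any one offset by fragment-footprint mixing
between compartments.  The RNA-IP stage on the same simulation

```sh
metachrom rnaip --signal clip_signal.bed --control clip_control.bed \
    --chip variant.bed --chrom-sizes chrom.sizes --genes genes.bed12 \
    --min-cov 10 --out-prefix rnaip
```

reports `"peak_offset": 65` — the control-subtracted RNA profile peaks
65 bp inside the exon from the acceptor, where the generator put it —
and an `overlap_fraction` of 0.076, the share of in-region ChIP signal
lying under well-supported RNA at this depth.

Other subcommands: `profile`, `metagene`, `heatmap`, `correlate`,
`subsample`, `gsea`, `qchip`, `tpm` (see `metachrom --help`).

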