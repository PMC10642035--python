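# Methods

## Arm chemistry and the unmixing model

Every sequencing arm is modelled by three probabilities: `a_C` (an
unmodified cytosine appears modified; one minus the conversion efficiency),
`a_mC` and `a_hmC` (retention of mC and hmC).  The apparent modified
fraction at a site with true composition `(f_C, f_mC, f_hmC)` is the linear
mixture `f_C·a_C + f_mC·a_mC + f_hmC·a_hmC`.  Default rates — BS:
(0.005, 0.98, 0.95); oxBS: (0.005, 0.98, 0.05); TET+: (0.005, 0.98, 0.95);
TET−: (0.005, 0.005, 0.95) — describe near-complete conversion of
unmodified C with slight under-retention of the modified bases, the regime
reported for spike-in QC of these chemistries.  All are configurable.

Conversion correction solves the two-arm 2×2 linear system for
`(f_mC, f_hmC)` given spike-in-estimated rates.  It is the unique linear
inversion consistent with the three-state chemistry; with identity rates it
reduces to plain subtraction.  Out-of-simplex solutions are clamped and
flagged, with the raw values preserved.  Corrected values are reported
alongside raw ones, never silently substituted.

## Subtraction estimates and clamping

Per-site hmC (BS − oxBS) or mC (TET+ − TET−) can be negative by sampling
noise.  Per-site output clamps negatives to zero for reporting but keeps the
raw difference in a diagnostic column.  Genome-wide hmC is computed from
aggregate arm levels (`genome_level(BS) − genome_level(oxBS)`), where
negative site noise cancels; averaging clamped site values would bias low-hmC
contexts (hmCH in particular) upward.  This is why the hmCH background study
reports values of order 0.01% rather than a positive clamping artefact.

## Tiled differential calling

Windows are 1000 bp, non-overlapping, final partial tile retained.  Windows
must be covered in all samples for count-based calling (mCG/mCH) and in at
least two samples per arm for subtraction-based calling (hmCG).

* **Count-based test.**  With group as the only covariate, the binomial GLM
  maximum-likelihood fits are the group-pooled proportions, so the
  likelihood-ratio statistic has the closed form of a two-group G-statistic
  against the pooled null; p from χ²(1).  No overdispersion correction is
  applied (matching the default replicate test of tiled bisulfite counts);
  the suite cross-checks the statistic against an independently fitted
  binomial GLM.  Group levels and the reported difference are
  coverage-weighted pooled proportions.
* **Subtraction-based test.**  Per-sample window hmC = BS − oxBS window
  level; two-sample pooled-variance Student t across replicates (Welch
  optional).  Identical groups (zero variance, zero difference) are defined
  as p = 1.
* **q-values.**  Step-up `q_i = min(p_i·N/rank_i, q_{i+1})`, equal to
  Benjamini–Hochberg on every input (tested against an independent
  implementation).  Ties share the step-up minimum through a stable sort.
  For the hmCG caller, q is computed over **all** windows tested within a
  comparison and the |Δ| ≥ 5 pp, p ≤ 0.05, q ≤ 0.05 filters are then
  applied.  Computing q only within the effect-size-filtered windows was
  evaluated and rejected: the ≥5 pp filter selects for extreme t statistics,
  and at the planted-power study's conditions that ordering yields an
  empirical FDR near 0.5 instead of the nominal 0.05 level.

## Feature assignment and enrichment

Each region resolves to exactly one label via priority: promoter tiers
(≤1 kb, 1–2 kb, 2–3 kb upstream of the nearest TSS, strand-oriented) >
5′UTR > 3′UTR > 1st exon > other exon > 1st intron > other intron >
downstream (≤300 bp) > distal intergenic.  Assignment uses the interval
midpoint by default (an any-overlap mode exists behind a flag); the
partition property (per-feature counts sum to the region total) is what
makes the contingency tables well-defined.  Log odds `ln((a·d)/(c·b))` get
a Haldane–Anscombe +0.5 on all cells only when a zero in b, c or d would
make the estimate infinite; `a = 0` is reported as `n.d.` with no estimate.
The Woolf CI uses the (possibly corrected) cells; Fisher's two-sided exact
p (point-probability convention) uses the raw table.

## Profiles, tertiles, and group tests

Metagene profiles use 4 kb flanks in 20 bins of 200 nt and a gene body
rescaled to 27 equal-width bins per gene (genes shorter than 27 nt are
dropped and counted) — the only reading of a fixed-length profile over
variable-length genes.  Bin values are coverage-weighted within a gene and
averaged unweighted across genes, so each gene counts equally.  Expression
classes: genes with zero counts in every sample are unexpressed; the rest
are ranked by mean count and cut into three equal tertiles, remainders going
to the higher tertiles ({4,3,3} for ten genes), ties broken by stable
gene-id order.  Region averages (upstream −4 kb..TSS, body, downstream
TES..+4 kb) are pooled coverage-weighted levels per replicate.  Group tests:
paired two-tailed t for the two-fraction design; a group × region cell-means
fit with single pooled residual variance and Sidak-corrected
(`1−(1−p)^m`, m = all contrasts computed) pairwise contrasts for the
multi-group design; the targeted-region (EM-seq) per-CpG test uses the same
pooled-variance construction over position × cell-type cells, Sidak over
positions.

## The synthetic-data generator

The generator emulates the statistical structure of cell-type-resolved
brain WGoxBS data, not its sequence content:

* **Layout.**  One data chromosome (default 10 Mb; the validation studies
  use 5 Mb), 250 non-overlapping genes of 5–30 kb with exon/intron/CDS
  structure, and non-overlapping repeat intervals whose per-class genome
  fractions (LINE 0.15, SINE 0.10, LTR 0.10, Simple_repeat 0.05) are
  realised exactly by construction.  CpG site density 0.03/bp, CH 0.10/bp —
  scaled-down but order-realistic densities that keep run times in seconds.
* **Levels.**  Genome-wide truths per cell type default to the three-cell
  ordering of brain data: mCG 0.70/0.76/0.80 and hmCG 0.22/0.15/0.10 for
  neuron/astrocyte/microglia, mCH 1.46/0.85/0.67 % with simple-repeat mCH
  2.51/1.54/1.17 % and hmCH 0.  Site values are Dirichlet draws on the
  (C, mC, hmC) simplex with concentration 0.8 for CpG (bimodal, as real
  CpG methylomes are) and 60 for CH; Dirichlet sampling preserves the
  configured means exactly, and a renormalisation pass keeps genome-wide
  means on target in the presence of genic/repeat multipliers.
* **Genic structure.**  A TSS-proximal dip (×0.3 over −2 kb..+500 nt),
  promoter and gene-body couplings to expression tier (promoter/body mCG
  inverse; gene-body hmCG positive; mCH inverse, applied to the neuron
  configuration only), and repeat-class multipliers.  Planted differential
  windows override the landscape with constant levels on tile boundaries, so
  the planted group difference is exact by construction.
* **Sequencing.**  Per site, coverage ~ Poisson(mean), modified ~
  Binomial(coverage, apparent probability) under the arm's rates; spike-in
  contigs carry 200 positions per C/mC/hmC class at 50× for rate estimation.
  Expression counts are negative binomial (size 20) around tier centres
  2000/200/20 with per-gene log-normal spread (σ=0.3); unexpressed genes
  emit exact zeros.

What the generator does **not** model: read-level data, sequence
composition, mapping artefacts, PCR duplicates, within-sample coverage
autocorrelation, overdispersion between biological replicates of count
data, and hemimethylation asymmetry between strands.  Passing tests
therefore demonstrate correctness of the estimators and calibration of the
statistics under the declared generative model, not robustness to alignment
or library artefacts in real data.

## Validation studies (problem sizes and expectations)

* **Sparse-coverage accuracy.**  A 5 Mb CG landscape (~150k sites, genome
  mean 0.75) at 30× is binomially thinned so retained total calls equal
  0.001 × genome length (~5000 calls), 100 thinning seeds.  The median
  absolute error of the genome-wide level is ~0.4 pp.  The error SD is
  √(p̄(1−p̄)/K) ≈ 0.61 pp — each retained call is a Bernoulli(p̄) draw
  whatever the site-level distribution — so ~90% of draws land within 1 pp
  at this desk scale; at a full-genome call count (~50k CpG calls at the
  same depth) the same estimator is within 1 pp essentially always.
* **hmCH background.**  CH arms for 4 replicates at 2× with true hmCH = 0
  and the default conversion errors: the replicate-averaged BS−oxBS genome
  level is ≈0.01%, far below 1% — identical error rates in the two arms
  cancel exactly in expectation.
* **mCH recovery.**  The neuron-configured simulation (genome 1.46%,
  simple-repeat 2.51%) is sequenced as an oxBS CH arm with ideal conversion
  chemistry and recovered by `genome_level` and `repeat_summary` to within
  ~0.05 pp.  Ideal chemistry isolates estimator recovery from conversion
  bias: with a 0.5% false-modification rate the raw oxBS level is higher by
  ~0.5 pp by construction of the chemistry, which is what the spike-in
  correction exists to remove.
* **Null calibration.**  500 replicates of an 8-sample, 200-window global
  null give rejected-window fractions ≪ 0.05 for both callers.
* **Planted power.**  20 pp hmCG differences in 10 of 1000 windows (n=4 per
  group, replicate noise SD 3 pp) are recovered with sensitivity ≈ 1 and
  FDR ≈ 0 at the standard thresholds.
* **Expression couplings.**  A full loop (landscape → expression counts →
  tertile classification → region averages on simulated arms) reproduces
  the expected tertile orderings: highest-expression tertile has the lowest
  promoter mCG, the highest gene-body hmCG, and the lowest gene-body mCH in
  the neuron configuration.  Asserted as orderings, not effect sizes.

## Numerical and degenerate-case choices

Counts reconstructed from percent columns round half up.  Call-table keys
are strand-specific; CpG destranding (merging dyads onto the plus-strand
coordinate) is available but off by default.  Duplicate keys with identical
rows collapse on read; conflicting duplicates raise rather than merge
silently.  Zero-coverage sites are not emitted by the simulator and make a
window's group untestable (skipped and counted).  `manual_q` caps q at 1.
The LRT log-likelihood kernel defines 0·log 0 = 0 so boundary proportions
are exact.  Intervals are 0-based half-open everywhere; call positions are
1-based; touching intervals are treated as disjoint.
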