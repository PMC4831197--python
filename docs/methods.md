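# Methods

## Assay model

Direct bisulphite Sanger sequencing reads the pooled PCR product of
bisulphite-converted genomic DNA. On the converted top strand every
unmethylated cytosine appears as T and every 5-methylcytosine as C, so a CpG
cytosine in a mixed cell population produces superimposed C and T peaks whose
heights are proportional to the methylated and unmethylated molecule
fractions. A reverse sequencing primer reads the complement of that strand,
so the same site appears as a G/A mixture and every converted non-CpG
cytosine as A. `bstrace.reference` builds this expectation explicitly: the
forward template replaces non-CpG C with T and CpG C with the IUPAC code Y;
the reverse template is its reverse complement, with R at CpG-derived
positions. Only the top-strand CpG cytosine is profiled; bottom-strand CpG
methylation is out of scope. Coordinates are 0-based and TSS-relative
(`position − tss_offset`, negative = upstream, counted from the C of the
dinucleotide).

## Quantification procedure

1. **Alignment.** The trace's called bases are globally aligned to the
   converted template (match +1, mismatch −1, linear gap −2; Y/R score as
   full matches against either allele). Identity — full-match columns over
   template length — below 0.8 rejects the trace. Alignment is delegated to
   Biopython's `PairwiseAligner` with a custom substitution matrix; the test
   suite checks the reached score against an independent exhaustive
   enumeration of the global-alignment graph on toy templates.
2. **Peak heights.** The height of a channel at a base is the maximum
   intensity within a half-spacing window around the called peak position
   (spacing estimated as the median inter-peak distance). Heights are never
   normalised across channels: only within-position ratios are used.
3. **Calling.** At a mapped CpG, `m = h_meth / (h_meth + h_unmeth)` with
   channels (C, T) forward and (G, A) reverse. If the minor peak is below
   10 % of the major (configurable `homogeneity_threshold`), the population
   is homogeneous and m is exactly 0 or 1. If both channels fall below 5 % of
   the trace's median called-peak height (`signal_floor_frac`) the call fails
   QC; unmapped sites are missing. Missing values are propagated, never
   imputed.
4. **Binning.** The published five intervals "0–0.2, 0.21–0.4, 0.41–0.6,
   0.61–0.8, 0.81–1" leave two-decimal display gaps; they are implemented as
   contiguous half-open bins (0, 0.2], (0.2, 0.4], …, (0.8, 1] with 0 in
   bin 1. An exhaustive 1e-3 grid test pins this closure and monotonicity.
5. **Conversion QC.** Every aligned non-CpG reference cytosine is scored
   converted iff its unconverted channel (C forward / G reverse) stays below
   the single-peak threshold relative to the converted channel. Efficiency
   below 0.95 (configurable) excludes the trace from profiles, with a logged
   reason. Templates without non-CpG cytosines make the QC not assessable
   rather than silently passing.

## Group statistics

Per-CpG comparisons use the tie-corrected Kruskal–Wallis H
(`1 − Σ(t³−t)/(N³−N)` correction) on raw proportions — the five-level bins
are presentational only. The χ² p-value (df = k−1) is reported always, but
with total N ≤ 10 the exact permutation p (full enumeration of group
assignments, ranks computed once on the pooled sample) is the significance
source: with three replicates per group the χ² approximation is poor and the
exact null is strongly discrete. All-identical inputs are defined as H = 0,
p = 1, avoiding the degenerate tie correction. No multiple-testing correction
is applied across CpGs; flags are raw p < α = 0.05 and the output notes this.

Contrast modes: `overall` (all groups jointly), `pooled` (control vs. all
other samples pooled) and `pairwise` (control vs. each group). The discrete
exact null makes the choice consequential at typical design sizes:

- 2 groups of 3 (N = 6): the smallest attainable p is 2/20 = 0.1, so **no
  pairwise 3 vs 3 contrast can ever reach p < 0.05** — the honest behaviour
  of an exact test, verified by the type-I-error test, whose null rejection
  rate is exactly 0.
- 3 groups of 3 (N = 9, `overall`): minimum p = 6/1680 ≈ 0.004, but when
  both treatment groups carry the same effect the two treated blocks
  interleave at random and only the more extreme interleavings reach
  p < 0.05 (per-site power ≈ 0.4 under complete separation).
- control (3) vs. pooled treatments (6): complete separation always attains
  H = 5.4, p = 2/84 ≈ 0.024, giving per-site power ≈ 1 and a null
  false-positive rate of 4/84 ≈ 0.048.

For this reason the power demonstration and the worked example use the
`pooled` contrast; both modes remain available because which contrast a given
study intends is a design decision, not a property of the data.

Concordance with pyrosequencing is ordinary least squares on paired
percentages (trace estimate ×100 vs. pyro percent): slope, intercept and
R² = 1 − SS_res/SS_tot; constant inputs are reported not-assessable.

## Synthetic traces

The simulator emulates the bulk-mixture physics that makes peak-height ratios
meaningful, not a particular instrument. At each template position the four
channels carry one Gaussian peak (width `peak_sd`, default 2.5 samples;
spacing 12 samples per base; pure-base amplitude 100) whose amplitude is
proportional to the population base fraction: `m` / `1−m` on the CpG channels
and pure base elsewhere. Peaks are truncated at half the base spacing, so
neighbouring bases contribute nothing inside each other's measurement window
and the ratio estimator is exact in the noiseless limit — this is what makes
the noiseless-inversion test meaningful to 1e-9. Additive Gaussian channel
noise (`noise_sd`, in amplitude units; 5 = 5 % of a pure peak is used as
"moderate" in tests) is clipped at zero to keep intensities non-negative.
Called bases are the argmax channel at each peak (ties broken in A,C,G,T
order).

Conversion failures are drawn per non-CpG-C position as Bernoulli events that
render the position fully unconverted; the expected converted fraction is
therefore `1 − conversion_failure_rate` and the QC's efficiency estimate is a
binomial proportion, which the tests check against 3σ bounds. Group designs
add per-group (optionally per-CpG) offsets to the baseline methylation,
clipped to [0, 1] with a logged warning; one seeded generator drives the whole
experiment, so identical seed + design is bit-reproducible. Default design
sizes — three biological replicates per group, a control plus two knockdown
groups with +0.4 methylation at 7 of 10 promoter CpGs on a 0.2 baseline —
mirror the knockdown experiment this pipeline is built around.

What the simulator does **not** model: dye blobs, mobility shifts, baseline
drift, basecaller quality scores, inter-channel cross-talk, PCR amplification
bias, or per-molecule (clonal) bisulphite patterns. Passing tests therefore
show the estimator inverts its own forward model and behaves sanely under
additive noise and conversion failure; they cannot certify accuracy on traces
whose artefacts fall outside that model — real chromatograms should always be
checked against the conversion QC and alignment-identity diagnostics, and
ideally an orthogonal assay.

## Numerical and design notes

- Binning uses a small (1e-9) guard when mapping proportions to levels so
  exact interval boundaries (0.2, 0.4, …) land in the lower bin despite
  floating-point representation.
- Exact permutation p-values count assignments with `H ≥ H_obs − 1e-12`;
  ranks are computed once on the pooled sample so ties are treated
  identically in every permutation.
- The lollipop SVG is assembled as plain text (no plotting library) because
  the renderer is specified to be a pure function: the same profile must give
  byte-identical documents. Circles are equally spaced with TSS-relative
  positions as labels; the default palette is a five-step white→black
  gradient, configurable.
- Profile TSVs serialise proportions at 4 decimals; export → import
  round-trips exactly at that precision. BED export (0-based, half-open, one
  row per CpG C) requires a genomic anchor and refuses otherwise.
- The pipeline validates its whole config — including that every referenced
  group label is defined — before any computation, and tags stage failures in
  the run log.

## Problem sizes

Tests and the acceptance script run desk-scale designs: a 70-bp, 10-CpG
synthetic promoter; 50 traces per truth on an 11-point recovery grid; 2000
null replicates for the type-I check; 10 seeds for the power summary. These
sizes give Monte-Carlo errors well inside the asserted bounds (e.g. binomial
SE ≈ 0.005 on the type-I rate) while keeping the full suite in the
tens-of-seconds range.
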