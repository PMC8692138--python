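# Methods

This note records the models the package implements, the defaults and
why, what the simulator does and does not emulate, and the numerical
choices a maintainer would want to know about.  It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Depth model and simulator

Window read counts are negative binomial with mean
`μ_w = d · g(GC_w) · (π·c_w + 1 − π)` and variance `μ + φμ²`, where `d`
is the mean depth per window (default 500 in the pipeline, 1000 in
focused simulations), `g` the GC bias curve, `π` the tumor purity
(default 1.0 — the mouse tumors' purity is not known, so the parameter
is exposed but not paper-derived), `c_w` the local copy ratio from the
implanted truth and `φ` the dispersion (default 0.005–0.01; `φ = 0`
gives the Poisson limit).  The negative binomial is the standard
over-dispersion model for WGS depth.  The default GC curve is quadratic,
peaking at GC 0.45 and floored at 0.2 — the canonical unimodal bias
shape, chosen so the GC-correction step has something real to undo.
Window GC fractions are drawn once per simulation from a clipped
normal (0.45 ± 0.06) and shared between tumor and normal.

The simulator emulates: GC-coupled coverage bias, over-dispersion,
purity dilution, implanted amp/del segments, mutation tables whose
predictor scores encode a known deleterious fraction, and cohort
profiles drawn from known category frequencies.  It does **not**
emulate read-level artifacts (mappability, alignment error), mutational
signatures, subclonal structure, or the correlated noise of real
sequencing; passing tests therefore demonstrate correctness of the
algorithms under the stated statistical model, not performance on real
libraries.  Hidden truth (implanted segments, intended deleterious
labels, true categories) is returned as separate sidecar objects and
never written into the primary tables, so a pipeline cannot leak it.

Cohort generation is constructed to be the exact inverse of the
classifier: inactivation events always hit both alleles (homozygous
deletion; het-loss plus deleterious mutation; two distinct deleterious
mutations), pathway activation uses PTEN inactivation or a hotspot, and
tumors outside a predicate's category carry nothing that could satisfy
it under either classifier mode.  Benign decoys (het-loss-only TP53,
synonymous driver changes, a non-hotspot PIK3CA change) are sprinkled
in to keep the classifier honest.  Background genes alter independently
at a per-gene rate (default 0.02–0.05) and never touch classification.

## CNV calling

*Normalization.*  Counts get a 0.5 pseudo-count (at raw-count scale,
where it is negligible against realistic depths but keeps log2 finite),
are divided by the median count of their GC bin (bin width 0.01), then
by the genome-wide median of that ratio, so normalized medians are
exactly 1.  Bins holding fewer than `min_bin_count = 10` windows fall
back to the genome-wide median divisor: a sparse bin's median is
dominated by the very windows being corrected, and dividing an
amplified window by itself erases real signal.  At genome scale
(thousands of windows per bin) the guard never fires.  Median-per-bin
was chosen over LOESS for determinism and testability.  Windows whose
raw normal count is below `min_normal_count = 5` are masked and excluded
from segmentation and from the MAD context.

*Segmentation.*  CBS works per chromosome on the unmasked log2 ratios.
For a stretch of `n` windows the candidate statistic over a circular
arc `x[i:j]` of length `k` is `|mean(arc) − mean(complement)| ·
√(k(n−k)/n)` — the known-variance standardized mean difference, whose
permutation p-value is scale-invariant so no variance estimate is
needed.  Arc lengths are bounded by `min_width = 3 ≤ k ≤ n − min_width`.
Arcs ending exactly at the right boundary with `i > 0` are skipped:
they define the same single change point as the complementary
left-anchored arc and differ only by float round-off (this also fixes
the tie-break, which is leftmost `i`, then shortest arc).  The maximal
candidate is accepted when its permutation p-value
`(1 + #{perm ≥ obs}) / (1 + B)` over `B` seeded shuffles (default 1000,
warning below 100) is `< α` (default 0.01); permutations stop early
once `p ≥ α` is guaranteed, which cannot change the decision.  Accepted
splits recurse on the resulting pieces; final segments tile the
unmasked windows and carry their mean ratio.

*Calling.*  The context is the global median and the unscaled MAD
(`median(|x − median(x)|)`, no 1.4826 consistency factor) of all
unmasked ratios, computed after masking.  A segment is `amp` when its
mean exceeds the median by strictly more than `multiplier × MAD`
(default 3) and `del` symmetrically; exact ties stay neutral.  With
constant data MAD is 0 and every segment equals the median, so nothing
is called.  Genes become CNA/CND records on ≥ 1 bp overlap with a
labelled segment; a gene spanning both an amp and a del segment is
reported under both classes with an ambiguity flag.  Coordinates are
0-based half-open throughout; SEG output converts to that format's
1-based inclusive convention.  Sex chromosomes are not special-cased.

## Mutation consensus

Predictor thresholds are the tools' published defaults — SIFT < 0.05
(strict), PolyPhen-2 ≥ 0.446 ("possibly damaging", inclusive), PROVEAN
≤ −2.5 — none being stated in the source analysis.  The default
consensus is SIFT ∧ PolyPhen, the pair named for the headline
deleterious counts; PROVEAN joins only in the `any` and
`majority_of_available` modes.  Truncating variants (nonsense,
frameshift) are deleterious regardless of scores; synonymous records
never are; a missing score drops that predictor from the vote, and a
missense record with no usable score is non-deleterious with a logged
warning.  Per-tumor summaries report means rounded half-up to one
decimal and `SEM = sd/√n` with the sample standard deviation.

## Genotype classification

Both readings of "functionally inactivated" ship because the source
analysis does not fully pin one down: `biallelic` (default — complete
functional loss: homozygous deletion, or het-loss plus a deleterious
mutation, or two distinct deleterious mutations) and `any_hit`
(dominant-negative reading: homozygous deletion or any single
deleterious mutation).  Heterozygous loss alone never qualifies in
either mode.  The hotspot set is exactly PIK3CA:H1047R, PIK3CA:E545K
and AKT1:E17K, configurable; unknown protein changes in hotspot genes
are ignored with a debug log entry.  Copy-number vocabulary follows the
discrete five-state convention of public cancer-genomics portals
(`homdel, hetloss, neutral, gain, amp`).  Categories compose the two
predicates; every tumor receives exactly one label.

## Cross-species comparison

The human inclusion rules: a CNV gene counts only when altered in ≥ 2
tumors (a curb on the sheer number of human CNV genes — deliberately
not applied to the mouse side, where the threshold is 1); CNA requires
whole-gene amplification (gene-level discrete states are treated as
whole-gene; an explicit `whole_gene=False` column excludes partial
events); CND genes must be longer than 1000 bp, a rule applied to the
human side only.  Ortholog mapping canonicalizes mouse symbols to
Title-case and human to UPPER-case, with explicit pairs overriding; a
mouse gene without an ortholog stays in the denominator and can never
be common.  The report percentage is `100·|common|/mouse_total`,
rounded half-up to one decimal.  Event rates are compared with Welch's
t-test (zero-variance inputs short-circuit to exact equality), and
over-representation uses the one-sided hypergeometric tail with
Benjamini-Hochberg q-values, skipping sets with fewer than 2 list hits.

## Rounding

Printed percentages and one-decimal means use round-half-up (via
`decimal`), not banker's rounding, so reported tables are stable and
reproducible across platforms.  Raw (unrounded) means are carried
alongside rounded ones everywhere.

## Problem sizes

The test suite and acceptance script run on deliberately small
problems chosen as the package's own desk-scale conditions: toy
genomes of 1–2 chromosomes of 120–600 kb with 1 kb windows, 3–8 mouse
tumors, cohorts of 80–2000 tumors, CBS with 150–300 permutations in
simulations (1000 by default in the API), 100 recovery and 50 null
replicates for the caller, and a 20-gene universe for exhaustive
hypergeometric enumeration.  The CBS permutation test is O(n²) per
scan, so desk-scale chromosomes keep full runs to seconds while
exercising every code path; nothing in the algorithms depends on these
sizes.

## Known limitations

No allele-specific copy number, purity/ploidy estimation, BAM/FASTQ
processing, germline filtering, or real predictor execution — scores
are inputs.  The CBS variant implements the classic permutation-tested
recursion without the pruning/undo heuristics of mature R
implementations, so very long chromosomes (≫10⁴ windows) would be
slow.  The over-representation test is a generic hypergeometric, not
the modified EASE statistic of annotation servers, and ships with no
ontology databases.
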