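# Methods

`clonecnv` implements the discovery-and-validation workflow for de novo
copy-number variants (CNVs) and copy-neutral loss of heterozygosity
(LOH) in genomes cloned from a single nuclear donor: the donor is the
hybridization reference, so any CNV called in a clone is by construction
a post-cloning (de novo) event. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not emulate.

## Coordinates

Internally every interval is 0-based half-open `[start, end)` and its
length is `end - start`. Report writers print 1-based inclusive starts
(`start + 1`) with the end unchanged and the length still equal to the
half-open span. Published CNV tables in this field are frequently
internally inconsistent about whether `length = end - start` or
`end - start + 1`; this package standardizes on `end - start`
throughout, and treats a printed coordinate pair `(a, b)` as spanning
`b - a` bases.

## aCGH segmentation and CNV calling

Probe-level log2(test/reference) ratios are modeled as Gaussian noise
around segment means `log2(c_clone / c_baseline)`; the baseline copy
number is 2 unless configured otherwise per chromosome (a male X/Y can
be set to 1).

The segmenter is a recursive rank-based procedure applied independently
to each contiguous probe run (runs break wherever adjacent probes are
more than `max_gap = 1 Mb` apart, an array-design artifact rather than
biology). At each recursion step the ranks of the log2 ratios within
the current run are scanned over all candidate arcs `[i, j)` — the
single-breakpoint configurations `i = 0` and `j = n` included — and a
Mann-Whitney rank-sum z statistic compares the arc against the rest of
the run. The best arc (largest |z|; leftmost on ties, for determinism)
is accepted as a split when its Bonferroni-adjusted two-sided p-value is
≤ `alpha = 1e-6`, and the procedure recurses into the resulting two or
three children. P-values are exact (the full permutation distribution
of the rank sum, via `scipy.stats.mannwhitneyu`) for tie-free runs below
50 probes, and the normal approximation with tie correction otherwise;
Monte Carlo permutation is deliberately not used because it cannot
resolve p-values near 1e-6 at any affordable iteration count.

Scanning arcs rather than single breakpoints is essential, not
cosmetic: for a k-probe interior event embedded in an n-probe run the
best *single-breakpoint* rank statistic is bounded near z ≈ 2
independent of effect size (the event contributes `k(n/2)` excess rank
mass against a denominator of order `n^(3/2)`), so a 20-probe event
inside a few-thousand-probe chromosome could never reach a 1e-6
significance level. The arc statistic compares the event directly
against everything else and reaches z ≈ 7–8 for a single-copy change at
noise SD 0.15. The Bonferroni adjustment over the ~n²/2 scanned arcs
is conservative, which keeps the family-wise false-split probability per
run at or below `alpha`; at the simulated scale (≤ ~3000 probes per
chromosome) true single-copy events retain p-values orders of magnitude
below the threshold after adjustment. The scan is O(n²) per recursion
step, which is entirely adequate at the problem sizes this package
targets (thousands of probes per chromosome) but would need windowing
for a full 720K-probe array at native resolution.

Calling applies the fixed criteria: a segment becomes a gain when its
mean log2 exceeds +0.2 (loss below −0.2) and it spans ≥ 5 probes.
Adjacent same-direction calls separated *only* by a `max_gap` break are
merged (gaps are array artifacts; a single biological event should be
reported once). Negation symmetry holds exactly: ranks reverse under
sign flip, so calling on −log2 returns the same intervals with gain and
loss exchanged.

### Dye-swap concordance

A true copy-number signal inverts its sign when the test and reference
dyes are exchanged. A forward call is dye-swap validated iff a call of
the *opposite* direction from the swapped hybridization (processed with
identical settings) overlaps it with reciprocal overlap ≥ 0.5. The 0.5
default is a package choice — published analyses of this design
typically judge concordance visually — and is configurable. An empty
swap call set fails (not NA) every forward call, because the swap
experiment was performed and detected nothing.

## SNP-array BAF/LRR analysis

Samples are accepted when the standard deviation of autosomal LRR is
below 0.24, the standard QC rule for this array family. At least 100
autosomal SNPs are required for the SD to be meaningful.

Heterozygous BAF bands sit at allele-dosage ratios `b / c`: 0.5 in a
diploid region, 1/3 and 2/3 at three copies. Allelic imbalance is
detected by segmenting the mirrored statistic `|BAF − 0.5|` of het SNPs
(band (0.2, 0.8)) with the same rank-segmentation engine used for aCGH —
one segmentation algorithm serves both platforms. A segment is
`imbalanced` when it spans ≥ 360 kb and its het BAFs form upper and
lower clusters with half-separation ≥ `mode_delta = 0.08`; segments with
fewer than 10 het SNPs are `indeterminate` (too small to interpret by
B-allele pattern, as for sub-100 kb events at ~13 kb SNP spacing). The
360 kb minimum window is taken from the recommended LOH window for a
*denser* array of the same family and kept as a conservative default;
`mode_delta = 0.08` separates the 3-copy mode shift (±1/6 ≈ 0.167) from
BAF noise (SD 0.03) with wide margin. Band centers are estimated as
cluster means, so mirror symmetry `mode_low + mode_high ≈ 1` is a
diagnostic invariant, not an imposed constraint.

Copy-neutral LOH is a maximal run of consecutive SNPs with no het call
that (a) spans ≥ 360 kb, (b) has run probability
`(1 − het_rate)^n_snps < 1e-6` under the genome-wide het rate, and
(c) satisfies |mean LRR| ≤ 0.1. The LRR gate is what separates
LOH/uniparental disomy from a deletion, which also silences the het band
but shifts LRR to log2(1/2) = −1. A sample with zero genome-wide
heterozygosity is refused (LOH undefinable).

## qPCR relative copy number

Fold change is `2^−ΔΔCt` with ΔCt normalizing the target against a
diploid internal control locus and the donor DNA as calibrator;
replicates (triplicate by default) are summarized by their mean Ct, with
no efficiency correction (the generator's efficiency knob defaults to
ideal doubling, 2.0). Classification thresholds 1.4 (gain) and 0.7
(loss) sit midway between the neutral expectation 1.0 and the
single-copy-change expectations 1.5 and 0.5; they are explicit
configuration, not published values. Multi-point validation of a call:
`validated` iff every inside primer point classifies in the called
direction and every outside point is neutral; `not_validated` iff no
inside point is concordant; anything mixed is `indeterminate`. The
refined boundary interval runs from the innermost neutral outside points
to the outermost concordant inside points.

## Overlap enrichment

Overlap between a CNV list and a database uses the any-overlap rule: a
query interval counts (once) when it shares ≥ 1 bp with the database in
half-open coordinates. The permutation null reshuffles each interval
independently to a uniform start on its own chromosome, preserving every
length and each chromosome's interval count; permuted intervals may
overlap each other and their original positions (exactness of the
uniform null is preferred over non-overlap constraints). The empirical
p-value is the fraction of permutations whose overlap count is
*strictly greater* than the observed one — ties count against
enrichment — and a zero numerator is reported as "< 1/n_iter"
(e.g. "< 0.001" at the default 1000 iterations).

With a strictly-greater rule on an integer statistic the null p-value is
discrete and slightly anti-conservative, so calibration checks use query
sets large enough (hundreds of intervals) that the count statistic is
well dispersed; at that scale the empirical p-values are
indistinguishable from uniform by a Kolmogorov-Smirnov test.

Segmental-duplication summaries report the number of CNVs touching an
SD, the summed *full* length of those CNVs, and that length as a
fraction of the total CNV length. Repeat-class profiles report, for the
merged CNV interior and for distance-banded flanking windows (defaults
0–10 kb, 10–100 kb, 100 kb–1 Mb, 1–10 Mb from the nearest CNV base), the
fraction of each band covered by LINE/SINE/LTR elements; bands are
assigned by minimum distance with ties to the left, so they are disjoint
by construction, and chromosomes with no CNV carry no flank. Both a
10 kb-scale and a multi-Mb-scale vicinity are reported because both are
used in the literature this workflow derives from.

## Probability of identity

Per-locus PI under Hardy-Weinberg equilibrium is `2·S2² − S4` and the
full-sibling PI is `0.25 + 0.5·S2 + 0.5·S2² − 0.25·S4`, with
`S2 = Σp_i²`, `S4 = Σp_i⁴`. Both closed forms are verified in the test
suite against a brute-force enumeration of genotype space (and, for
siblings, of parental allele draws and Mendelian inheritance choices) to
1e-12 on a thousand random frequency vectors; the enumeration oracle is
implemented independently of the closed forms. Multilocus PI is the
product across loci under independence. Allele frequencies must be
supplied (or generated synthetically): PI is meaningless without a
reference population, and no frequency table ships with the package.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the analysis
relies on — segment means at `log2(c/baseline)`, dye-swap sign inversion
with an independent noise realization, BAF bands at allele-dosage
ratios truncated to [0, 1], het-band removal with neutral LRR inside
cn-LOH, ideal-efficiency Ct shifts, HWE genotypes — with defaults:
3.3 kb aCGH probe spacing, 13 kb SNP spacing, aCGH/LRR noise SD 0.15,
BAF noise SD 0.03, heterozygosity rate 0.3. The spacings are the two
array platforms' nominal densities; the noise SDs and het rate are
package choices (no platform noise model is published for this design)
set so that a single-copy change is ~4 noise SDs and the 3-copy BAF
mode shift ~5.5 noise SDs — comfortably detectable but far from
noise-free.

Not emulated: GC waves and spatial autocorrelation in array noise,
probe-specific response, population LD structure between SNPs, mosaic
(sub-clonal) events, genotyping error, and qPCR efficiency variation.
Passing tests therefore demonstrate correctness of the algorithms under
the stated noise model, not robustness to every artifact of real arrays.

Simulation studies in the tests and the acceptance script run on
deliberately desk-scale genomes (a few chromosomes of 8–80 Mb; roughly
2 500–7 500 probes per genome), a package choice keeping the suites
quick while leaving every event ≥ 20 probes, the regime the claims are
about. Embedded-event recovery uses 50 seeded genomes; specificity and
dye-swap reciprocity use 100; permutation calibration uses 200 datasets
at 200 iterations.

## Pipeline

Stage order per clone: QC → segmentation/calling → dye-swap → BAF/LOH →
qPCR → overlap/permutation → gene annotation → identity → report. A QC
failure skips that sample's SNP-based stages only, with the failure
recorded. One global seed fans out to per-stage, per-clone child seeds
by fixed offsets, so identical config + seed yields byte-identical
reports and any stage can be reproduced alone. In the consolidated
report, validation flags are printed as Q (qPCR), S (dye swap) and
B (B-allele profile); a qPCR verdict of `indeterminate` maps to NA
rather than fail, since mixed multi-point results assert neither
existence nor absence.

## Known limitations

* The arc scan is quadratic per run; full-resolution 720K arrays would
  need windowed scanning or a coarse-to-fine pass.
* The Bonferroni adjustment is conservative; extremely low-amplitude
  events (|log2| well below 0.2) near the 5-probe floor are not
  reliably separable from noise — by design, matching the fixed calling
  thresholds.
* BAF mode estimation by cluster means is biased toward 0.5 when the
  het band tails cross 0.5; at the default noise (0.03) and 3-copy
  separation (0.167) the bias is negligible, but mosaic events with
  small deviations would need a mixture model.
* cn-LOH detection assumes a spatially uniform het rate; regions of
  genuinely low diversity (long runs of homozygosity in inbred
  populations) can mimic LOH — on real data the donor genome should be
  used as the comparator, as the pipeline does for clones.
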