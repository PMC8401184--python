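# Methods

## Differential methylation

Per-CpG methylation is summarized by the β value, meth/(meth+unmeth),
after removing CpGs whose coverage is not *strictly greater* than the
scheme's minimum (5× for the screening schemes, 10× for the matrix
schemes) — the filter follows the "greater than" wording of the
protocols it encodes and is configurable. Replicates within a phenotype
are pooled by count summation before testing.

A CpG is called differentially methylated when it satisfies every
inequality of the selected threshold scheme **and** reaches significance
in a two-sided Fisher's exact test with Benjamini–Hochberg control at
FDR < 0.05, computed over all CpGs shared by the two phenotypes. The
`readjusted` scheme is formalized as β_S < 0.2 and (β_R − β_S) > 0.4
with no absolute β_R floor; `matrix_b` uses Δβ ≥ 0.14 inclusively. The
β-threshold and FDR filters commute because the BH adjustment is always
computed over the full joined CpG set, never over a pre-thresholded
subset. The exact test is a transparent stand-in for a dedicated DM
caller (e.g. methylKit's per-CpG logistic/Fisher machinery); it is
vectorized over the hypergeometric support with identical-table
de-duplication, and unit tests pin it to `scipy.stats.fisher_exact`
row by row. Tables with an empty margin carry no information and return
p = 1 with a warning.

## CpG islands and genomic zones

Islands are detected with the Takai–Jones criteria — GC ≥ 55 %,
observed/expected CpG = (N_CpG·L)/(N_C·N_G) ≥ 0.65, length ≥ 500 bp — by
sliding a 200-bp window at 1-bp steps, unioning qualifying windows into
runs and trimming each run to the *longest* sub-interval whose full span
still meets all three criteria (ties break leftmost). The original
screening used web scanners; this explicit local algorithm is the
package's reimplementation, and an exhaustive-enumeration oracle checks
it on sequences up to 5 kb. "Obs/Exp ≥ 65" is read as the ratio 0.65,
the convention of the criteria's source. Soft-masked (lowercase) bases
stand in for RepeatMasker output: any window touching one is ineligible,
which keeps ALU-like CpG-rich repeats out of the island set.

Zones: **alpha** is the promoter window TSS −2000/+500 in gene
orientation (adopted globally; the first-pass screening left the
promoter extent unquantified). **beta** comprises the island shore
(0–2 kb) and shelf (2–4 kb) measured 5′ upstream of the island start on
the annotated gene's strand; downstream shores are available behind
`symmetric_shores` but off by default, matching the upstream-only
definition of the regions being emulated. **gamma** is the gene body.
Precedence alpha > beta_shore > beta_shelf > gamma, so a position gets
exactly one label; ties within a level resolve to the nearest TSS.
Coordinates are 0-based half-open internally and 1-based in CpG-report
I/O, with the conversion confined to the I/O layer.

## Expression

Array-style tables use a gene-wise Welch two-sample *t* on log2 values
with BH adjustment; zero-variance ties return p = 1 (identical groups)
or p = 0 (separated constants). Count tables pass the CPM presence
filter (discard genes with < 1 CPM in < 6 samples) and TMM
normalization — reference column by 75th CPM percentile, 30 % trim on
M-values, 5 % on A-values, delta-method precision weights, factors
rescaled to geometric mean 1 — before the same two-group test on
log2 CPM. This Welch+TMM route replaces limma's moderated variance and
edgeR's quasi-likelihood dispersion; the substitution is isolated behind
the differential-expression result interface, and the TMM implementation
is pinned in tests to factors computed once with edgeR's
`calcNormFactors` on a frozen fixture. Duplicate probes collapse to the
max-variance row (the emulated protocol says duplicates were eliminated
without stating a rule). Re-expression after reactivation requires
RT − R log2 fold change ≥ log2(2) at FDR ≤ 0.05; the 2-fold default is a
package choice, not a published cutoff.

## qMSP, viability, survival

With a common amplification efficiency E (default 2.0, perfect doubling;
configurable per probe, since no standard-curve data are modeled), the
percent of methylated molecules is 100/(1 + E^(CtM−CtU)); an undetected
channel gives exactly 0 or 100. A sample is MSP-positive strictly above
29.74 %, the lowest quantitative value observed to coincide with a
positive qualitative call in the emulated assay. Reactivation
demethylation is reported in absolute percentage points.

IC50 is obtained by linear interpolation of the mean normalized
viability curve at its first (lowest-dose) 50 % crossing — chosen for
transparency over a 4-parameter logistic fit, which is out of scope.
On a sparse geometric dose grid this interpolation is mildly biased
upward between doses (the simulated resistance index reads ≈ 2.4–2.5
against a generative 2.3), which is inherent to the estimator, not the
data. The resistance index is IC50(resistant)/IC50(sensitive), reported
at two decimals with the raw ratio retained.

Kaplan–Meier estimation and the two-group log-rank test wrap lifelines
(deaths precede censorings at tied times, the standard convention);
tests check them against hand-computed product limits and a hand-rolled
O−E/V statistic. Patients stratify into methylated/unmethylated by the
qualitative MSP call when present, else by the qMSP percentage against
the 29.74 % threshold; both OS and PFS endpoints are supported.

## Funnel, contrasts, ranking

Cohort presets: `approach1` = platinum therapy + expression data + death
within 1100 days (event observed and OS ≤ 1100); `approach2` = platinum
+ RNA-seq expression + 450K-style methylation + relapse within 183 days
(6 months). The funnel intersects, in order: resistance DE genes, the
cohort-concordant DE set, re-expressed genes, promoter-CGI genes, and
WGBS DM genes, reporting each stage's size and nearest-integer
percentage of the previous stage. "Concordant in the selected patients"
is implemented as cohort-level DE plus a per-patient consistency rule —
each selected patient's normalized expression must lie on the DE side of
the control mean in at least a configurable fraction of patients
(default 1.0) — because the emulated per-patient DE mechanics are not
published.

Twenty-four contrast specs ship as YAML in three groups, combining the
direction-resolved layers (WGBS hyper/hypo, array down/up, 450K
hyper/hypo, cohort RNA-seq down/up, approach-1 cohort DE); users can add
their own. The matrix filter keeps genes with strictly more than 10 DM
CpG positions. Ranking is by recurrence across contrasts, then DM-CpG
count, then maximum |Δβ|, then gene id — a deterministic total order.
Candidates must carry at least one WGBS DM CpG.

## Synthetic study

The generator emulates the experimental design end to end: paired
sensitive (S) and resistant (R) phenotypes plus a reactivation phenotype
(RT), and a platinum-treated cohort. Distributions are the minimal
standard models per data type: Poisson(depth) coverage with
Binomial(coverage, β) methylated counts (destranded, pooled at the
forward-strand C), Gaussian log2 intensities, negative-binomial RNA-seq
counts (size 10), exponential survival with administrative censoring at
5 years.

Defaults define the study: 200 genes (10 planted) on 2 × 800 kb
chromosomes, depth 30×, background β_S = 0.05, planted β_R = 0.8,
β_RT = 0.65·β_R (matching the ~13–15 percentage-point demethylation the
RT condition is meant to show), 2-log2 silencing in R and 2-log2
recovery in RT with replicate sd 0.25 at n = 4, a 200-patient cohort
(50 % resistant; 70 %/10 % methylated among resistant/sensitive), death
hazard ratio 3 for methylated patients over a 600-day baseline median
OS. No effect-size distribution for resistant-cell hypermethylation is
published beyond the threshold definitions, so these levels are stated
choices, held fixed.

Planted genes rotate through the three zones: alpha plants methylation
across the promoter island; beta adds a distal gene-body island and
plants a CpG-enriched but sub-island segment (GC ≈ 47 %) in its upstream
shore; gamma plants such a segment mid-body. Every planted gene keeps a
promoter island so the funnel's promoter-CGI stage tests methylation,
not island presence; 60 % of background genes get promoter islands.
Background sequence is GC-poor with 85 % of CpGs broken, and two
soft-masked CpG-rich decoys per chromosome emulate repeats the scanner
must skip. One integer seed reproduces every artifact byte-for-byte via
independent per-artifact substreams.

What the generator does **not** emulate: read-level errors and bisulfite
conversion failure, strand asymmetry, copy-number and SNP effects,
array probe biases, batch structure, or realistic linkage between
methylation, expression and outcome beyond the planted monotone effects.
Passing recovery tests therefore shows the pipeline's logic is sound and
calibrated under its stated models — not that it would achieve the same
operating characteristics on real tumors.

## Numerical choices and problem sizes

Acceptance-style checks run the full pipeline over 20 seeds at the
default study size (a few seconds per seed), the null methylome on
24-gene/2×200 kb genomes over 20 seeds, log-rank calibration over 200
cohort draws and power over 100 — sizes chosen so the whole suite stays
desk-scale while the stochastic assertions (sensitivity ≥ 0.9,
precision ≥ 0.8, KS p > 0.01, power ≥ 0.9) remain well away from their
thresholds. Known limitations: the island trimmer returns the single
longest qualifying sub-interval per merged run (a run hiding two
disjoint qualifying intervals after trimming would report only the
longer); rank ties beyond the four sort keys cannot occur by
construction; the funnel treats layers as plain gene sets, so a gene
hyper- and hypomethylated at different CpGs appears in both direction
layers.
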