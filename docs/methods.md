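# Methods

## Coordinate and status conventions

Amplicon coordinates are 1-based and inclusive on the primer-trimmed
top strand; CpG index *k* denotes the k-th CpG ("Ck") of the locus.
Only the bisulfite top strand is modelled: locus-specific primers for
these assays target one converted strand, and reverse-strand (OB)
products are out of scope. Status "C" means methylated (cytosine
retained through conversion), "T" unmethylated (converted).

The three bundled loci reproduce the studied amplicon geometry —
(length, CpG count) of (142, 17), (161, 17) and (89, 5) — with
deterministically generated sequence content: random filler at ~55% GC
that never creates a CG dinucleotide outside the designated positions
and always leaves at least 10 non-CpG cytosines, so conversion-rate QC
has something to measure. Real reference amplicons can be supplied as
FASTA (record id = locus name) and override the generated sequences;
CpG positions are then re-derived from the supplied sequence.

## Synthetic cohorts

The generator's defaults are the study-scale conditions: 19 case and
18 control samples; 10,000 molecules per sample per locus at full
scale, 1,000 for desk-scale runs (the scale used by the test suite and
the acceptance script, chosen as the smallest coverage at which the
designed contrasts are comfortably resolved); per-position background
methylation 0.3%; conversion failure 0.005 per convertible cytosine;
substitution error 0.001 per base per mate; chimera rate 0.01;
150-nt mates; constant maximal quality strings (quality-aware
processing is out of scope, as are indels, PCR duplicates and
amplification bias).

Case/control contrast comes from a latent per-sample **tumor
fraction** f ~ Uniform(0.06, 0.13). Each molecule of a case sample is
tumor-derived with probability f; tumor molecules are methylated
jointly (all-or-none) at each designated CpG block — by default a
single block covering every position, i.e. fully methylated tumor
epialleles — while background molecules methylate positions
independently at the control rate. Expected case methylation at a
block position is therefore f + (1−f)·p₀, and block positions are
strongly pairwise-correlated within the case group (r > 0.9), while
control methylation stays near zero. This latent-fraction mechanism is
the simplest generative model reproducing those three observables; it
is a stand-in for real inter-patient heterogeneity, not a claim about
it. Consequently, passing tests demonstrate correctness of the
pipeline's bookkeeping and statistics under this model — they say
nothing about indel robustness, quality-dependent errors, or
non-block-structured methylation in real data.

Barcoding follows the published dual-index scheme: two 8-bp families
(X1–X8, Y1–Y12; which family sits on the forward primer is
locus-specific), with case and control groups drawing from disjoint
barcode subsets (cases X1–X4 × Y1–Y6, controls X5–X8 × Y7–Y12) so any
cross-group chimera is recognisable from its barcode pair alone. A
simulated chimera swaps the reverse-side barcode for one that makes
the pair invalid. The X8 and Y8 entries of the published table share
one sequence; the two families are only ever looked up on their own
side of the read, so demultiplexing stays unambiguous.

## Read processing

Mates are overlap-merged by sliding the reverse-complemented mate 2
against mate 1, scanning candidate product lengths from shortest
(maximal overlap) upward and accepting the first candidate with ≥ 20
overlapping bases and ≤ 10% mismatches in the overlap; overlap
disagreements take the mate-1 base. Unmergeable pairs are dropped
rather than rescued from a single mate, because every CpG position of
the insert must be observed.

Demultiplexing is exact (8 bp, zero mismatches): tolerance would blur
the group-disjointness guarantee that chimera exclusion rests on. A
pair whose two barcodes are both known but whose combination was never
used in any library is chimeric and excluded; unknown barcodes are
unassigned. The locus of a merged product is identified by its total
length (16 + insert length; the bundled loci are length-distinct), with
reference-mismatch count breaking ties if lengths collide.

Methylation calling is fixed-length, no-indel matching against the
pre-bisulfite reference — amplicon inserts are constant-length
products of known primers. At each CpG position C → 1, T → 0, any
other base rejects the read ("unrecognized site"). The conversion rate
is the fraction of the locus's non-CpG reference cytosines read as T;
reads below 0.95 are rejected, the threshold inclusive (exactly 0.95
passes). The denominator is all non-CpG reference cytosines of the
insert. Reads with more than 10% of non-CpG positions disagreeing with
the converted reference are rejected as mismatches.

## Variables and transforms

Singles are canonically C-status; T-singles are the complement
100 − Ci and are not enumerated separately. Pair variables carry all
four statuses (CC, CT, TC, TT), giving the closure invariants
CC+CT+TC+TT = 100 and Ci = Ci.Cj + Ci.Tj per sample. A sample with
zero accepted molecules for a locus gets missing values there and is
excluded from that locus's group tests (no imputation).

Correlation analyses use binary logarithms. Zeros are handled with a
per-variable pseudocount of half the smallest positive value of that
variable across all samples, applied only when the variable actually
contains zeros; strictly positive variables are transformed exactly.
Boxplot summaries use linear-interpolation quartiles.

## Statistical battery

**Exact Mann–Whitney.** The two-sided p is
min(1, 2·min(P(W ≤ w), P(W ≥ w))) where W is the rank-sum of the case
group under random relabeling. Midranks (doubled to integers) make the
distribution computable exactly for any tie pattern by 0/1-knapsack
dynamic programming over (group size × doubled rank sum); for 37
samples the table is ~20 × 1400 and the computation takes milliseconds,
so no Monte-Carlo fallback is needed at cohort scale. Counts use int64
(an object-dtype fallback engages when C(n, n₁) approaches the int64
limit). Tie-free distributions are cached and shared across variables.

**Orientation.** C-status variables are tested case-high and T-status
variables case-low; mixed pairs (CT/TC) follow the observed group
means. The orientation is recorded in every output row.

**LOO-CV logistic classification.** Each training fold fits a
one-predictor logistic model by IRLS with a 10⁻⁸ ridge stabiliser
(survives quasi-separation in folds) on a standardised predictor, with
per-sample weights 0.5/n_g so both groups contribute equal total
weight. Held-out probability > 0.5 classifies as case; exactly 0.5
classifies as control (with balanced weights a constant predictor
yields exactly 0.5, hence accuracy n_control/n_total on null data).
A fold with an empty training group predicts the weighted prior and is
logged. When the full data are completely separated in either
direction, accuracy, sensitivity, specificity and AUC are reported as
100 without cross-validating.

**DeLong CI.** AUC is concordant-pair counting (ties ½), oriented so
separation gives 1; the variance is the structural-components
estimator S₁₀/n₁ + S₀₁/n₀ with a normal-approximation interval
truncated to [0, 1], suppressed when AUC = 1 (degenerate).

**Display conventions.** Adjusted p at two significant figures in
plain decimal, ">1" past 1; means and cutoffs at three significant
figures; percentages at one decimal.

## Assay-design search

Regions (forward primer C1–C6, probe C6–C15, reverse primer C11–C17 on
the GSTP1-geometry locus) partially overlap. Candidate combinations
are all-C subsets of a region's CpG indices, size 2 up to the region
width, optionally with single-T "error" variants; enumeration refuses
to exceed 2¹⁶ combinations per region. Admission requires complete
separation and case-mean representation above 0.5%. Ranking within a
region is by case mean descending (the selection criterion is
inferred from how such results are customarily presented and is
recorded as such), ties by fewer constraints then name. Composites
concatenate one of the top-5 admitted combinations per region and are
re-evaluated per molecule — never as products of means — so composite
means respect set-intersection monotonicity by construction.

## Reproducibility

A single global seed fans out to per-stage seeds via SHA-256
derivation, making full runs byte-identical (gzip outputs are written
with zeroed timestamp and no embedded filename). The simulator's
profile and read synthesis draw from independently spawned
SeedSequence children, so ground truth is unchanged by toggling read
synthesis.

## Known limitations

No indel handling, quality trimming or reverse-strand support; exact
barcode matching only; the generator's block model cannot express
partially methylated tumor epialleles or position-specific error
rates; multi-variable (joint) classifiers are out of scope. The
optional boxplot rendering is not included — the five-number summary
TSV feeds any standard plotting tool.
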