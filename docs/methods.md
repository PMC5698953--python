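# Methods

`agetx` re-implements, as a tested pipeline over synthetic data with known
truth, the computational analysis of an aging time-course transcriptome in
photoreceptor-type sensory neurons: polynomial time-course differential
expression, temporal trajectory clustering, promoter-motif combination ROC
analysis with a random-matrix control, gene-characteristic bias analysis,
and circRNA back-splice junction quantification with an age-trend
regression. This note records the models, the parameters that matter, and
the design choices made where the procedure was genuinely open.

## Study design emulated by the generator

The synthetic study is a bulk RNA-seq time course over five ages (10, 20,
25, 30, 40 days) with three biological replicates per age and library
sizes of roughly 32 million reads (drawn uniformly in ±20% of 32M). Counts
are negative-binomial: the expected CPM of gene *g* in a library of age
*t* is

    cpm_g(t) = b_g * 2^( s_g * A_g * v_g(t) )

where `b_g` is a log-normal day-10 baseline (meanlog = log 50,
sdlog = 1.2 — a realistic spread for genes passing an expression filter),
`A_g` is the log2 amplitude, `s_g` the direction sign, and `v_g` one of 11
quadratic trajectory templates normalized to [0, 1] over the sampled ages.
Counts are gamma–Poisson draws with dispersion 0.1 (a typical biological
replicate dispersion for bulk tissue). By default 10% of genes are
regulated, cycling through the templates, with amplitudes uniform on
[1.5, 3]; all other genes are flat with amplitude 0.

The 11 templates (7 up, 4 down, with early/middle/late variants) are
quadratics in age chosen so that (a) the direction/timing classifier
assigns each template its intended label and (b) the max-normalized linear
profiles of distinct templates are separable by k-means at the planted
noise level. Truth tables record exactly the planted labels.

What the generator does **not** emulate: isoform-level expression dynamics
(isoform counts are a multinomial split of gene counts at fixed weights),
GC/length sequencing bias, batch effects, and correlated genes. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated model, not robustness to those real-data
artifacts.

## Expression filtering and time-course DE

Counts are CPM-normalized per library; genes are retained when CPM is
strictly above 1 in at least three samples. Age-regulated genes are called
by ordinary least squares of `log2(CPM + 1)` on `(age, age²)` with an
F-test of the quadratic against the intercept-only model,
`(2, n − 3)` degrees of freedom, and Benjamini–Hochberg control at
FDR < 0.05. This replaces a two-stage GLM with stepwise term selection by
a single quadratic F-test: only the gene-level FDR call and the quadratic
shape are consumed downstream, and the single test is deterministic and
exactly characterizable. Ages enter as uncentered numeric days, so
coefficients are in per-day units. Direction is the sign of the fitted
day-40 minus day-10 value. A constant response (zero total sum of squares
up to a 1e-10 relative tolerance) reports F = 0, p = 1.

Under the null (flat genes, NB noise at the default depth) the p-values
are uniform to a Kolmogorov–Smirnov statistic of about 0.014 at 2000
genes; at the default planted conditions sensitivity is ≥ 0.85 with
empirical FDR well under 0.1.

Pairwise differential expression of low-count features uses a two-sided
Fisher's exact test on pooled counts (feature counts vs remaining library
counts per group), with fold change computed on group mean CPM with a 0.5
pseudocount, and a call at p ≤ 0.05 and fold change ≥ 2 in either
direction. Fisher on pooled counts is deliberately conservative for
overdispersed data; its empirical type-I error at nominal 0.05 is ≈ 0.04
in the null simulation.

## Temporal clustering and trajectory classification

Called genes are represented by per-age replicate means divided by the
per-gene maximum ("relative expression", maximum exactly 1), clustered by
Euclidean k-means with k = 11 (k fixed, not selected), k-means++
initialization and the best of 50 restarts by within-cluster sum of
squares. Each cluster's per-age **median** profile is fitted with a
quadratic in age (medians rather than all member profiles: the median is
the robust single-curve summary of a cluster, and the choice only affects
the cluster summary, not memberships); r² = 1 − RSS/TSS, with TSS = 0
reported as r² = 1 and flagged degenerate.

Classification from the fitted curve f: direction is the sign of
f(40) − f(10) (an exact tie falls back to the signed net change along the
sampled curve and is flagged; a fully constant curve reports a "tie"
direction with "middle" timing). Timing compares the early change
Δe = |f(20) − f(10)| with the late change Δl = |f(40) − f(30)|: early if
Δe ≥ 2Δl, late if Δl ≥ 2Δe, else middle. The factor 2 operationalizes
"maximal change in the first (last) interval" while leaving a middle band
for near-linear curves; it is a package decision, stable for the template
shapes used.

## Promoter motifs and greedy ROC combination

Promoters are 1001-nt windows (±500 nt of the TSS, strand-aware; the TSS
base included). Motifs are IUPAC strings (exact degenerate match, either
strand) or PWMs (log-odds against a uniform background; hit when the
score reaches 0.8 of the maximum attainable, either strand; `N` never
matches). The 0.8 fraction is a package default — per-motif calibrated
thresholds of motif-discovery suites are not reproduced.

Enrichment of a motif in a target set against the expressed background is
the upper hypergeometric tail, significant at p < 0.001. The combination
analysis scores a gene by the **count** of selected motifs present in its
promoter — the simplest monotone pooling of a motif set; greedy forward
selection starts from the best single-motif AUC and at each step adds the
motif maximizing the combined AUC (ties broken lexicographically).
AUC is the Mann–Whitney probability with ties counted 0.5. Each step's
improvement is assessed by DeLong's paired test on the step's and the
previous step's score vectors; the "top motifs" are the longest prefix in
which every single addition significantly improves the AUC (p < 0.05 and
AUC increased). Step 1 is included by convention.

The random-matrix control draws, for each of 100 matrices of 7580 genes ×
40 motifs, a per-motif presence probability uniform on [0, 0.145]
(the observed cap on background presence), Bernoulli entries, a fixed set
of 288 positive labels, and reports the maximum AUC along the greedy
trajectory, maximized over matrices. With these parameters the control
lands at ≈ 0.59 (0.587–0.606 across master seeds), the chance-level
ceiling against which real combinations are judged. The label count 288
matches the upregulated set paired with the 40-motif control; it is
configurable.

The co-occurrence network connects two motifs when their promoter
co-occurrence count exceeds the hypergeometric expectation (upper-tail
test, BH-corrected q < 0.05 — the edge criterion is a package decision);
node metrics are degree and the triangle-based local clustering
coefficient (0 for degree < 2).

## Gene characteristics

Per gene: length is the genomic span (introns included) of the most
abundant expressed isoform, abundance measured as total assigned counts
across all samples with ties broken by the longer isoform; mean RPKM
across all samples; expressed exons are union exons with count > 1
(strictly) in at least one sample; expressed isoforms have any assigned
count. Distribution differences across clusters and the non-significant
set use Kruskal–Wallis plus pairwise Wilcoxon rank-sum tests (exact
enumeration for tie-free groups ≤ 25, otherwise the tie- and
continuity-corrected normal approximation), BH-corrected within feature;
groups under 3 members are reported missing rather than raising. Feature
ROC uses the raw feature values, making the AUC invariant under monotone
transforms.

## circRNA quantification

Each candidate circle (BED-style 0-based half-open coordinates on host
exons) yields a junction scaffold: the last `min(85, available)` exonic nt
ending at the back-splice donor followed by the first `min(85, available)`
nt from the acceptor, walking the multi-exon structure, strand-aware —
170 nt when both flanks are full, shorter for small circles (no
wrap-around). Reads are aligned ungapped end-to-end at every scaffold
offset with a budget of 2 mismatches (the equivalent of a stringent
end-to-end mapping score floor; gapped alignments are not supported).
A read must overlap the junction by ≥ 15 nt on **each** side (the
per-side reading of the minimum-overlap rule, standard back-splice
practice; configurable). Reads matching several scaffolds go to the
strictly best by mismatch count; exact ties are dropped (conservative).
Duplicates — identical (circRNA, scaffold offset, read sequence) within a
library — collapse to one record.

Count tiers: reported at total ≥ 2 reads over all libraries, abundant at
total > 6, and eligible for a pairwise comparison at an average of ≥ 1
read per involved library. CPM uses supplied total library sizes (not
junction-mapped totals). Abundance shifts across ages compare per-circ
mean CPM distributions: baseline-vs-age Wilcoxon (continuity-corrected),
Kruskal–Wallis overall, and Nemenyi post-hoc pairs via the studentized
range on mean ranks. Host independence pairs each circRNA's day-10→40
log2 fold change with its host gene's linear fold change (Spearman). The
age trend regresses per-library mean CPM of a circRNA subset on age;
r² is the squared Pearson correlation, defined 0 for a constant response.

The junction-read generator draws each read's junction offset without
replacement within a (circRNA, library) pair, so noise-free reads are
pairwise distinct and duplicate removal provably returns the planted
truth; a plan requesting more reads than distinct offsets raises. This is
also why the noise-free end-to-end test can require exact equality with
the truth table.

## Numerical conventions and degenerate inputs

- BH adjustment: step-up with a monotone cumulative minimum, capped at 1.
- AUC on a single-class label vector raises (degenerate ROC).
- DeLong on identical score vectors returns p = 1; a zero-variance
  difference with unequal AUCs returns p = 0 with a degeneracy flag.
- All-zero expression profiles cannot be max-normalized and raise.
- Every generator accepts a seed and is byte-identical across runs for a
  fixed seed and configuration.

## Problem sizes

Tests and drivers run at desk scale, chosen to keep the full suite under
a minute while leaving comfortable statistical margins: 2000 genes for DE
and null-calibration suites, 1000–2000 genes for motif recovery, 120 host
genes / 50 circRNAs for the circRNA pipeline, and the full reference
parameters (7580 × 40 × 100 iterations) for the random-matrix control,
which is cheap after vectorizing the histogram form of the Mann–Whitney
statistic.

## Known limitations

- The NB generator ignores gene–gene correlation and mean–dispersion
  trends; FDR calibration on real data will be somewhat worse.
- The quadratic F-test cannot represent non-polynomial trajectories
  (e.g. step changes); such genes load on the quadratic only partially.
- The greedy combination explores a single forward path; it is the
  procedure under study, not an optimal subset search.
- PWM scanning uses one global score fraction rather than per-motif
  calibrated thresholds.
- The bias mode of the gene-model generator plants length and exon-count
  bias but no isoform-count bias, so the isoform-number ROC on synthetic
  data stays near chance.
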