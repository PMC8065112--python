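# Methods

This note documents the models, conventions and numerical choices behind
`ctclone`, in the spirit of a package vignette: what is computed, under
which assumptions, and what the synthetic-data checks do and do not show.

## Cancer fraction and clonal dominance

For each patient the maximum VAF over retained somatic calls (mVAF) is
taken as the allele frequency of a truncal mutation present in every
tumour cell; every mutation's cancer fraction is `CF = VAF / mVAF`, a
proxy for the fraction of tumour cells carrying it. `CF >= 0.5` is called
clonally dominant (ties at exactly 0.5 are dominant), `CF < 0.5`
subclonal. Samples with a single retained alteration are *not assessable*:
with nothing to normalise against, CF would be 1 by construction.

Assumptions worth keeping in mind:

* the truncal mutation is heterozygous and copy-neutral — local copy-number
  events at either the truncal or the query locus bias CF;
* mVAF is computed over **all** retained somatic calls by default.
  Whether non-pathogenic calls should anchor the maximum is genuinely
  ambiguous; `compute_mvaf(..., pathogenic_only=True)` switches the
  convention. Copy-number calls never enter mVAF.
* dominance of a (gene, patient) pair uses each mutation separately; no
  per-patient consensus is formed.

Gene-level dominance (a gene's CFs versus the pooled CFs of all other
genes) uses a two-sided Mann–Whitney rank-sum test. A signed-rank test is
sometimes named for this comparison in the field, but the samples are
unpaired, so the rank-sum form is the statistically coherent choice; the
statistic is configurable (`statistic="ranksums"` for the
normal-approximation form). The asymptotic Mann–Whitney without continuity
correction is used throughout so that exactly symmetric inputs give
p = 1. Benjamini–Hochberg correction is applied across the genes of one
analysis.

## Tumour fraction and plasma copy number

`T = 2 x mVAF / 100` converts the truncal VAF into the fraction of plasma
DNA that is tumour-derived; `adjusted pCN = (observed - 2 (1 - T)) / T`
then removes the dilution by normal DNA. The formula has two fixed points
used as tests: observed = 2 maps to 2 for every T, and T = 1 is the
identity. mVAF above 50 % implies T > 1, which the linear model cannot
represent (it signals loss of heterozygosity or copy-number effects); T is
clamped to 1 with a warning. Negative adjusted values (purity
overestimated) are floored at 0; cohort tables keep the raw value in a
separate column.

Amplification calling uses the strict rule `adjusted pCN > threshold`
(default 2.0). Sensitivity and specificity at the operating threshold
carry exact Clopper–Pearson 95 % intervals (the conservative choice; the
method name is recorded in the result object), and the ROC is traced over
the sorted unique adjusted values with trapezoidal AUC.

## Germline filtering and pathogenicity

A call is removed as likely germline iff VAF ∈ [48, 52] % **and** its
population allele frequency exceeds 0.001 %. Both conditions are required:
a 50 %-VAF call absent from population databases may be a clonal somatic
event in a high-purity sample. An absent population AF counts as 0. VAF
and population AF are both stored in percent; fraction-scaled inputs are
converted only via the reader's explicit `vaf_scale="fraction"` flag.

Pathogenicity is rule-based from user-supplied plain-table resources
(hotspot and oncogenic annotation sets, recurrence counts): a variant is
pathogenic if it is an annotated hotspot or oncogenic change, a recurrent
change (≥ 3 reports by default) in a key breast-cancer gene
(ESR1, HER2, PIK3CA, EGFR, RB1, FGFR2), or a splice mutation. The
annotation databases themselves are inputs, never bundled, so results are
reproducible from pinned files. MAPK-pathway alterations are pathogenic
point mutations in EGFR, HRAS, KRAS, NRAS, ARAF, BRAF, RAF1, MAP2K1,
MAP2K2, MAPK1, MAPK3, FGFR1, FGFR2, FGFR3; FGFR2/FGFR3 fusions; or plasma
copy number strictly above 3 in BRAF, EGFR, FGFR1, FGFR2, KRAS.

## Association statistics

Two-sided throughout. Fisher's exact test uses the probability-mass
definition of the two-sided p (sum of hypergeometric probabilities no
larger than the observed table's); a zero-margin table returns p = 1 with
a warning. The chi-squared test applies **no** Yates continuity
correction — the uncorrected form is what reproduces the published
worked examples (e.g. 3/41 vs 8/32 gives χ² ≈ 4.39, p ≈ 0.036). FDR
families follow analysis panels (one BH family per co-occurrence matrix,
per grouping, per gene-dominance table), not one global family.
Co-occurrence testing includes genes altered in at least 5 % of the
cohort; direction comes from the odds ratio relative to 1.

## Signature refitting

Catalogues live on the standard 96 strand-collapsed channels
(six pyrimidine substitution classes × 16 flanking-base contexts,
substitution-major order). Purine-frame calls are reverse-complemented on
entry, making catalogues strand-invariant. Indels and SNVs without a
trinucleotide context carry no channel and are excluded from catalogues
(but retained in every counting analysis). Contexts may be supplied in
the input table or derived from a user-provided indexed FASTA; no genome
is bundled.

For clonal-versus-subclonal analysis, SNVs are aggregated per subtype
regardless of pathogenicity; each unique site (chrom, pos, ref, alt)
counts once per set, and a site dominant in one patient but subclonal in
another counts once in *each* set.

`SignatureDeconvolution` fits non-negative exposures by greedy forward
selection: starting from an empty exposure vector, each round finds, for
every candidate signature, the single weight in [0, 1] minimising the
squared error between the normalised catalogue and the exposure-weighted
signature mix (golden-section search, absolute tolerance 1e-4; the SSE
along the line is evaluated from precomputed inner products). If adding
the best weight pushes the exposure total above 1, exposures are
renormalised by their sum. Iteration stops when the relative SSE
improvement falls below `tol` (default 1e-3). Exposures below the discard
threshold (default 0.06, the conventional default of refitting tools) are
zeroed and the surviving signatures re-fitted. The result object reports
the weights, the unassigned residual `1 - Σw` and the reconstruction SSE.
Exome/genome trinucleotide renormalisation is off by default: panel
catalogues are compared against panel-generated synthetic truths, and no
occurrence table is bundled.

Uncertainty comes from subsampling 90 % of the mutation set without
replacement in 200 iterations and re-fitting (a with-replacement flag is
available; the subsampling form matches the 90 %-of-data description of
the procedure being reproduced). Conditions are compared per signature by
a two-sided Mann–Whitney U test on the two bootstrap exposure vectors,
and a signature is *highlighted* only when p < 0.05 **and** the two
interquartile ranges are disjoint.

**Known limitation.** Subsample bootstraps quantify within-set stability,
not the sampling noise *between* two independently drawn mutation sets:
between-set exposure differences have standard deviation ~√2 × SE while a
90 % subsample spreads only ~SE/3. Under a true null the IQR-disjoint
flag therefore fires far more often than 5 %, and the geometry is
scale-free, so larger cohorts do not cure it. The power direction is
unaffected (large real differences are flagged essentially always), but
"highlighted" should be read as *large and stable*, not as a calibrated
type-I-controlled test. The test suite measures both rates honestly on
synthetic cohorts.

The built-in `synthetic_signatures()` set is a clearly-labelled synthetic
stand-in (five distributions named by role analogy: ageing-like C>T at
NpCpG, APOBEC-like C>T at TpCpW, flat, broad T>C-leaning, and APOBEC-like
C>G/C>A concentrated on the consensus channels). Real analyses should
pass a COSMIC-layout probabilities TSV via `read_signature_matrix`.

APOBEC consensus sites are T(C>G)T, T(C>G)A and T(C>A)N evaluated on
either strand — six channels of the 96.

## Synthetic cohorts

`ctclone.simulate.generate_cohort` emulates the statistical structure the
analyses assume, with all randomness drawn from one seeded generator:

* subtype mix 64.4 / 5.0 / 4.1 / 17.3 / 9.2 % (HR+HER2-, HR+HER2+,
  HR-HER2+, TNBC, unknown), matching a large metastatic breast-cancer
  screening population;
* one truncal mutation per patient with
  mVAF ~ LogNormal(median 10 %, σ_log 1.0) truncated to (0.1, 80) %, plus
  Poisson(2) subclonal mutations at CF ~ Beta(1.2, 2.5) — both dominance
  classes populated;
* relative gene weights from published alteration frequencies (TP53 0.44,
  PIK3CA 0.35, ESR1 0.33, ...), hotspot spectra per gene with fixed
  synthetic genomic identities so recurrent sites deduplicate across
  patients, and multi-hit probabilities ESR1 0.50 / PIK3CA 0.23;
* VAF observation noise: truncated Gaussian, σ = 0.25 percentage points,
  approximating binomial counting error at the unique-molecule depths of
  duplex panels over the simulated VAF range;
* germline contaminants: Poisson(0.2) per patient, VAF ~ Normal(50, 1),
  population AF 10^U(-2.5, 0) % (always above the 0.001 % threshold, so
  survival of the filter is exactly the Normal tail mass outside
  [48, 52] %, 2Φ(−2) ≈ 4.6 %);
* SNV channels for private mutations drawn from an APOBEC/background
  signature mixture with enrichment per (HR class × dominance): HR+
  subclonal 0.40 vs dominant 0.05, other subtypes 0.10/0.10; hotspot
  channels are fixed. Half of all records are emitted in the purine frame
  to exercise strand collapsing;
* HER2 amplification in 9 % of patients with true CN 10 (otherwise 2);
  observed pCN = 2(1−t) + t·CN_true + Normal(0, 0.5), where t is the true
  tumour fraction.

Coordinates live on a toy contig with self-consistent contexts; no
reference genome is required. The ground-truth manifest records true CF,
dominance, APOBEC status and germline flags per variant, and true tumour
fraction and HER2 CN per patient.

What passing the synthetic checks shows: the pipeline inverts its own
generative model — exact CF recovery without noise, > 95 % dominance
accuracy under the default noise, analytic germline-survival mass,
purity-model round trips, and end-to-end detection of planted APOBEC
enrichment. What it does not show: robustness to real-data features the
generator omits — copy-number-distorted VAFs, clonal haematopoiesis,
panel-footprint context bias, subtype-specific gene interactions, or
calling errors upstream of the variant table.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` use: 500-patient cohorts
(~1 500–1 800 calls) for recovery and pipeline rates; 100 replicate
cohorts per condition for the APOBEC detection rates; catalogues of 1 000
mutations for mixture recovery; the exhaustive Fisher sweep covers all
2×2 tables with total ≤ 60 in the suite (~5 minutes) and total ≤ 30 in
the acceptance script. These sizes make the statistical assertions sharp
while keeping a full run in the minutes range on one CPU.

## Degenerate inputs and tie-breaks

* mVAF = 0 with variants present is an error (inconsistent input);
  absent variants give an absent mVAF, not an error.
* Zero-margin 2×2 tables: Fisher returns 1 with a warning; chi-squared
  raises.
* All-tied rank comparisons return p = 1 (no evidence either way);
  two constant-but-different bootstrap distributions return p = 0
  (complete separation).
* Golden-section line search evaluates the interval midpoint after
  convergence, so boundary optima (pure single-signature catalogues)
  fit to weight ≥ 0.9999.
* Bootstrap subsampling requires at least 10 mutations; below that the
  90 % subsample is degenerate and the call errors.
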