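# Methods

This note documents the models, defaults and design decisions behind
`traitboost`, and what the synthetic-data experiments do and do not show.

## Synthetic study generator (`traitboost.simulate`)

The generator emulates a resequencing panel of several hundred crop
accessions drawn from a handful of structured populations.

**Population structure.** Ancestral alternative-allele frequencies are
uniform on [0.05, 0.95]. Each population's frequency is a Beta draw with
mean p and variance p(1−p)·F (the Balding–Nichols model), so drift has
closed-form moments that the tests verify directly (frequency variance and
the 1−F reduction of expected heterozygosity, both at 10⁴ variants with a
15% tolerance). Admixture events replace a target population's frequency
vector by α·source + (1−α)·target, applied in configuration order. Any
structured-population generator would do for exercising the pipeline;
this one was chosen because its moments are testable in closed form.

**Genotypes and LD.** Genotypes are Binomial(2, p) draws per sample.
Local LD is created by grouping consecutive variants into blocks of
`ld_block_size` (default 5) where non-leader columns copy the block leader
entrywise and are independently redrawn with probability `ld_decay`
(default 0.1); `ld_decay = 0` gives r² = 1 within a block, `1` gives
independence. Causal variants are removed from their block (drawn
independently) so that recovery metrics can distinguish causal variants
from tagged neighbours; a `tagged_truth` mode instead plants causal
variants as block leaders, making their block mates r²-controlled proxies.
Missing calls are masked uniformly at `missing_rate` (default 2%).

**Trait model.** A binary trait arises from a liability model: the
liability is Σ effect·dosage over causal variants (missing dosages
contribute 0, which keeps the trait well-defined under missingness
independent of phenotype), the offset is the median liability (keeping the
marginal class balance near 0.5), and class 1 is drawn with probability
sigmoid(liability − offset). Defaults — 4 populations × 75 samples,
5 000 variants, F = 0.1, 10 causal variants at 1.5 log-odds per
alternative allele copy — define the reference test regime used throughout
the suite. F = 0.1 is a moderate between-country differentiation typical of
outcrossing crop panels; 1.5 log-odds per allele with 10 loci yields a
liability AUC above 0.8 against the drawn labels.

**Fixture files.** `write_fixture` emits VCF 4.2 (unphased GT, synthetic
AC/MQ/DP/SOR/QD/FS/*RankSum INFO metrics), phenotype and population TSVs, a
tiled GFF3 (alternating-strand genes with two exons, CDS inset to leave
UTR stubs and an intron) and a truth JSON. AC is the true alternative-allele
count of the genotypes; the other metrics are drawn inside their hard-filter
pass regions, except that a configurable fraction (default 10%) of
non-causal variants is planted to fail exactly one randomly chosen filter
expression so the filtering stage has something to do. Causal variants are
always given passing metrics: recovery metrics are only meaningful if the
planted truth survives QC. Fixtures are byte-identical under a fixed seed.

## Ingestion and filtering (`traitboost.vcfio`)

Dosage is the GT alternative-allele count; `./.` becomes NaN
(−1 in the heatmap recode). Multiallelic records raise by default or are
skipped with a warning. Hard filtering keeps biallelic variants satisfying
*all* expressions of the form `metric < c` / `metric > c`; the default set
is the ten-expression GATK-style panel listed in the README. Records with a
missing metric value fail that expression (conservative). Phenotype
classification maps two inclusive value ranges (or two category labels) to
classes 0/1; values outside both ranges are excluded from the trait, and
overlapping ranges are a configuration error.

## LD pruning (`traitboost.prune`)

Greedy windowed pruning with plink `--indep-pairwise W S r²` semantics in
*variant-count* units: within each window of `window` consecutive variants
(per chromosome, position order) every retained pair with r² above the
threshold loses its lower-MAF member (ties drop the later position), then
the window advances by `step`. The flag-style variant-count reading (50,
10) is the default; a physical-distance window is a documented alternative
reading of the same parameters, and the window/step are configurable if a
kb-based interpretation is wanted. r² is the squared Pearson correlation of
dosages over pairwise-complete samples — phase is unavailable in the dosage
data model, so haplotype-level composite LD is out of scope. Degenerate
cases: pairs with fewer than 2 complete samples or zero variance count as
r² = 0, and monomorphic variants are never dropped and never drop others.
The retained set is re-verified exhaustively in the tests (no surviving
within-window pair above the threshold) and the whole procedure is checked
for equality against an independent loop-based reference implementation on
random toy matrices.

## Resampled boosting selection (`traitboost.boost`)

The classifier is XGBoost (`binary:logistic`, histogram trees, missing
dosages routed natively). Hyperparameters are held in a frozen `ModelSpec`;
the default is conservatively regularised for p ≫ n genotype matrices
(learning rate 0.1, depth 3, min_child_weight 5, gamma 1, subsample 0.8,
colsample_bytree 0.8, 100 boosting rounds — the round count is a fixed
default, not tuned). Optional tuning is a seeded random search over
learning_rate ∈ [0.01, 0.3] (log), max_depth ∈ {2..10},
min_child_weight ∈ [1, 10], gamma ∈ [0, 5], subsample and
colsample_bytree ∈ [0.5, 1], scored by held-out accuracy on a single 80/20
split and frozen thereafter; the search strategy is deliberately pluggable
and the demonstration/acceptance runs use the default spec directly so
their results do not depend on a noisy tuning objective.

`resample_fit` refits the frozen spec on n_fits = 100 unstratified 80/20
splits (a split that leaves a single-class training set is redrawn with the
next seed and logged; a stratified option exists). Each fit records
held-out accuracy and the booster's gain map. "Appearance" means presence
in the gain map — used in at least one split; gain magnitude is recorded
but plays no role in selection. Selection is strict:
appearance_count > threshold (default 20 of 100, so 21 selects and 20 does
not). Everything is deterministic given (spec, base seed).

### Calibration of the appearance statistic — a known limitation

The appearance-frequency statistic is **not** calibrated under a
permutation null at desk scale. The 100 resampled training sets share ~80%
of their samples, so the variants with the largest spurious (or
population-structure-driven) marginal association are picked by the greedy
tree learner in nearly every fit: with n = 300 and ~10³ variants in the
pruned pool, label permutation still yields dozens-to-hundreds of
selections at the >20/100 threshold, and on planted fixtures the selected
set contains many non-causal variants alongside the recovered causal ones.
The effect weakens as the variant pool grows (with ~10⁵–10⁶ variants the
per-fit feature budget of a few hundred splits is spread over a vastly
wider competitive set, which is the regime where selected sets of a few
dozen variants arise naturally), but users should treat the selected set as
an enriched candidate pool, not a false-discovery-controlled list. The
acceptance suite measures exactly this: recall of planted causal variants
is high, while the null-selection and false-selection checks document the
miscalibration rather than hiding it. A practical mitigation (not
implemented here) is to compare each variant's appearance count against
its own permutation distribution.

## Baseline and 5×2cv test (`traitboost.validate`)

The baseline predicts the majority training class (ties resolve to class
0). The 5×2cv paired t-test follows Dietterich (1998): five replications
of 2-fold CV, per-fold accuracy differences d, per-replication variance
sᵢ² = (dᵢ₁ − d̄ᵢ)² + (dᵢ₂ − d̄ᵢ)², statistic t = d₁₁ / √(mean sᵢ²), two-sided
p from t₅. Folds are stratified by class (avoids single-class folds at
small n). Degenerate cases: all ten differences zero → t = 0, p = 1; zero
variance with a nonzero d₁₁ → p = 0 with a warning. The statistic is
unit-tested against hand arithmetic and its exact antisymmetry; its null
rejection rate over 200 replicates is checked to sit in the conservative
[0.02, 0.09] band around the nominal 5% level. The model entering the test
is refit per fold from the frozen tuned/default spec.

## Correlation expansion (`traitboost.expand`)

For each selected variant, Pearson r against every variant of the full
(unpruned) matrix over pairwise-complete samples; companions with
r ≥ 0.97 are kept. The threshold applies to *signed* r by default (the
documented convention of the upstream analysis); an `absolute` flag covers
the |r| reading. Missing data: pairwise-complete with a minimum of 10
complete pairs (below that the pair is skipped with a warning);
zero-variance companions are skipped. Verified against a brute-force
all-pairs oracle on toy matrices.

## Gene assignment and heatmap ordering (`traitboost.genes`)

Region taxonomy: exon_cds, utr5, utr3 (exon minus CDS, strand-aware),
intron, upstream/downstream (within a 5 kb window of the gene boundary on
the coding strand — the window is configurable; 5 kb matches common
annotator defaults), intergenic. Every variant receives exactly one region;
multi-gene hits report the highest-priority region
(exon_cds > UTR > intron > up/downstream), ties going to the nearest gene
start. Candidate genes are ranked by the number of selected/expanded
variants they carry. Heatmap ordering clusters accessions (within each
phenotype group) and variants hierarchically with Euclidean distance and
complete linkage on the −1/0/1/2 codes, treating −1 as an ordinary value —
this mirrors the recode-then-cluster convention; a missing-aware distance
would be a straightforward extension.

## F4 statistics (`traitboost.f4`)

Population frequencies are simple allele-count ratios over called
genotypes; variants with an uncalled population are dropped (the analysis
assumes a no-missing-data variant set). F4 is the plain frequency-product
form, mean of (p_A − p_B)(p_C − p_D), without small-sample bias
correction; an `f2`-decomposition route
(f2(A,D) + f2(B,C) − f2(A,C) − f2(B,D))/2 is exposed and, because the
per-population sampling terms cancel in this combination, agrees with the
product route to machine precision — the tests use this as an internal
cross-check. The jackknife is delete-one-block over contiguous blocks of
500 variants per chromosome (variant-count blocks; no genetic map exists
for synthetic data), using the unequal-block-size weighted jackknife
variance (Busing et al. 1999), which reduces to the classic delete-one
jackknife for equal blocks. p-values use the normal approximation to
z = F4/SE, standard for this statistic family. Quartets come from
configured migration hypotheses (source, sister, target) with a fixed
outgroup as A; graph inference (Treemix-style) is deliberately out of
scope. Interpretation: significantly positive → B–D gene flow,
significantly negative → B–C.

Calibration measured by the acceptance suite: on four drifted populations
with no admixture (10⁴ unlinked variants, blocks of 500), |z| < 3 in at
least 97 of 100 replicates; a planted B→D event at α = 0.3 yields a
significantly positive F4 in at least 90% of 50 replicates; and the mean
jackknife SE is within 30% of the across-replicate SD of the estimate.

## Problem sizes used by the tests and acceptance script

Unit tests run on toy matrices (tens of samples/variants). The study-scale
checks use the default fixture (300 samples × 5 000 variants, pruned to
~1 100) with 100 resampled fits — three fixture seeds for recovery, twenty
label permutations for null calibration — and the F4 simulations above;
the acceptance script runs one recovery seed and five permutations. These
sizes were chosen as the smallest at which the statistics stabilise.

## Acceptance-script output

`scripts/acceptance.py --seed S --out results/acceptance.json` writes one
JSON object; every value is recomputed at run time. Keys:
`causal_recall` and `false_selections` (planted-truth recovery on the
default fixture, proxies at r² > 0.8 counted as recovered),
`selected_variants`, `mean_model_accuracy_pct` and `baseline_accuracy_pct`
(held-out accuracy over the 100 resampled fits vs the majority share),
`cv52_t_vs_baseline` / `cv52_p_vs_baseline`, `null_zero_selection_rate`
and `null_mean_selected` (label-permutation runs), `cv52_null_rejection_rate`
(200 null replicates), the F4 block (`f4_worked_example`,
`f4_null_abs_z_below3_rate`, `f4_admixture_alpha03_power`,
`f4_jackknife_se_over_empirical_sd`), and the exactness oracles
(`ld_prune_oracle_agreement`, `gt_recode_exact`,
`hard_filter_truth_table_exact`, `region_classification_exact_rate`,
`expansion_oracle_agreement`).

## What passing tests do and do not show

The generator produces idealised panels: Hardy–Weinberg genotypes,
block-uniform LD, missingness independent of genotype and phenotype, a
purely additive liability trait and uniform ancestral frequencies. Passing
recovery tests therefore demonstrate correctness of the machinery, not
performance on real data, where linked selection, genotyping error
correlated with depth, dominance/epistasis and environment-dependent traits
all degrade recovery. The F4 module assumes unlinked variants within
blocks and drift-only divergence; recurrent mutation and ascertainment bias
are not modelled. No multiple-testing correction is applied across traits
or quartets, matching the analysis this package reproduces.
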