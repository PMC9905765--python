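# Methods

## Scope and data model

The package analyses two-group (case vs control) 16S OTU tables from
oral tongue-coating samples. Inputs are an integer count matrix
(samples × OTUs; every sample must have positive depth), a six-rank
taxonomy (domain…genus; a lineage that stops early is completed as
`<deepest named ancestor>_unclassified`, so e.g. a family-level
Micrococcaceae OTU aggregates under `Micrococcaceae_unclassified`),
per-sample metadata (group, cohort, SLEDAI, gender, clinical indices;
missing clinical values propagate as NaN and analyses are
pairwise-complete), and optionally a rooted newick phylogeny over OTU
ids for UniFrac. Orientation of the count table is never guessed — the
caller states whether samples are rows or columns, and both
orientations canonicalise to the same samples × OTUs table.

Counts are required to be integers. A `relative=True` flag admits
pre-normalised abundance tables everywhere except the abundance-based
richness estimators (Chao1, ACE), which are undefined for non-integer
data and refuse it. Whether to analyse raw counts, rarefied counts
(`rarefy`, default depth = minimum library size) or relative abundances
is left to the caller; every comparative stage internally uses
relative abundances.

## Diversity

Alpha indices follow the classical estimator definitions: Shannon
H = −Σ pᵢ ln pᵢ (natural log by default; the base is a parameter),
finite-sample Simpson D = Σ nᵢ(nᵢ−1)/(N(N−1)) with the complement 1−D
reported as the headline "Simpson diversity" (so that, like Shannon, it
increases with evenness — both columns are emitted because the bare
name "Simpson index" is ambiguous between D, 1−D and 1/D),
bias-corrected Chao1 = S_obs + F₁(F₁−1)/(2(F₂+1)), and ACE with the
community-standard rare/abundant threshold of 10 (the degenerate
C_ace = 0 case returns NaN). These agree with scikit-bio's estimators
to machine precision; the test suite asserts both that equivalence and
independent hand computations.

The accumulation curve is sample-based (distinct OTUs seen in the
first n randomly ordered samples, averaged over permutations), not
within-sample rarefaction; its endpoint equals total observed richness
exactly for any seed.

Beta diversity: Bray–Curtis on relative abundances and unweighted
UniFrac (presence = count > 0, no minimum-abundance filter), both in
[0, 1]; UniFrac is computed through scikit-bio and is cross-checked in
the tests against a brute-force edge-enumeration oracle. PCoA is
classical scaling (double-centre −½JD²J, eigendecompose; explained
proportions over positive eigenvalues only; axes beyond the positive
spectrum are reduced with a warning, never fabricated). NMDS minimises
Kruskal stress-1 with isotonic regression defining the monotone fit,
taking the best of 20 restarts (first initialised from PCoA, the rest
random; 300 iterations; stress tolerance 1e-7). Which distance
underlies an ordination is selectable; Bray–Curtis is the default.

## Differential abundance

Counts are aggregated to a rank by summing OTUs sharing the rank-level
name (per-sample totals conserved exactly; unclassified names stay
distinct per parent). Each taxon is tested with a two-sided Wilcoxon
rank-sum on relative abundances: exact enumeration when both groups
have ≤ 12 observations and the pooled values are tie-free, otherwise
the normal approximation with midranks and tie-corrected variance (no
continuity correction). A taxon constant across all samples is flagged
degenerate with p = 1. No multiple-testing correction is applied by
default — the screening protocol uses raw p < 0.05 — with
Benjamini–Hochberg available by flag as the safer option. Direction is
by group mean relative abundance.

The LDA effect size is a deliberately simplified two-class LEfSe:
Kruskal–Wallis screen at p < 0.05, then for 30 bootstrap subsamples of
two-thirds of each class, the one-dimensional linear-discriminant
effect of each surviving taxon — its absolute between-class mean
difference on abundances scaled to one million per sample — averaged
and reported as log₁₀ with pass threshold 3. There is no
subclass/one-against-all logic because the target study design has
none. The per-sample scaling makes scores invariant to multiplying all
abundances by a constant. On simulated null cohorts ≈ 97 % of taxa
score below the threshold; the few that cross are abundant taxa whose
chance mean differences exceed 10³ ppm, which is inherent to the
absolute-difference effect size.

Activity trends use Kruskal–Wallis across the mild (SLEDAI ≤ 6),
moderate (7–11) and severe (≥ 12) strata, with direction from the
Spearman correlation against the ordinal level; with only two
non-empty strata the test falls back to Wilcoxon with a warning.

## Marker selection, POD and ROC

Candidates for the classifier are the Wilcoxon-screen survivors.
Importance is out-of-bag permutation importance (Mean Decrease
Accuracy): per tree, the drop in OOB accuracy when one feature column
is permuted among that tree's OOB samples, averaged over trees; ties
in the ranking break alphabetically for determinism. All forest fits
use whole-community relative abundances restricted to the panel —
never re-normalised within the panel, which would make a one-OTU model
degenerate.

The five CV-error curves are five independently seeded repetitions of
stratified five-fold cross-validation (a single five-fold split would
yield per-fold curves of unequal test sizes; repetitions match the
"mean of five curves" construction). The published protocol ranks
importance once on the full derivation set before cross-validation,
which leaks ranking information into the fold errors; this is
reproduced as the default, with `rerank_in_folds=True` available to
re-rank inside each training fold. The cut-off is min(mean curve) +
across-repeat SD at the argmin, the optimal panel the smallest size
strictly below it (≤ when that SD is 0, so the argmin always
qualifies).

POD is the case-vote share of the final forest, in [0, 1]; the
case/control vote-odds form is emitted alongside and, being a monotone
transform, yields identical ROC analyses. AUC is the Mann–Whitney
probability with ties counted ½ (verified against exhaustive pair
counting), and the 95 % CI is DeLong's placement-value method
(S₁₀/m + S₀₁/n variance, normal quantile, truncated to [0, 1]) —
validated against a 2000-replicate bootstrap. External validation
applies the frozen model only; marker OTUs absent from an external
table are treated as relative abundance 0 with a warning, and any
sample-id overlap with training aborts.

Forest sizes default to 1000 trees for importance ranking and final
POD models and 200 inside the CV curves. OOB permutation importance
costs O(trees × features) tree predictions and the CV study fits
O(M × repeats × folds) forests, so these defaults keep a full
multi-seed selection study at minutes-per-seed while leaving rankings
and error curves stable; `n_trees` is a parameter at every call site
for users who want larger forests.

## Clinical statistics

Continuous indices: pooled-variance t-test with mean ± SD summaries
when the caller declares the index normal, otherwise Wilcoxon rank-sum
with median (IQR) — normality is caller-supplied, never auto-tested.
Categorical indices default to Pearson chi-square WITHOUT continuity
correction, the form that reproduces published case-control
gender-split p-values; a `method="auto"` switch applies Fisher's exact
test when any expected cell is < 1 or more than 20 % of cells are
< 5. OTU–clinical association is Spearman's rho with midranks, exact
permutation p for tie-free n ≤ 9 and the t-approximation otherwise;
gender is encoded F = 0, M = 1, and the grid defaults to case samples
only (the clinical indices of interest are the patients'), with
pooling available.

## The synthetic cohort generator

`simulate_cohort` draws a log-normal baseline composition
(`base_logmean_sd = 2`, giving a few dominant taxa and a long rare
tail), plants `n_markers = 10` differentially abundant OTUs — half
case-enriched by `marker_fold = 4`, half case-depleted by ¼, sampled
from the mid-abundance band (≈ 2×10⁻³–2×10⁻²) where real biomarker
OTUs live. Folds are planted exactly on the composition scale: marker
abundances are set to baseline × fold and the non-marker block absorbs
the compositional remainder. Subject-level variation is Dirichlet with
concentration `dispersion = 50`; the case-group concentration is
inflated by `1 + evenness_shift` (default 0.3), which makes case
communities more even and reproduces the direction of the
increased-diversity finding (case − control Shannon gap ≈ +0.05–0.15
at derivation scale). Counts are multinomial at a gamma-Poisson
library size (mean 20 000 reads, shape 10, floor 500). The default
three-cohort design is derivation 100/200, validation 40/80 and
cross-regional 42/80, the last perturbed by a shared multiplicative
log-normal batch shift (SD 0.35 on the log scale) that degrades but
does not destroy external AUC. Cases receive SLEDAI scores in
mild/moderate/severe proportions 0.50/0.40/0.10 (echoing published
derivation-cohort strata), with `activity_markers = 4` OTUs from a low-
abundance band scaled ×2 per stratum step, half up, half down.
Clinical indices get group-level shifts in the published directions
(lower WBC/RBC/Hb/Plt/lymphocytes, higher globulin in cases; 94 %
female); linked indices are instead generated by a Gaussian copula
against the OTU's pooled abundance ranks, so the target Spearman rho
holds marginally across the pooled cohort — within the case group
alone it attenuates, because the marker's group shift consumes part of
the rank range. Everything is reproducible byte-identically from the
seed.

What the generator does **not** emulate: phylogenetic signal in
composition (the provided random tree is a labelled stand-in for
UniFrac testing only), taxon–taxon interaction structure,
zero-inflation beyond what Dirichlet-multinomial induces, read-level
artefacts (chimeras, contamination), or longitudinal/treatment
dynamics. Tests passing on these cohorts therefore demonstrate the
correctness and calibration of the procedures, not their field
performance on real tongue-coating data.

## Study problem sizes

The multi-seed studies (`oramark.studies`) run the full screen → rank
→ CV-curves → cut-off → POD → cross-cohort ROC chain on ten
independent simulated studies at 300 OTUs, with 300-tree ranking,
50-tree CV forests capped at panel size 15, and 500-tree final models
— sizes chosen so one study seed completes in under half a minute on a
single core while preserving the marker-recovery and AUC behaviour of
larger settings. Typical results: the optimal panel is contained in
the planted marker set (± 1 extra) in ≥ 8/10 seeds; mean AUCs run
≈ 1.00 (resubstitution) / ≈ 0.99 (validation) / ≈ 0.99
(cross-regional); label-permuted training gives external AUC ≈ 0.5;
realized marker log-folds sit within ≈ 17 % of the planted log-fold.

## Numerical choices and degenerate inputs

Seeds: a single global seed expands into per-stage substreams (stable
hashes below 2³¹), so toggling one pipeline stage does not shift
another's randomness. Constant taxa: p = 1 and degenerate flags rather
than errors. Simpson needs N ≥ 2 reads; ACE returns NaN when every
rare taxon is a singleton; PCoA reduces k to the positive spectrum
with a warning; NMDS returns best-so-far with a converged flag on
hitting the iteration cap. Result tables are written as TSV with ≥ 10
significant digits so read∘write is the identity within 1e-9.

## Known limitations

Resubstitution AUC on the derivation cohort is optimistic (the model
is evaluated on its training samples), and the default
rank-before-CV protocol adds further optimism to the error curves —
both mirror the published procedure; nested CV is documented but not
implemented. The LEfSe variant omits subclass logic and cladograms.
Weighted UniFrac and Faith's PD are out of scope. The chi-square /
Fisher auto rule is advisory; sparse published tables were evidently
analysed by chi-square, hence the default.
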