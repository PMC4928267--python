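# Methods

## The model

A hybrid cultivar's genome is treated as a mixture of two ancestral gene
pools, domesticated *V. vinifera* and wild *Vitis*. All inference happens
in the dosage representation: at each curated biallelic site a diploid
sample carries 0, 1 or 2 copies of the ALT allele. Principal axes are
computed from the two ancestral panels **only**; every other sample is
located on those axes by projection. Because the two pools are strongly
diverged, PC1 is, to first order, the wild↔vinifera axis, and a sample's
position along it is an affine function of its expected ancestry
fraction. The ancestry coefficient is the PC1 distance ratio

    % vinifera = b / (a + b) * 100,

with a = |PC1 − mean_vinifera| and b = |PC1 − mean_wild|, the means taken
over the ancestral fitting samples' own scores. Within the inter-mean
interval the coefficient is strictly monotone (indeed linear) in the PC1
score; scores outside the interval are reported as computed and flagged
`out_of_interval` rather than clipped.

### Normalisation and projection

Sites are standardised as (g − μ_j)/√(p̂_j(1−p̂_j)) with
p̂_j = (1 + Σ_i g_ij)/(2 + 2n) over the n ancestral samples — the usual
eigenanalysis scaling for SNP dosages, with the +1/+2 adjustment keeping
the scale strictly positive. Loadings come from the SVD of the
standardised ancestral matrix; PC1 is sign-fixed so the vinifera panel
mean exceeds the wild mean (the coefficient is invariant to this
orientation, which tests verify). Held-out samples are projected as plain
dot products with the fitted loadings. When a projected sample has
missing dosages the dot product is restricted to its observed sites and
rescaled by (total sites / observed sites), which is unbiased when
missingness is unrelated to genotype; the main pipeline imputes first, so
this path is a fallback.

### Projection shrinkage and the two validation designs

Projecting samples that were not used in the fit shrinks their scores
toward the origin when the panel is small: the fitted axis partially
aligns with the panels' sampling noise, so fitting samples score
"too far out" relative to fresh draws from the same populations. The two
validation designs interact with this differently:

- **Cross-simulated offspring** (F1, backcrosses) are Mendelian
  combinations of the fitting samples themselves. Projection is linear in
  the genotype, so an offspring's expected score is the average of its
  parents' (unshrunk) scores, and cohort means recover 50/25/75% at *any*
  panel size. This is why the 7+7 study design validates cleanly despite
  tiny panels, and why the package's cross-validation runs at exactly
  those conditions.
- **Frequency-drawn admixed individuals** (fresh draws with true fraction
  α) do shrink. With 7-per-panel fitting samples at FST 0.3 and ~2,000
  sites the measured attenuation slope is ≈0.86 (a pure-wild individual
  is estimated near 7% instead of 0%). The parameter-recovery analysis
  therefore uses 30-per-panel fitting samples, where the residual
  attenuation is small (slope ≈0.96, per-level mean absolute error
  ≤ ~2 points across α ∈ {0, 0.1, …, 1}). No shrinkage correction is
  applied anywhere — hybrids and simulated offspring go through the
  identical projection, keeping the ratio estimator internally
  consistent. Users comparing cultivars against tiny panels should read
  extreme estimates (near 0 or 100%) as mildly compressed toward the
  centre.

## Curation chain

Defaults (CurationConfig) and their boundary semantics, which tests pin
bit-exactly:

| step | threshold | boundary |
|---|---|---|
| depth mask | minDP 8 reads | depth = 8 kept |
| site missingness | 20% | exactly 20% **dropped** (strict <) |
| sample missingness | 20% | exactly 20% **kept** (≤) |
| genome-wide MAF | 0.05 | exactly 0.05 **kept** (≥) |
| HWE heterozygote excess | p < 0.001 | exact one-sided test |
| ancestral MAF (pooled panels) | 0.1 | exactly 0.10 **dropped** (strict >) |

The asymmetry is deliberate: each filter's phrasing fixes its own
boundary. The ancestral-MAF filter is computed on the pooled (wild +
vinifera) panel and applied to all samples; a per-population variant
could be added but the pooled reading is the default. Filter order:
biallelic (at read) → depth → site missing → sample missing → MAF → HWE →
IBS report → imputation → panel equalisation → ancestral MAF → LD
pruning. All filters are idempotent.

### HWE heterozygote-excess test

Exact conditional (Levene–Haldane) test: given n diploids carrying
n_minor copies of the minor allele, the heterozygote count h (same parity
as n_minor) has

    P(h) ∝ n! · 2^h / (n_AA! · h! · n_aa!),

and the one-sided p-value sums P(h′) for h′ ≥ h_obs. Heterozygote excess
— not deficit — is the target because collapsed paralogs in GBS data
masquerade as universally heterozygous sites. Implemented in log-space
with gamma functions and renormalised over the parity class; the suite
checks it against exhaustive exact-rational enumeration for every
configuration with n ≤ 20 (tolerance 1e−10). A chi-square asymptotic
variant is available (`method="asymptotic"`) but exact is the default. A
two-sided option sums all outcomes no more likely than the observed one.

## LD and pruning

r² is the squared Pearson correlation of dosages over pairwise-complete
samples (composite genotype LD, not haplotype r²). Pruning slides a
10-site window in steps of 3 along each chromosome (site counts, never
spanning chromosomes); within a window, each pair of still-kept sites
with r² > 0.5 loses one member — the lower-MAF site, ties broken by
removing the later position. Undefined r² (monomorphic or <2 complete
pairs) never triggers removal. The procedure is deterministic and matches
a literal brute-force reimplementation on random instances.

## LD-kNN imputation

For a missing cell (sample i, site j): rank all other sites by r² to j
and take the top l (default 6, ties by site order); candidate samples are
those observed at j; the distance from i to a candidate is the **mean**
absolute dosage difference over the l sites where both are observed
(candidates with no comparable site are excluded), floored at
ε = 10⁻⁹; the k (default 17) nearest candidates — including all
candidates tied with the k-th distance, which makes the result invariant
to sample order — vote for their dosage at j with weight 1/d²; ties
between dosage classes break toward the smaller dosage. Imputation is
single-pass: every vote reads only pre-imputation values, so no imputed
value feeds another. Accuracy is estimated by masking observed cells
(seeded), re-imputing, and scoring exact recovery; the (l, k) grid search
evaluates every grid point on one fixed mask and breaks ties toward
smaller l then smaller k. The distance/weight details (mean vs sum,
exponent 2) are pinned here so results are deterministic; other
implementations of the same idea may differ in edge cases.

## Cross simulation

Gametes sample one allele per site per parent (dosage 1 → fair coin),
sites independent — no recombination map, as linkage between the sparse
curated sites is deliberately ignored. F1: one random parent from each
panel. Backcross: each offspring crosses a **freshly simulated** F1
(drawn with replacement) with a random panel member. Cohort summaries
report the mean and the empirical 2.5/97.5 percentile interval (linear
interpolation) of per-offspring estimates — an offspring-spread interval,
not a standard error of the mean, which is why it is several points wide
even at n = 10,000.

## Synthetic data generator

Emulates the curated study dataset's structure: per site an ancestral
frequency p ~ U(0.1, 0.9), population frequencies Beta-distributed with
mean p and variance FST·p(1−p) (Balding–Nichols; FST default 0.3 — strong
interspecific divergence, chosen so panels separate on PC1 the way two
grape species do), panels of 7+7 binomial diploids, 64 admixed hybrids
with true α evenly spaced on [0.1, 0.8], ~2.2% of sites written as
indels, positions uniform over 19 chromosomes (so pruning and distance
code paths are exercised), optional uniform missingness and Poisson
depth. LD-block mode draws individuals as two haplotypes per block from a
finite per-population haplotype pool, inducing within-block correlation
for imputation and pruning tests. What the generator does **not**
emulate: coalescent haplotype structure, allele-frequency spectra of real
GBS panels, depth-genotype error coupling, batch effects. Tests passing
on this generator demonstrate the estimator's internal calibration and
the filters' exact semantics, not robustness to real-data artefacts.

## Numerical choices and degenerate inputs

- Dosage is the ALT-allele count; "minor" is recomputed per context,
  never assumed to be ALT. Half-calls ("./1") and cells below minDP are
  missing; phased separators are accepted and ignored.
- Sites monomorphic in the ancestral panel make PCA normalisation
  meaningless and raise a named error; the ancestral-MAF filter
  guarantees they are gone in the pipeline.
- `ancestry_percent` raises if the two panel means coincide (a + b = 0).
- Variance explained uses all singular values of the standardised panel
  matrix as the denominator; retained components are capped at the
  numerical rank.
- Seeds: every stochastic routine takes an integer seed or Generator;
  pipeline stages split a master seed via `SeedSequence` so stages are
  independently reproducible. Outputs are byte-identical across reruns.

## Problem sizes

The shipped analyses and checks run on: 2,500-site cohorts with 7+7 (or
30+30 for parameter recovery) ancestral samples, 10,000 offspring per
simulated cross design, 50 admixed samples per α level, 100-seed PC1
separation batches, and exhaustive HWE enumeration to n = 20. These sizes
reproduce the study-scale behaviour on a single CPU in seconds to a few
minutes.

## Known limitations

- The coefficient is a one-dimensional (PC1) summary; cultivars with
  ancestry from a third gene pool, or wild parents unlike the wild panel,
  will be mis-summarised. Local (segment-level) ancestry is out of scope.
- Small-panel projection shrinkage compresses estimates for samples that
  are not linear combinations of the fitting panels (see above).
- First-degree relationship calling from IBS is out of scope; the IBS
  table is a vetting report, not a kinship estimator.
- The exact HWE filter assumes a single pooled population; stratified
  panels can fail it for demographic rather than technical reasons.
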