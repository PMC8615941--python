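# Methods

## Scientific setting

A single olfactory-receptor variant, rs6591536 (G>A, N183D) in *OR5A1*,
largely determines whether a person can smell beta-ionone (βI), a floral
aroma compound: the A allele abolishes sensitive detection and the
insensitive phenotype is recessive. The allele's frequency differs sharply
between continental populations — roughly 0.50 in African and 0.70 in East
Asian sources for the admixed Malagasy highland population this package
models — so the continental origin of the *OR5A1* locus copies inside an
admixed genome predicts the phenotype, and gene flow changes the population
prevalence of βI hyposmia. The package implements that whole inference
chain on synthetic cohorts with known ground truth, and accepts user data
(VCF genotypes, tidy response tables, ancestry-call tables) at every stage.

## Synthetic cohort model

**Admixture and tracts.** A single pulse of admixture `g` generations ago
(default 40 ≈ 1000 years at 25 y/generation) between an African (proportion
`alpha`, default 0.313) and an East Asian source. Each haplotype of a
chromosomal window of length `L` morgans carries ancestry tracts generated
by a Poisson breakpoint process with rate `g·L`; each tract's source is
African with probability `alpha`, independently. This is the simplest
generative model under which Markovian decoding is exactly well-posed: the
marginal per-haplotype ancestry process is a two-state Markov chain with
switch probability `1 − exp(−g·d)` over distance `d`, followed by a redraw
from the admixture prior.

**Focal genotype.** Each locus copy carries the insensitive allele A with
its source's frequency (`f_A_afr = 0.50`, `f_A_eas = 0.704`, the values the
homogeneous-ancestry strata of the cohort yield). Marker genotypes are
drawn the same way from per-marker source frequencies.

**Marker panel.** The default panel places 200 evenly spaced markers across
a 0.5-morgan window centred on the focal SNP (0.25 cM spacing) with
alternate-allele frequencies 0.9 (African) vs 0.1 (East Asian). Rationale:
at `g = 40` the unordered diplotype ancestry process switches at rate
`2g`, so ancestry segments span only ~1.25 cM; reliable decoding needs
several strongly informative markers per segment. Dense genotyping chips
provide orders of magnitude more markers than this over such a window, and
for source populations separated ~60 kya a curated ancestry-informative
subset with allele-frequency differentials around 0.8 is realistic. With a
sparser or less differentiated panel (e.g. 200 markers per morgan at
|Δf| = 0.6) posterior concentration drops sharply and most calls fall under
the 0.9 threshold — a genuine property of locus-ancestry inference, not of
this implementation.

**Phenotype.** A recessive penetrance model generates the measured
hyposmic/normosmic class: P(hyposmic | AA) = 0.95,
P(normosmic | AG) = 0.989, P(normosmic | GG) = 0.929 — the published
misclassification-aware rates, which already absorb phenotyping noise.

**Detection responses.** Normosmic simulants receive a true threshold at
ladder rung 4 of 6 (2.05×10⁻⁴ mol/L, the concentration that defines
normosmic); hyposmic simulants a threshold above the ladder top. At or
above threshold the correct vial is always chosen (rated *slight* at the
threshold rung, *distinct* above); below it the correct vial is hit with
the 4-AFC chance probability 0.25 and rated odorless. Because scoring uses
the maximal all-correct suffix, a truly insensitive simulant is classified
normosmic by k consecutive lucky guesses, where k is the number of rungs
from the cutoff to the top: probability 0.25² ≈ 6.25% at the 2.05×10⁻³
mol/L discrimination cutoff and 0.25³ ≈ 1.6% at the 2.05×10⁻⁴ normosmic
definition. Both floors are verified by simulation in the test suite.

**Ratings.** The four 7-point scales (hedonic, intensity, familiarity,
edibility) are rounded, [1,7]-clipped normal draws with genotype-specific
means/SDs taken from the published per-genotype summaries (e.g. intensity
AA 3.22 ± 1.06, AG 4.14 ± 1.12, GG 4.36 ± 0.78).

**Demographics.** Sex and age are generated labels with no effect on any
phenotype (the study found none): P(male) = 154/237, age ≈ round
N(23, 2.82) clipped to 18–33. The source report's sex margins (154 + 83)
exceed its n = 235; the proportion is therefore just a default.

**Reproducibility.** One root seed spawns named child streams
(`tracts, focal, markers, phenotype, afc, ratings, demographics`) via
`numpy.random.SeedSequence.spawn`, in that fixed order; identical
configuration + seed reproduces the cohort exactly.

## Threshold scoring and classification

The detection threshold is the lowest concentration answered correctly
together with *all* higher concentrations (maximal all-correct suffix);
isolated low-concentration hits are discarded, and a wrong answer at the
top rung yields the ANOSMIC sentinel (threshold = +inf). Intensity labels
are recorded but never affect scoring; a correct choice with a missing
rating counts as correct and is flagged.

Classification is `normosmic iff threshold ≤ cutoff`. The cutoff is a
mandatory, explicit parameter because the study uses different operating
points in different places; three presets are provided: `methods`
(2.05×10⁻³ mol/L, the sensitive/insensitive discrimination), `normosmic`
(2.05×10⁻⁴) and `hyposmic` (2.05×10⁻², the ladder top). The tie at an
exact rung-equal cutoff is resolved inclusively (a threshold equal to the
cutoff is normosmic), with a 1e-9 relative tolerance for float-identical
concentrations.

## Exact tests and odds ratios

* **Hardy–Weinberg**: exact test conditioning on allele counts; the p-value
  sums probabilities of heterozygote counts no more probable than observed
  (plain exact p, not mid-p; a `mid_p` flag exists).
* **2×2 association**: sample OR `ad/bc` (∞ on a zero cross-product cell,
  with a Haldane–Anscombe +0.5 corrected OR co-reported for transparency);
  conditional-MLE OR via the exponential-family score equation
  E[a | ψ] = a, solved by bracketed root finding on log ψ (tolerance
  1e-10 relative); 95% CI by inverting the one-sided exact
  (noncentral-hypergeometric) tests at 2.5% each tail; two-tailed p by
  point-probability summation (scipy's convention). Note that statistical
  packages differ here: on the reconstructed recessive table (80,4,3,119)
  the exact CMLE is 691.2 and the exact tail-inversion CI upper bound
  4984.7, whereas R's `fisher.test` prints 698.3 and 6709 for the same
  table because of looser internal root-finding; values in that
  neighbourhood printed elsewhere reflect that software path.
* **Identification control**: an r×2 conditional exact test (Freeman–Halton
  for two columns) by full enumeration — feasible because failure counts
  are small.
* **Genome scan**: per-site allelic 2×2 chi-square without continuity
  correction, replaced by Fisher's exact test when any expected cell < 5;
  sites filtered first by missingness (> 0.2) then by HWE exact p
  (< 1e-6); raw and Bonferroni p reported, plus the genomic inflation
  factor λ = median χ² / 0.4549.

## Local-ancestry HMM

A single-layer, three-state HMM on the unordered ancestry diplotype
{AFR/AFR, AFR/EAS, EAS/EAS} of unphased genotypes. Prior
(α², 2α(1−α), (1−α)²); per-interval transitions from two independent
per-haplotype chains with switch probability `1 − exp(−g·d)`; emissions
from within-source Hardy–Weinberg and independence of the two copies.
Decoding is scaled forward–backward (per-marker normalisation), stable for
panels of 10⁵+ markers; missing genotypes emit 1 in every state, and an
all-zero emission column raises an error naming the marker. Production
local-ancestry tools add a haplotype-cluster layer per source to model
within-source linkage disequilibrium; this simplification is intentional
and declared, and externally produced calls can be substituted via the
calls-table input everywhere downstream.

Hard calls take the argmax state when its posterior reaches the call
threshold (default 0.9), else UNASSIGNED. The threshold trades recall for
precision: at the default panel roughly a fifth of individuals are
UNASSIGNED while assigned calls match the simulated truth ~97% of the
time. Population-level African ancestry is best read from the expected
African dosage `2·P(AFR/AFR) + P(AFR/EAS)` averaged over individuals
(unbiased), not from the called strata (which under-represent the
heterozygous state).

## Stratification, source estimates, projection

Genotype (and phenotype) counts are cross-tabulated by ancestry diplotype;
UNASSIGNED individuals are excluded and counted. Source-population allele
and genotype frequencies come from the homogeneous strata only (AFR/AFR →
African source, EAS/EAS → East Asian), with Wilson 95% intervals (good
coverage at stratum sizes as small as 16). The ancestry–phenotype
association contrasts the homogeneous strata (EAS/EAS vs AFR/AFR ×
hyposmic/normosmic); the dual-ancestry stratum is reported separately.

Counterfactual AA prevalence at admixture proportion α:
`(α·f_A_afr + (1−α)·f_A_eas)²` under random mating (the default — the
cohort passes HWE, implying effectively random mating since admixture), or
a side-by-side mode `α²·f_AA_afr + 2α(1−α)·f_A_afr·f_A_eas +
(1−α)²·f_AA_eas` that uses observed within-source genotype frequencies;
the two coincide exactly when each source is itself in Hardy–Weinberg
proportions. Prevalence is monotone in α with the sign of
`f_A_afr − f_A_eas`, so with a lower African allele frequency any African
gene flow reduces insensitivity prevalence.

At the published counts this chain yields: mean African locus ancestry
31.2–31.3%, source insensitive-genotype prevalences 18.75% (African) and
48.9% (East Asian), projected cohort AA prevalence 0.410 at α = 0.313
versus 0.496 with no gene flow.

## Numerical and degenerate-input choices

Strictly increasing ladders and panel positions are enforced; tenfold
spacing is not. α ∈ {0, 1} collapses the HMM prior (warning, not error).
Zero within-group variance makes the ANOVA F undefined (NaN, flagged,
warning). Empty age bins are dropped with a warning; fewer than two
populated bins is an error. Genetic distances come from the panel's morgan
coordinates; file output maps morgans to base pairs at a constant 1 cM/Mb.
VCF coordinates are 1-based, tract files 0-based half-open (stated in
their headers). Table renderings use two-decimal, half-up "percent
(count)" cells so they compare by string with the published table.

## What the simulations do and do not show

The generator matches the analysis model by construction (i.i.d. tract
sources, within-source HWE, no LD within sources, no genotyping error, one
chromosome window, two sources). Passing recovery tests therefore show the
chain is internally consistent and correctly implemented, not that the HMM
is robust to model misspecification (reference-panel mismatch, source
substructure, LD) as real data would probe. The penetrance parameters are
themselves estimates from the modelled cohort, so the simulated
genotype→phenotype accuracy (~94–97% depending on the scoring cutoff)
brackets, rather than pins, the published 96.6%. Single-realisation
statistics from small strata (e.g. an ancestry odds ratio of 14 where the
model's expectation is ~2.5) are reproduced from the printed counts
exactly, but a calibrated simulation's typical value differs — that
distinction is deliberate and visible in the reports.

## Problem sizes used by the test suite and acceptance script

Recovery simulation n = 5000 (200 markers), guessing floor n = 10,000,
enumeration oracles over all 2×2 tables with total ≤ 14 plus seeded samples
to total 40, HMM path enumeration on 3- and 5-marker panels over all
genotype inputs, and smaller replicate studies (tens to hundreds of
simulations) for power/calibration properties.
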