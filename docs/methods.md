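# Methods

## Scope and model chain

The package models how conspicuous flowers are to each colour-vision
phenotype of a polymorphic primate population, and whether phenotype
predicts flower-foraging counts. The chain is: reflectance spectra →
quantum catches → receptor-noise-limited chromatic distance (JND) and
achromatic contrast → detectability/advantage summaries and SVM
discriminability; behavioural count tables → negative-binomial mixed models
with offsets.

## Spectra

Spectra are stored on the instrument's own reflectance scale. All chromatic
quantities are built from log catch *ratios*, so a global scale factor (or
the fraction-vs-percent convention) cancels exactly; no unit normalisation
is imposed. The analysis window is 400–700 nm, the range relevant to the
study species' cone vision; rows outside it are kept but flagged.

Dark correction subtracts the minimum reading inside the window, so the
corrected minimum is exactly zero (idempotent by construction). Resampling
is linear interpolation onto the regular 400…700 nm grid (default step
1 nm); extrapolation is refused. Negative readings (instrument noise around
the dark floor) are clipped to zero before quantum catches, with a logged
count. Replicates are averaged within (species, kind, part, surface).

The leafy background is the unweighted arithmetic mean of all leaf spectra,
pooling upper and lower surfaces of every species: a single adapting
background for the JND analysis. The SVM analysis deliberately does *not*
pool — each flower replicate is assessed against all individual leaf
spectra, preserving background heterogeneity.

## Photoreceptors and phenotypes

Pigment absorbance templates are generated from λmax with the Lamb
exponential closed form, S(x) ∝ 1/(e^{a(A−x)} + e^{b(B−x)} + e^{c(C−x)} + D),
x = λmax/λ, with a=70, A=0.880, b=28.5, B=0.924, c=−14.1, C=1.104, D=0.655,
peak-normalised on the evaluation grid. The Govardovskii A1 nomogram
(α band plus β band) is selectable per phenotype; both families are
config-exposed because template choice shifts absolute JNDs by a few
percent. Ocular-media transmission is not applied (identity); a hook exists
for supplying a transmission spectrum.

Phenotypes are one (dichromat) or two distinct (trichromat) L/M peaks from
{532, 543, 561} nm plus an S cone. The S-cone peak defaults to 430 nm — the
conventional capuchin value in the RNL modelling literature — and is
configurable, since absolute JND levels depend on it.

Receptor noise: Weber fraction ω_i = ν/√η_i with relative densities
η(S) : η(L/M pool) = 1 : 16, the pool split equally between the two classes
of a trichromat (8:8) and held whole for a dichromat (16). ν is scaled so
the most abundant class has ω = 0.05, the standard primate setting. These
defaults give dichromats ω = (0.20, 0.05) and trichromats
ω = (0.141, 0.05, 0.05). Absolute JND values scale with these settings;
*comparisons between phenotypes*, the quantity of scientific interest here,
are far less sensitive. All noise parameters live in the YAML phenotype
registry. The luminance channel is the equal-weight sum of the L/M
templates (a single template for dichromats) with its own Weber fraction
ω_lum = 0.05.

## RNL distances

Quantum catches are trapezoid quadrature of R·I·S on the common grid. The
illuminant defaults to an equal-photon (flat) spectrum; any measured
illuminant can be loaded from CSV. Von Kries adaptation to the mean leaf
background divides each catch by the background catch; because contrasts
are log ratios, this provably leaves Δf and every JND unchanged — it is
therefore implemented (and tested) as a coordinate transformation only.
Catches are floored at 1e-9 × the largest catch in a comparison before
logs, so dark-corrected zeros stay finite; all-zero comparisons raise a
degenerate-input error.

The dichromat and trichromat opponent formulas are equivalent to the
noise-weighted quadratic form min_t Σ_i (Δf_i − t)²/ω_i² (the projection of
Δf orthogonal to the intensity direction); the test suite verifies this
equivalence numerically to 1e-9 on random inputs.

Chromaticity coordinates for the SVM feature space: dichromat
ln(Q_LM/Q_S); trichromat (ln(Q_L/Q_M), ln(Q_S/√(Q_L·Q_M))); optional
lightness coordinate ln(Q_lum). The chromatic coordinates are invariant to
uniform intensity scaling.

## Detectability, advantage, and ambiguous aggregations

A part is detectable for a phenotype at ΔS > 1 and marginal in [1, 2);
cells at exactly 1.0 are counted detectable and flagged, so boundary
behaviour is visible rather than silent. Because "not detectable for
dichromats" can be read per-phenotype or pooled, both the any-dichromat and
all-dichromat counts are reported, with the full per-phenotype breakdown.
A part is *advantaged* for a trichromat phenotype when its ΔS exceeds the
best dichromat ΔS by ≥ 1 JND (boundary inclusive); species-level advantage
uses the any-part rule with the all-parts count reported alongside. Class
mean JNDs are reported both as pooled-cell means and as means of per-part
means (identical on complete tables).

## SVM discriminability

The instrument is fixed: an SVC with RBF kernel, C = 1, bandwidth from the
median heuristic on the standardised training rows (linear kernel
selectable), and inverse-frequency class weights — without weighting, the
hundreds of leaf rows would trivially outvote ~5 flower replicates.
Leave-one-out holds out each flower replicate in turn and trains on all
leaves plus the remaining replicates of the same part; leaves are never
held out, because the question is flower detectability against the
background. Standardisation is fitted per fold on training rows only. A
part counts as correctly categorised when the majority of its held-out
replicates are; per-replicate counts are always exported. Single-replicate
parts are flagged as degenerate. A zero-information geometry (all training
rows identical, held-out sample identical to them) defaults to the
background class.

A measured property of this instrument worth knowing: with balanced class
weights, a *tight* cluster of flower replicates is recovered by the RBF
machine even when it sits inside the leaf cloud (each held-out replicate is
rescued by its training mates). Discrimination failure — the behaviour
expected of a dichromat facing a background-matching flower — emerges when
within-part chromatic spread is comparable to the leaf population's spread.
The synthetic scenarios are built in that regime (below).

## Count models

Both behavioural analyses are NB2 (variance μ + μ²/θ) with log link,
fitted by maximising the Laplace-approximate marginal likelihood over
Gaussian random intercepts. θ is estimated on the log scale together with
the fixed effects and random-effect standard deviations by bounded
quasi-Newton (L-BFGS-B); the inner latent-field mode is found by damped
Newton with analytic gradient and Hessian. Starting values: β from a
no-random-effect NB regression (statsmodels GLM), σ = 0.1, θ = 1; the
closed-form NB score is supplied to the optimiser when there are no random
effects. Standard errors come from the observed information (central-
difference Hessian of the marginal likelihood), z = estimate/SE, and
two-sided p values from the normal approximation. Variance estimates at the
lower optimisation bound are flagged as boundary fits (their SEs are
reported as NaN rather than a fabricated number).

The scan model: flower scans per individual-cycle, offset log(total scans),
trichromat indicator, crossed random intercepts for individual and cycle
("repeated measures" read minimally; a nested alternative is selectable).
Individuals with fewer than 7 of 13 cycles are excluded. The FLPV model:
total small-patch flower-patch visits per individual, offset log(group
observation hours), random intercept for group. The small-patch filter
keeps the 11 listed small-crop species (names normalised for case and
whitespace), logs and excludes everything else, and retains zero-visit
individuals from the roster. Control contrasts refit the same families on
subsets: male vs female 561 dichromats, females only, and 532- vs
561-dichromat males.

At the study's realistic scan rates (≈0.4% of scans, ~50 scans per cycle)
the individual- and cycle-level variances are only weakly identified and
often collapse to the boundary, their overdispersion being absorbed by θ;
this is a property of the data regime, not of the optimiser, and the
phenotype z-test remains calibrated (verified by simulation).

Validation: the likelihood agrees with direct adaptive quadrature of the
random-effect integral to 1e-4 (relative) on toy models; the no-random-
effect Poisson limit matches the independent IRLS solution to 1e-6; offset
identities (exposure doubling, constant shifts) hold to their exact or
near-exact forms.

## Synthetic data

The spectral generator produces parametric curves, not measured spectra.
Foliage: a dark floor, a Gaussian green reflectance bump near 552 nm, and a
logistic near-infrared rise centred just beyond the window; 28 species with
log-normal parameter diversity, two surfaces (the lower ~1.35× brighter),
five replicates each — a few hundred leaf spectra of genuinely
heterogeneous chromaticity. Flower classes: *red-edge* (logistic step at
583 nm by default: dark-ish below, bright above — near-metameric with
foliage for dichromats, strongly separated on the trichromat red–green
axis), *white* (flat, bright, conspicuous to everyone), and *white-green*
(a bright foliage-shaped spectrum with a small flat admixture —
chromatically inside the leaf cloud for every phenotype, separable mainly
by lightness). Replicate-level jitter is deliberately large in the
dimensions where flower and foliage overlap, reflecting pigmentation and
maturity variation and placing the fixtures in the regime where
discrimination failure is possible at all (see the SVM section). All
reflectances are clipped to [0, 1]; one explicit seeded generator drives
everything, and equal seeds reproduce bit-identical output.

What the scenarios do *not* emulate: measured spectral shapes, specular
effects, canopy illumination geometry, phenology, or realistic proportions
of flower classes. Passing fixture tests therefore demonstrates that the
analysis chain detects the planted phenotype structure — not that any
particular wild flower is or is not conspicuous.

The behaviour generator draws the roster from the study population's
phenotype distribution (including its sex structure: all males dichromats,
no female 532 dichromats), then NB2 counts with planted log-rate ratios,
offsets and Gaussian random intercepts exactly matching the model
structure. Defaults: trichromat effect 0.6882 for patch visits and 0.3153
for scan counts (the two analyses' reference values), θ = 1.5, group sd
0.3, individual sd 0.3, cycle sd 0.2, ~50 scans per individual-cycle,
380–520 observation hours per group, and a small fraction of sporadically
present individuals to exercise the eligibility filter. FLPV records mix
small-patch species with large-patch distractor species so the species
filter does real work.

## Problem sizes and numerical settings

The acceptance study uses 200 replicates of 60 individuals for parameter
recovery and 100 for type-I calibration — sizes at which the whole script
completes in about half a minute on one CPU while holding Monte-Carlo error
on the bias near 0.02. Tolerances: inner Newton 1e-11 on the penalised
objective; outer optimiser 1e-10 relative with finite-difference step 1e-5
(analytic score when no random effects); catch flooring 1e-9 relative;
quadrature step = resampling step (1 nm). Ties at the 1-JND boundary are
counted detectable and flagged. Degenerate inputs (all-zero catches, empty
subsets, non-positive exposures) raise typed errors rather than producing
numbers.

## Known limitations

Absolute JND levels depend on the S-cone position, template family, noise
settings and illuminant, none of which are measured here; reproducing a
specific field study's absolute values requires calibrating those settings
against its own supplementary data, for which the config hooks exist. The
Laplace approximation can be optimistic for binary-ish counts in very small
groups; the quadrature cross-check covers the regimes used here. The SVM
verdicts are statements about one fixed instrument in a low-dimensional
chromaticity space, not about the best achievable classifier.
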