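# Methods

## Scope and model

`microrep` analyses fundus-controlled (MAIA-style) microperimetry of the
central visual field as a clinical-trial outcome measure, with X-linked
rod-cone dystrophy (RPGR-associated retinitis pigmentosa) as the motivating
population. An examination is a threshold in dB at each of the 68 loci of
the 10-2 grid, on a 0–36 dB dynamic range; a stimulus not seen at maximum
intensity is coded −1.0 dB by the device. The package computes three
sensitivity indices, quantifies their test–retest repeatability, and asks
what a *clinically significant* change is once natural variability is
accounted for.

### Grid

The 10-2 loci are the odd-integer lattice points (x, y) with
x² + y² ≤ 82, in degrees of visual angle. This is the unique circular
cutoff on the 2°-spaced odd lattice that yields 68 loci, with the |x|,|y| ≤ 3
square giving the central-16 subset and |x|,|y| ≤ 5 the central-36 subset
used for clustered endpoints. Ordering is row-major (y descending, x
ascending) so locus ids align across follow-up exams. Coordinates are
device/field coordinates; no nasal–temporal mirroring between eyes is
applied (devices report aligned follow-up grids, and published analyses do
not mirror).

Area weights for volume sensitivity: the default `uniform` method gives
every locus a 2°×2° = 4 deg² cell (total 272 deg²). A `voronoi_clipped`
method (Voronoi cells clipped to the 10° disc within the [−10, 10]²
square) is provided for irregular custom grids; on the standard grid the
interior cells are exactly 4 deg² and all cells tile the disc (sum 100π).

### Indices

- **Mean sensitivity (MS)** — arithmetic mean of raw thresholds with
  non-seen loci entering as −1.0 dB, then clamped below at 0.0 dB. The
  clamped-raw-mean convention is the only one consistent with both a
  "very low (<1 dB)" mean when over half the loci are non-seen and device
  outputs of exactly 0.0 dB despite residual seen loci; the unclamped mean
  is also exposed. Whether the device averages exactly this way is not
  documented publicly; the convention is stated, not asserted as
  device-identical.
- **Volume sensitivity** — remap −1.0 → 0.0 dB and just-seen 0.0 → 0.1 dB
  (the nominal value used in static perimetry volumetrics), then take the
  area-weighted sum Σ s·a over loci (dB·deg²). Implemented as the discrete
  sum, not a fitted hill-of-vision surface: the definition is the product
  of point sensitivities with the area each covers, and the discrete sum
  implements it exactly and reproducibly. Volume is zero iff every locus
  is non-seen, which is why it resists the floor effect that drives MS to
  0.0 in late disease. The remap happens at computation time only; stored
  thresholds are never mutated.
- **Median of seen loci** — median over thresholds > −1.0 dB; explicitly
  undefined (raised, not 0) when no locus is seen.

### Repeatability

Test–retest agreement uses Bland–Altman statistics on second-minus-first
raw differences (so −1.0 → 6.0 dB counts as +7.0 dB; with the dynamic
range this bounds differences to [−37, +37]). The **coefficient of
repeatability** is CoR = 1.96 × SD(differences) — the band containing 95%
of repeat measurements — with the conventional 1.96 multiplier rather than
a t-quantile.

Pointwise series contribute 68 correlated differences per patient-eye, so
the SD must respect clustering. The `mixed` method fits the
random-intercept model

    d_il = μ + b_i + ε_il,  b_i ~ N(0, σ_b²),  ε_il ~ N(0, σ_ε²)

by REML (statsmodels `MixedLM`; Powell optimisation, which reached the
REML optimum reliably in our checks where the default quasi-Newton
sometimes stopped short, e.g. at the σ_b ≈ 0 boundary) and uses
sd_diff = √(σ_b² + σ_ε²). For balanced data this REML estimate coincides
with the closed-form one-way ANOVA estimator, which the test suite uses as
an independent oracle. The `naive` method is the plain sample SD, used for
global indices where each patient-eye contributes a single difference.
A secondary formulation mirroring the common alternative — sensitivity as
the response with test-occasion and locus fixed effects plus a patient
random intercept — is provided (`mixed_sensitivity_cor`); its implied
difference SD is √2 × residual SD. Both are offered because published
descriptions of the mixed model in this setting are ambiguous between the
difference-response and sensitivity-response forms.

Confidence intervals are percentile intervals from a cluster bootstrap:
patients are resampled with replacement (preserving within-patient
correlation), the model refit per replicate, default 1000 replicates, seed
mandatory. Case resampling at patient level was chosen over parametric
simulation because the pointwise distributions are zero-inflated and
skewed, which a Gaussian parametric bootstrap would misrepresent.

Paired comparisons (e.g. test 2 vs test 3 per eye per index) use the
Wilcoxon signed-rank test with zero differences dropped (Wilcoxon's
original policy); an all-zero difference set raises an explicit
undefined-statistic error. Family-wise adjustment defaults to Holm
(step-down), configurable to Bonferroni; the choice of adjustment among
standard FWER methods is a free parameter here.

### Endpoints and classification

A k-of-n pointwise endpoint ("≥ k loci changing by ≥ δ dB", default k=5,
δ=7.0) is met by chance with probability P(X ≥ k), X ~ Binomial(n, p),
where p is the per-locus probability of exceeding the repeatability band —
0.05 by the CoR's definition when δ equals the (rounded-down) CoR. The
implementation uses the numerically stable binomial survival function;
a brute-force pmf summation and a Monte-Carlo simulation serve as oracles.
With p = 0.05 this gives ≈25.3% for n=68, ≈3.2% for n=36 and ≈0.09% for
n=16 — the quantitative argument for restricting clustered endpoints to
central subsets. For δ below the CoR the per-point probability exceeds
0.05 and the defaults must be overridden; p is always configurable.

Pointwise classification counts n_gain (differences ≥ +δ) and n_decline
(≤ −δ) over the chosen region and reports *all* flags — gain-significant
(n_gain ≥ k), decline-significant, mixed (both directions present and
total ≥ k), subthreshold (1 ≤ total < k), no-change — because the
categories genuinely overlap (a pair can be decline-significant *and*
mixed). A single label with precedence decline > gain > mixed >
subthreshold > none is offered for summary tables; the precedence is an
explicit documented choice, not a claim about how any published table was
built. Global index changes are three-way classified against a CoR cutoff
with an inclusive boundary (|Δ| = cutoff is significant). For cross-index
concordance each index is collapsed to gain/decline/within (pointwise
pairs significant in both directions map to "mixed" and therefore count as
discordant), and agreement is the fraction of pairs with identical
categories across all indices.

All cutoffs (δ, k, region, global cutoffs) are configuration, never
constants: repeatability is population-specific, so what counts as
clinically significant must be estimated for the population under study.

### Reliability filter

Fixation losses — button presses to blind-spot stimuli — at or above 30%
mark an exam unreliable. The boundary is excluded (≥ 30% fails) and a
warning is logged at exactly 30%, because clinical phrasing is ambiguous
("30% or greater excluded" vs "30% or less included"); exclusion is
per-exam, never per-patient, so a reliable fellow-eye exam is retained.

## Synthetic cohort generator

No public pointwise microperimetry datasets exist for this population, so
validation uses a generator that emulates the statistical structure the
analyses rely on. The latent field is radial:

    latent(r) = s_center − ring_depth·exp(−(r − ring_radius)²/(2·ring_width²))
                − slope·max(0, r − ring_radius) − rate·years

a preserved central island, a parafoveal ring scotoma and a peripheral
decline, progressing uniformly at `rate` dB/year. Observation adds a
per-exam patient shift (sd σ_patient, inducing clustered differences),
per-locus Gaussian noise (sd σ_within per exam, so the test–retest
difference sd is σ_within√2 when σ_patient = 0), optional integer-dB
quantization standing in for the 4-2 staircase's grid, a 36 dB ceiling,
and the device floor: values below 0 dB are recorded as −1.0. A full
staircase psychophysics simulation is deliberately out of scope — the
analyses consume thresholds, and what must hold is the CoR-recovery
property, which Gaussian noise with quantization satisfies (quantization
adds ≈1/12 dB² per exam, inflating a 4.85 dB difference sd to ≈4.87).

Presets (`data/presets.yaml`, config not code) define early/mid/late
disease stages plus a `flat` field for noise-recovery studies. The `mid`
preset is calibrated so a default cohort has roughly a third of loci
non-seen (band 25–45%) with the pointwise distribution mode at −1.0 dB —
the zero-inflated positive skew characteristic of mid-stage RP fields.
The `late` preset produces fields where MS floors at 0.0 dB while volume
stays positive. Both eyes share a patient's field model up to a small
(0.5 dB sd) offset, reflecting the high inter-eye symmetry of progression
in this disease; the progression default (0.8 dB/year) is a free parameter
with no claimed fidelity to natural history. Fixation losses are drawn
from 100·Beta(1, 19) (mean 5%, occasional >30% values exercising the
reliability filter).

What the generator does **not** emulate: fixation instability and
eye-tracking error, fatigue trends within or across tests (the observed
higher left-eye variability in real data), transition-zone-specific
variability, learning effects in test 1, or treatment effects. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not fidelity to any particular patient population.

## Problem sizes and numerical choices

Simulated studies use 13 patients × 2 eyes × 3 tests (repeatability) and
14 patients × 2 visits (longitudinal) — the scale typical of rare-disease
cohorts and sufficient for the parameter-recovery checks; recovery tests
average 20 seeds. Degenerate inputs are handled explicitly: all-equal
differences give CoR 0 (not an error); the mixed method requires ≥2
patients; an all-non-seen exam has volume 0, MS 0 and an *undefined*
seen-median; sub-1 dB CoRs round down to 0 with a warning since the
resulting cutoff degenerates. Bootstrap percentile intervals use the
0.025/0.975 quantiles; REML variance components at the σ_b = 0 boundary
are accepted as 0.

## Known limitations

- CoR values from synthetic cohorts characterise the generator, not any
  real population; real per-eye CoRs must be estimated from that
  population's own triplicate data.
- The binomial endpoint analysis assumes independent per-locus
  exceedances; spatial correlation of errors (e.g. at scotoma borders)
  would change the tail probabilities.
- The volume index depends on the area method; uniform weights are exact
  for the regular 10-2 grid but not for radial custom grids, where the
  Voronoi method should be preferred.
- Mean sensitivity's clamp makes it non-invertible at 0.0 dB; analyses of
  floored exams should use volume or the exposed unclamped mean.
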