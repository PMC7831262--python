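# Methods

## Scope

`phenoscreen` analyses a medium-throughput phenotypic screen for compounds
that expand retinal stem and progenitor cells (RSPCs) in culture, plus the
downstream assays used to characterise the hits: dose-response
fold-of-control summaries, receptor-antagonist effect partitioning,
clonal sphere assays (retinal and pancreatic), monolayer
viability/proliferation time courses, differentiation marker proportions,
in-vivo co-label densities, and intravitreal dosing arithmetic. A
synthetic-data generator with explicit ground truth drives all testing;
no external data are required.

## Screen model and hit calling

Each screen consists of 96-well plates carrying, in total, 80 vehicle
(0.1% DMSO) control wells seeded at 1x density, 12 pseudo-positive
control wells seeded at 2x density (substituting for a reference active
compound), and one well per library compound at 1 μM. Two channels are
read per well after 7 days: Hoechst-positive nuclei count and total GFP
area of an actin-GFP reporter strain.

Values are normalised as percent of control, POC = 100 · x / mean(1x
controls); the control set's own POC values average exactly 100. A hit
is a compound exceeding

    mean(control) + k · SD(control)        (k = 3 by default)

on *both* channels. The inequality is strict; compounds sitting exactly
on a threshold are flagged (`boundary_tie`) rather than silently resolved
— the source assays state "3 SD above" without boundary semantics, so the
convention is explicit and reported. Because the criterion is affine in
each channel, calling on raw values and on POC values is equivalent
(property-tested). Thresholds are computed per screen from the pooled 1x
controls (one 80-well control set per screen); a per-plate mode exists
for designs with plate-level controls.

The hypertrophy ratio POC(area)/POC(nuclei) distinguishes "more cells"
from "bigger cells". The flag threshold of 1.5 is this package's
convention (the underlying observation is only "much greater than 1");
the raw ratio is always reported beside the flag.

Screen QC uses the 1x/2x control separation: SSMD in the two-group
unequal-variance form (m₂ − m₁)/√(s₁² + s₂²), signal-to-noise
(m₂ − m₁)/s₁, and per-group CVs (sample SD, n − 1, throughout). These are
the standard HTS definitions; the source names the metrics without
formulas, so the forms used are documented here and configurable at the
reporting layer.

Class enrichment is the exact upper-tail hypergeometric probability
P(X ≥ k) of k class members among n hits drawn from an N-compound library
containing K class members. The draw count n is whatever hit list the
caller supplies — union across screens by default, per-screen optionally —
because the original analysis does not state which was used; both modes
give the same qualitative conclusion at the screen's geometry
(N = 400, K = 4).

## Synthetic screen generator

Noise is multiplicative and CV-parameterised. Default distribution is
lognormal with unit mean (σ² = ln(1 + CV²), location −σ²/2): strictly
positive and CV-stable, matching cell-count behaviour. A Gaussian option
(1 + CV·z) supports analytic-tail calibration. The two channels share a
latent bivariate-normal factor with configurable correlation (default
0.5: both channels read the same underlying cell population; the joint
model is unstated in the source, so this is a package choice). Counts are
rounded; negative draws are truncated at zero with a logged warning.
Compound wells are single-replicate, as in the screen design. Control CV
defaults to 0.1 — the screen reports low control variability but no
per-channel CV value, so this is a modelling default, flagged here.

One master seed per config; every table derives a named
`SeedSequence([seed, stream])` child, so adding a generator never shifts
existing streams, and identical seed + config is byte-identical after
serialization.

### Calibration note

With thresholds estimated from n = 80 controls, the expected per-channel
null hit rate under Gaussian noise is not the known-threshold tail
Φ̄(3) = 1.350 × 10⁻³ but its exact finite-sample form

    P(t₇₉ > 3/√(1 + 1/80)) = 1.907 × 10⁻³,

since a new well exceeds x̄ + 3s with t-distributed standardised margin.
The test suite checks both layers: generator output against Φ̄(3) using
the *true* threshold, and the full hit-calling path against the t-form.

## Downstream quantifications

**Dose-response.** Fold-of-control = mean(drug)/mean(vehicle) (ratio of
group means; a paired mean-of-ratios mode exists since the source does
not state which was used). SE by the delta method on the numerator with
the vehicle mean treated as fixed, matching how percent-of-control data
are conventionally reported. No EC50/4PL fitting: the assays report folds
at discrete doses only.

**Effect partitioning.** For a drug at FC_d-fold of control reduced to
FC_c under a receptor antagonist, the blocked receptor mediated
100·(FC_d − FC_c)/(FC_d − 1) percent of the increase. Defined only for
FC_d > 1; values outside [0, 100] are reported with an out-of-range flag,
never clamped, because a combo above the drug or below control is itself
diagnostic. The formula is invariant to re-expressing folds as percent
increases (property-tested).

**Intravitreal dilution.** final = injected · bolus/final_volume with
defaults 2 μL and 7 μL (standard mouse vitreous volume); inverse mode
returns the required injected concentration. Round-trip identity holds to
1e-12 relative.

**Sphere assays.** Retinal assay: spheres ≥ 80 μm are stem-derived,
< 80 μm progenitor-derived; the boundary is inclusive on the stem side
("80 μm or above") and held in one configurable constant. Pancreatic
assay: objects < 30 μm are aggregation artifacts and excluded; bins are
total ≥ 30, 30–49, ≥ 50 μm (boundaries inclusive upward). Sphere-forming
frequency carries a Clopper-Pearson 95% CI. Condition comparisons use
Welch's t on per-replicate counts (the variant is unstated in the source;
Welch is the default here). Diameters are taken as given — deriving them
from masks is out of scope; only the mask → per-label mean-gray-value step
is implemented (arithmetic mean of intensity pixels under each positive
integer label, background excluded, via labelled-array reduction).

**Time courses.** Live fraction = 1 − EthD-1⁺/total and EdU fraction =
EdU⁺/total are computed per well, then averaged within condition × day
with SE across wells (the well is the replicate unit in vitro; the eye in
vivo). Folds vs control are taken at matching days; a zero control
fraction yields an explicit undefined flag, not infinity. The generator
draws labelled counts binomially; since binomial sampling has no CV dial,
the zero-noise analog is `sampling="expected"` (rounded expected counts),
and the defaults (2000 cells/well; live fractions 0.42/0.80/0.90 at days
2/4/6; control EdU 0.02/0.05/0.005 peaking at day 4) make expected counts
integral so recovery is exact. The EdU defaults are package choices
consistent with the reported ~5.6-fold day-4 treatment effect remaining a
valid fraction.

**Group comparisons.** Two groups: two-tailed Welch t (pooled optional —
the source says "Student's t" without a variance assumption). Three or
more: one-way ANOVA with Holm-Sidak-adjusted pairwise Welch t post hocs,
or Fisher LSD (pooled-MSE t, unadjusted) as the stated alternative.
Factorial designs: two-way ANOVA with type-II sums of squares, which
coincides with type I/III for the balanced designs in scope.

## What the generator does and does not emulate

It reproduces the screen's statistical geometry (well counts, control
structure, single-replicate compounds, two correlated channels, CV-scale
noise), rare binomial sphere founding with lognormal diameters, and
binomial label counts. It does not emulate plate-edge or drift artifacts,
compound precipitation or fluorescence artifacts, pipetting failures,
segmentation error, or inter-plate batch effects. Passing recovery and
calibration tests therefore demonstrates correctness of the estimators
under the assumed noise model, not robustness to those real-data
pathologies (spatial correction such as B-score is deliberately out of
scope — the analysed screen used none).

## Problem sizes

Calibration and recovery suites run at: 1000 simulated null screens
(80 controls + 400 compounds each) for false-positive calibration; 500
screens with eight fold-3 spikes for recovery rates; 1000 replicates for
estimator unbiasedness (dose-response at N = 3, CV = 0.1; sphere
frequency at 10⁵ plated cells, where the binomial CI is tight enough to
resolve 1% bias; time courses at assay defaults). Exhaustive
hypergeometric cross-checks cover every (N ≤ 30, K, n, k) plus a 10⁶-draw
sampling check at N = 400.

## Known limitations

- Compound wells are single-replicate by design, so per-compound
  variance is not estimable from a screen; hit confidence rests entirely
  on control statistics.
- The hypergeometric draw-count convention (union vs per-screen hits)
  changes p-values slightly; both are exposed, neither asserted as the
  original choice.
- The generator's channel correlation is specified on the latent normal
  scale; the realised count-scale correlation is marginally smaller at
  high CV.
- No image segmentation: sphere diameters and well-level measurements
  enter as numbers.
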