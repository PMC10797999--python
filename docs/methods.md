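# Methods

## Scope and model

`tfscreen` implements the statistical chain of a DoE-based overexpression
screen: design generation, synthetic readout simulation, control-normalized
phenotyping, response-surface modeling with contribution rankings, and
condition-responsive querying/classification. It does not model wet-lab
protocol details (buffers, plate geometry, dilution corrections are assumed
pre-applied), kinetic growth curves, or any mechanistic TF regulatory
network.

## Experimental design

The design is a face-centered central composite design: for k numeric
factors, the 2^k factorial corners, 2k axial points at face distance α = 1
and the center point, deduplicated (for k = 1 the axial points coincide with
the corners; for k = 2 the set equals the full 3×3 grid). This point set is
crossed with every combination of the binary categoric factors. Central
variants are exactly those with all numeric codes 0, so there are 2^m of
them. Replication is per variant (default central ×5, outer ×1) and the
execution order is a uniform random permutation drawn from
`numpy.random.default_rng(seed)`; the seed is mandatory. Biological
replicates multiply runs into cultures downstream.

Coded → actual mapping is piecewise-linear through the center for numeric
factors (exact roundtrip), a two-level lookup for categoric factors. The
default factor battery is oxygen availability (low/high), carbon source
(glucose/glycerol), nitrogen source (ammonium sulfate/casamino acids), pH
(3/5/7) and temperature (22/28/34 °C), in that fixed order. Printed summary
moments of the original DoE software (means/SDs of factor columns) are
display artifacts and are not reproduced.

## Synthetic data generator

Ground truth is a quadratic surface over the coded factors per measure
(growth, fluorescence), with positivity required at every design point. The
default control strain grows best near the center of the pH/temperature
range (negative curvature in both) with a positive high-oxygen effect, and
its fluorescence carries a strong positive high-oxygen main effect — the
dominant promoter of reporter-protein synthesis — plus a mild
oxygen×nitrogen interaction so that the "displayed contributions sum to
< 100%" behavior is exercised.

Noise is multiplicative lognormal with unit mean, parameterized by a
coefficient of variation (`noise_cv`, default 0.08): plate-reader error is
scale-proportional, and a multiplicative model keeps readouts positive for
every seed. Values are clipped at a per-surface floor. No well-position,
plate-edge or batch effects are simulated, and no time courses — a passing
pipeline therefore demonstrates statistical correctness under idealized
replicate noise, not robustness to spatially structured artifacts.

Phenotype archetypes deform the control surfaces by condition-dependent
FC multipliers: `global_enhancer` (fluorescence ×2.0 everywhere),
`global_silencer` (×0.45, within the 0.4–0.5 band typical of dedicated
r-Prot silencers; growth untouched), `inverted` (fluorescence FC ramping
linearly along one numeric variable, default 1.4 at pH −1 to 0.6 at +1),
`oa_growth_enhancer` (growth ×1.10 under low oxygen only, fluorescence
×0.95), `oa_sensitive` (growth ×0.85 under low oxygen only), and
`null_tf`/`control` (identity). Truth labels travel out-of-band (a separate
mapping), so analysis code cannot read them.

## Measures and fold changes

RFU is computed per replicate and then averaged; FC is the ratio of
per-variant replicate means (TF over control at the identical variant) —
with duplicate-level replication the ratio of means is the stabler
aggregate, and it makes control-vs-control FC exactly 1. Consequently
normalized-r-Prot FC equals total-r-Prot FC divided by growth FC exactly
only in the noise-free limit; the test suite asserts it there.

Significance is a per-condition two-group one-way ANOVA (equivalent to the
squared pooled-variance t, asserted in tests) at α = 0.05, with no
multiple-testing correction by default — per-point reporting is the
screening convention here — and an optional Benjamini–Hochberg mode.
Groups with fewer than two replicates yield a missing p and a
non-significant call. Identical groups are reported at p = 1. Degenerate
wells (OD600 ≤ 0) are flagged, logged and excluded, never imputed.

## Response-surface models and contributions

The model per strain × measure is OLS on coded factors with intercept, five
main effects, two quadratics and all ten two-factor interactions (single-df
terms throughout); it can be fitted on raw per-culture responses (`raw`
mode, 208 observations) or on one FC per variant (`fc` mode, 72
observations). Rank deficiency raises an error naming the aliased terms.

The ANOVA partition is Type II (partial) SS computed by reduced-model RSS
differences with the standard containment rule; it is cross-checked in
tests against `statsmodels`' formula-based `anova_lm(typ=2)` and coincides
with sequential SS for the main effects on this balanced design. Quadratic
terms are correlated with each other under center replication, so their
Type II and sequential SS differ slightly; the equivalence is asserted for
main effects only.

Contribution percentages divide each variable's Type II SS by the sum of
all model-term SS. Design choices: a numeric variable is displayed as one
pooled (linear + quadratic) percentage; the direction sign comes from the
linear/main coefficient; interactions contribute to the denominator only.
Control normalization of contributions is a percentage-point *difference*
(TF minus control) — the natural reading of "higher by X%" phrasing — with
the ratio available to callers by dividing the columns themselves. A
zero-signal model yields an all-zero table with a warning rather than an
error, because a control strain normalized against itself legitimately has
constant FC ≡ 1.

## Queries and classification

The 10% FC margin is applied multiplicatively around FC = 1 (hits need
FC ≥ 1.1 or ≤ 0.9), the natural null for a ratio. The inverted search
requires *both* extremes significant and pairs conditions with all other
variables matched. Ranking: highest FC (up), lowest (down), largest
|FC delta| between extremes (inverted); ties break on strain id.

Classifier rules, in precedence order (first match wins):

1. `global_rprot_silencer`: |mean growth FC − 1| ≤ 0.05, mean normalized
   r-Prot FC ≤ 0.5, ≥ 50% of conditions significant;
2. `global_rprot_enhancer`: mean normalized r-Prot FC ≥ 1.25, ≥ 50%
   significant;
3. `oa_growth_enhancer`: mean growth FC under low oxygen ≥ 1.05 and a
   positive low-oxygen growth-contribution delta vs the control (FC-mode
   fit);
4. `oa_sensitive`: mean growth FC under low oxygen ≤ 0.95 and a negative
   low-oxygen delta — defined symmetrically to rule 3, a package choice
   since only the enhancer side has a canonical description;
5. `none`.

All thresholds live in `ClassifierThresholds` and are configurable. The
`inverted` archetype maps to `none` by design: its condition-averaged FC is
~1, and inverted responders are found by the dedicated query, not by the
global classifier.

## Numerical and testing choices

Monte-Carlo problem sizes: parameter-recovery uses 500 replicates at
noise_cv = 0.08 over 104 runs × 2 replicates; calibration uses 2000
null-response model fits in the test suite and 400 in the acceptance
script; archetype recovery uses a 60-strain screen (10 per archetype) and
100 silencer replicates. Unbiasedness of the 8 surface coefficients is
asserted family-wise (mean |z| ≤ 2, max |z| ≤ 3.5 over the coefficient
z-scores): eight simultaneous raw 2σ checks would reject an exactly
unbiased estimator about a third of the time, so the family-wise bound is
the calibrated equivalent of "within two standard errors".

Exports sort strains and variants, fix float formatting (10 significant
digits) and round JSON values to 10 decimals so re-export is
byte-identical. All randomness flows through `numpy.random.default_rng`
seeds; screen-level seeds spawn per-strain sub-seeds below 2^31.

## Known limitations

- Heteroscedasticity is ignored by OLS (weights would be needed for
  efficiency; estimates remain unbiased).
- No lack-of-fit test against pure error, despite replicated centers — a
  natural extension.
- The classifier's precedence is hard (mutually exclusive labels); mixed
  phenotypes report only the first matching rule.
- FC-mode fits treat the 72 FC values as independent observations, ignoring
  the shared control denominator.
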