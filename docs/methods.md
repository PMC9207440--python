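# Methods

This note records the statistical model, the generator's assumptions, the
numerical choices, and the places where the design was genuinely open.

## Cosinor model and estimation

The single-component cosinor f(t) = M + A·cos(ωt − Φ) is fitted with the
angular frequency fixed at ω = π/12 rad/h (24-h period; no period
estimation, no multi-component extension). Estimation uses the linear
reparameterisation f(t) = M + β_c·cos(ωt) + β_s·sin(ωt), solved by
`numpy.linalg.lstsq`; A = √(β_c² + β_s²) and Φ = atan2(β_s, β_c). Because
the reparameterisation is exact, the linear solution is the global optimum
of the nonlinear problem — the test suite verifies this against a
brute-force acrophase grid search (10⁻³ rad grid, iterated parabolic
refinement) on random instances.

Standard errors come from the residual sum of squares: Cov(M, β_c, β_s) =
σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n − 3), and SE(A), SE(Φ) by first-order
(delta-method) propagation. Monte-Carlo calibration (10,000 replicates of
the 7-time × 7-fish design at M = 5, A = 2, σ = 0.5) shows the empirical SD
of Â within a few percent of the reported SE(A). Interval checks pair these
residual-based SEs with t critical values on n − 3 degrees of freedom (the
standard regression interval); with the z value 1.96 instead, true coverage
at 46 df would be ≈ 94.4 % rather than 95 %.

Conventions and edge cases:

- The fit runs on individual measurements (n_obs = total individuals), not
  time-point means; `StudyConfig(fit_on_means=True)` provides the
  means-based alternative for sensitivity analysis. Which variant original
  field studies use is rarely stated; both are exposed and logged.
- The next-day follow-up sample ("ZT 3b") enters at t = 27 h, which is
  phase-equivalent to 3 h under the fixed period; `include_follow_up=False`
  drops it (useful when it is reserved for the postprandial contrast).
- Amplitudes below 10⁻¹² × max(1, |M|) are treated as exactly zero: the
  acrophase and SE(A)/A are then undefined (NaN) and such a series can
  never be called rhythmic.
- Â = |β| is upward-biased when the true amplitude is near zero; this is a
  property of the estimator, not a defect, and the null false-positive rate
  is controlled by the joint criterion (see below).
- Fewer than 4 observations, or fewer than 3 distinct sampling phases
  modulo 24 h, is a rank-deficient design and raises an error.

## Rhythm decision

A series is rhythmic iff (1) ANOVA p < α, (2) SE(A)/A < 0.3, and (3) A > 1,
with defaults α = 0.05, ratio 0.3, amplitude 1.0 — all configurable through
`Thresholds`, because the amplitude bound is scale-dependent: for expression
it is meaningful in calibrator-relative fold units (the lowest-expression
cell sits at fold 1), while for measurements in native units (glucose,
mg/dl) a different bound may be appropriate. Decisions are made per series
with no cross-gene multiplicity correction — a deliberate fidelity choice
matching how such criteria are applied in practice in this field. The
conjunction is at most as liberal as the ANOVA alone; on simulated null
genes its empirical false-positive rate is essentially zero, because a flat
series rarely reaches A > 1.

Cosinor fits use untransformed values; the normalising transformation below
applies to the ANOVA/SNK stage only, since its purpose is distributional.

## ANOVA, transformation ladder, SNK letters

The across-time comparison is a classical one-way ANOVA (F and p via
`scipy.stats.f_oneway`). Before it, a transformation is chosen from the
ladder identity → log → √: the first candidate whose pooled within-group
residuals pass Shapiro–Wilk and whose groups pass Levene (median-centred)
at α = 0.05; candidates outside their domain (log with zeros) are skipped,
and if none passes the identity is kept with a warning. The chosen
transform is always recorded. The specific tests in the ladder are this
package's policy; field papers usually state only that data were
transformed "when necessary".

Post hoc structure uses the Student–Newman–Keuls multiple-range test:
means ordered, each span of p consecutive ordered means tested against the
studentized-range critical value q(α, p, df_within), stepping down from the
full range, with the blocking rule (spans nested in a non-significant span
are non-significant). The range standard error uses MS_within and the
harmonic mean of the two compared groups' n (the conventional unequal-n
extension for 5–7 individuals per cell). Critical values are computed
numerically from `scipy.stats.studentized_range` (cached; no interpolation
tables) and are validated against Monte-Carlo quantiles in the tests.
Letters are assigned by insert-and-absorb, so two time points share a
letter exactly when their SNK comparison is non-significant; the ZT 3
vs ZT 3b (1-h postprandial vs 25-h fasting) contrast is read directly off
the letter display since both are ordinary cells in the ANOVA.

Degenerate inputs: `one_way_anova` rejects all-identical data and
zero-within-variance data with distinct means (infinite F). The pipeline
maps these two cases to their limits (F = 0, p = 1 and F = ∞, p = 0,
letters skipped) so that noise-free simulations classify correctly; the
within-variance test uses a relative tolerance of 10⁻²⁰ × SS_between
because residuals of constant groups can be ~10⁻³⁰ rather than exactly
zero after mean round-off.

## 2^−ΔΔCt quantification

Duplicate wells are averaged per individual × gene; the replicate spread is
kept as a QC column and spreads above 0.5 cycles are flagged, never
dropped. ΔCt = Ct_target − Ct_reference per individual; the calibrator is
the sampling-time cell with the highest mean ΔCt (lowest expression), ties
broken by earliest sampling time then group order; fold = 2^−(ΔCt −
ΔCt_cal). Amplification efficiency is fixed at 2 — no efficiency
correction, no inter-plate calibration, no outlier-well rejection.

"Lowest-level group" is ambiguous when several experimental groups share a
gene: the calibrator scope is therefore configurable — `across_groups`
(default; one calibrator per gene × tissue, keeping all groups on one
comparable scale) or `within_group`. Neither is asserted as the choice of
any particular study.

Because folds are calibrator-relative, recovered mesors and amplitudes are
the generating values divided by the calibrator cell's true level;
`recovery_report` undoes this rescaling using the reported calibrator
identity, which is how the noise-free round trip recovers the generating
parameters to machine precision.

## Synthetic-data generator

The generator reproduces the design of a three-zeitgeber study: groups
12L:12D + scheduled feeding, 12L:12D + random feeding, and constant
darkness + scheduled feeding; sampling at ZT/CT 3, 7, 11, 15, 19, 23 and 3
next day (27 h); default 7 individuals per cell with per-cell n in {5,6,7}
supported; tissues hypothalamus and liver. Each gene's mean trajectory is
M + A·cos(ω(t − acrophase)); configs whose trough M − A would make expected
expression non-positive are rejected with the gene named.

Noise model (the field reports none, so these are the package's choices,
fixed once):

- Biological between-individual noise on the log2-expression scale by
  default (multiplicative, keeps expression positive; sd in log2 units);
  an additive-Gaussian alternative is selectable and is used where a
  signal-to-noise ratio A/σ must be specified in measurement units.
- Ct values: target Ct = ct_base_target − log2(expression) (efficiency 2,
  matching the quantification), reference gene time-invariant in
  expectation with between-individual sd, duplicate wells with technical
  sd, all Ct clamped to (0, 40].
- Defaults in the bundled study-like scenario: acrophases follow the
  rhythmic profiles such designs are built around (*per* genes peaking at
  the end of the dark phase, e.g. ZT 22.3–23.1; *bmal1a* in antiphase at
  ZT 7.7–8.8; *nr1d1* mid-dark at ZT 17.5), fold-scale mesors 2–4.5 and
  amplitudes 1.6–3.2 chosen so troughs sit near the calibrator level,
  amplitude scaled ×0.6 under random feeding, hypothalamic rhythms
  abolished and hepatic ones damped (×0.4) under constant darkness,
  log2-scale biological sd 0.18, reference sd 0.15, technical sd 0.12.

The random feeding schedule draws one feeding time per day uniformly over
the 24-h day ("fed once in every 24-h day, at an unpredictable time"). Note
that with independent daily draws the gap between consecutive absolute
feeding events ranges up to 48 h; the "maximum 24 h fasting-eating
interval" of such designs is honoured in the sense that no day is skipped.
A stricter reading (every inter-event gap ≤ 24 h) is incompatible with
uniform, independent daily times and was not adopted.

What the generator does **not** emulate: amplification-efficiency
differences between genes, inter-plate effects, ultradian components,
non-sinusoidal waveforms, correlated noise between genes of one animal, or
missing samples. Passing tests therefore demonstrate the correctness of
the estimators and decision rules under the stated model, not robustness
to these real-data features.

## Problem sizes in tests and the acceptance script

Oracle equivalence uses 1,000 random series; SE calibration 10,000
Monte-Carlo replicates; type-I error 2,000 null genes; power 60 rhythmic
genes (A/σ = 4) plus 40 flat genes; SNK validation 18 (p, df) combinations
at 300,000 Monte-Carlo samples each and 500 random letter instances. These
sizes give Monte-Carlo standard errors comfortably below the asserted
tolerances while keeping a full run around a minute.

## Known limitations

- Single-component, fixed-period cosinor only; no period scanning
  (periodogram, Lomb–Scargle) and no population-mean cosinor hierarchy.
- The transform ladder tests normality/homoscedasticity at α = 0.05 per
  series; with many series some transform choices will differ from what an
  analyst would pick by eye.
- SNK (like all stepwise range tests) does not control the family-wise
  error rate at α in all configurations; it is provided because it is the
  convention this pipeline mirrors, not as the best available procedure.
- The amplitude criterion A > 1 is scale-dependent and should be
  reconsidered whenever the calibrator convention or measurement units
  change.
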