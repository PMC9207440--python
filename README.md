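# rhythmq

Circadian rhythm analysis for RT-qPCR time series: 2^−ΔΔCt relative
quantification, one-way ANOVA with Student–Newman–Keuls letters across
sampling times, fixed-period 24-h cosinor fitting, and a three-criterion
daily-rhythm call — plus a synthetic-data generator that reproduces a
three-zeitgeber experimental design (light–dark cycle × feeding schedule) so
the whole chain can be validated against known ground truth.

It is written for chronobiologists analysing daily gene-expression or
physiological profiles: fish (or other animals) sampled every few hours
across a 24-h cycle under different lighting/feeding regimes, with duplicate
qPCR wells, a stable reference gene, and 5–7 individuals per time point.

## The model

Each series (one gene in one tissue in one experimental group) is fitted by
least squares to the single-component cosinor

    f(t) = M + A·cos(t·π/12 − Φ)

with the period fixed at 24 h: *M* (mesor) is the rhythm-adjusted mean, *A*
the amplitude, and Φ the acrophase (peak time, reported in ZT/CT hours).
Through the reparameterisation f(t) = M + β_c·cos(ωt) + β_s·sin(ωt) the
problem is linear, so the solution is the global optimum of the nonlinear
fit. Standard errors are computed from the residual sum of squares
(covariance σ̂²(XᵀX)⁻¹, delta method for A and Φ).

A series is called **rhythmic** when all three criteria hold:

1. ANOVA across sampling times, p < 0.05 (after an automatic
   identity → log → √ normalising-transform ladder),
2. amplitude noise/signal ratio SE(A)/A < 0.3,
3. A > 1 in the data's native units (fold change for expression, where the
   2^−ΔΔCt calibrator — the lowest-expression cell — pins fold 1).

Quantification follows 2^−ΔΔCt with amplification efficiency fixed at 2:
ΔCt = Ct_target − Ct_reference per individual, ΔΔCt relative to the mean ΔCt
of the lowest-expression (group × time) cell, fold = 2^−ΔΔCt. Pairwise
time-point structure is summarised with SNK multiple-range tests and a
compact letter display (groups share a letter iff not significantly
different), the same convention used to annotate daily-profile figures.

## Worked example

```python
from rhythmq import run_study, recovery_report
from rhythmq.simulate import study_scenario, generate_dataset

scenario = study_scenario(seed=42)     # 3 groups x 2 tissues, known truth
table = generate_dataset(scenario)     # 5,586 duplicate-well Ct records
report = run_study(table)              # quantify -> ANOVA/SNK -> cosinor -> call
frame = report.frame()
print(frame[(frame.tissue == "liver") & (frame.gene == "per1a")]
      [["group", "mesor", "amplitude", "acrophase_h", "noise_signal",
        "is_rhythmic"]])
```

prints (seed 42):

```
       group  mesor  amplitude  acrophase_h  noise_signal  is_rhythmic
DD_scheduled  3.030      0.693       22.199         0.169        False
   LD_random  3.260      1.354       22.845         0.094         True
LD_scheduled  3.165      2.180       23.167         0.077         True
```

The generating truth for liver *per1a* peaks at ZT 22.7; with both
zeitgebers present (`LD_scheduled`) the rhythm is recovered with acrophase
ZT 23.2 and a large amplitude, under random feeding the amplitude is reduced
but the rhythm persists, and under constant darkness the damped rhythm falls
below the A > 1 criterion. Comparing against the embedded ground truth:

```python
rec = recovery_report(report, scenario)
print(rec["confusion"], rec["acrophase_median_abs_err_h"])
# {'tp': 22, 'fp': 0, 'fn': 17, 'tn': 12} 0.232
```

No false-positive rhythm calls, and a median acrophase error of about a
quarter hour on the truly rhythmic series. The same pipeline runs from the
shell:

```
rhythmq simulate --seed 42 --out sim/
rhythmq run --input sim/data.csv --reference-gene eef-1a1 --out results/
rhythmq recover --report results/ --truth sim/truth.yaml --input sim/data.csv
```

Measurement tables with a `value` column (e.g. plasma glucose in mg/dl) skip
quantification and go straight to the statistics.

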