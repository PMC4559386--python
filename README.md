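# tempodisc

Delay discounting and episodic memory in older adults, as a tested, reusable
analysis pipeline.

`tempodisc` implements the full analysis chain of an intertemporal-choice
study: from raw binary choices between a smaller-sooner and a larger-later
monetary reward, through per-block indifference points and discount-model
fits, to hierarchical regressions testing whether the relationship between
episodic memory performance and discounting differs by gender. Because raw
participant data for this kind of lab study are rarely deposited, the package
ships a first-class synthetic-cohort generator with known ground truth, used
for parameter-recovery, calibration, and power experiments.

## The task and models

Each participant completes 6 blocks of 18 choices. The later option is always
20 € ; the sooner option varies over 0–20 € in 2.50 € steps (each amount twice
per block). In blocks 1–4 the sooner option is available *tomorrow* (encoded
T = 0 months) and the later at T = 3, 6, 9 or 12 months; in blocks 5–6 the
sooner option is itself delayed 6 months. Trials offering 0 € or 20 € sooner
are catch trials with a logically dominant answer; participants failing more
than half of the 24 catch trials are excluded.

Per block, the indifference point (IP) — the sooner amount at which either
option is equally attractive — is estimated by logistic regression of choice
on amount (with a midpoint fallback for the perfectly separated choice
patterns deterministic responders produce), and expressed as a proportion of
the 20 € reward. Two discount functions are fitted by least squares to the
four tomorrow-anchored IPs:

* **hyperbolic**: SV(T) = 1 / (1 + kT), steepness k per month;
* **quasi-hyperbolic (β–δ)**: SV(0) = 1, SV(T) = β·δ^T for T > 0, where β
  indexes present-bias and δ patience (discount rate log(1/δ)).

Models are compared by the least-squares AIC, n·ln(SSE/n) + 2p. A model-free
impulsivity index NImp counts sooner choices on the 84 non-catch trials.

Episodic memory is scored three ways: FNPA-PF (face–name paired associates,
hit rate minus false-alarm rate, in [−1, 1]) and two autobiographical scores
in [0, 2]: IGD-C1 (personal events: recalled-events proportion plus
quality-rating proportion) and IGD-C2 (personal facts/dates: yes-proportion
plus confidence proportion).

The inferential core regresses each discounting outcome (ln k, β, δ, NImp) on
a nested predictor hierarchy — memory scores; + gender, age, income, IQ;
+ gender × mean-centred memory interactions — with standardized betas,
R²-change F-tests between adjacent models, EM imputation of missing income,
Shapiro-gated t/Mann-Whitney group comparisons, and Holm–Bonferroni-corrected
memory–covariate correlations.

## Worked example

```python
from tempodisc import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    mode="simulate", seed=1,
    cohort=CohortConfig(n_participants=58),
    outdir="out", verbosity=0,
)
result = run_pipeline(config)
fits = result.discount_fits
print("mean k     = %.3f" % fits["k"].mean())
print("mean beta  = %.3f" % fits["beta"].mean())
print("mean delta = %.3f" % fits["delta"].mean())
print("quasi-hyperbolic preferred for %d of %d participants"
      % ((fits["preferred_model"] == "quasi-hyperbolic").sum(), len(fits)))
m3 = result.regressions["ln_k"][2]
beta, p = m3.coefficients["gender_x_igd_c2"]
print("model 3 on ln k: R2 = %.3f, gender x IGD-C2 beta = %.3f (p = %.3f)"
      % (m3.r2, beta, p))
```

prints

```
mean k     = 0.390
mean beta  = 0.613
mean delta = 0.973
quasi-hyperbolic preferred for 51 of 58 participants
model 3 on ln k: R2 = 0.190, gender x IGD-C2 beta = -0.026 (p = 0.891)
```

Read: this default cohort (no interaction injected) discounts at a mean
hyperbolic rate of 0.39/month with moderate present-bias (β ≈ 0.61) and high
long-run patience (δ ≈ 0.97); the two-parameter β–δ model wins the AIC
comparison for most participants; and, correctly, the gender × IGD-C2
interaction term is null. Setting
`CohortConfig(effect_gender_memory_on_lnk=...)` injects a real interaction
and the same term becomes significant.

The same pipeline is available from the shell:

```sh
tempodisc simulate --seed 1 --n 58 --out out/      # synthetic cohort + analysis
tempodisc analyze --trials t.csv --memory m.csv --covariates c.csv --out out/
tempodisc recover --seed 1 --out recovery.csv      # beta-delta parameter recovery
tempodisc power --seed 1 --out power.csv           # interaction power curve
```

All outputs are plain CSV/JSON tables (QC report, indifference points,
discount fits, analysis table, group comparisons, correlations, regression
hierarchy) with the seed and configuration echoed alongside.

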