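# codactivity

Acoustic-telemetry activity analysis of sex- and depth-dependent
behaviour in spawning Atlantic cod (*Gadus morhua*), with a synthetic
tag/receiver simulator that makes every stage verifiable by parameter
recovery.

Mature cod at Norwegian coastal spawning grounds carry acoustic tags
whose accelerometer reports, at random ~250-s intervals, one smoothed
activity value (the mean of tri-axial samples at 12.5 Hz over a 25-s
window, right-censored at the 3.43 or 4.9 m/s² tag ceiling),
alternating 1:1 with a depth sensor. Because male cod lek — they dwell
deeper than females and fight for territory — high accelerometer values
in deep water during the spawning season are a proxy for male–male
agonistic interactions. This package implements the full analysis chain
a telemetry ecologist needs to test that hypothesis:

1. **Detection processing** — linear receiver clock correction; removal
   of dead fish (no vertical movement for more than a day); collapse of
   the same transmission logged at several receivers within the minimum
   tag delay; removal of lone daily detections; pairing of each
   accelerometer value with the nearest-in-time depth value (within
   1800 s); restriction to depths ≤ 60 m and the tagging year; thinning
   of high-rate (2024-protocol) tags to every fifth value.
2. **Censoring imputation** — a right-censored Gaussian (Tobit) model
   fitted by maximum likelihood per dataset with fish identity as the
   covariate; ceiling values are replaced by draws from the fitted
   truncated upper tail.
3. **Per-fish statistics** — one mean activity value per fish (or per
   fish × depth stratum, split at 20 m), weighted by log(number of
   detections); the high-activity proportion `P_HV = Pr(accel > 2 m/s²)`
   squeezed into (0,1) as `(p·(n−1)+0.5)/n` for beta regression.
4. **Inference** — weighted LM/LMM for overall sex differences; a gamma
   GLMM (log link) for mean activity and a beta GLMM (logit link) for
   `P_HV`, both with sex × depth-category fixed effects and fish (plus
   year) random intercepts, fitted by adaptive Gauss–Hermite maximum
   likelihood; all-subsets AICc selection retaining every term that
   appears within 2 AICc units of the best model. Treatment contrasts
   use female and the shallow (< 20 m) stratum as reference levels.
5. **Simulator** — tags (uniform delays, sensor alternation, 8-bit
   quantisation, censoring), fish behaviour (baseline locomotion plus
   Poisson bursts whose rate depends on sex, season and depth stratum;
   sex-specific mean-reverting depth tracks with female descents), and
   receivers (per-transmission detection probability, linear clock
   drift, spurious detections), all seeded through named substreams.

## Worked example

`examples/04_sex_depth_models.py` simulates a 60-fish, 30-day spawning
deployment in which males burst more often than females *only* below
20 m, runs the whole chain, and fits the two depth-dependent models:

```
simulated detections: 311249 from 60 fish
paired activity records in scope: 154727 (pairing fraction 0.995)
ceiling values imputed: 2849
model table: 120 fish-by-stratum aggregates

Response: mean_activity   Family: gamma_log_glmm
Reference levels: treatment contrasts; intercept = female, <20 m (shallow)

Predictors                   Estimates                    CI         p
(Intercept)                      -1.00         -1.05 – -0.95    <0.001
Sex [M]                           0.01          -0.06 – 0.08     0.770
Depth Cat [>20m]                 -0.13         -0.16 – -0.10    <0.001
Sex [M] × Depth Cat [>20m]        0.21           0.16 – 0.26    <0.001
```

Read: at the reference level (females, shallow) mean activity is
exp(−1.00) ≈ 0.37 m/s²; males do not differ from females in shallow
water (p = 0.77); activity is lower in deep water; and the positive,
significant interaction says males are relatively more active than
females below 20 m — exactly the generating configuration. The beta
GLMM on the squeezed `P_HV` recovers the same interaction
(0.68, p < 0.001). Other capabilities are demonstrated in
`examples/01_tag_protocol.py` (transmission protocol and censoring),
`examples/02_filtering_pipeline.py` (cleaning chain and removal
ledger), and `examples/03_censored_imputation.py` (Tobit recovery and
tail imputation).

## Command line

A thin CLI wraps the library for shell use:

```bash
codactivity simulate --scenario scenario.yaml --seed 1 --out sim/
codactivity process  --in sim/ --out proc/
codactivity run-all  --config run.yaml --seed 1 --out run/
```

`run-all` executes simulate → process → impute → aggregate → fit and
writes every intermediate (CSV), a per-stage removal ledger, model
summaries, and a provenance file (config hash, seed, version).

## Layout

- `src/codactivity/simulate.py` — tags, behaviour, receivers, scenarios
- `src/codactivity/processing.py` — the detection cleaning chain
- `src/codactivity/censoring.py` — Tobit fitting and imputation
- `src/codactivity/aggregate.py` — per-fish statistics, `P_HV`, squeeze
- `src/codactivity/glmm.py` — weighted LMM and adaptive-quadrature GLMMs
- `src/codactivity/inference.py` — model specs, AICc selection, reports
- `src/codactivity/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, defaults, and limitations
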