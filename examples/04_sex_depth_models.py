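"""Sex-by-depth activity models on a simulated spawning ground.

End to end: simulate a 60-fish, 30-day spawning deployment in which
males burst more often than females only in deep water (> 20 m), clean
and pair the detections, impute ceiling values, aggregate per fish and
depth stratum, and fit the gamma GLMM for mean activity and the beta
GLMM for the high-activity proportion P_HV.
"""

import warnings

import numpy as np

import codactivity as ca

warnings.filterwarnings("ignore")

scenario = ca.spawning_field_scenario(n_males=30, n_females=30, days=30)
study = ca.simulate_study(scenario, seed=1)
print(f"simulated detections: {len(study.detections)} from {len(study.fish)} fish")

pairs, ledger, stats = ca.process_detections(
    study.detections, study.fish, study.receivers
)
print(f"paired activity records in scope: {len(pairs)} "
      f"(pairing fraction {stats['pairing']['pairing_fraction']:.3f})")

rng = np.random.default_rng(2)
pairs, report = ca.impute_pairs(pairs, study.fish, rng)
print(f"ceiling values imputed: {report['n_censored'].sum()}")

table = ca.build_model_table(
    pairs, study.fish, season="spawning", grouping="by_depth_category"
)
print(f"model table: {len(table)} fish-by-stratum aggregates\n")

for response, family in (
    ("mean_activity", "gamma_log_glmm"),
    ("p_hv_transformed", "beta_logit_glmm"),
):
    spec = ca.ModelSpec(
        response,
        family,
        ("sex", "depth_category", "sex:depth_category"),
        ("fish_id",),
    )
    res = ca.fit_model(spec, table)
    print(ca.summarize_result(res))
print(
    "A positive Sex [M] x Depth Cat [>20m] interaction with p < 0.05 in both\n"
    "models recovers the configured pattern: males are more active than\n"
    "females only below 20 m, the depth stratum where males concentrate."
)
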