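"""Full pipeline on a mixed synthetic cohort: compliance screening,
imputation, bouts, monthly normalization, decomposition, Mann-Kendall
labels, and the compliance-balance check.
"""

import patx

cfg = patx.SynthConfig(
    seed=19, drift_groups=((4, 1.5), (4, -1.5), (4, 0.0))
)
series, truth = patx.generate_cohort(cfg)
ages = {s: truth.physiology[s][1] for s in truth.labels}
rhr = {s: truth.physiology[s][0] for s in truth.labels}

result = patx.run_pipeline(series, cfg.resolved_calendar(), ages=ages, rhr=rhr)
print(result.trend_table()[["subject_id", "s_statistic", "z_score", "p_value", "label"]]
      .to_string(index=False))
print("\nlabel counts:", result.label_counts())
print("injected:    ", {k: list(truth.labels.values()).count(k)
                        for k in ("positive", "negative", "none")})
if result.balance:
    h, p = result.balance
    print(f"Kruskal-Wallis compliance balance: H = {h:.2f}, p = {p:.3f}")
# Subjects with injected +/-1.5 min/day-per-month drift are labeled
# reliably. Zero-drift subjects are over-labeled: the Mann-Kendall test
# runs on the smoothed trend component, whose autocorrelation inflates
# false positives (see docs/methods.md). A non-significant Kruskal-Wallis
# p says label groups contributed similar compliant days per month.
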