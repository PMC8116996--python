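"""Full analysis on a synthetic cohort: clusters, stress waves, mixed model.

Generates the study-preset cohort (47 physicians, three work-pattern
groups), runs every stage, and prints the headline numbers.
"""

from inboxstress import pipeline, synthetic_data as sd

cohort = sd.generate_cohort(seed=1)
cfg = pipeline.PipelineConfig(seed=1, out_dir="scratch/example_run")
res = pipeline.run_pipeline(cfg, events=cohort.events, stress=cohort.stress, roster=cohort.roster)

r = res["report"]
d = r["descriptives"]
print(f"daily EHR time   : {d['mean_daily_ehr_hours']:.2f} h (inbox {d['mean_daily_inbox_hours']:.2f} h)")
print(f"patient messages : {d['message_share_percent']['patient']:.0f}% of inbox time")
print(f"window switching : {d['mean_switch_rate_per_min']:.1f} per EHR minute")
print(f"clusters         : sizes {r['group_sizes']}, silhouette {r['silhouette']:.2f}")
print(f"hour filter      : {r['filter_report'][0]['percent_removed']}% of hours removed (<20 valid min)")
print(f"mixed model      : {r['n_model_days']} physician-days, marginal R2 {r['model']['r2_marginal']:.2f}, "
      f"conditional R2 {r['model']['r2_conditional']:.2f}")
# Group 1 works evenings/early mornings, group 2 mostly in hours, group 3
# after hours contiguous to shifts. The conditional R2 far above the
# marginal R2 says stable physician-level differences, not the usage
# covariates, absorb most stress variation - the study's key contrast.
# Artifacts (tables, stress-curve and work-pattern plots) are under
# scratch/example_run/.
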