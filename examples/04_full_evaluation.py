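"""Repeated-holdout evaluation of the full pipeline.

A 47 unhealed / 17 healed cohort is split 70/30 (stratified) twenty
times.  For each split: PCA is fitted on the training rows only, the
network width is selected by log evidence, and sensitivity/specificity
are computed on both sides.  The report aggregates mean +/- SD and keeps
the best repetition's training ROC curve.

Run:  python examples/04_full_evaluation.py   (about half a minute)
"""

from woundtherm import (
    PipelineConfig,
    SplitSpec,
    extract_feature_table,
    generate_cohort,
    run_experiment,
)

cohort = generate_cohort(n_unhealed=47, n_healed=17, seed=42)
table = extract_feature_table(cohort)

spec = SplitSpec(train_fraction=0.70, n_repetitions=20, master_seed=42)
cfg = PipelineConfig(n_components=3, h_range=(1, 2, 3, 4, 5), restarts=2)
report = run_experiment(table, spec, cfg)

mt, st = report.mean_test, report.sd_test
print(f"test sensitivity  {mt[0]:.4f} +/- {st[0]:.4f}")
print(f"test specificity  {mt[1]:.4f} +/- {st[1]:.4f}")
best = report.repetitions[report.best_rep_index]
print(f"best repetition: #{best.rep_index} "
      f"(sens {best.test_sensitivity:.4f}, spec {best.test_specificity:.4f}, "
      f"h={best.selected_h})")
print(f"best repetition training AUC: {report.best_train_auc:.4f}")
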