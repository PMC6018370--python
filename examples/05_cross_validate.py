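"""Leave-one-subject-out evaluation of the full two-stage classifier.

Both eyes of a held-out subject are scored by networks trained on all
other subjects; a subject's DR probability is the max over its eyes.
Reported: accuracy, sensitivity, specificity, AUC and a bootstrap 95% CI
(resampling subjects, respecting intra-subject eye correlation).
"""

from octdr import (
    AutoencoderSpec,
    PhantomConfig,
    descriptors_from_cohort,
    plan_folds,
    run_cv,
)
from octdr.synthetic import generate_cohort

# 24 subjects keeps this example quick; the study-scale run (80 subjects)
# is what scripts/acceptance.py performs
records, manifest = generate_cohort(24, (0.5, 0.25, 0.25), PhantomConfig(),
                                    seed=1)
descriptors = descriptors_from_cohort(records)

plan = plan_folds(manifest, "loso")
print(f"LOSO: {plan.n_folds} folds -> {plan.n_folds} training runs")

reports = run_cv(descriptors, plan, AutoencoderSpec(seed=0), n_boot=1000)
for stage, rep in reports.items():
    lo, hi = rep.ci95
    print(f"{stage:6s}: acc={rep.accuracy:.3f} sens={rep.sensitivity:.3f} "
          f"spec={rep.specificity:.3f} auc={rep.auc:.3f} "
          f"95% CI [{lo:.3f}, {hi:.3f}]")

# 'screen' is normal-vs-DR over all subjects; 'grade' is subclinical-vs-
# mild/moderate over the true-DR subjects only.
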