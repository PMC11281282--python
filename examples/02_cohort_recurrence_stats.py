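"""Recurrence statistics on a simulated two-group patient cohort.

Simulates 12 non-recurrent and 14 recurrent patients with 6-18 fields of
view each and a true recurrent-group effect of +0.5 on log percent fiber
volume, then runs the full statistical chain: patient-level one-tailed
t-test, FOV-level random-intercept model on log volumes, and the
median-split survival analysis.
"""

import shgfiber as sf
from shgfiber.stats import compare_groups_report, survival_report

params = sf.CohortParams(n_patients_per_group=(12, 14), group_effect_log=0.5, seed=42)
fovs, patients = sf.generate_cohort(params)

report = compare_groups_report(fovs, patients)
tt, mm = report["ttest"], report["mixed"]
print(f"patients: {len(patients)}, FOVs: {len(fovs)}")
print(f"t-test (recurrent > non-recurrent): t={tt['t']:.3f}, df={tt['df']:.0f}, "
      f"one-sided p={tt['p_one']:.4f}")
print(f"mixed model: beta={mm['beta']:.3f} (log scale), SE={mm['se']:.3f}, "
      f"one-sided p={mm['p_one']:.4f}")
print(f"variance components: between-patient {mm['var_between']:.3f}, "
      f"within-patient {mm['var_within']:.3f}")

surv = survival_report(patients)
print(f"median split at {surv['median']:.2f} % fiber volume "
      f"({surv['n_high']} high vs {surv['n_low']} low)")
print(f"log-rank chi2={surv['chi2']:.3f}, p={surv['p']:.4f}, "
      f"O/E hazard ratio={surv['hr']:.2f} (Cox {surv['cox_hr']:.2f})")
print()
print("beta is the estimated recurrent-group shift in log percent volume")
print("(truth here: 0.5); the hazard ratio compares mortality of patients")
print("above vs below the median fiber volume (generator's truth: 2.7,")
print("attenuated by splitting on the noisy observed means).")
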