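"""Cohort protocols: routine stability vs pattern predictiveness.

A 24-user synthetic cohort spanning a stability gradient is evaluated
with day-of-week contexts: per-user routine stability (mean Jaccard of
consecutive same-weekday slot sets), prediction performance of patterns
built from k = 1..4 weekly observations, the Pearson association between
the two, and the cohort-derived change threshold mu + sigma.
"""

from datetime import date

import numpy as np

from sociability import CohortSpec, MinerParams, evaluate_cohort, generate_cohort

spec = CohortSpec(n_users=24, n_days=66, start_date=date(2024, 1, 1), seed=1)
report = evaluate_cohort(generate_cohort(spec), MinerParams(), ks=(1, 2, 3, 4))

print("mean prediction performance by observations-per-pattern:")
for k in (1, 2, 3, 4):
    mean_perf = np.mean(list(report.user_mean_performance[k].values()))
    print(f"  k={k}: {mean_perf:.3f}")

print(f"\nPearson r (stability vs performance, k=2): {report.overall_r[2]:+.3f}")
print("per-context r:", {ca: round(r, 2) for ca, r in report.per_ca_r.items()})
print(f"\ncohort stability mu={report.mu:.3f}, sigma={report.sigma:.3f} "
      f"-> change threshold {report.threshold:.3f}")

# One observation yields clearly weaker patterns than two, while two or
# more perform similarly; the strong positive r shows patterns explain
# stable routines well and unstable ones poorly, and mu + sigma is the
# threshold a specialist would use for change detection on this cohort.
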