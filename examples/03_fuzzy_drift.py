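"""Grade behavior-change severity with the fuzzy drift assessor.

A crisp threshold treats similarity 45.9% and 46.3% categorically
differently.  The Mamdani system instead maps (specialist sensitivity,
observed similarity) to a graded drift value with per-term membership
degrees, and can be calibrated so its "change" verdict boundary sits at
a crisp threshold.
"""

from sociability import calibrate_sensitivity, default_fis, fis_assess

fis = default_fis()
sensitivity = calibrate_sensitivity(fis, threshold=0.461)
print(f"sensitivity calibrated to {sensitivity:.2f} "
      f"(change verdict at/below the crisp threshold)\n")

print(f"{'similarity':>10s}  {'drift':>6s}  {'no_change':>9s}  "
      f"{'moderate':>8s}  {'change':>6s}  verdict")
for similarity in (0.95, 0.65, 0.52, 0.46, 0.43, 0.20):
    a = fis_assess(fis, sensitivity, similarity * 100)
    print(f"{similarity:10.2f}  {a.crisp:6.1f}  "
          f"{a.degrees['no_change']:9.2f}  {a.degrees['moderate_change']:8.2f}  "
          f"{a.degrees['change']:6.2f}  {a.verdict}")

# drift is the defuzzified (center-of-gravity) output on a 0-100 scale;
# the degree columns show how much the crisp value belongs to each
# linguistic term, so near-threshold similarities read as partial rather
# than absolute verdicts.
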