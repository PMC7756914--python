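"""Network density vs treatment outcome.

Each patient's mean pairwise DTW distance measures how loosely their
symptom trajectories are coupled (larger = sparser network).  After
adjusting for the number of assessments and the baseline HRSD-17 sum, the
residual densities of responders and remitters are compared with rank-sum
tests.
"""

import warnings

from symdyn import GeneratorConfig, density_comparison, generate_cohort

warnings.filterwarnings("ignore")

cohort = generate_cohort(GeneratorConfig(seed=2020))
dc = density_comparison(cohort.patients)  # adjusted, zeros excluded

t = dc.table
for name, col in (("response", "responder"), ("remission", "remitter")):
    yes = t.loc[t[col] == True, "residual"]  # noqa: E712
    no = t.loc[t[col] == False, "residual"]  # noqa: E712
    u, p = dc.tests[name]
    print(f"{name:9s}: median residual {yes.median():+.3f} (yes, n={len(yes)}) "
          f"vs {no.median():+.3f} (no, n={len(no)}); rank-sum p = {p:.2e}")

print("\nNegative residuals mean shorter-than-expected average DTW distances,")
print("i.e. denser, more synchronous symptom networks; patients who reach")
print("response or remission show systematically denser networks.")
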