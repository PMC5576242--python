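"""Liability-threshold clinical utility: from AUC to expected decile odds ratios.

Given only a score's AUC and the population prevalence, the liability-
threshold model yields the variance in liability the score explains and,
from it, the expected odds ratio of disease between the top and bottom
score deciles - the number a screening programme cares about.
"""

import polyrisk as pr

for label, auc, prevalence in [
    ("Crohn's-like disease", 0.746, 0.005),
    ("ulcerative-colitis-like disease", 0.696, 0.002),
]:
    spec = pr.auc_to_liability_v(auc, prevalence)
    or_quad = pr.expected_decile_or(auc, prevalence)
    or_mc = pr.expected_decile_or(auc, prevalence, method="mc",
                                  mc_draws=2_000_000, seed=0)
    print(f"{label}: AUC {auc}, prevalence {prevalence}")
    print(f"  liability threshold t = {spec.t:.3f}, "
          f"variance explained v = {spec.v:.3f}")
    print(f"  expected top-vs-bottom decile OR: {or_quad:.2f} "
          f"(Monte-Carlo cross-check {or_mc:.2f})")

print("\nA value near 32 means a person scoring in the top decile is about "
      "32 times more likely to be a case than one in the bottom decile, "
      "even though the score is useless as a diagnostic at such low "
      "prevalence.")

# the relative AUC gain between two predictors, on the percent scale
gain = pr.relative_auc_gain(0.779, 0.715)
print(f"\nexample relative AUC gain 100 x (0.779/0.715 - 1) = {gain}%")
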