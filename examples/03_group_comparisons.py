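"""Compare TRD vs non-TRD groups with the package's inferential tools.

Runs the two-sample t-test (pooled and Welch-Satterthwaite), the
large-sample two-proportion z-test, and the Bonferroni correction on
summary statistics of the kind the episode comparison produces.
"""

from trd_episodes import bonferroni_threshold, two_proportion_test, two_sample_t

# episode durations: TRD episodes are far longer on average
r = two_sample_t(1004, 950, 3134, 452, 520, 44520, variance_rule="auto")
print(f"duration comparison: {r.method}, t={r.statistic:.2f}, "
      f"df={r.degrees_of_freedom:.0f}, p={r.p_value:.3g}")

# share of female patients between groups
z = two_proportion_test(2237, 3095, 25733, 37255)
print(f"female share: z={z.statistic:.2f}, p={z.p_value:.3g}")

cutoff = bonferroni_threshold(0.05, 44)
print(f"Bonferroni cutoff for a 44-comparison family: {cutoff:.5f}")
print(f"both comparisons significant at the cutoff: "
      f"{r.p_value < cutoff and z.p_value < cutoff}")
print("\nThe t-test 'auto' rule picks the pooled statistic unless a 5%"
      "\nF-test rejects equal variances, in which case Welch-Satterthwaite"
      "\ndegrees of freedom are used.")
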