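"""Reliability and validity metrics on a simulated assessment.

Computes Cronbach's alpha of the raw responses, the split-half retest
consistency of the WGNPC classifications (how stably two random half-tests
reproduce the same mastery calls), and the Pearson correlation between
mastery level (number of attributes mastered) and total score.  High alpha
says the items rank examinees consistently; consistency near 1 says the
classifications are stable; a clearly positive correlation says mastery
levels track overall performance without duplicating it.
"""

from npcda import (
    SimulationSpec,
    cronbach_alpha,
    mastery_total_correlation,
    retest_consistency,
    simulate_dataset,
    wgnpc_classify,
)

spec = SimulationSpec(
    n_examinees=25, n_items=80, n_attributes=5,
    slip=0.1, guess=0.2, mastery_prob=0.6, seed=3,
)
q, y, _ = simulate_dataset(spec)

alpha = cronbach_alpha(y)
print(f"Cronbach's alpha: {alpha:.3f}")

report = retest_consistency(y, q, method="wgnpc", replicates=10, seed=3)
print(f"attribute retest consistency: {report.attribute_consistency:.3f}")
print(f"pattern retest consistency:   {report.pattern_consistency:.3f}")
print(f"  ({report.replicates} replicates, design: {report.design})")

result = wgnpc_classify(y, q)
r = mastery_total_correlation(result.mastery_levels(), y.total_scores())
print(f"mastery level vs total score correlation: r = {r:.3f}")
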