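"""Minimum sample size for detecting an accuracy difference between two
networks with a two-sample t-test.

At a standardized effect size d = 0.50 (a 'medium' difference), two-sided
alpha = 0.05 and target power 0.80, the exact noncentral-t computation
gives 64 subjects per group — total N = 128. The closed-form normal
approximation (126) is what the noncentral-t result refines.
"""

from m3mc.experiment import PowerSpec, required_sample_size

spec = PowerSpec(effect_size=0.50, alpha=0.05, power=0.80)
print("noncentral-t total N :", required_sample_size(spec))
print("normal approximation :", required_sample_size(spec, method="normal"))
print("paired design (pairs):", required_sample_size(PowerSpec(0.50, 0.05, 0.80, design="paired")))
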