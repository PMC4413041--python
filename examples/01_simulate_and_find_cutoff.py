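"""Simulate a two-group study and locate the disease-specific cutoff.

Builds a 93-gene matrix (9 disease, 8 normal samples) in which a 30-gene
block is tightly coexpressed in the disease group (|r| = 0.8) but loosely in
the normal group (|r| = 0.2), then compares the two coexpression
distributions and reports the maximum deviation D, the cutoff C at which it
occurs, and the KS significance.
"""

from coexshift import (
    BlockSpec,
    SimulationConfig,
    ks_cutoff,
    pairwise_abs_pearson,
    simulate_expression,
)

config = SimulationConfig(
    n_genes=93, n_disease=9, n_normal=8,
    blocks=(BlockSpec(30, r_disease=0.8, r_normal=0.2),), seed=42,
)
matrix = simulate_expression(config)
pc = pairwise_abs_pearson(matrix)
result = ks_cutoff(pc)

print(f"gene pairs per group: {pc.n_pairs}")
print(f"maximum deviation D = {result.D:.3f}")
print(f"disease-specific cutoff C = {result.C:.3f}")
print(f"asymptotic KS p-value = {result.p_value:.3g}")
print()
print("D is the largest gap between the two groups' survival curves of |r|;")
print("C is the coexpression level where that gap occurs, and a small p means")
print("the two coexpression distributions differ in overall structure.")
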