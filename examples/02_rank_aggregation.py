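"""Robust rank aggregation on toy ranked lists.

Three lists rank element "hub" first out of ten elements; the order-statistic
beta score gives it rho = P(all three uniform ranks <= 0.1) = 0.001, and the
Bonferroni-corrected p-value multiplies by the universe size (10 -> p = 0.01).
Elements with inconsistent ranks stay non-significant.
"""

from gedinet import aggregate_ranked_lists, rra_rho

lists = [
    ["hub", "e3", "e5", "e2", "e8", "e1", "e7", "e9", "e4", "e6"],
    ["hub", "e9", "e2", "e6", "e3", "e4", "e8", "e5", "e1", "e7"],
    ["hub", "e4", "e1", "e8", "e5", "e2", "e9", "e7", "e6", "e3"],
]

print("rho for normalized ranks (0.1, 0.1, 0.1):", rra_rho([0.1, 0.1, 0.1]))

print("\naggregated ranking (element, rho, corrected p):")
for a in aggregate_ranked_lists(lists):
    print(f"  {a.element:4s} rho={a.rho:.6f} p={a.p_value:.6f} mean_rank={a.mean_rank:.2f}")
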