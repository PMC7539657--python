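"""Compare gene counts between species groups with the Mann-Whitney U test.

Uses the exact null distribution for small tie-free samples and the
tie-corrected normal approximation otherwise.
"""

from rcdprofiler import mann_whitney_u

# apoptosis gene counts for two small groups of species
mro_counts = [1, 2, 3]        # e.g. mitosome-bearing parasites
aerobic_counts = [4, 5, 6]    # e.g. fully aerobic free-living species

c = mann_whitney_u(mro_counts, aerobic_counts, "MRO", "aerobic")
print(f"{c.label_a}: mean {c.mean_a:.1f} +/- {c.sd_a:.1f} (n={c.n_a})")
print(f"{c.label_b}: mean {c.mean_b:.1f} +/- {c.sd_b:.1f} (n={c.n_b})")
print(f"U = {c.U:.0f}, two-tailed p = {c.p_two_tailed} ({c.method})")

# U = 0 means every MRO count ranks below every aerobic count; with 3+3
# observations the exact two-tailed p for that most extreme ranking is
# 2/20 = 0.1 (20 equally likely rank assignments under the null).

large_a = list(range(30))
large_b = [v + 4 for v in range(30)]
c2 = mann_whitney_u(large_a, large_b)
print(f"\nlarger samples: U = {c2.U:.0f}, p = {c2.p_two_tailed:.4f} "
      f"({c2.method})")
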