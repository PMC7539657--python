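"""Simulate the default 67-species cohort and run the whole pipeline.

Builds a synthetic evidence bundle (manifest, domain scan, homology hits,
ortholog groups), screens and calls every gene family, clusters the
apoptosis profile and prints the group statistics.
"""

import tempfile
from pathlib import Path

from rcdprofiler import default_sim_config, parse_rules_config, run_all
from rcdprofiler.simulate import simulate_bundle

rules = parse_rules_config()
cfg = default_sim_config(seed=1)

with tempfile.TemporaryDirectory() as td:
    sim, bundle = simulate_bundle(cfg, rules, Path(td) / "evidence")
    report = run_all(bundle.manifest, bundle.directory, Path(td) / "out")

    print(f"{report.stage_counts['species']} species, "
          f"{report.stage_counts['families']} gene families, "
          f"{report.stage_counts['calls_present']} present calls")
    sel = report.cluster_selection["homologs.apoptosis"]
    print(f"apoptosis profile splits into k = {sel['k_best']} clusters")
    print()
    print("group comparisons (homolog-based matrix):")
    for c in report.comparisons:
        if c["matrix"] != "homologs" or c["category"] == "necrosis":
            continue
        print(
            f"  {c['category']:9s} {c['group_a']:>13s} "
            f"{c['mean_a']:5.2f} +/- {c['sd_a']:4.2f} (n={c['n_a']:2d})  vs  "
            f"{c['group_b']:>14s} {c['mean_b']:5.2f} +/- {c['sd_b']:4.2f} "
            f"(n={c['n_b']:2d})   p = {c['p_two_tailed']:.2e}"
        )

# Each line compares mean gene-family counts between two species groups
# (two-tailed Mann-Whitney U).  With the default planted rates, species
# with diverged mitochondria and parasites carry significantly fewer
# apoptosis genes, while transiently multicellular species are enriched
# in both apoptosis and autophagy genes.
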