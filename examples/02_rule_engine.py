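"""Evaluate domain-architecture formulas on individual proteins.

Shows how family presence is decided from Pfam domain content: ``+``
means both domains must co-occur on the same protein, ``/`` separates
alternative architectures.
"""

from rcdprofiler import evaluate_protein, parse_rule_expr, parse_rules_config

tsn = parse_rule_expr("PF00565 + PF00567")     # Tudor + SN nuclease
htra = parse_rules_config()
htra = next(r for r in htra if r.family_id == "HTRA").domain_expr

proteins = {
    "tudor_only": {"PF00565"},
    "full_tsn": {"PF00565", "PF00567"},
    "tsn_with_extra": {"PF00565", "PF00567", "PF00001"},
    "htra_trypsin_pdz": {"PF13365", "PF00595"},
    "htra_trypsin_alone": {"PF13365"},
    "htra_variant": {"PF13180"},
}

print(f"TSN rule : {tsn}")
print(f"HTRA rule: {htra}")
print()
for name, domains in proteins.items():
    expr = tsn if name.startswith(("tudor", "full", "tsn")) else htra
    verdict = evaluate_protein(expr, domains)
    print(f"  {name:20s} {sorted(domains)!s:40s} -> {verdict}")

# True means the protein's domain set satisfies at least one alternative
# of the formula; the TSN conjunction needs both domains on one protein,
# while HTRA accepts either trypsin+PDZ or any single divergent variant.
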