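# Default gene-family definitions for the protist RCD inventory.
#
# One block per family.  Keys:
#   category = apoptosis | autophagy | necrosis
#   mode     = homology_only | domain_only | combined
#   expr     = Pfam formula; "+" requires co-occurrence on the same protein,
#              "/" separates alternatives; "+" binds tighter than "/".
#              Omitted exactly when mode = homology_only.
#   pathway  = optional pathway group within the category
#   baits    = optional seed-sequence set id for homology search
#
# Apoptosis: ancestral conserved apoptosis-associated gene families (10).

[ZEN1_ENDOG_NUC1]
category = apoptosis
mode = combined
expr = PF02265 / PF01223 / PF03265

[AIF_AMID]
category = apoptosis
mode = homology_only
baits = aif_amid

[HTRA]
category = apoptosis
mode = combined
expr = PF13365 + PF00595 / PF12812 / PF13180 / PF17815 / PF17820
baits = omi_htra

[METACASPASE]
category = apoptosis
mode = combined
expr = PF00656
baits = caspase_family

[TSN]
category = apoptosis
mode = combined
expr = PF00565 + PF00567

[BAX_INHIBITOR]
category = apoptosis
mode = domain_only
expr = PF01027

[API5]
category = apoptosis
mode = domain_only
expr = PF05918

[DAD]
category = apoptosis
mode = domain_only
expr = PF02109

[BIR]
category = apoptosis
mode = domain_only
expr = PF00653

[NBARC_NACHT]
category = apoptosis
mode = domain_only
expr = PF00931 / PF05729

# Autophagy: conserved ATG machinery (12), grouped by pathway step.

[ATG1]
category = autophagy
pathway = induction
mode = domain_only
expr = PF12063

[ATG13]
category = autophagy
pathway = induction
mode = domain_only
expr = PF10033

[ATG101]
category = autophagy
pathway = induction
mode = domain_only
expr = PF07855

[TOR]
category = autophagy
pathway = induction
mode = combined
expr = PF08771
baits = tor

[ATG11]
category = autophagy
pathway = cargo_selection
mode = domain_only
expr = PF10377

[ATG6_BECLIN]
category = autophagy
pathway = cargo_selection
mode = domain_only
expr = PF04111 / PF17675

[ATG3_10]
category = autophagy
pathway = vesicle_expansion
mode = domain_only
expr = PF03986 / PF03987 / PF10381

[ATG4]
category = autophagy
pathway = vesicle_expansion
mode = domain_only
expr = PF03416

[ATG5]
category = autophagy
pathway = vesicle_expansion
mode = domain_only
expr = PF04106

[ATG7]
category = autophagy
pathway = vesicle_expansion
mode = domain_only
expr = PF16420

[ATG8]
category = autophagy
pathway = vesicle_expansion
mode = domain_only
expr = PF02991

[ATG12]
category = autophagy
pathway = vesicle_expansion
mode = domain_only
expr = PF04110

# Regulated necrosis: described mammalian regulators (3).

[RIPK1_3]
category = necrosis
mode = combined
expr = PF12721 / PF00531
baits = ripk_human

[GASDERMIN_D]
category = necrosis
mode = combined
expr = PF04598 / PF17708
baits = gsdmd_human

[MLKL]
category = necrosis
mode = homology_only
baits = mlkl_human
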