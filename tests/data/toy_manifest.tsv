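species_id	taxon_name	superphylum	mito_class	lifestyle	proteome_path
DDIS	Dictyostelium discoideum	AMO	aerobic	M
SCER	Saccharomyces-like yeast	AMO	aerobic	F
TTHE	Tetrahymena thermophila	SAR	aerobic	F
PTET	Paramecium tetraurelia	SAR	aerobic	F
EHUX	Emiliania huxleyi	HAP	aerobic	F
GTHE	Guillardia theta	CRYP	aerobic	F
CMER	Cyanidioschyzon merolae	ARC	aerobic	F
BNAT	Blastocystis sp.	SAR	anaerobic	P
TVAG	Trichomonas vaginalis	EXC	hydrogenosome	P
GLAM	Giardia lamblia	EXC	mitosome	P
EHIS	Entamoeba histolytica	AMO	mitosome	P
MEXI	Monocercomonoides exilis	EXC	amitochondriate	F
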