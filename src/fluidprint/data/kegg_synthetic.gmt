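Citrate cycle (TCA cycle)	synthetic KEGG-style fixture	citrate	succinate	fumarate	2-oxoglutarate	malate	pyruvate
Alanine, aspartate and glutamate metabolism	synthetic KEGG-style fixture	alanine	aspartate	glutamate	glutamine	succinate	2-oxoglutarate	pyruvate
Glyoxylate and dicarboxylate metabolism	synthetic KEGG-style fixture	citrate	malate	glycine	formate	2-oxoglutarate	acetate	glycolate
Starch and sucrose metabolism	synthetic KEGG-style fixture	glucose	maltose	sucrose	UDP-glucose
Neomycin, kanamycin and gentamicin biosynthesis	synthetic KEGG-style fixture	glucose	glucose-6-phosphate
Primary bile acid biosynthesis	synthetic KEGG-style fixture	taurine	glycine	cholate	chenodeoxycholate
Galactose metabolism	synthetic KEGG-style fixture	glucose	galactose	sorbitol	myo-inositol
Cysteine and methionine metabolism	synthetic KEGG-style fixture	cysteine	methionine	serine	pyruvate	2-oxoglutarate
Valine, leucine and isoleucine biosynthesis	synthetic KEGG-style fixture	valine	leucine	isoleucine	2-oxoglutarate	pyruvate
Lipoic acid metabolism	synthetic KEGG-style fixture	lipoate	glycine	pyruvate
Glutathione metabolism	synthetic KEGG-style fixture	glutathione	glutamate	glycine	cysteine
Porphyrin metabolism	synthetic KEGG-style fixture	glycine	succinate	heme	bilirubin
Glycine, serine and threonine metabolism	synthetic KEGG-style fixture	glycine	serine	threonine	betaine	creatine	pyruvate
Pyruvate metabolism	synthetic KEGG-style fixture	pyruvate	lactate	acetate	malate	fumarate
Glycolysis / Gluconeogenesis	synthetic KEGG-style fixture	glucose	pyruvate	lactate	acetate
Pantothenate and CoA biosynthesis	synthetic KEGG-style fixture	valine	alanine	pantothenate	beta-alanine
Phenylalanine, tyrosine and tryptophan biosynthesis	synthetic KEGG-style fixture	phenylalanine	tyrosine	tryptophan
Phenylalanine metabolism	synthetic KEGG-style fixture	phenylalanine	tyrosine	hippurate	succinate
Arginine and proline metabolism	synthetic KEGG-style fixture	creatine	creatinine	glutamate	arginine	proline	2-oxoglutarate
Butanoate metabolism	synthetic KEGG-style fixture	3-hydroxybutyrate	butyrate	glutamate	succinate	pyruvate
Tyrosine metabolism	synthetic KEGG-style fixture	tyrosine	fumarate	pyruvate	acetate
Valine, leucine and isoleucine degradation	synthetic KEGG-style fixture	valine	leucine	isoleucine	3-hydroxybutyrate	acetate
Glycerophospholipid metabolism	synthetic KEGG-style fixture	choline	betaine	glycerophosphocholine	serine
Caffeine metabolism	synthetic decoy set	caffeine	theobromine	xanthine
Purine metabolism	synthetic decoy set	hypoxanthine	urate	formate	glutamine
Taurine and hypotaurine metabolism	synthetic decoy set	taurine	hypotaurine	acetate
Nicotinate and nicotinamide metabolism	synthetic decoy set	nicotinate	trigonelline	nicotinamide
Histidine metabolism	synthetic decoy set	histidine	glutamate	formate
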