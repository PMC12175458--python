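name,formula,source,activity_note
Sorbistin A2,C16H33N3O9,Pseudomonas sorbicinii D496-B83,broad antibacterial incl. aminoglycoside-resistant organisms
Nb-(5-Methylhexanoyl)tryptamine,C17H24N2O,Xenorhabdus doucetiae,cytotoxic tryptamine family; insecticidal
Eutypoid B,C17H14O4,Penicillium sp. KF620,GSK-3beta inhibitor
"5,7-Dimethoxy-4-phenylcoumarin",C17H14O4,Streptomyces aureofaciens CMUAc130,cytotoxic (LLC; A427); antifungal
"3-Hydroxy-3-[(4-methoxyphenyl)methyl]-1,4-dimethyl-2,5-piperazinedione",C14H18N2O4,Penicillium brevi-compactum,antiviral; cytotoxic
3'-N-Formylfusarochromanone,C16H20N2O5,Fusarium equiseti,parent compound broadly cytotoxic
Aerucyclamide B,C24H32N6O4S2,Microcystis aeruginosa PCC 7806,anthelminthic (LC50 33.8 uM vs T. platyurus)
6-Hydroxypterulone,C13H11ClO3,Mycena galopus,antifungal; weak antitumor
5-Chloroilicicolin B,C23H31ClO3,Stachybotrys sp.,ilicicolin family; receptor antagonism
Antibiotic C 13648,C21H26N2O4,Streptomyces antibioticus C13648,antibacterial
"Ikarugamycin 26R-methoxy-16-hydroxy-4,5-epoxide",C30H40N2O7,Streptomyces sp.,antimicrobial; cytotoxic ikarugamycin family
TMC-1 D,C30H40N2O7,Streptomyces sp. A-230,antitumor (HCT-116; HL-60; HeLa S3)
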