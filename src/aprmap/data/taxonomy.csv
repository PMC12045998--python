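ai_name,chem_class_code,chem_class_name,major_group,crops
"2,4-d",H01_01,Phenoxy H,H,ALL
"2,4-db",H01_01,Phenoxy H,H,PasHay
Dichlorprop,H01_01,Phenoxy H,H,PasHay
Mcpa,H01_01,Phenoxy H,H,Wheat;PasHay
Metribuzin,H02_03,Triazinone H,H,Soybean;PasHay;Other
Dimethenamid(-p),H03_01,H based on amide and anilide,H,Corn;Soybean;Other
Metolachlor(-s),H03_03,Chloroacetalinide H,H,Corn;Soybean;VegFru;PasHay;Other
Pendimethalin,H05_01,Dinitro Aniline H,H,Corn;Soybean;Rice;VegFru;OrcGra;Other
Halosulfuron,H06_01,Sulfonylurea H,H,Rice
Metsulfuron,H06_01,Sulfonylurea H,H,PasHay
Diuron,H06_03,Urea H,H,OrcGra;PasHay
Cyhalofop,H99_01,Aryloxyphenoxy-propionic H,H,Rice
Dicamba,H99_03,Benzoic Acid H,H,Corn;Soybean;Wheat;PasHay;Other
Cletodim,H99_05,Cyclohexanedione H,H,Soybean;PasHay
Flumioxazyn,H99_07,Dicarboximide H,H,Soybean
Oxyfluorfen,H99_08,Diphenyl ether H,H,OrcGra
Isoxaflutole,H99_11,Isoxazole H,H,Corn
Bromoxynil,H99_13,Nitrile H,H,Wheat;Other
Glufosinate,H99_14,Organophosphorus H,H,Corn;Soybean;OrcGra;PasHay
Glyphosate,H99_14,Organophosphorus H,H,ALL
Pinoxaden,H99_15,Phenylpirazole H,H,Wheat
Aminopyralid,H99_18,Pyridinecarboxylic H,H,PasHay
Clopyralid,H99_18,Pyridinecarboxylic H,H,Corn;Wheat;PasHay
Picloram,H99_18,Pyridinecarboxylic H,H,PasHay
Fluroxypyr,H99_19,Pyrodyloxyacetic-acid H,H,Wheat;PasHay
Triclopyr,H99_19,Pyrodyloxyacetic-acid H,H,Rice;PasHay
Bentazone,H99_21,Thiadiazine H,H,Rice;VegFru
Tri-allate,H99_22,Thiocarbamate H,H,Wheat
Mesotrione,H99_26,Triketone H,H,Corn
Clomazone,H99_99,Unclassified H,H,Rice
Copper hydroxide,F01_01,Copper Compounds,F,VegFru;OrcGra
Copper sulfate,F01_01,Copper Compounds,F,Rice;OrcGra
Copper sulfate tribasic,F01_01,Copper Compounds,F,OrcGra
Calcium polysulfide,F01_99,Other inorganic F,F,OrcGra
Mancozeb,F02_03,Dithiocarbamate F,F,VegFru;OrcGra
Ziram,F02_03,Dithiocarbamate F,F,OrcGra
Thiophanate-methyl,F03_01,Benzimidazole F,F,Wheat;VegFru
Metconazole,F04_01,Conazole F,F,Wheat
Propiconazole,F04_01,Conazole F,F,Wheat;Rice
Prothioconazole,F04_01,Conazole F,F,Wheat
Tebuconazole,F04_01,Conazole F,F,Wheat
Bacillus amyloliquifacien,F06_01,Microbiological F,F,VegFru;Other
Flutolanil,F99_03,Anilide F,F,Other
Chlorothalonil,F99_05,Aromatic F,F,VegFru;OrcGra;Other
Captan,F99_12,Phthalamide F,F,VegFru;OrcGra
Azoxystrobin,F99_16,Strobilurine F,F,Corn;Wheat;Rice
Pyraclostrobin,F99_16,Strobilurine F,F,Corn;Soybean;Wheat
Trifloxystrobin,F99_16,Strobilurine F,F,Rice
Cyhalothrin-lambda,I01_01,Pyrethroid I,I,Rice
Chlorpyrifos,I04_01,Organophosphorus I,I,Corn;Soybean;Wheat;OrcGra;Other
Dimethoate,I04_01,Organophosphorus I,I,Wheat
Ethoprophos,I04_01,Organophosphorus I,I,VegFru
Clothianidin,I99_08,Nitroguanidine I,I,Rice
Metam,ZR03_99,Other soil sterilant,Z,VegFru;Other
Metam potassium,ZR03_99,Other soil sterilant,Z,VegFru
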