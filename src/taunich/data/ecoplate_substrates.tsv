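substrate	category
Pyruvic Acid Methyl Ester	esters
Tween 40	polymers
Tween 80	polymers
alpha-Cyclodextrin	polymers
Glycogen	polymers
D-Cellobiose	carbohydrates
alpha-D-Lactose	carbohydrates
beta-Methyl-D-Glucoside	carbohydrates
D-Xylose	carbohydrates
i-Erythritol	carbohydrates
D-Mannitol	carbohydrates
N-Acetyl-D-Glucosamine	carbohydrates
D-Glucosaminic Acid	carboxylic acids
Glucose-1-Phosphate	phosphorylated
D,L-alpha-Glycerol Phosphate	phosphorylated
D-Galactonic Acid gamma-Lactone	carboxylic acids
D-Galacturonic Acid	carboxylic acids
2-Hydroxy Benzoic Acid	carboxylic acids
4-Hydroxy Benzoic Acid	carboxylic acids
gamma-Hydroxybutyric Acid	carboxylic acids
Itaconic Acid	carboxylic acids
alpha-Ketobutyric Acid	carboxylic acids
D-Malic Acid	carboxylic acids
L-Arginine	amino acids
L-Asparagine	amino acids
L-Phenylalanine	amino acids
L-Serine	amino acids
L-Threonine	amino acids
Glycyl-L-Glutamic Acid	amino acids
Phenylethylamine	amines
Putrescine	amines
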