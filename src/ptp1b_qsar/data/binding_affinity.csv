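name,mw,pkd,pkd_std,delta_g_kcal_mol,delta_g_std,ligand_efficiency,ligand_efficiency_std,n_heavy,n_heavy_provenance
Catechol,110.04,3.62,0.17,-4.89,-0.24,-0.61,-0.03,8,derived
Metformin,129.10,3.56,0.49,-4.81,-0.66,-0.53,0.07,9,derived
(-)-Epicatechin,290.08,6.01,0.40,-8.12,-0.54,-0.39,-0.03,21,derived
Cianidanol,290.08,5.75,0.20,-7.76,-0.27,-0.37,-0.01,21,derived
Salacinol,334.04,5.28,0.71,-7.13,-0.95,-0.36,-0.05,,
Luteolin,286.05,5.38,0.40,-7.26,-0.54,-0.35,-0.03,21,derived
Topiramate,339.10,5.52,0.56,-7.46,-0.76,-0.34,-0.03,22,derived
Baicalein,270.05,5.00,0.45,-6.75,-0.06,-0.34,-0.03,20,derived
Morin,302.04,5.46,0.36,-7.37,-0.48,-0.34,-0.02,22,derived
Ellagic acid,302.01,5.24,0.78,-7.08,-1.06,-0.32,-0.05,22,derived
Cajanin,300.06,5.07,0.28,-6.85,-0.37,-0.31,-0.02,22,derived
Apigenin,270.05,4.54,0.47,-6.13,-0.64,-0.31,-0.03,20,derived
Leucopelargonidin,290.08,4.85,0.43,-6.55,-0.58,-0.31,-0.03,21,derived
Wogonin,284.07,4.62,0.46,-6.24,-0.62,-0.30,-0.03,21,derived
Malic acid,134.02,1.95,0.39,-2.64,-0.53,-0.29,-0.06,9,derived
Rosmarinic acid,360.08,5.41,0.66,-7.30,-0.90,-0.28,-0.03,26,derived
Curcumin,368.13,5.43,0.76,-7.33,-1.02,-0.27,-0.04,27,derived
Brevifolin carboxylic acid,292.02,3.42,0.44,-4.61,-0.60,-0.22,-0.03,21,derived
Tolazamide,311.13,3.40,0.49,-4.59,-0.66,-0.22,-0.03,21,derived
Rosiglitazone,357.11,4.16,0.57,-5.62,-0.77,-0.22,-0.03,25,derived
Pioglitazone,356.12,3.87,0.48,-5.23,-0.64,-0.21,-0.03,25,derived
Chlorpropamide,276.03,2.65,0.17,-3.57,-0.23,-0.21,-0.01,17,derived
Silydianin,482.12,5.20,0.35,-7.02,-0.47,-0.20,-0.01,35,printed
Tolbutamide,270.10,2.70,0.24,-3.64,-0.32,-0.20,-0.02,18,derived
Acetohexamide,324.11,2.88,0.42,-3.89,-0.57,-0.18,-0.03,22,derived
Glibenclamide,493.14,3.61,0.43,-4.87,-0.58,-0.15,-0.02,33,derived
Glipizide,445.18,3.31,0.38,-4.47,-0.51,-0.14,-0.02,31,derived
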