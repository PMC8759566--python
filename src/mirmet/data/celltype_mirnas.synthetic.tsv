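# Synthetic stand-in for the curated 45-miRNA cell-type-specific marker list.
# Pairs reported in the study's results are included verbatim; remaining rows
# are plausible fillers following standard marker assignments.  Replace with
# the real curation for production use.
mirna	celltype
Mir-122_5p	hepatocyte
Mir-192-P1_5p	epithelial
Mir-375_3p	epithelial
Mir-194_5p	epithelial
Mir-200-P1_3p	epithelial
Mir-200-P2_3p	epithelial
Mir-203_3p	epithelial
Mir-205_5p	epithelial
Mir-215_5p	epithelial
Mir-143_5p	mesenchymal
Mir-143_3p	mesenchymal
Mir-145_5p	mesenchymal
Mir-199-P1_3p	mesenchymal
Mir-214_3p	mesenchymal
Mir-490_3p	mesenchymal
Mir-150_5p	lymphocyte
Mir-155_5p	lymphocyte
Mir-142_3p	lymphocyte
Mir-142_5p	lymphocyte
Mir-342_3p	dendritic_lymphocyte_macrophage
Mir-223_3p	dendritic
Mir-223_5p	dendritic
Mir-17-P1a_5p	monocyte
Mir-17-P1b_5p	monocyte
Mir-146-P1_5p	monocyte
Mir-146-P2_5p	monocyte
Mir-486_5p	erythrocyte
Mir-451_5P	erythrocyte
Mir-144_3p	erythrocyte
Mir-144_5p	erythrocyte
Mir-126_3p	endothelial
Mir-126_5p	endothelial
Mir-139_5p	endothelial
Mir-1-P1_3p	muscle
Mir-133-P1_3p	muscle
Mir-208_3p	muscle
Mir-499_5p	muscle
Mir-9-P1_5p	neural
Mir-124-P1_3p	neural
Mir-128-P1_3p	neural
Mir-219-P1_5p	neural
Mir-7-P1_5p	neuroendocrine
Mir-96_5p	sensory_epithelial
Mir-183_5p	sensory_epithelial
Mir-34-P2b_5p	pneumocyte
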