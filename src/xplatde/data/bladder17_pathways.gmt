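KEGG:cardiac_muscle_contraction	Cardiac muscle contraction	70	7169
KEGG:dilated_cardiomyopathy	Dilated cardiomyopathy	70	7169
KEGG:hypertrophic_cardiomyopathy	Hypertrophic cardiomyopathy (HCM)	70	7169
KEGG:calcium_signaling	Calcium signaling pathway	3973	6870
KEGG:neuroactive_ligand_receptor	Neuroactive ligand-receptor interaction	3973	6870
PC:signaling_by_gpcr	Signaling by GPCR	3973	6870
PC:class_a1_rhodopsin_like	Class A/1 (Rhodopsin-like receptors)	3973	6870
WP:striated_muscle_contraction	Striated Muscle Contraction	70	7169
WP:peptide_gpcrs	Peptide GPCRs	3973	6870
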