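motif	incidence	gene_ids
_WTGAAAT_UNKNOWN	4	8404,1421,4807,6870
_CCAWWNAAGG_V$SRF_Q4	2	7169,6876
_V$STAT3_02	2	652,10548
_RNGTGGGC_UNKNOWN	3	2705,652,4359
_V$HMEF2_Q6	2	652,7169
_V$SRF_Q4	2	7169,6876
_V$SMAD_Q6	2	652,6876
_V$HEN1_01	2	652,4239
_V$SRF_Q6	2	7169,6876
_TTGTTT_V$FOXO4_01	4	8404,652,3052,4359
_V$ZIC3_01	2	2705,4807
_V$TTF1_Q6	2	652,7169
_V$GR_Q6_01	2	4359,4807
_V$HEN1_02	2	652,4239
_V$ZIC1_01	2	2705,7169
_V$SRF_Q5_01	2	7169,6876
_V$CEBPB_02	2	1621,4807
_V$POU1F1_Q6	2	652,4807
_SCGGAAGY_V$ELK1_02	3	2705,10548,3052
_CAGGTG_V$E12_Q6	4	2705,652,4239,4807
_YNGTTNNNATT_UNKNOWN	2	652,7169
_WGGAATGY_V$TEF1_Q6	2	652,4359
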