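# APP/PSEN1 cortex miRNA differential-expression calls, 6-month stage.
# Normalized means are on the DESeq2 median-of-ratios scale
# (mean_ctrl = wild type, mean_case = APP/PSEN1).
# Rows below the concordant set are non-concordant decoys.
feature_id	rna_class	mean_ctrl	mean_case	direction
mmu-miR-339-3p	miRNA	86	110	up
mmu-miR-369-5p	miRNA	2999	3361	up
mmu-miR-450b-5p	miRNA	10	18	up
mmu-miR-881-3p	miRNA	17	33	up
mmu-miR-1983	miRNA	335	423	up
mmu-miR-31-5p	miRNA	195	160	down
mmu-miR-122-5p	miRNA	42	24	down
mmu-miR-146a-5p	miRNA	300	251	down
mmu-miR-132-3p	miRNA	150	101	down
mmu-miR-709	miRNA	50	82	up
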