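# APP/PSEN1 cortex miRNA differential-expression calls, 9-month stage.
# Normalized means are on the DESeq2 median-of-ratios scale
# (mean_ctrl = wild type, mean_case = APP/PSEN1).
# Rows below the concordant set are non-concordant decoys.
feature_id	rna_class	mean_ctrl	mean_case	direction
mmu-miR-24-3p	miRNA	21261	23968	up
mmu-miR-99b-3p	miRNA	785	905	up
mmu-miR-149-5p	miRNA	2240	2806	up
mmu-miR-187-3p	miRNA	1348	1655	up
mmu-miR-369-5p	miRNA	2962	3232	up
mmu-miR-434-5p	miRNA	104812	116640	up
mmu-miR-467a-5p	miRNA	2758	3252	up
mmu-miR-666-5p	miRNA	1165	1441	up
mmu-miR-1198-5p	miRNA	1258	1428	up
mmu-miR-3074-5p	miRNA	21228	23940	up
mmu-miR-10b-5p	miRNA	218	161	down
mmu-miR-34b-5p	miRNA	30	12	down
mmu-miR-34c-5p	miRNA	7020	4872	down
mmu-miR-340-5p	miRNA	7643	6290	down
mmu-miR-369-3p	miRNA	1674	1456	down
mmu-miR-499-5p	miRNA	187	154	down
mmu-miR-128-3p	miRNA	400	521	up
mmu-miR-709	miRNA	55	86	up
mmu-miR-132-3p	miRNA	160	112	down
mmu-miR-138-5p	miRNA	600	452	down
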