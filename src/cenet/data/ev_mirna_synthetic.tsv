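# Neuron-derived extracellular-vesicle miRNA differential-expression calls
# (APP-overexpressing neuronal model vs control), applied to all stages.
# SYNTHETIC/RECONSTRUCTED: the published record lists only the cortex side
# of the concordant sets; the EV-side directions here are the ones implied
# by the concordance rule, and the expression means are invented
# placeholders consistent with those directions. Decoy rows carry
# directions that break concordance on purpose.
feature_id	rna_class	mean_ctrl	mean_case	direction
mmu-miR-339-3p	miRNA	120	180	up
mmu-miR-369-5p	miRNA	2100	3000	up
mmu-miR-450b-5p	miRNA	15	27	up
mmu-miR-881-3p	miRNA	22	41	up
mmu-miR-1983	miRNA	280	390	up
mmu-miR-24-3p	miRNA	18000	24500	up
mmu-miR-99b-3p	miRNA	640	880	up
mmu-miR-149-5p	miRNA	1900	2700	up
mmu-miR-187-3p	miRNA	1100	1600	up
mmu-miR-434-5p	miRNA	88000	118000	up
mmu-miR-467a-5p	miRNA	2300	3200	up
mmu-miR-666-5p	miRNA	950	1350	up
mmu-miR-1198-5p	miRNA	1050	1450	up
mmu-miR-3074-5p	miRNA	17500	24000	up
mmu-miR-31-5p	miRNA	260	170	down
mmu-miR-122-5p	miRNA	60	31	down
mmu-miR-10b-5p	miRNA	300	190	down
mmu-miR-34b-5p	miRNA	45	19	down
mmu-miR-34c-5p	miRNA	8100	5200	down
mmu-miR-340-5p	miRNA	8900	6400	down
mmu-miR-369-3p	miRNA	2000	1500	down
mmu-miR-499-5p	miRNA	240	170	down
mmu-miR-185-5p	miRNA	1500	600	down
mmu-miR-146a-5p	miRNA	700	1000	up
mmu-miR-21a-5p	miRNA	5000	7200	up
mmu-miR-132-3p	miRNA	900	1300	up
mmu-miR-128-3p	miRNA	2600	1800	down
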