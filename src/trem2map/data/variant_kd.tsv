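# TREM2 variant panel with per-ligand equilibrium dissociation constants.
# Empty cell = not measured for that ligand. Sentinel entries are kept as
# printed text: "N.B.D." (no binding detected), "No Binding",
# "Decreased binding", "Binding (not fit)". Fold columns keep the printed
# arrow text verbatim; see variants.fold_change for the computed quantity.
# provenance: this-paper | previous-publication (previously determined K_D).
name	site_class	provenance	apoe4_kd_nM	apoe4_err_nM	apoe4_fold_printed	c1q_kd_uM	c1q_err_uM	il34_kd_nM	il34_err_nM	il34_fold_printed
WT	wild-type	previous-publication	281	43	-	0.65	0.03	16.5	0.2	-
R47H	basic	previous-publication	643	91	dn 2.29	0.18	0.01	79.8	2.4	dn 4.8
R62H	basic	previous-publication	561	117	dn 2.00	1.66	0.06	75		dn 4.5
D87N	AD-risk	this-paper	25	6	dn 11.24			28.4	0.5	dn 1.7
T96K	AD-risk	previous-publication	891	196	dn 3.17	No Binding		23.7	0.4	dn 1.4
M41D	hydrophobic	previous-publication	1426	566	dn 5.07	2.54	0.52
W44D	hydrophobic	previous-publication	2565	710	dn 9.12
L69D	hydrophobic	previous-publication	55060	20390	dn 195.94	Decreased binding
W70D	hydrophobic	previous-publication	28110	14380	dn 100.04	Decreased binding
L71D	hydrophobic	this-paper				0.058	0.002
F74D	hydrophobic	previous-publication	9709	1163	dn 34.55	0.11	0.01
L89D	hydrophobic	this-paper				Decreased binding
L69D/L71D	hydrophobic	this-paper	N.B.D.		-	Binding (not fit)		20.2	0.3	dn 1.2
W44D/L69D/L71D	hydrophobic	this-paper	N.B.D.		-	Binding (not fit)		25.8	0.3	dn 1.6
R46A	basic	this-paper				No Binding
R46D	basic	this-paper				No Binding		18.0	0.3	dn 1.1
R46A/R47A	basic	this-paper	388	141	dn 1.38	No Binding
R76D	basic	this-paper	1529	693	dn 5.44	13.8	4.86	N.B.D.		-
R77D	basic	this-paper	1659	379	dn 5.90	No Binding		114	4	dn 6.9
W78D	basic	this-paper						17.2	0.4	dn 1.04
L75D	basic-adjacent	this-paper				0.11	0.01	36.6	0.9	dn 2.2
T85D	basic-adjacent	this-paper				0.11	0.01	21.5	0.6	dn 1.3
R122E	site2	this-paper						29.4	0.4	dn 1.8
R122D/K123D	site2	this-paper	120	22	up 2.30	0.82	0.04	18.5	0.3	dn 1.1
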