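rsid	effect_allele	beta_exposure	se_exposure	beta_outcome	se_outcome	chromosome	nearby_gene	other_allele	eaf	f_statistic	p_exposure	p_outcome	proxy_of	proxy_r2
rs1801725	T	0.071	0.004	-0.032	0.027	3	CASR		0.15	299	8.9E-86	0.236
rs1570669	G	0.018	0.003	0.014	0.018	20	CYP24A1		0.34	37	9.1E-12	0.457
rs1550532	C	0.018	0.003	0.004	0.018	2	DGKD		0.31	37	8.2E-11	0.829
rs7481584	G	0.018	0.003	0.003	0.018	11	CARS		0.70	37	1.2E-10	0.888
rs780094	T	0.017	0.003	0.008	0.017	2	GCKR		0.42	37	1.3E-10	0.652
rs7336933	G	0.022	0.004	-0.013	0.024	13	DGKH/KIAA0564		0.85	31	9.1E-10	0.594
rs10491003	T	0.027	0.005	-0.030	0.031	10	GATA3		0.09	31	4.8E-09	0.344
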