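rsid	effect_allele	beta_exposure	se_exposure	beta_outcome	se_outcome	chromosome	nearby_gene	other_allele	eaf	f_statistic	p_exposure	p_outcome	proxy_of	proxy_r2
rs4072037	T	0.010	0.001	0.006	0.017	1	MUC1		0.53	136	2.1E-36	0.744
rs7965584	A	0.007	0.001	-0.021	0.020	12	ATP2B1		0.71	60	1.1E-16	0.286	rs10858938	0.95
rs3925584	T	0.006	0.001	0.009	0.017	11	DCDC5		0.55	60	5.2E-16	0.607
rs11144134	C	0.011	0.001	-0.022	0.032	9	TRPM6		0.08	55	8.2E-15	0.505
rs13146355	A	0.005	0.001	-0.052	0.018	4	SHROOM3		0.44	45	6.3E-13	0.003
rs448378	A	0.004	0.001	0.003	0.017	3	MDS1		0.53	31	1.3E-08	0.864
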