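gene	pattern	transcript_id	dmr_id	delta_beta_1	meth_p_1	delta_beta_2	meth_p_2	fc_1	expr_p_1	fc_2	expr_p_2
2310035C23Rik	A	NM_173187	chr1$105680001$105681000	17.91792	0.001044	-14.3229	0.000793	-7.15782	0.003233	5.794239	0.01018
2310035C23Rik	A	NM_173187	chr1$105680501$105681500	17.91792	0.001044	-14.6318	0.000691	-7.15782	0.003233	5.794239	0.01018
Acsl4	A	NM_019477	chrX$142468501$142469500	20.1579	4.01e-8	-18.5894	3.60e-9	-3.31049	0.008914	2.466142	0.036953
Clec4d	A	NM_010819	chr6$123258501$123259500	13.24306	3.05e-6	-12.7135	8.06e-8	-1.8897	0.031682	1.659789	0.047727
Dlg3	A	NM_001177780	chrX$100801001$100802000	21.42624	2.03e-5	-15.8962	0.000187	-3.39981	0.001902	2.512896	0.013947
Errfi1	A	NM_133753	chr4$150851001$150852000	10.49137	6.31e-5	-10.8417	1.84e-6	-2.72862	0.000324	1.392076	0.044534
Gpr155	A	NM_001190297	chr2$73402501$73403500	14.45583	0.001214	-13.4888	0.000127	-2.73567	0.000478	1.421815	0.047225
Gtf2e2	A	NM_026584	chr8$33705501$33706500	14.15904	2.14e-7	-11.7841	8.08e-8	-4.88319	0.011646	5.739732	0.003803
Gtf2e2	A	NM_026584	chr8$33721001$33722000	17.11279	0.000173	-19.3001	6.24e-8	-4.88319	0.011646	5.739732	0.003803
Gtf2e2	A	NM_026584	chr8$33721501$33722500	14.40352	0.000466	-20.3312	8.98e-12	-4.88319	0.011646	5.739732	0.003803
Hopx	A	NM_001159900	chr5$77114001$77115000	17.89375	2.10e-9	-11.912	5.71e-6	-2.37969	0.00221	1.429905	0.04741
Ints6	A	NM_008715	chr14$62774001$62775000	12.51032	0.0003	-18.3492	3.51e-9	-3.22793	0.001325	3.076277	0.001547
Kat6a	A	NM_001081149	chr8$22873001$22874000	21.42651	0.002265	-40.3226	7.75e-14	-2.32499	0.028763	3.024011	0.004454
Kit	A	NM_001122733	chr5$75579001$75580000	11.51523	7.89e-5	-10.3308	3.31e-5	-7.78059	0.000103	6.402056	0.00061
Kit	A	NM_001122733	chr5$75579501$75580500	10.35753	1.89e-6	-11.8328	2.81e-10	-7.78059	0.000103	6.402056	0.00061
Ndel1	A	NM_023668	chr11$68825001$68826000	21.79487	0.000464	-22.6016	3.14e-5	-4.91466	0.000645	4.250178	0.001895
Pcmtd1	A	NM_183028	chr1$7543001$7544000	10.6038	0.001635	-11.7335	2.64e-5	-5.37129	3.98e-7	2.821372	0.002068
Rps24	A	NM_011297	chr14$24497001$24498000	17.13836	0.000641	-17.2688	0.00011	-4.04976	0.001056	2.911984	0.01074
Rps24	A	NM_207635	chr14$24497001$24498000	17.13836	0.000641	-17.2688	0.00011	-4.00879	0.000414	3.224884	0.002518
Rps24	A	NM_011297	chr14$24497501$24498500	17.13836	0.000641	-17.2688	0.00011	-4.04976	0.001056	2.911984	0.01074
Rps24	A	NM_207635	chr14$24497501$24498500	17.13836	0.000641	-17.2688	0.00011	-4.00879	0.000414	3.224884	0.002518
Shroom2	A	NM_001290684	chrX$152750501$152751500	19.51472	1.06e-5	-16.7372	4.44e-6	-11.7053	2.06e-6	9.44746	0.00004
Shroom2	A	NM_001290684	chrX$152751001$152752000	19.51472	1.06e-5	-16.7372	4.44e-6	-11.7053	2.06e-6	9.44746	0.00004
Sppl3	A	NM_029012	chr5$115027001$115028000	10.11934	9.88e-7	-11.4787	2.84e-11	-2.95759	0.000555	2.19341	0.006261
Zfp568	A	NM_001167873	chr7$30013001$30014000	10.90426	0.00247	-17.1518	1.59e-7	-4.33247	0.007645	4.172162	0.008244
Vegfa	B	NM_001025257	chr17$46024501$46025500	-13.0325	0.004499	18.71345	3.94e-6	2.522877	0.014275	-2.46869	0.007728
Vegfa	B	NM_001025257	chr17$46025001$46026000	-13.0325	0.004499	18.71345	3.94e-6	2.522877	0.014275	-2.46869	0.007728
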