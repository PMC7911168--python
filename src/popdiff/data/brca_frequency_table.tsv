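gene	variant_id	region	change	impact	IND	AFR	AMR	EAS	EUR	SAS
BRCA1	rs799923	intronic	G > A	modifier	0.016	0.0389	0.0845	0.0007	0.2299	0.1797
BRCA1	rs16941	CDS	T > C	moderate	0.453	0.1797	0.3083	0.3777	0.3254	0.4996
BRCA1	rs16942	CDS	T > C	moderate	0.453	0.2358	0.3141	0.3827	0.3259	0.4999
BRCA1	rs1799966	other	T > C	moderate	0.453	0.2397	0.3138	0.3805	0.3268	0.5001
BRCA1	rs12516	UTR3	G > A	modifier	0.24	0.3012	0.3433	0.4286	0.3841	0.4839
BRCA1	rs799905	intronic	G > C	modifier	0.4754	0.7789	0.4468	0.4403	0.3796	0.5116
BRCA1	rs1799949	other	G > A	moderate	0.4531	0.2364	0.3138	0.3783	0.3252	0.5002
BRCA1	rs799917	CDS	G > A	moderate	0.4841	0.8193	0.3435	0.378	0.3341	0.5285
BRCA2	rs11571769	CDS	G > A	moderate	0.1111	0.0012	0.0349	0	0.0044	0.014
BRCA2	rs144848	CDS	A > C	moderate	0.5078	0.1249	0.3049	0.2728	0.2818	0.3558
BRCA2	rs1799943	UTR5	G > A	modifier	0.0937	0.1005	0.1895	0.3805	0.2581	0.2829
BRCA2	rs11571651	intronic	G > T	modifier	0	0.0238	0.0633	0.0994	0.0335	0.1157
BRCA2	rs1799944	CDS	A > G	moderate	0.1406	0.0427	0.0672	0.1002	0.035	0.1151
BRCA2	rs11571707	CDS	T > C	moderate	0.3203	0.0026	0.1409	0.0036	0.0003	0.0018
BRCA2	rs766173	CDS	A > C	moderate	0.1379	0.024	0.0667	0.1002	0.035	0.1159
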