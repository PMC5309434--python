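Gene symbol	Ensembl ID	Probability	Permutation FDR	MIS	MFS
ANK2	ENSP00000349588	4.53E-05	<0.001	990	0.997
ANK1	ENSP00000265709	3.52E-05	0.034	995	0.995
EPHA7	ENSP00000358309	3.28E-05	0.025	906	0.988
EPHA5	ENSP00000273854	3.46E-05	0.032	906	0.988
PRIKCG	ENSP00000263431	4.75E-05	0.025	905	0.987
PTK7	ENSP00000230419	3.10E-05	0.023	943	0.987
EPHA3	ENSP00000337451	4.40E-05	0.017	912	0.986
PDE6C	ENSP00000360502	3.61E-05	0.032	900	0.980
EPHA4	ENSP00000281821	4.16E-05	0.008	990	0.980
YWHAQ	ENSP00000238081	5.50E-05	0.004	999	0.978
GSK3A	ENSP00000222330	6.40E-05	0.017	977	0.976
CALM1	ENSP00000349467	6.55E-05	0.023	966	0.976
EPHB2	ENSP00000363763	4.39E-05	0.026	908	0.975
PRIKCA	ENSP00000408695	7.02E-05	0.039	992	0.975
CALM2	ENSP00000272298	5.52E-05	0.048	985	0.974
YWHAE	ENSP00000264335	1.63E-04	0.009	999	0.973
YWHAB	ENSP00000300161	5.56E-05	0.047	999	0.971
ATP2A2	ENSP00000440045	5.03E-05	0.005	908	0.970
YES1	ENSP00000324740	6.54E-05	0.002	967	0.969
CALML3	ENSP00000315299	3.96E-05	0.027	906	0.968
SGK1	ENSP00000356832	4.90E-05	0.034	999	0.966
CALML6	ENSP00000304643	4.44E-05	0.01	909	0.965
YWHAZ	ENSP00000309503	1.86E-04	0.002	999	0.958
MAPK7	ENSP00000311005	7.15E-05	0.031	999	0.956
RRAS	ENSP00000246792	5.94E-05	0.004	951	0.941
RAP2A	ENSP00000245304	4.97E-05	0.021	940	0.937
RALA	ENSP00000005257	6.57E-05	0.006	981	0.932
RAP1B	ENSP00000250559	5.28E-05	0.009	972	0.931
MRAS	ENSP00000289104	4.70E-05	0.022	932	0.931
INSR	ENSP00000303830	7.27E-05	0.024	996	0.927
PAP1A	ENSP00000348786	6.49E-05	0.014	995	0.925
RND1	ENSP00000308461	5.70E-05	0.002	996	0.903
FYN	ENSP00000346671	1.02E-04	<0.001	999	0.900
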