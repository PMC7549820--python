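# 12 CiPA reference compounds used in the channel-block study.
# IC50 (hERG / Cav1.2 / Nav1.5), concentrations and cmax in uM.
# Censored potencies are kept verbatim as '>x' / '<x'; 'NA' = no block data.
name,ic50_herg,ic50_cav12,ic50_nav15,hill,concentrations,cmax,tdp_label,channel_labels,split
Loratadine,6.1,11.4,28.9,1,0.001;0.003;0.0095;0.03,0.00046,no_risk,K;Ca,V
Ibutilide,0.018,62.5,42.5,1,0.0001;0.001;0.01;0.1,0.1,risk,K,T
Droperidol,0.06,7.6,22.7,1,0.03169;0.10014;0.31646;1.0,0.02,risk,K,T
Mexiletine,62.2,125,38,1,0.1;1.0;10;100,2.5,no_risk,Na;K,T
Dofetilide,0.03,26.7,162.1,1,0.0003;0.001;0.0032;0.01,0.002,risk,K,V
Diltiazem,13.2,0.76,22.4,1,0.01;0.1;1.0;10,0.13,no_risk,Ca,T
Chlorpromazine,1.5,3.4,3.0,1,0.0951;0.3004;0.9494;3,0.0345,risk,K;Ca;Na,V
Clozapine,2.3,3.6,15.1,1,0.0951;0.3004;0.9494;3,0.07,risk,K;Ca,T
Clarithromycine,32.9,>30,NA,1,0.1;1;10;100,1.2,risk,K,V
Cisapride,0.02,11.8,337,1,0.0032;0.01;0.0316;0.1,0.0026,risk,K,V
Bepridil,0.16,1.0,2.3,1,0.01;0.1;1;10,0.03,risk,K;Ca;Na,V
Azimilide,<1,17.8,19,1,0.01;0.1;1;10,0.07,risk,K;Na;Ca,V
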