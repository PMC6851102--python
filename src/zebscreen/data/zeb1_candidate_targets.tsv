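gene	OE_393P_p	OE_393P_fold	miR200_344SQ_p	miR200_344SQ_fold	ZEB1_3T3L1_p	ZEB1_3T3L1_fold	shZEB1_MDA231_p	shZEB1_MDA231_fold
KCNK1	0.000	0.003	0.000	33.603	0.000	0.053	0.129	0.610
TBC1D2	0.000	0.057	0.066	0.800	0.008	0.645	0.562	1.107
MUC1	0.000	0.057	0.000	3.764	0.014	0.532	0.521	1.712
C1orf210	0.005	0.062	0.016	1.659	0.000	0.095	0.038	0.348
PTPN6	0.001	0.063	0.050	1.359	0.010	0.433	0.396	0.874
MACC1	0.000	0.085	0.000	30.483	0.000	0.036	0.046	0.425
ATG4D	0.000	0.141	0.039	1.207	0.057	0.630	0.783	0.956
IFNGR1	0.041	0.170	0.032	0.706	0.038	1.310	0.210	1.088
EPS8L2	0.000	0.170	0.002	1.154	0.706	1.021	0.663	0.867
GADD45B	0.000	0.215	0.015	2.316	0.007	0.758	0.836	1.145
DNM1	0.004	0.227	0.120	1.416	0.158	1.416	0.216	1.472
FAM188A	0.000	0.236	0.006	1.630	0.018	0.453	0.438	1.168
GTPBP2	0.001	0.247	0.393	1.695	0.045	0.908	0.511	0.914
TERF2IP	0.032	0.282	0.144	3.603	0.001	1.910	0.992	0.996
SCAF8	0.000	0.307	0.005	1.215	0.023	0.492	0.753	0.939
PLLP	0.006	0.318	0.010	0.549	0.004	1.674	0.442	1.306
MPC1	0.001	0.320	0.159	0.746	0.030	1.393	0.410	0.849
ANKRD17	0.086	0.348	0.005	1.511	0.060	0.716	0.255	0.752
UBE2Q2	0.000	0.348	0.069	1.645	0.273	0.727	0.864	0.961
TBC1D2B	0.001	0.353	0.105	2.741	0.195	1.340	0.904	1.012
EBI3	0.221	0.384	0.483	1.088	0.035	0.604	0.025	1.445
FAM207A	0.000	0.400	0.047	1.475	0.617	0.885	0.090	0.892
CHKA	0.002	0.424	0.004	2.358	0.372	0.802	0.194	1.437
TXNIP	0.000	0.428	0.549	0.598	0.583	1.096	0.621	1.095
TTC21A	0.368	0.435	0.122	0.539	0.132	0.390	0.028	1.247
GTF2I	0.125	0.436	0.042	1.696	0.230	0.802	0.226	0.727
FGFR1OP2	0.001	0.440	0.039	0.818	0.001	0.656	0.918	1.023
KCTD5	0.000	0.441	0.045	1.184	0.013	0.794	0.948	1.021
IPMK	0.000	0.464	0.016	1.652	0.400	0.954	0.123	1.171
STXBP5	0.002	0.471	0.033	1.456	0.640	1.069	0.263	0.768
MAN1A2	0.001	0.473	0.052	1.128	0.019	1.546	0.520	0.846
DIAPH3	0.000	0.483	0.594	1.781	0.013	0.758	0.340	0.786
SH3GL1	0.000	0.483	0.001	1.651	0.025	1.153	0.350	1.157
CAB39L	0.001	0.484	0.029	0.828	0.202	0.827	0.299	0.719
CENPO	0.000	0.485	0.286	1.461	0.371	0.868	0.748	0.972
ZDHHC14	0.370	0.490	0.023	2.400	0.282	0.855	0.619	1.125
CD164L2	0.476	0.499	0.010	2.065	NA	NA	NA	NA
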