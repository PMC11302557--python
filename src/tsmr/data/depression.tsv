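group	taxon	nsnp	method	se	or	ci_low	ci_high	pvalue
Phylum	Lentisphaerae	9	Inverse variance weighted	0.002	1.004	1.000	1.007	0.035
Phylum	Lentisphaerae	9	MR Egger	0.007	1.008	0.995	1.021	0.261
Phylum	Lentisphaerae	9	Simple mode	0.004	1.001	0.994	1.009	0.725
Phylum	Lentisphaerae	9	Weighted median	0.002	1.003	0.998	1.007	0.266
Phylum	Lentisphaerae	9	Weighted mode	0.004	1.002	0.995	1.009	0.626
Class	Lentisphaeria	12	Inverse variance weighted	0.002	1.004	1.001	1.008	0.019
Class	Lentisphaeria	12	MR Egger	0.007	1.009	0.996	1.022	0.227
Class	Lentisphaeria	12	Simple mode	0.004	1.002	0.995	1.010	0.533
Class	Lentisphaeria	12	Weighted median	0.002	1.003	0.998	1.007	0.263
Class	Lentisphaeria	12	Weighted mode	0.004	1.003	0.995	1.010	0.527
Order	Actinomycetales	5	Inverse variance weighted	0.003	1.007	1.000	1.013	0.047
Order	Actinomycetales	5	MR Egger	0.009	1.011	0.993	1.030	0.320
Order	Actinomycetales	5	Simple mode	0.005	1.007	0.997	1.018	0.255
Order	Actinomycetales	5	Weighted median	0.004	1.007	1.000	1.015	0.047
Order	Actinomycetales	5	Weighted mode	0.005	1.007	0.997	1.017	0.241
Order	Victivallales	8	Inverse variance weighted	0.007	1.004	1.001	1.008	0.019
Order	Victivallales	8	MR Egger	0.002	1.009	0.996	1.022	0.227
Order	Victivallales	8	Simple mode	0.007	1.002	0.995	1.010	0.563
Order	Victivallales	8	Weighted median	0.004	1.003	0.998	1.007	0.265
Order	Victivallales	8	Weighted mode	0.002	1.002	0.995	1.010	0.541
Family	Actinomycetaceae	5	Inverse variance weighted	0.003	1.007	1.000	1.013	0.046
Family	Actinomycetaceae	5	MR Egger	0.009	1.011	0.993	1.030	0.319
Family	Actinomycetaceae	5	Simple mode	0.005	1.007	0.996	1.018	0.262
Family	Actinomycetaceae	5	Weighted median	0.004	1.007	1.000	1.014	0.046
Family	Actinomycetaceae	5	Weighted mode	0.005	1.007	0.997	1.017	0.244
Family	Peptostreptococcaceae	14	Inverse variance weighted	0.002	1.005	1.001	1.009	0.014
Family	Peptostreptococcaceae	14	MR Egger	0.005	1.009	0.992	1.010	0.865
Family	Peptostreptococcaceae	14	Simple mode	0.005	1.009	0.100	1.019	0.079
Family	Peptostreptococcaceae	14	Weighted median	0.003	1.006	0.100	1.012	0.065
Family	Peptostreptococcaceae	14	Weighted mode	0.004	0.100	0.991	1.009	0.981
Family	Streptococcaceae	14	Inverse variance weighted	0.003	0.993	0.988	0.999	0.013
Family	Streptococcaceae	14	MR Egger	0.011	0.984	0.963	1.007	0.194
Family	Streptococcaceae	14	Simple mode	0.007	0.992	0.979	1.005	0.251
Family	Streptococcaceae	14	Weighted median	0.004	0.993	0.986	1.001	0.069
Family	Streptococcaceae	14	Weighted mode	0.007	0.993	0.980	1.007	0.330
Genus	Eubacterium ventriosum group	15	Inverse variance weighted	0.002	1.006	1.001	1.011	0.017
Genus	Eubacterium ventriosum group	15	MR Egger	0.011	1.023	1.002	1.045	0.052
Genus	Eubacterium ventriosum group	15	Simple mode	0.005	1.012	1.001	1.023	0.049
Genus	Eubacterium ventriosum group	15	Weighted median	0.003	1.008	1.002	1.015	0.010
Genus	Eubacterium ventriosum group	15	Weighted mode	0.005	1.011	1.000	1.022	0.060
Genus	Ruminococcus gnavus group	12	Inverse variance weighted	0.002	1.004	1.001	1.008	0.025
Genus	Ruminococcus gnavus group	12	MR Egger	0.009	1.009	0.991	1.027	0.332
Genus	Ruminococcus gnavus group	12	Simple mode	0.004	1.007	0.100	1.015	0.084
Genus	Ruminococcus gnavus group	12	Weighted median	0.002	1.006	1.002	1.011	0.008
Genus	Ruminococcus gnavus group	12	Weighted mode	0.004	1.007	1.000	1.015	0.073
Genus	Ruminiclostridium6	16	Inverse variance weighted	0.002	1.005	1.002	1.009	0.006
Genus	Ruminiclostridium6	16	MR Egger	0.005	0.999	0.990	1.009	0.860
Genus	Ruminiclostridium6	16	Simple mode	0.006	1.012	1.001	1.024	0.050
Genus	Ruminiclostridium6	16	Weighted median	0.003	1.005	0.999	1.010	0.084
Genus	Ruminiclostridium6	16	Weighted mode	0.005	0.999	0.988	1.010	0.856
Genus	Streptococcus	15	Inverse variance weighted	0.003	0.993	0.986	0.997	0.003
Genus	Streptococcus	15	MR Egger	0.009	0.969	0.952	0.986	0.002
Genus	Streptococcus	15	Simple mode	0.006	0.989	0.977	1.002	0.122
Genus	Streptococcus	15	Weighted median	0.003	0.992	0.985	0.999	0.020
Genus	Streptococcus	15	Weighted mode	0.006	0.990	0.978	1.001	0.095
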