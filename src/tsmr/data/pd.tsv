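group	taxon	nsnp	method	se	or	ci_low	ci_high	pvalue
Phylum	Lentisphaerae	9	Inverse variance weighted	0.074	0.836	0.724	0.965	0.015
Phylum	Lentisphaerae	9	MR Egger	0.258	0.715	0.431	1.186	0.235
Phylum	Lentisphaerae	9	Simple mode	0.162	0.743	0.542	1.020	0.104
Phylum	Lentisphaerae	9	Weighted median	0.099	0.762	0.628	0.924	0.006
Phylum	Lentisphaerae	9	Weighted mode	0.149	0.745	0.556	0.998	0.084
Order	Bacillales	8	Inverse variance weighted	0.077	1.144	1.013	1.292	0.030
Order	Bacillales	8	MR Egger	0.255	0.743	0.450	1.225	0.288
Order	Bacillales	8	Simple mode	0.166	0.747	0.540	1.035	0.123
Order	Bacillales	8	Weighted median	0.105	0.783	0.638	0.962	0.020
Order	Bacillales	8	Weighted mode	0.155	0.751	0.555	1.017	0.107
Order	Victivallales	8	Inverse variance weighted	0.077	0.847	0.728	0.986	0.032
Order	Victivallales	8	MR Egger	0.255	0.743	0.450	1.225	0.288
Order	Victivallales	8	Simple mode	0.169	0.747	0.537	1.040	0.128
Order	Victivallales	8	Weighted median	0.108	0.783	0.634	0.969	0.024
Order	Victivallales	8	Weighted mode	0.163	0.751	0.546	1.033	0.122
Class	Lentisphaeria	8	Inverse variance weighted	0.077	0.847	0.728	0.986	0.032
Class	Lentisphaeria	8	MR Egger	0.255	0.743	0.450	1.225	0.288
Class	Lentisphaeria	8	Simple mode	0.177	0.747	0.528	1.058	0.145
Class	Lentisphaeria	8	Weighted median	0.107	0.783	0.635	0.966	0.022
Class	Lentisphaeria	8	Weighted mode	0.160	0.751	0.549	1.027	0.116
Family	Oxalobacteraceae	14	Inverse variance weighted	0.061	1.130	1.003	1.273	0.044
Family	Oxalobacteraceae	14	MR Egger	0.259	1.422	0.856	2.362	0.198
Family	Oxalobacteraceae	14	Simple mode	0.135	1.194	0.915	1.557	0.213
Family	Oxalobacteraceae	14	Weighted median	0.079	1.177	1.008	1.375	0.040
Family	Oxalobacteraceae	14	Weighted mode	0.137	1.202	0.919	1.571	0.202
Genus	Anaerostipes	11	Inverse variance weighted	0.129	0.768	0.596	0.990	0.041
Genus	Anaerostipes	11	MR Egger	0.411	0.568	0.254	1.270	0.201
Genus	Anaerostipes	11	Simple mode	0.291	0.976	0.552	1.726	0.935
Genus	Anaerostipes	11	Weighted median	0.169	0.792	0.569	1.103	0.168
Genus	Anaerostipes	11	Weighted mode	0.304	1.024	0.565	1.858	0.938
Genus	Clostridium sensustricto1	7	Inverse variance weighted	0.121	1.354	1.068	1.716	0.012
Genus	Clostridium sensustricto1	7	MR Egger	0.275	1.728	1.009	2.959	0.103
Genus	Clostridium sensustricto1	7	Simple mode	0.220	1.404	0.912	2.161	0.174
Genus	Clostridium sensustricto1	7	Weighted median	0.160	1.413	1.034	1.933	0.030
Genus	Clostridium sensustricto1	7	Weighted mode	0.195	1.416	0.966	2.075	0.125
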