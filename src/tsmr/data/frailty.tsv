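group	taxon	nsnp	method	se	or	ci_low	ci_high	pvalue
Class	Bacteroidia	13	Inverse variance weighted	0.018	0.958	0.924	0.993	0.020
Class	Bacteroidia	13	MR Egger	0.042	0.944	0.870	1.026	0.202
Class	Bacteroidia	13	Simple mode	0.039	0.954	0.885	1.030	0.257
Class	Bacteroidia	13	Weighted median	0.026	0.960	0.913	1.009	0.107
Class	Bacteroidia	13	Weighted mode	0.031	0.957	0.901	1.016	0.174
Class	Betaproteobacteria	11	Inverse variance weighted	0.024	1.050	1.002	1.101	0.042
Class	Betaproteobacteria	11	MR Egger	0.087	1.021	0.861	1.210	0.820
Class	Betaproteobacteria	11	Simple mode	0.048	1.092	0.993	1.200	0.100
Class	Betaproteobacteria	11	Weighted median	0.028	1.079	1.022	1.139	0.006
Class	Betaproteobacteria	11	Weighted mode	0.048	1.087	0.990	1.194	0.112
Genus	Clostridiuminnocuum group	9	Inverse variance weighted	0.011	1.023	1.001	1.045	0.036
Genus	Clostridiuminnocuum group	9	MR Egger	0.055	1.133	1.017	1.263	0.059
Genus	Clostridiuminnocuum group	9	Simple mode	0.023	1.017	0.972	1.065	0.490
Genus	Clostridiuminnocuum group	9	Weighted median	0.015	1.022	0.993	1.052	0.137
Genus	Clostridiuminnocuum group	9	Weighted mode	0.022	1.017	0.974	1.062	0.465
Genus	Eubacterium coprostanoligenes	13	Inverse variance weighted	0.018	1.056	1.019	1.094	0.003
Genus	Eubacterium coprostanoligenes	13	MR Egger	0.073	1.072	0.929	1.237	0.363
Genus	Eubacterium coprostanoligenes	13	Simple mode	0.037	1.084	1.008	1.166	0.051
Genus	Eubacterium coprostanoligenes	13	Weighted median	0.024	1.070	1.021	1.122	0.005
Genus	Eubacterium coprostanoligenes	13	Weighted mode	0.037	1.085	1.008	1.168	0.050
Genus	Eubacteriumruminantiumgroup	18	Inverse variance weighted	0.012	0.973	0.950	0.997	0.028
Genus	Eubacteriumruminantiumgroup	18	MR Egger	0.043	1.042	0.958	1.133	0.350
Genus	Eubacteriumruminantiumgroup	18	Simple mode	0.025	1.003	0.954	1.054	0.921
Genus	Eubacteriumruminantiumgroup	18	Weighted median	0.015	0.997	0.969	1.027	0.860
Genus	Eubacteriumruminantiumgroup	18	Weighted mode	0.023	1.003	0.959	1.050	0.891
Genus	Allisonella	8	Inverse variance weighted	0.013	1.033	1.007	1.059	0.012
Genus	Allisonella	8	MR Egger	0.072	0.898	0.779	1.034	0.186
Genus	Allisonella	8	Simple mode	0.029	1.061	1.003	1.122	0.078
Genus	Allisonella	8	Weighted median	0.015	1.017	0.988	1.047	0.255
Genus	Allisonella	8	Weighted mode	0.022	1.003	0.961	1.046	0.904
Genus	Bifidobacterium	12	Inverse variance weighted	0.017	1.041	1.007	1.076	0.016
Genus	Bifidobacterium	12	MR Egger	0.045	1.089	0.997	1.189	0.089
Genus	Bifidobacterium	12	Simple mode	0.041	1.015	0.935	1.101	0.732
Genus	Bifidobacterium	12	Weighted median	0.023	1.032	0.987	1.079	0.166
Genus	Bifidobacterium	12	Weighted mode	0.042	1.014	0.933	1.101	0.757
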