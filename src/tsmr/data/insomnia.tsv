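group	taxon	nsnp	method	se	or	ci_low	ci_high	pvalue
Phylum	Verrucomicrobia	12	Inverse variance weighted	0.007	0.985	0.972	0.998	0.022
Phylum	Verrucomicrobia	12	MR Egger	0.019	0.983	0.947	1.020	0.377
Phylum	Verrucomicrobia	12	Simple mode	0.015	0.990	0.961	1.019	0.515
Phylum	Verrucomicrobia	12	Weighted median	0.009	0.986	0.969	1.003	0.107
Phylum	Verrucomicrobia	12	Weighted mode	0.014	0.989	0.962	1.017	0.450
Class	Negativicutes	12	Inverse variance weighted	0.008	1.033	1.016	1.050	0.000
Class	Negativicutes	12	MR Egger	0.026	1.042	0.990	1.098	0.147
Class	Negativicutes	12	Simple mode	0.019	1.047	1.008	1.087	0.035
Class	Negativicutes	12	Weighted median	0.011	1.046	1.023	1.069	0.000
Class	Negativicutes	12	Weighted mode	0.020	1.047	1.008	1.088	0.038
Order	Selenomonadales	12	Inverse variance weighted	0.008	1.033	1.016	1.050	0.000
Order	Selenomonadales	12	MR Egger	0.026	1.042	0.990	1.098	0.147
Order	Selenomonadales	12	Simple mode	0.019	1.047	1.008	1.088	0.038
Order	Selenomonadales	12	Weighted median	0.011	1.046	1.023	1.069	0.000
Order	Selenomonadales	12	Weighted mode	0.020	1.047	1.008	1.088	0.039
Genus	Clostridium innocuum group	9	Inverse variance weighted	0.007	1.019	1.004	1.034	0.012
Genus	Clostridium innocuum group	9	MR Egger	0.040	0.998	0.924	1.079	0.968
Genus	Clostridium innocuum group	9	Simple mode	0.009	1.008	0.990	1.027	0.403
Genus	Clostridium innocuum group	9	Weighted median	0.007	1.012	0.997	1.026	0.111
Genus	Clostridium innocuum group	9	Weighted mode	0.009	1.007	0.989	1.026	0.448
Genus	Lachnoclostridium	13	Inverse variance weighted	0.012	1.029	1.006	1.053	0.015
Genus	Lachnoclostridium	13	MR Egger	0.043	1.009	0.926	1.098	0.844
Genus	Lachnoclostridium	13	Simple mode	0.022	1.027	0.983	1.072	0.254
Genus	Lachnoclostridium	13	Weighted median	0.013	1.028	1.002	1.056	0.038
Genus	Lachnoclostridium	13	Weighted mode	0.022	1.024	0.980	1.070	0.305
Genus	Marvinbryantia	10	Inverse variance weighted	0.008	1.016	1.001	1.032	0.043
Genus	Marvinbryantia	10	MR Egger	0.030	0.982	0.926	1.043	0.576
Genus	Marvinbryantia	10	Simple mode	0.020	1.028	0.988	1.069	0.207
Genus	Marvinbryantia	10	Weighted median	0.010	1.0182	0.998	1.039	0.078
Genus	Marvinbryantia	10	Weighted mode	0.020	1.026	0.986	1.067	0.233
Genus	Oscillibacter	14	Inverse variance weighted	0.006	0.987	0.974	0.999	0.031
Genus	Oscillibacter	14	MR Egger	0.023	1.007	0.962	1.053	0.779
Genus	Oscillibacter	14	Simple mode	0.014	0.983	0.957	1.011	0.250
Genus	Oscillibacter	14	Weighted median	0.008	0.987	0.972	1.003	0.109
Genus	Oscillibacter	14	Weighted mode	0.015	0.983	0.955	1.012	0.277
Genus	Oxalobacter	11	Inverse variance weighted	0.005	1.011	1.001	1.021	0.036
Genus	Oxalobacter	11	MR Egger	0.024	1.019	0.971	1.069	0.461
Genus	Oxalobacter	11	Simple mode	0.009	1.011	0.994	1.029	0.242
Genus	Oxalobacter	11	Weighted median	0.006	1.012	1.000	1.024	0.058
Genus	Oxalobacter	11	Weighted mode	0.008	1.010	0.994	1.027	0.250
Genus	Paraprevotella	13	Inverse variance weighted	0.005	1.011	1.001	1.021	0.031
Genus	Paraprevotella	13	MR Egger	0.016	0.980	0.949	1.012	0.237
Genus	Paraprevotella	13	Simple mode	0.011	1.014	0.992	1.037	0.228
Genus	Paraprevotella	13	Weighted median	0.007	1.009	0.996	1.022	0.185
Genus	Paraprevotella	13	Weighted mode	0.011	1.010	0.989	1.031	0.368
Genus	Prevotella7	11	Inverse variance weighted	0.004	1.009	1.001	1.017	0.022
Genus	Prevotella7	11	MR Egger	0.024	0.989	0.943	1.037	0.665
Genus	Prevotella7	11	Simple mode	0.009	1.006	0.989	1.024	0.505
Genus	Prevotella7	11	Weighted median	0.006	1.009	0.998	1.020	0.129
Genus	Prevotella7	11	Weighted mode	0.009	1.007	0.989	1.024	0.470
Genus	Rikenellaceae RC9 gut group	11	Inverse variance weighted	0.004	1.010	1.002	1.018	0.015
Genus	Rikenellaceae RC9 gut group	11	MR Egger	0.025	0.997	0.949	1.046	0.898
Genus	Rikenellaceae RC9 gut group	11	Simple mode	0.008	1.011	0.996	1.027	0.186
Genus	Rikenellaceae RC9 gut group	11	Weighted median	0.005	1.010	1.000	1.020	0.040
Genus	Rikenellaceae RC9 gut group	11	Weighted mode	0.008	1.011	0.995	1.027	0.217
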