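group	taxon	nsnp	method	se	or	ci_low	ci_high	pvalue
Phylum	Verrucomicrobia	12	Inverse variance weighted	0.183	1.444	1.009	2.065	0.044
Phylum	Verrucomicrobia	12	MR Egger	0.478	1.740	0.682	4.438	0.273
Phylum	Verrucomicrobia	12	Simple mode	0.411	2.053	0.917	4.596	0.108
Phylum	Verrucomicrobia	12	Weighted median	0.259	1.505	0.906	2.500	0.114
Phylum	Verrucomicrobia	12	Weighted mode	0.347	1.473	0.746	2.906	0.288
Family	Desulfovibrionaceae	10	Inverse variance weighted	0.217	1.926	1.259	2.946	0.003
Family	Desulfovibrionaceae	10	MR Egger	0.507	0.975	0.361	2.631	0.961
Family	Desulfovibrionaceae	10	Simple mode	0.536	1.540	0.538	4.404	0.441
Family	Desulfovibrionaceae	10	Weighted median	0.311	1.492	0.811	2.745	0.198
Family	Desulfovibrionaceae	10	Weighted mode	0.351	1.252	0.630	2.490	0.537
Genus	Ruminococcus gnavus group	12	Inverse variance weighted	0.139	0.731	0.557	0.960	0.024
Genus	Ruminococcus gnavus group	12	MR Egger	0.656	0.538	0.149	1.943	0.366
Genus	Ruminococcus gnavus group	12	Simple mode	0.269	0.608	0.359	1.030	0.091
Genus	Ruminococcus gnavus group	12	Weighted median	0.187	0.648	0.449	0.933	0.020
Genus	Ruminococcus gnavus group	12	Weighted mode	0.268	0.616	0.365	1.043	0.099
Class	Candidatus Soleaferrea	10	Inverse variance weighted	0.151	1.381	1.027	1.857	0.033
Class	Candidatus Soleaferrea	10	MR Egger	1.621	1.344	0.056	32.211	0.860
Class	Candidatus Soleaferrea	10	Simple mode	0.343	1.132	0.577	2.219	0.726
Class	Candidatus Soleaferrea	10	Weighted median	0.201	1.240	0.835	1.840	0.286
Class	Candidatus Soleaferrea	10	Weighted mode	0.323	1.114	0.592	2.096	0.747
Class	Holdemania	14	Inverse variance weighted	0.154	0.737	0.545	0.997	0.048
Class	Holdemania	14	MR Egger	0.453	0.401	0.165	0.973	0.066
Class	Holdemania	14	Simple mode	0.315	0.764	0.412	1.415	0.407
Class	Holdemania	14	Weighted median	0.202	0.749	0.504	1.113	0.153
Class	Holdemania	14	Weighted mode	0.319	0.738	0.394	1.380	0.358
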