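VASCULAR_SMOOTH_MUSCLE_CONTRACTION	toy pathway	g0077	g0202	g0333	g0024	g0037	g0274	g0048	g0187	g0298	g0029	g0259	g0109	g0019	g0044	g0222	g0214	g0035	g0123	g0046	g0282
FOCAL_ADHESION	toy pathway	g0030	g0289	g0063	g0114	g0322	g0321	g0298	g0031	g0295	g0299	g0203	g0025	g0113	g0023	g0285	g0068	g0148	g0214	g0073	g0276	g0060	g0292	g0157
DILATED_CARDIOMYOPATHY	toy pathway	g0052	g0297	g0292	g0327	g0096	g0190	g0049	g0280	g0364	g0032	g0288	g0030	g0316	g0105	g0254
CARDIAC_MUSCLE_CONTRACTION	toy pathway	g0397	g0160	g0238	g0299	g0232	g0185	g0153	g0127	g0092	g0357	g0399	g0124	g0041	g0294	g0268	g0253	g0175	g0373	g0229	g0147	g0311	g0037	g0060
OXIDATIVE_PHOSPHORYLATION	toy pathway	g0084	g0387	g0175	g0077	g0250	g0215	g0020	g0342	g0039	g0391	g0285	g0293	g0160	g0174	g0355	g0179	g0304	g0254	g0296	g0233	g0035	g0047	g0138
NOTCH_SIGNALING	toy pathway	g0356	g0340	g0033	g0031	g0374	g0359	g0158	g0331	g0295	g0348	g0228	g0145	g0366	g0197	g0342	g0177	g0011	g0236	g0181	g0086	g0312	g0059	g0252	g0030	g0111
TGF_BETA_SIGNALING	toy pathway	g0066	g0378	g0126	g0203	g0200	g0254	g0041	g0085	g0229	g0205	g0281	g0142	g0070	g0220	g0361	g0212	g0183	g0349	g0194
WNT_SIGNALING	toy pathway	g0077	g0042	g0090	g0118	g0337	g0119	g0006	g0248	g0301	g0093	g0134	g0144	g0002	g0074	g0214	g0273	g0189
MAPK_SIGNALING	toy pathway	g0064	g0353	g0263	g0316	g0335	g0346	g0378	g0027	g0233	g0399	g0348	g0286	g0200	g0203	g0204	g0201	g0053	g0246	g0324	g0205
CELL_CYCLE	toy pathway	g0097	g0034	g0106	g0225	g0083	g0056	g0174	g0307	g0026	g0052	g0000
ECM_RECEPTOR_INTERACTION	toy pathway	g0274	g0051	g0186	g0314	g0013	g0036	g0106	g0192	g0076	g0324	g0129	g0177	g0308	g0242
REGULATION_OF_ACTIN_CYTOSKELETON	toy pathway	g0059	g0249	g0238	g0245	g0247	g0159	g0043	g0073	g0052	g0383	g0175	g0379	g0135
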