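mirna	cell_line	fold_change	regulation
hsa-miR-125a-3p	H929	35.19	up
hsa-miR-125a-3p	MM1S	126.42	up
hsa-miR-125a-3p	OPM2	54.71	up
hsa-miR-125a-3p	8226	102.25	up
hsa-miR-135a*	H929	55.11	up
hsa-miR-135a*	MM1S	5.36	up
hsa-miR-135a*	OPM2	10.97	up
hsa-miR-135a*	8226	37.37	up
hsa-miR-188-5p	H929	2.67	up
hsa-miR-188-5p	MM1S	618.7	up
hsa-miR-188-5p	OPM2	2.84	up
hsa-miR-188-5p	8226	6.17	up
hsa-miR-155	H929	8.52	up
hsa-miR-155	MM1S	2.6	up
hsa-miR-155	OPM2		n.d.
hsa-miR-155	8226		n.d.
hsa-miR-198	H929		n.d.
hsa-miR-198	MM1S	13.22	up
hsa-miR-198	OPM2		n.d.
hsa-miR-198	8226	14.41	up
hsa-miR-200c	H929		n.d.
hsa-miR-200c	MM1S	36.26	up
hsa-miR-200c	OPM2		n.d.
hsa-miR-200c	8226	55.71	up
hsa-miR-483-5p	H929	2.6	up
hsa-miR-483-5p	MM1S	297.01	up
hsa-miR-483-5p	OPM2	131.91	up
hsa-miR-483-5p	8226	343.55	up
hsa-miR-663	H929	107.25	up
hsa-miR-663	MM1S	445.96	up
hsa-miR-663	OPM2	2.01	up
hsa-miR-663	8226	2.9	up
hsa-miR-630	H929	2.63	up
hsa-miR-630	MM1S	50.31	up
hsa-miR-630	OPM2	2.72	up
hsa-miR-630	8226	7.14	up
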