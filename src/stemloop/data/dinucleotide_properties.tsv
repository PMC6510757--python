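# RNA dinucleotide step properties used by the structure-based encoder.
# One row per 5'->3' dinucleotide (RNA spelling); 10 properties per row.
# Transcription of published experimental compilations (DiProDB-style):
#! shift	helical step translation along the x-axis, Angstrom; crystallographic analyses of RNA duplexes (Perez et al. 2004 compilation)
#! slide	helical step translation along the y-axis, Angstrom; same source as shift
#! rise	helical step translation along the z-axis, Angstrom; same source as shift
#! tilt	helical step rotation about the x-axis, degrees; same source as shift
#! roll	helical step rotation about the y-axis, degrees; same source as shift
#! twist	helical step rotation about the z-axis, degrees; same source as shift
#! enthalpy	nearest-neighbor duplex formation dH, kcal/mol; optical melting of RNA duplexes (Xia et al. 1998)
#! entropy	nearest-neighbor duplex formation dS, cal/(mol K); Xia et al. 1998
#! free_energy	nearest-neighbor dG at 37 C, kcal/mol; Xia et al. 1998
#! hydrophilicity	relative retention-derived hydrophilicity of dinucleoside phosphates; after Weber & Lacey 1978
dinucleotide	shift	slide	rise	tilt	roll	twist	enthalpy	entropy	free_energy	hydrophilicity
AA	-0.08	-1.27	3.18	-0.8	7.0	31	-6.82	-19.0	-0.93	0.04
AC	0.23	-1.43	3.24	0.8	4.8	32	-11.40	-29.5	-2.24	0.14
AG	-0.04	-1.50	3.30	0.5	8.5	30	-10.48	-27.1	-2.08	0.08
AU	-0.06	-1.36	3.24	1.1	7.1	33	-9.38	-26.7	-1.10	0.14
CA	0.11	-1.46	3.09	1.0	9.9	31	-10.44	-26.9	-2.11	0.21
CC	-0.01	-1.78	3.32	0.3	8.7	32	-13.39	-32.7	-3.26	0.49
CG	0.30	-1.89	3.30	-0.1	12.1	27	-10.64	-26.7	-2.36	0.35
CU	0.23	-1.43	3.24	0.8	4.8	32	-10.48	-27.1	-2.08	0.52
GA	0.07	-1.70	3.38	1.3	9.4	32	-12.44	-32.5	-2.35	0.10
GC	0.07	-1.39	3.22	0.0	6.1	35	-14.88	-36.9	-3.42	0.26
GG	-0.01	-1.78	3.32	0.3	8.7	32	-13.39	-32.7	-3.26	0.17
GU	0.23	-1.43	3.24	0.8	4.8	32	-11.40	-29.5	-2.24	0.27
UA	-0.02	-1.45	3.26	-0.2	10.7	32	-7.69	-20.5	-1.33	0.21
UC	0.07	-1.70	3.38	1.3	9.4	32	-12.44	-32.5	-2.35	0.48
UG	0.11	-1.46	3.09	1.0	9.9	31	-10.44	-26.9	-2.11	0.34
UU	-0.08	-1.27	3.18	-0.8	7.0	31	-6.82	-19.0	-0.93	0.44
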