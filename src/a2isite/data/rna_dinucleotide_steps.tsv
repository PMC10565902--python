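# RNA dinucleotide base-step parameters for A-form duplex RNA, as used by
# pseudo-dinucleotide-composition descriptors (PseDNC/DPCP lineage).
# Translational parameters (shift, slide, rise) in angstrom; rotational
# (tilt, roll, twist) in degrees.  Table version 1.
dinucleotide	rise	roll	shift	slide	tilt	twist
AA	3.18	7.0	-0.08	-1.27	-0.8	31.0
AC	3.24	4.8	0.23	-1.43	0.8	32.0
AG	3.30	8.5	-0.04	-1.50	0.5	30.0
AU	3.24	7.1	-0.06	-1.36	1.1	33.0
CA	3.09	9.9	0.11	-1.46	1.0	31.0
CC	3.32	8.7	-0.01	-1.78	0.3	32.0
CG	3.30	12.1	0.30	-1.89	-0.1	27.0
CU	3.30	8.5	-0.04	-1.50	0.5	30.0
GA	3.38	9.4	0.07	-1.70	1.3	32.0
GC	3.22	6.1	0.07	-1.39	0.0	35.0
GG	3.32	8.7	-0.01	-1.78	0.3	32.0
GU	3.24	4.8	0.23	-1.43	0.8	32.0
UA	3.26	10.7	-0.02	-1.45	-0.2	32.0
UC	3.38	9.4	0.07	-1.70	1.3	32.0
UG	3.09	9.9	0.11	-1.46	1.0	31.0
UU	3.18	7.0	-0.08	-1.27	-0.8	31.0
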