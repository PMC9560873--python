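lineage	omega0	omega1	p_value	significance	selection	change
Arecaceae	0.4106	0.3777	0.6097	not significant	Negative	intensification
Cactaceae	0.1520	0.7628	0.0000	significant	Negative	relaxation
Geraniaceae	0.1799	0.2870	0.0000	significant	Negative	relaxation
Leguminosae	0.1612	0.2858	0.0000	significant	Negative	relaxation
Camoensia	0.2028	0.3950	0.0000	significant	Negative	relaxation
the putranjivoid clade	0.2042	0.4302	0.0000	significant	Negative	relaxation
Passiflora	0.1998	0.3226	0.0000	significant	Negative	relaxation
Cupressophyta	0.1905	0.3499	0.0000	significant	Negative	relaxation
Pinaceae	0.2157	0.4162	0.0000	significant	Negative	relaxation
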