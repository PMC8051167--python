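# Synthetic default donor (5') splice-site frequency matrix.
# Built from the classical mammalian splice-consensus base frequencies
# (3 exonic + 6 intronic positions, consensus MAG|GTRAGT); replace via
# config with site-specific matrices if you have them.
pos	A	C	G	T
-3	0.33	0.37	0.18	0.12
-2	0.61	0.13	0.12	0.14
-1	0.10	0.03	0.79	0.08
1	0.00	0.00	1.00	0.00
2	0.00	0.00	0.00	1.00
3	0.60	0.03	0.34	0.03
4	0.71	0.08	0.12	0.09
5	0.08	0.06	0.82	0.04
6	0.16	0.15	0.21	0.48
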