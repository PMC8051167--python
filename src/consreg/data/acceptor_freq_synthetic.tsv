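# Synthetic default acceptor (3') splice-site frequency matrix.
# Built from the classical mammalian splice-consensus base frequencies:
# a 10-position pyrimidine tract, one weakly constrained position, then
# the C A G acceptor core. Replace via config if you have site-specific
# matrices.
pos	A	C	G	T
-13	0.10	0.31	0.10	0.49
-12	0.10	0.31	0.10	0.49
-11	0.10	0.31	0.10	0.49
-10	0.10	0.31	0.10	0.49
-9	0.10	0.31	0.10	0.49
-8	0.10	0.31	0.10	0.49
-7	0.10	0.31	0.10	0.49
-6	0.10	0.31	0.10	0.49
-5	0.10	0.31	0.10	0.49
-4	0.10	0.31	0.10	0.49
-3	0.24	0.28	0.22	0.26
-2	0.05	0.75	0.05	0.15
-1	1.00	0.00	0.00	0.00
1	0.00	0.00	1.00	0.00
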