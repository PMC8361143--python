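# Monoisotopic masses and natural isotope abundances, CIAAW/NIST 2021 values.
# columns: element	nominal	mass_da	abundance
H	1	1.00782503207	0.999885
H	2	2.01410177785	0.000115
C	12	12.0000000000	0.9893
C	13	13.00335483507	0.0107
N	14	14.00307400443	0.99636
N	15	15.00010889888	0.00364
O	16	15.99491461957	0.99757
O	17	16.99913175650	0.00038
O	18	17.99915961286	0.00205
P	31	30.97376199842	1.0
S	32	31.97207117441	0.9499
S	33	32.97145890982	0.0075
S	34	33.96786700425	0.0425
S	36	35.96708071000	0.0001
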