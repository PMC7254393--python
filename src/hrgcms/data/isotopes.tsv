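# Isotope masses (Da) and natural abundances, IUPAC/CODATA 2013-2017 values.
# Columns: element, mass_number, mass, abundance. The most abundant isotope of
# each element is its monoisotopic mass. Version 1.
element	mass_number	mass	abundance
H	1	1.00782503207	0.999885
H	2	2.01410177785	0.000115
C	12	12.0	0.9893
C	13	13.00335483780	0.0107
N	14	14.00307400520	0.99636
N	15	15.00010889840	0.00364
O	16	15.99491461956	0.99757
O	17	16.99913170	0.00038
O	18	17.99916040	0.00205
P	31	30.97376163	1.0
S	32	31.97207100	0.9499
S	33	32.97145876	0.0075
S	34	33.96786690	0.0425
S	36	35.96708076	0.0001
Si	28	27.97692653250	0.92223
Si	29	28.97649470	0.04685
Si	30	29.97377017	0.03092
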