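# DNA hairpin loop initiation free energies at 37 C, kcal/mol
# (SantaLucia & Hicks 2004, Table 4). Loop sizes not listed are interpolated;
# sizes > 30 are extrapolated with the Jacobson-Stockmayer term
# dG(n) = dG(30) + 1.75 * R * T * ln(n/30).
loop_size	dG37
3	3.5
4	3.5
5	3.3
6	4.0
7	4.1
8	4.1
9	4.2
10	4.3
12	4.5
14	4.6
16	4.7
18	4.8
20	4.9
25	5.2
30	5.4
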