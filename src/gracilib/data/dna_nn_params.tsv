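# Unified DNA nearest-neighbor thermodynamic parameters
# (SantaLucia 1998, PNAS 95:1460; SantaLucia & Hicks 2004, Annu Rev Biophys 33:415).
# Stack written 5'->3' on the top strand; dH kcal/mol, dS cal/(mol K).
# dG at 37 C = dH - 310.15*dS/1000.
stack	dH	dS
AA	-7.9	-22.2
AT	-7.2	-20.4
TA	-7.2	-21.3
CA	-8.5	-22.7
GT	-8.4	-22.4
CT	-7.8	-21.0
GA	-8.2	-22.2
CG	-10.6	-27.2
GC	-9.8	-24.4
GG	-8.0	-19.9
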