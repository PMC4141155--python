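# Atomic mass table used for all mass arithmetic in gqbind.
# average: IUPAC standard atomic weights (conventional values).
# monoisotopic: mass of the principal (most abundant) isotope.
# Values are frozen here so that computed masses are bit-stable.
# columns: element	average_Da	monoisotopic_Da
element	average	monoisotopic
H	1.008	1.0078250319
C	12.011	12.0
N	14.007	14.0030740052
O	15.999	15.9949146221
P	30.974	30.97376151
S	32.06	31.97207069
Na	22.990	22.98976928
K	39.098	38.96370649
Cl	35.45	34.96885268
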