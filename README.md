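# gqbind

Native electrospray mass spectrometry (ESI-MS) lets you read the binding
stoichiometry of a small molecule with a nucleic-acid structure directly
off the spectrum: under gentle ionization, noncovalent complexes survive
into the gas phase, and free target, 1:1 complex, and 1:2 complex appear
as separate charge-state ladders.  `gqbind` implements the quantitative
workflow for such experiments on G-quadruplex-forming oligonucleotides
(here the human telomeric DNA 27-mer d[(TTAGGG)₄TTA] and its RNA
analogue r[(UUAGGG)₄UUA]) titrated with the tetracationic porphyrin
ligand TMPyP4:

- **oligonucleotide mass arithmetic** — parse sequence notation, build
  elemental compositions (free-acid, 5′-OH/3′-OH desalted-oligo
  convention), and compute average/monoisotopic masses;
- **complex-ion m/z** — enumerate species (quadruplex : ligand :
  counter-ion : ammonium, charge −4…−6) with explicit charge
  bookkeeping: the ligand is an intrinsic 4+ cation, charged adducts are
  compensated by backbone deprotonation;
- **peak assignment** — greedy nearest-m/z matching of observed peaks to
  theoretical ions, pooling areas per stoichiometry class;
- **binding inference** — the fraction of bound quadruplex and the
  sequential association constants

  K₁ = [QL] / ([Q][L]),  K₂ = [QL₂] / ([QL][L]),

  computed from relative peak areas with the free ligand closed by mass
  balance, plus the forward solver (concentrations from constants) as a
  single bracketed root-find;
- **UV melting** — Tm from absorbance-vs-temperature curves (baseline
  midpoint with two-state refinement, or 1/T-derivative) and
  ligand-induced ΔTm with replicate statistics;
- **synthetic data** — a seeded generator for spectra and melting curves
  with the exact statistical structure the analysis assumes, used for
  end-to-end validation and parameter-recovery tests.

## Worked example

Mass report for the telomeric 27-mer:

```
$ gqbind --log-level WARNING mass "d[(TTAGGG)4TTA]"
sequence      d[TTAGGGTTAGGGTTAGGGTTAGGGTTA] (27 nt, DNA)
composition   C270H335N105O165P26
average       8496.5 Da
monoisotopic  8492.4229 Da
```

Simulate an equimolar 10 µM DNA/TMPyP4-tetrachloride infusion with 5 %
area noise and run the full inference:

```python
from gqbind import (SpectrumSimConfig, TELOMERIC_DNA_CONSTANTS, format_constant,
                    infer_binding, parse_oligo_notation, simulate_binding_spectrum)

seq = parse_oligo_notation("d[(TTAGGG)4TTA]")
cfg = SpectrumSimConfig(truth=TELOMERIC_DNA_CONSTANTS, area_noise_sd=0.05, seed=7)
spectrum, truth = simulate_binding_spectrum(cfg, seq)
frac, state, k = infer_binding(spectrum, seq)
print(f"fraction bound : {100*frac:.2f} %  (truth {100*truth.state.fraction_bound:.2f} %)")
print(f"K1 = {format_constant(k.K1)}   K2 = {format_constant(k.K2)}")
```

prints

```
fraction bound : 71.83 %  (truth 72.38 %)
K1 = 1.73 × 10^6 M⁻¹   K2 = 2.73 × 10^5 M⁻¹
```

i.e. at this noise level a single replicate recovers K₁ = 1.87 × 10⁶ M⁻¹
within ~8 %; the `bind` subcommand pools replicates into mean ± SD.  The
same spectrum annotated (`gqbind annotate`) labels each peak with its
species, e.g. `[Q]^5- +2NH4` for the free quadruplex retaining the two
inter-tetrad ammonium ions, or `[1:1]^5- +1Ts` for the 1:1 complex with
one tosylate adduct.

The CLI offers `mass`, `simulate`, `annotate`, `bind` (replicate
manifest → pooled constants and RNA/DNA affinity ratios), and `melt`
(ΔTm between +ligand/−ligand melting-curve arms).

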