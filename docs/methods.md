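# Methods

## Scope and model

`gqbind` quantifies noncovalent binding of a small cationic ligand to a
G-quadruplex-forming oligonucleotide from native negative-mode ESI-MS
peak lists, and thermal stabilization from UV melting curves.  The
binding model is sequential two-site association,

    Q + L  <=> QL      K1 = [QL] / ([Q][L])
    QL + L <=> QL2     K2 = [QL2] / ([QL][L]),

with two assumptions inherited from the experimental method:

1. **Proportional response.** Peak areas of Q, QL, and QL2 ions are
   proportional to the solution concentrations of those species, with a
   common response factor.  No correction is applied; the synthetic
   generator exposes per-class response factors precisely to demonstrate
   the bias non-unit factors cause (a ~1.3× factor on complex classes
   inflates K1 roughly threefold at equimolar 10 µM).
2. **Known totals.** Total strand (C_Q) and ligand (C_L) concentrations
   are known, so relative areas fix absolute concentrations and the free
   ligand follows by difference: [L] = C_L − [QL] − 2[QL2].  If the
   implied [L] ≤ 0 the input is inconsistent with the totals and a
   saturation error names the violated balance rather than returning a
   negative concentration.

## Mass and m/z arithmetic

Strand compositions follow the free-acid, neutral, 5′-OH/3′-OH
convention of vendor desalted oligos: sum of
nucleoside-5′-monophosphate-minus-water residues, plus H2O, minus HPO3
(a 5′-phosphate flag restores it).  This reproduces the vendor-quoted
8496.6 Da for d[(TTAGGG)₄TTA] to 0.06 Da.  For r[(UUAGGG)₄UUA] the same
convention computes 8788.25 Da, ~1.0 Da below the vendor-quoted 8789.3
Da, whose mass convention is not stated; the computed value is used
throughout.  Atomic masses (average and principal-isotope) are frozen in
`src/gqbind/data/atomic_weights.tsv` so results are bit-stable.

Ion m/z uses explicit charge bookkeeping.  TMPyP4 attaches as an
intrinsic tetracation (C44H38N8, +4), ammonium (+1) and tosylate (−1) as
charged adducts, all compensated by deprotonation of the phosphate
backbone: with intrinsic charge i = 4·n_L + n_NH4 − n_Ts and target
charge z < 0, n_H = i − z protons are removed and

    m/z = (n_Q·M_Q + n_L·M_L + n_Ts·M_Ts + n_NH4·M_NH4 − n_H·1.007276) / |z|.

The proton mass is used even in average-mass mode (the distinction is
far below the assignment tolerance).  Consequences that double as
checks: one ammonium spaces peaks by (M_NH4 − m_p)/|z| ≈ 17.03/|z|, one
tosylate by (M_Ts + m_p)/|z| ≈ 34.44/|z|; both are property-tested.

## Assignment

Candidate species are enumerated over configurable ranges (defaults:
ligand 0–2, tosylate 0–3, ammonium 0–2, charge −4…−6, i.e. 108 species)
and matched greedily in increasing |observed − theoretical|, each peak
and each theoretical ion used at most once; |Δ| is quantized at 1e-6 Da
so coincident distances resolve by the parsimony rule (fewer total
adducts, then lexicographic species order) instead of floating-point
noise.  The default tolerance of 1.0 Da/charge is an absolute
(not ppm) window: adduct ladders are evenly spaced per charge state,
observed-vs-theoretical offsets behave like a per-spectrum calibration
constant (up to ~0.6 Da/charge in practice), and the smallest
inter-species spacing at z = −5 is ≈ 3.4 Da/charge, so the window
separates all species while absorbing calibration offset.

Areas pool per (n_ligand, n_counterion) class, collapsing charge states
and ammonium counts, which are gas-phase degrees of freedom of one
solution species.  Area is conserved exactly: class sums plus unassigned
area equal the input total.  For the equilibrium the counter-ion
dimension collapses too — tosylate adducts of a ligand-bound complex
count toward that complex.  Tosylate-only adducts of the free quadruplex
default to the free class (the two-site model has no tosylate species);
the `counterion_only_is_bound` policy flag moves them to the bound side
of the fraction-bound statistic only.

## Equilibrium solver and estimator

Forward problem: free ligand l is the root of

    g(l) = l + (K1·l + 2·K1·K2·l²)·C_Q / (1 + K1·l + K1·K2·l²) − C_L

on (0, C_L]; g is continuous, strictly increasing, g(0) = −C_L < 0,
g(C_L) ≥ 0, so Brent's method on [0, C_L] (rtol at machine precision)
finds the unique root; the remaining species follow in closed form and
both mass balances are verified to 1e-12 relative.  The estimator is the
exact inverse on noise-free proportional areas: round trips recover K1
and K2 to better than 1e-6 relative across K1 ∈ [1e4, 1e9], K2 ∈ [1e3,
1e8], C ∈ [1, 50] µM (excluding near-saturation, free L < 1e-12 M,
where the ratio of vanishing concentrations is numerically meaningless).

One property worth noting because intuition suggests otherwise: the
fraction of bound quadruplex is *not* monotone in K2 at ligand-limited
(equimolar) totals.  Each QL2 sequesters two ligands, so strengthening
the second binding step depletes free ligand and can lower the fraction
of strands that are bound at all (doubling K2 at the DNA defaults drops
it from 72.4 % to 69.5 %).  Monotonicity in K2 holds under ligand
excess and is tested there; the ligand-limited counterexample is tested
explicitly.

Replicate statistics use the arithmetic mean and sample SD (n−1
denominator), reported as "mean ± SD (n)"; SD is reported missing for
n = 1 rather than 0.  K2 = 0 (no observed 1:2 complex) is flagged "not
estimable" rather than raised.

## Melting analysis

Two-state van't Hoff folding with linear folded/unfolded baselines:

    θ(T) = 1 / (1 + exp[(ΔH/R)(1/Tm − 1/T)])   (temperatures in K),

so θ(Tm) = 1/2 exactly.  Both hypo- and hyperchromic transitions are
supported (sign comes from baseline ordering); quadruplex melting at
295 nm is hypochromic.

- **midpoint** (default): straight lines fitted to the first/last 10 %
  of points (or explicit windows) give θ; Tm interpolates the θ = 0.5
  crossing nearest the steepest part of the curve.  Because linear
  baselines extrapolated from end windows are contaminated by the
  transition tails (a ~0.25–0.35 °C bias at ΔH ≈ 50 kcal/mol), the
  construction seeds a 6-parameter two-state least-squares fit
  (2 baselines + Tm + ΔH) that removes the bias; if the fit fails to
  converge the construction's value is returned.  The construction also
  supplies the error cases: no crossing, degenerate baselines.
- **derivative**: Savitzky–Golay smoothing, then the extremum of
  |dA/d(1/T)|.  The 1/T abscissa matters: for a van't Hoff transition
  dA/d(1/T) peaks exactly at Tm, while dA/dT peaks ~0.7 °C below Tm at
  ΔH = 30 kcal/mol.  Kept as an independent cross-check of the midpoint
  method (agreement within 0.5 °C on clean curves is tested).

ΔTm is the difference of arm means with SDs combined as
√(sd₁²/n₁ + sd₂²/n₂).  Heating rate and buffer are metadata only; no
kinetic correction is attempted.

## Synthetic data

The spectrum generator forward-solves the equilibrium at the configured
true constants, assigns each solution species an area proportional to
its concentration (normalized by C_Q, times its response factor), and
splits it *deterministically* across counter-ion × ammonium × charge
states by the configured probability vectors — so a noise-free run is an
exact fixture and the zero-noise pipeline reproduces the forward solve
to machine precision.  Noise enters as (i) Gaussian m/z jitter
(default SD 0.02 Da/charge, well under the 1.0 tolerance), (ii)
log-normal multiplicative area noise (areas are positive and detector
variation is multiplicative; default SD 5 %, loosely calibrated to the
~10 % relative SDs of triplicate constants such experiments report),
and (iii) uniform decoy peaks over the spectrum window ± 50 Da at 1 % of
the maximum area.  All randomness flows from one `numpy` Generator
seeded by the mandatory config seed.

Default study conditions are the equimolar 10 µM strand:ligand mixture
with ammonium probabilities {0: 0.1, 1: 0.3, 2: 0.6} (the 2-ammonium
ion is the dominant form of the quadruplex), charge probabilities
{−4: 0.2, −5: 0.6, −6: 0.2} (−5 predominant), and no counter-ion
adducts (tetrachloride mode); a tosylate-weighted `counterion_probs`
vector switches to tetratosylate-like spectra.  The melting generator
defaults to the 20–95 °C range at 0.5 °C spacing with ΔH_vH = 50
kcal/mol, typical of intramolecular telomeric quadruplexes.

What the generator does **not** emulate — and hence what passing
recovery tests do not establish about real data: isotope envelopes and
peak shapes (peaks are points), species-dependent ionization response
(except as an explicit bias knob), in-source dissociation, overlapping
charge envelopes from higher-order aggregates, and drift within an
infusion.  Recovery results therefore validate the estimator and the
assignment logic under the method's stated assumptions, not the
assumptions themselves.

## Numerical choices

- Atomic weights frozen to ≥ 4 decimals in one table; proton mass
  1.007276 Da.
- Brent root-finding with xtol ~1e-300, rtol 8.9e-16 (machine limit),
  bracket [0, C_L]; mass-balance residuals checked at 1e-12 relative.
- Assignment distance quantized at 1e-6 Da/charge before tie-breaking.
- Savitzky–Golay window: ~1/10 of the curve, minimum 5 points, order 3;
  parabolic interpolation around the derivative extremum.
- Two-state refinement accepts the fit only if converged, Tm within the
  data range and within 5 °C of the construction, and RMS residual
  < 20 % of the absorbance scale; otherwise the construction's Tm
  stands.
- Problem sizes in the test suite and acceptance script (single
  spectra of ≤ 108 species, 20-seed recovery batches, 151-point melting
  curves) keep any single check under a few seconds while matching the
  study's replicate structure (n = 3).

## Known limitations

- The 1:2 model caps stoichiometry; higher-order complexes in the input
  are rejected, not fitted.
- No response-factor correction or titration-series global fitting;
  constants come from single equimolar points, as in the underlying
  method.
- mzML ingestion handles centroided scans only; profile data should go
  through `centroid_profile`.
- The melting module fits one transition; multiphasic melts are out of
  scope.
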