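# pyrodaem

Multi-distribution **D**istributed **A**ctivation **E**nergy **M**odel
analysis of slow biomass pyrolysis from TGA/DSC thermograms.

Thermogravimetric analysis (TGA) of a pyrolyzing sample records overlapping
decomposition stages — cellulose, lignin and char chemistry do not take
turns.  `pyrodaem` deconvolves a measured DTG curve (dx/dT, the temperature
derivative of conversion) into *pseudo-components*, each a continuum of
parallel irreversible first-order reactions whose activation energies follow
a probability density F(E):

    dx/dT = Σᵢ cᵢ ∫₀^∞ (k₀/β) exp[−(E/RT + (k₀/β)∫_{T₀}^{T} e^{−E/RT′} dT′)] Fᵢ(E) dE

with heating rate β, fixed frequency factor k₀ = 1.67 × 10¹³ s⁻¹ (fixing k₀
defeats the kinetic compensation effect), contribution fractions cᵢ on the
simplex, and F(E) drawn from four families — Gaussian, Logistic, Gumbel,
Cauchy — parameterized by mean activation energy Ēᵢ and scale σᵢ.
Parameters (cᵢ, Ēᵢ, σᵢ) are estimated by bounded nonlinear least squares on
the residual dx/dT|exp − dx/dT|sim, with goodness of fit reported as R².

The package is aimed at thermal-analysis practitioners who want a tested,
scriptable version of this workflow:

* forward simulation of TGA/DSC-like thermograms from pseudo-component
  models (including a synthetic-data generator with seeded instrument
  noise, built on published cellulose and lignin parameter sets);
* preprocessing of raw traces: Savitzky–Golay smoothing, conversion
  normalization, differentiation, window truncation, replicate averaging;
* multi-component DAEM fitting, component-count/family scans with a
  parsimony rule, and Kissinger-condition-based initialization;
* rationalization of the pseudo-component count by DTG/DSC peak
  concordance, and endothermic/exothermic classification of DSC windows.

## Worked example

Generate two-replicate synthetic thermograms from the built-in fixtures and
fit a one-component Gaussian DAEM to the cellulose DTG:

```
$ daemfit make-fixtures --outdir fixtures --seed 1
$ daemfit fit fixtures/cellulose_gaussian.csv --out params.csv --seed 1
  family  component  fraction  e_mean_kJ_per_mol  sigma_kJ_per_mol  r_squared
gaussian          1       1.0         178.649016          1.640534   0.999213
R² = 0.9992; wrote params.csv
```

The fixture was generated with Ē = 178.6488 kJ mol⁻¹ and
σ = 1.6320 kJ mol⁻¹ plus 0.1 % mass noise; the fit recovers
178.649 kJ mol⁻¹ and 1.64 kJ mol⁻¹ from the noisy trace — a narrow
single-energy decomposition, peaking near 330 °C, which is why one
pseudo-component suffices for cellulose.

How many pseudo-components does lignin need?  Ask the DTG/DSC concordance
heuristic, which counts mass-loss peaks plus heat-flow events that move
heat but too little mass to raise their own DTG peak:

```
$ daemfit suggest fixtures/lignin_gaussian.csv
channel  temperature_C  matched_partner_C
    dtg          308.5              313.5
    dsc          256.0                NaN
    dsc          369.5                NaN
    dsc          426.0                NaN
suggested pseudo-components: 4
```

One dominant DTG peak near 310 °C matches an endothermic DSC dip; three
further DSC events (exothermic rise ≈ 256 °C, endothermic dip ≈ 370 °C,
broad exothermic char hump ≈ 426 °C) have no DTG counterpart — four stages
in total.  A four-component Gaussian fit
(`daemfit fit fixtures/lignin_gaussian.csv -n 4 --out lignin.csv`)
then recovers the generating energies near 157, 175, 193 and 211 kJ mol⁻¹.

The same steps are available as a library (`pyrodaem.fit_daem`,
`pyrodaem.model_scan`, `pyrodaem.suggest_component_count`, …) and as a
one-shot pipeline (`daemfit run --config config.yaml`) that writes
parameter tables, per-component curve files and a deconvolution plot,
stamped with a configuration hash and seed for bit-level reproducibility.

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.

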