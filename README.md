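# allokin

Analysis pipelines for **multi-step allosteric autoactivation of protein
kinases**, built around the Aurora B/IN-box system: an obligate
kinase–cofactor complex that switches itself on by phosphorylating two
sites — a threonine in the kinase activation loop and a TSS motif in its
partner's IN-box. The package provides, as a tested library with seeded
synthetic-data generators for every stage:

- **Coupled-assay enzyme kinetics** (`allokin.kinetics`): NADH-coupled
  (pyruvate kinase / lactate dehydrogenase) absorbance traces →
  Beer–Lambert product curves → initial rates from the early linear window
  (< 10% substrate conversion) → nonlinear Michaelis–Menten fits
  `v = v_max·S/(K_M + S)`, with `k_cat = v_max/[E]`, catalytic efficiency
  `k_cat/K_M`, and fold-change comparisons between constructs.
- **Four-state autoactivation model** (`allokin.autoactivation`): each
  enzyme molecule is in one of four phospho-states with relative specific
  activities (no-P 1%, loop-P 10%, IN-P 5%, all-P 100%). Loop
  phosphorylation proceeds in *cis* (intramolecular, `k_cis`, s⁻¹); IN-box
  phosphorylation in *trans* (intermolecular, `k_trans`, M⁻¹s⁻¹) catalysed
  by the activity-weighted enzyme pool `C = E_tot·Σ aᵢⱼeᵢⱼ`. Includes the
  preincubation-assay emulation, the concentration-normalization (Dodson)
  cis/trans diagnostic, and rate-constant estimation from progress curves.
- **Differential HDX-MS** (`allokin.hdx`): per-peptide deuterium uptake
  normalization (`MaxUptake = N − P − 2` or a fully-deuterated control),
  significance filtering (|ΔD%| > 5% *and* a pooled-variance 95% CI
  excluding zero), cumulative butterfly differences, EX1/EX2 classification
  of isotope envelopes by BIC-selected Gaussian-mixture deconvolution, and
  EX1 unfolding-rate fits `f(t) = 1 − exp(−k_op·t)`.
- **Trajectory collective motions** (`allokin.trajectory`): rigid-body
  superposition, per-particle RMSF with block-resampled densities, atom-pair
  distances, Cartesian PCA, the cosine-content diagnostic of diffusive vs
  concerted motion, and open-close/twist collective coordinates between two
  kinase lobes with occupancy-basin counting.

The public face is the importable API plus `examples/` (one short narrative
script per capability). A thin `allokin` CLI covers the common
file-in/file-out runs.

## Worked example

`python examples/michaelis_menten_fit.py` simulates coupled-assay traces
for the fully phosphorylated complex (kcat 12 s⁻¹, K_M 179 µM, 100 nM
enzyme) at seven substrate concentrations and refits them:

```
[S] =     25 µM   initial rate = 0.1660 µM/s
...
[S] =   1600 µM   initial rate = 1.0631 µM/s

fit: kcat = 11.9 s⁻¹ (true 12.0), KM = 180 µM (true 179.0)
catalytic efficiency kcat/KM = 6.63e+04 M⁻¹s⁻¹ (table rounding 7e+04)
```

The recovered constants match the generating ones within the noise, and the
efficiency rounds to the 7×10⁴ M⁻¹s⁻¹ a summary table would print.

`python examples/autoactivation_cis_trans.py` integrates the four-state
model and runs the cis/trans diagnostic:

```
fully phosphorylated fraction at end: 1.0000
specific-activity gain: 100.0-fold
IN-P-like (cis step remains) : lag-phase spread = 0.020 -> cis
loop-P-like (trans step remains): lag-phase spread = 0.454 -> trans
```

A lag-phase spread below 5% across a fourfold enzyme-concentration range
marks the remaining activation step as concentration independent
(intramolecular); the spread-out, concentration-ordered curves mark the
IN-box step as intermolecular. The 100-fold specific-activity gain is the
ratio of the fully activated to the unphosphorylated activity-weighted
turnover rate.

The other examples (`hdx_differential.py`, `ex1_classification.py`,
`trajectory_modes.py`) demonstrate the significance filter finding a
protected helix, bimodal-envelope deconvolution recovering an unfolding
rate and a rate ratio between phosphorylation states, and the
cosine-content separation of concerted (0.001) versus diffusive (0.987)
trajectories.

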