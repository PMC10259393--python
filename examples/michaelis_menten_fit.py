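"""Coupled-assay kinetics: from absorbance traces to Michaelis-Menten constants.

Simulates NADH-coupled assay traces for the fully phosphorylated kinase
complex (kcat 12 s⁻¹, KM 179 µM at 100 nM enzyme) over a range of substrate
concentrations, converts each trace to a product time course, extracts the
initial rate from the early linear window, and fits v = vmax·S/(KM+S).
"""

import numpy as np

from allokin import kinetics as kin
from allokin.synthetic import SyntheticConfig, gen_assay_trace

KCAT, KM, E_NM = 12.0, 179.0, 100.0
substrates = np.array([25, 50, 100, 200, 400, 800, 1600], float)

rates = []
for s0 in substrates:
    true_rate = (KCAT * E_NM * 1e-3) * s0 / (KM + s0)   # µM/s
    cfg = SyntheticConfig(seed=int(s0), noise_sd=2e-4,
                          time_grid=tuple(np.arange(0.0, 60.0, 0.5)))
    trace = gen_assay_trace(true_rate, s0, cfg, enzyme_conc=E_NM)
    t, product = kin.trace_to_product(trace)
    rate, _ = kin.initial_rate(t, product, substrate_0=s0)
    rates.append(rate)
    print(f"[S] = {s0:6.0f} µM   initial rate = {rate:.4f} µM/s")

params = kin.fit_michaelis_menten(substrates, np.array(rates), enzyme_conc=E_NM)
eff, eff_rounded = kin.catalytic_efficiency(params.kcat, params.km)
print(f"\nfit: kcat = {params.kcat:.1f} s⁻¹ (true {KCAT}), "
      f"KM = {params.km:.0f} µM (true {KM})")
print(f"catalytic efficiency kcat/KM = {eff:.3g} M⁻¹s⁻¹ "
      f"(table rounding {eff_rounded:.2g})")
# The efficiency is the second-order rate constant for the enzyme-substrate
# encounter at sub-saturating substrate; the table rounding is how such
# constants are usually reported.
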