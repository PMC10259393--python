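"""Autoactivation kinetics and the concentration-normalization (Dodson) test.

Integrates the four-phospho-state model from a fully unphosphorylated pool
to show the overall activity gain, then runs the cis/trans diagnostic: when
only the intramolecular loop step remains (IN-box already phosphorylated)
the concentration-normalized progress curves overlap in the lag phase; when
only the intermolecular IN-box step remains (loop already phosphorylated)
they spread apart, ordered by enzyme concentration.
"""

import numpy as np

from allokin import autoactivation as aa
from allokin.synthetic import SyntheticConfig, gen_autoactivation_curves

HOUR = 3600.0

# full autoactivation from the unphosphorylated pool at 12 µM
params = aa.AutoactivationParams()
t = np.linspace(0, 12 * HOUR, 600)
traj = aa.simulate_autoactivation(params, 12e-6, 600.0, t)
print(f"fully phosphorylated fraction at end: {traj.fractions[-1, 3]:.4f}")
print(f"specific-activity gain: {traj.activity[-1] / traj.activity[0]:.1f}-fold")

# Dodson test at 25/50/100 nM, 450 min continuous monitoring
e_tots = [25e-9, 50e-9, 100e-9]
cfg = SyntheticConfig(seed=0, time_grid=tuple(np.linspace(0, 7.5 * HOUR, 600)))
for name, p, start in [
    ("IN-P-like (cis step remains) ", aa.AutoactivationParams(k_inbox_trans=0.0),
     (0, 0, 1, 0)),
    ("loop-P-like (trans step remains)", aa.AutoactivationParams(k_cis=0.0,
                                                                 k_inbox_trans=2e4),
     (0, 1, 0, 0)),
]:
    curves, _ = gen_autoactivation_curves(p, e_tots, cfg, initial_fractions=start)
    spread, sign, label = aa.cis_trans_statistic(
        aa.normalize_progress_curves(curves))
    print(f"{name}: lag-phase spread = {spread:.3f} -> {label}")
# A spread below 5% across a fourfold concentration range means the
# activation step is concentration independent, i.e. intramolecular.
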