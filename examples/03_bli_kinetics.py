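"""Simulate and refit a 1:1 Langmuir biolayer-interferometry titration.

Generates a noiseless threefold dilution series (200 nM top, 900 s
association, 1,200 s dissociation) from kon = 1e5 /M/s and Kd = 0.48 nM,
then recovers the kinetic constants by global fitting and the Kd again
from the equilibrium plateaus.
"""

import numpy as np

from il4model import (
    fit_equilibrium_titration,
    fit_langmuir_global,
    simulate_bli_experiment,
)

traces = simulate_bli_experiment(kd=0.48e-9, k_on=1e5)
fit = fit_langmuir_global(traces)
print(
    f"global kinetic fit: kon = {fit.k_on:.3e} /M/s, koff = {fit.k_off:.3e} /s,"
    f" Kd = {fit.kd * 1e9:.3f} nM"
)

# Equilibrium titrations need full equilibration: at sub-nM analyte the
# observed rate kon*C + koff is ~1e-4/s, so a 900 s step is nowhere near
# steady state. Simulate long association steps for the titration route.
eq_traces = simulate_bli_experiment(
    kd=0.48e-9, k_on=1e5, t_assoc=2e5, t_dissoc=100, dt=500.0
)
plateaus = [tr.signal[np.searchsorted(tr.time, tr.t_assoc_end)] for tr in eq_traces]
eq = fit_equilibrium_titration([tr.analyte_conc for tr in eq_traces], plateaus)
print(f"equilibrium titration: Kd = {eq.kd * 1e9:.3f} nM (extrapolated: {eq.extrapolated})")
print(
    "\nBoth routes recover the generating 0.48 nM dissociation constant;\n"
    "the kinetic route also separates it into on- and off-rates, and works\n"
    "on the standard 900 s association step where the slow-equilibrating\n"
    "low concentrations never reach their plateau."
)
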