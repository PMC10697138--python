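"""Solve receptor-dimerization equilibria and show the hook effect.

Builds a type I-biased cell (abundant gamma-c, no IL-13R-alpha-1), solves
both model variants over a wide dose range, and prints the ternary-complex
abundances. The multivalent model lets free ligand capture the co-receptor
from solution, so at very high dose the co-receptor is sequestered in
unproductive binary complexes and signaling declines (the hook); the
sequential model, which only reaches the co-receptor through the
private-chain intermediate, saturates monotonically.
"""

import numpy as np

from il4model import (
    AffinityTable,
    CrosslinkConstant,
    ReceptorPanel,
    solve_equilibrium_multivalent,
    solve_equilibrium_sequential,
)

panel = ReceptorPanel("B-cell-like", r_alpha_total=2000, r_gamma_total=3000, r_13_total=0)
affinity = AffinityTable("IL-4-like", ka_alpha=1 / 1e-9, ka_gamma=1 / 100e-9, ka_13=0.0)
kx = CrosslinkConstant(1e-8)

doses = np.logspace(-12, -4, 9)
print(f"{'dose (M)':>10s} {'type I (multivalent)':>22s} {'type I (sequential)':>21s}")
for dose in doses:
    multi = solve_equilibrium_multivalent(dose, panel, affinity, kx)
    seq = solve_equilibrium_sequential(dose, panel, affinity, kx)
    print(f"{dose:10.1e} {multi.type_i:22.1f} {seq.type_i:21.1f}")

print(
    "\nComplexes/cell at each dose. The multivalent column rises then falls\n"
    "(hook effect: free ligand saturates gamma-c as unproductive binary\n"
    "complexes); the sequential column saturates and stays there."
)
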