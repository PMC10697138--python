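"""Globally fit ligand-receptor affinities and the shared Kx* to a
simulated signaling panel.

Simulates noisy pSTAT6 dose-responses for three human cell types x three
ligands from the packaged constants, then refits every binding constant
and the single crosslinking constant jointly and reports per-cell-type
prediction accuracy (R^2).
"""

from il4model import FitConfig, build_human_panel, fit_global, simulate_signaling_dataset

cfg = build_human_panel()
ds = simulate_signaling_dataset(
    cfg, replicates=2, seed=3, noise_sd=0.05,
    cell_types=["Ramos", "monocytes", "A549"],
)

free_pairs = tuple(
    (ligand, receptor)
    for ligand, aff in cfg.affinities.items()
    for receptor, ka in (
        ("alpha", aff.ka_alpha), ("gamma", aff.ka_gamma), ("il13ra1", aff.ka_13)
    )
    if ka > 0  # "no binding" entries stay fixed at zero
)
# single start = local fit anchored at the seed (BLI-prior) affinities;
# extra Latin-hypercube multistarts can land on equally good compensation
# manifolds where individual constants trade off against Kx*
result = fit_global(
    ds.data, cfg.panels, cfg.affinities,
    FitConfig(free_pairs=free_pairs, multistart=1, seed=0),
)

print("fitted dissociation constants (nM):")
for (ligand, receptor), kd in sorted(result.kd_table.items()):
    print(f"  {ligand:7s} {receptor:8s} {kd * 1e9:10.2f}")
print(f"fitted Kx* = {result.kx_star:.3e} M*cell/receptor")
print("prediction accuracy (R^2) per cell type:")
for cell_type, acc in result.accuracy_by_cell.items():
    print(f"  {cell_type:10s} {acc:6.3f}")
print(
    "\nAccuracies near 1 mean the refit equilibrium model reproduces the\n"
    "observed normalized responses; individual constants on weakly\n"
    "identified combinations may drift while their products stay pinned."
)
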