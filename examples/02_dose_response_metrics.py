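"""Fit Hill curves to a synthetic pSTAT6 panel and derive potency metrics.

Simulates the packaged Ramos B-cell responses to the natural cytokine
(hIL-4) and the type I-exclusive mimetic (hNeo-4) with 5% multiplicative
noise, refits each with the variable-slope logistic, and prints EC50s,
their fold-potency ratio, and the area under each curve in log10-dose.
"""

from il4model import (
    auc_log_dose,
    build_human_panel,
    fit_hill,
    fold_potency,
    simulate_signaling_dataset,
)

cfg = build_human_panel()
ds = simulate_signaling_dataset(
    cfg, replicates=3, seed=7, noise_sd=0.05,
    cell_types=["Ramos"], ligands=["hIL-4", "hNeo-4"],
)

fits = {}
for ligand, sub in ds.data.groupby("ligand"):
    fit = fit_hill(sub["dose_molar"].to_numpy(), sub["response"].to_numpy())
    fits[ligand] = fit
    auc = auc_log_dose(fit, min(cfg.doses), max(cfg.doses))
    print(
        f"{ligand:7s} EC50 = {fit.ec50 * 1e12:7.1f} pM   slope = {fit.slope:4.2f}"
        f"   AUC(log10 dose) = {auc:5.2f}"
    )

ratio = fold_potency(fits["hIL-4"], fits["hNeo-4"])
print(
    f"\nfold potency (hNeo-4 vs hIL-4) = {ratio:.1f}\n"
    "EC50 is the half-maximal dose; the mimetic's weaker IL-4R-alpha\n"
    "affinity shows up as a roughly tenfold potency loss on this type\n"
    "I-biased cell, while both reach the same maximal signal."
)
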