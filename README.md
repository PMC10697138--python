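# il4model

Mechanistic analysis of type I vs type II IL-4 receptor signaling.

IL-4 signals through two heterodimeric receptor complexes that share the
IL-4Rα chain: the **type I** complex (IL-4Rα·γc, typical of hematopoietic
cells) and the **type II** complex (IL-4Rα·IL-13Rα1, shared with IL-13 and
typical of non-hematopoietic cells). Engineered type I-exclusive mimetics
(Neo-4-style ligands that bind IL-4Rα and γc but not IL-13Rα1) make it
possible to ask which complex drives which response — if one can model how
receptor abundances and per-chain affinities combine into a cell's
dose-response. This package is for modelers and quantitative biologists
doing exactly that: it fits equilibrium receptor-dimerization models to
pSTAT6 dose-response panels and provides the surrounding quantitation
toolkit.

## The model

At free ligand concentration L, free receptor abundances (r_a, r_g, r_13)
solve the mass-action conservation system

    Ra_T  = r_a  [1 + Ka_a L (1 + Kx*(Ka_g r_g + Ka_13 r_13))]
    Rg_T  = r_g  [1 + Ka_g L + Kx* Ka_a Ka_g L r_a]
    R13_T = r_13 [1 + Ka_13 L + Kx* Ka_a Ka_13 L r_a]

with ternary complexes typeI = Kx*·Ka_a·Ka_g·L·r_a·r_g and
typeII = Kx*·Ka_a·Ka_13·L·r_a·r_13; predicted signal is their sum,
max-normalized per cell type. Ka are solution association constants (1/Kd);
the single crosslinking constant **Kx*** (molar·cell/receptor) converts a
solution affinity into the surface second-step gain Kx*·Ka·r_free and is
shared across all ligands and cell types. A **multivalent** variant lets
either chain be captured from solution first (and shows a high-dose hook
effect); a **sequential** variant forces the private chain first (and is
monotone in dose). Global least-squares fitting estimates all log10 Ka plus
log10 Kx* jointly from normalized panels, scored by per-cell-type R²,
leave-one-curve-out cross-validation, and receptor-density sensitivity
scans.

Around the core model: variable-slope logistic (Hill) fitting with
EC50/AUC/[C]10%/activity-retention metrics, global 1:1 Langmuir BLI kinetic
and equilibrium-titration fitting, bead-calibrated receptor counting
(MFI → receptors/cell), Livak 2^−ΔΔCt fold changes, gene-set overlap
arithmetic, AUC-matrix PCA, and seeded synthetic-data generators for every
input format.

## Worked example

Fit a Hill curve to a simulated Ramos B-cell panel and compare the natural
cytokine with the type I-exclusive mimetic (`examples/02_dose_response_metrics.py`):

```sh
$ python examples/02_dose_response_metrics.py
hIL-4   EC50 =    12.1 pM   slope = 0.83   AUC(log10 dose) =  3.78
hNeo-4  EC50 =   137.6 pM   slope = 0.90   AUC(log10 dose) =  2.89

fold potency (hNeo-4 vs hIL-4) = 11.4
```

The EC50s are the half-maximal doses recovered from noisy synthetic data
(generating values 11 pM and 140 pM): on this type I-biased cell the
mimetic is about tenfold less potent, consistent with its weaker IL-4Rα
affinity, while reaching the same maximal signal. The other examples cover
the equilibrium solvers and hook effect (01), BLI kinetics (03), the global
affinity fit (04), bead-calibrated receptor counting — including the 381:1
γc:IL-13Rα1 macrophage ratio (05) — and Livak/overlap/PCA summaries (06).

The end-to-end pipeline (simulate → Hill fits → global fit → evaluation →
PCA) runs from a YAML config:

```sh
python -m il4model.pipeline demo.yaml   # keys: panel, seed, model, out_dir, ...
```

## Layout

```
src/il4model/
  binding.py      equilibrium solvers (multivalent / sequential), prediction
  doseresponse.py Hill fitting, EC50/AUC/[C]f/fold metrics, normalization
  bli.py          1:1 Langmuir simulation and global kinetic fitting
  globalfit.py    global affinity + Kx* estimation, R², CV, sensitivity
  quantify.py     bead calibration, Livak, overlaps, AUC-matrix PCA
  synthesize.py   packaged panel constants and seeded generators
  io.py           CSV/JSON interfaces (atomic writes)
  pipeline.py     YAML-configured end-to-end run
examples/         one narrative script per capability
docs/methods.md   model derivation, assumptions, identifiability, limits
```
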