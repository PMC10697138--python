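# Methods

## The binding models

IL-4-family ligands signal by heterodimerizing receptor chains on the cell
surface. The private chain of IL-4-class ligands (including engineered type
I-exclusive mimetics such as Neo-4) is IL-4Rα; the co-receptor is either
the common gamma chain γc (type I complex) or IL-13Rα1 (type II complex).
IL-13-class ligands use IL-13Rα1 as the private chain and recruit IL-4Rα.
The predicted signaling readout (a proxy for pSTAT6) is the sum of type I
and type II ternary complexes per cell.

Both model variants solve mass-action conservation equations for the free
receptor abundances r_a, r_g, r_13 at a fixed free-ligand concentration L:

**Multivalent** (either chain may be captured from solution first):

    Ra_T  = r_a  [1 + Ka_a L (1 + Kx*(Ka_g r_g + Ka_13 r_13))]
    Rg_T  = r_g  [1 + Ka_g L + Kx* Ka_a Ka_g L r_a]
    R13_T = r_13 [1 + Ka_13 L + Kx* Ka_a Ka_13 L r_a]

with binary complexes Ka_x·L·r_x and ternary complexes
typeI = Kx*·Ka_a·Ka_g·L·r_a·r_g, typeII = Kx*·Ka_a·Ka_13·L·r_a·r_13.
The ternary expressions are symmetric in binding order (detailed balance),
so the same system serves every ligand class. A ligand has exactly one
co-receptor site: no γc–IL-13Rα1 co-complex exists.

**Sequential** (private chain strictly first): identical except that
non-private chains are not solution-accessible — their Ka·L terms are
removed, so those chains are consumed only through ternary complexes formed
via the private-receptor intermediate. For an IL-13-class ligand this means
only the type II complex can form.

**Units and the crosslinking constant.** Solution concentrations are molar;
surface abundances are receptors/cell; Ka = 1/Kd in 1/M. The second
(surface) binding step proceeds with dimensionless gain Kx*·Ka·r_free,
making Kx* a lumped constant in molar·cell/receptor. A single Kx* is shared
by every ligand, experiment and cell type. This lumping keeps fitted
affinities on the familiar solution scale while capturing that the surface
step's effective association constant is proportional to free co-receptor
abundance.

**Assumptions.** Free ligand equals the nominal dose: at assay densities
(~2e5 cells in ~100 µl), even 10^5 receptors/cell is ~0.3 pM of binding
sites, far below the pM–µM doses used, so depletion is negligible. "No
binding" is encoded as Ka exactly 0 and such pairs never enter any
optimizer; a tiny stand-in affinity would be a silent modeling choice.
Stoichiometry is strictly 1:1:1; receptor clustering, kinetics, and
downstream JAK/STAT dynamics are out of scope. Whether IL-13 carries a
small γc affinity is not resolvable here; it is excluded a priori (Ka=0).

**Solver.** Damped fixed-point iteration on (r_a, r_g, r_13) in linear
space (damping 0.5, relative tolerance 1e-12, budget 1e5 iterations),
vectorized over dose arrays; the update map is a contraction over physical
parameter ranges because each free abundance is a decreasing function of
the others. On non-convergence the solver falls back to a log-space Newton
iteration (positivity by construction) and raises a named solver error if
that also fails. Receptor conservation holds to ≤1e-9 relative error at
every solved state; chains with zero total stay exactly zero.

## Forward prediction and normalization

Predicted signal is typeI + typeII. Curves are normalized jointly per cell
type: every ligand's curve is divided by the maximum signal over all
ligands and doses of that cell type, mirroring per-cell-type
max-normalization of a pSTAT6 readout. If all signals are zero (a cell
with no co-receptor for any ligand) the normalized curves are zero rather
than undefined. Normalization is recomputed inside every objective
evaluation during fitting so it tracks the current parameters.

## Global affinity fitting

Free parameters are log10 Ka for each (ligand, receptor) pair that binds,
plus log10 Kx*. Bounds: log10 Ka ∈ [4, 12] (Kd 100 µM to 1 pM), log10 Kx*
∈ [−15, −5]. The objective is the unweighted sum of squared differences
between observed and predicted normalized responses over every data point,
minimized with SciPy's bounded trust-region least squares.

**Initialization.** The first start is the seed affinity table — in
practice BLI-measured or literature priors, the values a modeler has in
hand before fitting. Additional starts (multistart − 1) are seeded
Latin-hypercube draws over the bounding box; the best final SSE wins. The
prior-anchored first start matters because the LS surface is *sloppy*: an
SVD of the sensitivity (Jacobian) at the generating parameters of the
packaged human panel spans four orders of magnitude of singular values, so
several parameter combinations are nearly — and one exactly — unconstrained:

* An IL-13-class ligand's two chain constants trade off exactly; only
  their product (equivalently the ternary gain Kx*·Ka_a·Ka_13) is
  identified by these panels. Random-start optimization lands anywhere on
  that manifold with identical SSE.
* The type I-exclusive mimetic's IL-4Rα and γc constants are individually
  very weakly identified (linearized SDs ≫ 1 log10 unit under 5%
  multiplicative noise) though exactly recoverable on noiseless data.

Users should therefore read individual fitted constants with their
identifiability in mind; prediction accuracy, cross-validation and
sensitivity conclusions are insensitive to movement along these manifolds.

**Accuracy.** Per-cell-type prediction accuracy is the coefficient of
determination R² = 1 − SSE/SStot over that cell type's points (NaN when the
observations have zero variance). R² is the package's declared reading of
a unitless "prediction accuracy" in [0, 1]; it is configurable in the sense
that residuals are exposed for any other summary.

**Cross-validation** holds out one (cell type, ligand) dose-response curve
at a time — curves are the natural exchangeable unit — refits all free
parameters on the remainder, and scores the held-out curve with R²
(prediction uses the full panel's normalization context). Folds that leave
a free parameter unconstrained are flagged and excluded from the summary
mean with a logged warning.

**Sensitivity scans** scale one receptor's abundance on one cell type by
log-spaced factors (default 13 points over 1e-2..1e2), refit all free
parameters at each factor, and record the mean squared error. Receptors
recorded as undetectable (abundance 0) are reported not-evaluable without
refitting; a failed refit records a NaN sentinel and the scan continues.
Refits default to the single prior-anchored start for runtime.

## Dose-response analysis

The variable-slope logistic y = bottom + (top − bottom)/(1 + (EC50/x)^h)
is fitted by least squares with EC50 in log10 space (bounds: dose range
widened 100× each way; a fit whose EC50 ends outside that window is
marked unconverged), slope constrained to (0.1, 10) — the physical Hill
cooperativity range — and bottom fixed at 0 by default, matching
background subtraction of unstimulated signal before fitting (a flag frees
it). Flat data return an unconverged fit with a NaN EC50 rather than an
error. The slope is left free rather than pinned at 1 because the
equilibrium model's forward curves are not exactly first-order.

Derived metrics: fold potency EC50_b/EC50_a; fold affinity Kd_b/Kd_a; AUC
of the fitted curve over log10-dose by 64-node Gauss–Legendre quadrature
(the integrand is a smooth logistic; the analytic antiderivative is used
only as a test oracle); [C]f — the concentration reaching fraction f of a
reference maximum — by closed-form inversion, raising an "unreachable
level" error when the target lies outside the curve's range (a treated
sample that never reaches 10% of the reference maximum); and activity
retention [C]f(untreated)/[C]f(treated).

## BLI kinetics

1:1 Langmuir traces: association y(t) = Req(1 − e^(−(kon·C+koff)t)) with
Req = rmax·C/(C+Kd), dissociation mono-exponential at koff. Kinetic
fitting is global — one (kon, koff, rmax) shared across a dilution series,
per-trace baseline offsets as nuisance parameters — matching
instrument-software convention; kon/koff are fitted in log10 space from
(1e5 /M/s, 1e-3 /s) with five log-spaced multistarts on failure, and Kd is
reported as koff/kon. Equilibrium titrations fit the one-site isotherm
rmax·C/(C+Kd) and flag the Kd "extrapolated" when it exceeds the highest
measured concentration (a non-saturating titration, as for interactions at
the edge of instrument sensitivity) rather than failing.

## Receptor quantification, Livak, overlaps, PCA

* **Bead calibration:** ordinary least squares of log10(net MFI) on
  log10(ABC) after background subtraction. Log-log because bead kits span
  decades — linear-scale OLS would be dominated by the brightest bead.
  Quantification inverts the line; nonpositive net MFI yields a
  below-detection sentinel (feeding the zero-abundance convention of
  receptor panels), and queries outside the calibrated span are answered
  but flagged extrapolated. Ratios are rounded only for display.
* **Livak:** ΔCt = Ct_gene − Ct_control-gene per sample; ΔΔCt subtracts the
  control-condition mean ΔCt per gene; FC = 2^−ΔΔCt. Summaries are
  arithmetic by default with a geometric option (geometric mean/SD is the
  convention for tissue-level panels).
* **Gene-set overlaps:** exact set arithmetic; both the asymmetric pairwise
  fraction |A∩B|/|A| and the k-way fraction |∩|/|∪| are reported, so either
  denominator convention is computable. Duplicates are deduplicated with a
  warning.
* **PCA:** the AUC matrix has one row per replicate response profile and
  one column per ligand; rows with any missing ligand are excluded
  (≥3 complete rows required). Columns are centered but not variance-scaled
  — AUCs of normalized responses already share a scale. Two components by
  default via scikit-learn.

## Synthetic data: what it emulates and what it does not

The packaged configurations define the study conditions: five human cell
types (Ramos B cells, monocytes, MDMs, fibroblasts, A549) × three ligands
(hIL-4, hIL-13, hNeo-4) and three mouse cell types (A20, BMDM, 3T3) × two
ligands (mIL-4, mNeo-4), dosed on 12-point threefold dilution series
(100 nM top for human, 3 µM for mouse).

Printed constants are packaged directly: hIL-4–IL-4Rα Kd 0.48 nM, hNeo-4
58 nM, hNeo-4–IL-13Rα1 no binding, mIL-4 3.9 nM, mNeo-4 78 nM, and the MDM
γc:IL-13Rα1 ratio of 381:1. Co-receptor step constants seed from the
reported complex-assembly affinities (γc 559 nM, IL-13Rα1 487 nM).
Constants the study does not print were set once by forward-simulation
calibration and frozen: Kx* = 1.017e-8 M·cell/receptor (so the forward
Ramos hIL-4 EC50 is 11 pM), hNeo-4 γc Kd 55.6 nM (Ramos EC50 140 pM), and
mIL-4 γc Kd 756 nM (A20 EC50 0.15 nM). Non-MDM receptor abundances are
plausible per-cell counts (10²–10⁵) arranged so the γc:IL-13Rα1 bias runs
from strongly type I (Ramos, 100:1) to strongly type II (A549, 1:200), with
fibroblast γc set to 0 to represent a chain undetectable by staining. Each
constant carries a provenance note in the config.

One structural limit: in this equilibrium model the forward EC50 of a
type-I ligand cannot exceed its private-chain Kd (the co-receptor step only
amplifies potency), so the mouse mimetic's forward A20 EC50 lands near its
78 nM Kd rather than the ~2× larger printed value; its γc step is set weak
(200 µM) to approach that bound.

Measurement noise is multiplicative log-normal (sd 0.05 in log units) on
the normalized response — flow-MFI error scales with signal. BLI fixtures
use kon = 1e5 /M/s with koff derived from Kd (recovered Kd is invariant to
the split), 900 s association / 1,200 s dissociation, threefold dilutions
from 200 nM. Bead fixtures use a log-log-linear calibration over ABC
1e3–1e6. Ct tables realize configured per-gene log2 fold changes against a
constant endogenous-control gene. Gene sets are built region-by-region from
target cardinalities (validated by inclusion-exclusion; infeasible targets
raise). All generators are deterministic given (config, seed).

What the synthetic data does **not** emulate: donor-to-donor biological
variability, receptor internalization and re-synthesis during stimulation,
the optimal-cluster-size effects suspected on myeloid cells, instrument
drift in BLI, or compensation/spillover in flow cytometry. Passing tests
therefore demonstrate correctness of the estimators and solvers under the
stated noise model, not robustness to every failure mode of real panels.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale problems chosen for
coverage: dose-response fits use the full 12-point grids; global-fit
evaluations use the whole human panel (recovery studies) or three-cell
subsets (cross-validation, sensitivity) with 1–3 replicates; the
Monte-Carlo studies use 100 seeds (Hill EC50), 50 seeds (BLI noise), and
10 seeds (global-fit recovery). Equilibrium properties are checked on 100
random parameter draws per invariant. Ties and degenerate inputs are
handled as described above (sentinels, flags, and named errors rather than
silent values).

## Known limitations

* Individual affinities on sloppy combinations are initialization-dependent
  (see Global affinity fitting); report products or profile likelihoods for
  publication-grade uncertainty statements.
* The equilibrium treatment cannot represent potency losses beyond the
  private-chain Kd bound, kinetic proofreading, or time-dependent readouts.
* The sequential variant forbids all solution capture by non-private
  chains; intermediate regimes (weak but nonzero capture) are representable
  only by the multivalent model.
* `accuracy` is undefined (NaN) for zero-variance observations, e.g. an
  all-zero held-out curve; cross-validation excludes such folds from its
  summary.
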