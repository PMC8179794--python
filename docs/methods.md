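# Methods

## Model

`gcmodel` implements a deterministic mass-action model of the common
γ-chain (γc) cytokine family: IL-2, IL-15, IL-4, IL-7, IL-9, and IL-21.
Each ligand first binds a private receptor chain — IL-2 and IL-15
additionally use a signaling-deficient α chain (IL-2Rα, IL-15Rα) next to
the shared signaling-competent IL-2Rβ; the other four ligands have a single
signaling-competent private chain — and the resulting complexes dimerize
with the shared γc. Direct ligand·γc binding is excluded (it is too weak to
matter). Any complex containing two signaling-competent (JAK-binding)
chains is an *active* species; the model's signaling output is the total
count of active complexes, linearly scaled to pSTAT5/pSTAT6 measurement
units by a fitted scalar.

For an α-chain ligand L, the per-compartment species are L·α, L·β, L·α·β,
L·α·γc, L·β·γc, and L·α·β·γc (active: the last two minus L·α·γc, i.e.
L·β·γc and L·α·β·γc); single-private-receptor ligands contribute L·R and
the active L·R·γc. Over the full family this gives 8 free receptors and 20
complexes per compartment; with two compartments and six endosomal ligand
pools the dynamic state has 62 entries.

### Units and rates

Membrane species are counted in molecules per cell; soluble ligand in nM.
Ligand association uses one rate `k_bnd` = 1e7 M⁻¹s⁻¹ = 0.6 nM⁻¹min⁻¹ for
every ligand–receptor pair; all receptor–receptor dimerizations share one
forward rate `k_fwd` (cell·#⁻¹·min⁻¹). Each reverse rate is unique
(`k_1_rev` … `k_35_rev`). Binary ligand–receptor reverse rates come from
literature affinities (KD × k_bnd): IL-2 binds IL-2Rα at 10 nM and IL-2Rβ
at 144 nM; IL-15 binds IL-15Rα at 0.065 nM and IL-2Rβ at 438 nM; IL-4,
IL-7, IL-9, IL-21 bind their private chains at 1.0, 59, 0.1, and 0.07 nM.
Three IL-2 dimerization reverse rates were measured directly:
`k_5_rev` = 1.5, `k_10_rev` = 12, `k_11_rev` = 63 min⁻¹.

### Detailed balance

Because the forward rates are shared, thermodynamic consistency reduces to
reverse-rate products around each assembly cycle. Each α-chain ligand's
binding graph has 9 reactions over 7 ligand-bound states, hence exactly
three independent cycles and three dependent rates:

    k_a_off(L·α·β)    = k_lig_off(α) · k_b_off(L·α·β) / k_lig_off(β)
    k_a_off(L·α·β·γc) = k_a_off(L·α·β) · k_g_off(L·α·β·γc) / k_g_off(L·β·γc)
    k_b_off(L·α·β·γc) = k_g_off(L·α·β·γc) · k_b_off(L·α·β) / k_g_off(L·α·γc)

For IL-2 these are `k_12_rev` (4.375 min⁻¹ under the defaults), `k_8_rev`
(35.0), and `k_9_rev`; for IL-15, `k_24_rev`, `k_20_rev`, `k_21_rev`.
`enforce_detailed_balance` overwrites exactly these six; everything else is
independent. Note that the cycle-space rank forces `k_22_rev` (γc off
IL-15·IL-15Rα·IL-2Rβ·γc) to be an independent, fitted slot — only three
IL-15 rates can be derived.

### Trafficking

Surface species are endocytosed at `k_endo` (inactive) or `k_endo_active`
(active); endosomal species either recycle at `k_rec` or are degraded at
`k_deg`, with sorting fraction `f_sort` to the lysosome for inactive species
and exactly 1.0 for active species (no recycling of actives). Endosomal
abundances are stored area-normalized: with φ the endosomal/plasma-membrane
area ratio (0.5), the total endosomal molecule count of a species is
φ × its stored value, and the per-chain conserved quantity is
surface + φ·endosomal. Receptor synthesis adds free surface receptors at a
constant per-receptor rate. One naming clash in the source equations (the
surface pool depleted by endocytosis being labeled "intracellular") is
resolved by the equation structure: `E` is the surface pool, `I` the
endosomal pool.

Endosomal ligand is a dynamic state in nM within a 10 fL endosome — one
molecule there is ≈ 0.166 nM, so the endosome is a strong ligand
concentrator. Endosomal ligand is produced by dissociation of endosomal
complexes, consumed by rebinding, and degrades at `k_deg` (sorting fraction
1: free ligand is not recycled). Extracellular ligand is clamped (no
depletion of the medium, no autocrine secretion). All endosomal reverse
rates carry a 5× acidic-pH penalty; forward rates are unchanged.

Endosomal active complexes keep signaling; they enter the pSTAT readout
with total-molecule weight φ × abundance.

### Defaults for unmeasured parameters

Parameters with no literature value are placeholders flagged `fitted` in
the `RateTable`; their defaults were chosen by forward simulation so that
the model's qualitative behavior matches what calibration to cell-line data
produces, and then frozen:

* `k_fwd` = 0.1 cell·#⁻¹·min⁻¹ — large enough that the two-step α-chain
  route (L·α → L·α·β → L·α·β·γc) sensitizes IL-2Rα-high cells at picomolar
  IL-2, the mechanism behind regulatory-T-cell selectivity.
* `k_4_rev` = 80 min⁻¹ (γc off L·α·γc; IL-15 mirror `k_16_rev` = 80) —
  through detailed balance this puts `k_9_rev` at 9.45 min⁻¹, i.e. IL-2Rβ
  unbinds the full quaternary complex slowly (IL-2 holds IL-2Rβ more
  tightly when α-anchored).
* `k_27_rev` = 0.05 (IL-7) vs `k_33_rev` = 5.0 min⁻¹ (IL-4) — a 100-fold
  γc-dimerization affinity advantage for IL-7·IL-7Rα, required for IL-7 to
  out-compete IL-4 for γc despite IL-4's much higher private-receptor
  occupancy at matched doses.
* Trafficking: `k_endo` = 0.08, `k_endo_active` = 0.8 min⁻¹ (the ~10×
  active-internalization ratio), `f_sort` = 1/3 (the Beta(20,40) prior
  mean), `k_rec` = 0.1, `k_deg` = 0.05 min⁻¹. `k_deg` deserves comment: it
  is shared by receptors and free endosomal ligand, and therefore sets how
  long recaptured ligand persists in the 10 fL endosome. At
  `k_deg` ≲ 0.01 the endosomal rebinding loop dominates the low-dose
  response and favors IL-2Rβ-rich cells, erasing the α-chain sensitization;
  0.05 (receptor half-life ≈ 35 min) keeps endosomal signaling present but
  not dominant.

These defaults are starting points for inference, not measurements.

### Numerics

The right-hand side is assembled once per parameter set into flat index
arrays plus dense stoichiometry matrices and evaluated by a numba-compiled
kernel (pure-numpy fallback when numba is absent). Integration uses LSODA
(stiff/non-stiff switching): `simulate` via `scipy.integrate.solve_ivp`
with default rtol 1e-9, restarting at each stimulus onset with the new
clamped ligand vector; the inference hot path uses `odeint` at rtol 1e-4
for throughput. Solver output is clipped at zero (negative excursions are
bounded by the tolerance). No-ligand steady states are closed-form: for an
inactive free receptor,
E = v(k_rec(1−f) + k_deg·f)/(k_endo·k_deg·f), I = k_endo·E/(φ(k_rec(1−f)+k_deg·f)),
and `synthesis_from_surface` is its exact inverse — measured surface counts
are converted to synthesis rates through whatever trafficking parameters
are current, so receptor expression co-varies with trafficking during
fitting.

## Inference

The likelihood is Gaussian on the sum of squared errors, one noise scale σ
per dataset (fixed, or fitted with a weak half-normal prior — the choice of
a proper likelihood form for an SSE objective is a design decision).
Readouts: scaled active-complex counts (pSTAT), or percent-of-initial
surface chain (receptor internalization). pSTAT observations in a scale
group share one fitted scalar. Priors are lognormal with log-sd 0.1 around
the documented defaults (prior centers are these defaults, since no
published prior means exist), except f_sort ~ Beta(20, 40). Detailed
balance is re-enforced inside every likelihood evaluation.

Sampling uses emcee's affine-invariant ensemble with differential-evolution
moves, ≥ 2·ndim walkers, walkers initialized in a small ball around the MAP
(found by Nelder–Mead), configurable warm-up, and optional thinning.
Walkers play the role of chains; identical seeds give bitwise-identical
draws. The Geweke diagnostic compares the first 10% and last 50% of a
chain with spectral (Bartlett-windowed) variance estimates; because the
z-score is only calibrated when draws are nearly independent, convergence
checks on ensemble output should be run on thinned, step-major-pooled
draws (the acceptance-level recovery test thins to ≈ unit autocorrelation
time before applying it). Credible bands use 100 posterior draws and report
10/25/75/90 percentiles; a posterior-predictive band adds observation noise
to each draw's prediction.

The no-trafficking variant zeroes all transport rates; receptor abundances
are then fixed surface constants (`surface:<receptor>` parameters) rather
than synthesis/turnover balances, and active signal is surface-only. Fitted
to data generated with trafficking, it systematically underestimates the
signaling-limiting receptor's abundance — the behavior that motivates
keeping trafficking in the model.

## Tensor factorization

Dose–response predictions (or measurements) are arranged as a labeled
`xarray` tensor, time × cell type × ligand condition (ligand identity and
concentration combined on one axis; a 4-way layout with separate
concentration and ligand axes is supported for mutein panels). Each cell
type's slice is divided by the standard deviation of its entries
(variance scaling; dividing by the sd rather than the variance keeps the
transform linear in the data's scale). Non-negative CP decomposition is
alternating exact non-negative least squares (scipy NNLS per factor row)
with 5 seeded random restarts, relative-change tolerance 1e-7, and at most
10⁴ iterations; R2X = 1 − ‖T−T̂‖²F/‖T‖²F. Non-negative Tucker uses the same
block updates plus an NNLS core solve, warm-started from the CP solution
(superdiagonal core) so its fit at matched ranks is never worse than CP's.
PCA of receptor panels operates on log10(1 + count), centered per receptor
(abundances span decades); loadings are orthonormal right singular vectors.
Factor comparison uses greedy maximum-cosine column pairing.

## Response metrics

EC50s come from unbounded least-squares Hill fits,
y = baseline + amplitude·xⁿ/(EC50ⁿ + xⁿ), with EC50 parameterized on the
log scale (positive without a bound constraint); negative fitted baselines
are reported as-is. Specificity is the ratio of a target cell's pSTAT to an
off-target cell's at a stated dose and time (default 38 pM, 60 min), after
normalizing each cell's dose–response curve by its own maximum — the
normalization convention is a documented choice, and it makes specificity
invariant to the pSTAT scale factor. Sensitivities are central finite
differences of specificity with respect to log reverse rates (relative step
1e-2, verified against 1e-3 within 1%), computed separately for the surface
copy and the endosomal copy of each rate via a per-rate endosomal scale
factor; these per-rate perturbations deliberately do not re-enforce
detailed balance (each rate is varied in isolation). Muteins are applied as
KD fold-changes: the IL-2Rα off-rate scales by KD(α)/KD(α, wt), and the
composite IL-2Rβ/γc affinity — measured against a preassembled β/γc
heterodimer — is mapped as one uniform fold on `k_2_rev`, `k_4_rev`,
`k_5_rev`, and `k_10_rev`, after which detailed balance is re-enforced.

## Synthetic data

The generator emulates the two experimental inputs. Ten cell archetypes
(four anchors — Treg: IL-2Rα 3000/IL-2Rβ 700/γc 3000; NK: 50/5000/800;
T helper: IL-7Rα 2000; CD8: IL-2Rβ 1500/γc 2000 — plus six fixed convex
interpolations) span ~10²–10⁴ receptors/cell with the qualitative PBMC
structure: Tregs IL-2Rα-high, NK cells IL-2Rβ-high/γc-low, helpers
IL-7Rα-high. Responses default to 12 log-spaced doses from 0.5 pM to 84 nM
at 30/60/120/240 min in duplicate, with multiplicative lognormal noise of
CV 0.10 (σ = √log(1+CV²), so the sampled CV matches and CV = 0 returns
exact predictions). The truth record stores every generating parameter.

What the generator does *not* emulate: cell-to-cell variability within a
population, systematic cell-line-to-primary-cell differences, receptor
shedding, downstream JAK-STAT dynamics, or measurement floor/saturation
effects. Tests passing on these fixtures therefore demonstrate correctness
of the machinery and internal consistency of the model, not predictive
accuracy on real cytometry data.

## Problem sizes

Test and acceptance computations are sized for a single CPU: the
tensor-factorization benchmark uses the 10 archetypes × 3 ligands ×
4 doses × 13 time points; the parameter-recovery benchmark fits 6
parameters to one cell type (8 pSTAT + 4 internalization observations)
with 2 × 1000 kept draws after 2000 warm-up steps. Larger designs — the
full 12-dose, 10-cell panel — run through the same code paths via the CLI.

## Known limitations

* Binding parameters for IL-9 and IL-21 beyond their binary KDs are
  topological placeholders; neither ligand has response data here.
* The single 5× endosomal penalty is the only pH effect; no
  compartment-specific forward-rate changes.
* Deterministic mass action only — no stochastic (Gillespie) simulation,
  no ligand depletion from the medium, no pharmacokinetics.
* The affine-invariant sampler mixes slowly on the
  (k_fwd, k_endo_active, scale) ridge; Geweke checks on unthinned ensemble
  traces over-reject, which is why thinning is built into the workflow.
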