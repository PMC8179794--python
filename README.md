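# gcmodel

A binding-and-trafficking model of the common γ-chain (γc) cytokine family
— IL-2, IL-15, IL-4, IL-7, IL-9, IL-21 — for predicting cell-type-specific
pSTAT responses to natural and engineered ligands.

Immune cell types respond very differently to the same cytokine because
they express different amounts of each receptor chain: regulatory T cells
are sensitized to picomolar IL-2 by high IL-2Rα, NK cells ride on abundant
IL-2Rβ, helper T cells on IL-7Rα. `gcmodel` is for computational
immunologists and ligand engineers who want to simulate, fit, and dissect
that selectivity — including how engineered IL-2 muteins with altered
IL-2Rα or IL-2Rβ/γc affinity shift it.

## The model

Mass-action ODEs over every γc-family receptor complex in two compartments
(plasma membrane and a single endosome). Each ligand L binds a private
chain (and for IL-2/IL-15 optionally a signaling-deficient α chain), then
dimerizes with the shared γc:

    L + α ⇌ L·α        L·α + β  ⇌ L·α·β        L·α·β + γc ⇌ L·α·β·γc
    L + β ⇌ L·β        L·β + γc ⇌ L·β·γc       ...

Association uses k_bnd = 10⁷ M⁻¹s⁻¹; all dimerizations share one forward
rate k_fwd; each reverse rate is unique, with dependent ones derived from
thermodynamic detailed balance (every cycle's equilibrium-constant product
is 1). Complexes with two JAK-binding chains are *active*; pSTAT5/6 is a
fitted scalar times the active-complex count. Species are endocytosed
(actives ~10× faster), recycled or degraded (sorting fraction f_sort;
actives sort fully to the lysosome), and keep signaling from the endosome,
where dissociation is 5× faster and one free ligand molecule in the 10 fL
lumen is already 0.17 nM. Receptor synthesis balances turnover, so measured
surface counts pin expression rates through a closed-form steady state.

On top of the simulator:

* **Bayesian inference** (emcee): lognormal/Beta priors, Gaussian SSE
  likelihood, Geweke diagnostics, credible-band predictions, and a
  no-trafficking variant for model comparison.
* **Tensor factorization**: non-negative CP and Tucker decomposition of
  time × cell × condition response grids (R2X curves, factor tables), plus
  PCA of receptor panels.
* **Response metrics**: Hill EC50 fits, Treg-vs-off-target specificity,
  per-rate surface/endosomal sensitivity, and mutein KD fold-change
  application.
* **Synthetic data**: ten PBMC-like receptor archetypes and noisy
  dose–response fixtures with recorded ground truth.

See `docs/methods.md` for assumptions, parameter defaults, and numerics.

## Worked example

```python
import numpy as np
from gcmodel import (CellProfile, TraffickingParams, default_rate_table,
                     dose_response_grid, fit_hill, specificity)

rates = default_rate_table()
traffic = TraffickingParams()
treg = CellProfile("Treg", receptor_surface={"IL2Ra": 3000, "IL2Rb": 700, "gc": 3000})
nk = CellProfile("NK", receptor_surface={"IL2Ra": 50, "IL2Rb": 5000, "gc": 800})

doses = np.logspace(-3, 1.5, 8)          # 1 pM .. ~32 nM
grid = dose_response_grid([treg, nk], ["IL2"], doses, [60.0], rates, traffic)

for cell in ("Treg", "NK"):
    ec50 = fit_hill(doses, grid.sel(cell=cell).values[:, 0]).ec50
    print(f"{cell:5s} IL-2 EC50 at 60 min: {ec50 * 1e3:.1f} pM")

resp = {c: grid.sel(cell=c).values[:, 0] for c in ("Treg", "NK")}
for dose in (0.01, 10.0):
    s = specificity(resp, doses, "Treg", "NK", dose_nM=dose)
    print(f"Treg/NK specificity at {s.dose_nM*1e3:7.1f} pM: {s.value:.2f}")
```

prints

```
Treg  IL-2 EC50 at 60 min: 8.0 pM
NK    IL-2 EC50 at 60 min: 17.8 pM
Treg/NK specificity at     4.4 pM: 1.84
Treg/NK specificity at  7196.9 pM: 1.00
```

The IL-2Rα-rich Treg profile responds at lower IL-2 doses than the NK
profile (lower EC50), and its selectivity advantage — the ratio of
max-normalized responses — is largest at picomolar doses and vanishes at
saturation. That dose-dependent selectivity is the core engineering handle
the package quantifies. (`specificity` snaps the requested dose to the
nearest grid point, hence 4.4 pM and 7.2 nM.)

## Command line

Each pipeline stage is also a `gcmodel` subcommand:

```sh
gcmodel synth   --seed 1 --out fixtures/                 # receptor + response tables
gcmodel fit     --data fixtures/responses.csv --profiles fixtures/receptors.csv \
                --chains 2 --draws 500 --seed 0 --out fit/
gcmodel predict --posterior fit/posterior.csv --profiles fixtures/receptors.csv \
                --ligand IL2 --out pred/                 # 10-90% credible bands
gcmodel factor  --data fixtures/responses.csv --rank 3 --out factors/
gcmodel metrics --data fixtures/responses.csv --out metrics/
gcmodel simulate --profiles fixtures/receptors.csv --protocol protocol.yaml --out sim/
```

All commands write a `metadata.json` (version, git hash, seed, arguments)
next to their outputs.

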