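"""Synthetic fixture generation: receptor panels and noisy pSTAT responses.

The generator emulates the two experimental inputs the model consumes: a
flow-cytometry-style receptor quantitation table across immune cell types,
and pSTAT dose-response measurements.  Ten cell archetypes span receptor
abundances of roughly 10^2-10^4 per cell with the qualitative structure of
human PBMC subsets: regulatory T cells are IL-2Rα-high, NK cells are
IL-2Rβ-high/γc-low, helper T cells are IL-7Rα-high, plus interpolated
naive/memory variants.  Responses are simulated from a known parameter
vector and corrupted with multiplicative lognormal noise; the generating
truth is recorded for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import RateTable, TraffickingParams, default_rate_table
from .simulate import CellProfile, dose_response_grid, readout_for

__all__ = ["ARCHETYPES", "archetype_profiles", "SyntheticConfig", "synth_generate"]

# Four anchor archetypes (receptors in #/cell)...
_ANCHORS = {
    "Treg":    {"IL2Ra": 3000, "IL2Rb": 700,  "gc": 3000, "IL15Ra": 100, "IL7Ra": 800,  "IL4Ra": 300},
    "NK":      {"IL2Ra": 50,   "IL2Rb": 5000, "gc": 800,  "IL15Ra": 200, "IL7Ra": 300,  "IL4Ra": 100},
    "Thelper": {"IL2Ra": 300,  "IL2Rb": 600,  "gc": 2500, "IL15Ra": 80,  "IL7Ra": 2000, "IL4Ra": 600},
    "CD8":     {"IL2Ra": 80,   "IL2Rb": 1500, "gc": 2000, "IL15Ra": 150, "IL7Ra": 1200, "IL4Ra": 200},
}

# ... and six interpolated subsets (fixed convex weights over the anchors),
# completing a 10-type panel with naive/memory gradations.
_MIXES = {
    "Treg_mem":      {"Treg": 0.7, "Thelper": 0.3},
    "Treg_naive":    {"Treg": 0.85, "CD8": 0.15},
    "Thelper_mem":   {"Thelper": 0.6, "CD8": 0.4},
    "Thelper_naive": {"Thelper": 0.85, "Treg": 0.15},
    "CD8_mem":       {"CD8": 0.6, "Treg": 0.2, "Thelper": 0.2},
    "NKT":           {"NK": 0.5, "CD8": 0.5},
}


def _build_archetypes() -> dict:
    out = {name: dict(recs) for name, recs in _ANCHORS.items()}
    for name, weights in _MIXES.items():
        out[name] = {
            rec: round(sum(w * _ANCHORS[a][rec] for a, w in weights.items()))
            for rec in next(iter(_ANCHORS.values()))
        }
    return out


#: receptor surface abundances (#/cell) for the 10 bundled cell archetypes
ARCHETYPES = _build_archetypes()


def archetype_profiles(names=None) -> list:
    """CellProfiles for the bundled archetypes (all ten by default)."""
    names = list(ARCHETYPES) if names is None else list(names)
    return [CellProfile(n, receptor_surface=dict(ARCHETYPES[n])) for n in names]


@dataclass
class SyntheticConfig:
    """Study conditions for fixture generation.

    Defaults mirror the profiled experimental design: 12 log-spaced doses
    from 0.5 pM to 84 nM, readouts at 30/60/120/240 min, duplicate
    measurements, 10% multiplicative lognormal noise.
    """

    ligands: tuple = ("IL2", "IL15", "IL7")
    doses_nM: np.ndarray = field(default_factory=lambda: np.logspace(np.log10(5e-4), np.log10(84.0), 12))
    times_min: np.ndarray = field(default_factory=lambda: np.array([30.0, 60.0, 120.0, 240.0]))
    cells: tuple = tuple(ARCHETYPES)
    replicates: int = 2
    cv: float = 0.10
    scale: float = 1.0
    seed: int = 0
    rates: RateTable | None = None
    traffic: TraffickingParams | None = None

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def synth_generate(config: SyntheticConfig):
    """Generate (receptor table, response table, truth record).

    Responses are noise-free model predictions multiplied by
    exp(N(0, sigma)) with sigma = sqrt(log(1 + CV^2)), so the sampled
    coefficient of variation equals the configured CV and CV = 0 returns the
    predictions exactly.  Bitwise reproducible for a fixed seed.
    """
    rates = config.rates if config.rates is not None else default_rate_table()
    traffic = config.traffic if config.traffic is not None else TraffickingParams()
    profiles = archetype_profiles(config.cells)
    rng = np.random.default_rng(config.seed)

    receptor_rows = [
        {"cell_type": p.name, "receptor": r, "count": c}
        for p in profiles for r, c in p.receptor_surface.items()
    ]
    receptor_df = pd.DataFrame(receptor_rows)

    grid = dose_response_grid(profiles, list(config.ligands), config.doses_nM,
                              config.times_min, rates, traffic, scale=config.scale)
    sigma = np.sqrt(np.log1p(config.cv**2))
    rows = []
    for cell in grid.coords["cell"].values:
        for cond in grid.coords["condition"].values:
            lig, conc = str(cond).split("@")
            for t in grid.coords["time"].values:
                mu = float(grid.sel(cell=cell, condition=cond, time=t))
                for rep in range(1, config.replicates + 1):
                    noise = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
                    rows.append({
                        "cell_type": cell, "ligand": lig,
                        "concentration_nM": float(conc), "time_min": float(t),
                        "readout": readout_for(lig), "value": mu * noise,
                        "replicate": rep,
                    })
    response_df = pd.DataFrame(rows)

    truth = {
        "rates": {k: float(v) for k, v in rates.values.items()},
        "traffic": {k: float(getattr(traffic, k)) for k in
                    ("k_endo", "k_endo_active", "f_sort", "k_rec", "k_deg", "phi", "v_endo_fL")},
        "scale": config.scale,
        "cv": config.cv,
        "seed": config.seed,
        "ligands": list(config.ligands),
        "doses_nM": [float(d) for d in config.doses_nM],
        "times_min": [float(t) for t in config.times_min],
    }
    return receptor_df, response_df, truth
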