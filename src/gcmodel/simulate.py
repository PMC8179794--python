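"""Cell-level simulation of γc cytokine stimulation.

Cells are initialized at their no-ligand steady state, where constant
receptor synthesis balances endocytic turnover; stimulation protocols are
integrated piecewise (the solver restarts at each stimulus onset, with
extracellular ligand clamped in between), and the readouts of interest —
active-complex counts scaled to pSTAT, surface-receptor depletion,
dose-response grids, and two-cytokine cross-inhibition — are computed from
the resulting trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy.integrate import solve_ivp

from .network import (
    NetworkSpec,
    RateTable,
    SystemState,
    TraffickingParams,
    assemble_rhs,
    build_network,
)

__all__ = [
    "CellProfile",
    "StimulusProtocol",
    "Trajectory",
    "steady_state",
    "synthesis_from_surface",
    "simulate",
    "active_signal",
    "pstat",
    "readout_for",
    "surface_fraction",
    "cross_inhibition",
    "dose_response_grid",
]

#: STAT isoform reported for each ligand's active complexes
STAT_READOUT = {
    "IL2": "pSTAT5", "IL15": "pSTAT5", "IL7": "pSTAT5",
    "IL9": "pSTAT5", "IL21": "pSTAT5", "IL4": "pSTAT6",
}


def readout_for(ligand: str) -> str:
    return STAT_READOUT[ligand]


@dataclass
class CellProfile:
    """A cell type, defined by receptor synthesis rates or surface counts.

    Exactly one of ``receptor_synthesis`` (#/cell/min) or
    ``receptor_surface`` (#/cell, converted to synthesis rates through the
    no-ligand steady state) should be provided; receptors absent from the
    mapping default to zero.
    """

    name: str
    receptor_synthesis: dict = field(default_factory=dict)
    receptor_surface: dict = field(default_factory=dict)

    def __post_init__(self):
        for table in (self.receptor_synthesis, self.receptor_surface):
            for rec, v in table.items():
                if v < 0:
                    raise ValueError(f"negative entry for {rec} in profile {self.name!r}")

    def synthesis(self, traffic: TraffickingParams) -> dict:
        if self.receptor_synthesis:
            return dict(self.receptor_synthesis)
        return {r: synthesis_from_surface(x, traffic) for r, x in self.receptor_surface.items()}


@dataclass
class StimulusProtocol:
    """Ligand events and output times.

    Each event (ligand, concentration_nM, onset_min) sets that ligand's
    clamped extracellular concentration from its onset onward (cytokines are
    co-present after sequential additions; pre-treatments are not washed
    out).
    """

    events: list
    t_grid: np.ndarray

    def __post_init__(self):
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        onsets = [t for (_, _, t) in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onset times must be non-decreasing")
        if any(c < 0 for (_, c, _) in self.events):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def single_dose(cls, ligand: str, conc_nM: float, times) -> "StimulusProtocol":
        return cls(events=[(ligand, float(conc_nM), 0.0)], t_grid=np.asarray(times, float))


@dataclass
class Trajectory:
    """Integrated time course with the objects needed to interpret it."""

    network: NetworkSpec
    times: np.ndarray
    states: np.ndarray          # (n_times, n_state)
    ext_ligand: np.ndarray      # (n_times, n_ligands), clamped values
    traffic: TraffickingParams
    diagnostics: dict = field(default_factory=dict)

    def state_at(self, k: int) -> SystemState:
        return SystemState.from_vector(self.network, self.states[k], self.ext_ligand[k])


def _free_receptor_steady_state(v: float, traffic: TraffickingParams):
    """Closed-form (surface, endosomal) abundance of one inactive receptor.

    At steady state, synthesis v balances lysosomal loss:
    E = v (k_rec (1-f) + k_deg f) / (k_endo k_deg f) and
    I = k_endo E / (phi (k_rec (1-f) + k_deg f)).
    """
    if v == 0.0:
        return 0.0, 0.0
    f, tr = traffic.f_sort, traffic
    denom = tr.k_endo * tr.k_deg * f
    if denom == 0.0:
        raise ValueError("no finite steady state: k_endo and k_deg must be positive")
    turn = tr.k_rec * (1.0 - f) + tr.k_deg * f
    surf = v * turn / denom
    endo = tr.k_endo * surf / (tr.phi * turn)
    return surf, endo


def steady_state(network: NetworkSpec, profile: CellProfile,
                 traffic: TraffickingParams) -> SystemState:
    """No-ligand steady state: free receptors only, complexes and ligand zero."""
    state = SystemState.zeros(network)
    synth = profile.synthesis(traffic)
    for rec, v in synth.items():
        if rec not in network.receptors:
            continue
        k = network.species.index(rec)
        state.surface[k], state.endosomal[k] = _free_receptor_steady_state(v, traffic)
    return state


def synthesis_from_surface(surface: float, traffic: TraffickingParams) -> float:
    """Receptor synthesis rate producing a given surface count at steady state."""
    if surface < 0:
        raise ValueError("surface abundance must be non-negative")
    if surface == 0.0:
        return 0.0
    f, tr = traffic.f_sort, traffic
    turn = tr.k_rec * (1.0 - f) + tr.k_deg * f
    return surface * tr.k_endo * tr.k_deg * f / turn


def simulate(state0: SystemState, protocol: StimulusProtocol, rates: RateTable,
             traffic: TraffickingParams, synthesis=None, rtol: float = 1e-9,
             atol: float = 1e-6) -> Trajectory:
    """Integrate a stimulation protocol from ``state0``.

    Integration restarts at every stimulus onset with the new clamped
    extracellular ligand vector; the stiff LSODA solver is used with a tight
    default relative tolerance.
    """
    network = state0.network
    t_grid = np.asarray(protocol.t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("output times must be strictly increasing")
    lig_index = {l: k for k, l in enumerate(network.ligands)}

    onsets = sorted({float(t) for (_, _, t) in protocol.events})
    boundaries = sorted({0.0, *onsets, float(t_grid[-1])})
    boundaries = [b for b in boundaries if b <= t_grid[-1]]

    ext = np.asarray(state0.ligand_extracellular, dtype=float).copy()
    y = state0.as_vector()
    times_out, states_out, ext_out = [], [], []
    if t_grid[0] == 0.0:
        times_out.append(0.0)
        states_out.append(y.copy())
        ext_out.append(ext.copy())

    nfev = 0
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        for (lig, conc, onset) in protocol.events:
            if onset == a:
                if lig not in lig_index:
                    raise ValueError(f"ligand {lig!r} not in network")
                ext[lig_index[lig]] = conc
        f = assemble_rhs(network, rates, traffic, synthesis, ext)
        wanted = t_grid[(t_grid > a) & (t_grid <= b)]
        t_eval = np.unique(np.append(wanted, b))
        sol = solve_ivp(f, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE solver failed in segment [{a}, {b}] min: {sol.message}")
        nfev += sol.nfev
        for k in range(sol.t.size):
            if np.any(np.isclose(sol.t[k], wanted)):
                times_out.append(sol.t[k])
                states_out.append(np.clip(sol.y[:, k], 0.0, None))
                ext_out.append(ext.copy())
        y = np.clip(sol.y[:, -1], 0.0, None)

    return Trajectory(
        network=network,
        times=np.asarray(times_out),
        states=np.vstack(states_out),
        ext_ligand=np.vstack(ext_out) if ext_out else np.zeros((0, len(network.ligands))),
        traffic=traffic,
        diagnostics={"nfev": nfev},
    )


def active_signal(traj: Trajectory, ligand: str) -> np.ndarray:
    """Total active complexes of one ligand over time (#/cell).

    Endosomal active complexes are counted with total-molecule weight
    phi x abundance; they keep signaling after internalization.
    """
    network = traj.network
    if ligand not in network.ligands:
        raise ValueError(f"ligand {ligand!r} not in network")
    n = network.n_comp_species
    idx = np.array([
        k for k, s in enumerate(network.species)
        if network.active_mask[k] and network.ligand_of_species.get(s) == ligand
    ], dtype=np.intp)
    surf = traj.states[:, idx].sum(axis=1)
    endo = traj.states[:, n + idx].sum(axis=1)
    return surf + traj.traffic.phi * endo


def pstat(active: np.ndarray, scale: float) -> np.ndarray:
    """Scale active-complex counts to the pSTAT measurement axis."""
    if not scale > 0:
        raise ValueError("pSTAT scale factor must be positive")
    return scale * np.asarray(active, dtype=float)


def surface_fraction(traj: Trajectory, receptor: str) -> np.ndarray:
    """Percent of the initial surface pool of one chain remaining over time.

    Counts the chain across all surface species (free and complexed).
    """
    network = traj.network
    if receptor not in network.receptors:
        raise ValueError(f"receptor {receptor!r} not in network")
    r = network.receptors.index(receptor)
    w = network.composition[:, r]
    n = network.n_comp_species
    totals = traj.states[:, :n] @ w
    if totals[0] <= 0:
        raise ValueError(f"zero initial surface abundance of {receptor}")
    return 100.0 * totals / totals[0]


def _pstat_endpoint(network, state0, events, t_end, rates, traffic, synthesis,
                    ligand, rtol):
    protocol = StimulusProtocol(events=events, t_grid=np.array([t_end]))
    traj = simulate(state0, protocol, rates, traffic, synthesis, rtol=rtol)
    return float(active_signal(traj, ligand)[-1])


def cross_inhibition(profile: CellProfile, pre_ligand: str, pre_doses, fixed_ligand: str,
                     fixed_dose: float, rates: RateTable, traffic: TraffickingParams,
                     pre_min: float = 10.0, stim_min: float = 10.0,
                     rtol: float = 1e-8) -> np.ndarray:
    """Percent inhibition of a fixed second stimulus by a pre-treatment.

    The cell is pre-treated with ``pre_ligand`` for ``pre_min`` minutes, the
    second cytokine is added (pre-treatment remains present), and the second
    cytokine's pSTAT readout after ``stim_min`` further minutes is compared
    with the same stimulus given alone:
    inhibition = 100 x (1 - response_with_pretreat / response_alone).
    """
    network = build_network({pre_ligand, fixed_ligand})
    synthesis = profile.synthesis(traffic)
    state0 = steady_state(network, profile, traffic)
    alone = _pstat_endpoint(network, state0, [(fixed_ligand, fixed_dose, 0.0)],
                            stim_min, rates, traffic, synthesis, fixed_ligand, rtol)
    if alone <= 0:
        raise ValueError("fixed-stimulus response alone is zero; inhibition undefined")
    out = []
    for dose in np.asarray(pre_doses, dtype=float):
        events = [(pre_ligand, float(dose), 0.0), (fixed_ligand, float(fixed_dose), pre_min)]
        resp = _pstat_endpoint(network, state0, events, pre_min + stim_min,
                               rates, traffic, synthesis, fixed_ligand, rtol)
        out.append(100.0 * (1.0 - resp / alone))
    return np.asarray(out)


def dose_response_grid(profiles, ligands, concentrations, times, rates: RateTable,
                       traffic: TraffickingParams, scale: float = 1.0,
                       rtol: float = 1e-8) -> xr.DataArray:
    """pSTAT predictions on a cell x (ligand, concentration) x time grid.

    ``concentrations`` is either one array shared by all ligands or a mapping
    ligand -> array.  Conditions are labeled "<ligand>@<conc nM>".
    """
    profiles = list(profiles)
    ligands = list(ligands)
    times = np.asarray(times, dtype=float)
    if not profiles or not ligands or times.size == 0:
        raise ValueError("profiles, ligands, and times must be non-empty")
    if isinstance(concentrations, dict):
        conc_of = {l: np.asarray(concentrations[l], float) for l in ligands}
    else:
        conc_of = {l: np.asarray(concentrations, float) for l in ligands}

    conditions = [(l, c) for l in ligands for c in conc_of[l]]
    labels = [f"{l}@{c:g}" for l, c in conditions]
    values = np.zeros((len(profiles), len(conditions), times.size))

    sim_times = times[times > 0]
    t0_included = times[0] == 0.0
    networks = {l: build_network({l}) for l in ligands}
    for ci, profile in enumerate(profiles):
        synthesis = profile.synthesis(traffic)
        for li, lig in enumerate(ligands):
            network = networks[lig]
            state0 = steady_state(network, profile, traffic)
            for ki, conc in enumerate(conc_of[lig]):
                j = sum(conc_of[l].size for l in ligands[:li]) + ki
                if sim_times.size:
                    protocol = StimulusProtocol.single_dose(lig, conc, sim_times)
                    traj = simulate(state0, protocol, rates, traffic, synthesis, rtol=rtol)
                    resp = pstat(active_signal(traj, lig), scale)
                    values[ci, j, (1 if t0_included else 0):] = resp
                # response at t = 0 is zero (no ligand exposure yet)

    return xr.DataArray(
        values,
        dims=("cell", "condition", "time"),
        coords={
            "cell": [p.name for p in profiles],
            "condition": labels,
            "time": times,
        },
        name="pstat",
    )
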