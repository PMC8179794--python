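"""Reaction network for the common gamma-chain (γc) cytokine family.

The γc cytokines (IL-2, IL-15, IL-4, IL-7, IL-9, IL-21) signal by assembling
receptor complexes on the cell surface: each ligand first binds a private
receptor chain (and, for IL-2/IL-15, optionally a signaling-deficient α
chain), after which the complex dimerizes with the shared γc.  Complexes
containing two JAK-binding (signaling-competent) chains are "active" and
drive STAT phosphorylation.  Species live in two compartments — the plasma
membrane and a single endosomal compartment — coupled by endocytosis,
recycling, and lysosomal degradation.

Units follow the convention of the underlying mass-action model:

* free receptors and complexes: number per cell (#/cell); endosomal species
  are stored area-normalized (total molecules = phi x stored value),
* soluble ligand: nM (extracellular ligand is clamped; endosomal ligand is a
  dynamic state within the fixed endosomal volume),
* ligand-receptor association: k_bnd in nM^-1 min^-1,
* receptor-receptor dimerization: a single shared forward rate k_fwd in
  cell #^-1 min^-1; every reverse rate (min^-1) is unique,
* all endosomal reverse rates carry a multiplicative penalty (default 5x)
  for the acidic endosomal pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

try:  # numba accelerates the ODE right-hand side; plain numpy otherwise
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco

__all__ = [
    "LIGANDS",
    "RECEPTORS",
    "ALPHA_CHAIN",
    "PRIVATE_CHAIN",
    "NetworkSpec",
    "RateTable",
    "TraffickingParams",
    "SystemState",
    "Reaction",
    "build_network",
    "default_rate_table",
    "enforce_detailed_balance",
    "assemble_rhs",
    "rhs",
    "endosome_concentration",
    "molecules_from_nM",
]

AVOGADRO = 6.02214076e23

#: canonical ligand ordering
LIGANDS = ("IL2", "IL15", "IL4", "IL7", "IL9", "IL21")

#: canonical receptor-chain ordering
RECEPTORS = ("IL2Ra", "IL2Rb", "gc", "IL15Ra", "IL4Ra", "IL7Ra", "IL9R", "IL21Ra")

#: signaling-deficient α chain per ligand (IL-2/IL-15 only)
ALPHA_CHAIN = {"IL2": "IL2Ra", "IL15": "IL15Ra"}

#: signaling-competent private chain per ligand (IL-2Rβ is shared by IL-2/IL-15)
PRIVATE_CHAIN = {
    "IL2": "IL2Rb",
    "IL15": "IL2Rb",
    "IL4": "IL4Ra",
    "IL7": "IL7Ra",
    "IL9": "IL9R",
    "IL21": "IL21Ra",
}

# Rate-table key of each reaction slot, per ligand.  Slots for the α-chain
# ligands: bind_a/bind_b (ligand on/off the free α or β=private chain),
# g_off_* (γc dissociation from the named complex), a_off_*/b_off_* (chain
# dissociation from ternary/quaternary complexes).  Single-private-receptor
# ligands only have bind_r (ligand off the private chain) and g_off (γc off
# the active complex).
RATE_SLOTS = {
    "IL2": {
        "bind_a": "k_1_rev", "bind_b": "k_2_rev",
        "g_off_ag": "k_4_rev", "g_off_bg": "k_5_rev",
        "a_off_abg": "k_8_rev", "b_off_abg": "k_9_rev", "g_off_abg": "k_10_rev",
        "b_off_ab": "k_11_rev", "a_off_ab": "k_12_rev",
    },
    "IL15": {
        "bind_a": "k_13_rev", "bind_b": "k_14_rev",
        "g_off_ag": "k_16_rev", "g_off_bg": "k_17_rev",
        "a_off_abg": "k_20_rev", "b_off_abg": "k_21_rev", "g_off_abg": "k_22_rev",
        "b_off_ab": "k_23_rev", "a_off_ab": "k_24_rev",
    },
    "IL4": {"bind_r": "k_32_rev", "g_off": "k_33_rev"},
    "IL7": {"bind_r": "k_25_rev", "g_off": "k_27_rev"},
    "IL9": {"bind_r": "k_29_rev", "g_off": "k_31_rev"},
    "IL21": {"bind_r": "k_34_rev", "g_off": "k_35_rev"},
}

#: literature dissociation constants (nM) of each ligand for its binding chains
LITERATURE_KD_NM = {
    ("IL2", "IL2Ra"): 10.0,
    ("IL2", "IL2Rb"): 144.0,
    ("IL15", "IL15Ra"): 0.065,
    ("IL15", "IL2Rb"): 438.0,
    ("IL4", "IL4Ra"): 1.0,
    ("IL7", "IL7Ra"): 59.0,
    ("IL9", "IL9R"): 0.1,
    ("IL21", "IL21Ra"): 0.07,
}


@dataclass(frozen=True)
class Reaction:
    """One reversible reaction within a compartment.

    kind is "bind" (soluble ligand + free receptor -> binary complex, forward
    rate k_bnd) or "dim" (membrane species + membrane species -> complex,
    forward rate k_fwd).  Indices refer to positions in the per-compartment
    species list; for "bind" reactions ``i`` is the ligand index instead.
    """

    kind: str           # "bind" | "dim"
    i: int              # ligand index (bind) or first membrane reactant (dim)
    j: int              # free receptor (bind) or second membrane reactant (dim)
    product: int
    rev_key: str


@dataclass(frozen=True)
class NetworkSpec:
    """Enumerated species and reactions for a subset of the γc family."""

    ligands: tuple
    receptors: tuple
    species: tuple              # per-compartment labels: receptors then complexes
    species_index: dict         # "surf/..."|"endo/..."|"endo/<ligand>" -> state position
    active_mask: np.ndarray     # bool per per-compartment species
    ligand_of_species: dict     # complex label -> ligand
    composition: np.ndarray     # (n_species, n_receptors) chain counts
    reactions: tuple            # Reaction instances (per-compartment template)

    @property
    def n_comp_species(self) -> int:
        return len(self.species)

    @property
    def n_state(self) -> int:
        """Dynamic state dimension: two compartments + endosomal ligands."""
        return 2 * len(self.species) + len(self.ligands)

    @property
    def active_species(self) -> tuple:
        return tuple(s for s, a in zip(self.species, self.active_mask) if a)

    def active_for(self, ligand: str) -> tuple:
        return tuple(
            s for s in self.active_species if self.ligand_of_species.get(s) == ligand
        )


def _complex_label(ligand: str, chains: tuple) -> str:
    return f"{ligand}:" + ".".join(chains)


def build_network(ligands) -> NetworkSpec:
    """Enumerate species, reactions, and state layout for ``ligands``.

    Shared receptors (IL-2Rβ for IL-2/IL-15, γc for all) appear once per
    compartment.  α-chain ligands contribute six complexes (L·α, L·β, L·α·β,
    L·α·γc, L·β·γc, L·α·β·γc); the others contribute two (L·R, L·R·γc).
    """
    ligands = tuple(ligands)
    if not ligands:
        raise ValueError("at least one ligand is required")
    for lig in ligands:
        if lig not in LIGANDS:
            raise ValueError(f"unknown ligand identifier: {lig!r}")
    ligands = tuple(l for l in LIGANDS if l in ligands)  # canonical order

    used = {"gc"}
    for lig in ligands:
        used.add(PRIVATE_CHAIN[lig])
        if lig in ALPHA_CHAIN:
            used.add(ALPHA_CHAIN[lig])
    receptors = tuple(r for r in RECEPTORS if r in used)
    ridx = {r: k for k, r in enumerate(receptors)}

    species = list(receptors)
    ligand_of = {}
    active = [False] * len(receptors)
    comp_rows = [np.eye(len(receptors))[k] for k in range(len(receptors))]

    def add_species(lig, chains, is_active):
        label = _complex_label(lig, chains)
        species.append(label)
        ligand_of[label] = lig
        active.append(is_active)
        row = np.zeros(len(receptors))
        for c in chains:
            row[ridx[c]] += 1.0
        comp_rows.append(row)
        return len(species) - 1

    reactions = []
    lidx = {l: k for k, l in enumerate(ligands)}
    for lig in ligands:
        slots = RATE_SLOTS[lig]
        b = PRIVATE_CHAIN[lig]
        if lig in ALPHA_CHAIN:
            a = ALPHA_CHAIN[lig]
            s_la = add_species(lig, (a,), False)
            s_lb = add_species(lig, (b,), False)
            s_lab = add_species(lig, (a, b), False)
            s_lag = add_species(lig, (a, "gc"), False)
            s_lbg = add_species(lig, (b, "gc"), True)
            s_labg = add_species(lig, (a, b, "gc"), True)
            ia, ib, ig = ridx[a], ridx[b], ridx["gc"]
            reactions += [
                Reaction("bind", lidx[lig], ia, s_la, slots["bind_a"]),
                Reaction("bind", lidx[lig], ib, s_lb, slots["bind_b"]),
                Reaction("dim", s_la, ig, s_lag, slots["g_off_ag"]),
                Reaction("dim", s_lb, ig, s_lbg, slots["g_off_bg"]),
                Reaction("dim", s_la, ib, s_lab, slots["b_off_ab"]),
                Reaction("dim", s_lb, ia, s_lab, slots["a_off_ab"]),
                Reaction("dim", s_lab, ig, s_labg, slots["g_off_abg"]),
                Reaction("dim", s_lbg, ia, s_labg, slots["a_off_abg"]),
                Reaction("dim", s_lag, ib, s_labg, slots["b_off_abg"]),
            ]
        else:
            s_lr = add_species(lig, (b,), False)
            s_lrg = add_species(lig, (b, "gc"), True)
            reactions += [
                Reaction("bind", lidx[lig], ridx[b], s_lr, slots["bind_r"]),
                Reaction("dim", s_lr, ridx["gc"], s_lrg, slots["g_off"]),
            ]

    n = len(species)
    index = {}
    for k, s in enumerate(species):
        index[f"surf/{s}"] = k
        index[f"endo/{s}"] = n + k
    for k, lig in enumerate(ligands):
        index[f"endo/{lig}"] = 2 * n + k

    return NetworkSpec(
        ligands=ligands,
        receptors=receptors,
        species=tuple(species),
        species_index=index,
        active_mask=np.asarray(active, dtype=bool),
        ligand_of_species=ligand_of,
        composition=np.vstack(comp_rows),
        reactions=tuple(reactions),
    )


@dataclass(frozen=True)
class RateTable:
    """All binding/dimerization rate constants.

    ``values`` maps flat keys (k_bnd, k_fwd, k_1_rev ... k_35_rev,
    endosomal_penalty) to floats; ``fitted`` flags the rates whose defaults
    are placeholders pending model fitting rather than literature values.
    ``endo_rev_scale`` optionally scales individual endosomal reverse rates
    on top of the global penalty (used for compartment-resolved sensitivity
    analysis).
    """

    values: dict
    fitted: frozenset = frozenset()
    endo_rev_scale: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    @property
    def endosomal_penalty(self) -> float:
        return self.values["endosomal_penalty"]

    def endo_rev(self, key: str) -> float:
        """Effective endosomal reverse rate for ``key``."""
        return self.values[key] * self.endosomal_penalty * self.endo_rev_scale.get(key, 1.0)

    def with_updates(self, **updates) -> "RateTable":
        vals = dict(self.values)
        vals.update(updates)
        return replace(self, values=vals)

    def validate(self) -> None:
        for k, v in self.values.items():
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"rate {k} must be strictly positive, got {v}")


# Spanning set for detailed balance: binary ligand-receptor KDs are from the
# literature, k_5/k_10/k_11 were measured for IL-2, and the remaining
# independent slots are fitted; the three dependent rates per α-chain ligand
# close the three independent thermodynamic cycles of its binding graph.
_DEPENDENT = {
    # a_off_ab = bind_a * b_off_ab / bind_b
    "k_12_rev": ("k_1_rev", "k_11_rev", "k_2_rev"),
    "k_24_rev": ("k_13_rev", "k_23_rev", "k_14_rev"),
    # a_off_abg = a_off_ab * g_off_abg / g_off_bg
    "k_8_rev": ("k_12_rev", "k_10_rev", "k_5_rev"),
    "k_20_rev": ("k_24_rev", "k_22_rev", "k_17_rev"),
    # b_off_abg = g_off_abg * b_off_ab / g_off_ag
    "k_9_rev": ("k_10_rev", "k_11_rev", "k_4_rev"),
    "k_21_rev": ("k_22_rev", "k_23_rev", "k_16_rev"),
}

_FITTED_DEFAULTS = {
    "k_fwd": 0.1,       # cell #^-1 min^-1, shared by all dimerizations
    "k_4_rev": 80.0,    # γc off IL2·IL2Ra·γc; sets a slow β off-rate for the
                        # quaternary complex through detailed balance
    "k_16_rev": 80.0,   # IL-15 slots mirror the IL-2 defaults
    "k_17_rev": 1.5,
    "k_22_rev": 12.0,
    "k_23_rev": 63.0,
    "k_27_rev": 0.05,   # γc off IL7·IL7Ra·γc (tighter γc dimerization than IL-4)
    "k_33_rev": 5.0,    # γc off IL4·IL4Ra·γc
    "k_31_rev": 0.5,
    "k_35_rev": 1.0,
}


def default_rate_table() -> RateTable:
    """Literature + placeholder rate constants, detailed balance enforced.

    k_bnd = 1e7 M^-1 s^-1 = 0.6 nM^-1 min^-1; binary reverse rates are
    KD x k_bnd from the printed literature affinities; k_5/k_10/k_11 are the
    experimentally measured 1.5/12/63 min^-1; everything else is a documented
    placeholder flagged as fitted.
    """
    k_bnd = 1e7 * 60.0 * 1e-9  # M^-1 s^-1 -> nM^-1 min^-1
    values = {"k_bnd": k_bnd, "endosomal_penalty": 5.0}
    for lig in LIGANDS:
        slots = RATE_SLOTS[lig]
        if lig in ALPHA_CHAIN:
            values[slots["bind_a"]] = LITERATURE_KD_NM[(lig, ALPHA_CHAIN[lig])] * k_bnd
            values[slots["bind_b"]] = LITERATURE_KD_NM[(lig, PRIVATE_CHAIN[lig])] * k_bnd
        else:
            values[slots["bind_r"]] = LITERATURE_KD_NM[(lig, PRIVATE_CHAIN[lig])] * k_bnd
    values["k_5_rev"] = 1.5
    values["k_10_rev"] = 12.0
    values["k_11_rev"] = 63.0
    values.update(_FITTED_DEFAULTS)
    table = RateTable(values=values, fitted=frozenset(_FITTED_DEFAULTS))
    return enforce_detailed_balance(table)


def enforce_detailed_balance(rates: RateTable) -> RateTable:
    """Overwrite dependent reverse rates so every binding cycle is balanced.

    Because forward rates are shared (k_bnd for ligand binding, k_fwd for
    dimerization) they cancel around every cycle, so cycle closure reduces to
    products of reverse rates.  Independent rates are left untouched;
    idempotent on an already-balanced table.
    """
    vals = dict(rates.values)
    independent = [k for k in vals if k not in _DEPENDENT]
    for k in independent:
        if k in ("endosomal_penalty",):
            continue
        if not (vals[k] > 0):
            raise ValueError(f"independent rate {k} must be positive, got {vals[k]}")
    for dep, (num1, num2, den) in _DEPENDENT.items():
        vals[dep] = vals[num1] * vals[num2] / vals[den]
    return replace(rates, values=vals)


@dataclass(frozen=True)
class TraffickingParams:
    """Endocytosis / sorting / recycling / degradation parameters.

    Active complexes are endocytosed at k_endo_active and sort to the
    lysosome with fraction exactly 1 (no recycling); inactive species use
    k_endo and f_sort.  phi is the endosomal membrane area as a fraction of
    the plasma membrane; v_endo_fL the endosomal volume in femtoliters.
    """

    k_endo: float = 0.08
    k_endo_active: float = 0.8
    f_sort: float = 1.0 / 3.0
    k_rec: float = 0.1
    k_deg: float = 0.05
    phi: float = 0.5
    v_endo_fL: float = 10.0

    def __post_init__(self):
        for name in ("k_endo", "k_endo_active", "k_rec", "k_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.f_sort < 1.0):
            raise ValueError("f_sort must lie in (0, 1)")
        if self.phi <= 0 or self.v_endo_fL <= 0:
            raise ValueError("phi and v_endo_fL must be positive")


def endosome_concentration(count: float, v_endo_fL: float = 10.0) -> float:
    """Convert molecules/cell in the endosomal volume to nM."""
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("molecule count must be non-negative")
    out = count / (AVOGADRO * v_endo_fL * 1e-15) * 1e9
    return float(out) if out.ndim == 0 else out


def molecules_from_nM(conc_nM: float, v_endo_fL: float = 10.0) -> float:
    """Inverse of :func:`endosome_concentration`."""
    conc_nM = np.asarray(conc_nM, dtype=float)
    if np.any(conc_nM < 0):
        raise ValueError("concentration must be non-negative")
    out = conc_nM * 1e-9 * AVOGADRO * v_endo_fL * 1e-15
    return float(out) if out.ndim == 0 else out


@dataclass
class SystemState:
    """Labeled system state: two membrane compartments plus ligand pools.

    ``surface`` / ``endosomal`` are #/cell (endosomal entries are
    area-normalized: total molecules = phi x value); ligand pools are nM.
    """

    network: NetworkSpec
    surface: np.ndarray
    endosomal: np.ndarray
    ligand_endosomal: np.ndarray
    ligand_extracellular: np.ndarray

    @classmethod
    def zeros(cls, network: NetworkSpec) -> "SystemState":
        n, m = network.n_comp_species, len(network.ligands)
        return cls(network, np.zeros(n), np.zeros(n), np.zeros(m), np.zeros(m))

    @classmethod
    def from_vector(cls, network: NetworkSpec, y, ligand_extracellular=None):
        n, m = network.n_comp_species, len(network.ligands)
        y = np.asarray(y, dtype=float)
        ext = np.zeros(m) if ligand_extracellular is None else np.asarray(ligand_extracellular, float)
        return cls(network, y[:n].copy(), y[n:2 * n].copy(), y[2 * n:].copy(), ext.copy())

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.surface, self.endosomal, self.ligand_endosomal])

    def __getitem__(self, label: str) -> float:
        idx = self.network.species_index[label]
        return self.as_vector()[idx]

    def chain_total(self, receptor: str, phi: float = 0.5) -> float:
        """Conserved total of one receptor chain: surface + phi x endosome.

        The phi weight converts area-normalized endosomal abundances to total
        molecules; pass the phi of the TraffickingParams in use.
        """
        r = self.network.receptors.index(receptor)
        w = self.network.composition[:, r]
        return float(w @ self.surface + phi * (w @ self.endosomal))


@_njit(cache=True)
def _rhs_kernel(y, ext, n, m,
                b_lig, b_rec, b_cpx, b_kr_s, b_kr_e,
                d_i, d_j, d_cpx, d_kr_s, d_kr_e,
                k_bnd, k_fwd, k_endo_vec, f_sort_vec,
                k_rec, k_deg, phi, conv, synthesis):  # pragma: no cover - jitted
    out = np.zeros(2 * n + m)
    for k in range(b_lig.shape[0]):
        r, c, l = b_rec[k], b_cpx[k], b_lig[k]
        fs = k_bnd * ext[l] * y[r] - b_kr_s[k] * y[c]
        out[r] -= fs
        out[c] += fs
        fe = k_bnd * y[2 * n + l] * y[n + r] - b_kr_e[k] * y[n + c]
        out[n + r] -= fe
        out[n + c] += fe
        out[2 * n + l] -= conv * phi * fe
    for k in range(d_i.shape[0]):
        i, j, c = d_i[k], d_j[k], d_cpx[k]
        fs = k_fwd * y[i] * y[j] - d_kr_s[k] * y[c]
        out[i] -= fs
        out[j] -= fs
        out[c] += fs
        fe = k_fwd * y[n + i] * y[n + j] - d_kr_e[k] * y[n + c]
        out[n + i] -= fe
        out[n + j] -= fe
        out[n + c] += fe
    for k in range(n):
        rec_flux = k_rec * (1.0 - f_sort_vec[k]) * y[n + k]
        out[k] += synthesis[k] - k_endo_vec[k] * y[k] + rec_flux * phi
        out[n + k] += k_endo_vec[k] * y[k] / phi - rec_flux - k_deg * f_sort_vec[k] * y[n + k]
    for l in range(m):
        out[2 * n + l] -= k_deg * y[2 * n + l]
    return out


class CompiledRHS:
    """Vectorized right-hand side of the two-compartment ODE system.

    Instances are callables ``f(t, y) -> dy/dt`` over the dynamic state
    ``y = [surface, endosomal, endosomal ligand]`` with extracellular ligand
    clamped to ``ext_ligand``.
    """

    def __init__(self, network: NetworkSpec, rates: RateTable,
                 traffic: TraffickingParams, synthesis, ext_ligand):
        self.network = network
        n = network.n_comp_species
        self.n = n
        self.m = len(network.ligands)
        rates.validate()

        binds = [r for r in network.reactions if r.kind == "bind"]
        dims = [r for r in network.reactions if r.kind == "dim"]
        self.b_lig = np.array([r.i for r in binds], dtype=np.intp)
        self.b_rec = np.array([r.j for r in binds], dtype=np.intp)
        self.b_cpx = np.array([r.product for r in binds], dtype=np.intp)
        self.b_kr_s = np.array([rates[r.rev_key] for r in binds])
        self.b_kr_e = np.array([rates.endo_rev(r.rev_key) for r in binds])
        self.d_i = np.array([r.i for r in dims], dtype=np.intp)
        self.d_j = np.array([r.j for r in dims], dtype=np.intp)
        self.d_cpx = np.array([r.product for r in dims], dtype=np.intp)
        self.d_kr_s = np.array([rates[r.rev_key] for r in dims])
        self.d_kr_e = np.array([rates.endo_rev(r.rev_key) for r in dims])
        self.k_bnd = rates["k_bnd"]
        self.k_fwd = rates["k_fwd"]
        # dense stoichiometry matrices (species x reaction); flux scatter is
        # then a small matmul, much cheaper than indexed accumulation
        self.S_bind = np.zeros((n, len(binds)))
        self.L_bind = np.zeros((len(network.ligands), len(binds)))
        for k, r in enumerate(binds):
            self.S_bind[r.j, k] -= 1.0
            self.S_bind[r.product, k] += 1.0
            self.L_bind[r.i, k] = 1.0
        self.S_dim = np.zeros((n, len(dims)))
        for k, r in enumerate(dims):
            self.S_dim[r.i, k] -= 1.0
            self.S_dim[r.j, k] -= 1.0
            self.S_dim[r.product, k] += 1.0

        self.k_endo_vec = np.where(network.active_mask, traffic.k_endo_active, traffic.k_endo)
        self.f_sort_vec = np.where(network.active_mask, 1.0, traffic.f_sort)
        self.traffic = traffic
        self.conv = 1e9 / (AVOGADRO * traffic.v_endo_fL * 1e-15)  # molecules -> nM

        self.synthesis = np.zeros(n)
        if synthesis:
            for rec, v in synthesis.items():
                if rec not in RECEPTORS:
                    raise ValueError(f"unknown receptor in synthesis table: {rec!r}")
                if v < 0:
                    raise ValueError(f"synthesis rate for {rec} must be non-negative")
                if rec in network.receptors:  # chains outside this network are inert
                    self.synthesis[network.species.index(rec)] = v
        self.ext_ligand = np.zeros(self.m) if ext_ligand is None else np.asarray(ext_ligand, float)

    def __call__(self, t, y):
        tr = self.traffic
        if _HAVE_NUMBA:
            return _rhs_kernel(
                np.asarray(y, dtype=np.float64), self.ext_ligand, self.n, self.m,
                self.b_lig, self.b_rec, self.b_cpx, self.b_kr_s, self.b_kr_e,
                self.d_i, self.d_j, self.d_cpx, self.d_kr_s, self.d_kr_e,
                self.k_bnd, self.k_fwd, self.k_endo_vec, self.f_sort_vec,
                tr.k_rec, tr.k_deg, tr.phi, self.conv, self.synthesis,
            )
        n = self.n
        surf = y[:n]
        endo = y[n:2 * n]
        lig = y[2 * n:]

        # ligand association/dissociation, then dimerization fluxes
        fb_s = self.k_bnd * self.ext_ligand[self.b_lig] * surf[self.b_rec] - self.b_kr_s * surf[self.b_cpx]
        fb_e = self.k_bnd * lig[self.b_lig] * endo[self.b_rec] - self.b_kr_e * endo[self.b_cpx]
        fd_s = self.k_fwd * surf[self.d_i] * surf[self.d_j] - self.d_kr_s * surf[self.d_cpx]
        fd_e = self.k_fwd * endo[self.d_i] * endo[self.d_j] - self.d_kr_e * endo[self.d_cpx]

        # trafficking between compartments
        rec_flux = tr.k_rec * (1.0 - self.f_sort_vec) * endo
        ds = (self.synthesis + self.S_bind @ fb_s + self.S_dim @ fd_s
              - self.k_endo_vec * surf + rec_flux * tr.phi)
        de = (self.S_bind @ fb_e + self.S_dim @ fd_e
              + self.k_endo_vec * surf / tr.phi - rec_flux - tr.k_deg * self.f_sort_vec * endo)
        # free endosomal ligand fully sorts to the lysosome
        dl = -tr.k_deg * lig - self.conv * tr.phi * (self.L_bind @ fb_e)
        return np.concatenate([ds, de, dl])


def assemble_rhs(network: NetworkSpec, rates: RateTable, traffic: TraffickingParams,
                 synthesis=None, ext_ligand=None) -> CompiledRHS:
    """Build a reusable, vectorized ODE right-hand side."""
    return CompiledRHS(network, rates, traffic, synthesis, ext_ligand)


def rhs(state: SystemState, rates: RateTable, traffic: TraffickingParams,
        synthesis=None) -> SystemState:
    """Time derivative of a labeled state (validating convenience wrapper).

    Extracellular ligand is clamped: its derivative is exactly zero.
    """
    y = state.as_vector()
    if np.any(y < 0) or np.any(state.ligand_extracellular < 0):
        raise ValueError("state must be non-negative")
    f = assemble_rhs(state.network, rates, traffic, synthesis, state.ligand_extracellular)
    dy = f(0.0, y)
    out = SystemState.from_vector(state.network, dy, np.zeros(len(state.network.ligands)))
    return out
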