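"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's vectorized/compiled code paths: the
ODE right-hand side is evaluated reaction by reaction with python floats and
lists, thermodynamic cycles are checked by exhaustive assembly-path
enumeration, and the binding equilibrium is solved from conservation +
equilibrium-constant relations.
"""

import numpy as np

AVOGADRO = 6.02214076e23


def rhs_reaction_list(network, rates, traffic, synthesis, ext_ligand, y):
    """Naive per-reaction evaluation of the two-compartment derivative."""
    n = network.n_comp_species
    m = len(network.ligands)
    ds = [0.0] * n
    de = [0.0] * n
    dl = [0.0] * m
    conv = 1e9 / (AVOGADRO * traffic.v_endo_fL * 1e-15)
    pen = rates.endosomal_penalty

    for r in network.reactions:
        kr = rates[r.rev_key]
        kr_e = kr * pen * rates.endo_rev_scale.get(r.rev_key, 1.0)
        if r.kind == "bind":
            flux_s = rates["k_bnd"] * ext_ligand[r.i] * y[r.j] - kr * y[r.product]
            ds[r.j] -= flux_s
            ds[r.product] += flux_s
            flux_e = rates["k_bnd"] * y[2 * n + r.i] * y[n + r.j] - kr_e * y[n + r.product]
            de[r.j] -= flux_e
            de[r.product] += flux_e
            dl[r.i] -= conv * traffic.phi * flux_e
        else:
            flux_s = rates["k_fwd"] * y[r.i] * y[r.j] - kr * y[r.product]
            ds[r.i] -= flux_s
            ds[r.j] -= flux_s
            ds[r.product] += flux_s
            flux_e = rates["k_fwd"] * y[n + r.i] * y[n + r.j] - kr_e * y[n + r.product]
            de[r.i] -= flux_e
            de[r.j] -= flux_e
            de[r.product] += flux_e

    for k in range(n):
        active = bool(network.active_mask[k])
        k_endo = traffic.k_endo_active if active else traffic.k_endo
        f_sort = 1.0 if active else traffic.f_sort
        ds[k] += -k_endo * y[k] + traffic.k_rec * (1 - f_sort) * y[n + k] * traffic.phi
        de[k] += (k_endo * y[k] / traffic.phi
                  - traffic.k_rec * (1 - f_sort) * y[n + k]
                  - traffic.k_deg * f_sort * y[n + k])
    for rec, v in (synthesis or {}).items():
        if rec in network.receptors:
            ds[network.species.index(rec)] += v
    for j in range(m):
        dl[j] -= traffic.k_deg * y[2 * n + j]
    return np.array(ds + de + dl)


def cycle_products(network, rates):
    """K_eq products around every independent assembly cycle.

    Each complex can be reached along multiple assembly paths; detailed
    balance requires the product of step equilibrium constants to be
    path-independent.  We enumerate paths through the complex lattice per
    ligand and compare the resulting formation constants.
    """
    products = []
    for lig in network.ligands:
        # formation constant of every complex relative to free components
        formation = {}
        # iterate to fixed point over reactions of this ligand
        changed = True
        paths = {}
        while changed:
            changed = False
            for r in network.reactions:
                label = network.species[r.product]
                if network.ligand_of_species.get(label) != lig:
                    continue
                keq = (rates["k_bnd"] if r.kind == "bind" else rates["k_fwd"]) / rates[r.rev_key]
                if r.kind == "bind":
                    base = 1.0
                else:
                    src = network.species[r.i]
                    if src not in formation:
                        continue
                    base = formation[src]
                val = base * keq
                paths.setdefault(label, []).append(val)
                if label not in formation:
                    formation[label] = val
                    changed = True
        for label, vals in paths.items():
            for v in vals[1:]:
                products.append(v / vals[0])
    return np.array(products)


def equilibrium_no_trafficking(kds, totals, ligand_conc):
    """Brute-force binding equilibrium of the 9-species α-ligand subsystem.

    kds: dict of per-step dissociation constants in concentration-free form
    (complex = K_step x reactant x partner):
      K_la = k_bnd/k1 (per nM), K_lb = k_bnd/k2,
      K_lag = k_fwd/k4, K_lbg = k_fwd/k5, K_lab_b = k_fwd/k11,
      K_labg_g = k_fwd/k10.
    Solves conservation for free alpha, beta, gamma by scipy root finding.
    """
    from scipy.optimize import brentq

    L = ligand_conc
    K_la, K_lb = kds["K_la"], kds["K_lb"]
    K_lag, K_lbg = kds["K_lag"], kds["K_lbg"]
    K_lab_b, K_labg_g = kds["K_lab_b"], kds["K_labg_g"]

    def complexes(a, b, g):
        la = K_la * L * a
        lb = K_lb * L * b
        lab = K_lab_b * la * b
        lag = K_lag * la * g
        lbg = K_lbg * lb * g
        labg = K_labg_g * lab * g
        return la, lb, lab, lag, lbg, labg

    def solve_a(b, g):
        def f(a):
            la, lb, lab, lag, lbg, labg = complexes(a, b, g)
            return a + la + lab + lag + labg - totals["a"]
        return brentq(f, 0, totals["a"], xtol=1e-14)

    def resid(bg):
        b, g = bg
        a = solve_a(b, g)
        la, lb, lab, lag, lbg, labg = complexes(a, b, g)
        return [b + lb + lab + lbg + labg - totals["b"],
                g + lag + lbg + labg - totals["g"]]

    from scipy.optimize import fsolve

    sol, info, ier, msg = fsolve(resid, [totals["b"] / 2, totals["g"] / 2],
                                 full_output=True, xtol=1e-13)
    assert ier == 1, msg
    b, g = sol
    a = solve_a(b, g)
    la, lb, lab, lag, lbg, labg = complexes(a, b, g)
    return {"a": a, "b": b, "g": g, "la": la, "lb": lb, "lab": lab,
            "lag": lag, "lbg": lbg, "labg": labg}
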