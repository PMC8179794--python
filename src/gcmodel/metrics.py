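"""Dose-response metrics, cell-type specificity, and mutein engineering.

EC50s are extracted by unbounded non-linear least squares fits of a Hill
function.  Specificity — the ratio of a target cell type's normalized pSTAT
response to an off-target cell type's — quantifies how selectively a ligand
activates, e.g., regulatory T cells over NK or helper T cells.  Sensitivity
of that specificity to each surface or endosomal reverse binding rate is
computed on the log-rate scale so that rates of different magnitudes are
comparable; engineered IL-2 muteins are represented by fold-changes of the
IL-2Rα and IL-2Rβ/γc affinities relative to wild type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .network import RATE_SLOTS, RateTable, TraffickingParams, enforce_detailed_balance
from .simulate import dose_response_grid

__all__ = [
    "HillFit",
    "MuteinSpec",
    "SpecificityReport",
    "fit_hill",
    "specificity",
    "specificity_gradient",
    "apply_mutein",
    "WT_KD_IL2RA_NM",
]

#: wild-type IL-2 dissociation constant for IL-2Rα (nM)
WT_KD_IL2RA_NM = 10.0


@dataclass(frozen=True)
class HillFit:
    """Hill curve fit: baseline + amplitude * x^n / (EC50^n + x^n)."""

    ec50: float          # nM
    hill: float
    amplitude: float
    baseline: float
    residual_norm: float

    def predict(self, doses) -> np.ndarray:
        x = np.asarray(doses, dtype=float)
        xn = x**self.hill
        return self.baseline + self.amplitude * xn / (self.ec50**self.hill + xn)


def fit_hill(doses, responses) -> HillFit:
    """Least-squares Hill fit of a dose-response curve.

    The fit is unbounded in amplitude/baseline/Hill coefficient (a negative
    fitted baseline is reported, not clipped); EC50 is parameterized on the
    log scale, which keeps it positive without imposing a bound.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct doses for a Hill fit")
    if np.any(x < 0):
        raise ValueError("doses must be non-negative")

    span = float(y.max() - y.min())
    if span == 0:
        raise ValueError("degenerate dose-response: all responses equal")
    half = y.min() + span / 2.0
    above = x[y >= half]
    ec50_0 = float(above.min()) if above.size and above.min() > 0 else float(np.median(x[x > 0]))

    def resid(p):
        log_ec50, n, amp, base = p
        xn = np.power(x, n, where=x > 0, out=np.zeros_like(x))
        return base + amp * xn / (np.exp(log_ec50 * n) + xn) - y

    p0 = np.array([np.log(ec50_0), 1.0, span, y.min()])
    sol = least_squares(resid, p0, method="lm", max_nfev=10_000)
    if not sol.success:
        raise RuntimeError(f"Hill fit did not converge: {sol.message} (x0={p0})")
    log_ec50, n, amp, base = sol.x
    return HillFit(ec50=float(np.exp(log_ec50)), hill=float(n), amplitude=float(amp),
                   baseline=float(base), residual_norm=float(np.linalg.norm(sol.fun)))


@dataclass(frozen=True)
class MuteinSpec:
    """An engineered IL-2 variant, characterized by its measured affinities."""

    name: str
    kd_il2ra_nM: float
    kd_il2rbg_nM: float
    fc_orientation: str = "none"   # "N-terminal" | "C-terminal" | "none"

    def __post_init__(self):
        if self.kd_il2ra_nM <= 0 or self.kd_il2rbg_nM <= 0:
            raise ValueError(f"mutein {self.name!r}: dissociation constants must be positive")


@dataclass(frozen=True)
class SpecificityReport:
    target: str
    off_target: str
    dose_nM: float
    time_min: float
    value: float


def _normalize_by_max(responses: dict) -> dict:
    out = {}
    for cell, series in responses.items():
        arr = np.asarray(series, dtype=float)
        m = arr.max()
        if m <= 0:
            raise ValueError(f"cell {cell!r} has no positive response to normalize by")
        out[cell] = arr / m
    return out


def specificity(responses: dict, doses, target: str, off_target: str,
                dose_nM: float = 0.038, time_min: float = 60.0) -> SpecificityReport:
    """Ratio of target to off-target normalized pSTAT at one dose.

    ``responses`` maps cell name -> response array over ``doses`` (already at
    the readout time).  Each cell's curve is normalized by its own maximum
    before the ratio, so the pSTAT scale factor cancels.
    """
    doses = np.asarray(doses, dtype=float)
    norm = _normalize_by_max({c: responses[c] for c in (target, off_target)})
    k = int(np.argmin(np.abs(doses - dose_nM)))
    off = norm[off_target][k]
    if off <= 0:
        raise ValueError(f"off-target {off_target!r} response is zero at {dose_nM} nM")
    return SpecificityReport(target=target, off_target=off_target,
                             dose_nM=float(doses[k]), time_min=time_min,
                             value=float(norm[target][k] / off))


def _specificity_value(rates: RateTable, traffic: TraffickingParams, profiles: dict,
                       target: str, off_target: str, ligand: str, doses,
                       dose_nM: float, time_min: float, rtol: float) -> float:
    grid = dose_response_grid([profiles[target], profiles[off_target]], [ligand],
                              doses, [time_min], rates, traffic, rtol=rtol)
    resp = {c: grid.sel(cell=c).values[:, 0] for c in (target, off_target)}
    return specificity(resp, doses, target, off_target, dose_nM, time_min).value


def specificity_gradient(rates: RateTable, traffic: TraffickingParams, profiles: dict,
                         target: str = "Treg", off_target: str = "NK",
                         ligand: str = "IL2", doses=None, dose_nM: float = 0.038,
                         time_min: float = 60.0, compartment: str = "surface",
                         rel_step: float = 1e-2, check_step: float = 1e-3,
                         rate_keys=None, rtol: float = 1e-7) -> dict:
    """d(specificity)/d(log k_rev) per reverse rate, by central differences.

    ``compartment`` selects whether the surface copy or the endosomal copy of
    each reverse rate is perturbed (endosomal rates can be varied
    independently through the per-rate endosomal scale).  Each derivative is
    verified against a refined step; disagreement beyond 1% emits a warning
    carrying both estimates.
    """
    if compartment not in ("surface", "endosome"):
        raise ValueError("compartment must be 'surface' or 'endosome'")
    if doses is None:
        doses = np.logspace(-3, 1, 7)
    if rate_keys is None:
        rate_keys = sorted(
            {k for lig in (ligand,) for k in RATE_SLOTS[lig].values()}
        )

    def perturbed(key: str, h: float) -> RateTable:
        if compartment == "surface":
            # scale the base rate; cancel it in the endosome so only the
            # surface copy moves
            new = rates.with_updates(**{key: rates[key] * np.exp(h)})
            scl = dict(rates.endo_rev_scale)
            scl[key] = scl.get(key, 1.0) * np.exp(-h)
            return replace(new, endo_rev_scale=scl)
        scl = dict(rates.endo_rev_scale)
        scl[key] = scl.get(key, 1.0) * np.exp(h)
        return replace(rates, endo_rev_scale=scl)

    def central(key: str, h: float) -> float:
        up = _specificity_value(perturbed(key, h), traffic, profiles, target,
                                off_target, ligand, doses, dose_nM, time_min, rtol)
        dn = _specificity_value(perturbed(key, -h), traffic, profiles, target,
                                off_target, ligand, doses, dose_nM, time_min, rtol)
        return (up - dn) / (2.0 * h)

    out = {}
    for key in rate_keys:
        d1 = central(key, rel_step)
        d2 = central(key, check_step)
        ref = max(abs(d1), abs(d2))
        if ref > 1e-9 and abs(d1 - d2) > 0.01 * ref:
            warnings.warn(
                f"finite-difference check for {key} ({compartment}): "
                f"step {rel_step} gives {d1:.4g}, step {check_step} gives {d2:.4g}",
                stacklevel=2,
            )
        out[key] = d2
    return out


def apply_mutein(rates: RateTable, spec: MuteinSpec, wildtype: MuteinSpec) -> RateTable:
    """Map measured mutein affinities onto the IL-2 rate constants.

    The IL-2Rα off-rate scales by the KD fold-change; the composite
    IL-2Rβ/γc affinity change is applied as one uniform fold on the β
    binding and γc-dimerization reverse rates.  Detailed balance is
    re-enforced afterward, so the dependent rates follow.
    """
    fold_a = spec.kd_il2ra_nM / wildtype.kd_il2ra_nM
    fold_bg = spec.kd_il2rbg_nM / wildtype.kd_il2rbg_nM
    new = rates.with_updates(
        k_1_rev=rates["k_1_rev"] * fold_a,
        k_2_rev=rates["k_2_rev"] * fold_bg,
        k_4_rev=rates["k_4_rev"] * fold_bg,
        k_5_rev=rates["k_5_rev"] * fold_bg,
        k_10_rev=rates["k_10_rev"] * fold_bg,
    )
    return enforce_detailed_balance(new)
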