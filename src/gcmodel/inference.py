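"""Bayesian estimation of unknown model parameters.

Unknown reaction rates, trafficking parameters, receptor abundances, and
readout scale factors are inferred from dose-response and receptor
internalization measurements by Markov chain Monte Carlo.  The likelihood is
Gaussian, built from the sum of squared errors between model predictions and
observations with one noise scale per dataset (fitted with a weak
half-normal prior unless fixed); priors are lognormal with log-scale
standard deviation 0.1 around documented centers, except the endosomal
sorting fraction f_sort which carries a Beta(20, 40) prior.  Detailed
balance is re-enforced at every likelihood evaluation, so fitted independent
rates always propagate to the dependent ones.

Sampling uses the affine-invariant ensemble sampler (emcee); each walker is
treated as a chain for the Geweke convergence diagnostic.  A no-trafficking
model variant (all trafficking rates zero, surface receptor abundances
fitted directly as constants) is provided for model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import emcee
import numpy as np
import pandas as pd
from scipy import stats

from .network import (
    RateTable,
    SystemState,
    TraffickingParams,
    assemble_rhs,
    build_network,
    enforce_detailed_balance,
)
from .simulate import CellProfile, steady_state

__all__ = [
    "LogNormalPrior",
    "BetaPrior",
    "HalfNormalPrior",
    "FitDataset",
    "PosteriorSamples",
    "InferenceProblem",
    "MCMCConfig",
    "fit_mcmc",
    "geweke",
    "posterior_bands",
    "no_trafficking_variant",
]

_TRAFFIC_KEYS = ("k_endo", "k_endo_active", "f_sort", "k_rec", "k_deg")


@dataclass(frozen=True)
class LogNormalPrior:
    """Lognormal prior: log x ~ Normal(log center, sd)."""

    center: float
    sd: float = 0.1
    transform: str = "log"

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        z = (np.log(x) - np.log(self.center)) / self.sd
        return -np.log(x) - np.log(self.sd) - 0.5 * np.log(2 * np.pi) - 0.5 * z * z

    def sample(self, rng) -> float:
        return float(np.exp(rng.normal(np.log(self.center), self.sd)))

    @property
    def mean(self) -> float:
        return self.center * np.exp(self.sd**2 / 2)

    @property
    def std(self) -> float:
        return self.mean * np.sqrt(np.exp(self.sd**2) - 1.0)


@dataclass(frozen=True)
class BetaPrior:
    a: float = 20.0
    b: float = 40.0
    transform: str = "logit"

    def logpdf(self, x: float) -> float:
        if not 0 < x < 1:
            return -np.inf
        return float(stats.beta.logpdf(x, self.a, self.b))

    def sample(self, rng) -> float:
        return float(rng.beta(self.a, self.b))

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def std(self) -> float:
        ab = self.a + self.b
        return float(np.sqrt(self.a * self.b / (ab**2 * (ab + 1))))


@dataclass(frozen=True)
class HalfNormalPrior:
    scale: float = 1.0
    transform: str = "log"

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        return float(stats.halfnorm.logpdf(x, scale=self.scale))

    def sample(self, rng) -> float:
        return float(abs(rng.normal(0.0, self.scale)))

    @property
    def mean(self) -> float:
        return self.scale * np.sqrt(2 / np.pi)

    @property
    def std(self) -> float:
        return self.scale * np.sqrt(1 - 2 / np.pi)


@dataclass
class FitDataset:
    """One experiment: observations on a single cell profile.

    ``data`` columns: ligand, concentration_nM, time_min, readout, value
    (plus optional replicate); readout is "pSTAT" or "surface_fraction:<R>".
    pSTAT observations in the same scale_group share one fitted scale
    factor; sigma fixes the noise scale (None fits "sigma:<name>").
    """

    name: str
    profile: CellProfile
    data: pd.DataFrame
    scale_group: str = "default"
    sigma: float | None = None

    def __post_init__(self):
        required = {"ligand", "concentration_nM", "time_min", "readout", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset {self.name!r} missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.data["value"].to_numpy(dtype=float))):
            raise ValueError(f"dataset {self.name!r} has non-finite values")


@dataclass
class PosteriorSamples:
    """MCMC draws, labeled and reproducible given the seed."""

    draws: np.ndarray            # (n_chains, n_draws, ndim), natural scale
    param_names: list
    log_prob: np.ndarray         # (n_chains, n_draws)
    seed: int
    config: dict = field(default_factory=dict)

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def summary(self) -> pd.DataFrame:
        flat = self.flat()
        try:
            z = geweke(flat)  # pooled-chain Geweke per parameter
        except ValueError:    # too short for a spectral estimate
            z = np.full(flat.shape[1], np.nan)
        rows = []
        for k, name in enumerate(self.param_names):
            q = np.percentile(flat[:, k], [10, 25, 50, 75, 90])
            rows.append({
                "parameter": name, "median": q[2],
                "q10": q[0], "q25": q[1], "q75": q[3], "q90": q[4],
                "geweke_z": z[k],
            })
        return pd.DataFrame(rows)


def no_trafficking_variant(traffic: TraffickingParams) -> TraffickingParams:
    """Trafficking-free configuration: all transport rates zeroed.

    With no turnover, receptor abundance is a fixed constant rather than a
    synthesis/degradation balance, and all species stay on the surface.
    """
    return replace(traffic, k_endo=0.0, k_endo_active=0.0, k_rec=0.0, k_deg=0.0)


def initial_state_no_trafficking(network, profile: CellProfile) -> SystemState:
    """Surface-only initial state from fixed receptor abundances."""
    state = SystemState.zeros(network)
    for rec, x in profile.receptor_surface.items():
        if rec in network.receptors:
            state.surface[network.species.index(rec)] = x
    return state


class InferenceProblem:
    """Posterior over a named subset of model parameters.

    ``priors`` maps parameter names to prior objects; the parameter vector
    theta follows the priors' insertion order.  Recognized names: any rate
    key (k_fwd, k_4_rev, ...), trafficking keys, "scale:<group>",
    "sigma:<dataset>", and "surface:<receptor>" (receptor abundance of every
    dataset's profile; in the no-trafficking variant this is the fixed
    surface count).
    """

    def __init__(self, datasets, priors: dict, base_rates: RateTable,
                 base_traffic: TraffickingParams, no_trafficking: bool = False,
                 rtol: float = 1e-6, atol: float = 1e-4):
        self.datasets = list(datasets)
        self.priors = dict(priors)
        self.param_names = list(self.priors)
        self.base_rates = base_rates
        self.base_traffic = no_trafficking_variant(base_traffic) if no_trafficking else base_traffic
        self.no_trafficking = no_trafficking
        self.rtol = rtol
        self.atol = atol
        for ds in self.datasets:
            if ds.sigma is None and f"sigma:{ds.name}" not in self.priors:
                raise ValueError(f"dataset {ds.name!r}: sigma is neither fixed nor given a prior")
        ligands = sorted({str(l) for ds in self.datasets for l in ds.data["ligand"]})
        self._networks = {lig: build_network({lig}) for lig in ligands}
        self._plans = {ds.name: self._build_plan(ds) for ds in self.datasets}

    # -- parameter unpacking -------------------------------------------------
    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        p = dict(zip(self.param_names, theta))
        rate_updates = {k: v for k, v in p.items() if k in self.base_rates.values}
        rates = enforce_detailed_balance(self.base_rates.with_updates(**rate_updates))
        traffic = replace(self.base_traffic,
                          **{k: v for k, v in p.items() if k in _TRAFFIC_KEYS})
        scales = {k.split(":", 1)[1]: v for k, v in p.items() if k.startswith("scale:")}
        sigmas = {k.split(":", 1)[1]: v for k, v in p.items() if k.startswith("sigma:")}
        surfaces = {k.split(":", 1)[1]: v for k, v in p.items() if k.startswith("surface:")}
        return rates, traffic, scales, sigmas, surfaces

    def _profile(self, ds: FitDataset, surfaces: dict) -> CellProfile:
        if not surfaces:
            return ds.profile
        surf = dict(ds.profile.receptor_surface)
        surf.update(surfaces)
        return CellProfile(ds.profile.name, receptor_surface=surf)

    # -- prediction ----------------------------------------------------------
    def _build_plan(self, ds: FitDataset) -> list:
        """Precompute the integration groups of one dataset.

        One group per (ligand, concentration): the network, sorted positive
        observation times, and for each data row its position, time index,
        and readout.  This keeps the per-evaluation work to the integrations
        themselves.
        """
        plan = []
        df = ds.data.reset_index(drop=True)
        for (lig, conc), rows in df.groupby(["ligand", "concentration_nM"], sort=True):
            times = np.array(sorted({t for t in rows["time_min"] if t > 0}), dtype=float)
            t_of = {t: k for k, t in enumerate(times)}
            obs = []
            for pos, row in rows.iterrows():
                readout = str(row["readout"])
                if readout.startswith("pSTAT"):
                    kind, rec = "pstat", None
                elif readout.startswith("surface_fraction:"):
                    kind, rec = "surface", readout.split(":", 1)[1]
                else:
                    raise ValueError(f"unknown readout {readout!r}")
                t = float(row["time_min"])
                obs.append((pos, None if t == 0 else t_of[t], kind, rec))
            network = self._networks.get(str(lig))
            if network is None:
                network = self._networks.setdefault(str(lig), build_network({str(lig)}))
            plan.append({"ligand": str(lig), "conc": float(conc),
                         "network": network, "times": times, "obs": obs})
        return plan

    def predict_dataset(self, ds: FitDataset, rates, traffic, scale, surfaces=None):
        """Model predictions aligned with the rows of ``ds.data``."""
        from scipy.integrate import odeint

        profile = self._profile(ds, surfaces or {})
        plan = self._plans.get(ds.name) or self._build_plan(ds)
        out = np.empty(len(ds.data))
        for group in plan:
            network = group["network"]
            if self.no_trafficking:
                y0 = initial_state_no_trafficking(network, profile).as_vector()
                synthesis = None
            else:
                y0 = steady_state(network, profile, traffic).as_vector()
                synthesis = profile.synthesis(traffic)
            f = assemble_rhs(network, rates, traffic, synthesis, [group["conc"]])
            if group["times"].size:
                ys, info = odeint(lambda y, t: f(t, y), y0,
                                  np.concatenate([[0.0], group["times"]]),
                                  rtol=self.rtol, atol=self.atol, full_output=True,
                                  mxstep=100_000)
                if info["message"] != "Integration successful.":
                    raise RuntimeError(
                        f"ODE solver failed for {ds.name!r} at {group['conc']} nM: "
                        f"{info['message']}")
                ys = np.clip(ys[1:], 0.0, None)
            else:
                ys = np.empty((0, network.n_state))
            n = network.n_comp_species
            act_idx = np.flatnonzero(network.active_mask
                                     & (np.array([network.ligand_of_species.get(s)
                                                  for s in network.species]) == group["ligand"]))
            act = ys[:, act_idx].sum(axis=1) + traffic.phi * ys[:, n + act_idx].sum(axis=1)
            for pos, tk, kind, rec in group["obs"]:
                if kind == "pstat":
                    out[pos] = 0.0 if tk is None else scale * act[tk]
                else:
                    w = network.composition[:, network.receptors.index(rec)]
                    if self.no_trafficking:
                        base = profile.receptor_surface.get(rec, 0.0)
                    else:
                        base = steady_state(network, profile, traffic).surface @ w
                    if base <= 0:
                        raise ValueError(f"zero initial surface abundance of {rec}")
                    out[pos] = 100.0 if tk is None else 100.0 * (ys[tk, :n] @ w) / base
        return out

    # -- posterior -----------------------------------------------------------
    def log_prior(self, theta) -> float:
        return float(sum(pr.logpdf(x) for pr, x in zip(self.priors.values(), theta)))

    def log_likelihood(self, theta) -> float:
        rates, traffic, scales, sigmas, surfaces = self.unpack(theta)
        total = 0.0
        for ds in self.datasets:
            scale = scales.get(ds.scale_group, 1.0)
            sigma = ds.sigma if ds.sigma is not None else sigmas[ds.name]
            try:
                pred = self.predict_dataset(ds, rates, traffic, scale, surfaces)
            except (RuntimeError, ValueError) as exc:
                warnings.warn(f"solver failure for dataset {ds.name!r}: {exc}", stacklevel=2)
                return -np.inf
            resid = pred - ds.data["value"].to_numpy(dtype=float)
            n = resid.size
            total += -0.5 * n * np.log(2 * np.pi * sigma**2) - 0.5 * np.sum(resid**2) / sigma**2
        return float(total)

    def log_posterior(self, theta) -> float:
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.log_likelihood(theta)
        return lp + ll if np.isfinite(ll) else -np.inf

    # -- transforms for unconstrained sampling --------------------------------
    def to_unconstrained(self, theta):
        z = []
        for pr, x in zip(self.priors.values(), theta):
            z.append(np.log(x) if pr.transform == "log" else np.log(x / (1 - x)))
        return np.asarray(z)

    def to_natural(self, z):
        x = []
        for pr, v in zip(self.priors.values(), z):
            x.append(np.exp(v) if pr.transform == "log" else 1.0 / (1.0 + np.exp(-v)))
        return np.asarray(x)

    def log_posterior_unconstrained(self, z) -> float:
        theta = self.to_natural(z)
        jac = 0.0
        for pr, x in zip(self.priors.values(), theta):
            jac += np.log(x) if pr.transform == "log" else np.log(x * (1 - x))
        lp = self.log_posterior(theta)
        return lp + jac if np.isfinite(lp) else -np.inf


@dataclass
class MCMCConfig:
    n_chains: int = 2
    n_draws: int = 1000
    warmup_frac: float = 0.5   # fraction of total raw steps spent on warm-up
    warmup_steps: int | None = None   # explicit raw warm-up steps (overrides frac)
    thin: int = 1              # keep every thin-th step (reduces autocorrelation)
    init: str = "map"          # walker init: small ball around the MAP, or "prior"
    seed: int = 0


def fit_mcmc(problem: InferenceProblem, config: MCMCConfig) -> PosteriorSamples:
    """Ensemble MCMC over the problem's parameters.

    ``n_chains`` x ``n_draws`` posterior draws are returned (walkers are the
    chains; at least 2 x ndim walkers are used, with the per-walker draw
    count adjusted so the total matches).  Fully reproducible given
    ``config.seed``.
    """
    if config.n_chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    ndim = len(problem.param_names)
    n_walkers = max(2 * ndim, config.n_chains)
    n_walkers += n_walkers % 2
    total = config.n_chains * config.n_draws
    n_steps = max(1, int(np.ceil(total / n_walkers)))   # kept (thinned) steps
    n_raw = n_steps * config.thin
    if config.warmup_steps is not None:
        n_warm = int(config.warmup_steps)
    else:
        n_warm = max(1, int(np.ceil(n_raw * config.warmup_frac / (1 - config.warmup_frac))))

    rng = np.random.default_rng(config.seed)
    if config.init == "map":
        # walkers start in a tight ball around the posterior mode (standard
        # ensemble-sampler initialization; removes most warm-up drift)
        from scipy.optimize import minimize

        z_center = problem.to_unconstrained(
            [pr.sample(rng) for pr in problem.priors.values()])
        res = minimize(lambda z: -problem.log_posterior_unconstrained(z), z_center,
                       method="Nelder-Mead",
                       options={"maxiter": 150 * ndim, "xatol": 1e-4, "fatol": 1e-4})
        z_center = res.x
        z0 = z_center[None, :] + 0.02 * rng.standard_normal((n_walkers, ndim))
    elif config.init == "prior":
        z0 = np.array([
            problem.to_unconstrained([pr.sample(rng) for pr in problem.priors.values()])
            for _ in range(n_walkers)
        ])
    else:
        raise ValueError(f"unknown init scheme {config.init!r}")
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, problem.log_posterior_unconstrained,
                                    moves=moves)
    sampler.random_state = np.random.RandomState(int(rng.integers(2**31))).get_state()
    state = sampler.run_mcmc(z0, n_warm, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_raw, progress=False)

    chain_z = sampler.get_chain(thin=config.thin)    # (n_steps, n_walkers, ndim)
    lp = sampler.get_log_prob(thin=config.thin).T    # (n_walkers, n_steps)
    draws = np.empty((n_walkers, n_steps, ndim))
    for w in range(n_walkers):
        for s in range(n_steps):
            draws[w, s] = problem.to_natural(chain_z[s, w])
    if not np.any(np.isfinite(lp)):
        raise RuntimeError("all chains diverged: no finite posterior values sampled")
    return PosteriorSamples(
        draws=draws, param_names=list(problem.param_names), log_prob=lp,
        seed=config.seed,
        config={"n_chains": config.n_chains, "n_draws": config.n_draws,
                "n_walkers": n_walkers, "n_steps": n_steps, "n_warmup": n_warm},
    )


def _spectral_var(x: np.ndarray) -> float:
    """Spectral-density-at-zero variance estimate (Bartlett-windowed)."""
    n = x.size
    x = x - x.mean()
    L = max(1, int(np.sqrt(n)))
    g0 = float(x @ x) / n
    s = g0
    for lag in range(1, min(L, n - 1) + 1):
        g = float(x[:-lag] @ x[lag:]) / n
        s += 2.0 * (1.0 - lag / (L + 1.0)) * g
    return max(s, 0.0)


def geweke(chain, first: float = 0.1, last: float = 0.5):
    """Geweke convergence z-score(s) comparing early and late chain segments.

    z = (mean_first - mean_last) / sqrt(S1(0)/n1 + S2(0)/n2) with spectral
    variance estimates; a zero-variance chain yields z = 0 (trivially
    stationary).  For a 2-D chain (draws x parameters) a z per parameter is
    returned.
    """
    x = np.asarray(chain, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
        squeeze = True
    else:
        squeeze = False
    n = x.shape[0]
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 100)")
    n1 = int(first * n)
    n2 = int(last * n)
    z = np.zeros(x.shape[1])
    for k in range(x.shape[1]):
        a, b = x[:n1, k], x[n - n2:, k]
        va, vb = _spectral_var(a), _spectral_var(b)
        denom = np.sqrt(va / n1 + vb / n2)
        z[k] = 0.0 if denom == 0 else (a.mean() - b.mean()) / denom
    return float(z[0]) if squeeze else z


def posterior_bands(samples: PosteriorSamples, predictor, n: int = 100,
                    quantiles=(10, 25, 75, 90), seed: int = 0) -> dict:
    """Pointwise quantile bands of ``predictor(theta)`` over posterior draws.

    ``predictor`` maps a parameter vector to an array of predictions; ``n``
    draws are selected (without replacement, seeded) and the requested
    percentiles are computed per prediction point.
    """
    flat = samples.flat()
    if n > flat.shape[0]:
        raise ValueError(f"requested {n} draws but only {flat.shape[0]} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.shape[0], size=n, replace=False)
    preds = np.vstack([np.atleast_1d(predictor(flat[i])) for i in idx])
    return {q: np.percentile(preds, q, axis=0) for q in quantiles}
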