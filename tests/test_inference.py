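import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from gcmodel import (
    BetaPrior,
    CellProfile,
    FitDataset,
    HalfNormalPrior,
    InferenceProblem,
    LogNormalPrior,
    MCMCConfig,
    StimulusProtocol,
    TraffickingParams,
    active_signal,
    build_network,
    default_rate_table,
    fit_mcmc,
    geweke,
    no_trafficking_variant,
    posterior_bands,
    simulate,
    steady_state,
)
from gcmodel.inference import initial_state_no_trafficking

from oracles import equilibrium_no_trafficking


def _dataset_from_model(rates, traffic, profile, doses, times, noise_cv=0.0, seed=0,
                        scale=1.0, rtol=1e-7):
    net = build_network({"IL2"})
    ss = steady_state(net, profile, traffic)
    synth = profile.synthesis(traffic)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for d in doses:
        traj = simulate(ss, StimulusProtocol.single_dose("IL2", d, times),
                        rates, traffic, synth, rtol=rtol)
        for t, a in zip(times, active_signal(traj, "IL2")):
            noise = np.exp(rng.normal(0, sigma)) if sigma > 0 else 1.0
            rows.append({"ligand": "IL2", "concentration_nM": d, "time_min": t,
                         "readout": "pSTAT", "value": scale * a * noise})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def small_problem(rates, traffic, treg):
    doses = np.logspace(-2.5, 0.5, 4)
    df = _dataset_from_model(rates, traffic, treg, doses, [60.0])
    ds = FitDataset("yt1", treg, df, scale_group="g", sigma=1.0)
    priors = {
        "k_fwd": LogNormalPrior(0.1),
        "k_endo_active": LogNormalPrior(0.8),
        "f_sort": BetaPrior(),
        "scale:g": LogNormalPrior(1.0),
    }
    return InferenceProblem([ds], priors, rates, traffic, rtol=1e-5)


class TestLogPosterior:
    def test_zero_sse_likelihood(self, small_problem):
        # perfect predictions with sigma = 1: loglik = -N/2 log(2 pi)
        theta = np.array([0.1, 0.8, 1 / 3, 1.0])
        n = len(small_problem.datasets[0].data)
        ll = small_problem.log_likelihood(theta)
        assert ll == pytest.approx(-0.5 * n * np.log(2 * np.pi), rel=1e-4)

    def test_residual_scaling(self, rates, traffic, treg, small_problem):
        # doubling every residual quadruples the SSE term
        theta = np.array([0.1, 0.8, 1 / 3, 1.0])
        ds = small_problem.datasets[0]
        n = len(ds.data)
        base = -0.5 * n * np.log(2 * np.pi)

        for delta in (5.0, 10.0):
            shifted = FitDataset("yt1", treg, ds.data.assign(value=ds.data["value"] + delta),
                                 scale_group="g", sigma=1.0)
            prob = InferenceProblem([shifted], small_problem.priors, rates, traffic, rtol=1e-5)
            sse = -2 * (prob.log_likelihood(theta) - base)
            if delta == 5.0:
                sse5 = sse
        assert sse == pytest.approx(4 * sse5, rel=1e-3)

    def test_matches_independent_prior_plus_sse(self, small_problem, rng):
        from scipy import stats

        theta = np.array([0.12, 0.7, 0.3, 1.1])
        ds = small_problem.datasets[0]
        rates2, traffic2, scales, _, _ = small_problem.unpack(theta)
        pred = small_problem.predict_dataset(ds, rates2, traffic2, scales["g"])
        sse = float(np.sum((pred - ds.data["value"].to_numpy()) ** 2))
        expected = (
            stats.lognorm.logpdf(theta[0], 0.1, scale=0.1)
            + stats.lognorm.logpdf(theta[1], 0.1, scale=0.8)
            + stats.beta.logpdf(theta[2], 20, 40)
            + stats.lognorm.logpdf(theta[3], 0.1, scale=1.0)
            - 0.5 * len(ds.data) * np.log(2 * np.pi) - 0.5 * sse
        )
        assert small_problem.log_posterior(theta) == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_dataset_order(self, rates, traffic, treg, nk):
        doses = np.logspace(-2, 0, 3)
        d1 = FitDataset("a", treg, _dataset_from_model(rates, traffic, treg, doses, [30.0]),
                        scale_group="g", sigma=2.0)
        d2 = FitDataset("b", nk, _dataset_from_model(rates, traffic, nk, doses, [30.0]),
                        scale_group="g", sigma=2.0)
        priors = {"k_fwd": LogNormalPrior(0.1), "scale:g": LogNormalPrior(1.0)}
        theta = np.array([0.11, 0.9])
        lp12 = InferenceProblem([d1, d2], priors, rates, traffic, rtol=1e-5).log_posterior(theta)
        lp21 = InferenceProblem([d2, d1], priors, rates, traffic, rtol=1e-5).log_posterior(theta)
        assert lp12 == pytest.approx(lp21, rel=1e-12)


class TestFitMCMC:
    def test_prior_recovery_from_empty_data(self, rates, traffic):
        priors = {
            "k_fwd": LogNormalPrior(0.1),
            "f_sort": BetaPrior(),
            "sigma:none": HalfNormalPrior(2.0),
        }
        prob = InferenceProblem([], priors, rates, traffic)
        samples = fit_mcmc(prob, MCMCConfig(n_chains=2, n_draws=2000, seed=11))
        flat = samples.flat()
        for k, (name, prior) in enumerate(priors.items()):
            se = prior.std / np.sqrt(200)  # generous ESS guess for 4000 correlated draws
            assert abs(flat[:, k].mean() - prior.mean) < 3 * max(se, 0.02 * prior.std + 1e-12), name
            assert flat[:, k].std() == pytest.approx(prior.std, rel=0.25), name

    def test_identical_seed_identical_draws(self, small_problem):
        cfg = MCMCConfig(n_chains=2, n_draws=12, seed=5)
        a = fit_mcmc(small_problem, cfg)
        b = fit_mcmc(small_problem, cfg)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.log_prob, b.log_prob)

    def test_requires_two_chains(self, small_problem):
        with pytest.raises(ValueError):
            fit_mcmc(small_problem, MCMCConfig(n_chains=1, n_draws=10, seed=0))


class TestGeweke:
    def test_constant_chain_is_stationary(self):
        assert geweke(np.ones(500)) == 0.0

    def test_iid_normal_chains_usually_converged(self):
        hits = 0
        for seed in range(20):
            z = geweke(np.random.default_rng(seed).normal(size=10_000))
            hits += abs(z) < 2
        assert hits >= 17  # ~95% coverage

    def test_mean_shift_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        x[1000:] += 5.0
        assert abs(geweke(x)) > 2

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke(np.arange(50.0))


class TestPosteriorBands:
    def _samples(self, draws):
        from gcmodel.inference import PosteriorSamples

        return PosteriorSamples(draws=draws, param_names=["a", "b"],
                                log_prob=np.zeros(draws.shape[:2]), seed=0)

    def test_degenerate_posterior_zero_width(self):
        draws = np.tile([[2.0, 3.0]], (1, 200, 1))
        bands = posterior_bands(self._samples(draws), lambda th: th * 2, n=100)
        for q in (10, 25, 75, 90):
            np.testing.assert_allclose(bands[q], [4.0, 6.0])

    def test_band_nesting_and_quantile_oracle(self, rng):
        draws = rng.normal(10, 2, size=(2, 300, 2))
        samples = self._samples(np.abs(draws))
        preds = []

        def predictor(th):
            preds.append(th.sum())
            return np.array([th.sum()])

        bands = posterior_bands(samples, predictor, n=150, seed=3)
        assert bands[10][0] <= bands[25][0] <= bands[75][0] <= bands[90][0]
        arr = np.array(preds)
        for q in (10, 25, 75, 90):
            assert bands[q][0] == pytest.approx(np.percentile(arr, q))

    def test_more_draws_than_available_rejected(self):
        draws = np.zeros((1, 50, 2))
        with pytest.raises(ValueError):
            posterior_bands(self._samples(draws), lambda th: th, n=100)


class TestNoTraffickingVariant:
    def test_transport_rates_zeroed(self, traffic):
        off = no_trafficking_variant(traffic)
        assert off.k_endo == off.k_endo_active == off.k_rec == off.k_deg == 0.0
        assert off.phi == traffic.phi

    def test_active_signal_is_surface_only(self, rates, traffic, treg):
        net = build_network({"IL2"})
        off = no_trafficking_variant(traffic)
        state0 = initial_state_no_trafficking(net, treg)
        traj = simulate(state0, StimulusProtocol.single_dose("IL2", 1.0, [120.0]),
                        rates, off, None)
        end = traj.state_at(-1)
        assert np.all(end.endosomal == 0)
        surface_active = end["surf/IL2:IL2Rb.gc"] + end["surf/IL2:IL2Ra.IL2Rb.gc"]
        assert active_signal(traj, "IL2")[-1] == pytest.approx(surface_active)

    def test_equilibrium_matches_algebraic_solution(self, rates, traffic, treg):
        net = build_network({"IL2"})
        off = no_trafficking_variant(traffic)
        state0 = initial_state_no_trafficking(net, treg)
        traj = simulate(state0, StimulusProtocol.single_dose("IL2", 0.2, [30_000.0]),
                        rates, off, None, rtol=1e-11, atol=1e-10)
        kb, kf = rates["k_bnd"], rates["k_fwd"]
        eq = equilibrium_no_trafficking(
            kds={"K_la": kb / rates["k_1_rev"], "K_lb": kb / rates["k_2_rev"],
                 "K_lag": kf / rates["k_4_rev"], "K_lbg": kf / rates["k_5_rev"],
                 "K_lab_b": kf / rates["k_11_rev"], "K_labg_g": kf / rates["k_10_rev"]},
            totals={"a": 3000.0, "b": 700.0, "g": 3000.0}, ligand_conc=0.2)
        assert active_signal(traj, "IL2")[-1] == pytest.approx(eq["lbg"] + eq["labg"], rel=1e-6)

    def test_underestimates_receptors_on_trafficking_data(self, rates, traffic, treg):
        # data generated WITH trafficking, fitted WITHOUT: the signaling-
        # limiting chain is inferred at a lower abundance than the truth
        doses = np.logspace(-3, 1.5, 6)
        df = _dataset_from_model(rates, traffic, treg, doses, [60.0])
        ds = FitDataset("d", treg, df, scale_group="g",
                        sigma=float(df["value"].max() * 0.05))
        priors = {
            "surface:IL2Rb": LogNormalPrior(700.0, sd=3.0),
            "surface:gc": LogNormalPrior(3000.0, sd=3.0),
            "scale:g": LogNormalPrior(1.0, sd=3.0),
        }
        prob = InferenceProblem([ds], priors, rates, traffic,
                                no_trafficking=True, rtol=1e-5)
        res = minimize(lambda z: -prob.log_posterior_unconstrained(z),
                       prob.to_unconstrained([700.0, 3000.0, 1.0]),
                       method="Nelder-Mead",
                       options={"maxiter": 300, "xatol": 1e-3, "fatol": 1e-3})
        fitted = dict(zip(prob.param_names, prob.to_natural(res.x)))
        assert fitted["surface:IL2Rb"] < 700.0
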