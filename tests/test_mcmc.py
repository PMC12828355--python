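"""Metropolis–Hastings sampler: correctness against analytic posteriors,
determinism, diagnostics and map fitting.

The conjugate-style oracle is a one-parameter isotropic-diffusivity model
whose posterior under the uniform prior is computed by grid integration.
"""

import numpy as np
import pytest

from microfit.compartments import Iso
from microfit.mcmc import (Chain, Noisemodel, Sampler, chain_diagnostics,
                           fit_maps, log_likelihood, mh_sample,
                           mh_sample_batch, posterior_summary,
                           two_stage_fit, two_stage_fit_batch)
from microfit.models import BiophysicalModel, Slot
from microfit.protocols import AcquisitionProtocol, ValidationError

from conftest import EXVIVO_GT


def iso_model(bounds=(0.1, 3.0)):
    return BiophysicalModel("iso-toy",
                            slots=[Slot("w", Iso, {"d": "d"})],
                            fraction_names=[], free={"d": bounds})


@pytest.fixture(scope="module")
def iso_setup():
    model = iso_model()
    protocol = AcquisitionProtocol(bval=[0.0, 0.5, 1.0, 2.0, 3.0])
    gt = {"d": 1.1}
    sigma = 0.03
    rng = np.random.default_rng(7)
    meas = model.signals(gt, protocol) + rng.normal(0, sigma, len(protocol))
    return model, protocol, meas, sigma


def grid_posterior_moments(model, protocol, meas, sigma, bounds,
                           ngrid=4001):
    """Oracle: posterior mean/std of d by direct grid integration."""
    d = np.linspace(*bounds, ngrid)
    ll = np.array([log_likelihood(meas, model.signals({"d": x}, protocol),
                                  sigma) for x in d])
    w = np.exp(ll - ll.max())
    w /= w.sum()
    mean = float((w * d).sum())
    std = float(np.sqrt((w * (d - mean) ** 2).sum()))
    return mean, std


class TestLogLikelihood:
    def test_perfect_fit_single_point(self):
        assert log_likelihood([1.0], [1.0], 1.0) == \
            pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_unit_residual(self):
        assert log_likelihood([1.0], [0.0], 1.0) == \
            pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5)

    def test_vectorized_equals_elementwise_sum(self, rng):
        meas = rng.normal(size=30)
        pred = rng.normal(size=30)
        total = log_likelihood(meas, pred, 0.2)
        bits = sum(log_likelihood([m], [p], 0.2)
                   for m, p in zip(meas, pred))
        assert total == pytest.approx(bits, abs=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError):
            log_likelihood([1.0], [1.0], 0.0)


class TestMHSampler:
    def test_zero_width_proposals_freeze_chain(self, iso_setup):
        model, protocol, meas, sigma = iso_setup
        s = Sampler(nsamples=50, burnin=10, proposal={"d": 0.0},
                    start={"d": 1.5})
        chain = mh_sample(model, meas, protocol, s,
                          Noisemodel(sigma_fixed=sigma),
                          np.random.default_rng(0))
        assert np.all(chain.draws == 1.5)

    def test_posterior_matches_grid_oracle(self, iso_setup):
        model, protocol, meas, sigma = iso_setup
        oracle_mean, oracle_std = grid_posterior_moments(
            model, protocol, meas, sigma, (0.1, 3.0))
        s = Sampler(nsamples=20000, burnin=2000, thinning=1)
        chain = mh_sample(model, meas, protocol, s,
                          Noisemodel(sigma_fixed=sigma),
                          np.random.default_rng(3))
        d = chain.posterior_draws()[:, 0]
        # crude MC standard error from the autocorrelated draws
        ess = max(len(d) / 20.0, 100.0)
        mcse = oracle_std / np.sqrt(ess)
        assert d.mean() == pytest.approx(oracle_mean, abs=3 * mcse)
        assert d.std() == pytest.approx(oracle_std, rel=0.25)

    def test_stationary_distribution_ks(self, iso_setup):
        # detailed-balance smoke test against the grid-integrated density
        from scipy.stats import ks_2samp
        model, protocol, meas, sigma = iso_setup
        grid = np.linspace(0.1, 3.0, 20001)
        ll = np.array([log_likelihood(
            meas, model.signals({"d": x}, protocol), sigma) for x in grid])
        w = np.exp(ll - ll.max())
        w /= w.sum()
        rng = np.random.default_rng(11)
        oracle_draws = rng.choice(grid, size=20000, p=w)
        s = Sampler(nsamples=52000, burnin=2000, thinning=10)
        chain = mh_sample(model, meas, protocol, s,
                          Noisemodel(sigma_fixed=sigma), rng)
        d = chain.posterior_draws(thinning=10)[:, 0]
        stat = ks_2samp(d, oracle_draws).statistic
        assert stat < 0.02

    def test_seeded_determinism(self, iso_setup):
        model, protocol, meas, sigma = iso_setup
        s = Sampler(nsamples=500, burnin=100)
        runs = [mh_sample(model, meas, protocol, s, Noisemodel(),
                          np.random.default_rng(42)) for _ in range(2)]
        np.testing.assert_array_equal(runs[0].draws, runs[1].draws)

    def test_wider_proposals_never_increase_acceptance(self, iso_setup):
        model, protocol, meas, sigma = iso_setup
        rates = []
        for width in (0.02, 0.1, 0.5, 2.0):
            s = Sampler(nsamples=3000, burnin=500,
                        proposal={"d": width}, start={"d": 1.1})
            chain = mh_sample(model, meas, protocol, s,
                              Noisemodel(sigma_fixed=sigma),
                              np.random.default_rng(5))
            rates.append(chain.accepted[500:].mean())
        assert np.all(np.diff(rates) <= 0.01)

    def test_out_of_model_params_rejected(self, iso_setup):
        model, protocol, meas, _ = iso_setup
        s = Sampler(params=["nonexistent"], nsamples=10, burnin=1)
        with pytest.raises(ValidationError):
            mh_sample(model, meas, protocol, s, Noisemodel(),
                      np.random.default_rng(0))

    def test_batch_matches_scalar_statistics(self, iso_setup):
        model, protocol, meas, sigma = iso_setup
        s = Sampler(nsamples=6000, burnin=1000, thinning=1)
        nm = Noisemodel(sigma_fixed=sigma)
        scalar = mh_sample(model, meas, protocol, s, nm,
                           np.random.default_rng(1))
        batch = mh_sample_batch(model, meas[None, :], protocol, s, nm,
                                np.random.default_rng(2))
        m1 = posterior_summary(scalar)["d"][0]
        m2 = batch.summary()["d"][0][0]
        assert m2 == pytest.approx(m1, abs=0.05)


class TestTwoStage:
    def test_identical_stages_equivalent_to_fresh_run(self, iso_setup):
        model, protocol, meas, sigma = iso_setup
        s = Sampler(nsamples=4000, burnin=1000)
        c1, c2, summ = two_stage_fit(model, meas, protocol, s, s,
                                     Noisemodel(sigma_fixed=sigma),
                                     np.random.default_rng(0))
        m1 = posterior_summary(c1, thinning=1)["d"]
        assert summ["d"][0] == pytest.approx(m1[0], abs=3 * m1[1])

    def test_stage2_superset_rejected(self, iso_setup):
        model, protocol, meas, _ = iso_setup
        s1 = Sampler(params=[], nsamples=10, burnin=1)
        s2 = Sampler(params=["d"], nsamples=10, burnin=1)
        with pytest.raises(ValidationError):
            two_stage_fit(model, meas, protocol, s1, s2, Noisemodel(),
                          np.random.default_rng(0))

    def test_batch_pins_dropped_parameters(self, excaliber, dt15_protocol,
                                           rng):
        clean = excaliber.signals(EXVIVO_GT, dt15_protocol)
        meas = clean + rng.normal(0, 0.01, (3, clean.size))
        s1 = Sampler(nsamples=400, burnin=100)
        s2 = Sampler(params=["da", "fia", "fdot"], nsamples=400, burnin=100)
        b1, b2, summ = two_stage_fit_batch(excaliber, meas, dt15_protocol,
                                           s1, s2, Noisemodel(), rng)
        assert np.all(summ["dpara"][1] == 0.0)      # pinned in stage 2
        assert b2.draws.shape[2] == 4               # 3 tissue + sigma


class TestSummariesAndDiagnostics:
    def test_constant_chain_zero_std(self):
        draws = np.ones((10, 1))
        chain = Chain(draws, np.zeros(10), np.ones((10, 1), bool), ["x"])
        mean, std = posterior_summary(chain, burnin=0, thinning=1)["x"]
        assert mean == 1.0 and std == 0.0

    def test_two_value_chain_moments(self):
        n = 10
        draws = np.tile([0.0, 1.0], n // 2)[:, None]
        chain = Chain(draws, np.zeros(n), np.ones((n, 1), bool), ["x"])
        mean, std = posterior_summary(chain, burnin=0, thinning=1)["x"]
        assert mean == pytest.approx(0.5)
        assert std == pytest.approx(np.sqrt(0.25 * n / (n - 1)))

    def test_rhat_near_one_for_iid_chains(self, rng):
        data = {"x": rng.standard_normal((4, 1000))}
        diag = chain_diagnostics(data)
        assert 0.99 <= diag["x"]["rhat"] <= 1.01
        assert diag["x"]["ess"] == pytest.approx(4000, rel=0.2)

    def test_rhat_flags_non_mixing(self, rng):
        data = {"x": np.stack([np.zeros(500), np.ones(500)])
                + 1e-6 * rng.standard_normal((2, 500))}
        assert chain_diagnostics(data)["x"]["rhat"] > 1.1

    def test_too_short_chain_rejected(self, iso_setup):
        model, protocol, meas, sigma = iso_setup
        s = Sampler(nsamples=5, burnin=3)
        chain = mh_sample(model, meas, protocol, s,
                          Noisemodel(sigma_fixed=sigma),
                          np.random.default_rng(0))
        with pytest.raises(ValidationError):
            chain_diagnostics([chain])


class TestFitMaps:
    def test_thread_count_does_not_change_results(self, iso_setup):
        model, protocol, meas, sigma = iso_setup
        rng = np.random.default_rng(0)
        data = np.tile(model.signals({"d": 1.0}, protocol), (2, 5, 1, 1))
        data = data + rng.normal(0, sigma, data.shape)
        mask = np.ones((2, 5, 1), bool)
        mask[0, 0, 0] = False
        s = Sampler(nsamples=300, burnin=100, thinning=2)
        nm = Noisemodel(sigma_fixed=sigma)
        out1 = fit_maps(data, mask, model, protocol, s, nm, nthreads=1,
                        seed=9)
        out4 = fit_maps(data, mask, model, protocol, s, nm, nthreads=4,
                        seed=9)
        np.testing.assert_array_equal(out1[0]["d"], out4[0]["d"])
        np.testing.assert_array_equal(out1[1]["d"], out4[1]["d"])
        assert np.isnan(out1[0]["d"][0, 0, 0])      # masked-out voxel
        assert out1[2][0, 0, 0] == 0.0

    def test_empty_mask_rejected(self, iso_setup):
        model, protocol, meas, sigma = iso_setup
        with pytest.raises(ValidationError):
            fit_maps(np.zeros((2, 2, 1, len(protocol))),
                     np.zeros((2, 2, 1), bool), model, protocol,
                     Sampler(nsamples=10, burnin=1), Noisemodel())
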