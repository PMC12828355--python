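"""Metropolis–Hastings posterior sampling for biophysical models.

The sampler draws tissue parameters (and optionally the Gaussian noise
level σ) under uniform priors on user-supplied bounds, using symmetric
Gaussian proposals updated one parameter at a time (Metropolis-within-
Gibbs sweeps). Out-of-bounds proposals — including fraction proposals
that would leave the simplex — are rejected, which keeps the uniform
prior exact. The two-stage scheme re-runs the sampler with poorly
determined parameters fixed at their stage-1 posterior means, which
sharpens the posteriors of the remaining parameters.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .models import BiophysicalModel
from .protocols import AcquisitionProtocol, ValidationError

__all__ = ["Sampler", "Noisemodel", "Chain", "log_likelihood", "mh_sample",
           "two_stage_fit", "posterior_summary", "chain_diagnostics",
           "fit_maps"]


@dataclass
class Sampler:
    """MCMC settings: which parameters to sample and how.

    ``proposal`` entries default to 5% of the prior width. ``start`` is a
    dict of initial values; if None, the start is drawn uniformly from the
    prior (re-drawn until the fraction simplex is satisfied).
    """
    params: list | None = None
    bounds: dict = field(default_factory=dict)
    proposal: dict = field(default_factory=dict)
    nsamples: int = 20000
    burnin: int = 1000
    thinning: int = 100
    start: dict | None = None

    def __post_init__(self):
        if self.burnin >= self.nsamples:
            raise ValidationError("burnin must be < nsamples")


@dataclass
class Noisemodel:
    """Gaussian noise model; σ is sampled unless ``sigma_fixed`` is set."""
    family: str = "gaussian"
    sigma_fixed: float | None = None
    bounds: tuple = (1e-4, 0.2)
    proposal: float = 0.005
    start: float = 0.02

    def __post_init__(self):
        if self.family != "gaussian":
            raise ValidationError("only the gaussian noise family is shipped")
        if self.sigma_fixed is not None and self.sigma_fixed <= 0:
            raise ValidationError("sigma must be > 0")


@dataclass
class Chain:
    """Posterior sample record from one MH run."""
    draws: np.ndarray            # (nsamples, nparams)
    logp: np.ndarray             # log-likelihood per stored draw
    accepted: np.ndarray         # (nsamples, nparams) per-move accept flags
    names: list
    stage: str = "stage1"
    burnin: int = 0
    thinning: int = 1

    def acceptance_rate(self):
        return self.accepted.mean(axis=0)

    def posterior_draws(self, burnin=None, thinning=None):
        b = self.burnin if burnin is None else burnin
        t = self.thinning if thinning is None else thinning
        return self.draws[b::max(t, 1)]


def log_likelihood(meas, pred, sigma) -> float:
    """Gaussian log-likelihood of measurements given predictions and σ."""
    meas = np.asarray(meas, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if meas.shape != pred.shape:
        raise ValidationError("measurement/prediction length mismatch")
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    n = meas.size
    resid = meas - pred
    return (-0.5 * n * np.log(2 * np.pi * sigma**2)
            - float(resid @ resid) / (2 * sigma**2))


def _setup(model, sampler, noisemodel):
    names = list(sampler.params) if sampler.params is not None \
        else list(model.free)
    unknown = set(names) - set(model.free)
    if unknown:
        raise ValidationError(
            f"sampler params not free in model: {sorted(unknown)}")
    bounds = {}
    steps = {}
    for p in names:
        lo, hi = sampler.bounds.get(p, model.free[p])
        bounds[p] = (lo, hi)
        steps[p] = sampler.proposal.get(p, 0.05 * (hi - lo))
        if steps[p] < 0:
            raise ValidationError(f"proposal std for {p} must be >= 0")
    sample_sigma = noisemodel.sigma_fixed is None
    if sample_sigma:
        names = names + ["sigma"]
        bounds["sigma"] = noisemodel.bounds
        steps["sigma"] = noisemodel.proposal
    return names, bounds, steps, sample_sigma


def _random_start(model, names, bounds, noisemodel, rng):
    frac_names = [p for p in model.fraction_names if p in names]
    for _ in range(1000):
        vals = {p: rng.uniform(*bounds[p]) for p in names if p != "sigma"}
        tot = sum(vals.get(f, model.fixed.get(f, 0.0)) for f in
                  model.fraction_names)
        if tot <= 1.0 or not frac_names:
            break
    else:  # pragma: no cover - would need pathological fixed fractions
        raise ValidationError("could not draw a valid simplex start")
    if "sigma" in names:
        vals["sigma"] = noisemodel.start
    return vals


def mh_sample(model: BiophysicalModel, meas, protocol: AcquisitionProtocol,
              sampler: Sampler, noisemodel: Noisemodel,
              rng: np.random.Generator, stage: str = "stage1") -> Chain:
    """Metropolis–Hastings sampling of the model posterior for one voxel."""
    meas = np.asarray(meas, dtype=float).ravel()
    if meas.size != protocol.nmeasurements:
        raise ValidationError("measurement length does not match protocol")
    names, bounds, steps, sample_sigma = _setup(model, sampler, noisemodel)
    tissue_names = [p for p in names if p != "sigma"]
    frac_set = set(model.fraction_names)
    fixed_frac = sum(v for k, v in model.fixed.items() if k in frac_set)

    if sampler.start is not None:
        current = dict(sampler.start)
        if sample_sigma and "sigma" not in current:
            current["sigma"] = noisemodel.start
    else:
        current = _random_start(model, names, bounds, noisemodel, rng)
    values = {p: current[p] for p in tissue_names}
    sigma = current["sigma"] if sample_sigma else noisemodel.sigma_fixed

    pred = model.signals(values, protocol, validate=False)
    ll = log_likelihood(meas, pred, sigma)

    nit, npar = sampler.nsamples, len(names)
    draws = np.empty((nit, npar))
    logp = np.empty(nit)
    accepted = np.zeros((nit, npar), dtype=bool)
    # pre-draw all randomness for speed
    noise = rng.standard_normal((nit, npar))
    uacc = rng.random((nit, npar))

    for it in range(nit):
        for j, p in enumerate(names):
            step = steps[p]
            old = sigma if p == "sigma" else values[p]
            new = old + step * noise[it, j]
            lo, hi = bounds[p]
            if new < lo or new > hi:
                continue
            if p in frac_set:
                tot = fixed_frac + new + sum(
                    values[f] for f in frac_set
                    if f in values and f != p)
                if tot > 1.0:
                    continue
            if p == "sigma":
                new_ll = log_likelihood(meas, pred, new)
            else:
                values[p] = new
                new_pred = model.signals(values, protocol, validate=False)
                new_ll = log_likelihood(meas, new_pred, sigma)
            if np.log(uacc[it, j]) < new_ll - ll:
                ll = new_ll
                if p == "sigma":
                    sigma = new
                else:
                    pred = new_pred
                accepted[it, j] = True
            elif p != "sigma":
                values[p] = old
        draws[it] = [sigma if p == "sigma" else values[p] for p in names]
        logp[it] = ll

    chain = Chain(draws, logp, accepted, names, stage=stage,
                  burnin=sampler.burnin, thinning=sampler.thinning)
    post_acc = accepted[sampler.burnin:].mean()
    if post_acc == 0:
        warnings.warn(
            "MCMC chain rejected every proposal after burn-in; "
            f"acceptance by parameter: {dict(zip(names, chain.acceptance_rate().round(3)))}",
            RuntimeWarning, stacklevel=2)
    return chain


@dataclass
class BatchChain:
    """Draws from many independent voxels/realizations sampled in lockstep.

    Statistically identical to running :func:`mh_sample` per voxel (each
    chain has its own proposals and accept decisions); the lockstep layout
    just vectorizes the forward model across chains.
    """
    draws: np.ndarray            # (nsamples, nchains, nparams)
    logp: np.ndarray             # (nsamples, nchains)
    accepted: np.ndarray         # (nsamples, nchains, nparams)
    names: list
    stage: str = "stage1"
    burnin: int = 0
    thinning: int = 1

    @property
    def nchains(self):
        return self.draws.shape[1]

    def chain(self, i) -> Chain:
        return Chain(self.draws[:, i], self.logp[:, i], self.accepted[:, i],
                     self.names, self.stage, self.burnin, self.thinning)

    def summary(self, burnin=None, thinning=None) -> dict:
        b = self.burnin if burnin is None else burnin
        t = max(self.thinning if thinning is None else thinning, 1)
        d = self.draws[b::t]
        return {name: (d[:, :, j].mean(axis=0), d[:, :, j].std(axis=0,
                                                               ddof=1))
                for j, name in enumerate(self.names)}


def _loglik_rows(meas, pred, sigma):
    n = meas.shape[-1]
    rss = np.square(meas - pred).sum(axis=-1)
    return -0.5 * n * np.log(2 * np.pi * sigma**2) - rss / (2 * sigma**2)


def mh_sample_batch(model: BiophysicalModel, meas, protocol,
                    sampler: Sampler, noisemodel: Noisemodel,
                    rng: np.random.Generator, pinned: dict | None = None,
                    stage: str = "stage1") -> BatchChain:
    """Run independent MH chains for a batch of measurement vectors.

    ``meas`` is (nchains, nmeasurements): one chain per row. ``pinned``
    optionally holds per-chain fixed values (arrays) for free parameters
    that are not sampled — the mechanism behind the batched two-stage fit.
    """
    meas = np.atleast_2d(np.asarray(meas, dtype=float))
    nchains = meas.shape[0]
    if meas.shape[1] != protocol.nmeasurements:
        raise ValidationError("measurement length does not match protocol")
    pinned = {k: np.broadcast_to(np.asarray(v, float), (nchains,)).copy()
              for k, v in (pinned or {}).items()}
    if sampler.params is None:
        base = [p for p in model.free if p not in pinned]
        sampler = Sampler(params=base, bounds=sampler.bounds,
                          proposal=sampler.proposal,
                          nsamples=sampler.nsamples, burnin=sampler.burnin,
                          thinning=sampler.thinning, start=sampler.start)
    names, bounds, steps, sample_sigma = _setup(model, sampler, noisemodel)
    tissue_names = [p for p in names if p != "sigma"]
    frac_set = set(model.fraction_names)
    fixed_frac = sum(v for k, v in model.fixed.items() if k in frac_set)
    pinned_frac = sum(pinned[f] for f in pinned if f in frac_set) \
        if any(f in frac_set for f in pinned) else 0.0

    # vectorized uniform start on the prior (re-draw simplex violations)
    values = {}
    if sampler.start is not None:
        for p in tissue_names:
            values[p] = np.full(nchains, float(sampler.start[p]))
        sigma = np.full(nchains, float(sampler.start.get(
            "sigma", noisemodel.start)))
    else:
        for p in tissue_names:
            lo, hi = bounds[p]
            values[p] = rng.uniform(lo, hi, size=nchains)
        fnames = [p for p in tissue_names if p in frac_set]
        if fnames:
            for _ in range(1000):
                tot = fixed_frac + pinned_frac + sum(values[f]
                                                     for f in fnames)
                bad = np.asarray(tot) > 1.0
                if not np.any(bad):
                    break
                for f in fnames:
                    lo, hi = bounds[f]
                    values[f][bad] = rng.uniform(lo, hi, size=int(bad.sum()))
        sigma = np.full(nchains, noisemodel.start)
    if not sample_sigma:
        sigma = np.full(nchains, noisemodel.sigma_fixed)

    def predict(vals):
        return model.signals({**vals, **pinned}, protocol, validate=False)

    pred = predict(values)
    ll = _loglik_rows(meas, pred, sigma)

    nit, npar = sampler.nsamples, len(names)
    draws = np.empty((nit, nchains, npar))
    logp = np.empty((nit, nchains))
    accepted = np.zeros((nit, nchains, npar), dtype=bool)
    noise = rng.standard_normal((nit, npar, nchains))
    uacc = rng.random((nit, npar, nchains))

    for it in range(nit):
        for j, p in enumerate(names):
            old = sigma if p == "sigma" else values[p]
            new = old + steps[p] * noise[it, j]
            lo, hi = bounds[p]
            valid = (new >= lo) & (new <= hi)
            if p in frac_set:
                others = fixed_frac + pinned_frac + sum(
                    values[f] for f in tissue_names
                    if f in frac_set and f != p)
                valid &= (new + others) <= 1.0
            trial = np.where(valid, new, old)
            if p == "sigma":
                new_ll = _loglik_rows(meas, pred, trial)
                accept = valid & (np.log(uacc[it, j]) < new_ll - ll)
                sigma = np.where(accept, trial, sigma)
            else:
                values[p] = trial
                new_pred = predict(values)
                new_ll = _loglik_rows(meas, new_pred, sigma)
                accept = valid & (np.log(uacc[it, j]) < new_ll - ll)
                values[p] = np.where(accept, trial, old)
                pred = np.where(accept[:, None], new_pred, pred)
            ll = np.where(accept, new_ll, ll)
            accepted[it, :, j] = accept
        for j, p in enumerate(names):
            draws[it, :, j] = sigma if p == "sigma" else values[p]
        logp[it] = ll

    return BatchChain(draws, logp, accepted, names, stage=stage,
                      burnin=sampler.burnin, thinning=sampler.thinning)


def two_stage_fit_batch(model: BiophysicalModel, meas, protocol,
                        stage1: Sampler, stage2: Sampler,
                        noisemodel: Noisemodel, rng: np.random.Generator):
    """Batched two-stage MCMC over rows of ``meas``.

    Per chain, the parameters dropped in stage 2 are pinned to their own
    stage-1 posterior means. Returns (batch1, batch2, summary-of-arrays).
    """
    p1 = list(stage1.params) if stage1.params is not None else \
        list(model.free)
    p2 = list(stage2.params) if stage2.params is not None else p1
    if not set(p2) <= set(p1):
        raise ValidationError("stage-2 params must be a subset of stage 1")
    b1 = mh_sample_batch(model, meas, protocol, stage1, noisemodel, rng,
                         stage="stage1")
    s1 = b1.summary()
    dropped = [p for p in p1 if p not in p2]
    pinned = {p: s1[p][0] for p in dropped}
    stage2 = Sampler(params=p2, bounds=stage2.bounds,
                     proposal=stage2.proposal, nsamples=stage2.nsamples,
                     burnin=stage2.burnin, thinning=stage2.thinning,
                     start=stage2.start)
    b2 = mh_sample_batch(model, meas, protocol, stage2, noisemodel, rng,
                         pinned=pinned, stage="stage2")
    summary = b2.summary()
    for p in dropped:
        summary[p] = (s1[p][0], np.zeros(b1.nchains))
    return b1, b2, summary


def posterior_summary(chain: Chain, burnin=None, thinning=None) -> dict:
    """Posterior mean and std per parameter from thinned post-burn-in draws."""
    d = chain.posterior_draws(burnin, thinning)
    return {name: (float(d[:, j].mean()), float(d[:, j].std(ddof=1))
                   if d.shape[0] > 1 else 0.0)
            for j, name in enumerate(chain.names)}


def two_stage_fit(model: BiophysicalModel, meas, protocol,
                  stage1: Sampler, stage2: Sampler, noisemodel: Noisemodel,
                  rng: np.random.Generator):
    """Two-stage MCMC: fix stage-1 posterior means of dropped parameters.

    ``stage2.params`` must be a subset of the stage-1 sampled parameters;
    the parameters not re-sampled are fixed at their stage-1 posterior
    means for the second run. Returns (chain1, chain2, summary) where the
    summary holds stage-2 moments plus the fixed values.
    """
    p1 = list(stage1.params) if stage1.params is not None else \
        list(model.free)
    p2 = list(stage2.params) if stage2.params is not None else p1
    if not set(p2) <= set(p1):
        raise ValidationError("stage-2 params must be a subset of stage 1")
    chain1 = mh_sample(model, meas, protocol, stage1, noisemodel, rng,
                       stage="stage1")
    s1 = posterior_summary(chain1)
    dropped = [p for p in p1 if p not in p2]
    model2 = model.with_fixed(**{p: s1[p][0] for p in dropped}) \
        if dropped else model
    stage2 = Sampler(params=p2, bounds=stage2.bounds,
                     proposal=stage2.proposal, nsamples=stage2.nsamples,
                     burnin=stage2.burnin, thinning=stage2.thinning,
                     start=stage2.start)
    chain2 = mh_sample(model2, meas, protocol, stage2, noisemodel, rng,
                       stage="stage2")
    summary = posterior_summary(chain2)
    for p in dropped:
        summary[p] = (s1[p][0], 0.0)
    return chain1, chain2, summary


def chain_diagnostics(chains, burnin=None) -> dict:
    """Split-R̂ (rank-normalized) and effective sample size per parameter.

    Accepts one or more :class:`Chain` objects sharing parameter names
    (or raw (nchains, ndraws) arrays per parameter via a dict).
    """
    import arviz as az

    if isinstance(chains, Chain):
        chains = [chains]
    if isinstance(chains, dict):
        data = {k: np.atleast_2d(np.asarray(v)) for k, v in chains.items()}
    else:
        names = chains[0].names
        stacked = [c.posterior_draws(burnin, thinning=1) for c in chains]
        if any(s.shape != stacked[0].shape for s in stacked):
            raise ValidationError("chains must have equal length")
        if stacked[0].shape[0] < 4:
            raise ValidationError("need at least 4 post-burn-in draws")
        data = {name: np.stack([s[:, j] for s in stacked])
                for j, name in enumerate(names)}
    ds = az.convert_to_dataset(data)
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    return {k: {"rhat": float(rhat[k].values), "ess": float(ess[k].values)}
            for k in data}


def fit_maps(volumes, mask, model: BiophysicalModel,
             protocol: AcquisitionProtocol, sampler: Sampler,
             noisemodel: Noisemodel, nthreads: int = 1, seed: int = 0,
             two_stage: Sampler | None = None):
    """Voxelwise MCMC over a masked 4D array; returns mean/std maps.

    Each voxel gets an independent generator seeded by (seed, voxel
    index), so results are identical for any thread count. Per-voxel
    failures are recorded in the returned ``qc`` volume (1 = OK, 0 =
    failed or masked out).
    """
    data = np.asarray(volumes, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    idx = np.argwhere(mask)
    param_names = (list(two_stage.params) if two_stage is not None and
                   two_stage.params else list(model.free))
    if sampler.params:
        param_names = [p for p in sampler.params]
    out_names = list(dict.fromkeys(param_names))
    shape = mask.shape
    means = {p: np.full(shape, np.nan) for p in out_names}
    stds = {p: np.full(shape, np.nan) for p in out_names}
    qc = np.zeros(shape, dtype=float)

    def work(k):
        i, j, l = idx[k]
        rng = np.random.default_rng([seed, int(k)])
        meas = data[i, j, l]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if two_stage is not None:
                    _, _, summ = two_stage_fit(model, meas, protocol,
                                               sampler, two_stage,
                                               noisemodel, rng)
                else:
                    chain = mh_sample(model, meas, protocol, sampler,
                                      noisemodel, rng)
                    summ = posterior_summary(chain)
            return k, summ, 1.0
        except Exception:
            return k, None, 0.0

    if nthreads > 1:
        with ThreadPoolExecutor(max_workers=nthreads) as ex:
            results = list(ex.map(work, range(len(idx))))
    else:
        results = [work(k) for k in range(len(idx))]
    for k, summ, ok in results:
        i, j, l = idx[k]
        qc[i, j, l] = ok
        if summ is not None:
            for p in out_names:
                if p in summ:
                    means[p][i, j, l] = summ[p][0]
                    stds[p][i, j, l] = summ[p][1]
    return means, stds, qc
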