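"""MC-dropout neural-network estimator.

Training data are synthesized from a biophysical model: tissue parameters
are drawn from user-controlled priors (uniform, truncated Gaussian, or a
Dirichlet block for the fraction simplex), pushed through the forward
model on the target protocol, and corrupted with Gaussian noise at the
level expected in the direction-averaged data. A small multi-layer
perceptron with dropout after every hidden layer regresses the (min–max
scaled) parameters from the noisy measurement vector. At inference the
dropout layers stay active and repeated stochastic forward passes give a
Bayesian-approximate posterior per parameter, summarized as mean and
standard deviation in physical units.

The network is implemented directly on numpy (dense layers, ReLU,
inverted dropout, Adam); networks of the sizes useful for microstructure
fitting (a few hidden layers of tens of units) train in seconds on one
CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import BiophysicalModel
from .protocols import AcquisitionProtocol, ValidationError

__all__ = ["PriorSpec", "NetworkArg", "TrainingArg", "TrainedEstimator",
           "generate_training_set", "recommend_nsamples", "train",
           "predict_mc", "evaluate"]


# ---------------------------------------------------------------------------
# Priors and training-set synthesis

@dataclass
class PriorSpec:
    """Sampling distributions for the free parameters of a model.

    ``params`` maps non-fraction parameter names to ("uniform", lo, hi) or
    ("gaussian", mu, sigma, lo, hi) (Gaussian truncated to [lo, hi]).
    ``dirichlet`` holds one concentration per compartment for the fraction
    simplex (default: all ones, i.e. uniform on the simplex).
    """
    params: dict = field(default_factory=dict)
    dirichlet: np.ndarray | None = None

    @classmethod
    def from_model(cls, model: BiophysicalModel) -> "PriorSpec":
        """Uniform-on-bounds priors plus a flat Dirichlet fraction block."""
        p = {k: ("uniform", lo, hi) for k, (lo, hi) in model.free.items()
             if k not in model.fraction_names}
        conc = np.ones(len(model.slots))
        return cls(params=p, dirichlet=conc)

    def validate(self, model: BiophysicalModel):
        for k, spec in self.params.items():
            if k not in model.free:
                raise ValidationError(f"prior for unknown parameter {k}")
            lo, hi = model.free[k]
            slo, shi = spec[-2], spec[-1]
            if slo < lo - 1e-9 or shi > hi + 1e-9:
                raise ValidationError(
                    f"prior support for {k} outside bounds [{lo}, {hi}]")
        missing = (set(model.free) - set(model.fraction_names)
                   - set(self.params))
        if missing:
            raise ValidationError(f"priors missing for {sorted(missing)}")
        if self.dirichlet is not None:
            conc = np.asarray(self.dirichlet, dtype=float)
            if conc.size != len(model.slots) or np.any(conc <= 0):
                raise ValidationError(
                    "Dirichlet needs one positive concentration per "
                    "compartment")

    def sample(self, model: BiophysicalModel, n: int,
               rng: np.random.Generator) -> dict:
        self.validate(model)
        out = {}
        for k, spec in self.params.items():
            if spec[0] == "uniform":
                out[k] = rng.uniform(spec[1], spec[2], size=n)
            elif spec[0] == "gaussian":
                _, mu, sd, lo, hi = spec
                x = rng.normal(mu, sd, size=n)
                bad = (x < lo) | (x > hi)
                while np.any(bad):   # truncation by redraw
                    x[bad] = rng.normal(mu, sd, size=int(bad.sum()))
                    bad = (x < lo) | (x > hi)
                out[k] = x
            else:
                raise ValidationError(f"unknown prior family {spec[0]!r}")
        if model.fraction_names:
            conc = np.asarray(self.dirichlet if self.dirichlet is not None
                              else np.ones(len(model.slots)), dtype=float)
            fr = rng.dirichlet(conc, size=n)
            for i, name in enumerate(model.fraction_names):
                out[name] = fr[:, i]
        return out


def _noise_sigma(noise, protocol: AcquisitionProtocol):
    """Per-measurement noise std from a σ scalar or ('snr', value) spec.

    With an SNR referred to a single b=0 measurement, direction averaging
    over n_dirs measurements leaves σ = 1 / (SNR · √n_dirs) per shell.
    """
    if isinstance(noise, tuple) and noise[0] == "snr":
        per_shell = 1.0 / (float(noise[1]) * np.sqrt(protocol.ndirs))
        return np.tile(per_shell, protocol.riorder // 2 + 1)
    sigma = float(noise)
    return np.full(protocol.nmeasurements, sigma)


def generate_training_set(model: BiophysicalModel,
                          protocol: AcquisitionProtocol,
                          priors: PriorSpec, n: int, noise,
                          rng: np.random.Generator):
    """Draw n (parameters, noisy signals) training pairs.

    Returns (params, signals): a DataFrame of free-parameter draws and an
    (n, nmeasurements) array of forward-model signals with additive
    Gaussian noise (``noise`` = σ scalar, or ("snr", value) for a b=0 SNR
    with per-shell direction averaging; σ = 0 gives noise-free signals).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    values = priors.sample(model, n, rng)
    signals = model.signals(values, protocol, validate=False)
    sigma = _noise_sigma(noise, protocol)
    if np.any(sigma > 0):
        signals = signals + rng.normal(0.0, 1.0, size=signals.shape) * sigma
    return pd.DataFrame({k: values[k] for k in model.free}), signals


# ---------------------------------------------------------------------------
# Network and training configuration

@dataclass
class NetworkArg:
    """MLP architecture + training-data recipe for one model/protocol."""
    model: BiophysicalModel
    protocol: AcquisitionProtocol
    hidden: tuple = (48, 48, 48)
    dropout: float = 0.1
    nsamples: int = 30000
    noise: object = ("snr", 50.0)
    priors: PriorSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.dropout < 1:
            raise ValidationError("dropout rate must be in (0, 1)")
        if self.nsamples < 1:
            raise ValidationError("nsamples must be >= 1")
        if self.priors is None:
            self.priors = PriorSpec.from_model(self.model)

    @property
    def input_dim(self):
        return self.protocol.nmeasurements

    @property
    def output_dim(self):
        return len(self.model.free)

    def nweights(self):
        dims = [self.input_dim, *self.hidden, self.output_dim]
        return sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))


@dataclass
class TrainingArg:
    epochs: int = 200
    batch_size: int = 128
    lr: float = 1e-3
    split: float = 0.2          # validation fraction
    loss: str = "rmse"          # "rmse" | "mse"
    patience: int = 30

    def __post_init__(self):
        if not 0 < self.split < 1:
            raise ValidationError("validation split must be in (0, 1)")
        if self.loss not in ("rmse", "mse"):
            raise ValidationError("loss must be 'rmse' or 'mse'")


def recommend_nsamples(netarg: NetworkArg, factor: int = 50) -> int:
    """Training-set size heuristic: factor × (number of MLP weights).

    The default factor 50 suits small MLPs; values outside [10, 100] are
    accepted with a warning.
    """
    if not 10 <= factor <= 100:
        warnings.warn(f"sample factor {factor} outside the recommended "
                      "[10, 100] range", UserWarning, stacklevel=2)
    return int(factor * netarg.nweights())


# ---------------------------------------------------------------------------
# The MLP

def _init_layers(dims, rng):
    layers = []
    for a, b in zip(dims[:-1], dims[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
        layers.append([w, np.zeros(b)])
    return layers


def _forward(layers, x, dropout, rng):
    """Forward pass; dropout active iff rng is given (inverted scaling)."""
    h = x
    cache = []
    for i, (w, b) in enumerate(layers):
        z = h @ w + b
        last = i == len(layers) - 1
        a = z if last else np.maximum(z, 0.0)
        mask = None
        if not last and rng is not None:
            mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
            a = a * mask
        cache.append((h, z, mask))
        h = a
    return h, cache


def _backward(layers, cache, grad_out, dropout):
    grads = [None] * len(layers)
    g = grad_out
    for i in range(len(layers) - 1, -1, -1):
        h, z, mask = cache[i]
        if i != len(layers) - 1:
            if mask is not None:
                g = g * mask
            g = g * (z > 0)
        grads[i] = (h.T @ g, g.sum(axis=0))
        g = g @ layers[i][0].T
    return grads


@dataclass
class TrainedEstimator:
    """Trained MLP + scaling + the prior/protocol provenance."""
    layers: list
    dropout: float
    param_names: list
    scale_lo: np.ndarray
    scale_hi: np.ndarray
    netarg: NetworkArg
    trainarg: TrainingArg
    validation_loss: float
    history: list = field(default_factory=list)

    def _scale(self, y):
        return (y - self.scale_lo) / (self.scale_hi - self.scale_lo)

    def _unscale(self, y):
        return y * (self.scale_hi - self.scale_lo) + self.scale_lo

    def predict(self, meas) -> np.ndarray:
        """Deterministic prediction (dropout off), physical units."""
        meas = np.atleast_2d(np.asarray(meas, dtype=float))
        out, _ = _forward(self.layers, meas, self.dropout, rng=None)
        return self._unscale(out)


def _scaling_from(model: BiophysicalModel, priors: PriorSpec):
    lo, hi = [], []
    for k, (blo, bhi) in model.free.items():
        spec = priors.params.get(k)
        if spec is not None and spec[0] in ("uniform", "gaussian"):
            blo, bhi = spec[-2], spec[-1]
        lo.append(blo)
        hi.append(bhi)
    return np.array(lo, dtype=float), np.array(hi, dtype=float)


def train(netarg: NetworkArg, trainarg: TrainingArg,
          data=None) -> TrainedEstimator:
    """Train the dropout MLP on synthetic (or user-provided) data.

    ``data`` is an optional (params DataFrame/array, signals array) pair;
    by default a fresh training set is synthesized from ``netarg``.
    Parameters are min–max scaled to [0, 1] before the loss; training
    minimizes the (R)MSE across all scaled parameters with Adam, and the
    weights with the best validation loss are kept (early stopping).
    Deterministic for a fixed ``netarg.seed``.
    """
    rng = np.random.default_rng(netarg.seed)
    model = netarg.model
    if data is None:
        params, signals = generate_training_set(
            model, netarg.protocol, netarg.priors, netarg.nsamples,
            netarg.noise, rng)
    else:
        params, signals = data
    y_raw = params[list(model.free)].to_numpy(float) \
        if isinstance(params, pd.DataFrame) else np.asarray(params, float)
    x = np.asarray(signals, dtype=float)
    if x.shape[0] != y_raw.shape[0]:
        raise ValidationError("params/signals sample counts differ")
    if x.shape[1] != netarg.input_dim:
        raise ValidationError("signal dimension does not match protocol")

    lo, hi = _scaling_from(model, netarg.priors)
    y = (y_raw - lo) / (hi - lo)

    nval = max(1, int(round(trainarg.split * x.shape[0])))
    perm = rng.permutation(x.shape[0])
    val_idx, tr_idx = perm[:nval], perm[nval:]
    xt, yt = x[tr_idx], y[tr_idx]
    xv, yv = x[val_idx], y[val_idx]

    dims = [netarg.input_dim, *netarg.hidden, netarg.output_dim]
    layers = _init_layers(dims, rng)
    mom = [[np.zeros_like(w), np.zeros_like(b)] for w, b in layers]
    vel = [[np.zeros_like(w), np.zeros_like(b)] for w, b in layers]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best = (np.inf, None)
    history = []
    wait = 0
    nbatch = max(1, xt.shape[0] // trainarg.batch_size)

    for epoch in range(trainarg.epochs):
        order = rng.permutation(xt.shape[0])
        for k in range(nbatch):
            sl = order[k * trainarg.batch_size:(k + 1) * trainarg.batch_size]
            xb, yb = xt[sl], yt[sl]
            pred, cache = _forward(layers, xb, netarg.dropout, rng)
            g = 2.0 * (pred - yb) / pred.size      # MSE gradient
            grads = _backward(layers, cache, g, netarg.dropout)
            t += 1
            for li, ((gw, gb), (w, b)) in enumerate(zip(grads, layers)):
                for gi, (grad, par) in enumerate(((gw, w), (gb, b))):
                    mom[li][gi] = beta1 * mom[li][gi] + (1 - beta1) * grad
                    vel[li][gi] = beta2 * vel[li][gi] + (1 - beta2) * grad**2
                    mhat = mom[li][gi] / (1 - beta1**t)
                    vhat = vel[li][gi] / (1 - beta2**t)
                    par -= trainarg.lr * mhat / (np.sqrt(vhat) + eps)
        vp, _ = _forward(layers, xv, netarg.dropout, rng=None)
        vmse = float(np.mean((vp - yv) ** 2))
        vloss = np.sqrt(vmse) if trainarg.loss == "rmse" else vmse
        if not np.isfinite(vloss):
            raise RuntimeError(
                f"validation loss became non-finite at epoch {epoch}")
        history.append(vloss)
        if vloss < best[0]:
            best = (vloss, [[w.copy(), b.copy()] for w, b in layers])
            wait = 0
        else:
            wait += 1
            if wait >= trainarg.patience:
                break

    return TrainedEstimator(best[1], netarg.dropout, list(model.free),
                            lo, hi, netarg, trainarg, best[0], history)


def predict_mc(est: TrainedEstimator, meas, ntests: int = 100,
               rng: np.random.Generator | None = None):
    """Posterior mean and std per parameter via Monte-Carlo dropout.

    Runs ``ntests`` stochastic forward passes (dropout active) per input
    row and returns (mean, std) arrays of shape (nvoxels, nparams) in
    physical units.
    """
    if ntests < 2:
        raise ValidationError("ntests must be >= 2")
    rng = np.random.default_rng(0) if rng is None else rng
    meas = np.atleast_2d(np.asarray(meas, dtype=float))
    acc = np.empty((ntests, meas.shape[0], len(est.param_names)))
    for i in range(ntests):
        out, _ = _forward(est.layers, meas, est.dropout, rng)
        acc[i] = out
    acc = est._unscale(acc)
    return acc.mean(axis=0), acc.std(axis=0, ddof=1)


def evaluate(est: TrainedEstimator, params_gt, signals, ntests: int = 100,
             rng=None, hist_bins: int = 50) -> dict:
    """Ground-truth-vs-estimate evaluation of a trained estimator.

    Returns, per parameter: bias, RMSE, Pearson r between posterior means
    and ground truth, mean posterior std normalized by the prior width,
    and a 2D histogram grid (GT vs estimate) ready for plotting.
    """
    y = params_gt[est.param_names].to_numpy(float) \
        if isinstance(params_gt, pd.DataFrame) else np.asarray(params_gt,
                                                               float)
    mean, std = predict_mc(est, signals, ntests=ntests, rng=rng)
    out = {}
    width = est.scale_hi - est.scale_lo
    for j, name in enumerate(est.param_names):
        gt, mu = y[:, j], mean[:, j]
        r = np.corrcoef(gt, mu)[0, 1] if np.std(mu) > 0 and \
            np.std(gt) > 0 else np.nan
        h, xe, ye = np.histogram2d(gt, mu, bins=hist_bins)
        out[name] = {
            "bias": float(np.mean(mu - gt)),
            "rmse": float(np.sqrt(np.mean((mu - gt) ** 2))),
            "pearson_r": float(r),
            "normalized_std": float(np.mean(std[:, j]) / width[j]),
            "hist2d": (h, xe, ye),
        }
    return out
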