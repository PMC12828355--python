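"""Estimator persistence: a single .npz with weights + JSON provenance."""

from __future__ import annotations

import io
import json

import numpy as np

from .models import make_model
from .nn import NetworkArg, PriorSpec, TrainedEstimator, TrainingArg
from .protocols import AcquisitionProtocol


def save_estimator(est: TrainedEstimator, path):
    arrays = {}
    for i, (w, b) in enumerate(est.layers):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    arrays["scale_lo"] = est.scale_lo
    arrays["scale_hi"] = est.scale_hi
    prot = est.netarg.protocol
    meta = {
        "param_names": est.param_names,
        "dropout": est.dropout,
        "nlayers": len(est.layers),
        "validation_loss": est.validation_loss,
        "model_name": est.netarg.model.name,
        "hidden": list(est.netarg.hidden),
        "nsamples": est.netarg.nsamples,
        "noise": list(est.netarg.noise)
        if isinstance(est.netarg.noise, tuple) else est.netarg.noise,
        "seed": est.netarg.seed,
        "priors": {k: list(v) for k, v in est.netarg.priors.params.items()},
        "dirichlet": None if est.netarg.priors.dirichlet is None
        else np.asarray(est.netarg.priors.dirichlet).tolist(),
        "protocol": {
            "bval": prot.bval.tolist(),
            "techo": None if prot.techo is None else prot.techo.tolist(),
            "tdelta": None if prot.tdelta is None else prot.tdelta.tolist(),
            "tsmalldel": None if prot.tsmalldel is None
            else prot.tsmalldel.tolist(),
            "ndirs": prot.ndirs.tolist(),
            "riorder": prot.riorder,
        },
        "training": {"epochs": est.trainarg.epochs,
                     "batch_size": est.trainarg.batch_size,
                     "lr": est.trainarg.lr, "split": est.trainarg.split,
                     "loss": est.trainarg.loss,
                     "patience": est.trainarg.patience},
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_estimator(path) -> TrainedEstimator:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        layers = [[z[f"w{i}"], z[f"b{i}"]]
                  for i in range(meta["nlayers"])]
        scale_lo = z["scale_lo"]
        scale_hi = z["scale_hi"]
    pm = meta["protocol"]
    protocol = AcquisitionProtocol(
        bval=np.array(pm["bval"]), techo=pm["techo"], tdelta=pm["tdelta"],
        tsmalldel=pm["tsmalldel"], ndirs=np.array(pm["ndirs"]),
        riorder=pm["riorder"])
    priors = PriorSpec(params={k: tuple(v)
                               for k, v in meta["priors"].items()},
                       dirichlet=meta["dirichlet"])
    noise = meta["noise"]
    if isinstance(noise, list):
        noise = (noise[0], float(noise[1]))
    netarg = NetworkArg(model=make_model(meta["model_name"]),
                        protocol=protocol, hidden=tuple(meta["hidden"]),
                        dropout=meta["dropout"], nsamples=meta["nsamples"],
                        noise=noise, priors=priors, seed=meta["seed"])
    trainarg = TrainingArg(**meta["training"])
    return TrainedEstimator(layers, meta["dropout"], meta["param_names"],
                            scale_lo, scale_hi, netarg, trainarg,
                            meta["validation_loss"])
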