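"""Synthetic voxels, phantoms and protocol presets for fitting evaluation.

Protocol presets reproduce the shell tables of three published
acquisition styles — a preclinical ex vivo multi-b protocol family at
three diffusion times (maximum gradient 660 mT/m), a clinical three-shell
protocol (90 directions per shell, 18 b=0), a short-diffusion-time
ultra-high-gradient protocol for soma imaging, and a multi-TE two-shell
protocol for diffusion–relaxometry — so that estimator evaluations can
run end-to-end without any external data.

Noise convention: voxel-level generators add Gaussian noise of standard
deviation 1/SNR directly to the normalized spherical-mean (or rotational-
invariant) signals. A separate per-direction mode synthesizes single-
fiber DWIs with noise per direction for testing the direction-averaging
itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compartments import Iso, Stick, Zeppelin
from .models import BiophysicalModel, make_model
from .protocols import AcquisitionProtocol, AcquisitionTable, ValidationError

__all__ = ["protocol_preset", "PRESETS", "synth_voxel", "sweep_evaluation",
           "PhantomSpec", "write_phantom", "fibonacci_directions",
           "single_fiber_dwi", "band_limited_dwi"]


def _exvivo(bvals, sd, de):
    b = np.array([0.0, *bvals])
    n = len(b)
    return AcquisitionProtocol(
        bval=b, tdelta=np.full(n, de), tsmalldel=np.full(n, sd),
        ndirs=np.r_[1, np.full(n - 1, 32)])


def _hcp_smt():
    return AcquisitionProtocol(bval=[0.0, 1.0, 2.0, 3.0],
                               ndirs=[18, 90, 90, 90])


def _connectome_sandi():
    b = np.array([0.0, 0.35, 0.8, 1.5, 2.4, 3.45, 4.75, 6.0])
    nd = np.where(b >= 2.4, 64, 32)
    return AcquisitionProtocol(bval=b, tdelta=np.full(8, 19.0),
                               tsmalldel=np.full(8, 8.0), ndirs=nd)


def _prisma_mte_smi():
    tes = np.arange(62.0, 133.0, 10.0)
    b, te, nd = [], [], []
    for t in tes:
        b += [0.0, 0.7, 2.0]
        te += [t, t, t]
        nd += [4, 30, 30]
    n = len(b)
    return AcquisitionProtocol(bval=b, techo=te,
                               tdelta=np.full(n, 25.2),
                               tsmalldel=np.full(n, 15.2),
                               ndirs=nd, riorder=2)


PRESETS = {
    "excaliber_exvivo_dt12": lambda: _exvivo(
        [1.0, 2.5, 5.0, 7.5, 11.1, 18.1, 25.0], 9.6, 12.0),
    "excaliber_exvivo_dt15": lambda: _exvivo(
        [1.0, 2.5, 5.0, 7.5, 11.1, 18.1, 25.0, 43.0], 11.0, 15.192),
    "excaliber_exvivo_dt21": lambda: _exvivo(
        [1.0, 2.5, 5.0, 7.5, 11.1, 18.1, 25.0, 43.0, 64.0], 11.0, 21.0),
    "hcp_smt": _hcp_smt,
    "connectome_sandi": _connectome_sandi,
    "prisma_mte_smi": _prisma_mte_smi,
}

#: ex vivo white-matter ground truth used for diameter sweep evaluations
EXVIVO_GT = {"da": 2.0, "fia": 0.7, "fdot": 0.15,
             "dpara": 0.6, "dperp_frac": 0.3}


def protocol_preset(name: str) -> AcquisitionProtocol:
    """Return one of the named shell tables (see :data:`PRESETS`)."""
    if name not in PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name]()


def combine_protocols(*protocols) -> AcquisitionProtocol:
    """Concatenate shell tables (e.g. multiple diffusion times)."""
    def cat(attr):
        vals = [getattr(p, attr) for p in protocols]
        if any(v is None for v in vals):
            return None
        return np.concatenate(vals)
    return AcquisitionProtocol(bval=cat("bval"), techo=cat("techo"),
                               tdelta=cat("tdelta"),
                               tsmalldel=cat("tsmalldel"),
                               ndirs=np.concatenate([p.ndirs
                                                     for p in protocols]),
                               riorder=protocols[0].riorder)


def synth_voxel(model: BiophysicalModel, gt: dict,
                protocol: AcquisitionProtocol, snr: float,
                nrealizations: int, rng) -> np.ndarray:
    """Noisy measurement matrix (nrealizations × nmeasurements).

    Gaussian noise with σ = 1/snr is added to the normalized signals
    (``snr=np.inf`` gives identical noise-free rows).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    clean = model.signals(gt, protocol)
    out = np.tile(clean, (nrealizations, 1))
    if np.isfinite(snr):
        out = out + rng.normal(0.0, 1.0 / snr, size=out.shape)
    return out


def sweep_evaluation(model: BiophysicalModel, gt_grid, sweep_param: str,
                     base_gt: dict, protocol: AcquisitionProtocol,
                     snr: float, nrealizations: int, estimator,
                     seed: int = 0):
    """Accuracy/precision sweep of one parameter over ground-truth values.

    For each value in ``gt_grid`` the voxel is simulated ``nrealizations``
    times and passed to ``estimator(meas_matrix, protocol, rng)``, which
    must return a mapping parameter → per-realization estimates. Returns a
    (stats DataFrame, metrics dict) pair: per-GT boxplot statistics of the
    swept parameter's estimates, and the Pearson correlation between
    estimates and ground truth (NaN for a degenerate/constant estimator).
    Per-cell estimator failures are recorded, not raised.
    """
    rows = []
    all_gt, all_est = [], []
    failures = []
    for gi, val in enumerate(gt_grid):
        gt = dict(base_gt)
        gt[sweep_param] = val
        rng = np.random.default_rng([seed, gi])
        meas = synth_voxel(model, gt, protocol, snr, nrealizations, rng)
        try:
            est = np.asarray(estimator(meas, protocol, rng)[sweep_param],
                             dtype=float)
        except Exception as err:   # record, keep sweeping
            failures.append((val, repr(err)))
            continue
        q1, med, q3 = np.percentile(est, [25, 50, 75])
        rows.append({"gt": val, "mean": est.mean(), "std": est.std(ddof=1),
                     "q1": q1, "median": med, "q3": q3,
                     "whisker_lo": est.min(), "whisker_hi": est.max()})
        all_gt.extend([val] * len(est))
        all_est.extend(est.tolist())
    stats = pd.DataFrame(rows)
    all_gt = np.array(all_gt)
    all_est = np.array(all_est)
    if len(all_est) and np.std(all_est) > 0 and np.std(all_gt) > 0:
        r = float(np.corrcoef(all_gt, all_est)[0, 1])
    else:
        r = float("nan")
    return stats, {"pearson_r": r, "failures": failures}


# ---------------------------------------------------------------------------
# Per-direction synthesis (for testing the direction averaging itself)

def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def single_fiber_dwi(mixture, table: AcquisitionTable,
                     orientation=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Orientation-resolved signals of a single-fiber compartment mixture.

    ``mixture`` is a list of (fraction, compartment) with Stick, Zeppelin
    or Iso compartments; the anisotropic compartments share the given
    fiber orientation. Returns one signal per table volume (b=0 → 1).
    """
    n = np.asarray(orientation, dtype=float)
    n = n / np.linalg.norm(n)
    if table.bvec is None:
        raise ValidationError("per-direction synthesis needs bvecs")
    xi2 = (table.bvec @ n) ** 2
    b = table.bval
    out = np.zeros(len(table))
    for f, c in mixture:
        if isinstance(c, Stick):
            s = np.exp(-b * c.dpara * xi2)
        elif isinstance(c, Zeppelin):
            s = np.exp(-b * c.dperp - b * (c.dpara - c.dperp) * xi2)
        elif isinstance(c, Iso):
            s = np.exp(-b * c.d)
        else:
            raise ValidationError(
                f"no orientation-resolved model for {type(c).__name__}")
        out += f * s
    return out


def band_limited_dwi(kernel, p2: float, table: AcquisitionTable,
                     protocol_b, orientation=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Signal with exactly the l ∈ {0, 2} rotational-invariant content.

    S(g) = Σ_l (2l+1) p_l K_l(b) P_l(g·n): a band-limited single-fiber
    voxel whose SH fit must return S_0 = K_0 and S_2 = p2·K_2 exactly (up
    to fit conditioning), used as the oracle for ``spherical_fit``.
    """
    from scipy.special import eval_legendre
    from .compartments import kernel_invariant
    nvec = np.asarray(orientation, dtype=float)
    nvec = nvec / np.linalg.norm(nvec)
    xi = table.bvec @ nvec
    k0 = kernel_invariant(kernel, protocol_b, 0)
    k2 = kernel_invariant(kernel, protocol_b, 2)
    # map each volume to its shell by b-value
    out = np.zeros(len(table))
    for i, b in enumerate(table.bval):
        si = int(np.argmin(np.abs(protocol_b.bval - b)))
        out[i] = k0[si] + 5.0 * p2 * k2[si] * eval_legendre(2, xi[i])
    return out


# ---------------------------------------------------------------------------
# Phantoms on disk

@dataclass
class PhantomSpec:
    """Recipe for a written-to-disk synthetic phantom.

    ``gt`` is either a constant parameter dict (every voxel identical) or
    a dict of parameter arrays of length ``nvoxels``. Realizations are
    stacked along the first image axis, voxels along the second.
    """
    model: BiophysicalModel | str
    gt: dict
    protocol: AcquisitionProtocol | str = "excaliber_exvivo_dt15"
    snr: float = 100.0
    nrealizations: int = 1
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.model, str):
            self.model = make_model(self.model)
        if isinstance(self.protocol, str):
            self.protocol = protocol_preset(self.protocol)


def write_phantom(spec: PhantomSpec, outdir) -> dict:
    """Write a phantom as NIfTI + side-car text files; returns the paths.

    Voxels are laid out as (nrealizations, nvoxels, 1); volumes are the
    protocol's shell measurements (already direction-averaged), so the
    written data round-trip through ``read_dwi``/``spherical_mean``
    unchanged up to float32 storage.
    """
    import nibabel as nib
    from .io import VolumeSeries, save_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    nvox = max((np.asarray(v).size for v in spec.gt.values()), default=1)
    gt = {k: np.broadcast_to(np.asarray(v, float), (nvox,))
          for k, v in spec.gt.items()}
    clean = spec.model.signals(gt, spec.protocol)      # (nvox, M)
    data = np.tile(clean[None], (spec.nrealizations, 1, 1))
    if np.isfinite(spec.snr):
        data = data + rng.normal(0.0, 1.0 / spec.snr, size=data.shape)
    vol = VolumeSeries(data[:, :, None, :])
    paths = {"dwi": outdir / "phantom.nii.gz",
             "protocol": outdir / "phantom.protocol.tsv",
             "gt": outdir / "phantom.gt.tsv"}
    save_volume(vol, paths["dwi"])
    spec.protocol.save(paths["protocol"])
    pd.DataFrame(gt).to_csv(paths["gt"], sep="\t", index=False)
    p = spec.protocol
    np.savetxt(outdir / "phantom.bvals", p.bval[None], fmt="%.6g")
    if p.techo is not None:
        np.savetxt(outdir / "phantom.techo", p.techo[None], fmt="%.6g")
    if p.tdelta is not None:
        np.savetxt(outdir / "phantom.tdelta", p.tdelta[None], fmt="%.6g")
        np.savetxt(outdir / "phantom.tsmalldel", p.tsmalldel[None],
                   fmt="%.6g")
    return paths
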