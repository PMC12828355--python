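"""Data I/O: DWI volumes, acquisition side-car files, and the reduction of
directional measurements to spherical means or spherical-harmonic
rotational invariants.

Side-car conventions (whitespace-delimited text, one value per volume):
``<stem>.bvals`` (s/mm² or ms/µm², auto-detected), ``<stem>.bvecs``
(3×N or N×3), ``<stem>.techo``, ``<stem>.tdelta``, ``<stem>.tsmalldel``
(all ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocols import (B0_THRESHOLD, AcquisitionProtocol, AcquisitionTable,
                        ValidationError, b_from_pgse, g_from_pgse)

__all__ = ["VolumeSeries", "read_acquisition", "read_dwi", "spherical_mean",
           "spherical_fit", "snr_map", "save_volume"]


@dataclass
class VolumeSeries:
    """A 4D volume series with geometry and an optional mask."""
    data: np.ndarray
    affine: np.ndarray = None
    voxel_size: tuple = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise ValidationError("volume series must be 3D or 4D")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValidationError("mask shape mismatch")

    @property
    def nvolumes(self):
        return self.data.shape[3]

    def in_mask(self):
        m = self.mask if self.mask is not None \
            else np.ones(self.data.shape[:3], bool)
        return self.data[m]


def _read_txt(path):
    return np.loadtxt(path, dtype=float)


def read_acquisition(bval_path, bvec_path=None, techo_path=None,
                     tdelta_path=None, tsmalldel_path=None) -> AcquisitionTable:
    """Read acquisition side-car files into a per-volume table.

    b-values with magnitude > 100 are interpreted as s/mm² (FSL style) and
    converted to ms/µm²; all times are expected in ms.
    """
    bval = np.atleast_1d(_read_txt(bval_path)).ravel()
    if np.any(np.abs(bval) > 100):
        bval = bval / 1000.0
    n = bval.size

    def opt(path, name):
        if path is None:
            return None
        v = np.atleast_1d(_read_txt(path))
        if name == "bvec":
            return v
        v = v.ravel()
        if v.size != n:
            raise ValidationError(
                f"{name} file has {v.size} entries, expected {n}")
        return v

    return AcquisitionTable(
        bval=bval,
        bvec=opt(bvec_path, "bvec"),
        techo=opt(techo_path, "techo"),
        tdelta=opt(tdelta_path, "tdelta"),
        tsmalldel=opt(tsmalldel_path, "tsmalldel"),
    )


def read_acquisition_stem(stem) -> AcquisitionTable:
    """Read ``<stem>.bvals`` plus any sibling side-cars that exist."""
    stem = Path(stem)
    def p(ext):
        f = stem.with_suffix(ext)
        return f if f.exists() else None
    bvals = p(".bvals") or p(".bval")
    if bvals is None:
        raise FileNotFoundError(f"{stem}.bvals not found")
    return read_acquisition(bvals, p(".bvecs") or p(".bvec"), p(".techo"),
                            p(".tdelta"), p(".tsmalldel"))


def read_dwi(path, mask_path=None) -> VolumeSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return VolumeSeries(data=data, affine=img.affine,
                        voxel_size=tuple(img.header.get_zooms()[:3]),
                        mask=mask)


def save_volume(vol: VolumeSeries, path):
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine),
             str(path))


# ---------------------------------------------------------------------------
# Shell grouping

def _group_shells(table: AcquisitionTable):
    """Sorted unique shells and member volume indices, ascending (TE, b)."""
    keys = table.shell_keys()
    uniq = sorted(set(keys))
    members = [np.array([i for i, k in enumerate(keys) if k == u])
               for u in uniq]
    return uniq, members


def _protocol_from_groups(uniq, members, riorder=0) -> AcquisitionProtocol:
    def col(i):
        v = np.array([k[i] for k in uniq])
        v[v == -1.0] = np.nan
        return None if np.all(np.isnan(v)) else v
    return AcquisitionProtocol(
        bval=np.array([k[1] for k in uniq]),
        techo=col(0), tdelta=col(2), tsmalldel=col(3),
        ndirs=np.array([len(m) for m in members]),
        riorder=riorder)


def _check_cover(dwi, table):
    if len(table) != dwi.nvolumes:
        raise ValidationError(
            f"table covers {len(table)} volumes, data has {dwi.nvolumes}")


def spherical_mean(dwi: VolumeSeries, table: AcquisitionTable):
    """Direction-average per unique (TE, b, δ, Δ) shell.

    Returns one output volume per shell in ascending (TE, b) order and the
    matching shell protocol (riorder 0, ndirs = volumes averaged). NaNs
    inside the mask propagate with a warning.
    """
    _check_cover(dwi, table)
    uniq, members = _group_shells(table)
    out = np.stack([dwi.data[..., m].mean(axis=-1) for m in members],
                   axis=-1)
    mask = dwi.mask if dwi.mask is not None \
        else np.ones(dwi.data.shape[:3], bool)
    nbad = int(np.isnan(out[mask]).sum())
    if nbad:
        warnings.warn(f"{nbad} NaN spherical-mean values inside the mask",
                      RuntimeWarning, stacklevel=2)
    vol = VolumeSeries(out, affine=dwi.affine, voxel_size=dwi.voxel_size,
                       mask=dwi.mask)
    return vol, _protocol_from_groups(uniq, members, riorder=0)


def _real_sh_basis(lmax, bvecs):
    """Real, symmetric (even-order) orthonormal SH design matrix."""
    from scipy.special import sph_harm_y
    x, y, z = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    cols = []
    orders = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ylm = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                col = ylm.real
            elif m > 0:
                col = np.sqrt(2.0) * (-1.0) ** m * ylm.real
            else:
                col = np.sqrt(2.0) * (-1.0) ** m * ylm.imag
            cols.append(col)
            orders.append(l)
    return np.column_stack(cols), np.array(orders)


def spherical_fit(dwi: VolumeSeries, table: AcquisitionTable, lmax: int = 2):
    """Rotational invariants per shell from a spherical-harmonic fit.

    Per shell, the even-order real SH coefficients up to ``lmax`` are fit
    by least squares and reduced to S_l = ‖c_l‖ / √(4π(2l+1)). The
    order-0 invariant is defined as the arithmetic shell mean — identical
    to :func:`spherical_mean` by construction — and higher orders come
    from the SH fit. Output volumes are ordered order-major: all S_0
    (ascending TE, b), then all S_2, etc. Negative values inside the mask
    are clamped to zero before fitting (count logged).
    """
    if lmax % 2 != 0 or lmax < 0:
        raise ValidationError("lmax must be a nonnegative even integer")
    _check_cover(dwi, table)
    mean_vol, protocol = spherical_mean(dwi, table)
    if lmax == 0:
        return mean_vol, protocol
    if table.bvec is None:
        raise ValidationError("spherical_fit at lmax > 0 needs bvecs")
    uniq, members = _group_shells(table)
    nshell = len(uniq)
    norders = lmax // 2 + 1
    shape = dwi.data.shape[:3]
    out = np.zeros(shape + (nshell * norders,))
    out[..., :nshell] = mean_vol.data
    mask = dwi.mask if dwi.mask is not None else np.ones(shape, bool)

    nneg = 0
    for si, (key, m) in enumerate(zip(uniq, members)):
        if key[1] < B0_THRESHOLD:
            continue   # b=0 carries no directional content: S_l>0 = 0
        basis, orders = _real_sh_basis(lmax, table.bvec[m])
        if len(m) < basis.shape[1] or \
                np.linalg.matrix_rank(basis) < basis.shape[1]:
            raise ValidationError(
                f"underdetermined SH fit for shell (TE={key[0]}, b={key[1]}):"
                f" {len(m)} directions for {basis.shape[1]} coefficients")
        sig = dwi.data[..., m].reshape(-1, len(m))
        neg = sig < 0
        nneg += int(neg[mask.ravel()].sum())
        sig = np.where(neg, 0.0, sig)
        coef, *_ = np.linalg.lstsq(basis, sig.T, rcond=None)
        for oi, l in enumerate(range(2, lmax + 1, 2)):
            sel = orders == l
            sl = np.linalg.norm(coef[sel], axis=0) / \
                np.sqrt(4 * np.pi * (2 * l + 1))
            out[..., (oi + 1) * nshell + si] = sl.reshape(shape)
    if nneg:
        warnings.warn(f"clamped {nneg} negative values inside the mask "
                      "before the SH fit", RuntimeWarning, stacklevel=2)
    protocol = AcquisitionProtocol(
        bval=protocol.bval, techo=protocol.techo, tdelta=protocol.tdelta,
        tsmalldel=protocol.tsmalldel, ndirs=protocol.ndirs, riorder=lmax)
    vol = VolumeSeries(out, affine=dwi.affine, voxel_size=dwi.voxel_size,
                       mask=dwi.mask)
    return vol, protocol


def snr_map(dwi: VolumeSeries, table: AcquisitionTable) -> VolumeSeries:
    """Voxelwise SNR = mean/std of the b=0 measurements, one map per TE.

    Requires at least two b=0 volumes per echo time. Voxels with zero
    standard deviation return +inf (flagged, not an error).
    """
    _check_cover(dwi, table)
    is_b0 = table.bval < B0_THRESHOLD
    if table.techo is not None:
        tes = np.unique(np.round(table.techo[is_b0], 3))
        groups = [np.where(is_b0 & (np.round(table.techo, 3) == te))[0]
                  for te in tes]
    else:
        groups = [np.where(is_b0)[0]]
    maps = []
    for g in groups:
        if len(g) < 2:
            raise ValidationError(
                "need >= 2 b=0 volumes per TE for an SNR map")
        sub = dwi.data[..., g]
        mean = sub.mean(axis=-1)
        std = sub.std(axis=-1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            maps.append(np.where(std > 0, mean / std, np.inf))
    return VolumeSeries(np.stack(maps, axis=-1), affine=dwi.affine,
                        voxel_size=dwi.voxel_size, mask=dwi.mask)
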