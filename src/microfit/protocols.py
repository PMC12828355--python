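"""Acquisition tables and shell protocols.

Canonical units throughout the package: time in ms, length in µm,
diffusivity in µm²/ms, b-value in ms/µm², gradient amplitude in mT/m.
The gyromagnetic ratio of the proton in these units is
γ = 2.6752e-4 rad · ms⁻¹ · µm⁻¹ · (mT/m)⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GAMMA = 2.6752e-4
"""Proton gyromagnetic ratio in rad/(ms·µm·(mT/m))."""

#: b-values below this (ms/µm²) are treated as b=0 measurements.
B0_THRESHOLD = 0.05

#: decimals used when grouping volumes into shells
_SHELL_DECIMALS = 3


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


def b_from_pgse(G, tsmalldel, tdelta):
    """b-value of a pulsed-gradient spin-echo encoding.

    b = γ²G²δ²(Δ − δ/3), with gradient amplitude ``G`` (mT/m), pulse
    duration ``tsmalldel`` = δ (ms) and separation ``tdelta`` = Δ (ms).
    Returns b in ms/µm².
    """
    G = np.asarray(G, dtype=float)
    d = np.asarray(tsmalldel, dtype=float)
    D = np.asarray(tdelta, dtype=float)
    if np.any(G < 0):
        raise ValidationError("gradient amplitude must be >= 0")
    if np.any((d <= 0) | (d >= D)):
        raise ValidationError("require 0 < delta < Delta")
    return GAMMA**2 * G**2 * d**2 * (D - d / 3.0)


def g_from_pgse(b, tsmalldel, tdelta):
    """Gradient amplitude (mT/m) that yields b-value ``b`` for given δ, Δ.

    Algebraic inverse of :func:`b_from_pgse`.
    """
    b = np.asarray(b, dtype=float)
    d = np.asarray(tsmalldel, dtype=float)
    D = np.asarray(tdelta, dtype=float)
    if np.any(b < 0):
        raise ValidationError("b must be >= 0")
    if np.any((d <= 0) | (d >= D)):
        raise ValidationError("require 0 < delta < Delta")
    return np.sqrt(b / (GAMMA**2 * d**2 * (D - d / 3.0)))


@dataclass
class AcquisitionTable:
    """Per-volume acquisition parameters.

    ``bval`` is mandatory; direction vectors, echo times and diffusion
    gradient timings are optional side-cars. All arrays share one entry
    per DWI volume.
    """

    bval: np.ndarray
    bvec: np.ndarray | None = None
    techo: np.ndarray | None = None
    tdelta: np.ndarray | None = None
    tsmalldel: np.ndarray | None = None

    def __post_init__(self):
        self.bval = np.asarray(self.bval, dtype=float).ravel()
        n = self.bval.size
        if np.any(self.bval < 0):
            raise ValidationError("negative b-values")
        for name in ("techo", "tdelta", "tsmalldel"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float).ravel()
                if v.size != n:
                    raise ValidationError(
                        f"{name} has {v.size} entries, expected {n}")
                setattr(self, name, v)
        if self.bvec is not None:
            bv = np.asarray(self.bvec, dtype=float)
            if bv.shape == (3, n) and n != 3:
                bv = bv.T
            if bv.shape != (n, 3):
                raise ValidationError(
                    f"bvec shape {bv.shape} incompatible with {n} volumes")
            norms = np.linalg.norm(bv, axis=1)
            ok = (norms < 1e-6) | (np.abs(norms - 1.0) < 1e-3)
            if not np.all(ok):
                raise ValidationError("bvec norms must be 0 or 1 (±1e-3)")
            self.bvec = bv
        if self.tdelta is not None and self.tsmalldel is not None:
            dw = self.bval > B0_THRESHOLD
            if np.any(self.tsmalldel[dw] >= self.tdelta[dw]):
                raise ValidationError("require delta < Delta on DW volumes")

    def __len__(self):
        return self.bval.size

    def shell_keys(self):
        """Rounded (TE, b, δ, Δ) tuple per volume; b=0 collapses b, δ, Δ.

        Missing values are encoded as -1.0 (never a valid time or b) so
        the tuples group and sort reliably.
        """
        n = len(self)
        def col(v):
            return np.round(np.nan_to_num(v, nan=-1.0), _SHELL_DECIMALS) \
                if v is not None else np.full(n, -1.0)
        b = np.round(self.bval, _SHELL_DECIMALS)
        te = col(self.techo)
        de = col(self.tdelta)
        sd = col(self.tsmalldel)
        is_b0 = self.bval < B0_THRESHOLD
        b = np.where(is_b0, 0.0, b)
        de = np.where(is_b0, -1.0, de)
        sd = np.where(is_b0, -1.0, sd)
        return [tuple(float(x) for x in row) for row in zip(te, b, de, sd)]


@dataclass
class AcquisitionProtocol:
    """Per-shell acquisition and estimation parameters.

    Shells are unique (b, TE, δ, Δ) combinations; ``gradient`` is derived
    from b through the PGSE relation when timings are available; ``ndirs``
    records how many measurements entered each shell's rotational
    invariant; ``riorder`` is the maximum rotational-invariant order the
    associated measurements carry (0 = spherical mean).
    """

    bval: np.ndarray
    techo: np.ndarray | None = None
    tdelta: np.ndarray | None = None
    tsmalldel: np.ndarray | None = None
    ndirs: np.ndarray | None = None
    riorder: int = 0
    gradient: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.bval = np.asarray(self.bval, dtype=float).ravel()
        n = self.bval.size
        for name in ("techo", "tdelta", "tsmalldel"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float).ravel())
        if self.ndirs is None:
            self.ndirs = np.ones(n, dtype=int)
        else:
            self.ndirs = np.asarray(self.ndirs, dtype=int).ravel()
            if np.any(self.ndirs < 1):
                raise ValidationError("ndirs must be >= 1")
        if self.riorder not in (0, 2):
            raise ValidationError("riorder must be 0 or 2")
        if self.gradient is None:
            self.gradient = self._derive_gradient()
        keys = list(zip(*[np.round(np.nan_to_num(v, nan=-1.0),
                                   _SHELL_DECIMALS)
                          for v in (self.bval,
                                    self._or_nan(self.techo),
                                    self._or_nan(self.tdelta),
                                    self._or_nan(self.tsmalldel))]))
        if len(set(keys)) != n:
            raise ValidationError("shells not unique on (b, TE, delta, Delta)")

    def _or_nan(self, v):
        return v if v is not None else np.full(self.bval.size, np.nan)

    def _derive_gradient(self):
        g = np.full(self.bval.size, np.nan)
        if self.tdelta is None or self.tsmalldel is None:
            return g
        for i, (b, de, sd) in enumerate(
                zip(self.bval, self.tdelta, self.tsmalldel)):
            if b < B0_THRESHOLD:
                g[i] = 0.0
            elif np.isfinite(de) and np.isfinite(sd):
                g[i] = g_from_pgse(b, sd, de)
        return g

    def __len__(self):
        return self.bval.size

    @property
    def nmeasurements(self):
        """Length of a measurement vector (shells × number of orders)."""
        return len(self) * (self.riorder // 2 + 1)

    @property
    def multi_te(self):
        return self.techo is not None and \
            np.unique(np.round(self.techo, _SHELL_DECIMALS)).size > 1

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame({
            "bval": self.bval,
            "techo": self._or_nan(self.techo),
            "tdelta": self._or_nan(self.tdelta),
            "tsmalldel": self._or_nan(self.tsmalldel),
            "gradient": self.gradient,
            "ndirs": self.ndirs,
            "riorder": np.full(n, self.riorder, dtype=int),
        })

    def save(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6g")

    @classmethod
    def load(cls, path) -> "AcquisitionProtocol":
        df = pd.read_csv(path, sep="\t")
        def opt(c):
            v = df[c].to_numpy(float)
            return None if np.all(np.isnan(v)) else v
        return cls(bval=df["bval"].to_numpy(float),
                   techo=opt("techo"), tdelta=opt("tdelta"),
                   tsmalldel=opt("tsmalldel"),
                   ndirs=df["ndirs"].to_numpy(int),
                   riorder=int(df["riorder"].iloc[0]))
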