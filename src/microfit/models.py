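"""Multi-compartment tissue models for spherical-mean and rotational-
invariant measurements.

A :class:`BiophysicalModel` is a fraction-weighted mixture of compartments
with named model-level parameters. Parameters may be *free* (with bounds),
*fixed* (constants), or *linked* (derived from other parameters, e.g. the
tortuosity relation D⊥ec = (1−fia)·D∥). Compartment signal fractions form
a simplex: the model stores the leading k−1 fractions as free parameters
and derives the last one.

Named constructors (:func:`make_model`) build the standard white- and
gray-matter models: SMT, MTE_SMT, SANDI, SANDIdot, MTE_SANDI, ExCaliber,
SMI and SMIfw. All parameter values are in canonical units (ms, µm,
µm²/ms).

``signals`` accepts scalar parameter values (one voxel) or equal-length
arrays (a batch of voxels/training samples); the forward physics is
vectorized across the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import compartments as cpt
from .compartments import (DEFAULT_GPD_TERMS, Cylinder, Iso, IsoKernel,
                           Sphere, Stick, StickKernel, Zeppelin,
                           ZeppelinKernel)
from .protocols import B0_THRESHOLD, AcquisitionProtocol, ValidationError

MODEL_NAMES = ("SMT", "MTE_SMT", "SANDI", "SANDIdot", "MTE_SANDI",
               "ExCaliber", "SMI", "SMIfw")


@dataclass
class Slot:
    """One compartment of a mixture.

    ``fields`` maps compartment constructor fields to either a model-level
    parameter name (str) or a literal constant (float).
    """
    label: str
    cls: type
    fields: dict


@dataclass
class BiophysicalModel:
    name: str
    slots: list
    fraction_names: list          # k-1 free fraction parameters, slot order
    free: dict                    # param name -> (lo, hi)
    fixed: dict = field(default_factory=dict)
    links: dict = field(default_factory=dict)  # name -> callable(params)
    riorder: int = 0
    has_fodf: bool = False        # adds the p2 invariant at order 2
    notes: dict = field(default_factory=dict)

    # -- parameter handling -------------------------------------------------

    @property
    def free_names(self):
        return list(self.free)

    def default_values(self):
        """Midpoint-of-bounds starting values for the free parameters."""
        return {k: 0.5 * (lo + hi) for k, (lo, hi) in self.free.items()}

    def resolve(self, values: dict) -> dict:
        """Full parameter dictionary: free values + fixed + links."""
        missing = set(self.free) - set(values)
        if missing:
            raise ValidationError(f"missing free parameters: {sorted(missing)}")
        full = dict(self.fixed)
        full.update({k: values[k] for k in self.free})
        for name, fn in self.links.items():
            full[name] = fn(full)
        return full

    def fractions(self, full: dict):
        """Per-slot signal fractions (the last one derived from the simplex)."""
        fr = [np.asarray(full[n], dtype=float) for n in self.fraction_names]
        rest = 1.0
        for f in fr:
            rest = rest - f
        fr.append(np.asarray(rest))
        return fr

    def with_fixed(self, **values) -> "BiophysicalModel":
        """Copy of the model with the given free parameters fixed."""
        free = dict(self.free)
        fixed = dict(self.fixed)
        fractions = list(self.fraction_names)
        for k, v in values.items():
            if k not in free:
                raise ValidationError(f"{k} is not a free parameter")
            del free[k]
            fixed[k] = float(v)
            if k in fractions:
                raise ValidationError(
                    f"cannot fix fraction {k}; fix the others instead")
        return BiophysicalModel(self.name, self.slots, fractions, free,
                                fixed, dict(self.links), self.riorder,
                                self.has_fodf, dict(self.notes))

    # -- forward prediction --------------------------------------------------

    def signals(self, values: dict, protocol: AcquisitionProtocol,
                nterms=DEFAULT_GPD_TERMS, validate=True) -> np.ndarray:
        """Normalized measurement vector for one voxel or a batch.

        Order-0 models return one value per shell; order-2 models return
        the concatenation [S0 per shell, S2 per shell]. With echo times
        present, the vector is normalized by the predicted signal at
        (minimum TE, b=0); this global-reference convention is recorded in
        ``notes['te_normalization']``.
        """
        if self.riorder > protocol.riorder and self.riorder > 0:
            raise ValidationError(
                f"model predicts order {self.riorder} invariants but the "
                f"protocol carries riorder={protocol.riorder}")
        full = self.resolve(values)
        fracs = self.fractions(full)
        if validate:
            last = np.asarray(fracs[-1])
            allf = np.stack([np.broadcast_to(np.asarray(f, float), last.shape)
                             for f in fracs])
            if np.any(allf < -1e-9) or np.any(allf > 1 + 1e-9):
                raise ValidationError("signal fractions outside the simplex")

        batch = max((np.asarray(full[k]).ndim for k in full), default=0) > 0
        s0 = 0.0
        s2 = 0.0
        ref = 0.0
        tmin = None
        if protocol.techo is not None:
            tmin = float(np.min(protocol.techo))
        for slot, f in zip(self.slots, fracs):
            vals = {k: (full[v] if isinstance(v, str) else v)
                    for k, v in slot.fields.items()}
            f = np.asarray(f, dtype=float)
            fcol = f[..., None] if f.ndim else f
            s0 = s0 + fcol * _slot_signal(slot.cls, vals, protocol, 0, nterms)
            if self.riorder == 2:
                s2 = s2 + fcol * _slot_signal(slot.cls, vals, protocol, 2,
                                              nterms)
            if tmin is not None:
                ref = ref + fcol * _relax_at(vals.get("t2", 0.0), tmin)
        if tmin is None:
            ref = 1.0
        out = s0 / ref
        if self.riorder == 2:
            p2 = np.asarray(full["p2"], dtype=float) if self.has_fodf else 1.0
            p2col = p2[..., None] if getattr(p2, "ndim", 0) else p2
            # measured rotational invariants are magnitudes ||c_l||, so the
            # prediction is |p2 · Σ f_i K2_i| (kernel projections are signed)
            out = np.concatenate([out, np.abs(p2col * s2 / ref) +
                                  np.zeros_like(out)], axis=-1)
        return out if batch else np.asarray(out).ravel()


def _col(v):
    v = np.asarray(v, dtype=float)
    return v[..., None] if v.ndim else v


def _relax_at(t2, te):
    t2 = np.asarray(t2, dtype=float)
    safe = np.where(t2 > 0, t2, 1.0)
    return np.where(t2 > 0, np.exp(-te / safe), 1.0)


def _relax_vec(t2, protocol):
    if protocol.techo is None:
        return 1.0
    t2 = _col(t2)
    safe = np.where(t2 > 0, t2, 1.0)
    return np.where(t2 > 0, np.exp(-protocol.techo / safe), 1.0)


def _gpd_vec(kind, radius, d0, protocol, nterms):
    """Vectorized GPD log-attenuation, safe for b=0 / missing timings."""
    if protocol.tdelta is None or protocol.tsmalldel is None:
        raise ValidationError(f"{kind} model needs delta/Delta in protocol")
    G = np.where(np.isfinite(protocol.gradient), protocol.gradient, 0.0)
    sd = np.where(np.isfinite(protocol.tsmalldel), protocol.tsmalldel, 1.0)
    de = np.where(np.isfinite(protocol.tdelta), protocol.tdelta, 2.0)
    return cpt.gpd_log_attenuation(kind, _col(radius), _col(d0), G, sd, de,
                                   nterms)


def _slot_signal(cls, vals, protocol, order, nterms):
    """Signal of one compartment, vectorized over batched parameter values."""
    b = protocol.bval
    rel = _relax_vec(vals.get("t2", 0.0), protocol)
    if order == 0:
        if issubclass(cls, (StickKernel, ZeppelinKernel, IsoKernel)):
            dpara, dperp = _kernel_d(cls, vals)
            return rel * cpt.kernel_invariant_gl(b * _col(dpara),
                                                 b * _col(dperp), 0)
        if issubclass(cls, Stick):
            return rel * cpt._sm_factor(b * _col(vals["dpara"]))
        if issubclass(cls, Zeppelin):
            dpara = np.asarray(vals["dpara"], dtype=float)
            dperp = dpara * np.asarray(vals["dperp_frac"], dtype=float)
            return rel * cpt.zeppelin_like_sm(b, _col(dpara), _col(dperp))
        if issubclass(cls, Cylinder):
            la = _gpd_vec("cylinder", np.asarray(vals["da"]) / 2.0,
                          vals["d0"], protocol, nterms)
            dperp = -la / np.where(b > B0_THRESHOLD, b, 1.0)
            return rel * cpt.zeppelin_like_sm(b, _col(vals["dpara"]), dperp)
        if issubclass(cls, Sphere):
            la = _gpd_vec("sphere", vals["rs"], vals["dis"], protocol, nterms)
            return rel * np.exp(la)
        if issubclass(cls, Iso):
            return rel * np.exp(-b * _col(vals["d"]))
        raise ValidationError(f"unsupported compartment {cls.__name__}")
    # order 2: only kernel compartments contribute
    if issubclass(cls, (StickKernel, ZeppelinKernel, IsoKernel)):
        dpara, dperp = _kernel_d(cls, vals)
        return rel * cpt.kernel_invariant_gl(b * _col(dpara),
                                             b * _col(dperp), 2)
    return np.zeros(len(protocol))


def _kernel_d(cls, vals):
    if issubclass(cls, StickKernel):
        return np.asarray(vals["dpara"], float), 0.0
    if issubclass(cls, ZeppelinKernel):
        dpara = np.asarray(vals["dpara"], float)
        return dpara, dpara * np.asarray(vals["dperp_frac"], float)
    return np.asarray(vals["d"], float), np.asarray(vals["d"], float)


# ---------------------------------------------------------------------------
# Named model constructors

def make_model(name: str, tissue: str = "exvivo", tortuosity: bool = False,
               shared_dpara: bool = True, fix: dict | None = None,
               bounds: dict | None = None) -> BiophysicalModel:
    """Build one of the named tissue models.

    Parameters
    ----------
    name:
        One of SMT, MTE_SMT, SANDI, SANDIdot, MTE_SANDI, ExCaliber, SMI,
        SMIfw (case-insensitive).
    tissue:
        For ExCaliber: 'exvivo' uses a zero-diffusivity dot compartment,
        'invivo' a free-water compartment (D = 3 µm²/ms).
    tortuosity:
        For SMT-family models: link D⊥ec = (1 − fia) · D∥ instead of
        estimating the perpendicular fraction.
    shared_dpara:
        Share the parallel diffusivity between the intra- and
        extra-cellular compartments (default, matching the standard SMT
        and ExCaliber assumptions). If False, SMT/SMI estimate separate
        ``dpara_ia``/``dpara_ec``.
    fix / bounds:
        Optional overrides: parameters to fix at given values, and
        replacement (lo, hi) bounds for free parameters.
    """
    key = name.lower()
    builders = {
        "smt": _smt, "mte_smt": _mte_smt, "sandi": _sandi,
        "sandidot": _sandidot, "mte_sandi": _mte_sandi,
        "excaliber": _excaliber, "smi": _smi, "smifw": _smifw,
    }
    if key not in builders:
        raise ValidationError(
            f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if tortuosity and key not in ("smt", "mte_smt"):
        raise ValidationError("tortuosity link applies to SMT-family models")
    m = builders[key](tissue=tissue, tortuosity=tortuosity,
                      shared_dpara=shared_dpara)
    if bounds:
        for k, v in bounds.items():
            if k not in m.free:
                raise ValidationError(f"{k} is not a free parameter")
            m.free[k] = (float(v[0]), float(v[1]))
    if fix:
        m = m.with_fixed(**fix)
    return m


def _smt(tissue, tortuosity, shared_dpara, t2=False):
    dp_ia = "dpara" if shared_dpara else "dpara_ia"
    dp_ec = "dpara" if shared_dpara else "dpara_ec"
    slots = [
        Slot("ia", Stick, {"dpara": dp_ia, "t2": "t2ia" if t2 else 0.0}),
        Slot("ec", Zeppelin, {"dpara": dp_ec, "dperp_frac": "dperp_frac",
                              "t2": "t2ec" if t2 else 0.0}),
    ]
    free = {"fia": (0.0, 1.0)}
    for d in dict.fromkeys([dp_ia, dp_ec]):
        free[d] = (1.0, 3.0)
    links = {}
    if tortuosity:
        links["dperp_frac"] = lambda p: 1.0 - p["fia"]
    else:
        free["dperp_frac"] = (0.0, 1.0)
    if t2:
        free["t2ia"] = (40.0, 200.0)
        free["t2ec"] = (40.0, 200.0)
    return BiophysicalModel("MTE_SMT" if t2 else "SMT", slots, ["fia"],
                            free, links=links,
                            notes={"te_normalization": "global-min-TE-b0"})


def _mte_smt(tissue, tortuosity, shared_dpara):
    return _smt(tissue, tortuosity, shared_dpara, t2=True)


def _sandi(tissue, tortuosity, shared_dpara, dot=False, t2=False):
    slots = [
        Slot("is", Sphere, {"dis": "dis", "rs": "rs",
                            "t2": "t2is" if t2 else 0.0}),
        Slot("in", Stick, {"dpara": "din", "t2": "t2in" if t2 else 0.0}),
        Slot("ec", Iso, {"d": "dec", "t2": "t2ec" if t2 else 0.0}),
    ]
    fractions = ["fis", "fin"]
    if dot:
        slots.append(Slot("dot", Iso, {"d": 0.0}))
        fractions = ["fis", "fin", "fec"]
    free = {f: (0.0, 1.0) for f in fractions}
    free.update({"rs": (2.0, 12.0), "din": (1.5, 2.5), "dec": (0.5, 3.0)})
    fixed = {"dis": 3.0}
    if t2:
        free.update({"t2is": (40.0, 200.0), "t2in": (40.0, 200.0),
                     "t2ec": (40.0, 200.0)})
    name = "MTE_SANDI" if t2 else ("SANDIdot" if dot else "SANDI")
    return BiophysicalModel(name, slots, fractions, free, fixed=fixed,
                            notes={"te_normalization": "global-min-TE-b0"})


def _sandidot(tissue, tortuosity, shared_dpara):
    return _sandi(tissue, tortuosity, shared_dpara, dot=True)


def _mte_sandi(tissue, tortuosity, shared_dpara):
    return _sandi(tissue, tortuosity, shared_dpara, t2=True)


def _excaliber(tissue, tortuosity, shared_dpara):
    d_dot = 0.0 if tissue == "exvivo" else 3.0
    slots = [
        Slot("ia", Cylinder, {"da": "da", "d0": "dpara", "dpara": "dpara"}),
        Slot("ec", Zeppelin, {"dpara": "dpara", "dperp_frac": "dperp_frac"}),
        Slot("dot", Iso, {"d": d_dot}),
    ]
    dp_hi = 1.2 if tissue == "exvivo" else 3.0
    free = {"da": (0.1, 12.0), "fia": (0.0, 1.0), "fdot": (0.0, 1.0),
            "dpara": (0.1, dp_hi), "dperp_frac": (0.0, 1.0)}
    m = BiophysicalModel("ExCaliber", slots, ["fia", "fdot"], free,
                         notes={"tissue": tissue,
                                "te_normalization": "global-min-TE-b0"})
    if not shared_dpara:
        raise ValidationError(
            "ExCaliber assumes equal intra/extra parallel diffusivity")
    return m


def _smi(tissue, tortuosity, shared_dpara, fw=False):
    dp_ia = "dpara" if shared_dpara else "dpara_ia"
    dp_ec = "dpara" if shared_dpara else "dpara_ec"
    slots = [
        Slot("ia", StickKernel, {"dpara": dp_ia, "t2": "t2ia"}),
        Slot("ec", ZeppelinKernel, {"dpara": dp_ec,
                                    "dperp_frac": "dperp_frac",
                                    "t2": "t2ec"}),
    ]
    fractions = ["fia"]
    fixed = {}
    if fw:
        # free fractions are positional with the leading slots, so the free
        # water kernel sits second and the extra-cellular fraction is derived
        slots.insert(1, Slot("iso", IsoKernel, {"d": "diso", "t2": "t2iso"}))
        fractions = ["fia", "fiso"]
        fixed = {"diso": 3.0, "t2iso": 2000.0}
    free = {f: (0.0, 1.0) for f in fractions}
    for d in dict.fromkeys([dp_ia, dp_ec]):
        free[d] = (1.0, 3.0)
    free.update({"dperp_frac": (0.0, 1.0), "p2": (0.0, 1.0),
                 "t2ia": (40.0, 200.0), "t2ec": (40.0, 200.0)})
    return BiophysicalModel("SMIfw" if fw else "SMI", slots, fractions,
                            free, fixed=fixed, riorder=2, has_fodf=True,
                            notes={"te_normalization": "global-min-TE-b0"})


def _smifw(tissue, tortuosity, shared_dpara):
    return _smi(tissue, tortuosity, shared_dpara, fw=True)


def model_signals(model: BiophysicalModel, values: dict,
                  protocol: AcquisitionProtocol, **kw) -> np.ndarray:
    """Functional alias for :meth:`BiophysicalModel.signals`."""
    return model.signals(values, protocol, **kw)


# ---------------------------------------------------------------------------
# Parameter vector packing (stick-breaking simplex encoding)

@dataclass
class ParameterVector:
    values: np.ndarray
    names: list
    bounds: list
    transforms: list

    def __len__(self):
        return self.values.size


def pack_parameters(model: BiophysicalModel, values: dict) -> ParameterVector:
    """Flatten free parameters; fractions become stick-breaking coordinates.

    The k−1 free fractions (f₁ … f_{k−1}) map to v_i = f_i / (1 − Σ_{j<i} f_j)
    so each coordinate is free in [0, 1]. Linked and fixed parameters are
    excluded. Out-of-bounds values raise with the offending names.
    """
    bad = []
    for k, (lo, hi) in model.free.items():
        v = values[k]
        if not (lo - 1e-12 <= v <= hi + 1e-12):
            bad.append(k)
    if bad:
        raise ValidationError(f"values out of bounds: {sorted(bad)}")
    out, names, bounds, transforms = [], [], [], []
    remaining = 1.0
    for fname in model.fraction_names:
        f = values[fname]
        out.append(f / remaining if remaining > 0 else 0.0)
        remaining -= f
        names.append(fname)
        bounds.append((0.0, 1.0))
        transforms.append("simplex")
    for k in model.free:
        if k in model.fraction_names:
            continue
        out.append(values[k])
        names.append(k)
        bounds.append(model.free[k])
        transforms.append("identity")
    return ParameterVector(np.array(out, dtype=float), names, bounds,
                           transforms)


def unpack_parameters(model: BiophysicalModel, vector) -> dict:
    """Inverse of :func:`pack_parameters`."""
    vals = vector.values if isinstance(vector, ParameterVector) \
        else np.asarray(vector, dtype=float)
    nf = len(model.fraction_names)
    out = {}
    remaining = 1.0
    for i, fname in enumerate(model.fraction_names):
        f = vals[i] * remaining
        out[fname] = f
        remaining -= f
    others = [k for k in model.free if k not in model.fraction_names]
    for k, v in zip(others, vals[nf:]):
        out[k] = float(v)
    return out
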