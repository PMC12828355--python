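"""Axon-diameter sensitivity range of a pulsed-gradient acquisition.

The direction-averaged cylinder signal is statistically distinguishable
from its two reference levels — the zero-diameter (stick) signal above
and the noise floor below — only for diameters whose signal falls inside
[σ̄, S_stick − σ̄], where σ̄ = z_α / (SNR₀ · √n) is the smallest robustly
measurable attenuation for n direction-averaged measurements at b=0
signal-to-noise ratio SNR₀.

For a single shell this yields crossing-point diameter bounds; for
multi-shell acquisitions the bounds are taken as the diameters minimizing
the summed squared error between the cylinder signal and the respective
signal bound across shells, restricting the noise-floor (upper-diameter)
search to high-b shells, whose signal decays low enough to reach the
floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .compartments import DEFAULT_GPD_TERMS, gpd_log_attenuation, _sm_factor
from .protocols import ValidationError, g_from_pgse

__all__ = ["Shell", "SensitivityConfig", "min_detectable_attenuation",
           "diameter_bounds_single_b", "diameter_bounds_multi_b",
           "UNBOUNDED"]

#: sentinel returned when a bound runs into the edge of the search grid
UNBOUNDED = float("nan")


@dataclass(frozen=True)
class Shell:
    """One PGSE shell: b (ms/µm²), δ and Δ (ms); G derived if omitted."""
    b: float
    tsmalldel: float
    tdelta: float
    G: float = None

    def __post_init__(self):
        if self.G is None:
            object.__setattr__(self, "G",
                               float(g_from_pgse(self.b, self.tsmalldel,
                                                 self.tdelta)))
        else:
            b_check = (self.G, self.tsmalldel, self.tdelta)
            from .protocols import b_from_pgse
            if abs(b_from_pgse(*b_check) - self.b) > 1e-6 * max(self.b, 1.0):
                raise ValidationError(
                    "shell G inconsistent with b via the PGSE relation")


@dataclass
class SensitivityConfig:
    """Tissue, noise and search-grid settings for the sensitivity range.

    ``d0``: intrinsic diffusivity inside the cylinder (µm²/ms);
    ``dpara``: parallel diffusivity of the zero-diameter reference stick
    (defaults to d0); ``snr_b0``: SNR of a single b=0 measurement;
    ``ndirs``: measurements averaged per shell; ``alpha``: one-sided
    significance level; the diameter grid spans [lo, hi] µm at ``step``.
    """
    d0: float = 0.6
    dpara: float | None = None
    snr_b0: float = 100.0
    ndirs: int = 32
    alpha: float = 0.05
    grid_lo: float = 0.1
    grid_hi: float = 20.0
    grid_step: float = 0.01
    high_b_threshold: float = 15.0
    nterms: int = DEFAULT_GPD_TERMS

    def __post_init__(self):
        if self.dpara is None:
            self.dpara = self.d0
        if self.snr_b0 <= 0 or self.ndirs < 1:
            raise ValidationError("snr_b0 must be > 0 and ndirs >= 1")
        if not (self.grid_lo < self.grid_hi and self.grid_step > 0):
            raise ValidationError("invalid diameter grid")

    @property
    def grid(self):
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step))
        return self.grid_lo + self.grid_step * np.arange(n + 1)

    @property
    def sigma_bar(self):
        return min_detectable_attenuation(self.snr_b0, self.ndirs,
                                          self.alpha)


def min_detectable_attenuation(snr_b0, ndirs, alpha=0.05) -> float:
    """Smallest robustly measurable attenuation σ̄ = z_α / (SNR₀·√n).

    Direction averaging over n measurements reduces the noise standard
    deviation by √n; z_α is the one-sided normal quantile (1.64 at
    α = 0.05).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if snr_b0 <= 0 or ndirs < 1:
        raise ValidationError("snr_b0 must be > 0 and ndirs >= 1")
    z = norm.ppf(1.0 - alpha)
    return z / (snr_b0 * np.sqrt(ndirs))


def _cylinder_curve(shell: Shell, cfg: SensitivityConfig):
    """Spherical-mean cylinder signal over the diameter grid (no T2)."""
    grid = cfg.grid
    la = gpd_log_attenuation("cylinder", grid / 2.0, cfg.d0, shell.G,
                             shell.tsmalldel, shell.tdelta, cfg.nterms)
    dperp = -la / shell.b
    d = np.maximum(cfg.dpara - dperp, 0.0)
    return np.exp(-shell.b * dperp) * _sm_factor(shell.b * d)


def _stick_level(shell: Shell, cfg: SensitivityConfig):
    return float(_sm_factor(np.asarray(shell.b * cfg.dpara)))


def diameter_bounds_single_b(shell: Shell,
                             cfg: SensitivityConfig) -> tuple:
    """(d_min, d_max) detectable at a single shell.

    d_min is the smallest grid diameter whose cylinder signal drops below
    S_stick − σ̄; d_max the largest whose signal stays above σ̄. A bound
    that runs into a grid edge is returned as NaN (``UNBOUNDED``); a shell
    with S_stick < 2σ̄ has no sensitive range and returns (NaN, NaN) with
    the ``empty`` flag set.
    """
    sb = cfg.sigma_bar
    s_stick = _stick_level(shell, cfg)
    if s_stick < 2 * sb:
        return UNBOUNDED, UNBOUNDED, {"empty": True}
    grid = cfg.grid
    s_cyl = _cylinder_curve(shell, cfg)
    below = s_cyl <= s_stick - sb
    above = s_cyl >= sb
    d_min = grid[np.argmax(below)] if below.any() else UNBOUNDED
    d_max = grid[len(grid) - 1 - np.argmax(above[::-1])] \
        if above.any() else UNBOUNDED
    flags = {"empty": False,
             "lower_unbounded": bool(below.all() or not below.any()),
             "upper_unbounded": bool(above.all() or not above.any())}
    if flags["lower_unbounded"]:
        d_min = UNBOUNDED
    if flags["upper_unbounded"]:
        d_max = UNBOUNDED
    return d_min, d_max, flags


def diameter_bounds_multi_b(shells, cfg: SensitivityConfig) -> tuple:
    """(d_min, d_max) from the multi-shell mean-squared-error criterion.

    d_min minimizes Σ_shells (S_cyl(d) − (S_stick − σ̄))² over all shells;
    d_max minimizes Σ (S_cyl(d) − σ̄)² over the high-b shells only
    (b ≥ ``cfg.high_b_threshold``). Ties break toward the smaller
    diameter (argmin returns the first minimum on the ascending grid).
    """
    shells = list(shells)
    if not shells:
        raise ValidationError("need at least one shell")
    high_b = [s for s in shells if s.b >= cfg.high_b_threshold]
    if not high_b:
        raise ValidationError(
            f"no shells with b >= {cfg.high_b_threshold} for the "
            "upper-bound search")
    sb = cfg.sigma_bar
    grid = cfg.grid
    lo_mse = np.zeros_like(grid)
    hi_mse = np.zeros_like(grid)
    for s in shells:
        curve = _cylinder_curve(s, cfg)
        lo_mse += (curve - (_stick_level(s, cfg) - sb)) ** 2
        if s.b >= cfg.high_b_threshold:
            hi_mse += (curve - sb) ** 2
    d_min = float(grid[np.argmin(lo_mse)])
    d_max = float(grid[np.argmin(hi_mse)])
    return d_min, d_max


def sensitivity_table(shells, cfgs) -> "pd.DataFrame":
    """Multi-shell bounds for several configurations (e.g. SNR levels)."""
    import pandas as pd
    rows = []
    for cfg in cfgs:
        d_min, d_max = diameter_bounds_multi_b(shells, cfg)
        rows.append({"snr_b0": cfg.snr_b0, "ndirs": cfg.ndirs,
                     "d0": cfg.d0, "sigma_bar": cfg.sigma_bar,
                     "d_min": d_min, "d_max": d_max})
    return pd.DataFrame(rows)
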