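"""Temporal SNR, grey-white contrast-to-noise, and t-test power analysis.

Raw tSNR is the voxel's temporal mean over its temporal SD; effective tSNR
replaces the SD with that of the GLM residuals (noise after removing
modelled variance); per-unit-time tSNR multiplies by the square root of the
sampling rate, crediting schemes that acquire more volumes per second.
The power calculator inverts the noncentral-t power function of a
one-sample t-test to give the smallest standardized effect size detectable
at given sample size, alpha and power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import VolumeSeries
from .firstlevel import GLMFit

__all__ = [
    "TsnrMaps",
    "PowerSpec",
    "tsnr_maps",
    "gm_wm_cnr",
    "detectable_effect_size",
    "power_of_test",
]


@dataclass
class TsnrMaps:
    """Raw, effective and per-unit-time temporal SNR maps (all >= 0)."""

    raw: np.ndarray
    effective: np.ndarray | None
    per_unit_time: np.ndarray | None
    mask: np.ndarray


def tsnr_maps(series: VolumeSeries, fit: GLMFit | None = None,
              mask: np.ndarray | None = None) -> TsnrMaps:
    """Temporal SNR maps of one run.

    ``raw = mean / SD``; with a fitted GLM, ``effective = mean /
    SD(residuals)`` and ``per_unit_time = effective * sqrt(1 / tr)``.
    Zero-SD voxels are masked out rather than set infinite.
    """
    if series.n_volumes < 10:
        raise ValueError("need >= 10 timepoints")
    m = (mask if mask is not None else
         (series.mask if series.mask is not None
          else np.ones(series.shape, bool))).astype(bool)
    data = series.data.astype(float)
    mean = data.mean(axis=3)
    sd = data.std(axis=3, ddof=1)
    good = m & (sd > 0)
    raw = np.zeros(series.shape)
    raw[good] = mean[good] / sd[good]
    effective = per_unit = None
    if fit is not None:
        rsd = fit.residuals.data.astype(float).std(axis=3, ddof=1)
        good = good & (rsd > 0)
        effective = np.zeros(series.shape)
        effective[good] = mean[good] / rsd[good]
        per_unit = effective * np.sqrt(1.0 / series.tr)
    return TsnrMaps(raw=raw, effective=effective, per_unit_time=per_unit,
                    mask=good)


def gm_wm_cnr(series: VolumeSeries, gm_mask: np.ndarray,
              wm_mask: np.ndarray) -> float:
    """Grey-white baseline contrast over pooled temporal noise.

    ``(mean GM baseline - mean WM baseline) / pooled temporal SD`` where the
    baseline is the temporal mean and the pooled SD averages the voxelwise
    temporal SDs of both tissues.
    """
    gm, wm = gm_mask.astype(bool), wm_mask.astype(bool)
    if not gm.any() or not wm.any():
        raise ValueError("tissue masks must be nonempty")
    data = series.data.astype(float)
    mean = data.mean(axis=3)
    sd = data.std(axis=3, ddof=1)
    pooled_sd = float(np.concatenate([sd[gm], sd[wm]]).mean())
    if pooled_sd == 0:
        raise ValueError("zero temporal noise: CNR undefined")
    return float((mean[gm].mean() - mean[wm].mean()) / pooled_sd)


def power_of_test(n: int, d: float, alpha: float = 0.05, tails: int = 1) -> float:
    """Power of a one-sample t-test of effect size ``d`` with ``n`` subjects.

    Noncentral-t tail probability beyond the central-t critical value;
    ``tails=2`` halves alpha (the tiny contribution of the opposite tail is
    ignored, as usual).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    dof = n - 1
    a = alpha / tails
    t_crit = stats.t.ppf(1.0 - a, dof)
    ncp = d * np.sqrt(n)
    return float(stats.nct.sf(t_crit, dof, ncp))


def detectable_effect_size(n: int, alpha: float = 0.05, power: float = 0.80,
                           tails: int = 1) -> float:
    """Smallest standardized effect size detectable with the requested power.

    Root of ``power_of_test(n, d) = power`` in ``d``, found by bisection on
    the noncentral-t power function (monotone increasing in ``d``).
    """
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    f = lambda d: power_of_test(n, d, alpha=alpha, tails=tails) - power
    lo, hi = 0.0, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("requested power unattainable")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


@dataclass(frozen=True)
class PowerSpec:
    """A power-analysis scenario; ``d`` is filled by ``solve``."""

    n: int
    alpha: float = 0.05
    power: float = 0.80
    tails: int = 1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")

    def solve(self) -> float:
        return detectable_effect_size(self.n, self.alpha, self.power, self.tails)
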