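"""Variance-component decomposition of the second-level residual variance.

A fixed-effects model stacks every subject's run into one GLM with a
block-diagonal design ``X1``.  With ``c`` the concatenation of each
subject's CA-CC contrast weights, the intra-subject (estimation) variance
map is

    sigma^2(v) = (1/N) * (c X1^- X1^-T c^T) * C1(v)

where ``X1^-`` is the generalized inverse of the block design and ``C1``
the pooled residual-variance map.  The scalar ``c X1^- X1^-T c^T`` is the
sum over subjects of each subject's contrast-estimate leverage, so dividing
by N yields the mean per-subject estimation variance.  Because the
random-effects second-level residual variance is (in expectation) the sum
of estimation variance and true between-subject variance, the
inter-subject component is obtained by subtraction,
``Sigma^2 = resms_rfx - sigma^2``; sampling noise can make it negative,
which is preserved and flagged rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import VolumeSeries
from .firstlevel import Contrast, DesignMatrix, GLMFit, fit_glm

__all__ = [
    "FixedEffectsModel",
    "VarianceMaps",
    "fit_fixed_effects",
    "intra_subject_variance",
    "inter_subject_variance",
    "roi_sphere_summary",
    "DEFAULT_ROI_CENTERS_MM",
]

#: Peak-activation sphere centres (mm) used for regional variance summaries.
DEFAULT_ROI_CENTERS_MM: tuple[tuple[float, float, float], ...] = (
    (-50.0, -24.0, 34.0),   # inferior parietal (area PF)
    (40.0, -32.0, 44.0),    # primary somatosensory (area 2)
    (30.0, -12.0, 60.0),    # superior frontal gyrus
    (-40.0, -6.0, 4.0),     # insula
    (38.0, -4.0, 10.0),     # secondary somatosensory (OP3)
)


@dataclass
class FixedEffectsModel:
    """Pooled GLM over all subjects with block-diagonal design.

    The per-subject blocks are never materialized as one giant matrix:
    block-diagonality makes the pooled leverage the sum of per-subject
    leverages and the pooled residual variance the dof-weighted combination
    of per-subject residual sums of squares.
    """

    subject_fits: list[GLMFit]
    contrasts: list[Contrast]
    resms: np.ndarray               # pooled C1 map
    dof: float                      # sum timepoints - sum ranks
    leverage: float                 # c X1^- X1^-T c^T (sum over subjects)
    n_subjects: int
    mask: np.ndarray

    @property
    def rank(self) -> int:
        return sum(int(f.design.n_timepoints - f.dof) for f in self.subject_fits)


def fit_fixed_effects(series_list: list[VolumeSeries],
                      design_list: list[DesignMatrix],
                      contrast_list: list[Contrast],
                      mask: np.ndarray,
                      whitening: str = "exp-basis",
                      pool_mask: np.ndarray | None = None) -> FixedEffectsModel:
    """Fit the pooled fixed-effects model over all subjects' runs.

    All runs must share one grid; each subject contributes one design block
    and one contrast (identical structure across subjects).  The pooled
    residual-variance map is ``C1 = sum_s RSS_s / sum_s dof_s``.
    """
    if not (len(series_list) == len(design_list) == len(contrast_list)):
        raise ValueError("series/design/contrast lists must align")
    if len(series_list) < 1:
        raise ValueError("need at least one subject")
    shape = series_list[0].shape
    if any(s.shape != shape for s in series_list):
        raise ValueError("all runs must share one grid")

    fits, rss_total, dof_total, leverage = [], None, 0.0, 0.0
    for series, design, con in zip(series_list, design_list, contrast_list):
        fit = fit_glm(series, design, whitening=whitening, pool_mask=pool_mask)
        w = np.asarray(con.weights, dtype=float)
        if w.size != design.n_regressors:
            raise ValueError("contrast length must match design columns")
        leverage += float(w @ fit.cov_unscaled @ w)
        rss = fit.resms * fit.dof
        rss_total = rss if rss_total is None else rss_total + rss
        dof_total += fit.dof
        fits.append(fit)
    resms = rss_total / dof_total
    return FixedEffectsModel(
        subject_fits=fits, contrasts=list(contrast_list), resms=resms,
        dof=dof_total, leverage=leverage, n_subjects=len(fits),
        mask=mask.astype(bool),
    )


@dataclass
class VarianceMaps:
    """Intra- (sigma^2) and inter-subject (Sigma^2) variance maps."""

    intra: np.ndarray
    inter: np.ndarray
    resms_rfx: np.ndarray
    negative_fraction: float = 0.0


def intra_subject_variance(model: FixedEffectsModel) -> np.ndarray:
    """``sigma^2(v) = (1/N) * leverage * C1(v)``; nonnegative everywhere."""
    sigma2 = (model.leverage / model.n_subjects) * model.resms
    return sigma2 * model.mask


def inter_subject_variance(resms_rfx: np.ndarray, sigma2: np.ndarray,
                           mask: np.ndarray | None = None) -> VarianceMaps:
    """``Sigma^2 = resms_rfx - sigma^2``, negatives preserved and flagged."""
    if resms_rfx.shape != sigma2.shape:
        raise ValueError("maps must share one grid")
    inter = resms_rfx - sigma2
    if mask is not None:
        m = mask.astype(bool)
        neg = float((inter[m] < 0).mean()) if m.any() else 0.0
    else:
        neg = float((inter < 0).mean())
    return VarianceMaps(intra=sigma2, inter=inter, resms_rfx=resms_rfx,
                        negative_fraction=neg)


def phantom_roi_centers(activation_truth: np.ndarray, affine: np.ndarray,
                        max_rois: int = 5) -> list[tuple[float, float, float]]:
    """Peak coordinates (mm) of the activation blobs of a synthetic phantom.

    Synthetic stand-in for the peak-activation ROI list used with real data
    (whose default is :data:`DEFAULT_ROI_CENTERS_MM`).
    """
    from scipy import ndimage

    structure = ndimage.generate_binary_structure(3, 2)
    labels, n = ndimage.label(activation_truth > 0, structure=structure)
    centers = []
    for lab in range(1, min(n, max_rois) + 1):
        vals = np.where(labels == lab, activation_truth, 0.0)
        vox = np.unravel_index(np.argmax(vals), vals.shape)
        world = affine[:3, :3] @ np.asarray(vox) + affine[:3, 3]
        centers.append(tuple(float(x) for x in world))
    return centers


def roi_sphere_summary(values: np.ndarray, affine: np.ndarray,
                       mask: np.ndarray,
                       centers_mm=DEFAULT_ROI_CENTERS_MM,
                       radius_mm: float = 6.0) -> pd.DataFrame:
    """Mean map value inside spheres of ``radius_mm`` around each centre.

    Centres are world (mm) coordinates; only in-mask voxels count.  Raises
    if a sphere contains no in-mask voxel.
    """
    mask = mask.astype(bool)
    idx = np.argwhere(np.ones(values.shape, bool))
    world = (affine[:3, :3] @ idx.T).T + affine[:3, 3]
    rows = []
    for i, c in enumerate(centers_mm, start=1):
        d2 = ((world - np.asarray(c)) ** 2).sum(axis=1)
        inside = (d2 <= radius_mm ** 2).reshape(values.shape) & mask
        if not inside.any():
            raise ValueError(f"ROI {i} at {c} has no in-mask voxel")
        rows.append(dict(roi=i, x_mm=c[0], y_mm=c[1], z_mm=c[2],
                         n_voxels=int(inside.sum()),
                         mean=float(values[inside].mean())))
    return pd.DataFrame(rows)
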