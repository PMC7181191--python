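"""Random-effects group statistics: one-sample t maps, Benjamini-Hochberg
FDR voxel thresholding with a fixed cluster-extent filter, t histograms,
between-map correlation, residual-smoothness estimation and run truncation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .core import StatMap, VolumeSeries
from .simulate import TaskDesign

__all__ = [
    "GroupResult",
    "rfx_ttest",
    "bh_fdr_threshold",
    "cluster_filter",
    "t_histogram",
    "map_correlation",
    "estimate_smoothness_fwhm",
    "truncate_run",
    "threshold_group",
]


@dataclass
class GroupResult:
    """Second-level one-sample t-test result, optionally thresholded."""

    tmap: StatMap
    pmap: StatMap
    resms_rfx: np.ndarray
    n_subjects: int
    mask: np.ndarray
    q_threshold: float | None = None
    t_at_q: float | None = None
    sig_mask: np.ndarray | None = None
    fdr_mask: np.ndarray | None = None      # FDR survivors before clustering
    cluster_min: int | None = None
    mean_map: np.ndarray | None = None


def rfx_ttest(con_maps: np.ndarray, mask: np.ndarray,
              tail: str = "two-sided") -> GroupResult:
    """One-sample t-test across subjects at every in-mask voxel.

    ``con_maps`` is (subjects, x, y, z); ``t = mean / (sd / sqrt(N))`` with
    ``dof = N - 1``.  The second-level residual variance map (``resms_rfx``)
    is the per-voxel sample variance of the contrast values.  Zero-variance
    voxels are excluded from the analysis mask.
    """
    con_maps = np.asarray(con_maps, dtype=float)
    n = con_maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if con_maps.shape[1:] != mask.shape:
        raise ValueError("maps and mask must share one grid")
    mask = mask.astype(bool)
    mean = con_maps.mean(axis=0)
    var = con_maps.var(axis=0, ddof=1)
    good = mask & (var > 0)
    t = np.zeros(mask.shape)
    t[good] = mean[good] / np.sqrt(var[good] / n)
    dof = n - 1
    p = np.ones(mask.shape)
    if tail == "two-sided":
        p[good] = 2.0 * stats.t.sf(np.abs(t[good]), dof)
    elif tail == "greater":
        p[good] = stats.t.sf(t[good], dof)
    else:
        raise ValueError("tail must be 'two-sided' or 'greater'")
    return GroupResult(
        tmap=StatMap(values=t, kind="t", dof=float(dof),
                     threshold_info={"tail": tail}),
        pmap=StatMap(values=p, kind="p", dof=float(dof)),
        resms_rfx=var * mask,
        n_subjects=n, mask=good, mean_map=mean * mask,
    )


def bh_fdr_threshold(pmap: np.ndarray, mask: np.ndarray, q: float = 0.05,
                     tmap: np.ndarray | None = None
                     ) -> tuple[float | None, np.ndarray]:
    """Benjamini-Hochberg step-up over in-mask voxels at level ``q``.

    Returns the significant-voxel mask and, when a t map is supplied, the
    smallest |t| among surviving voxels (the effective t cutoff at ``q``).
    """
    from statsmodels.stats.multitest import multipletests

    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    p = np.asarray(pmap)[mask]
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    sig = np.zeros(mask.shape, bool)
    sig[mask] = reject
    t_at_q = None
    if tmap is not None and sig.any():
        t_at_q = float(np.min(np.abs(np.asarray(tmap)[sig])))
    return t_at_q, sig


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def cluster_filter(sig_mask: np.ndarray, k: int = 50,
                   connectivity: int = 18) -> np.ndarray:
    """Remove connected components smaller than ``k`` voxels.

    ``connectivity`` is 6 (faces), 18 (faces+edges, default) or 26 (full).
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    sig_mask = sig_mask.astype(bool)
    if k <= 1 or not sig_mask.any():
        return sig_mask.copy()
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(sig_mask, structure=structure)
    if n == 0:
        return sig_mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, bool)
    keep[1:] = sizes[1:] >= k
    return keep[labels]


def threshold_group(group: GroupResult, q: float = 0.05, k: int = 50,
                    connectivity: int = 18) -> GroupResult:
    """Apply voxel-level FDR at ``q`` then the cluster-extent filter ``k``."""
    t_at_q, fdr = bh_fdr_threshold(group.pmap.values, group.mask, q,
                                   tmap=group.tmap.values)
    sig = cluster_filter(fdr, k=k, connectivity=connectivity)
    group.q_threshold = q
    group.t_at_q = t_at_q
    group.sig_mask = sig
    group.fdr_mask = fdr
    group.cluster_min = k
    group.tmap.threshold_info.update(q=q, t_at_q=t_at_q, cluster_min=k,
                                     connectivity=connectivity)
    return group


def t_histogram(group: GroupResult, bins: np.ndarray | int = 30
                ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of t values over the significant-voxel mask.

    Returns (counts, bin_edges); the count total equals the size of the
    significant mask.
    """
    if group.sig_mask is None:
        raise ValueError("group result must be thresholded first")
    vals = group.tmap.values[group.sig_mask]
    if vals.size == 0:
        if np.isscalar(bins):
            edges = np.linspace(0.0, 1.0, int(bins) + 1)
        else:
            edges = np.asarray(bins, dtype=float)
        return np.zeros(len(edges) - 1, int), edges
    counts, edges = np.histogram(vals, bins=bins)
    return counts, edges


def survival_count(tmap: np.ndarray, region: np.ndarray,
                   thresholds: np.ndarray) -> np.ndarray:
    """N(t >= x) over ``region`` for each threshold x."""
    vals = np.sort(np.asarray(tmap)[region.astype(bool)])
    return vals.size - np.searchsorted(vals, thresholds, side="left")


def map_correlation(a: StatMap | np.ndarray, b: StatMap | np.ndarray,
                    mask: np.ndarray) -> float:
    """Pearson correlation of two maps over in-mask voxels."""
    av = (a.values if isinstance(a, StatMap) else np.asarray(a))[mask.astype(bool)]
    bv = (b.values if isinstance(b, StatMap) else np.asarray(b))[mask.astype(bool)]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("constant map: correlation undefined")
    return float(np.corrcoef(av, bv)[0, 1])


def estimate_smoothness_fwhm(residuals: VolumeSeries, mask: np.ndarray
                             ) -> np.ndarray:
    """Effective spatial smoothness (FWHM, mm) per axis from residuals.

    Classic residual-derivative estimator: each residual frame is variance
    normalized, the in-mask variance of its spatial derivative along axis i
    gives ``FWHM_i = voxel_i * sqrt(4 ln 2 / var(dz/dx_i))``; frames are
    averaged.
    """
    if residuals.n_volumes < 10:
        raise ValueError("need >= 10 timepoints to estimate smoothness")
    mask = mask.astype(bool)
    vs = residuals.voxel_sizes()
    fwhms = []
    # in-mask voxel pairs along each axis
    for axis in range(3):
        shifted = np.roll(mask, -1, axis=axis)
        pair = mask & shifted
        # drop wraparound slice
        sl = [slice(None)] * 3
        sl[axis] = slice(-1, None)
        pair[tuple(sl)] = False
        if pair.sum() < 10:
            raise ValueError("mask too thin for derivative estimation")
        var_d = []
        for ti in range(residuals.n_volumes):
            frame = residuals.data[..., ti].astype(float)
            sd = frame[mask].std()
            if sd == 0:
                raise ValueError("constant residual frame")
            z = frame / sd
            d = (np.roll(z, -1, axis=axis) - z)[pair]
            var_d.append(d.var())
        v = float(np.mean(var_d))
        v = min(v, 2.0)  # derivative variance of white noise; floor at voxel size
        fwhms.append(vs[axis] * np.sqrt(4.0 * np.log(2.0) / v))
    return np.asarray(fwhms)


def truncate_run(series: VolumeSeries, design: TaskDesign,
                 fraction: float = 1.0 / 3.0
                 ) -> tuple[VolumeSeries, TaskDesign]:
    """Keep the first ``fraction`` of volumes and the blocks wholly within.

    The truncated pair feeds the unchanged first-level/group stages.  A
    warning is issued when fewer than 2 blocks per condition remain.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n_keep = int(np.floor(fraction * series.n_volumes))
    trunc_series = series.truncated(n_keep)
    trunc_design = design.truncated(n_keep * series.tr)
    for cond in set(design.conditions):
        if sum(c == cond for c in trunc_design.conditions) < 2:
            warnings.warn(f"truncation leaves < 2 blocks of {cond}",
                          stacklevel=2)
    return trunc_series, trunc_design
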