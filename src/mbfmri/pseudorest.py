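"""Dual-regression analysis of pseudo resting-state data.

Task-residualized runs are analysed in two stages against a set of 20
network template maps: stage 1 regresses each volume (spatially, over the
brain mask) on the templates, yielding one time course per network per run;
stage 2 uses those time courses as temporal predictors (with the 16
nuisance regressors and drift terms) to produce subject-level network beta
and t maps.  Group one-sample t-tests per network, FDR + cluster
thresholding and supra-threshold voxel counts then quantify how well each
acquisition scheme recovers the networks; normalized cumulative histograms
``N(t >= x) / N_ref`` compare schemes free of any single threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StatMap, VolumeSeries
from .firstlevel import DesignMatrix, dct_highpass_basis, fit_glm
from .grouplevel import GroupResult, rfx_ttest, survival_count, threshold_group

__all__ = [
    "NetworkTimecourses",
    "CumulativeCurve",
    "spatial_glm_timecourses",
    "network_subject_maps",
    "network_group_counts",
    "cumulative_curves",
]


@dataclass
class NetworkTimecourses:
    """Stage-1 output: (time, n_networks) coefficient matrix for one run."""

    matrix: np.ndarray
    subject: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite time courses")


def spatial_glm_timecourses(residuals: VolumeSeries, templates: np.ndarray,
                            mask: np.ndarray, subject: str = "",
                            sequence: str = "") -> NetworkTimecourses:
    """Stage 1: regress every volume on the template maps over the mask.

    Templates are z-scored over the mask before regression (stabilizes
    scale across networks); an intercept column absorbs the global mean.
    Collinear templates raise an error naming the offending pair.
    """
    mask = mask.astype(bool)
    n_net = templates.shape[0]
    tmpl = templates.reshape(n_net, -1)[:, mask.ravel()].astype(float).T  # (V, K)
    sd = tmpl.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate (constant) template map")
    tmpl = (tmpl - tmpl.mean(axis=0)) / sd
    design = np.column_stack([tmpl, np.ones(tmpl.shape[0])])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(tmpl.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(f"collinear templates: {i} and {j} "
                         f"(|r| = {abs(corr[i, j]):.3f})")
    Y = residuals.data[mask].astype(float)                 # (V, T)
    coef = np.linalg.pinv(design) @ Y                      # (K+1, T)
    return NetworkTimecourses(matrix=coef[:n_net].T, subject=subject,
                              sequence=sequence)


def network_subject_maps(series: VolumeSeries, timecourses: NetworkTimecourses,
                         nuisance: np.ndarray | None = None,
                         highpass_cutoff: float = 128.0,
                         whitening: str = "exp-basis",
                         pool_mask: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Stage 2: temporal GLM of the (smoothed) run on the network time courses.

    Returns per-network beta maps and t maps, each (n_networks, x, y, z).
    The design carries the network time courses, the nuisance columns, the
    drift (discrete-cosine) set and an intercept.
    """
    tc = timecourses.matrix
    n_vol, n_net = tc.shape
    if n_vol != series.n_volumes:
        raise ValueError("time courses must match run length")
    cols, names = [], []
    for k in range(n_net):
        col = tc[:, k] - tc[:, k].mean()
        cols.append(col)
        names.append(f"net_{k + 1:02d}")
    if nuisance is not None:
        nu = np.asarray(nuisance, dtype=float)
        for i in range(nu.shape[1]):
            cols.append(nu[:, i] - nu[:, i].mean())
            names.append(f"nuisance_{i + 1}")
    dct = dct_highpass_basis(n_vol, series.tr, highpass_cutoff)
    for i in range(dct.shape[1]):
        cols.append(dct[:, i])
        names.append(f"dct_{i + 1}")
    cols.append(np.ones(n_vol))
    names.append("intercept")
    design = DesignMatrix(matrix=np.column_stack(cols), column_names=names,
                          tr=series.tr, highpass_cutoff=highpass_cutoff)
    fit = fit_glm(series, design, whitening=whitening, pool_mask=pool_mask)

    betas = fit.betas[:n_net]
    tmaps = np.zeros_like(betas)
    good = fit.mask
    for k in range(n_net):
        var_k = fit.resms * float(fit.cov_unscaled[k, k])
        ok = good & (var_k > 0)
        tmaps[k][ok] = betas[k][ok] / np.sqrt(var_k[ok])
    return betas, tmaps


def network_group_counts(subject_maps: dict[str, np.ndarray],
                         mask: np.ndarray, q: float = 0.05, k: int = 50,
                         connectivity: int = 18,
                         reference: str | None = None
                         ) -> tuple[pd.DataFrame, dict[str, list[GroupResult]]]:
    """Group analysis per network per scheme; supra-threshold voxel counts.

    ``subject_maps`` maps scheme name to an array (subjects, networks, x, y,
    z) of per-subject network betas.  Each network gets a one-sample group
    t-test, FDR at ``q`` and cluster filter ``k``; the table lists one row
    per (scheme, network) with the significant-voxel count, plus percent
    change of the scheme's mean count relative to ``reference``.
    """
    rows = []
    results: dict[str, list[GroupResult]] = {}
    for seq, maps in subject_maps.items():
        n_net = maps.shape[1]
        results[seq] = []
        for net in range(n_net):
            g = rfx_ttest(maps[:, net], mask)
            g = threshold_group(g, q=q, k=k, connectivity=connectivity)
            results[seq].append(g)
            rows.append(dict(sequence=seq, network=net + 1,
                             n_significant=int(g.sig_mask.sum()),
                             t_at_q=g.t_at_q))
    table = pd.DataFrame(rows)
    means = table.groupby("sequence")["n_significant"].mean()
    ref = reference if reference is not None else means.index[0]
    table = table.merge(
        means.rename("mean_count"), left_on="sequence", right_index=True)
    ref_mean = means[ref]
    table["pct_change_vs_ref"] = 100.0 * (table["mean_count"] - ref_mean) / ref_mean
    return table, results


@dataclass
class CumulativeCurve:
    """Normalized survival curve ``y = N(t >= x) / N_ref`` for one network."""

    x: np.ndarray
    y: np.ndarray
    n_ref: int
    network_id: int
    sequence: str = ""


def cumulative_curves(group_results: dict[str, list[GroupResult]],
                      reference: str, mask: np.ndarray,
                      n_points: int = 50) -> list[CumulativeCurve]:
    """Per-network curves of supra-threshold counts relative to the reference.

    For each network, ``x0`` is the reference scheme's FDR t cutoff and
    ``N_ref`` its significant-voxel count; for every scheme, ``y(x) =
    N_seq(t >= x) / N_ref`` on a grid from ``x0`` upward.  Networks where
    the reference finds nothing are skipped with a warning.
    """
    mask = mask.astype(bool)
    curves: list[CumulativeCurve] = []
    n_net = len(group_results[reference])
    for net in range(n_net):
        ref_g = group_results[reference][net]
        if ref_g.t_at_q is None:
            warnings.warn(f"network {net + 1}: reference has no significant "
                          "voxels; skipped", stacklevel=2)
            continue
        x0 = ref_g.t_at_q
        # N_ref = positive FDR survivors = N(t >= x0) at the reference, so
        # the reference curve starts at exactly 1
        n_ref = int(survival_count(ref_g.tmap.values, mask,
                                   np.array([x0]))[0])
        if n_ref == 0:
            warnings.warn(f"network {net + 1}: reference has no significant "
                          "voxels; skipped", stacklevel=2)
            continue
        t_max = max(float(g[net].tmap.values[mask].max())
                    for g in group_results.values())
        x = np.linspace(x0, max(t_max, x0 + 1e-6), n_points)
        for seq, glist in group_results.items():
            y = survival_count(glist[net].tmap.values, mask, x) / n_ref
            curves.append(CumulativeCurve(x=x, y=y, n_ref=n_ref,
                                          network_id=net + 1, sequence=seq))
    return curves
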