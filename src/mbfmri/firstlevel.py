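"""Subject-level GLM: canonical-HRF task regressors, 16 nuisance regressors,
discrete-cosine high-pass set, autocorrelation whitening, contrasts,
task residualization for pseudo-rest, and Gaussian smoothing.

The temporal model per voxel is ``y = X b + e`` with ``e`` temporally
autocorrelated; estimation is generalized least squares after whitening with
an autocorrelation model pooled over brain voxels.  Three whitening choices
are exposed: ``none`` (ordinary least squares), ``ar1`` (single pooled lag-1
coefficient) and ``exp-basis`` (default: the pooled residual autocorrelation
function is fit with a small set of exponentially decaying components, in
the spirit of covariance-basis autocorrelation models designed for short-TR
data, then inverted into a whitening transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.linalg import cholesky, solve_triangular, toeplitz

from .core import StatMap, VolumeSeries
from .sequences import SequenceSpec
from .simulate import TaskDesign

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "Contrast",
    "canonical_hrf",
    "build_design",
    "compcor_regressors",
    "fit_glm",
    "contrast_tmap",
    "residualize_for_rest",
    "gaussian_smooth",
]

HRF_LENGTH_S = 32.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def canonical_hrf(dt: float, dispersion: float = 1.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled every ``dt`` s.

    Positive gamma lobe (delay 6 s, dispersion 1) minus a 1/6-amplitude
    undershoot (delay 16 s, dispersion 1), 32 s long, peak-normalized to 1.
    The peak sits near 5 s after onset.
    """
    from scipy.stats import gamma as gamma_dist

    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= HRF_LENGTH_S:
        raise ValueError("dt must be smaller than the 32 s kernel length")
    t = np.arange(0.0, HRF_LENGTH_S, dt)
    h = (gamma_dist.pdf(t, 6.0 / dispersion, scale=dispersion)
         - gamma_dist.pdf(t, 16.0 / dispersion, scale=dispersion) / 6.0)
    return h / h.max()


def _hrf_basis(dt: float, variant: str) -> list[np.ndarray]:
    """Canonical kernel plus optional temporal/dispersion derivatives."""
    h = canonical_hrf(dt)
    basis = [h]
    if variant in ("canonical+temporal", "canonical+temporal+dispersion"):
        shifted = np.roll(h, max(int(round(1.0 / dt)), 1))
        shifted[: max(int(round(1.0 / dt)), 1)] = 0.0
        basis.append(h - shifted)               # finite-difference time derivative
    if variant == "canonical+temporal+dispersion":
        dh = (canonical_hrf(dt, dispersion=1.01) - h) / 0.01
        basis.append(dh)
    if variant not in ("canonical", "canonical+temporal",
                       "canonical+temporal+dispersion"):
        raise ValueError(f"unknown hrf_variant {variant!r}")
    return basis


@dataclass
class DesignMatrix:
    """Time x regressor design with named columns.

    Task columns are mean-centred HRF-convolved boxcars; the intercept is
    always the last column; a discrete-cosine set implements the high-pass
    filter inside the design.
    """

    matrix: np.ndarray
    column_names: list[str]
    tr: float
    hrf_variant: str = "canonical"
    highpass_cutoff: float = 128.0

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match matrix columns")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(self.matrix.T)
            corr = np.nan_to_num(corr)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise ValueError(
                "design matrix is rank deficient; most collinear columns: "
                f"{self.column_names[i]!r} / {self.column_names[j]!r}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def task_columns(self) -> list[int]:
        return [i for i, n in enumerate(self.column_names) if n.startswith("task_")]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.column_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names)


def dct_highpass_basis(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift regressors for a high-pass ``cutoff`` (seconds).

    Returns ``K = floor(2 * n * tr / cutoff)`` unit-norm cosine columns of
    periods longer than the cutoff (the constant term is excluded; the
    intercept carries it).
    """
    n_basis = int(np.floor(2.0 * n_volumes * tr / cutoff))
    n = np.arange(n_volumes)
    cols = [np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * n + 1) * k / (2 * n_volumes))
            for k in range(1, n_basis + 1)]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def build_design(design: TaskDesign, spec: SequenceSpec,
                 motion: pd.DataFrame | np.ndarray | None = None,
                 compcor: np.ndarray | None = None,
                 hrf_variant: str = "canonical",
                 highpass_cutoff: float = 128.0,
                 oversample: int = 16) -> DesignMatrix:
    """Assemble the first-level design matrix.

    Columns, in order: task regressors (one per condition, times the HRF
    basis size), motion (6) and CompCor (typically 5 + 5) nuisance columns,
    discrete-cosine high-pass set, intercept.  Boxcars are built on a 16-bin
    sub-TR grid, convolved, then sampled at the middle bin of each volume.
    """
    n_vol, tr = spec.n_volumes, spec.tr
    dt = tr / oversample
    basis = _hrf_basis(dt, hrf_variant)
    t_fine = np.arange(n_vol * oversample) * dt

    cols, names = [], []
    conditions = sorted(set(design.conditions))
    suffixes = ["", "_tderiv", "_dderiv"]
    for cond in conditions:
        box = np.zeros(n_vol * oversample)
        for o, d in zip(design.onsets_for(cond), design.durations_for(cond)):
            box[(t_fine >= o) & (t_fine < o + d)] = 1.0
        for bi, kern in enumerate(basis):
            conv = np.convolve(box, kern)[: len(box)] * dt
            sampled = conv[oversample // 2::oversample][:n_vol]
            cols.append(sampled - sampled.mean())
            names.append(f"task_{cond}{suffixes[bi]}")

    if motion is not None:
        m = np.asarray(motion, dtype=float)
        if m.shape[0] != n_vol:
            raise ValueError("motion table row count must equal n_volumes")
        for i in range(m.shape[1]):
            cols.append(m[:, i] - m[:, i].mean())
            names.append(f"motion_{i + 1}")
    if compcor is not None:
        cc = np.asarray(compcor, dtype=float)
        if cc.shape[0] != n_vol:
            raise ValueError("compcor row count must equal n_volumes")
        for i in range(cc.shape[1]):
            cols.append(cc[:, i] - cc[:, i].mean())
            names.append(f"compcor_{i + 1}")

    dct = dct_highpass_basis(n_vol, tr, highpass_cutoff)
    for i in range(dct.shape[1]):
        cols.append(dct[:, i])
        names.append(f"dct_{i + 1}")

    cols.append(np.ones(n_vol))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), column_names=names,
                        tr=tr, hrf_variant=hrf_variant,
                        highpass_cutoff=highpass_cutoff)


def compcor_regressors(series: VolumeSeries, mask: np.ndarray,
                       k: int = 5) -> np.ndarray:
    """Top-``k`` principal-component time courses of the in-mask signal.

    Computed on unsmoothed data; each component is unit-variance and the
    set is mutually orthogonal.  Voxel means and linear trends are removed
    before the decomposition.
    """
    if k == 0:
        return np.empty((series.n_volumes, 0))
    mask = mask.astype(bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("compcor mask is empty")
    if n_vox < k:
        raise ValueError(f"compcor mask has {n_vox} voxels < k={k}")
    if k >= series.n_volumes:
        raise ValueError("k must be smaller than the number of timepoints")
    mat = series.data[mask].astype(float)                 # (voxels, time)
    mat = mat - mat.mean(axis=1, keepdims=True)
    t = np.arange(series.n_volumes, dtype=float)
    t = (t - t.mean()) / (t.std() + 1e-12)
    mat -= (mat @ t)[:, None] * t[None, :] / series.n_volumes  # detrend
    _, _, vt = np.linalg.svd(mat, full_matrices=False)
    comps = vt[:k].T
    comps = comps - comps.mean(axis=0, keepdims=True)
    sd = comps.std(axis=0)
    sd[sd == 0] = 1.0
    return comps / sd


@dataclass
class GLMFit:
    """Fitted subject-level GLM.

    ``betas`` stacks one 3D map per regressor; ``residuals`` are the
    unwhitened model residuals (saved for effective tSNR and pseudo-rest);
    ``resms`` is the residual variance map (RSS / dof under whitening);
    ``cov_unscaled`` is ``(X'V^-1 X)^-1`` so a contrast variance is
    ``resms * c cov_unscaled c'``.
    """

    betas: np.ndarray                       # (n_regressors, x, y, z)
    residuals: VolumeSeries
    resms: np.ndarray                       # 3D
    dof: float
    cov_unscaled: np.ndarray                # (R, R)
    design: DesignMatrix
    mask: np.ndarray
    whitening: str = "none"
    autocorr: dict = field(default_factory=dict)


def _pooled_autocorr(resid: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation function of residuals pooled (averaged) over voxels."""
    r = resid - resid.mean(axis=1, keepdims=True)
    denom = (r * r).sum(axis=1)
    good = denom > 0
    r, denom = r[good], denom[good]
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for lag in range(1, max_lag + 1):
        acf[lag] = ((r[:, lag:] * r[:, :-lag]).sum(axis=1) / denom).mean()
    return acf


def _exp_basis_corr(acf: np.ndarray, taus=(1.0, 4.0, 16.0)) -> np.ndarray:
    """Fit acf with nonneg. combination of a delta and decaying exponentials."""
    lags = np.arange(len(acf))
    basis = [np.where(lags == 0, 1.0, 0.0)]
    basis += [np.exp(-lags / tau) for tau in taus]
    b = np.column_stack(basis)
    w, _ = optimize.nnls(b, acf)
    fit = b @ w
    return fit / fit[0] if fit[0] > 0 else acf


def _whitening_matrix(corr: np.ndarray, n: int) -> np.ndarray:
    """W with W V W' = I for the Toeplitz correlation built from ``corr``."""
    rho = np.zeros(n)
    rho[: len(corr)] = corr[:n]
    v = toeplitz(rho)
    # small ridge keeps Cholesky stable for near-singular fits
    v[np.diag_indices(n)] += 1e-8
    l = cholesky(v, lower=True)
    return solve_triangular(l, np.eye(n), lower=True)


def fit_glm(series: VolumeSeries, X: DesignMatrix,
            whitening: str = "exp-basis",
            pool_mask: np.ndarray | None = None,
            max_lag: int = 30) -> GLMFit:
    """Per-voxel generalized least squares under a pooled whitening model.

    A first OLS pass estimates residual autocorrelation pooled over in-mask
    voxels (or ``pool_mask``, typically grey matter); the fitted correlation
    is inverted into a whitening transform and the model is refit.
    ``dof = timepoints - rank(X)``.
    """
    if series.n_volumes != X.n_timepoints:
        raise ValueError("series timepoints must match design rows")
    mask = (series.mask if series.mask is not None
            else np.ones(series.shape, bool)).astype(bool)
    Y = series.data[mask].astype(float).T                  # (T, V)
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in the data")
    # exclude zero-variance voxels from statistics
    var0 = Y.std(axis=0) > 0
    Xm = X.matrix
    T, R = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    dof = T - rank

    def _ols(Xw: np.ndarray, Yw: np.ndarray):
        pinv = np.linalg.pinv(Xw)
        beta = pinv @ Yw
        resid = Yw - Xw @ beta
        return beta, resid, pinv

    beta, resid_w, _ = _ols(Xm, Y)
    autocorr: dict = {}
    if whitening not in ("none", "ar1", "exp-basis"):
        raise ValueError(f"unknown whitening {whitening!r}")
    if whitening != "none":
        if pool_mask is not None:
            # pool over requested voxels (typically grey matter) inside the mask
            pool_rows = pool_mask.astype(bool)[mask]
            sel = pool_rows & var0
            if sel.sum() < 10:
                sel = var0
        else:
            sel = var0
        lag_cap = min(max_lag, T - 2)
        acf = _pooled_autocorr(resid_w.T[sel], lag_cap)
        if whitening == "ar1":
            phi = float(np.clip(acf[1], 0.0, 0.99))
            corr = phi ** np.arange(lag_cap + 1)
            autocorr = {"model": "ar1", "phi": phi}
        else:
            corr = _exp_basis_corr(acf)
            autocorr = {"model": "exp-basis", "acf": acf, "corr": corr}
        W = _whitening_matrix(corr, T)
        Xw, Yw = W @ Xm, W @ Y
        beta, resid_white, _ = _ols(Xw, Yw)
        rss = (resid_white ** 2).sum(axis=0)
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    else:
        rss = (resid_w ** 2).sum(axis=0)
        xtx_inv = np.linalg.pinv(Xm.T @ Xm)
    # exact fits leave only rounding error: treat as zero residual variance
    rss[rss < 1e-20 * (Y ** 2).sum(axis=0)] = 0.0

    resid_unw = Y - Xm @ beta

    betas = np.zeros((R, *series.shape))
    betas[:, mask] = beta
    resms = np.zeros(series.shape)
    resms[mask] = np.where(var0, rss / max(dof, 1), 0.0)
    resid4d = np.zeros((*series.shape, T), dtype=np.float32)
    resid4d[mask] = resid_unw.T.astype(np.float32)
    stat_mask = np.zeros(series.shape, bool)
    stat_mask[mask] = var0

    return GLMFit(
        betas=betas,
        residuals=VolumeSeries(data=resid4d, affine=series.affine,
                               tr=series.tr, mask=mask, name=series.name),
        resms=resms, dof=float(dof), cov_unscaled=xtx_inv, design=X,
        mask=stat_mask, whitening=whitening, autocorr=autocorr,
    )


@dataclass(frozen=True)
class Contrast:
    """Linear contrast over design columns."""

    weights: tuple[float, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.weights):
            raise ValueError("contrast must not be all zero")

    @classmethod
    def from_names(cls, design: DesignMatrix, positive: str, negative: str | None = None,
                   name: str = "") -> "Contrast":
        w = np.zeros(design.n_regressors)
        w[design.column_names.index(positive)] = 1.0
        if negative is not None:
            w[design.column_names.index(negative)] = -1.0
        return cls(weights=tuple(w), name=name or f"{positive}-{negative}")


def contrast_tmap(fit: GLMFit, c: Contrast) -> tuple[StatMap, np.ndarray]:
    """Contrast t map and the contrast-of-parameter-estimates map.

    ``t = c b / sqrt(resms * c (X'V^-1 X)^-1 c')``; voxels with zero residual
    variance are flagged (excluded from ``mask``) rather than set infinite.
    """
    w = np.asarray(c.weights, dtype=float)
    if w.size != fit.design.n_regressors:
        raise ValueError("contrast length must match design columns")
    con = np.tensordot(w, fit.betas, axes=1)
    var_factor = float(w @ fit.cov_unscaled @ w)
    denom2 = fit.resms * var_factor
    good = fit.mask & (denom2 > 0)
    t = np.zeros(con.shape)
    t[good] = con[good] / np.sqrt(denom2[good])
    sm = StatMap(values=t, kind="t", affine=None, dof=fit.dof,
                 threshold_info={"contrast": c.name, "mask_voxels": int(good.sum())})
    sm.threshold_info["valid_mask"] = good
    return sm, con


def residualize_for_rest(series: VolumeSeries, X: DesignMatrix) -> VolumeSeries:
    """Project out every design column (task + nuisance + drift + intercept).

    The returned residual series is the pseudo resting-state dataset: BOLD
    correlated with the task model removed, everything else retained.
    """
    if series.n_volumes != X.n_timepoints:
        raise ValueError("series timepoints must match design rows")
    mask = (series.mask if series.mask is not None
            else np.ones(series.shape, bool)).astype(bool)
    Y = series.data[mask].astype(float).T
    Q, _ = np.linalg.qr(X.matrix)
    resid = Y - Q @ (Q.T @ Y)
    out = np.zeros_like(series.data)
    out[mask] = resid.T.astype(series.data.dtype)
    return VolumeSeries(data=out, affine=series.affine, tr=series.tr,
                        mask=mask, name=series.name)


def gaussian_smooth(obj: VolumeSeries | np.ndarray, fwhm: float,
                    voxel_sizes: np.ndarray | None = None):
    """Separable Gaussian smoothing with ``fwhm`` in millimetres.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, divided by the voxel size;
    accepts a 3D array (with explicit ``voxel_sizes``) or a ``VolumeSeries``
    (smoothed frame by frame).  ``fwhm=0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if isinstance(obj, VolumeSeries):
        if fwhm == 0:
            return obj
        vs = obj.voxel_sizes()
        sigma = [fwhm * FWHM_TO_SIGMA / v for v in vs] + [0.0]
        sm = ndimage.gaussian_filter(obj.data.astype(float), sigma=sigma)
        return VolumeSeries(data=sm.astype(obj.data.dtype), affine=obj.affine,
                            tr=obj.tr, mask=obj.mask, name=obj.name)
    arr = np.asarray(obj, dtype=float)
    if fwhm == 0:
        return arr
    if voxel_sizes is None:
        raise ValueError("voxel_sizes required for bare arrays")
    sigma = [fwhm * FWHM_TO_SIGMA / v for v in np.atleast_1d(voxel_sizes)]
    return ndimage.gaussian_filter(arr, sigma=sigma)
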