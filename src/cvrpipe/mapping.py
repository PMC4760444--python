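"""Voxelwise CVR mapping: preprocessing, GLM, z maps and resel thresholds.

The BOLD series is spatially smoothed (mask-aware Gaussian), temporally
high-passed (Gaussian-weighted running straight-line fit), and fit voxel by
voxel with an ordinary-least-squares GLM in which the delay-corrected
end-tidal PCO2 excursion is the explanatory variable and SpO2 (from the
Severinghaus equation) a nuisance covariate.  The petCO2 beta divided by
the voxel baseline gives CVR in % per mmHg; the t statistic is mapped to a
z score; residual spatial smoothness calibrates a resel-based
multiple-comparison threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "BoldSeries",
    "GlmResult",
    "SmoothnessEstimate",
    "ThresholdResult",
    "CvrRunResult",
    "make_design",
    "smooth_spatial",
    "highpass_temporal",
    "fit_glm",
    "cvr_from_glm",
    "zstat_map",
    "estimate_smoothness",
    "resel_corrected_threshold",
    "significant_mask",
    "compute_cvr_run",
]

_Z_CLIP = 38.0  # |z| beyond this is numerically indistinguishable from infinity


@dataclass
class BoldSeries:
    """4D BOLD data with its repetition time, voxel size and brain mask."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    voxel_size: tuple[float, float, float]
    mask: np.ndarray  # bool, (x, y, z)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask must match the spatial grid")
        self.mask = self.mask.astype(bool)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def global_signal(self) -> np.ndarray:
        """Per-volume mean signal over the brain mask."""
        return self.data[self.mask].mean(axis=0)

    def to_nifti(self):
        import nibabel as nib

        affine = np.diag(list(self.voxel_size) + [1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        img.header.set_zooms(tuple(self.voxel_size) + (self.tr,))
        return img

    @classmethod
    def from_nifti(cls, img, mask: np.ndarray | None = None) -> "BoldSeries":
        zooms = img.header.get_zooms()
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if mask is None:
            mask = data.mean(axis=3) > 0
        return cls(data=data, tr=float(zooms[3]), voxel_size=tuple(map(float, zooms[:3])), mask=mask)


def make_design(petco2: np.ndarray, spo2: np.ndarray | None = None) -> pd.DataFrame:
    """GLM design: intercept plus mean-centred petCO2 (and SpO2 nuisance)."""
    petco2 = np.asarray(petco2, float)
    cols = {"intercept": np.ones_like(petco2), "petco2": petco2 - petco2.mean()}
    if spo2 is not None:
        spo2 = np.asarray(spo2, float)
        if len(spo2) != len(petco2):
            raise ValueError("petco2 and spo2 must have equal length")
        cols["spo2"] = spo2 - spo2.mean()
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def smooth_spatial(series: BoldSeries, fwhm_mm: float) -> BoldSeries:
    """Mask-aware 3D Gaussian smoothing of every volume.

    sigma per axis = fwhm / (2 sqrt(2 ln 2)) converted to voxels; the
    smoothed series is renormalized by the smoothed mask so edge voxels are
    not diluted by out-of-mask zeros.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return BoldSeries(series.data.copy(), series.tr, series.voxel_size, series.mask)
    sigma_vox = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in series.voxel_size]
    m = series.mask.astype(float)
    msm = ndimage.gaussian_filter(m, sigma_vox)
    out = np.zeros_like(series.data)
    for j in range(series.n_volumes):
        num = ndimage.gaussian_filter(series.data[..., j] * m, sigma_vox)
        out[..., j] = np.where(series.mask, num / np.maximum(msm, 1e-12), series.data[..., j])
    return BoldSeries(out, series.tr, series.voxel_size, series.mask)


def _running_line_matrix(n: int, tr: float, sigma_s: float) -> np.ndarray:
    """n x n matrix H with (H y) the Gaussian-weighted running line fit of y."""
    t = np.arange(n) * tr
    H = np.empty((n, n))
    for i in range(n):
        w = np.exp(-0.5 * ((t - t[i]) / sigma_s) ** 2)
        d = t - t[i]
        s0, s1, s2 = w.sum(), (w * d).sum(), (w * d * d).sum()
        det = s0 * s2 - s1 * s1
        # weighted LS line evaluated at t[i]: a + b*0 with
        # a = (s2*sum(w y) - s1*sum(w d y)) / det
        H[i] = (s2 * w - s1 * w * d) / det
    return H


def highpass_temporal(
    series: BoldSeries, sigma_s: float = 50.0, allow_short: bool = False
) -> BoldSeries:
    """Remove slow drift with a Gaussian-weighted running straight-line fit.

    Per voxel the locally fitted line of temporal width ``sigma_s`` is
    subtracted and the voxel temporal mean restored.  Sigmas shorter than
    2*TR fit noise rather than drift and are rejected unless
    ``allow_short=True``.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    if sigma_s < 2 * series.tr and not allow_short:
        raise ValueError(
            f"sigma_s={sigma_s} s is shorter than 2*TR={2 * series.tr} s; "
            "pass allow_short=True to override"
        )
    H = _running_line_matrix(series.n_volumes, series.tr, sigma_s)
    flat = series.data.reshape(-1, series.n_volumes)
    trend = flat @ H.T
    mean = flat.mean(axis=1, keepdims=True)
    out = (flat - trend + mean).reshape(series.data.shape)
    return BoldSeries(out, series.tr, series.voxel_size, series.mask)


@dataclass
class GlmResult:
    """Per-voxel OLS fit of the BOLD series against the design."""

    beta: dict[str, np.ndarray]  # 3D map per design column
    resid_var: np.ndarray  # 3D, SSR / dof
    dof: int
    baseline: np.ndarray  # 3D voxel temporal mean
    mask: np.ndarray
    xtx_inv: np.ndarray  # (p, p)
    columns: list[str]
    residuals: np.ndarray | None = None  # 4D float32, for smoothness estimation


def fit_glm(series: BoldSeries, design: pd.DataFrame, keep_residuals: bool = True) -> GlmResult:
    """Ordinary least squares per voxel inside the mask.

    The baseline map is the voxel temporal mean of the (preprocessed)
    series; degrees of freedom are ``n_volumes - rank(design)``.
    """
    X = design.to_numpy(float)
    n, p = X.shape
    if n != series.n_volumes:
        raise ValueError("design rows must equal the number of volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    if n < p + 2:
        raise ValueError("too few volumes for the design")

    Y = series.data[series.mask]  # (N, T)
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv.T  # (N, p)
    resid = Y - B @ X.T
    dof = n - rank
    ssr = np.einsum("ij,ij->i", resid, resid)

    shape = series.mask.shape
    beta = {}
    for j, name in enumerate(design.columns):
        m = np.full(shape, np.nan)
        m[series.mask] = B[:, j]
        beta[name] = m
    var = np.full(shape, np.nan)
    var[series.mask] = ssr / dof
    base = np.full(shape, np.nan)
    base[series.mask] = Y.mean(axis=1)

    res4d = None
    if keep_residuals:
        res4d = np.zeros(shape + (n,), dtype=np.float32)
        res4d[series.mask] = resid.astype(np.float32)

    return GlmResult(
        beta=beta,
        resid_var=var,
        dof=dof,
        baseline=base,
        mask=series.mask.copy(),
        xtx_inv=xtx_inv,
        columns=list(design.columns),
        residuals=res4d,
    )


def cvr_from_glm(result: GlmResult, column: str = "petco2") -> np.ndarray:
    """CVR map in % per mmHg: 100 * beta_petco2 / baseline signal.

    Voxels with non-positive baseline cannot be percent-normalized; they
    are removed from the result's mask (logged) and set to NaN.
    """
    bad = result.mask & ~(result.baseline > 0)
    if bad.any():
        log.warning("excluding %d voxels with non-positive baseline", int(bad.sum()))
        result.mask &= ~bad
    cvr = np.full(result.baseline.shape, np.nan)
    m = result.mask
    cvr[m] = 100.0 * result.beta[column][m] / result.baseline[m]
    return cvr


def zstat_map(result: GlmResult, column: str = "petco2") -> np.ndarray:
    """z map for a design column: t = beta/SE mapped through t-CDF -> normal.

    The mapping is done on tail probabilities of |t| (numerically stable
    far into the tails); z is clipped at +/-38.  Voxels with zero residual
    variance get the clipped value with a log note.
    """
    j = result.columns.index(column)
    m = result.mask
    b = result.beta[column][m]
    var = result.resid_var[m]
    se = np.sqrt(var * result.xtx_inv[j, j])
    z = np.full(b.shape, 0.0)
    ok = se > 0
    n_degenerate = int((~ok & (b != 0)).sum())
    if n_degenerate:
        log.warning("%d voxels with zero residual variance; z clipped", n_degenerate)
    t = np.zeros_like(b)
    t[ok] = b[ok] / se[ok]
    with np.errstate(divide="ignore"):
        ztail = stats.norm.isf(stats.t.sf(np.abs(t), result.dof))
    z = np.sign(t) * np.minimum(ztail, _Z_CLIP)
    z[~ok] = np.sign(b[~ok]) * _Z_CLIP
    out = np.full(result.baseline.shape, np.nan)
    out[m] = z
    return out


@dataclass(frozen=True)
class SmoothnessEstimate:
    """Residual spatial smoothness: per-axis FWHM (voxels) and resel count."""

    fwhm: tuple[float, float, float]
    resel_count: float
    n_voxels: int


def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray) -> SmoothnessEstimate:
    """Smoothness of the residual field from lag-1 spatial autocorrelation.

    Residual time courses are standardized per voxel; along each axis the
    correlation rho of in-mask neighbor pairs (pooled over volumes) gives
    ``FWHM = sqrt(4 ln 2 / (-2 ln rho))`` — the Gaussian-autocorrelation
    relation — floored at one voxel (nothing can be narrower than the
    lattice).  The resel count is ``n_voxels / prod(FWHM)``, at least 1.
    """
    if residuals.ndim != 4 or residuals.shape[3] < 2:
        raise ValueError("need a 4D residual array with >= 2 volumes")
    if int(mask.sum()) < 27:
        raise ValueError("mask too small for smoothness estimation (< 3^3 voxels)")
    r = residuals[mask].astype(np.float64)
    sd = r.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    std = np.zeros(residuals.shape, dtype=np.float64)
    std[mask] = r / sd

    fwhm = []
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        a = std[tuple(sl_a)][pair]
        b = std[tuple(sl_b)][pair]
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        rho = float((a * b).sum() / denom) if denom > 0 else 0.0
        if rho <= 0 or rho >= 1:
            fwhm.append(1.0)
        else:
            fwhm.append(max(1.0, float(np.sqrt(4.0 * np.log(2.0) / (-2.0 * np.log(rho))))))
    n_vox = int(mask.sum())
    resels = max(1.0, n_vox / float(np.prod(fwhm)))
    return SmoothnessEstimate(fwhm=tuple(fwhm), resel_count=resels, n_voxels=n_vox)


@dataclass(frozen=True)
class ThresholdResult:
    z_threshold: float
    alpha: float
    method: str
    resel_count: float
    n_comparisons: float
    two_sided: bool


def _ec_density_3d(z: np.ndarray | float) -> np.ndarray | float:
    """Expected Euler characteristic density of a 3D Gaussian field, per resel."""
    z = np.asarray(z, float)
    return (4 * np.log(2)) ** 1.5 / (2 * np.pi) ** 2 * (z * z - 1.0) * np.exp(-z * z / 2.0)


def resel_corrected_threshold(
    smoothness: SmoothnessEstimate,
    alpha: float = 0.05,
    method: str = "grf",
    two_sided: bool = True,
) -> ThresholdResult:
    """Multiple-comparison z threshold calibrated by the resel count.

    ``method="grf"`` (default) solves ``resels * EC_density(z) = alpha``
    (doubled when two-sided) — the Gaussian-random-field expected-Euler-
    characteristic correction — capped at the voxelwise Bonferroni
    threshold (always valid) and floored at the single-comparison quantile.
    ``method="resel_bonferroni"`` treats the resels as independent samples:
    the smallest z* with ``resels * P(|Z| > z*) = alpha``; a simpler rule
    that is markedly anticonservative for smooth fields.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    R = smoothness.resel_count
    sides = 2.0 if two_sided else 1.0
    z_single = stats.norm.isf(alpha / sides)
    z_vox_bonf = stats.norm.isf(alpha / (sides * smoothness.n_voxels))

    if method == "resel_bonferroni":
        z = float(stats.norm.isf(alpha / (sides * R)))
        n_comp = R
    elif method == "grf":
        f = lambda z: sides * R * _ec_density_3d(z) - alpha
        hi = 40.0
        lo = 1.001  # EC density is positive and decreasing beyond z=1
        if f(lo) <= 0:
            z_grf = lo
        else:
            z_grf = float(optimize.brentq(f, lo, hi, xtol=1e-10))
        z = float(np.clip(z_grf, z_single, z_vox_bonf))
        n_comp = R
    else:
        raise ValueError(f"unknown method {method!r}")
    z = max(z, float(z_single))
    return ThresholdResult(
        z_threshold=z,
        alpha=alpha,
        method=method,
        resel_count=R,
        n_comparisons=n_comp,
        two_sided=two_sided,
    )


def significant_mask(
    z: np.ndarray,
    cvr: np.ndarray,
    threshold: float,
    sign: str = "both",
) -> np.ndarray:
    """Binary mask of voxels with |z| >= threshold and the requested CVR sign."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    with np.errstate(invalid="ignore"):
        sig = np.abs(z) >= threshold
    sig &= np.isfinite(z)
    if sign == "positive":
        sig &= cvr > 0
    elif sign == "negative":
        sig &= cvr < 0
    elif sign != "both":
        raise ValueError(f"unknown sign {sign!r}")
    return sig


@dataclass
class CvrRunResult:
    """Everything one CVR run produces, plus the metadata a sidecar records."""

    cvr: np.ndarray
    z: np.ndarray
    significant: np.ndarray
    smoothness: SmoothnessEstimate
    threshold: ThresholdResult
    lag_s: float
    glm: GlmResult
    params: dict = field(default_factory=dict)

    def sidecar(self) -> dict:
        from . import __version__

        return {
            "software": f"cvrpipe {__version__}",
            "lag_s": self.lag_s,
            "fwhm_voxels": list(self.smoothness.fwhm),
            "resel_count": self.smoothness.resel_count,
            "n_mask_voxels": self.smoothness.n_voxels,
            "z_threshold": self.threshold.z_threshold,
            "threshold_method": self.threshold.method,
            "alpha": self.threshold.alpha,
            **self.params,
        }


def compute_cvr_run(
    series: BoldSeries,
    petco2: np.ndarray,
    peto2: np.ndarray | None = None,
    fwhm_mm: float = 6.0,
    highpass_sigma_s: float = 50.0,
    alpha: float = 0.05,
    max_lag_s: float = 20.0,
    threshold_method: str = "grf",
) -> CvrRunResult:
    """Full single-run pipeline: preprocess, align, GLM, maps, threshold.

    ``petco2``/``peto2`` are per-volume end-tidal series (mmHg).  The same
    temporal high-pass filter applied to the data is applied to the
    regressors so the petCO2 beta is not attenuated by the filtering.
    """
    from .gas import align_to_bold, severinghaus_spo2

    sm = smooth_spatial(series, fwhm_mm)
    hp = highpass_temporal(sm, highpass_sigma_s)
    H = _running_line_matrix(series.n_volumes, series.tr, highpass_sigma_s)

    cols = {"petco2_mmHg": np.asarray(petco2, float)}
    if peto2 is not None:
        cols["peto2_mmHg"] = np.asarray(peto2, float)
    regs = pd.DataFrame(cols)
    aligned, lag_s = align_to_bold(
        regs, hp.global_signal(), series.tr, max_lag_s, trend_matrix=H
    )
    x = aligned["petco2_mmHg"].to_numpy(float)
    x = x - H @ x
    spo2 = None
    if peto2 is not None:
        s = severinghaus_spo2(aligned["peto2_mmHg"].to_numpy(float))
        spo2 = s - H @ s
        if np.ptp(spo2) < 1e-12 * max(1.0, np.abs(s).max()):
            # a perfectly clamped petO2 makes the nuisance constant, which the
            # intercept already spans
            log.info("SpO2 regressor is constant; dropping the nuisance column")
            spo2 = None

    design = make_design(x, spo2)
    glm = fit_glm(hp, design)
    cvr = cvr_from_glm(glm)
    z = zstat_map(glm)
    smooth = estimate_smoothness(glm.residuals, glm.mask)
    thr = resel_corrected_threshold(smooth, alpha=alpha, method=threshold_method)
    sig = significant_mask(z, cvr, thr.z_threshold, sign="both")
    return CvrRunResult(
        cvr=cvr,
        z=z,
        significant=sig,
        smoothness=smooth,
        threshold=thr,
        lag_s=lag_s,
        glm=glm,
        params={
            "fwhm_mm": fwhm_mm,
            "highpass_sigma_s": highpass_sigma_s,
            "max_lag_s": max_lag_s,
        },
    )
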