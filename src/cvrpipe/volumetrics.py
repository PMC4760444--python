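"""Two-time-point structural analysis: segmentation, PBVC, lesion counts.

Tissue volumes come from a three-class Gaussian-mixture segmentation of the
masked intensities (partial volumes = posterior class probabilities).
Percent brain volume change (PBVC) between two rigidly aligned volumes is
estimated SIENA-style: brain-surface edge points are found on the baseline
brain mask, the intensity profile along each outward surface normal is
sampled in both volumes, the half-maximum edge crossing is located with
sub-voxel precision in each, and the area-weighted mean perpendicular
displacement is converted to a global volume change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.mixture import GaussianMixture

__all__ = [
    "TissueSegmentation",
    "TissueVolumes",
    "EdgePointSet",
    "VolumeChangeResult",
    "LesionCount",
    "segment_tissues",
    "tissue_volumes",
    "brain_mask_from_segmentation",
    "edge_displacement",
    "pbvc",
    "count_lesions",
    "percent_volume_change",
    "two_timepoint_analysis",
]


@dataclass
class TissueSegmentation:
    """Per-voxel partial volume estimates for CSF, GM and WM."""

    pv_csf: np.ndarray
    pv_gm: np.ndarray
    pv_wm: np.ndarray
    mask: np.ndarray
    class_means: tuple[float, float, float]


def segment_tissues(
    volume: np.ndarray,
    mask: np.ndarray,
    random_state: int = 0,
) -> TissueSegmentation:
    """Three-class Gaussian mixture segmentation of the masked intensities.

    Classes are identified by ascending mean intensity (CSF < GM < WM on
    T1-like contrast); partial volumes are the posterior probabilities.
    Component means are initialized at the 10th/50th/90th intensity
    percentiles for determinism.
    """
    vals = volume[mask].reshape(-1, 1).astype(float)
    if vals.size < 30:
        raise ValueError("mask too small to segment")
    if np.unique(vals).size < 3 or np.ptp(vals) == 0:
        raise ValueError("need at least three distinct intensity modes to fit three classes")
    init = np.percentile(vals, [10, 50, 90]).reshape(-1, 1)
    if np.unique(init).size < 3:
        raise ValueError("degenerate intensity distribution inside the mask")
    # tied covariance keeps the posterior decision boundaries at the class
    # midpoints, so partial-volume ramps at tissue interfaces integrate to
    # (nearly) their true volumes
    gmm = GaussianMixture(
        n_components=3,
        covariance_type="tied",
        means_init=init,
        reg_covar=1e-6 * float(np.var(vals)) + 1e-10,
        random_state=random_state,
        max_iter=200,
    )
    gmm.fit(vals)
    order = np.argsort(gmm.means_.ravel())
    post = gmm.predict_proba(vals)[:, order]

    maps = []
    for k in range(3):
        m = np.zeros(volume.shape)
        m[mask] = post[:, k]
        maps.append(m)
    means = tuple(float(x) for x in gmm.means_.ravel()[order])
    return TissueSegmentation(pv_csf=maps[0], pv_gm=maps[1], pv_wm=maps[2], mask=mask, class_means=means)


@dataclass(frozen=True)
class TissueVolumes:
    csf_ml: float
    gm_ml: float
    wm_ml: float


def tissue_volumes(seg: TissueSegmentation, voxel_volume_mm3: float) -> TissueVolumes:
    """Partial-volume-weighted tissue volumes in mL."""
    f = voxel_volume_mm3 / 1000.0
    return TissueVolumes(
        csf_ml=float(seg.pv_csf.sum()) * f,
        gm_ml=float(seg.pv_gm.sum()) * f,
        wm_ml=float(seg.pv_wm.sum()) * f,
    )


def brain_mask_from_segmentation(seg: TissueSegmentation, threshold: float = 0.5) -> np.ndarray:
    """Brain (GM+WM) mask from the partial volume maps."""
    return (seg.pv_gm + seg.pv_wm) > threshold


@dataclass
class EdgePointSet:
    """Brain-surface sample points with normals and measured displacements.

    Points are marching-cubes triangle centroids of the baseline brain
    surface (mm coordinates); ``areas`` are the exact triangle areas, so
    the set carries an unbiased estimate of the surface area.  Displacement
    is the perpendicular edge shift in mm, positive outward (growth).
    """

    points: np.ndarray  # (n, 3) mm
    normals: np.ndarray  # (n, 3) unit, outward
    displacement: np.ndarray  # (n,) mm
    areas: np.ndarray  # (n,) mm^2
    n_dropped: int


def _surface_mesh(
    field: np.ndarray, voxel_size, level: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Triangle centroids, outward normals and areas of an isosurface."""
    m = np.asarray(field, float)
    verts, faces, vnormals, _ = measure.marching_cubes(m, level=level, spacing=tuple(voxel_size))
    tri = verts[faces]  # (n, 3, 3)
    centroids = tri.mean(axis=1)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    normals = vnormals[faces].mean(axis=1)
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)

    # orient outward: occupancy must decrease along the normal
    vox = np.asarray(voxel_size)
    probe = lambda pts: ndimage.map_coordinates(m, (pts / vox).T, order=1, mode="nearest")
    step = float(np.mean(vox))
    flip = probe(centroids + step * normals) > probe(centroids - step * normals)
    normals[flip] *= -1.0
    keep = areas > 0
    return centroids[keep], normals[keep], areas[keep]


def _half_max_crossing(
    profiles: np.ndarray, s: np.ndarray, half: np.ndarray | float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-voxel position of the inside->outside half-maximum crossing.

    ``profiles`` is (n, m) sampled at offsets ``s`` (ascending, inside to
    outside).  The half level is either given (e.g. the midpoint of the
    segmentation's brain and CSF class means) or estimated per profile from
    the medians of the inner and outer fifths.  The first bracketed
    crossing below the half level is located by linear interpolation;
    profiles that start below the level or never cross it are invalid.
    """
    n, m = profiles.shape
    if half is None:
        q = max(2, m // 5)
        inside = np.median(profiles[:, :q], axis=1)
        outside = np.median(profiles[:, -q:], axis=1)
        half = 0.5 * (inside + outside)
        valid = inside > outside + 1e-6
    else:
        half = np.broadcast_to(np.asarray(half, float), (n,)).copy()
        valid = np.ones(n, dtype=bool)

    below = profiles < half[:, None]
    valid &= ~below[:, 0]  # must start above the level
    below[:, 0] = False
    first = np.argmax(below, axis=1)
    has_cross = below[np.arange(n), np.clip(first, 0, m - 1)] & (first > 0)
    valid &= has_cross

    i = np.clip(first, 1, m - 1)
    y0 = profiles[np.arange(n), i - 1]
    y1 = profiles[np.arange(n), i]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (y0 - half) / np.maximum(y0 - y1, 1e-12)
    frac = np.clip(frac, 0.0, 1.0)  # stay inside the bracketing interval
    pos = s[i - 1] + frac * (s[i] - s[i - 1])
    return pos, valid


def edge_displacement(
    vol_pre: np.ndarray,
    vol_post: np.ndarray,
    brain_mask_pre: np.ndarray,
    voxel_size,
    profile_half_length_mm: float = 9.0,
    step_mm: float = 0.5,
    half_level: float | None = None,
) -> EdgePointSet:
    """Perpendicular brain-edge displacement between two aligned volumes.

    At each baseline surface point the intensity profile along the outward
    normal is sampled in both volumes (trilinear interpolation) and the
    half-maximum edge crossing located in each; the displacement is the
    post-minus-pre crossing position in mm (positive = outward growth).
    ``half_level`` fixes the edge intensity (midpoint of the brain and CSF
    class means, as the segmentation provides); when None it is estimated
    per profile.  Profiles without a clean inside-to-outside crossing are
    dropped and counted.
    """
    vox = np.asarray(voxel_size, float)
    if half_level is not None:
        # the half-level isosurface of the (lightly regularized) baseline
        # image is the brain/nonbrain edge itself: sub-voxel accurate mesh,
        # unbiased surface area
        field = ndimage.gaussian_filter(np.asarray(vol_pre, float), 0.5)
        centroids, normals, areas = _surface_mesh(field, vox, level=half_level)
    else:
        centroids, normals, areas = _surface_mesh(
            ndimage.gaussian_filter(brain_mask_pre.astype(float), 0.5), vox, level=0.5
        )
    s = np.arange(-profile_half_length_mm, profile_half_length_mm + step_mm / 2, step_mm)

    pts = centroids[:, None, :] + s[None, :, None] * normals[:, None, :]  # (n, m, 3)
    coords = (pts / vox).reshape(-1, 3).T

    prof_pre = ndimage.map_coordinates(vol_pre.astype(float), coords, order=1, mode="nearest")
    prof_post = ndimage.map_coordinates(vol_post.astype(float), coords, order=1, mode="nearest")
    prof_pre = prof_pre.reshape(len(centroids), len(s))
    prof_post = prof_post.reshape(len(centroids), len(s))

    pos_pre, ok_pre = _half_max_crossing(prof_pre, s, half_level)
    pos_post, ok_post = _half_max_crossing(prof_post, s, half_level)
    ok = ok_pre & ok_post
    disp = pos_post[ok] - pos_pre[ok]
    return EdgePointSet(
        points=centroids[ok],
        normals=normals[ok],
        displacement=disp,
        areas=areas[ok],
        n_dropped=int((~ok).sum()),
    )


@dataclass(frozen=True)
class VolumeChangeResult:
    pbvc: float  # %, signed
    mean_displacement_mm: float
    n_edge_points: int
    surface_area_mm2: float


def pbvc(edges: EdgePointSet, brain_volume_mm3: float) -> VolumeChangeResult:
    """Percent brain volume change from the edge displacement field.

    ``PBVC = 100 * sum(d_i * a_i) / V`` — the area-weighted displacement
    integrated over the surface, i.e. ``100 * mean_disp * area / V`` with
    an unbiased (mesh-triangle) surface area.
    """
    if len(edges.displacement) < 100:
        raise ValueError("too few edge points for a stable PBVC estimate (< 100)")
    if brain_volume_mm3 <= 0:
        raise ValueError("brain volume must be > 0")
    area = float(edges.areas.sum())
    mean_disp = float(np.average(edges.displacement, weights=edges.areas))
    return VolumeChangeResult(
        pbvc=100.0 * mean_disp * area / brain_volume_mm3,
        mean_displacement_mm=mean_disp,
        n_edge_points=len(edges.displacement),
        surface_area_mm2=area,
    )


@dataclass(frozen=True)
class LesionCount:
    n_lesions: int
    sizes_mm3: tuple[float, ...]


def count_lesions(
    mask: np.ndarray, voxel_volume_mm3: float, min_size_mm3: float = 5.0
) -> LesionCount:
    """26-connected components of a binary lesion mask above a minimum size."""
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return LesionCount(0, ())
    counts = np.bincount(labeled.ravel())[1:]
    sizes = counts * voxel_volume_mm3
    keep = sizes >= min_size_mm3
    return LesionCount(int(keep.sum()), tuple(float(x) for x in np.sort(sizes[keep])[::-1]))


def percent_volume_change(pre_ml: float, post_ml: float) -> float:
    """100 * (post - pre) / pre."""
    if pre_ml <= 0:
        raise ValueError("pre volume must be > 0")
    return 100.0 * (post_ml - pre_ml) / pre_ml


def two_timepoint_analysis(
    vol_pre: np.ndarray,
    vol_post: np.ndarray,
    head_mask: np.ndarray,
    voxel_size,
    lesion_mask: np.ndarray | None = None,
) -> dict:
    """Segment both time points, estimate PBVC, and count lesions.

    Returns a flat dict of per-subject volumetric results (tissue volumes
    in mL at both time points, their percent changes, PBVC, and the lesion
    count if a mask is given).
    """
    vox = np.asarray(voxel_size, float)
    voxvol = float(np.prod(vox))
    seg_pre = segment_tissues(vol_pre, head_mask)
    seg_post = segment_tissues(vol_post, head_mask)
    tv_pre = tissue_volumes(seg_pre, voxvol)
    tv_post = tissue_volumes(seg_post, voxvol)

    brain_pre = brain_mask_from_segmentation(seg_pre)
    brain_vol_mm3 = float((seg_pre.pv_gm + seg_pre.pv_wm).sum()) * voxvol
    # brain/nonbrain edge intensity: midpoint of the GM and CSF class means
    half = 0.5 * (seg_pre.class_means[0] + seg_pre.class_means[1])
    edges = edge_displacement(vol_pre, vol_post, brain_pre, vox, half_level=half)
    change = pbvc(edges, brain_vol_mm3)

    out = {
        "gm_ml_pre": tv_pre.gm_ml,
        "gm_ml_post": tv_post.gm_ml,
        "wm_ml_pre": tv_pre.wm_ml,
        "wm_ml_post": tv_post.wm_ml,
        "pct_change_gm": percent_volume_change(tv_pre.gm_ml, tv_post.gm_ml),
        "pct_change_wm": percent_volume_change(tv_pre.wm_ml, tv_post.wm_ml),
        "pbvc": change.pbvc,
        "mean_edge_displacement_mm": change.mean_displacement_mm,
        "n_edge_points": change.n_edge_points,
    }
    if lesion_mask is not None:
        out["wmhi_n"] = count_lesions(lesion_mask, voxvol).n_lesions
    return out
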