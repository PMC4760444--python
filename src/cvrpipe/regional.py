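"""Regional CVR extraction and positive/negative-CVR dichotomization.

Each atlas structure (and the gray/white tissue masks) is summarized by its
mean CVR; at baseline every structure is split into its significant
positive-CVR and significant negative-CVR compartments, and those exact
masks are reapplied at follow-up so that a change in the negative
compartment (e.g. reversal of vascular steal) can be separated from the
behavior of the positively responding tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import GM, WM, PhantomSpec

__all__ = [
    "LabelAtlas",
    "DichotomyMasks",
    "FrequencyDistribution",
    "tissue_masks",
    "phantom_atlas",
    "extract_region_cvr",
    "region_summaries",
    "dichotomize",
    "apply_masks_at_followup",
    "fractional_distribution",
    "percent_change",
]

# the ten structures the regional analysis reports
SUBCORTICAL_STRUCTURES = (
    "brainstem",
    "accumbens",
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
)


@dataclass
class LabelAtlas:
    """Integer label volume plus its id -> (name, hemisphere) table."""

    labels: np.ndarray
    table: pd.DataFrame  # columns: id, name, hemisphere in {left, right, none}

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        known = set(self.table["id"])
        if not present <= known:
            raise ValueError(f"labels {sorted(present - known)} missing from the table")

    def mask(self, structure: str, hemisphere: str | None = None) -> np.ndarray:
        rows = self.table[self.table["name"] == structure]
        if hemisphere is not None:
            rows = rows[rows["hemisphere"] == hemisphere]
        if len(rows) == 0:
            raise KeyError(f"{structure!r} ({hemisphere!r}) not in atlas")
        return np.isin(self.labels, rows["id"].to_numpy())


def tissue_masks(
    tissue_labels: np.ndarray, erode_voxels: int = 1
) -> dict[str, np.ndarray]:
    """Gray/white matter masks from a tissue label volume.

    Masks are eroded by ``erode_voxels`` (default 1) so tissue means are
    not contaminated by partial-volume mixing at interfaces — the standard
    convention when extracting tissue-level CVR.  Pass 0 for the raw masks.
    """
    out = {}
    for name, lab in (("gray_matter", GM), ("white_matter", WM)):
        m = tissue_labels == lab
        if erode_voxels > 0:
            m = ndimage.binary_erosion(m, iterations=erode_voxels)
        out[name] = m
    return out


def phantom_atlas(phantom: PhantomSpec, sphere_radius_mm: float = 7.5) -> LabelAtlas:
    """Deterministic subcortical-style atlas for a phantom grid.

    Places a midline brainstem sphere and left/right spheres for the seven
    bilateral structures at fixed fractional positions inside the brain, so
    regional operations can be exercised with known geometry.
    """
    shape = phantom.grid_dims
    vox = np.asarray(phantom.voxel_size)
    brain = phantom.brain_mask
    center = np.array([(s - 1) / 2 for s in shape])

    rows = [{"id": 1, "name": "brainstem", "hemisphere": "none"}]
    # fractional offsets (axis0, axis1, axis2) from the brain center, in units
    # of the grid half-extent; bilateral structures mirrored on axis 0
    offsets = {
        "accumbens": (0.18, -0.15, 0.0),
        "amygdala": (0.30, 0.0, -0.15),
        "caudate": (0.15, 0.15, 0.1),
        "hippocampus": (0.32, 0.12, 0.12),
        "pallidum": (0.22, 0.0, 0.05),
        "putamen": (0.28, -0.05, 0.08),
        "thalamus": (0.12, 0.0, 0.15),
    }
    labels = np.zeros(shape, dtype=np.int16)
    zz, yy, xx = np.indices(shape).astype(float)

    def carve(lab_id, pos_vox):
        d2 = sum(((g - p) * v) ** 2 for g, p, v in zip((zz, yy, xx), pos_vox, vox))
        sphere = (d2 <= sphere_radius_mm**2) & brain
        labels[sphere] = lab_id

    half = np.array([s / 2 for s in shape])
    carve(1, center + np.array([0.0, 0.25, 0.0]) * half)  # brainstem, midline
    next_id = 2
    for name, frac in offsets.items():
        for hemi, sign in (("left", -1.0), ("right", 1.0)):
            pos = center + np.array([sign * frac[0], frac[1], frac[2]]) * half
            carve(next_id, pos)
            rows.append({"id": next_id, "name": name, "hemisphere": hemi})
            next_id += 1
    return LabelAtlas(labels=labels, table=pd.DataFrame(rows))


def extract_region_cvr(cvr: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """Arithmetic mean CVR over the masked voxels, with the voxel count."""
    m = mask & np.isfinite(cvr)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty region mask")
    return float(cvr[m].mean()), n


def region_summaries(
    cvr: np.ndarray,
    atlas: LabelAtlas,
    session: str,
    tissue_labels: np.ndarray | None = None,
    erode_voxels: int = 1,
) -> pd.DataFrame:
    """Tidy per-structure summary (one row per structure x hemisphere)."""
    rows = []
    if tissue_labels is not None:
        for name, m in tissue_masks(tissue_labels, erode_voxels).items():
            mean, n = extract_region_cvr(cvr, m)
            rows.append(
                {"session": session, "structure": name, "hemisphere": "none",
                 "mean_cvr": mean, "n_voxels": n}
            )
    for _, r in atlas.table.iterrows():
        m = atlas.labels == r["id"]
        if not m.any():
            continue
        mean, n = extract_region_cvr(cvr, m)
        rows.append(
            {"session": session, "structure": r["name"], "hemisphere": r["hemisphere"],
             "mean_cvr": mean, "n_voxels": n}
        )
    return pd.DataFrame(rows)


@dataclass
class DichotomyMasks:
    """Pre-test significant positive/negative compartments of one structure.

    A compartment with no voxels is recorded as ``None`` (absent), which
    downstream statistics treat as listwise-excludable.
    """

    positive: np.ndarray | None
    negative: np.ndarray | None
    structure: str = ""

    @property
    def has_both(self) -> bool:
        return self.positive is not None and self.negative is not None


def dichotomize(
    pre_cvr: np.ndarray,
    pre_significant: np.ndarray,
    structure_mask: np.ndarray,
    structure: str = "",
) -> DichotomyMasks:
    """Split a structure into significant positive- and negative-CVR voxels.

    Voxels must be inside the structure, significant at baseline, and have
    strictly positive (resp. negative) CVR; CVR exactly zero belongs to
    neither compartment.  Empty compartments come back as ``None``.
    """
    base = structure_mask & pre_significant & np.isfinite(pre_cvr)
    pos = base & (pre_cvr > 0)
    neg = base & (pre_cvr < 0)
    return DichotomyMasks(
        positive=pos if pos.any() else None,
        negative=neg if neg.any() else None,
        structure=structure,
    )


def apply_masks_at_followup(
    post_cvr: np.ndarray,
    masks: DichotomyMasks,
    pre_cvr: np.ndarray,
) -> pd.DataFrame:
    """Pre/post compartment means over the frozen baseline masks.

    One row per non-absent compartment with columns ``structure,
    compartment, pre_mean, post_mean, n_voxels`` — the cells the 2x2
    repeated-measures ANOVA consumes.
    """
    rows = []
    for comp, m in (("positive", masks.positive), ("negative", masks.negative)):
        if m is None:
            continue
        pre_mean, n = extract_region_cvr(pre_cvr, m)
        post_mean, _ = extract_region_cvr(post_cvr, m)
        rows.append(
            {"structure": masks.structure, "compartment": comp,
             "pre_mean": pre_mean, "post_mean": post_mean, "n_voxels": n}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FrequencyDistribution:
    """Fractional histogram of a masked CVR map, with its mean."""

    bin_edges: np.ndarray
    fractions: np.ndarray
    mean: float
    n_voxels: int


def fractional_distribution(
    cvr: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 0.025,
    value_range: tuple[float, float] = (-1.0, 1.0),
) -> FrequencyDistribution:
    """Histogram of masked CVR normalized to fractions summing to one.

    Values outside ``value_range`` are clipped into the end bins so no
    voxel is dropped; the reported mean is the (unclipped) voxelwise mean.
    """
    m = mask & np.isfinite(cvr)
    vals = cvr[m]
    if vals.size == 0:
        raise ValueError("empty mask")
    lo, hi = value_range
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(nbins + 1) * bin_width
    counts, _ = np.histogram(np.clip(vals, lo, hi - 1e-12), bins=edges)
    return FrequencyDistribution(
        bin_edges=edges,
        fractions=counts / counts.sum(),
        mean=float(vals.mean()),
        n_voxels=int(vals.size),
    )


def percent_change(pre: float, post: float) -> float:
    """Signed percent change 100 * (post - pre) / pre."""
    if pre == 0:
        raise ValueError("percent change undefined for zero baseline")
    return 100.0 * (post - pre) / pre
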