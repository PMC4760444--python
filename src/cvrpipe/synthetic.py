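"""Synthetic gas traces, BOLD phantoms and paired structural phantoms.

Every generator records its ground truth so downstream stages (breath
detection, end-tidal extraction, the voxelwise GLM, segmentation, edge
displacement) can be validated against known answers.

The default protocol emulates a stepped end-tidal forcing CVR test: two
2-minute hypocapnic steps (-10, -5 mmHg relative to baseline) followed by a
return to baseline and three 2-minute hypercapnic steps (+5, +10, +15 mmHg),
with end-tidal O2 clamped at 100 mmHg throughout.  The BOLD phantom responds
linearly to the CO2 excursion with gray-matter reactivity about twice that
of white matter, scattered negative-reactivity foci, and a uniform
circulatory delay between the gas trace and the BOLD response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = [
    "ProtocolSpec",
    "PhantomSpec",
    "AtrophySpec",
    "LesionSpec",
    "generate_protocol_trace",
    "schedule_per_volume",
    "generate_bold_phantom",
    "generate_structural_pair",
    "default_bold_phantom",
    "default_structural_phantom",
]

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3

# Default stepped protocol: hypocapnia first, a return to baseline, then
# graded hypercapnia.  Deltas in mmHg relative to baseline, durations in s.
DEFAULT_STEPS: tuple[tuple[float, float], ...] = (
    (-10.0, 120.0),
    (-5.0, 120.0),
    (0.0, 120.0),
    (5.0, 120.0),
    (10.0, 120.0),
    (15.0, 120.0),
)


@dataclass(frozen=True)
class ProtocolSpec:
    """Stepped end-tidal CO2 protocol with a clamped end-tidal O2.

    Parameters
    ----------
    baseline_petco2 : float
        Resting end-tidal PCO2 target, mmHg.
    baseline_duration : float
        Leading baseline block, s.
    steps : sequence of (delta_petco2, duration)
        Ordered petCO2 excursions relative to baseline (mmHg, s).
    peto2_clamp : float
        End-tidal PO2 held constant for the whole test, mmHg.
    breath_period : float
        Prescribed breath duration, s (ventilation is forced, no
        chemoreflex feedback is modelled).
    sample_rate : float
        Mouth-sampling rate of the gas/flow analyzers, Hz.
    tidal_volume : float
        Prescribed tidal volume, L.
    """

    baseline_petco2: float = 41.4
    baseline_duration: float = 120.0
    steps: tuple[tuple[float, float], ...] = DEFAULT_STEPS
    peto2_clamp: float = 100.0
    breath_period: float = 5.0
    sample_rate: float = 200.0
    tidal_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_duration <= 0:
            raise ValueError("baseline_duration must be > 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.breath_period <= 0:
            raise ValueError("breath_period must be > 0")
        if self.peto2_clamp <= 0:
            raise ValueError("peto2_clamp must be > 0")
        if not self.steps:
            raise ValueError("steps must be non-empty")
        if any(d <= 0 for _, d in self.steps):
            raise ValueError("step durations must be > 0")

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + sum(d for _, d in self.steps)

    def delta_at(self, t: np.ndarray | float) -> np.ndarray:
        """Scheduled petCO2 excursion (mmHg relative to baseline) at time t."""
        t = np.asarray(t, dtype=float)
        edges = np.cumsum([self.baseline_duration] + [d for _, d in self.steps])
        deltas = np.array([0.0] + [dv for dv, _ in self.steps])
        idx = np.searchsorted(edges, t, side="right")
        idx = np.clip(idx, 0, len(deltas) - 1)
        return deltas[idx]


def generate_protocol_trace(
    spec: ProtocolSpec,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthesize mouth-sampled PCO2/PO2 and respiratory flow for a protocol.

    Within each breath the PCO2 waveform sits at the inspired level during
    inspiration and rises to the scheduled expired plateau (a square plateau
    with a linear transition); PO2 falls from the inspired level to the
    clamp during expiration.  Flow is a sinusoidal inspiration/expiration
    cycle scaled to the prescribed tidal volume.

    Returns
    -------
    gas : DataFrame with columns ``time_s, pco2_mmHg, po2_mmHg``
    flow : DataFrame with columns ``time_s, flow_lps`` (positive = inspiration)
    schedule : DataFrame with one row per breath
        (``breath, onset_s, offset_s, petco2_mmHg, peto2_mmHg``) — the exact
        plateau the generator imposed.
    """
    rng = np.random.default_rng(seed)
    fs, T = spec.sample_rate, spec.breath_period
    n = int(round(spec.total_duration * fs))
    t = np.arange(n) / fs

    onsets = np.arange(0.0, spec.total_duration - 1e-9, T)
    plateaus = spec.baseline_petco2 + spec.delta_at(onsets)
    schedule = pd.DataFrame(
        {
            "breath": np.arange(len(onsets)),
            "onset_s": onsets,
            "offset_s": np.minimum(onsets + T, spec.total_duration),
            "petco2_mmHg": plateaus,
            "peto2_mmHg": np.full(len(onsets), spec.peto2_clamp),
        }
    )

    phase = (t % T) / T  # 0..1 within breath; inspiration first half
    ibreath = np.minimum((t // T).astype(int), len(onsets) - 1)
    plateau_t = plateaus[ibreath]
    inspired_co2 = np.maximum(0.0, plateau_t - spec.baseline_petco2)

    # expiration occupies phase in [0.5, 1); plateau reached after a 30%
    # linear transition so the expiratory maximum equals the plateau exactly
    ramp = np.clip((phase - 0.5) / 0.15, 0.0, 1.0)
    pco2 = np.where(phase < 0.5, inspired_co2, inspired_co2 + ramp * (plateau_t - inspired_co2))

    inspired_po2 = spec.peto2_clamp + 50.0
    po2 = np.where(
        phase < 0.5, inspired_po2, inspired_po2 + ramp * (spec.peto2_clamp - inspired_po2)
    )

    amp = np.pi * spec.tidal_volume / T  # integral of A*sin over half-cycle = VT
    flow = amp * np.sin(2 * np.pi * phase)

    if noise_sd > 0:
        pco2 = np.maximum(pco2 + rng.normal(0.0, noise_sd, n), 0.0)
        po2 = np.maximum(po2 + rng.normal(0.0, noise_sd, n), 0.0)
        flow = flow + rng.normal(0.0, noise_sd * amp, n)

    gas = pd.DataFrame({"time_s": t, "pco2_mmHg": pco2, "po2_mmHg": po2})
    flow_df = pd.DataFrame({"time_s": t, "flow_lps": flow})
    return gas, flow_df, schedule


def schedule_per_volume(spec: ProtocolSpec, tr: float, n_volumes: int | None = None) -> np.ndarray:
    """Ideal per-volume petCO2 excursion (mmHg relative to baseline).

    Used to drive the BOLD phantom; volume k is acquired at t = k*tr.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if n_volumes is None:
        n_volumes = int(spec.total_duration // tr)
    t = np.arange(n_volumes) * tr
    return spec.delta_at(t)


# ---------------------------------------------------------------------------
# BOLD phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Voxelized brain phantom: geometry, true reactivity and noise model.

    ``tissue_labels`` uses 0=background, 1=CSF, 2=GM, 3=WM.  ``true_cvr`` is
    the signed reactivity in % per mmHg; ``delay_map`` the circulatory delay
    in s between the end-tidal excursion and the BOLD response;
    ``baseline_signal`` the mean BOLD intensity (arbitrary units).
    """

    voxel_size: tuple[float, float, float]
    tissue_labels: np.ndarray
    true_cvr: np.ndarray
    delay_map: np.ndarray
    baseline_signal: np.ndarray
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    seed: int = 0
    # analytic spherical geometry (center_mm, r_brain_mm, r_wm_mm, r_head_mm);
    # when present the structural generator uses exact signed distances
    # instead of voxel-quantized ones
    radial_geometry: dict | None = None

    def __post_init__(self) -> None:
        shp = self.tissue_labels.shape
        for name in ("true_cvr", "delay_map", "baseline_signal"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != grid {shp}")
        if not np.all(np.isfinite(self.true_cvr)):
            raise ValueError("true_cvr must be finite everywhere")
        if np.any(self.delay_map < 0):
            raise ValueError("delay_map must be >= 0")
        brain = self.tissue_labels > 0
        if np.any(self.baseline_signal[brain] <= 0):
            raise ValueError("baseline_signal must be > 0 inside the brain")

    @property
    def grid_dims(self) -> tuple[int, ...]:
        return self.tissue_labels.shape

    @property
    def brain_mask(self) -> np.ndarray:
        """Analysis mask: gray plus white matter."""
        return np.isin(self.tissue_labels, (GM, WM))


def default_bold_phantom(
    shape: tuple[int, int, int] = (40, 48, 40),
    voxel_size: float = 3.0,
    gm_cvr: float = 0.30,
    wm_cvr: float = 0.15,
    negative_cvr: float = -0.20,
    n_negative_foci: int = 6,
    focus_radius_mm: float = 9.0,
    delay_s: float = 6.0,
    noise_sd: float = 8.0,
    drift_amplitude: float = 0.0,
    seed: int = 0,
    gm_shell_voxels: float = 4.0,
) -> PhantomSpec:
    """Ellipsoidal brain phantom with a GM shell over a WM core.

    Defaults reproduce the study conditions the pipeline is validated
    against: GM reactivity twice WM, scattered negative-reactivity foci, a
    uniform 6 s circulatory delay and noise of 1% of the GM baseline signal.
    """
    rng = np.random.default_rng(seed)
    grid = np.indices(shape).astype(float)
    center = [(s - 1) / 2 for s in shape]
    radii = [0.40 * s for s in shape]
    r = np.sqrt(sum(((g - c) / rr) ** 2 for g, c, rr in zip(grid, center, radii)))
    brain = r <= 1.0
    csf = (r > 1.0) & (r <= 1.0 + 1.0 / min(radii))  # one-voxel CSF rim

    dist = ndimage.distance_transform_edt(brain)
    labels = np.zeros(shape, dtype=np.int16)
    labels[csf] = CSF
    labels[brain & (dist <= gm_shell_voxels)] = GM
    labels[brain & (dist > gm_shell_voxels)] = WM

    cvr = np.zeros(shape)
    cvr[labels == GM] = gm_cvr
    cvr[labels == WM] = wm_cvr

    # scattered negative-reactivity foci, seeded away from the brain edge
    interior = np.argwhere(dist > 2.0)
    focus_r_vox = focus_radius_mm / voxel_size
    for _ in range(n_negative_foci):
        cz, cy, cx = interior[rng.integers(len(interior))]
        zz, yy, xx = np.indices(shape)
        sphere = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= focus_r_vox**2
        cvr[sphere & brain] = negative_cvr

    s0 = np.zeros(shape)
    s0[labels == CSF] = 400.0
    s0[labels == GM] = 800.0
    s0[labels == WM] = 700.0

    return PhantomSpec(
        voxel_size=(voxel_size,) * 3,
        tissue_labels=labels,
        true_cvr=cvr,
        delay_map=np.where(labels > 0, delay_s, 0.0),
        baseline_signal=s0,
        noise_sd=noise_sd,
        drift_amplitude=drift_amplitude,
        seed=seed,
    )


def generate_bold_phantom(
    phantom: PhantomSpec,
    schedule: np.ndarray,
    tr: float = 2.0,
) -> tuple["BoldSeries", dict]:
    """4D BOLD series responding linearly to the petCO2 excursion.

    ``S(v, t) = S0(v) * (1 + CVR(v)/100 * dPetCO2(t - delay(v))) + drift + noise``

    The excursion is shifted per voxel by the phantom's delay map (linear
    interpolation on the volume grid, held at the first value before the
    run starts).  Noise is i.i.d. Gaussian; drift is a linear ramp of total
    amplitude ``drift_amplitude`` over the run.
    """
    from .mapping import BoldSeries  # local import to avoid a cycle

    schedule = np.asarray(schedule, dtype=float)
    if schedule.ndim != 1 or schedule.size < 2:
        raise ValueError("schedule must be a 1D per-volume series")
    n_vol = schedule.size
    t = np.arange(n_vol) * tr

    shape = phantom.grid_dims
    data = np.zeros(shape + (n_vol,), dtype=np.float64)

    delays = phantom.delay_map
    for d in np.unique(delays):
        sel = delays == d
        x = np.interp(t - d, t, schedule, left=schedule[0])
        s0 = phantom.baseline_signal[sel][:, None]
        c = phantom.true_cvr[sel][:, None]
        data[sel] = s0 * (1.0 + c / 100.0 * x[None, :])

    if phantom.drift_amplitude:
        drift = phantom.drift_amplitude * (t / t[-1] - 0.5)
        data += drift[None, None, None, :]
    if phantom.noise_sd > 0:
        rng = np.random.default_rng(phantom.seed)
        data += rng.normal(0.0, phantom.noise_sd, data.shape)

    series = BoldSeries(
        data=data,
        tr=tr,
        voxel_size=phantom.voxel_size,
        mask=phantom.brain_mask,
    )
    truth = {
        "cvr": phantom.true_cvr,
        "delay_s": phantom.delay_map,
        "tissue_labels": phantom.tissue_labels,
        "schedule": schedule,
    }
    return series, truth


# ---------------------------------------------------------------------------
# Paired structural phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtrophySpec:
    """Volumetric change imposed between the two structural time points.

    ``boundary_shift`` (mm) moves the outer brain surface inward (positive =
    atrophy).  ``gm_scale``/``wm_scale`` rescale tissue volumes; the
    corresponding sub-voxel surface shifts are solved numerically.
    """

    boundary_shift: float = 0.0
    gm_scale: float = 1.0
    wm_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.gm_scale <= 0 or self.wm_scale <= 0:
            raise ValueError("tissue scales must be > 0")


@dataclass(frozen=True)
class LesionSpec:
    """White-matter hyperintensity-like lesions seeded into the phantom."""

    n_lesions: int = 0
    radius_range_mm: tuple[float, float] = (2.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.radius_range_mm[0] <= 0:
            raise ValueError("lesion radii must be > 0")


def default_structural_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: float = 3.0,
    brain_radius_mm: float = 67.4,
    wm_radius_mm: float = 52.8,
    csf_thickness_mm: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Spherical structural phantom with T1-like tissue volumes.

    The default radii give roughly 670 mL of gray and 615 mL of white
    matter, matching adult human magnitudes.
    """
    grid = np.indices(shape).astype(float) * voxel_size
    center = [(s - 1) / 2 * voxel_size for s in shape]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grid, center)))
    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= brain_radius_mm + csf_thickness_mm] = CSF
    labels[r <= brain_radius_mm] = GM
    labels[r <= wm_radius_mm] = WM
    zeros = np.zeros(shape)
    s0 = np.where(labels > 0, 100.0, 0.0)
    return PhantomSpec(
        voxel_size=(voxel_size,) * 3,
        tissue_labels=labels,
        true_cvr=zeros,
        delay_map=zeros,
        baseline_signal=np.maximum(s0, 1e-3),
        noise_sd=noise_sd,
        seed=seed,
        radial_geometry={
            "center_mm": tuple(center),
            "r_brain_mm": brain_radius_mm,
            "r_wm_mm": wm_radius_mm,
            "r_head_mm": brain_radius_mm + csf_thickness_mm,
        },
    )


# T1-like class intensities (arbitrary units), CSF < GM < WM
_CSF_I, _GM_I, _WM_I, _LESION_I = 30.0, 60.0, 90.0, 120.0


def _signed_distance(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Signed Euclidean distance to the mask surface (mm), positive inside.

    Voxel-center EDT distances are corrected by half a voxel so the zero
    level sits on the physical boundary (midway between the adjacent
    inside and outside voxel centers) instead of jumping across it.
    """
    half = 0.5 * float(np.mean(voxel_size))
    inside = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    outside = ndimage.distance_transform_edt(~mask, sampling=voxel_size)
    return np.where(mask, inside - half, -(outside - half))


def _partial_volume(sdf: np.ndarray, h: float) -> np.ndarray:
    """Antialiased occupancy from a signed distance, linear over one voxel."""
    return np.clip(0.5 + sdf / h, 0.0, 1.0)


def generate_structural_pair(
    phantom: PhantomSpec,
    atrophy: AtrophySpec = AtrophySpec(),
    lesions: LesionSpec = LesionSpec(),
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Paired T1-like volumes with known volumetric change and lesions.

    Time point 2 displaces the outer brain surface inward by
    ``atrophy.boundary_shift`` mm plus whatever sub-voxel shift is needed to
    hit the requested tissue scale factors (solved on the antialiased
    partial-volume representation, so the imposed change is sub-voxel
    accurate).  Lesions are bright spheres seeded in white matter,
    identical at both time points.

    Returns ``(volume1, volume2, truth)`` where ``truth`` carries exact
    pre/post tissue volumes in mL, the applied surface shifts, the lesion
    count and the lesion mask.
    """
    labels = phantom.tissue_labels
    voxel_size = phantom.voxel_size
    h = float(np.mean(voxel_size))
    voxvol = float(np.prod(voxel_size))

    brain = np.isin(labels, (GM, WM))
    wm = labels == WM
    head = labels > 0

    if phantom.radial_geometry is not None:
        # exact signed distances for spherical phantoms: sub-voxel partial
        # volumes are real, so imposed shifts render faithfully
        geo = phantom.radial_geometry
        grid = np.indices(labels.shape).astype(float)
        r = np.sqrt(
            sum(
                (g * v - c) ** 2
                for g, v, c in zip(grid, voxel_size, geo["center_mm"])
            )
        )
        sdf_brain = geo["r_brain_mm"] - r
        sdf_wm = geo["r_wm_mm"] - r if wm.any() else np.full_like(r, -np.inf)
        sdf_head = geo["r_head_mm"] - r
    else:
        sdf_brain = _signed_distance(brain, voxel_size)
        sdf_wm = (
            _signed_distance(wm, voxel_size) if wm.any() else np.full_like(sdf_brain, -np.inf)
        )
        sdf_head = _signed_distance(head, voxel_size)

    max_inradius = float(sdf_brain.max())
    if abs(atrophy.boundary_shift) >= max_inradius:
        raise ValueError(
            f"boundary_shift {atrophy.boundary_shift} mm exceeds the object inradius "
            f"({max_inradius:.1f} mm)"
        )

    def vol_ml(sdf, shift=0.0):
        return float(_partial_volume(sdf - shift, h).sum()) * voxvol / 1000.0

    def solve_shift(sdf, target_ml):
        f = lambda s: vol_ml(sdf, s) - target_ml
        lo, hi = -2.0 * h, max_inradius - 1e-6
        if f(lo) < 0:  # growth: search outward
            lo = -0.5 * max_inradius
        return optimize.brentq(f, lo, hi, xtol=1e-6)

    brain_pre = vol_ml(sdf_brain)
    wm_pre = vol_ml(sdf_wm) if wm.any() else 0.0
    gm_pre = brain_pre - wm_pre

    # white matter first (its boundary is interior to the brain)
    wm_shift = 0.0
    if wm.any() and atrophy.wm_scale != 1.0:
        wm_shift = solve_shift(sdf_wm, atrophy.wm_scale * wm_pre)
    wm_post = vol_ml(sdf_wm, wm_shift) if wm.any() else 0.0

    brain_shift = atrophy.boundary_shift
    if atrophy.gm_scale != 1.0:
        # additional sub-voxel shift of the (already displaced) outer surface
        # so that GM volume = gm_scale * GM volume at time point 1
        target_brain = atrophy.gm_scale * gm_pre + wm_post
        brain_shift = atrophy.boundary_shift + solve_shift(
            sdf_brain - atrophy.boundary_shift, target_brain
        )
    brain_post = vol_ml(sdf_brain, brain_shift)
    gm_post = brain_post - wm_post

    def render(b_shift, w_shift):
        a_head = _partial_volume(sdf_head, h)
        a_brain = _partial_volume(sdf_brain - b_shift, h)
        a_wm = _partial_volume(sdf_wm - w_shift, h) if wm.any() else 0.0
        return _CSF_I * a_head + (_GM_I - _CSF_I) * a_brain + (_WM_I - _GM_I) * a_wm

    vol1 = render(0.0, 0.0)
    vol2 = render(brain_shift, wm_shift)

    lesion_mask = np.zeros(labels.shape, dtype=bool)
    n_placed = 0
    if lesions.n_lesions > 0:
        rng = np.random.default_rng(lesions.seed)
        lo, hi = lesions.radius_range_mm
        candidates = np.argwhere(sdf_wm - wm_shift > hi + h)
        if len(candidates) == 0:
            raise ValueError("no white-matter interior to seed lesions into")
        centers: list[np.ndarray] = []
        radii: list[float] = []
        grid_mm = np.indices(labels.shape).astype(float) * np.asarray(voxel_size)[:, None, None, None]
        attempts = 0
        while n_placed < lesions.n_lesions and attempts < 1000:
            attempts += 1
            c = candidates[rng.integers(len(candidates))].astype(float) * np.asarray(voxel_size)
            radius = float(rng.uniform(lo, hi))
            if any(np.linalg.norm(c - p) < radius + pr + 2 * h for p, pr in zip(centers, radii)):
                continue
            d = np.sqrt(sum((grid_mm[i] - c[i]) ** 2 for i in range(3)))
            a_les = _partial_volume(radius - d, h)
            vol1 += (_LESION_I - vol1) * a_les
            vol2 += (_LESION_I - vol2) * a_les
            lesion_mask |= a_les > 0.5
            centers.append(c)
            radii.append(radius)
            n_placed += 1
        if n_placed < lesions.n_lesions:
            raise ValueError("could not place all lesions without overlap")

    if phantom.noise_sd > 0:
        rng = np.random.default_rng(phantom.seed)
        vol1 = vol1 + rng.normal(0.0, phantom.noise_sd, vol1.shape)
        vol2 = vol2 + rng.normal(0.0, phantom.noise_sd, vol2.shape)

    truth = {
        "gm_ml_pre": gm_pre,
        "gm_ml_post": gm_post,
        "wm_ml_pre": wm_pre,
        "wm_ml_post": wm_post,
        "brain_ml_pre": brain_pre,
        "brain_ml_post": brain_post,
        "brain_shift_mm": brain_shift,
        "wm_shift_mm": wm_shift,
        "n_lesions": n_placed,
        "lesion_mask": lesion_mask,
        "head_mask": head,
        "brain_mask_pre": _partial_volume(sdf_brain, h) > 0.5,
    }
    return vol1, vol2, truth
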