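"""Per-breath reduction of mouth-sampled gas traces and regressor building.

Raw PCO2/PO2/flow traces are reduced breath by breath: expiration is
defined as negative flow, end-tidal PCO2 as the expiratory maximum and
end-tidal PO2 as the expiratory minimum (the standard end-tidal
convention).  The per-breath series is resampled to the BOLD volume grid
and time-aligned to the global BOLD signal by cross-correlation to absorb
the gas-sampling and circulatory delay.  Arterial oxyhemoglobin saturation
is computed from end-tidal PO2 with the Severinghaus equation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "detect_breaths",
    "extract_end_tidal",
    "severinghaus_spo2",
    "resample_to_tr",
    "align_to_bold",
    "summarize_rest",
]


def detect_breaths(
    flow: pd.DataFrame,
    min_breath_duration: float = 1.0,
    hysteresis: float = 0.05,
) -> np.ndarray:
    """Breath onset times from a flow trace (positive flow = inspiration).

    Onsets are inspiratory zero-crossings with hysteresis: a new breath
    starts when flow rises above ``+hysteresis * max|flow|`` after having
    been below the negative threshold (i.e. after an expiration).  Onsets
    closer together than ``min_breath_duration`` are merged.

    Returns the onset times in seconds (at least one full breath required).
    """
    t = flow["time_s"].to_numpy(float)
    f = flow["flow_lps"].to_numpy(float)
    if len(f) == 0:
        raise ValueError("no breaths detected: empty flow trace")
    amp = np.max(np.abs(f))
    if amp == 0 or np.ptp(f) == 0:
        raise ValueError("no breaths detected: constant flow signal")
    th = hysteresis * amp

    state = np.zeros(len(f), dtype=np.int8)
    state[f > th] = 1
    state[f < -th] = -1
    nz = np.flatnonzero(state)
    if nz.size == 0:
        raise ValueError("no breaths detected: flow never exceeds hysteresis band")
    s = state[nz]
    # indices (into nz) where the decided state flips from -1 to +1
    flips = np.flatnonzero((s[1:] == 1) & (s[:-1] == -1)) + 1
    onset_idx = nz[flips]
    if f[nz[0]] > 0:  # trace starts mid-inspiration: first onset at start
        onset_idx = np.concatenate([[nz[0]], onset_idx])
    onsets = t[onset_idx]

    merged = [onsets[0]]
    for o in onsets[1:]:
        if o - merged[-1] >= min_breath_duration:
            merged.append(o)
    if len(merged) == 0:
        raise ValueError("no breaths detected")
    return np.asarray(merged)


def extract_end_tidal(
    gas: pd.DataFrame,
    flow: pd.DataFrame,
    onsets: np.ndarray,
) -> pd.DataFrame:
    """Reduce a gas trace to one row per breath.

    For each breath (interval between consecutive onsets, the last breath
    ending at the end of the trace): end-tidal PCO2 = max PCO2 during
    expiration (flow < 0), end-tidal PO2 = min PO2 during expiration, and
    inspired/expired tidal volumes as flow integrals.  Breaths with no
    expiratory samples are excluded (flagged in the ``excluded`` attr).

    Returns a DataFrame with columns ``onset_s, offset_s, petco2_mmHg,
    peto2_mmHg, vt_insp_l, vt_exp_l, fb_bpm``.
    """
    t = gas["time_s"].to_numpy(float)
    pco2 = gas["pco2_mmHg"].to_numpy(float)
    po2 = gas["po2_mmHg"].to_numpy(float)
    f = flow["flow_lps"].to_numpy(float)
    if len(t) != len(f):
        raise ValueError("gas and flow traces must share the sampling grid")
    onsets = np.asarray(onsets, float)
    if onsets.size == 0 or onsets[0] < t[0] or onsets[-1] > t[-1]:
        raise ValueError("breath boundaries outside the trace span")
    dt = float(np.median(np.diff(t)))

    edges = np.concatenate([onsets, [t[-1] + dt]])
    rows, excluded = [], []
    for k in range(len(onsets)):
        sel = (t >= edges[k]) & (t < edges[k + 1])
        if not sel.any():
            excluded.append(k)
            continue
        fx = f[sel]
        exp = fx < 0
        if not exp.any():
            excluded.append(k)
            continue
        insp = fx > 0
        rows.append(
            {
                "onset_s": edges[k],
                "offset_s": min(edges[k + 1], t[-1] + dt),
                "petco2_mmHg": float(pco2[sel][exp].max()),
                "peto2_mmHg": float(po2[sel][exp].min()),
                "vt_insp_l": float(fx[insp].sum() * dt) if insp.any() else 0.0,
                "vt_exp_l": float(-fx[exp].sum() * dt),
                "fb_bpm": 60.0 / (edges[k + 1] - edges[k]),
            }
        )
    breaths = pd.DataFrame(rows)
    breaths.attrs["excluded"] = excluded
    return breaths


def severinghaus_spo2(po2):
    """Arterial O2 saturation (fraction) from PO2 (mmHg), Severinghaus form.

    ``S = 1 / (23400 / (PO2^3 + 150 PO2) + 1)`` — strictly increasing,
    bounded in (0, 1), S(100) ~= 0.977 and S ~= 0.50 near a P50 of 26.9 mmHg.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 <= 0):
        raise ValueError("po2 must be > 0 mmHg")
    s = 1.0 / (23400.0 / (po2**3 + 150.0 * po2) + 1.0)
    return float(s) if s.ndim == 0 else s


def resample_to_tr(
    breaths: pd.DataFrame,
    tr: float,
    n_volumes: int,
    mode: str = "hold",
) -> pd.DataFrame:
    """Per-volume end-tidal series from the per-breath table.

    ``mode="hold"`` (default) assigns each volume the end-tidal plateau of
    the breath covering its acquisition time (end-tidal values are
    step-like between breaths, as on an online end-tidal display);
    ``mode="linear"`` interpolates through the breath midpoints.  Volume k
    is acquired at ``t = k * tr``.
    """
    if tr <= 0 or n_volumes <= 0:
        raise ValueError("tr and n_volumes must be > 0")
    if mode not in ("hold", "linear"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(breaths) == 0:
        raise ValueError("empty breath table")
    tvol = np.arange(n_volumes) * tr
    onsets = breaths["onset_s"].to_numpy(float)
    offsets = breaths["offset_s"].to_numpy(float)
    if tvol[-1] > offsets[-1] + 1e-9:
        raise ValueError("acquisition extends beyond the recorded breaths")

    out = {}
    for col in ("petco2_mmHg", "peto2_mmHg"):
        v = breaths[col].to_numpy(float)
        if mode == "hold":
            idx = np.searchsorted(onsets, tvol, side="right") - 1
            idx = np.clip(idx, 0, len(v) - 1)
            out[col] = v[idx]
        else:
            mid = 0.5 * (onsets + offsets)
            out[col] = np.interp(tvol, mid, v)
    series = pd.DataFrame(out)
    series.attrs["lag_s"] = 0.0
    series.attrs["tr"] = tr
    return series


def align_to_bold(
    series: pd.DataFrame,
    global_bold: np.ndarray,
    tr: float,
    max_lag_s: float = 20.0,
    trend_matrix: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Shift the end-tidal series to maximize correlation with global BOLD.

    Searches non-negative integer volume lags (the BOLD response trails the
    gas excursion) up to ``max_lag_s``; the petCO2 series shifted by each
    candidate lag is correlated with the per-volume global BOLD signal and
    the correlation-maximizing lag wins, ties going to the smallest lag.
    PetO2 is shifted by the same lag.  When the BOLD series has been
    temporally filtered, pass the filter's trend matrix so each shifted
    candidate is detrended the same way before correlation.  Returns the
    shifted series and the lag in seconds.
    """
    bold = np.asarray(global_bold, float)
    x = series["petco2_mmHg"].to_numpy(float)
    if len(bold) != len(x):
        raise ValueError("series and global BOLD must have equal length")
    if np.ptp(x) == 0 or np.ptp(bold) == 0:
        raise ValueError("correlation undefined for constant input")
    max_k = int(max_lag_s // tr)

    def shifted(v, k):
        return np.concatenate([np.full(k, v[0]), v[: len(v) - k]]) if k else v

    best_k, best_r = 0, -np.inf
    for k in range(max_k + 1):
        xs = shifted(x, k)
        if trend_matrix is not None:
            xs = xs - trend_matrix @ xs
        if np.ptp(xs) == 0:
            continue
        r = float(np.corrcoef(xs, bold)[0, 1])
        if r > best_r:
            best_k, best_r = k, r

    out = pd.DataFrame(
        {col: shifted(series[col].to_numpy(float), best_k) for col in series.columns}
    )
    out.attrs["lag_s"] = best_k * tr
    out.attrs["lag_volumes"] = best_k
    out.attrs["correlation"] = best_r
    out.attrs["tr"] = tr
    return out, best_k * tr


def summarize_rest(breaths: pd.DataFrame, window: tuple[float, float]) -> dict:
    """Resting ventilatory summary over a time window.

    Means over breaths whose onset falls in ``window``: breathing frequency
    (min^-1), expired tidal volume (L), minute ventilation VE = mean(VT*Fb)
    (L/min), end-tidal pressures (mmHg), and SpO2 (fraction) from the mean
    end-tidal PO2 via :func:`severinghaus_spo2`.
    """
    t0, t1 = window
    sel = breaths[(breaths["onset_s"] >= t0) & (breaths["onset_s"] < t1)]
    if len(sel) == 0:
        raise ValueError("no breaths in the requested window")
    fb = sel["fb_bpm"].to_numpy(float)
    vt = sel["vt_exp_l"].to_numpy(float)
    peto2 = float(sel["peto2_mmHg"].mean())
    return {
        "fb_bpm": float(fb.mean()),
        "vt_l": float(vt.mean()),
        "ve_lpm": float((vt * fb).mean()),
        "petco2_mmHg": float(sel["petco2_mmHg"].mean()),
        "peto2_mmHg": peto2,
        "spo2": severinghaus_spo2(peto2),
        "n_breaths": int(len(sel)),
    }
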