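"""Single-particle peak detection and transit-time estimation.

Candidate events are contiguous above-threshold runs of a trace. Each
candidate is fit with a single Gaussian; the fitted FWHM is the
particle's transit time (PT) across that beam, and the coefficient of
determination of the fit acts as a Gaussian-likeness gate: events whose
shape a single Gaussian cannot explain (coeluting particles, wall
interactions, clipped detectors) are rejected rather than mis-measured.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .trace import Trace, _FWHM_PER_SIGMA

logger = logging.getLogger(__name__)

REQUIRED_PEAK_COLUMNS = ("channel", "t_center_ms", "height", "pt_ms", "fit_quality")

_EMPTY_PEAKS = pd.DataFrame(
    {
        "channel": pd.Series(dtype=str),
        "t_center_ms": pd.Series(dtype=float),
        "height": pd.Series(dtype=float),
        "pt_ms": pd.Series(dtype=float),
        "fit_quality": pd.Series(dtype=float),
    }
)


def _gaussian(t, amplitude, center, sigma):
    return amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def estimate_baseline(values: np.ndarray) -> tuple[float, float]:
    """Baseline level and noise scale of a trace.

    Returns ``(median, 1.4826 * MAD)`` — robust to the sparse positive
    excursions that particle bursts add on top of the baseline.
    """
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, 1.4826 * mad


def detect_peaks(
    trace: Trace,
    threshold: float | None = None,
    min_fit_quality: float = 0.9,
    mad_k: float = 5.0,
    min_samples: int = 4,
    pad_samples: int = 3,
) -> pd.DataFrame:
    """Detect single-particle peaks and estimate their transit times.

    Parameters
    ----------
    trace : Trace
        The channel record to scan.
    threshold : float, optional
        Absolute detection threshold in intensity units. When omitted it
        is set to ``baseline + mad_k * (1.4826 * MAD)``.
    min_fit_quality : float
        Minimum coefficient of determination (R²) of the single-Gaussian
        fit; poorer candidates are rejected.
    mad_k : float
        Noise multiple used for the automatic threshold.
    min_samples : int
        Minimum run length (samples) for a candidate to be fit.
    pad_samples : int
        Samples of context added on each side of a run before fitting.

    Returns
    -------
    pandas.DataFrame
        Peak table sorted by center time with columns ``channel``,
        ``t_center_ms``, ``height``, ``pt_ms`` (fitted FWHM),
        ``fit_quality``.
    """
    values = trace.values
    if values.size == 0:
        return _EMPTY_PEAKS.copy()
    baseline, noise = estimate_baseline(values)
    if threshold is None:
        threshold = baseline + mad_k * noise
    mask = values > threshold
    if not mask.any():
        return _EMPTY_PEAKS.copy()
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1  # exclusive

    dt = trace.dt_ms
    rows = []
    for s, e in zip(run_starts, run_ends):
        if e - s < min_samples:
            continue
        lo = max(0, s - pad_samples)
        hi = min(values.size, e + pad_samples)
        window = values[lo:hi] - baseline
        t = trace.start_time + np.arange(lo, hi) * dt
        top = window.max()
        # Saturation guard: a flat-topped run (3+ consecutive samples at
        # the run maximum) indicates detector clipping.
        at_top = np.flatnonzero(np.isclose(window, top, rtol=0, atol=1e-12))
        consec = _longest_consecutive(at_top)
        if consec >= 3:
            logger.info(
                "rejected candidate at %.3f ms: clipped/saturated top (%d flat samples)",
                t[np.argmax(window)], consec,
            )
            continue
        p0 = _initial_guess(t, window)
        try:
            popt, _ = curve_fit(
                _gaussian,
                t,
                window,
                p0=p0,
                bounds=([0.0, t[0] - dt, dt / 10.0], [np.inf, t[-1] + dt, (t[-1] - t[0]) * 10 + dt]),
                maxfev=2000,
            )
        except RuntimeError:
            logger.info("rejected candidate at %.3f ms: Gaussian fit failed", t[np.argmax(window)])
            continue
        amplitude, center, sigma = popt
        resid = window - _gaussian(t, *popt)
        ss_tot = float(np.sum((window - window.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        fit_quality = min(max(r2, 0.0), 1.0)
        if fit_quality < min_fit_quality:
            logger.info(
                "rejected candidate at %.3f ms: fit quality %.3f < %.3f (not Gaussian-like)",
                center, fit_quality, min_fit_quality,
            )
            continue
        if amplitude <= 0 or sigma <= 0:
            continue
        rows.append(
            {
                "channel": trace.channel,
                "t_center_ms": float(center),
                "height": float(amplitude),
                "pt_ms": float(_FWHM_PER_SIGMA * sigma),
                "fit_quality": fit_quality,
            }
        )
    if not rows:
        return _EMPTY_PEAKS.copy()
    out = pd.DataFrame(rows)
    return out.sort_values("t_center_ms", kind="mergesort", ignore_index=True)


def _longest_consecutive(indices: np.ndarray) -> int:
    if indices.size == 0:
        return 0
    runs = np.split(indices, np.flatnonzero(np.diff(indices) > 1) + 1)
    return max(len(r) for r in runs)


def _initial_guess(t: np.ndarray, window: np.ndarray) -> tuple[float, float, float]:
    amp = float(window.max())
    center = float(t[np.argmax(window)])
    w = np.clip(window, 0, None)
    total = w.sum()
    if total > 0:
        mu = float(np.sum(t * w) / total)
        var = float(np.sum((t - mu) ** 2 * w) / total)
        sigma = max(np.sqrt(var), (t[1] - t[0]) / 2.0)
    else:
        sigma = (t[-1] - t[0]) / 4.0 or 1.0
    return amp, center, sigma


def write_peak_table(peaks: pd.DataFrame, path) -> None:
    """Write a peak table as CSV (times in ms, 6 decimals)."""
    missing = [c for c in REQUIRED_PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table missing required column(s): {', '.join(missing)}")
    peaks.to_csv(path, index=False, float_format="%.6f")


def read_peak_table(path) -> pd.DataFrame:
    """Read a peak-table CSV, enforcing the schema invariants.

    Unknown extra columns are preserved untouched. Rows violating
    ``pt_ms > 0`` or ``height > 0`` raise with the offending (1-based
    data) row number.
    """
    peaks = pd.read_csv(path)
    for col in REQUIRED_PEAK_COLUMNS:
        if col not in peaks.columns:
            raise ValueError(f"peak table is missing required column '{col}'")
    for col, label in (("pt_ms", "transit time"), ("height", "height")):
        bad = np.flatnonzero(~(peaks[col].to_numpy(dtype=float) > 0))
        if bad.size:
            raise ValueError(
                f"peak table row {bad[0] + 1}: {label} ({col}) must be positive"
            )
    return peaks.sort_values("t_center_ms", kind="mergesort", ignore_index=True)
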