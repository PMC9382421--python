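"""Calcium-imaging analysis: dF/F0 transients and amplitude-profile synchrony.

Fluorescence traces (default 15.3 Hz) are background-corrected with their
twin ROI, transients are detected as excursions above the running baseline by
``k`` noise SDs (default k = 2), and each transient is quantified as
dF/F0 with F0 the mean corrected intensity over the 1 s window preceding the
onset.  Per-ROI statistics are event frequency (per min) and mean amplitude;
ROIs with no transient are excluded from the analysis set.  Network synchrony
is the Pearson correlation of per-event amplitude profiles between all ROI
pairs of a field of view, with a neuron absent from an event contributing
amplitude 0.

Detection details (declared approximations; the threshold and F0 window are
the study's, the onset/offset logic is the package's): the running baseline
is a 20th-percentile filter over a 2 s window, corrected for the Gaussian
bias of that percentile (+0.8416 SD) so the detection threshold sits k SDs
above the quiescent *mean*; events must stay above threshold for a minimum
number of consecutive frames (default 5) and end with hysteresis at
0.5 k SD; events closer than 3 frames are merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter

from .core import FluorescenceTrace, Transient
from .spike_burst import MAD_TO_SD
from .stats import ConstantInputError, pearson_with_p
from .synchrony import CATEGORIES, ClassificationCounts, PairResult, _categorize

#: z-score of the 20th percentile of a Gaussian; used to de-bias the
#: percentile baseline back to the quiescent mean.
_P20_Z = 0.8416212335729143


class RoiRejectedError(ValueError):
    """Raised when an ROI cannot be analysed (e.g. non-positive corrected trace)."""


def subtract_background(trace: FluorescenceTrace) -> tuple[np.ndarray, float]:
    """Framewise twin-ROI background subtraction plus a robust noise SD.

    The noise SD is estimated from the first difference of the corrected
    trace (MAD scaled to SD, divided by sqrt(2)), which is insensitive to the
    slow transients riding on the trace.
    """
    corrected = trace.raw - trace.background
    if np.all(corrected <= 0):
        raise RoiRejectedError(
            f"ROI {trace.roi_id}: corrected trace is nowhere positive"
        )
    d = np.diff(corrected)
    sd = float(np.median(np.abs(d - np.median(d))) * MAD_TO_SD / np.sqrt(2.0))
    return corrected, sd


def detect_transients(
    corrected: np.ndarray,
    noise_sd: float,
    frame_rate: float = 15.3,
    k: float = 2.0,
    f0_window: float = 1.0,
    baseline_window: float = 2.0,
    min_frames: int = 5,
    merge_gap: int = 3,
) -> list[Transient]:
    """Detect dF/F0 transients above ``k`` noise SDs over the running baseline.

    Candidate events are runs of at least ``min_frames`` consecutive frames
    exceeding baseline + k*SD; each run is extended forward until the trace
    falls below baseline + 0.5*k*SD, and runs closer than ``merge_gap`` frames
    are merged.  F0 is the mean corrected intensity over the ``f0_window``
    seconds preceding the onset (the available prefix, flagged, for early
    events) and the amplitude is (F_peak - F0) / F0 with the peak estimated
    by an exponential-decay matched filter (robust to frame noise, exact for
    noiseless transients).
    """
    f = np.asarray(corrected, dtype=float)
    n = f.size
    w_f0 = int(round(f0_window * frame_rate))
    if n <= w_f0:
        raise ValueError("trace shorter than the F0 window")
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    w_base = max(3, int(round(baseline_window * frame_rate)) | 1)  # odd size
    baseline = percentile_filter(f, 20, size=w_base, mode="nearest")
    quiescent = baseline + _P20_Z * noise_sd
    thr_on = quiescent + k * noise_sd
    thr_off = quiescent + 0.5 * k * noise_sd
    if noise_sd == 0:
        eps = 1e-9 * max(1.0, np.max(np.abs(f)))
        thr_on = thr_off = baseline + eps

    above = f > thr_on
    events: list[list[int]] = []  # [onset, end] inclusive
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= min_frames:
            end = j - 1
            while end + 1 < n and f[end + 1] >= thr_off[end + 1]:
                end += 1
            if events and i - events[-1][1] - 1 < merge_gap:
                events[-1][1] = max(events[-1][1], end)
            else:
                events.append([i, end])
            i = end + 1
        else:
            i = j
    # First pass: per-event F0, peak, and a free-decay fit collecting tau
    # estimates; second pass re-estimates each amplitude with tau fixed at
    # the ROI median (the decay constant is a property of the indicator and
    # ROI, so pooling it across events sharpens every amplitude).
    prelim = []
    taus = []
    for idx, (onset, end) in enumerate(events):
        lo = max(0, onset - w_f0)
        truncated = onset < w_f0
        if onset == 0:
            continue  # no pre-onset data at all: cannot define F0
        f0 = float(np.mean(f[lo:onset]))
        if f0 <= 0:
            continue
        peak = onset + int(np.argmax(f[onset : end + 1]))
        next_onset = events[idx + 1][0] if idx + 1 < len(events) else None
        prev_end = events[idx - 1][1] if idx > 0 else None
        tau = _fit_decay_tau(f, onset, f0, next_onset)
        if tau is not None:
            taus.append(tau)
        prelim.append((onset, end, peak, f0, next_onset, prev_end, truncated))
    tau_roi = float(np.median(taus)) if taus else None
    transients: list[Transient] = []
    for onset, end, peak, f0, next_onset, prev_end, truncated in prelim:
        peak_val = _amplitude_fixed_tau(f, onset, peak, f0, next_onset,
                                        prev_end, tau_roi)
        amp = (peak_val - f0) / f0
        if amp <= 0:
            continue
        transients.append(
            Transient(onset_frame=int(onset), peak_frame=int(peak),
                      end_frame=int(end), amplitude=float(amp), f0=f0,
                      f0_truncated=truncated)
        )
    return transients


def _decay_window(f: np.ndarray, onset: int, f0: float,
                  next_onset: int | None, max_window: int = 48
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Post-onset frames used for decay fitting, capped at the next event."""
    hi = min(onset + max_window, f.size)
    if next_onset is not None:
        hi = min(hi, next_onset - 1)
    i = np.arange(onset, hi, dtype=float)
    return i, f[onset:hi] - f0


def _fit_decay_tau(f: np.ndarray, onset: int, f0: float,
                   next_onset: int | None) -> float | None:
    """Decay time constant (frames) of one event from a free (A, tau) fit.

    The transient is modelled as ``A * exp(-(i - t_e) / tau)`` with the event
    time fixed half a frame before the first supra-threshold sample (the
    indicator rise is fast relative to one frame).
    """
    from scipy.optimize import least_squares

    i, y = _decay_window(f, onset, f0, next_onset)
    if i.size < 4 or y[0] <= 0:
        return None
    t_e = float(onset) - 0.5

    def residuals(params):
        a, tau = params
        return a * np.exp(-(i - t_e) / tau) - y

    x0 = np.clip([float(y[0]), 15.0], [1e-12, 1.0], [np.inf, 1e4])
    try:
        res = least_squares(residuals, x0, bounds=([1e-12, 1.0], [np.inf, 1e4]),
                            xtol=1e-12, ftol=1e-12)
    except Exception:
        return None
    a, tau = res.x
    if not (np.isfinite(a) and a > 0 and np.isfinite(tau)):
        return None
    return float(tau)


def _amplitude_fixed_tau(f: np.ndarray, onset: int, peak: int, f0: float,
                         next_onset: int | None, prev_end: int | None,
                         tau: float | None, pre_window: int = 30,
                         post_window: int = 60) -> float:
    """Peak height from a joint baseline + decay-kernel least-squares fit.

    With tau pooled across the ROI's events, the frames around the event are
    regressed on [1, kernel] where the kernel is the exponential decay of
    known tau starting half a frame before onset.  Estimating the local
    baseline jointly (rather than subtracting the noisy F0 first) keeps the
    F0 measurement error out of the amplitude coefficient; the half-frame
    event-time offset undoes the sampling-delay bias of the raw peak sample.
    Falls back to the raw peak sample when the decay segment is unusable.
    """
    lo = max(0, onset - pre_window)
    if prev_end is not None:
        lo = max(lo, prev_end + 3)
    hi = min(onset + post_window, f.size)
    if next_onset is not None:
        hi = min(hi, next_onset - 1)
    if tau is None or hi - onset < 4 or lo >= onset or f[peak] <= f0:
        return float(f[peak])
    i = np.arange(lo, hi, dtype=float)
    kernel = np.where(i >= onset, np.exp(-(i - (onset - 0.5)) / tau), 0.0)
    design = np.column_stack([np.ones(i.size), kernel])
    coef, *_ = np.linalg.lstsq(design, f[lo:hi], rcond=None)
    a = float(coef[1])
    if not np.isfinite(a) or a <= 0:
        return float(f[peak])
    return float(f0 + a)


def analyze_trace(
    trace: FluorescenceTrace,
    k: float = 2.0,
    f0_window: float = 1.0,
    **kwargs,
) -> list[Transient]:
    """Background-correct one ROI and detect its transients."""
    corrected, sd = subtract_background(trace)
    return detect_transients(corrected, sd, frame_rate=trace.frame_rate,
                             k=k, f0_window=f0_window, **kwargs)


def transient_stats(
    transients: Mapping[str, Sequence[Transient]],
    duration: float,
) -> pd.DataFrame:
    """Frequency (events/min) and mean amplitude per ROI.

    ROIs with zero transients are reported with ``included=False`` and
    excluded from downstream analysis, mirroring the inclusion rule that a
    neuron must exhibit at least one spontaneous transient.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rows = []
    for roi, evs in transients.items():
        n = len(evs)
        rows.append({
            "roi_id": roi,
            "n_transients": n,
            "frequency_per_min": n / duration * 60.0,
            "mean_amplitude": float(np.mean([e.amplitude for e in evs])) if n else np.nan,
            "included": n > 0,
        })
    return pd.DataFrame(rows)


def amplitude_profiles(
    transients: Mapping[str, Sequence[Transient]],
    match_window: int = 2,
) -> pd.DataFrame:
    """Align per-ROI transients into network events (frames within +-2 by default).

    Returns an events x ROIs matrix of peak amplitudes, 0 where a neuron did
    not participate in an event.  Only ROIs with at least one transient enter
    the matrix.
    """
    peaks = [
        (ev.peak_frame, roi, ev.amplitude)
        for roi, evs in transients.items()
        for ev in evs
    ]
    rois = sorted(roi for roi, evs in transients.items() if evs)
    if not peaks:
        return pd.DataFrame(columns=rois)
    peaks.sort()
    events: list[dict[str, float]] = []
    anchor = None
    for frame, roi, amp in peaks:
        if anchor is None or frame - anchor > match_window:
            events.append({})
            anchor = frame
        current = events[-1]
        current[roi] = max(current.get(roi, 0.0), amp)
    mat = pd.DataFrame(events, columns=rois).fillna(0.0)
    mat.index.name = "event"
    return mat


def amplitude_correlation(
    profiles: pd.DataFrame,
    alpha: float = 0.05,
    condition: str = "",
) -> tuple[list[PairResult], ClassificationCounts]:
    """Pearson correlation of amplitude profiles for all ROI pairs.

    Classification enables the negative category (unlike MEA burst synchrony,
    anticorrelated amplitude profiles are a meaningful outcome here).
    """
    rois = list(profiles.columns)
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    if len(profiles) < 3:
        raise ValueError("need at least 3 network events")
    results: list[PairResult] = []
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            a, b = rois[i], rois[j]
            try:
                r, p = pearson_with_p(profiles[a].to_numpy(), profiles[b].to_numpy())
            except ConstantInputError:
                results.append(PairResult((a, b), np.nan, np.nan, "excluded",
                                          "zero-variance amplitude profile"))
                continue
            results.append(PairResult((a, b), r, p, _categorize(r, p, alpha)))
    counts = ClassificationCounts(condition)
    for res in results:
        counts.counts[res.category] += 1
    return results, counts
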