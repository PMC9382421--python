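"""Spike detection, burst detection and per-well network metrics.

Spikes are detected as negative-going threshold crossings at ``k`` times the
baseline noise SD (default k = 5), with a short dead time so one biphasic
waveform yields one spike.  Bursts are the maximal runs of >= ``n_min``
consecutive spikes whose internal inter-spike intervals are all <= ``isi_max``
(defaults 5 spikes / 100 ms).  From spikes and bursts the five network metrics
are computed per electrode and averaged per well: mean firing rate, burst
rate, mean burst duration, percentage of spikes in burst, and intraburst
spike frequency.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Burst, SpikeTrain, VoltageTrace, WellRecording

#: Conversion factor between median absolute deviation and Gaussian SD.
MAD_TO_SD = 1.0 / 0.674489750196082


def estimate_noise_sd(trace: VoltageTrace) -> float:
    """Robust baseline noise SD of a voltage trace.

    Uses the median absolute deviation scaled to Gaussian SD, which is
    insensitive to the (rare, large) spike deflections riding on the noise.
    A constant trace returns 0.0 with a warning.
    """
    v = trace.samples
    if v.size < trace.sampling_rate:
        raise ValueError("need at least 1 s of samples to estimate noise")
    mad = np.median(np.abs(v - np.median(v)))
    if mad == 0.0:
        warnings.warn("constant trace: noise SD is 0", stacklevel=2)
        return 0.0
    return float(mad * MAD_TO_SD)


def detect_spikes(
    trace: VoltageTrace,
    k: float = 5.0,
    dead_time: float = 0.001,
    noise_sd: float | None = None,
) -> SpikeTrain:
    """Detect negative-going threshold crossings at ``k`` times the noise SD.

    Each crossing contributes one spike timed at the local voltage minimum;
    subsequent crossings within ``dead_time`` seconds are ignored so that a
    biphasic waveform is not double counted.
    """
    fs = trace.sampling_rate
    dead_samples = int(round(dead_time * fs))
    if dead_samples < 1:
        raise ValueError("sampling rate too low to honor the dead time")
    if noise_sd is None:
        noise_sd = estimate_noise_sd(trace)
    if noise_sd <= 0:
        raise ValueError("noise SD must be positive for spike detection")
    threshold = -k * noise_sd
    v = trace.samples
    below = v <= threshold
    # indices where the trace crosses from above to at-or-below threshold
    crossings = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    times = []
    last = -np.inf
    for idx in crossings:
        if idx - last < dead_samples:
            continue
        stop = min(idx + dead_samples + 1, v.size)
        peak = idx + int(np.argmin(v[idx:stop]))
        times.append(peak / fs)
        last = peak
    t = np.asarray(times, dtype=float)
    # dead time is enforced on crossing indices; peak alignment keeps order
    t = np.unique(t)
    return SpikeTrain(trace.electrode_id, t, trace.duration)


def detect_bursts(
    times: np.ndarray | SpikeTrain,
    n_min: int = 5,
    isi_max: float = 0.100,
) -> list[Burst]:
    """Maximal runs of >= ``n_min`` spikes with all internal ISIs <= ``isi_max``.

    Burst duration is last minus first spike time of the run.  The result is
    exactly the set of maximal valid runs: extending any reported burst by one
    spike on either side breaks the ISI condition or the train boundary.
    """
    if isinstance(times, SpikeTrain):
        times = times.times
    t = np.asarray(times, dtype=float)
    if n_min < 2:
        raise ValueError("n_min must be at least 2")
    if isi_max <= 0:
        raise ValueError("isi_max must be positive")
    if t.size < n_min:
        return []
    ok = np.diff(t) <= isi_max  # ok[i]: spikes i, i+1 are within isi_max
    bursts: list[Burst] = []
    i = 0
    n_isi = ok.size
    while i < n_isi:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n_isi and ok[j]:
            j += 1
        run_len = j - i + 1  # spikes i..j inclusive
        if run_len >= n_min:
            bursts.append(Burst(start=float(t[i]), end=float(t[j]),
                                first_index=int(i), n_spikes=int(run_len)))
        i = j + 1
    return bursts


_METRIC_COLUMNS = [
    "firing_rate_hz",
    "burst_rate_per_min",
    "mean_burst_duration_s",
    "pct_spikes_in_burst",
    "intraburst_freq_hz",
]


def electrode_metrics(train: SpikeTrain, bursts: Sequence[Burst]) -> dict:
    """The five network metrics for one electrode.

    Rates are zero for silent electrodes; means that are undefined without
    spikes or bursts are reported as NaN rather than zero.
    """
    n = train.n_spikes
    dur = train.duration
    n_bursts = len(bursts)
    in_burst = sum(b.n_spikes for b in bursts)
    out = {
        "n_spikes": n,
        "n_bursts": n_bursts,
        "firing_rate_hz": n / dur,
        "burst_rate_per_min": n_bursts / dur * 60.0,
        "mean_burst_duration_s": np.nan,
        "pct_spikes_in_burst": np.nan,
        "intraburst_freq_hz": np.nan,
    }
    if n > 0:
        out["pct_spikes_in_burst"] = 100.0 * in_burst / n
    if n_bursts > 0:
        out["mean_burst_duration_s"] = float(np.mean([b.duration for b in bursts]))
        # per burst (n_spikes - 1) / duration, averaged over bursts
        out["intraburst_freq_hz"] = float(
            np.mean([(b.n_spikes - 1) / b.duration for b in bursts if b.duration > 0])
        )
    return out


def compute_metrics(
    recording: WellRecording,
    bursts: Mapping[str, Sequence[Burst]],
) -> pd.DataFrame:
    """Per-electrode metrics plus a ``WELL_MEAN`` aggregate row.

    The well value is the unweighted mean over all electrodes for the two
    rates and the percentage (silent electrodes enter with zero rates), and
    the mean over electrodes with at least one burst for burst duration and
    intraburst frequency.
    """
    rows = []
    for eid in recording.electrode_ids:
        train = recording.train(eid)
        m = electrode_metrics(train, bursts.get(eid, []))
        m["well_id"] = recording.well_id
        m["electrode_id"] = eid
        rows.append(m)
    df = pd.DataFrame(rows)
    well = {
        "well_id": recording.well_id,
        "electrode_id": "WELL_MEAN",
        "n_spikes": df["n_spikes"].sum(),
        "n_bursts": df["n_bursts"].sum(),
        "firing_rate_hz": df["firing_rate_hz"].mean(),
        "burst_rate_per_min": df["burst_rate_per_min"].mean(),
        # undefined (NaN) electrode means are excluded from the well mean
        "mean_burst_duration_s": df["mean_burst_duration_s"].mean(),
        "pct_spikes_in_burst": df["pct_spikes_in_burst"].mean(),
        "intraburst_freq_hz": df["intraburst_freq_hz"].mean(),
    }
    df = pd.concat([df, pd.DataFrame([well])], ignore_index=True)
    cols = ["well_id", "electrode_id", "n_spikes", "n_bursts"] + _METRIC_COLUMNS
    return df[cols]


def analyze_well(
    recording: WellRecording,
    n_min: int = 5,
    isi_max: float = 0.100,
) -> tuple[dict[str, list[Burst]], pd.DataFrame]:
    """Convenience wrapper: detect bursts on every electrode and compute metrics."""
    bursts = {
        eid: detect_bursts(recording.spike_trains[eid], n_min=n_min, isi_max=isi_max)
        for eid in recording.electrode_ids
    }
    return bursts, compute_metrics(recording, bursts)
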