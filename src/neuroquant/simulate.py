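"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the structure of the recordings the pipeline was
designed for, with planted ground truth so every detection stage has an
oracle:

* MEA wells: network-burst-driven spiking on 9 electrodes for 5 min, with a
  genotype-dependent rate scale (Het/KO at 0.5x WT), per-electrode burst
  participation, onset jitter controlling synchrony, and tonic background
  spikes.
* Raw voltage: Gaussian noise plus a biphasic extracellular spike template at
  each planted spike time.
* Calcium fluorescence at 15.3 Hz: exponential-decay transients whose
  amplitudes share a lognormal per-event scale (the synchrony dial) on top of
  private lognormal variability, plus a twin background trace.
* qPCR Ct tables: triplicates with per-gene amplification efficiencies and
  planted fold changes.

Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_ELECTRODES, FluorescenceTrace, SpikeTrain, VoltageTrace, WellRecording

GENOTYPE_FACTORS = {"WT": 1.0, "Het": 0.5, "KO": 0.5}


@dataclass
class NetworkSimParams:
    """Generative model of one MEA well (defaults: the emulated study conditions)."""

    n_electrodes: int = 9
    duration: float = 300.0  # s (5 min recordings)
    lambda_net: float = 12.0  # network-burst events per minute (WT)
    p_part: float = 0.9  # per-electrode participation probability
    mu_spikes: float = 12.0  # mean spikes per electrode-burst (>= n_min)
    burst_isi_scale: float = 0.020  # s, exponential ISI scale inside bursts
    jitter_sd: float = 0.010  # s, burst-onset jitter across electrodes
    lambda_tonic: float = 0.5  # background spikes per second per electrode (WT)
    genotype: str = "WT"
    genotype_factor: float | None = None  # default: WT 1.0, Het/KO 0.5
    n_min: int = 5  # planted minimum spikes per burst
    isi_max: float = 0.100  # s, detectability bound for burst_isi_scale
    independent_electrodes: bool = False  # per-electrode event processes

    def __post_init__(self) -> None:
        if self.genotype_factor is None:
            if self.genotype not in GENOTYPE_FACTORS:
                raise ValueError(f"unknown genotype {self.genotype!r}")
            self.genotype_factor = GENOTYPE_FACTORS[self.genotype]
        if min(self.lambda_net, self.lambda_tonic, self.genotype_factor) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.p_part <= 1:
            raise ValueError("p_part must lie in [0, 1]")
        if self.mu_spikes < self.n_min:
            raise ValueError("mu_spikes must be at least n_min")
        if self.burst_isi_scale >= self.isi_max:
            raise ValueError(
                "burst_isi_scale must be below isi_max so planted bursts are "
                "detectable by construction"
            )
        if self.duration <= 0 or self.n_electrodes < 1:
            raise ValueError("duration and n_electrodes must be positive")


def simulate_well(
    params: NetworkSimParams,
    seed: int,
    well_id: str = "W1",
) -> tuple[WellRecording, dict]:
    """One synthetic MEA well plus planted truth.

    Truth carries ``event_times`` (network-burst event times) and
    ``bursts[electrode] = list of (onset, offset, n_spikes)`` planted burst
    intervals.
    """
    rng = np.random.default_rng(seed)
    factor = params.genotype_factor
    electrodes = (
        tuple(DEFAULT_ELECTRODES[: params.n_electrodes])
        if params.n_electrodes <= 9
        else tuple(f"E{i}" for i in range(1, params.n_electrodes + 1))
    )
    rate = factor * params.lambda_net / 60.0  # events per second

    def draw_events() -> np.ndarray:
        n = rng.poisson(rate * params.duration)
        return np.sort(rng.uniform(0.0, params.duration, size=n))

    shared_events = None if params.independent_electrodes else draw_events()
    trains: dict[str, np.ndarray] = {}
    truth_bursts: dict[str, list[tuple[float, float, int]]] = {}
    truth_events: dict[str, np.ndarray] = {}
    for eid in electrodes:
        events = draw_events() if params.independent_electrodes else shared_events
        truth_events[eid] = events
        spikes = []
        planted = []
        for t_event in events:
            if rng.random() > params.p_part:
                continue
            n_sp = params.n_min + rng.poisson(params.mu_spikes - params.n_min)
            onset = t_event + rng.normal(0.0, params.jitter_sd)
            isis = rng.exponential(params.burst_isi_scale, size=n_sp - 1)
            ts = onset + np.concatenate(([0.0], np.cumsum(isis)))
            ts = ts[(ts >= 0.0) & (ts <= params.duration)]
            if ts.size:
                spikes.append(ts)
                planted.append((float(ts[0]), float(ts[-1]), int(ts.size)))
        n_tonic = rng.poisson(factor * params.lambda_tonic * params.duration)
        if n_tonic:
            spikes.append(rng.uniform(0.0, params.duration, size=n_tonic))
        all_spikes = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        trains[eid] = np.unique(all_spikes)  # strictly increasing
        truth_bursts[eid] = planted
    rec = WellRecording(
        well_id=well_id,
        spike_trains=trains,
        duration=params.duration,
        electrode_ids=electrodes,
        metadata={"genotype": params.genotype},
    )
    truth = {
        "event_times": shared_events if shared_events is not None else truth_events,
        "bursts": truth_bursts,
    }
    return rec, truth


# ---------------------------------------------------------------------------
# raw voltage

#: Biphasic extracellular spike template parameters (seconds).
_NEG_WIDTH = 0.0001
_POS_WIDTH = 0.00015
_POS_DELAY = 0.0004
_POS_FRACTION = 0.4


def spike_template(fs: float, snr: float) -> tuple[np.ndarray, int]:
    """Biphasic waveform (~1 ms) with negative peak ``-snr`` at index ``peak``."""
    t = np.arange(-0.0003, 0.0009, 1.0 / fs)
    wave = -snr * np.exp(-0.5 * (t / _NEG_WIDTH) ** 2)
    wave += _POS_FRACTION * snr * np.exp(-0.5 * ((t - _POS_DELAY) / _POS_WIDTH) ** 2)
    return wave, int(np.argmin(wave))


def simulate_voltage(
    train: SpikeTrain,
    fs: float = 10_000.0,
    snr: float = 8.0,
    seed: int = 0,
) -> VoltageTrace:
    """Unit-variance Gaussian noise plus a biphasic template at each spike time."""
    if fs < 5_000:
        raise ValueError("sampling rate must be at least 5 kHz")
    rng = np.random.default_rng(seed)
    n = int(round(train.duration * fs))
    v = rng.normal(0.0, 1.0, size=n)
    wave, peak = spike_template(fs, snr)
    if train.times.size > 1 and np.any(np.diff(train.times) < wave.size / fs):
        warnings.warn("planted spikes overlap within the template width",
                      stacklevel=2)
    for t in train.times:
        center = int(round(t * fs))
        lo = center - peak
        hi = lo + wave.size
        wlo, whi = max(0, -lo), wave.size - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        v[lo:hi] += wave[wlo:whi]
    return VoltageTrace(v, fs, train.electrode_id)


# ---------------------------------------------------------------------------
# calcium fluorescence


@dataclass
class CaSimParams:
    """Generative model of one field of view of somatic calcium traces."""

    n_rois: int = 10
    frame_rate: float = 15.3  # Hz
    duration: float = 300.0  # s (5 min recordings)
    event_rate: float = 3.0  # network events per minute
    min_event_gap: float = 4.0  # s, refractory between network events
    decay_tau: float = 1.0  # s, indicator decay
    amplitude: float = 0.5  # median event dF/F0
    shared_scale_sd: float = 0.4  # lognormal sigma of the shared event scale
    private_sd: float = 0.2  # lognormal sigma of per-ROI amplitude noise
    participation_prob: float = 0.8
    noise_sd: float = 0.01  # per-channel Gaussian noise, fraction of F0
    f0: float = 100.0  # cell baseline fluorescence (camera units)
    bg_level: float = 50.0  # shared background level (camera units)

    def __post_init__(self) -> None:
        if min(self.shared_scale_sd, self.private_sd, self.noise_sd) < 0:
            raise ValueError("variance components must be non-negative")
        if not 0 <= self.participation_prob <= 1:
            raise ValueError("participation_prob must lie in [0, 1]")
        if min(self.n_rois, self.frame_rate, self.duration, self.event_rate,
               self.decay_tau, self.amplitude, self.f0) <= 0:
            raise ValueError("sizes, rates and scales must be positive")


def _poisson_events_with_gap(rng, rate_per_s: float, duration: float,
                             gap: float, t_min: float, t_max: float) -> np.ndarray:
    """Poisson event times on [t_min, t_max], thinned to a minimum gap.

    The refractory gap keeps planted events individually resolvable so that
    detection-count oracles compare like with like.
    """
    n = rng.poisson(rate_per_s * duration)
    times = np.sort(rng.uniform(t_min, t_max, size=n))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= gap:
            kept.append(float(t))
    return np.asarray(kept)


def simulate_fluorescence(
    params: CaSimParams,
    seed: int,
) -> tuple[list[FluorescenceTrace], dict]:
    """Synthetic fluorescence traces plus planted truth.

    Truth carries ``event_times``, per-event shared scales, and
    ``transients[roi] = list of (event_index, time, amplitude)`` with
    amplitude in dF/F0 units.
    """
    rng = np.random.default_rng(seed)
    if params.event_rate * params.duration / 60.0 < 1:
        warnings.warn("expected fewer than one event in the recording",
                      stacklevel=2)
    fs = params.frame_rate
    n_frames = int(round(params.duration * fs))
    t = np.arange(n_frames) / fs
    t_min = 3.0  # leave room for the F0 window before the first event
    t_max = max(t_min + 1.0, params.duration - 3.0 * params.decay_tau)
    events = _poisson_events_with_gap(
        rng, params.event_rate / 60.0, params.duration, params.min_event_gap,
        t_min, t_max)
    scales = np.exp(rng.normal(0.0, params.shared_scale_sd, size=events.size))
    traces: list[FluorescenceTrace] = []
    truth_tr: dict[str, list[tuple[int, float, float]]] = {}
    for i in range(params.n_rois):
        roi = f"ROI{i + 1:02d}"
        signal = np.zeros(n_frames)
        planted = []
        for e_idx, (t_e, s) in enumerate(zip(events, scales)):
            if rng.random() > params.participation_prob:
                continue
            a = params.amplitude * s * np.exp(rng.normal(0.0, params.private_sd))
            mask = t >= t_e
            signal[mask] += a * np.exp(-(t[mask] - t_e) / params.decay_tau)
            planted.append((e_idx, float(t_e), float(a)))
        raw = (params.bg_level + params.f0 * (1.0 + signal)
               + params.f0 * params.noise_sd * rng.normal(size=n_frames))
        background = (params.bg_level
                      + params.f0 * params.noise_sd * rng.normal(size=n_frames))
        traces.append(FluorescenceTrace(roi, raw, background, fs))
        truth_tr[roi] = planted
    truth = {"event_times": events, "shared_scales": scales,
             "transients": truth_tr}
    return traces, truth


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class QpcrSimParams:
    """Generative model of a triplicate Ct table with planted fold changes."""

    groups: dict[str, int] = field(
        default_factory=lambda: {"WT_Ctrl": 6, "Het": 6})
    calibrator_group: str = "WT_Ctrl"
    target_folds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"Itgb3": {"WT_Ctrl": 1.0, "Het": 0.5}})
    ref_genes: dict[str, float] = field(
        default_factory=lambda: {"GAPDH": 0.05, "ACTB": 0.05, "HPRT1": 0.05})
    efficiencies: dict[str, float] = field(default_factory=dict)
    ct0: float = 22.0  # cycles at calibrator expression
    replicate_sd: float = 0.1  # cycles, technical noise
    sample_sd_log2: float = 0.15  # biological noise on expression
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for gene in list(self.target_folds) + list(self.ref_genes):
            self.efficiencies.setdefault(gene, 2.0)
        for g, e in self.efficiencies.items():
            if not 1.0 < e <= 2.2:
                raise ValueError(f"efficiency for {g!r} out of range (1, 2.2]")
        if self.replicate_sd < 0 or self.sample_sd_log2 < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.calibrator_group not in self.groups:
            raise ValueError("calibrator group missing from groups")


def simulate_ct_table(
    params: QpcrSimParams,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Triplicate Ct table: Ct = ct0 - log_E(expression) + technical noise."""
    rng = np.random.default_rng(seed)
    rows = []
    truth_expr: dict[tuple[str, str], float] = {}
    for group, n_samples in params.groups.items():
        for s in range(n_samples):
            sid = f"{group}_{s + 1}"
            for gene, folds in params.target_folds.items():
                expr = folds[group] * 2.0 ** rng.normal(0.0, params.sample_sd_log2)
                truth_expr[(sid, gene)] = expr
                _append_ct(rows, rng, params, sid, group, gene, expr)
            for gene, stability_sd in params.ref_genes.items():
                expr = 2.0 ** rng.normal(0.0, stability_sd)
                truth_expr[(sid, gene)] = expr
                _append_ct(rows, rng, params, sid, group, gene, expr)
    table = pd.DataFrame(rows)
    truth = {"folds": params.target_folds, "expression": truth_expr}
    return table, truth


def _append_ct(rows, rng, params: QpcrSimParams, sid, group, gene, expr) -> None:
    e = params.efficiencies[gene]
    base_ct = params.ct0 - np.log(expr) / np.log(e)
    for rep in range(params.n_replicates):
        rows.append({
            "sample_id": sid, "group": group, "gene": gene, "replicate": rep,
            "ct": base_ct + rng.normal(0.0, params.replicate_sd),
        })
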