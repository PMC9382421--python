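"""Pairwise burst-synchrony analysis within MEA wells.

Burst activity of each electrode is binarized on a fixed time grid (default
100 ms bins, matching the burst ISI criterion); network synchrony is the
Pearson correlation of these burst-state series for every electrode pair.
Pairs are classified at a per-pair significance level (default 0.05) into
positively correlated, negatively correlated and non-correlated, and the
classification distributions of two conditions are compared by chi-square.
Electrodes with fewer than 5 bursts per recording are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Burst, WellRecording
from .stats import ConstantInputError, chi2_independence, pearson_with_p

CATEGORIES = ("positive", "negative", "non_correlated", "excluded")

#: Selectable signals to correlate: binary burst state, burst counts per bin,
#: or spike counts per bin.
SIGNALS = ("binary", "burst_count", "spike_count")


@dataclass
class BurstStateMatrix:
    electrode_ids: tuple[str, ...]
    bin_width: float
    states: np.ndarray  # electrodes x bins

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.electrode_ids):
            raise ValueError("states must be an electrodes x bins matrix")

    @property
    def n_bins(self) -> int:
        return int(self.states.shape[1])


@dataclass(frozen=True)
class PairResult:
    pair: tuple[str, str]
    r: float
    p: float
    category: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class ClassificationCounts:
    condition: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in CATEGORIES:
            self.counts.setdefault(c, 0)

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    def fractions(self, include_excluded: bool = False) -> dict[str, float]:
        cats = CATEGORIES if include_excluded else CATEGORIES[:3]
        total = sum(self.counts[c] for c in cats)
        return {c: self.counts[c] / total for c in cats} if total else {}


def burst_state_series(
    recording: WellRecording,
    bursts: Mapping[str, Sequence[Burst]],
    bin_width: float = 0.100,
    signal: str = "binary",
) -> BurstStateMatrix:
    """Bin burst activity on a half-open time grid ``[b*dt, (b+1)*dt)``.

    In binary mode a bin is 1 for an electrode iff any of its (closed) burst
    intervals intersects the bin; ``burst_count`` counts intersecting bursts
    and ``spike_count`` counts spikes per bin.
    """
    if signal not in SIGNALS:
        raise ValueError(f"signal must be one of {SIGNALS}")
    if bin_width >= recording.duration:
        raise ValueError("bin_width must be smaller than the recording duration")
    n_bins = math.ceil(recording.duration / bin_width)
    states = np.zeros((len(recording.electrode_ids), n_bins))
    for i, eid in enumerate(recording.electrode_ids):
        if signal == "spike_count":
            t = recording.spike_trains[eid]
            idx = np.minimum((t / bin_width).astype(int), n_bins - 1)
            np.add.at(states[i], idx, 1)
            continue
        for b in bursts.get(eid, []):
            lo = int(b.start / bin_width)
            hi = int(b.end / bin_width)  # closed end touches bin floor(end/dt)
            hi = min(hi, n_bins - 1)
            if signal == "binary":
                states[i, lo : hi + 1] = 1
            else:
                states[i, lo : hi + 1] += 1
    return BurstStateMatrix(tuple(recording.electrode_ids), bin_width, states)


def _circular_shift_p(a: np.ndarray, b: np.ndarray, r_obs: float,
                      n_shifts: int, rng: np.random.Generator) -> float:
    """Permutation p-value from circular shifts of one series (two-sided)."""
    n = a.size
    hits = 1
    for _ in range(n_shifts):
        shift = int(rng.integers(1, n))
        r = np.corrcoef(a, np.roll(b, shift))[0, 1]
        if not np.isfinite(r) or abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    return hits / (n_shifts + 1)


def pairwise_burst_correlation(
    states: BurstStateMatrix,
    bursts: Mapping[str, Sequence[Burst]],
    min_bursts: int = 5,
    pvalue: str = "t",
    n_shifts: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[PairResult]:
    """Pearson r and p for every unordered electrode pair.

    Electrodes with fewer than ``min_bursts`` bursts are excluded from the
    analysis; their pairs are reported with category ``excluded``.  ``pvalue``
    selects the t-transform test (default) or a circular-shift permutation
    test ("perm").
    """
    if pvalue not in ("t", "perm"):
        raise ValueError("pvalue must be 't' or 'perm'")
    if pvalue == "perm" and rng is None:
        rng = np.random.default_rng(0)
    eids = states.electrode_ids
    active = {eid for eid in eids if len(bursts.get(eid, [])) >= min_bursts}
    if len(active) < 2:
        raise ValueError("need at least 2 electrodes meeting the burst minimum")
    results: list[PairResult] = []
    for i in range(len(eids)):
        for j in range(i + 1, len(eids)):
            a, b = eids[i], eids[j]
            if a not in active or b not in active:
                few = [e for e in (a, b) if e not in active]
                results.append(PairResult((a, b), np.nan, np.nan, "excluded",
                                          f"fewer than {min_bursts} bursts: {','.join(few)}"))
                continue
            try:
                r, p = pearson_with_p(states.states[i], states.states[j])
            except ConstantInputError:
                results.append(PairResult((a, b), np.nan, np.nan, "excluded",
                                          "zero-variance state series"))
                continue
            if pvalue == "perm":
                p = _circular_shift_p(states.states[i], states.states[j], r,
                                      n_shifts, rng)
            results.append(PairResult((a, b), r, p, _categorize(r, p)))
    return results


def _categorize(r: float, p: float, alpha: float = 0.05) -> str:
    if p < alpha:
        return "positive" if r > 0 else "negative"
    return "non_correlated"


def classify_pairs(
    results: Sequence[PairResult],
    alpha: float = 0.05,
    allow_negative: bool = True,
    condition: str = "",
) -> ClassificationCounts:
    """Tally pair categories at level ``alpha``.

    With ``allow_negative`` off (MEA mode, where all pairs are expected to
    correlate positively), negative pairs are still counted but flagged as
    anomalous via ``ClassificationCounts`` metadata in the returned object.
    """
    if not results:
        raise ValueError("no pair results to classify")
    counts = ClassificationCounts(condition)
    for res in results:
        if res.category == "excluded":
            counts.counts["excluded"] += 1
        else:
            counts.counts[_categorize(res.r, res.p, alpha)] += 1
    counts.anomalous_negative = (not allow_negative) and counts.counts["negative"] > 0
    return counts


def compare_classifications(
    a: ClassificationCounts,
    b: ClassificationCounts,
    categories: Sequence[str] = ("positive", "non_correlated"),
) -> tuple[float, int, float]:
    """Pearson chi-square of the condition x category contingency table."""
    table = [[a.counts[c] for c in categories], [b.counts[c] for c in categories]]
    return chi2_independence(table)


def pair_table(results: Sequence[PairResult], well_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "well_id": well_id,
            "electrode_a": res.pair[0],
            "electrode_b": res.pair[1],
            "r": res.r,
            "p": res.p,
            "category": res.category,
            "reason": res.reason,
        }
        for res in results
    ]
    return pd.DataFrame(rows)
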