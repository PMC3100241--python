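"""ISI-threshold burst detection and burst/interburst statistics.

A burst is a maximal run of consecutive spikes on one electrode whose
interspike intervals (ISIs) are all at or below a cutoff (default 20 ms),
kept only if the run contains at least a minimum number of spikes
(default 20). Interburst intervals (IBIs) run end-of-burst to
start-of-next on the same electrode. Doublet/triplet motifs are runs of
bursts whose connecting IBIs are only just above the ISI cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import SpikeTrain

__all__ = [
    "BurstParams",
    "Burst",
    "BurstTrain",
    "MotifSummary",
    "detect_bursts",
    "burst_metric_table",
    "interburst_intervals",
    "pooled_interburst_intervals",
    "label_motifs",
]

# absolute slack (seconds) for the inclusive ISI boundary: an ISI equal to
# the cutoff joins a burst even after float round-off in timestamp math
_ISI_EPS_S = 1e-12


@dataclass(frozen=True)
class BurstParams:
    min_spikes: int = 20
    max_isi_ms: float = 20.0
    motif_gap_max_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")
        if self.max_isi_ms <= 0:
            raise ValueError("max_isi_ms must be > 0")
        if self.motif_gap_max_ms <= self.max_isi_ms:
            raise ValueError("motif_gap_max_ms must exceed max_isi_ms")


@dataclass(frozen=True)
class Burst:
    """One detected burst: first/last spike times and spike count."""

    electrode_id: int
    t_start_s: float
    t_end_s: float
    n_spikes: int

    @property
    def duration_ms(self) -> float:
        return (self.t_end_s - self.t_start_s) * 1000.0


@dataclass
class BurstTrain:
    """Time-ordered bursts of one electrode."""

    electrode_id: int
    bursts: list[Burst] = field(default_factory=list)

    @property
    def ibis_ms(self) -> list[float]:
        return [
            (b2.t_start_s - b1.t_end_s) * 1000.0
            for b1, b2 in zip(self.bursts, self.bursts[1:])
        ]

    def __len__(self) -> int:
        return len(self.bursts)


@dataclass(frozen=True)
class MotifSummary:
    n_singletons: int
    n_doublets: int
    n_triplets: int


def detect_bursts(train: SpikeTrain, params: BurstParams | None = None) -> BurstTrain:
    """Partition a spike train into maximal ISI-bounded runs.

    Runs of consecutive spikes with every ISI <= max_isi_ms (inclusive
    boundary) that contain >= min_spikes spikes become bursts; all other
    spikes fall outside bursts. Maximality is inherent: runs are split
    exactly where an ISI exceeds the cutoff.
    """
    params = params or BurstParams()
    times = np.asarray(train.times_s, dtype=float)
    out = BurstTrain(electrode_id=train.electrode_id)
    if times.size == 0:
        return out
    isi = np.diff(times)
    if np.any(isi < 0):
        raise ValueError("spike times must be sorted")
    max_isi_s = params.max_isi_ms / 1000.0
    breaks = np.flatnonzero(isi > max_isi_s + _ISI_EPS_S)
    for seg in np.split(times, breaks + 1):
        if seg.size >= params.min_spikes:
            out.bursts.append(
                Burst(
                    electrode_id=train.electrode_id,
                    t_start_s=float(seg[0]),
                    t_end_s=float(seg[-1]),
                    n_spikes=int(seg.size),
                )
            )
    return out


def burst_metric_table(trains: list[BurstTrain]) -> pd.DataFrame:
    """One row per burst pooled over electrodes, ordered by (electrode, time)."""
    rows = [
        {
            "electrode_id": b.electrode_id,
            "t_start_s": b.t_start_s,
            "t_end_s": b.t_end_s,
            "n_spikes": b.n_spikes,
            "duration_ms": b.duration_ms,
        }
        for bt in trains
        for b in bt.bursts
    ]
    df = pd.DataFrame(
        rows,
        columns=["electrode_id", "t_start_s", "t_end_s", "n_spikes", "duration_ms"],
    )
    return df.sort_values(["electrode_id", "t_start_s"], kind="stable").reset_index(
        drop=True
    )


def interburst_intervals(train: BurstTrain) -> list[float]:
    """End-to-start gaps between consecutive bursts on one electrode, in ms."""
    return train.ibis_ms


def pooled_interburst_intervals(trains: list[BurstTrain]) -> np.ndarray:
    """IBIs computed per electrode, pooled across electrodes (ms)."""
    vals: list[float] = []
    for bt in trains:
        vals.extend(bt.ibis_ms)
    return np.asarray(vals, dtype=float)


def label_motifs(train: BurstTrain, params: BurstParams | None = None) -> MotifSummary:
    """Greedy left-to-right grouping of bursts into singlet/doublet/triplet motifs.

    Consecutive bursts whose connecting IBI is <= motif_gap_max_ms join the
    current group; a group closes when it reaches three bursts or the next
    gap is long. Groups of one, two and three bursts count as singletons,
    doublets and triplets.
    """
    params = params or BurstParams()
    counts = {1: 0, 2: 0, 3: 0}
    gaps = train.ibis_ms
    size = 0
    for i in range(len(train.bursts)):
        size += 1
        last = i == len(train.bursts) - 1
        if size == 3 or last or gaps[i] > params.motif_gap_max_ms:
            counts[size] += 1
            size = 0
    return MotifSummary(
        n_singletons=counts[1], n_doublets=counts[2], n_triplets=counts[3]
    )
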