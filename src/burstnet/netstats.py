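"""Culture-level burst statistics, histograms and condition comparisons.

The unit of analysis is the individual burst, pooled over electrodes (and
cultures where applicable); per-culture summaries report mean ± SEM of
burst duration and spikes per burst, the active-electrode count, and the
pooled interburst-interval sample. Conditions are compared with one-way
ANOVA on the pooled per-burst values; p-values are reported raw, with no
multiple-testing correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .bursts import BurstTrain, burst_metric_table, pooled_interburst_intervals

__all__ = [
    "CultureSummary",
    "HistogramSpec",
    "GroupComparison",
    "culture_summary",
    "histogram",
    "cumulative_fraction",
    "fraction_le",
    "find_ibi_modes",
    "one_way_anova",
    "compare_conditions",
]


@dataclass
class CultureSummary:
    """Burst statistics of one culture over an analysis window."""

    condition_label: str
    div: int | None
    n_bursts: int
    mean_duration_ms: float
    sem_duration_ms: float
    mean_spikes_per_burst: float
    sem_spikes_per_burst: float
    n_active_electrodes: int
    durations_ms: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    spikes_per_burst: np.ndarray = field(
        repr=False, default_factory=lambda: np.empty(0)
    )
    ibi_values_ms: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "condition_label": self.condition_label,
            "div": self.div,
            "n_bursts": self.n_bursts,
            "mean_duration_ms": self.mean_duration_ms,
            "sem_duration_ms": self.sem_duration_ms,
            "mean_spikes_per_burst": self.mean_spikes_per_burst,
            "sem_spikes_per_burst": self.sem_spikes_per_burst,
            "n_active_electrodes": self.n_active_electrodes,
        }


@dataclass(frozen=True)
class HistogramSpec:
    """Binning for distribution histograms.

    Linear scale uses ``bin_width`` (ms for durations, spikes for counts);
    log10 scale uses ``bins_per_decade``. ``range`` (lo, hi) is optional
    and must cover the data when given.
    """

    scale: str = "linear"
    bin_width: float | None = 25.0
    bins_per_decade: int | None = None
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and (self.bin_width is None or self.bin_width <= 0):
            raise ValueError("linear scale needs a positive bin_width")
        if self.scale == "log10" and (
            self.bins_per_decade is None or self.bins_per_decade <= 0
        ):
            raise ValueError("log10 scale needs a positive bins_per_decade")


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA contrast between groups for a single metric."""

    metric: str
    group_labels: tuple
    group_means: tuple
    F: float
    df_between: int
    df_within: int
    p: float

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "group_labels": list(self.group_labels),
            "group_means": list(self.group_means),
            "F": self.F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p,
        }


def _sem(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def culture_summary(
    metric_table: pd.DataFrame | None = None,
    burst_trains: list[BurstTrain] | None = None,
    window_s: float | None = None,
    condition_label: str = "",
    div: int | None = None,
) -> CultureSummary:
    """Pool per-burst values across electrodes into one culture summary.

    Either a burst metric table or the burst trains themselves may be
    given (trains additionally provide pooled IBIs). An electrode is
    active if it has at least one detected burst starting inside the
    window; with no window, the whole recording counts.
    """
    if metric_table is None:
        if burst_trains is None:
            raise ValueError("need metric_table or burst_trains")
        metric_table = burst_metric_table(burst_trains)
    df = metric_table
    if window_s is not None:
        df = df[df["t_start_s"] <= window_s]
    ibis = (
        pooled_interburst_intervals(burst_trains)
        if burst_trains is not None
        else _ibis_from_table(df)
    )
    n = len(df)
    if n == 0:
        return CultureSummary(
            condition_label=condition_label,
            div=div,
            n_bursts=0,
            mean_duration_ms=float("nan"),
            sem_duration_ms=float("nan"),
            mean_spikes_per_burst=float("nan"),
            sem_spikes_per_burst=float("nan"),
            n_active_electrodes=0,
            ibi_values_ms=ibis,
        )
    dur = df["duration_ms"].to_numpy(dtype=float)
    spk = df["n_spikes"].to_numpy(dtype=float)
    return CultureSummary(
        condition_label=condition_label,
        div=div,
        n_bursts=n,
        mean_duration_ms=float(dur.mean()),
        sem_duration_ms=_sem(dur),
        mean_spikes_per_burst=float(spk.mean()),
        sem_spikes_per_burst=_sem(spk),
        n_active_electrodes=int(df["electrode_id"].nunique()),
        durations_ms=dur,
        spikes_per_burst=spk,
        ibi_values_ms=ibis,
    )


def _ibis_from_table(df: pd.DataFrame) -> np.ndarray:
    vals: list[float] = []
    for _, sub in df.groupby("electrode_id"):
        sub = sub.sort_values("t_start_s")
        gaps = sub["t_start_s"].to_numpy()[1:] - sub["t_end_s"].to_numpy()[:-1]
        vals.extend(gaps * 1000.0)
    return np.asarray(vals, dtype=float)


def histogram(values, spec: HistogramSpec) -> tuple[np.ndarray, np.ndarray]:
    """Bin values per the spec; counts always sum to n."""
    values = np.asarray(values, dtype=float)
    if spec.scale == "log10":
        if values.size and np.any(values <= 0):
            raise ValueError("log10 scale requires positive values")
        if spec.range is not None:
            lo, hi = spec.range
            if lo <= 0:
                raise ValueError("log10 range must be positive")
        elif values.size:
            lo, hi = values.min(), values.max()
        else:
            lo, hi = 1.0, 10.0
        w = 1.0 / spec.bins_per_decade
        lo_e = np.floor(np.log10(lo) / w) * w
        n_bins = max(1, int(np.ceil((np.log10(hi) - lo_e) / w + 1e-9)))
        edges = 10 ** (lo_e + w * np.arange(n_bins + 1))
        # guard against round-off excluding the extremes
        edges[0] = min(edges[0], lo)
        edges[-1] = max(edges[-1], hi)
    else:
        w = spec.bin_width
        if spec.range is not None:
            lo, hi = spec.range
        elif values.size:
            lo, hi = min(values.min(), 0.0), values.max()
        else:
            lo, hi = 0.0, w
        n_bins = max(1, int(np.ceil((hi - lo) / w - 1e-9)))
        edges = lo + w * np.arange(n_bins + 1)
        edges[-1] = max(edges[-1], hi)
    if values.size and (values.min() < edges[0] or values.max() > edges[-1]):
        raise ValueError("histogram range does not cover the data")
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts


def cumulative_fraction(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF on the sorted values; reaches exactly 1 at the max."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cumulative fraction of an empty sample is undefined")
    srt = np.sort(values)
    frac = np.arange(1, srt.size + 1) / srt.size
    return srt, frac


def fraction_le(values, cutoff: float) -> float:
    """Fraction of values at or below the cutoff."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("fraction of an empty sample is undefined")
    return float(np.mean(values <= cutoff))


def find_ibi_modes(
    ibi_values_ms,
    bins_per_decade: int = 5,
    smooth_bins: int = 3,
    min_prominence_frac: float = 0.25,
) -> list[float]:
    """Locations (geometric bin centers, ms) of the modes of a log-binned
    IBI histogram.

    Counts are smoothed with a boxcar before peak finding, and peaks must
    have a topographic prominence of at least ``min_prominence_frac`` of
    the tallest smoothed bin. The coarse default binning and smoothing
    matter when network-wide silences are shared across electrodes: one
    culture then carries only tens of independent long gaps, and a finer
    histogram splits the long-silence peak into replicated lumps.
    """
    ibis = np.asarray(ibi_values_ms, dtype=float)
    if ibis.size == 0:
        return []
    edges, counts = histogram(
        ibis, HistogramSpec(scale="log10", bin_width=None, bins_per_decade=bins_per_decade)
    )
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(counts.astype(float), kernel, mode="same")
    padded = np.concatenate(([0.0], smooth, [0.0]))
    prominence = max(1.0, min_prominence_frac * smooth.max())
    peaks, _ = signal.find_peaks(padded, prominence=prominence)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return [float(centers[p - 1]) for p in peaks]


def one_way_anova(groups: list, metric: str = "", labels=None) -> GroupComparison:
    """Fixed-effects one-way ANOVA.

    F = (SSB/df_between) / (SSW/df_within); p from the F distribution.
    If both between- and within-group sums of squares are zero (all values
    identical) F is reported as 0 with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ssw == 0.0:
        F = 0.0 if ssb == 0.0 else float("inf")
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        F = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(arrays)))
    return GroupComparison(
        metric=metric,
        group_labels=tuple(labels),
        group_means=tuple(float(a.mean()) for a in arrays),
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=float(p),
    )


_METRIC_FIELDS = {
    "duration_ms": "durations_ms",
    "spikes_per_burst": "spikes_per_burst",
}


def compare_conditions(summaries: list[CultureSummary]) -> dict:
    """Omnibus and pairwise ANOVA across cultures for each burst metric.

    Uses the pooled per-burst values carried by each summary. Returns a
    machine-readable dict: metric -> {"omnibus": ..., "pairwise":
    {"a|b": ...}}, all GroupComparison dicts.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 culture summaries to compare")
    report: dict = {}
    for metric, attr in _METRIC_FIELDS.items():
        groups = [getattr(s, attr) for s in summaries]
        labels = [s.condition_label for s in summaries]
        if any(np.asarray(g).size < 2 for g in groups):
            raise ValueError(f"metric {metric}: every culture needs >= 2 bursts")
        entry = {
            "omnibus": one_way_anova(groups, metric=metric, labels=labels).to_dict(),
            "pairwise": {},
        }
        for (la, ga), (lb, gb) in itertools.combinations(zip(labels, groups), 2):
            cmp_ = one_way_anova([ga, gb], metric=metric, labels=[la, lb])
            entry["pairwise"][f"{la}|{lb}"] = cmp_.to_dict()
        report[metric] = entry
    return report
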