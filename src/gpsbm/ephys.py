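"""Spike trains to binary functional networks.

The construction follows the standard MEA functional-connectivity recipe:

1. *Channel bursts*: >= 4 spikes on one electrode within a sliding 100 ms
   window; the burst extent runs from the first to the last member spike,
   and overlapping qualifying windows merge into a single burst.
2. *Global bursts*: epochs in which channel bursts start on >= 4 distinct
   electrodes within 250 ms of the earliest (anchor) start.
3. *Cross-correlation*: inside each global burst, spikes are binned at
   10 ms and zero-lag Pearson correlation is computed per electrode pair;
   the matrix entry is the average over the global bursts where both
   electrodes were active.
4. *Thresholding*: an edge is added where the correlation strictly exceeds
   a fixed threshold (0.20 by default).

Electrode activity outside bursts is sparse, so correlating entire
recordings would inflate the correlations; restricting to global bursts is
what makes the resulting graphs meaningful.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import FunctionalNetwork

__all__ = [
    "SpikeRecording",
    "ChannelBurst",
    "GlobalBurst",
    "CorrelationMatrix",
    "read_spikes",
    "detect_channel_bursts",
    "detect_global_bursts",
    "cross_correlation_matrix",
    "threshold_network",
    "threshold_sweep",
    "mean_firing_rate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpikeRecording:
    """Per-electrode spike timestamps for one device at one DIV.

    ``spikes`` maps each entry of ``channels`` (in order) to a sorted array
    of timestamps in seconds within [0, duration]. Channels with no spikes
    are retained with empty arrays.
    """

    device_id: str
    div: int
    duration: float
    channels: tuple
    spikes: tuple  # tuple of np.ndarray, aligned with channels

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        channels = tuple(self.channels)
        if len(set(channels)) != len(channels):
            raise ValueError("duplicate channel ids")
        if len(self.spikes) != len(channels):
            raise ValueError("spikes must align with channels")
        clean = []
        for ch, s in zip(channels, self.spikes):
            s = np.asarray(s, dtype=float)
            if s.size and (np.any(np.diff(s) <= 0)):
                raise ValueError(f"channel {ch!r}: timestamps not strictly sorted")
            if s.size and (s[0] < 0 or s[-1] > self.duration):
                raise ValueError(
                    f"channel {ch!r}: timestamp outside [0, {self.duration}]"
                )
            clean.append(s)
        object.__setattr__(self, "channels", channels)
        object.__setattr__(self, "spikes", tuple(clean))

    @property
    def n(self) -> int:
        return len(self.channels)

    def shifted(self, dt: float) -> "SpikeRecording":
        """Recording with all timestamps translated by ``dt`` (for invariance
        checks; the duration window is translated implicitly by re-anchoring)."""
        spikes = tuple(s + dt for s in self.spikes)
        lo = min((s[0] for s in spikes if s.size), default=0.0)
        spikes = tuple(s - min(lo, 0.0) for s in spikes)
        return SpikeRecording(
            self.device_id, self.div, self.duration + max(dt, 0.0),
            self.channels, spikes,
        )


@dataclass(frozen=True)
class ChannelBurst:
    channel: object
    t_start: float
    t_end: float
    n_spikes: int

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")
        if self.n_spikes < 2:
            raise ValueError("a burst needs at least 2 spikes")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class GlobalBurst:
    t_start: float
    t_end: float
    member_bursts: tuple
    n_channels: int


@dataclass(frozen=True)
class CorrelationMatrix:
    values: np.ndarray
    channels: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", np.clip(v, -1.0, 1.0))
        object.__setattr__(self, "channels", tuple(self.channels))


def read_spikes(path) -> SpikeRecording:
    """Read a spike table (TSV/CSV, columns ``channel``, ``time_s``) with a
    JSON sidecar header ``{device, div, duration_s, channels}``.

    The sidecar sits next to the table with a ``.json`` suffix. Channels
    listed in the header but absent from the table come back with zero
    spikes.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar header {sidecar}")
    header = json.loads(sidecar.read_text())
    for key in ("device", "div", "duration_s", "channels"):
        if key not in header:
            raise ValueError(f"sidecar {sidecar} missing field {key!r}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if not {"channel", "time_s"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'channel' and 'time_s'")
    duration = float(header["duration_s"])
    channels = [str(c) for c in header["channels"]]
    df["channel"] = df["channel"].astype(str)
    unknown = set(df["channel"]) - set(channels)
    if unknown:
        raise ValueError(f"{path}: rows reference unlisted channels {sorted(unknown)}")
    bad = df[(df["time_s"] < 0) | (df["time_s"] > duration)]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"{path}: row {row} has timestamp {bad['time_s'].iloc[0]} outside "
            f"[0, {duration}]"
        )
    spikes = []
    for ch in channels:
        times = df.loc[df["channel"] == ch, "time_s"].to_numpy(dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: channel {ch!r} timestamps not strictly sorted")
        spikes.append(times)
    return SpikeRecording(
        str(header["device"]), int(header["div"]), duration,
        tuple(channels), tuple(spikes),
    )


def _burst_spans(s: np.ndarray, min_spikes: int, window: float):
    """Maximal merged index spans [i, j] such that some window of ``window``
    seconds anchored at a spike contains >= min_spikes spikes."""
    spans = []
    for i in range(len(s)):
        j = bisect_right(s, s[i] + window) - 1
        if j - i + 1 >= min_spikes:
            if spans and i <= spans[-1][1]:
                spans[-1][1] = max(spans[-1][1], j)
            else:
                spans.append([i, j])
    return spans


def detect_channel_bursts(
    rec: SpikeRecording, min_spikes: int = 4, window: float = 0.100
) -> dict:
    """Channel bursts per electrode: maximal merged spans of spikes in which
    some sliding ``window`` contains >= ``min_spikes`` spikes. Returns a dict
    mapping channel id to an ordered list of disjoint :class:`ChannelBurst`.
    """
    out = {}
    for ch, s in zip(rec.channels, rec.spikes):
        bursts = []
        for i, j in _burst_spans(s, min_spikes, window):
            bursts.append(ChannelBurst(ch, float(s[i]), float(s[j]), j - i + 1))
        out[ch] = bursts
    return out


def detect_global_bursts(
    bursts_by_channel: dict, min_channels: int = 4, window: float = 0.250
) -> list:
    """Group channel-burst starts into global bursts.

    Starts are scanned in ascending order; the earliest unassigned start
    anchors a 250 ms window, and if the unassigned bursts starting inside it
    cover >= ``min_channels`` distinct electrodes they form one global burst
    (extent = min member start to max member end). Each channel burst joins
    at most one global burst.
    """
    flat = []
    for ch, bursts in bursts_by_channel.items():
        for b in bursts:
            flat.append(b)
    flat.sort(key=lambda b: (b.t_start, str(b.channel), b.t_end))
    assigned = [False] * len(flat)
    out = []
    for i, anchor in enumerate(flat):
        if assigned[i]:
            continue
        group = [
            j for j in range(i, len(flat))
            if not assigned[j] and flat[j].t_start <= anchor.t_start + window
        ]
        channels = {flat[j].channel for j in group}
        if len(channels) >= min_channels:
            members = tuple(flat[j] for j in group)
            for j in group:
                assigned[j] = True
            out.append(
                GlobalBurst(
                    t_start=min(b.t_start for b in members),
                    t_end=max(b.t_end for b in members),
                    member_bursts=members,
                    n_channels=len(channels),
                )
            )
    return out


def cross_correlation_matrix(
    rec: SpikeRecording, gbursts, bin_width: float = 0.010
) -> CorrelationMatrix:
    """Average zero-lag Pearson correlation of binned spike counts over
    global bursts.

    Within each global burst, every channel's spikes in [t_start, t_end] are
    binned at ``bin_width``; pairs where both binned vectors have nonzero
    variance contribute their Pearson correlation. The final entry averages
    over the global bursts where the pair was defined; never-defined pairs
    are 0. Diagonal entries are 1 for channels active in at least one burst.
    """
    n = rec.n
    sums = np.zeros((n, n))
    cnts = np.zeros((n, n), dtype=int)
    ever_active = np.zeros(n, dtype=bool)
    gbursts = list(gbursts)
    if not gbursts:
        logger.warning(
            "no global bursts in recording %s DIV %s; correlation matrix is zero",
            rec.device_id, rec.div,
        )
    for gb in gbursts:
        span = max(gb.t_end - gb.t_start, bin_width)
        nbins = int(np.ceil(span / bin_width))
        edges = gb.t_start + np.arange(nbins + 1) * bin_width
        counts = np.stack(
            [np.histogram(s, bins=edges)[0] for s in rec.spikes]
        ).astype(float)
        active = counts.std(axis=1) > 0
        ever_active |= active
        idx = np.flatnonzero(active)
        if len(idx) >= 2:
            r = np.corrcoef(counts[idx])
            sums[np.ix_(idx, idx)] += r
            cnts[np.ix_(idx, idx)] += 1
    values = np.zeros((n, n))
    defined = cnts > 0
    values[defined] = sums[defined] / cnts[defined]
    np.fill_diagonal(values, 0.0)
    values[np.diag_indices(n)] = ever_active.astype(float)
    return CorrelationMatrix(values, rec.channels)


def threshold_network(
    C: CorrelationMatrix, threshold: float = 0.20, device_id: str = "", div: int = 0
) -> FunctionalNetwork:
    """Edge (u, v) present iff the correlation is strictly above ``threshold``."""
    if not -1.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [-1, 1], got {threshold}")
    adj = (C.values > threshold).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return FunctionalNetwork(adj, C.channels, device_id, div)


def threshold_sweep(C: CorrelationMatrix, thresholds) -> list:
    """(threshold, average node degree) for each threshold, ascending."""
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    out = []
    for th in thresholds:
        g = threshold_network(C, th)
        out.append((float(th), float(g.degrees().mean())))
    return out


def mean_firing_rate(rec: SpikeRecording) -> np.ndarray:
    """Per-channel mean firing rate in Hz (spike count / duration)."""
    return np.array([len(s) for s in rec.spikes], dtype=float) / rec.duration


def build_network(
    rec: SpikeRecording,
    threshold: float = 0.20,
    bin_width: float = 0.010,
    min_spikes: int = 4,
    burst_window: float = 0.100,
    min_channels: int = 4,
    global_window: float = 0.250,
) -> FunctionalNetwork:
    """Full pipeline: bursts -> global bursts -> correlation -> threshold."""
    cb = detect_channel_bursts(rec, min_spikes, burst_window)
    gb = detect_global_bursts(cb, min_channels, global_window)
    C = cross_correlation_matrix(rec, gb, bin_width)
    return threshold_network(C, threshold, rec.device_id, rec.div)
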