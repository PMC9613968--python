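"""Trial I/O, stride segmentation and 101-point time normalization.

A trial is a multivariate joint-angle time series (degrees) sampled at a
fixed rate, with channels labelled ``<joint>_<side>_<plane>``. Gait cycles
(strides) are delimited by successive initial contacts of the same foot and
are linearly resampled onto a 101-point phase grid (0-100% of the cycle)
before any waveform statistic is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

JOINTS = ("hip", "knee", "ankle")
SIDES = ("L", "R")
PLANES = ("sagittal", "frontal", "transverse")

#: canonical channel order: hip-knee-ankle x L-R x sagittal-frontal-transverse
CANONICAL_CHANNELS = tuple(
    f"{j}_{s}_{pl}" for j in JOINTS for s in SIDES for pl in PLANES
)

DEFAULT_PHASE_POINTS = 101


@dataclass
class KinematicsTrial:
    """One trial's joint-angle series.

    samples : (frames, p) array of angles in degrees
    fs      : sampling rate in Hz
    channels: ordered channel labels, one per column
    """

    samples: np.ndarray
    fs: float
    channels: tuple[str, ...]
    trial_id: str = ""
    activity_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channels = tuple(self.channels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (frames x channels) array")
        if self.samples.shape[0] < 2:
            raise ValueError("trial needs at least 2 frames")
        if self.samples.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[1]} columns but {len(self.channels)} channel labels"
            )
        if self.samples.shape[1] < 1:
            raise ValueError("trial needs at least one channel")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain NaN/inf after construction")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D array; error lists available labels."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in trial; available: {list(self.channels)}"
            ) from None
        return self.samples[:, idx]

    def sagittal_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c.endswith("_sagittal"))


@dataclass
class FootContactSeries:
    """Ordered frame indices of initial contact for one foot."""

    events: np.ndarray
    foot: str = "R"

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=int)
        if self.events.ndim != 1:
            raise ValueError("events must be 1-D")
        if self.events.size >= 2 and not (np.diff(self.events) > 0).all():
            raise ValueError("contact events must be strictly increasing")
        if self.foot not in SIDES:
            raise ValueError(f"foot must be one of {SIDES}")


@dataclass
class NormalizedCycleSet:
    """N gait cycles x T phase points x p joints (degrees)."""

    cycles: np.ndarray
    channels: tuple[str, ...] = ()
    source_trial_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        if self.cycles.ndim != 3:
            raise ValueError("cycles must be N x T x p")
        n, t, p = self.cycles.shape
        if n < 1 or p < 1:
            raise ValueError("need N >= 1 cycles and p >= 1 joints")

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]

    @property
    def n_phase(self) -> int:
        return self.cycles.shape[1]

    @property
    def n_joints(self) -> int:
        return self.cycles.shape[2]


def _validate_channel_labels(labels: list[str]) -> None:
    bad = [c for c in labels if c not in CANONICAL_CHANNELS]
    if bad:
        raise ValueError(
            f"unknown channel label(s) {bad}; valid labels are "
            f"{list(CANONICAL_CHANNELS)}"
        )


def canonical_order(labels: list[str]) -> list[str]:
    """Sort recognised labels into the canonical hip-knee-ankle ordering."""
    _validate_channel_labels(labels)
    return sorted(labels, key=CANONICAL_CHANNELS.index)


def load_trial(
    path,
    fs: float = 60.0,
    trial_id: str = "",
    activity_label: str = "",
    strict_labels: bool = True,
) -> KinematicsTrial:
    """Read a wide CSV (column 1 = time in s, rest = angle channels).

    Channels are reordered canonically when ``strict_labels`` is true; a NaN
    anywhere raises an error naming the offending row and column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("trial CSV needs a time column plus >= 1 angle column")
    angle_cols = list(df.columns[1:])
    if strict_labels:
        angle_cols = canonical_order(angle_cols)
    data = df[angle_cols]
    if data.isna().any().any():
        r, c = np.argwhere(data.isna().to_numpy())[0]
        raise ValueError(f"missing value at row {int(r)}, column {angle_cols[int(c)]!r}")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    if time.size >= 2:
        dt = np.median(np.diff(time))
        if dt > 0:
            fs = 1.0 / dt
    return KinematicsTrial(
        samples=data.to_numpy(dtype=float),
        fs=fs,
        channels=tuple(angle_cols),
        trial_id=trial_id or str(path),
        activity_label=activity_label,
    )


def save_trial(trial: KinematicsTrial, path) -> None:
    """Write a trial as the wide CSV accepted by :func:`load_trial`."""
    t = np.arange(trial.n_frames) / trial.fs
    df = pd.DataFrame(trial.samples, columns=list(trial.channels))
    df.insert(0, "time", t)
    # %.17g guarantees a bitwise float round-trip through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


def load_contacts(path) -> dict[str, FootContactSeries]:
    """Read a (frame_index, foot) CSV into one series per foot."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["frame_index", "foot"]:
        raise ValueError("contacts CSV must have columns frame_index, foot")
    out = {}
    for foot, grp in df.groupby("foot"):
        out[str(foot)] = FootContactSeries(
            events=np.sort(grp["frame_index"].to_numpy(dtype=int)), foot=str(foot)
        )
    return out


def save_contacts(contacts: FootContactSeries, path) -> None:
    pd.DataFrame(
        {"frame_index": contacts.events, "foot": contacts.foot}
    ).to_csv(path, index=False)


def segment_cycles(
    trial: KinematicsTrial,
    contacts: FootContactSeries,
    min_duration_s: float = 0.4,
) -> list[np.ndarray]:
    """Slice the trial into strides [IC_i, IC_{i+1}) on one foot.

    Strides shorter than ``min_duration_s`` (spurious double contacts) are
    dropped with a warning.
    """
    events = contacts.events
    if events.size < 2:
        raise ValueError("cannot segment: need at least 2 contact events")
    if events[0] < 0 or events[-1] > trial.n_frames:
        raise ValueError("contact events outside trial length")
    min_frames = max(2, int(np.ceil(min_duration_s * trial.fs)))
    cycles = []
    n_dropped = 0
    for a, b in zip(events[:-1], events[1:]):
        if b - a < min_frames:
            n_dropped += 1
            continue
        cycles.append(trial.samples[a:b])
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} cycle(s) shorter than {min_duration_s} s",
            stacklevel=2,
        )
    return cycles


def time_normalize(
    cycles: list[np.ndarray],
    n_points: int = DEFAULT_PHASE_POINTS,
    channels: tuple[str, ...] = (),
    source_trial_ids: tuple[str, ...] = (),
) -> NormalizedCycleSet:
    """Linearly resample each stride onto ``n_points`` phase points (0-100%).

    The grid includes both endpoints, so cycle boundary values are preserved
    exactly; a cycle already on the grid passes through unchanged.
    """
    if not cycles:
        raise ValueError("no cycles to normalize")
    out = np.empty((len(cycles), n_points, cycles[0].shape[1]))
    grid = np.linspace(0.0, 1.0, n_points)
    for i, cyc in enumerate(cycles):
        cyc = np.asarray(cyc, dtype=float)
        if cyc.ndim != 2 or cyc.shape[0] < 2:
            raise ValueError(f"cycle {i} has fewer than 2 frames")
        x = np.linspace(0.0, 1.0, cyc.shape[0])
        for k in range(cyc.shape[1]):
            out[i, :, k] = np.interp(grid, x, cyc[:, k])
        # np.interp is exact at grid endpoints; pin them to kill round-off
        out[i, 0] = cyc[0]
        out[i, -1] = cyc[-1]
    return NormalizedCycleSet(
        cycles=out, channels=tuple(channels), source_trial_ids=tuple(source_trial_ids)
    )


def save_cycles(cycles: NormalizedCycleSet, path) -> None:
    """Serialize a cycle set as one long-format CSV (cycle, phase, channels)."""
    n, t, p = cycles.cycles.shape
    cols = list(cycles.channels) if cycles.channels else [f"ch{k}" for k in range(p)]
    df = pd.DataFrame(cycles.cycles.reshape(n * t, p), columns=cols)
    df.insert(0, "phase_index", np.tile(np.arange(t), n))
    df.insert(0, "cycle", np.repeat(np.arange(n), t))
    df.to_csv(path, index=False, float_format="%.17g")


def load_cycles(path) -> NormalizedCycleSet:
    df = pd.read_csv(path, float_precision="round_trip")
    chans = [c for c in df.columns if c not in ("cycle", "phase_index")]
    n = df["cycle"].nunique()
    t = df["phase_index"].nunique()
    arr = df[chans].to_numpy(dtype=float).reshape(n, t, len(chans))
    return NormalizedCycleSet(cycles=arr, channels=tuple(chans))
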