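"""Event-series containers and history-embedding construction.

A point process is represented by the strictly increasing occurrence times of
its events (seconds).  The past of a process, as seen either from a target
event or from an arbitrary time point, is approximated by a finite-dimensional
*history embedding*: the time elapsed since the most recent event followed by
the preceding inter-event intervals.  These embeddings are the raw material of
the nearest-neighbor entropy estimates in :mod:`ppmir.estimators`.

Conventions
-----------
* time unit: seconds; rates in events/s.
* embedding coordinate ``j`` (0-based) of a block is the ``(j+1)``-th interval
  counting backwards in time, so event-sampled and time-sampled embeddings live
  in the same space (at an event, "time since the most recent previous event"
  *is* the last inter-event interval).
* joint embeddings put the ``l`` target coordinates first, then the ``l``
  source coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._seeds import spawn_rng

__all__ = [
    "EventSeries",
    "IntervalSeries",
    "EmbeddingSet",
    "SimultaneousEventError",
    "EmptyEmbeddingError",
    "intervals",
    "events_from_intervals",
    "embed_at_events",
    "embed_at_times",
    "sample_random_times",
    "jitter_events",
    "read_event_series",
    "write_event_series",
    "read_interval_series",
    "write_interval_series",
]


class SimultaneousEventError(ValueError):
    """Two processes share an event timestamp, violating the x_i != y_j assumption."""


class EmptyEmbeddingError(ValueError):
    """No sampling point admits a full history embedding."""


@dataclass(frozen=True)
class EventSeries:
    """Ordered event timestamps of one point process.

    Parameters
    ----------
    times : array-like of float
        Strictly increasing event times in seconds; at least two events.
    label : str
        Free-text name used in reports ("X", "R-times", ...).
    """

    times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.array(self.times, dtype=float)  # copy: frozen container owns it
        if t.ndim != 1 or t.size < 2:
            raise ValueError("an event series needs at least 2 scalar timestamps")
        if not np.all(np.isfinite(t)):
            raise ValueError("event times must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        t.flags.writeable = False
        object.__setattr__(self, "times", t)

    @property
    def n(self) -> int:
        """Number of events."""
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Observation span, last minus first timestamp (s)."""
        return float(self.times[-1] - self.times[0])

    @property
    def rate(self) -> float:
        """Mean event rate N / T (events/s)."""
        return self.n / self.duration


@dataclass(frozen=True)
class IntervalSeries:
    """Inter-event intervals plus the start time needed to rebuild the events."""

    start_time: float
    intervals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.array(self.intervals, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("an interval series needs at least 1 interval")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("all intervals must be finite and > 0")
        w.flags.writeable = False
        object.__setattr__(self, "intervals", w)
        object.__setattr__(self, "start_time", float(self.start_time))

    @property
    def n(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class EmbeddingSet:
    """Matrix of history embeddings.

    ``samples`` has one row per usable sampling point; ``l`` coordinates per
    embedded process (``l`` columns for ``target_only`` scope, ``2*l`` for
    ``joint`` with the target block first).  ``sample_times`` records the
    event time x_i or random time u_i each row refers to.
    """

    samples: np.ndarray
    l: int
    kind: str  # "at_target_events" | "at_random_times"
    scope: str  # "target_only" | "joint"
    sample_times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if self.kind not in ("at_target_events", "at_random_times"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.scope not in ("target_only", "joint"):
            raise ValueError(f"unknown scope {self.scope!r}")
        expected = self.l if self.scope == "target_only" else 2 * self.l
        if s.ndim != 2 or s.shape[1] != expected:
            raise ValueError(f"expected {expected} columns for scope {self.scope!r}")
        if np.any(s < 0):
            raise ValueError("embedding coordinates must be non-negative")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "sample_times", np.asarray(self.sample_times, dtype=float))

    @property
    def n(self) -> int:
        return int(self.samples.shape[0])


# ---------------------------------------------------------------------------
# interval <-> event conversions


def intervals(series: EventSeries) -> IntervalSeries:
    """Inter-event intervals w_i = t[i+1] - t[i] of an event series."""
    return IntervalSeries(
        start_time=float(series.times[0]),
        intervals=np.diff(series.times),
        label=series.label,
    )


def events_from_intervals(iv: IntervalSeries) -> EventSeries:
    """Rebuild the event series start_time + cumulative sums of the intervals."""
    times = iv.start_time + np.concatenate([[0.0], np.cumsum(iv.intervals)])
    return EventSeries(times=times, label=iv.label)


# ---------------------------------------------------------------------------
# history embeddings


def _check_disjoint(target: EventSeries, source: EventSeries) -> None:
    shared = np.intersect1d(target.times, source.times)
    if shared.size:
        raise SimultaneousEventError(
            f"{shared.size} timestamp(s) shared between the two series (first: "
            f"{shared[0]!r}); the estimator assumes x_i != y_j.  Apply "
            "jitter_events() if the data share a sampling grid."
        )


def embed_at_events(
    target: EventSeries, source: EventSeries, l: int
) -> tuple[EmbeddingSet, EmbeddingSet]:
    """History embeddings observed at target events.

    For each target event x_i with a full history, the joint row is::

        [x_i - x_{i-1}, ..., x_{i-l+1} - x_{i-l},       # l target intervals
         x_i - y_p, y_p - y_{p-1}, ..., y_{p-l+2} - y_{p-l+1}]   # source block

    where y_p is the most recent source event strictly before x_i.  An event
    is usable iff it has >= l target predecessors and y_p exists with >= l-1
    source predecessors; earlier events are dropped.

    Returns
    -------
    (joint, target_only) : tuple of EmbeddingSet
        The 2l-column joint embeddings and the same rows restricted to the
        l target coordinates.
    """
    if l < 1:
        raise ValueError("embedding length l must be >= 1")
    _check_disjoint(target, source)
    t, s = target.times, source.times
    p = np.searchsorted(s, t, side="left") - 1
    idx = np.arange(t.size)
    usable = (idx >= l) & (p >= l - 1)
    ui = idx[usable]
    if ui.size == 0:
        raise EmptyEmbeddingError(
            f"no target event admits a full joint embedding at l={l}"
        )
    pu = p[usable]
    rows = np.empty((ui.size, 2 * l))
    for k in range(1, l + 1):
        rows[:, k - 1] = t[ui - k + 1] - t[ui - k]
    rows[:, l] = t[ui] - s[pu]
    for k in range(1, l):
        rows[:, l + k] = s[pu - k + 1] - s[pu - k]
    times = t[ui]
    joint = EmbeddingSet(rows, l, "at_target_events", "joint", times)
    marg = EmbeddingSet(rows[:, :l].copy(), l, "at_target_events", "target_only", times)
    return joint, marg


def embed_at_times(
    target: EventSeries,
    source: EventSeries,
    l: int,
    u_times,
) -> tuple[EmbeddingSet, EmbeddingSet]:
    """History embeddings observed at arbitrary time points u_i.

    Each usable row is ``[u - x_p, l-1 target intervals, u - y_p, l-1 source
    intervals]`` with x_p (y_p) the most recent target (source) event strictly
    before u.  Points coinciding with an event time, or lacking l events of
    history in either process, are dropped.
    """
    if l < 1:
        raise ValueError("embedding length l must be >= 1")
    _check_disjoint(target, source)
    u = np.atleast_1d(np.asarray(u_times, dtype=float))
    t, s = target.times, source.times
    coincide = np.isin(u, t) | np.isin(u, s)
    xp = np.searchsorted(t, u, side="left") - 1
    yp = np.searchsorted(s, u, side="left") - 1
    ok = (~coincide) & (xp >= l - 1) & (yp >= l - 1)
    if not np.any(ok):
        raise EmptyEmbeddingError(
            f"no time point admits a full joint embedding at l={l}"
        )
    u, xp, yp = u[ok], xp[ok], yp[ok]
    rows = np.empty((u.size, 2 * l))
    rows[:, 0] = u - t[xp]
    for k in range(1, l):
        rows[:, k] = t[xp - k + 1] - t[xp - k]
    rows[:, l] = u - s[yp]
    for k in range(1, l):
        rows[:, l + k] = s[yp - k + 1] - s[yp - k]
    joint = EmbeddingSet(rows, l, "at_random_times", "joint", u)
    marg = EmbeddingSet(rows[:, :l].copy(), l, "at_random_times", "target_only", u)
    return joint, marg


def valid_sampling_window(
    target: EventSeries, source: EventSeries, l: int
) -> tuple[float, float]:
    """Open interval of time points at which the full joint embedding exists.

    Starts after both processes have accumulated l events and extends to the
    end of the record (the later of the two final events).
    """
    if l < 1:
        raise ValueError("embedding length l must be >= 1")
    if target.n < l + 1 or source.n < l:
        raise EmptyEmbeddingError("too few events for the requested l")
    lo = max(target.times[l - 1], source.times[l - 1])
    hi = max(target.times[-1], source.times[-1])
    if not lo < hi:
        raise EmptyEmbeddingError("empty valid sampling window")
    return float(lo), float(hi)


def sample_random_times(
    target: EventSeries,
    source: EventSeries,
    l: int,
    n_u: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n_u random time points uniformly from the valid sampling window.

    The window is restricted to the region where both joint embeddings are
    defined, so every returned point yields a usable row in
    :func:`embed_at_times`.  Reproducible under a fixed seed.
    """
    if n_u < 1:
        raise ValueError("n_u must be >= 1")
    lo, hi = valid_sampling_window(target, source, l)
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 0)
    u = rng.uniform(lo, hi, size=n_u)
    # exact collisions with event times have probability zero but would be
    # rejected downstream; resample them defensively
    for _ in range(100):
        bad = np.isin(u, target.times) | np.isin(u, source.times)
        if not bad.any():
            break
        u[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
    return np.sort(u)


def jitter_events(
    series: EventSeries, amplitude: float = 1e-6, seed: int | None = None
) -> EventSeries:
    """Opt-in deterministic jitter (uniform in +/-amplitude s) for quantized data.

    Intended for real recordings sharing a sampling grid, where exact timestamp
    collisions across series violate the no-simultaneous-events assumption.
    Raises if the jitter breaks strict monotonicity (amplitude too large).
    """
    rng = spawn_rng(seed, 0)
    t = series.times + rng.uniform(-amplitude, amplitude, size=series.n)
    return replace(series, times=t)


# ---------------------------------------------------------------------------
# plain-text I/O: one float per line, '#' comments permitted


def read_event_series(path, label: str | None = None) -> EventSeries:
    """Read an event series from a single-column ASCII file (seconds per line)."""
    path = Path(path)
    times = _read_floats(path)
    return EventSeries(times=times, label=label if label is not None else path.stem)


def write_event_series(series: EventSeries, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# event series: {series.label}\n")
        for t in series.times:
            fh.write(f"{float(t)!r}\n")


def read_interval_series(path, label: str | None = None) -> IntervalSeries:
    """Read an interval series; a '# start=<t0>' header carries the start time."""
    path = Path(path)
    start = 0.0
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#") and "start=" in line:
                start = float(line.split("start=", 1)[1].strip())
                break
    vals = _read_floats(path)
    return IntervalSeries(
        start_time=start, intervals=vals, label=label if label is not None else path.stem
    )


def write_interval_series(iv: IntervalSeries, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# start={float(iv.start_time)!r}\n")
        for w in iv.intervals:
            fh.write(f"{float(w)!r}\n")


def _read_floats(path: Path) -> np.ndarray:
    vals = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals.append(float(line))
    return np.asarray(vals, dtype=float)
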