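"""Invasive-chain track metrics.

Quantifies chain trajectories the way time-lapse tracking studies report
them: total path length, net displacement, velocity, and pre/post
comparisons around a leader-detachment event.  Two velocity readings are
computed because both appear in practice:

* ``mean_velocity`` — path length / elapsed time (speed along the path);
* ``net_velocity`` — net displacement / elapsed time.

Coordinates are pixels (x = column, y = row); time is derived from the
frame interval in minutes and reported in hours.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackMetrics",
    "EventSplit",
    "track_metrics",
    "split_at_event",
    "distance_profile",
    "relative_positions",
    "read_tracks_csv",
    "metrics_table",
]


@dataclass(frozen=True)
class Track:
    """One chain trajectory: strictly increasing frames, >= 2 samples."""

    track_id: int | str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float = 10.0  # minutes
    pixel_size: float | None = None  # um / px

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.size < 2:
            raise ValueError(f"track {self.track_id}: need >= 2 samples")
        if not (np.diff(frames) > 0).all():
            raise ValueError(f"track {self.track_id}: frames must strictly increase")
        if not (frames.size == len(self.x) == len(self.y)):
            raise ValueError(f"track {self.track_id}: ragged columns")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class TrackMetrics:
    path_length: float       # px
    displacement: float      # px
    mean_velocity: float     # px / h, along the path
    net_velocity: float      # px / h, displacement-based
    duration_h: float
    n_samples: int
    path_length_um: float | None = None
    displacement_um: float | None = None


def _steps(track: Track) -> np.ndarray:
    """Euclidean length of each consecutive step; a frame gap is one step."""
    return np.linalg.norm(np.diff(track.xy, axis=0), axis=1)


def track_metrics(track: Track) -> TrackMetrics:
    """Path length, displacement and velocities of one track.

    ``path_length`` sums consecutive Euclidean steps; ``displacement`` is
    the straight-line distance from first to last sample.  The triangle
    inequality guarantees path_length >= displacement.
    """
    steps = _steps(track)
    path = float(steps.sum())
    disp = float(np.linalg.norm(track.xy[-1] - track.xy[0]))
    duration_h = float((track.frames[-1] - track.frames[0]) * track.frame_interval / 60.0)
    px = track.pixel_size
    return TrackMetrics(
        path_length=path,
        displacement=disp,
        mean_velocity=path / duration_h,
        net_velocity=disp / duration_h,
        duration_h=duration_h,
        n_samples=len(track.frames),
        path_length_um=path * px if px else None,
        displacement_um=disp * px if px else None,
    )


@dataclass(frozen=True)
class EventSplit:
    event_frame: int
    pre: TrackMetrics
    post: TrackMetrics


def split_at_event(track: Track, event_frame: int) -> EventSplit:
    """Metrics before and after a detachment event.

    The event frame must be a sampled frame strictly inside the track; the
    event sample itself belongs to both halves (pre ends there, post starts
    there).
    """
    frames = track.frames
    if event_frame <= frames[0] or event_frame >= frames[-1]:
        raise ValueError(
            f"event frame {event_frame} must lie strictly inside "
            f"[{frames[0]}, {frames[-1]}]"
        )
    hits = np.flatnonzero(frames == event_frame)
    if hits.size == 0:
        raise ValueError(f"event frame {event_frame} is not a sampled frame")
    k = int(hits[0])

    def sub(sl: slice) -> Track:
        return Track(track.track_id, frames[sl], track.x[sl], track.y[sl],
                     track.frame_interval, track.pixel_size)

    return EventSplit(
        event_frame=event_frame,
        pre=track_metrics(sub(slice(None, k + 1))),
        post=track_metrics(sub(slice(k, None))),
    )


def distance_profile(track: Track) -> pd.DataFrame:
    """Cumulative path length over time: columns ``time_h``, ``cumulative_px``.

    Monotone non-decreasing, starting at 0; a stationary stretch shows as a
    plateau (the signature of chain arrest after leader detachment).
    """
    cum = np.concatenate([[0.0], np.cumsum(_steps(track))])
    time_h = (track.frames - track.frames[0]) * track.frame_interval / 60.0
    return pd.DataFrame({"time_h": time_h, "cumulative_px": cum})


def relative_positions(track: Track, reference: tuple[float, float]) -> np.ndarray:
    """Translate samples so `reference` (x, y) maps to the origin."""
    return track.xy - np.asarray(reference, dtype=float)


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------

def read_tracks_csv(path: str | Path, frame_interval: float = 10.0,
                    pixel_size: float | None = None) -> list[Track]:
    """Load tracks from a CSV with columns track_id, frame, x, y."""
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracks CSV missing columns: {sorted(missing)}")
    return tracks_from_frame(df, frame_interval=frame_interval, pixel_size=pixel_size)


def tracks_from_frame(df: pd.DataFrame, frame_interval: float = 10.0,
                      pixel_size: float | None = None) -> list[Track]:
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(Track(tid, sub.frame.to_numpy(), sub.x.to_numpy(),
                            sub.y.to_numpy(), frame_interval, pixel_size))
    return tracks


def metrics_table(tracks: list[Track],
                  events: dict | None = None) -> pd.DataFrame:
    """One row per track (or per pre/post half when an event is known)."""
    rows = []
    for tr in tracks:
        event = (events or {}).get(tr.track_id)
        if event is None:
            rows.append({"track_id": tr.track_id, "segment": "full",
                         **vars(track_metrics(tr))})
        else:
            split = split_at_event(tr, event)
            for name, m in (("pre", split.pre), ("post", split.post)):
                rows.append({"track_id": tr.track_id, "segment": name,
                             "event_frame": event, **vars(m)})
    return pd.DataFrame(rows)
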