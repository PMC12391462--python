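"""Core data types and I/O for spike/position/LFP recordings on the square detour maze.

Conventions shared by every module:

* time is seconds, float64, session-relative starting at 0;
* the linear coordinate is 0-based, in cm, continuous within each track;
  tracks are concatenated with explicit offsets recorded in :class:`MazeConfig`;
* unit IDs are stable across all sessions of a day (stable-cluster assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import yaml

__all__ = [
    "SpikeTrain",
    "TrajectorySession",
    "MazeConfig",
    "LfpChannel",
    "Session",
    "SessionSet",
    "ValidationError",
    "linearize",
    "save_session_set",
    "load_session_set",
]

TRACK_LENGTH = 150.0  #: cm, each of the four outer tracks
SEGMENT_LENGTH = 50.0  #: cm, stationary / mobile pieces
DETOUR_LENGTH = 150.0  #: cm, U-shaped detour replacing a mobile segment

SEGMENTS = ("first-stationary", "mobile", "last-stationary", "detour")


class ValidationError(ValueError):
    """Raised when a record violates a session invariant."""


@dataclass
class SpikeTrain:
    """Spike times of one sorted unit.

    Parameters
    ----------
    unit_id : opaque identifier, stable across sessions.
    times : 1-D array of spike times in seconds, strictly increasing.
    label : putative cell class; analyses use pyramidal units only.
    """

    unit_id: int
    times: np.ndarray
    label: str = "pyramidal"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: times must be 1-D")
        if np.any(~np.isfinite(self.times)):
            raise ValidationError(f"unit {self.unit_id}: non-finite spike time")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not sorted")
        if self.label not in ("pyramidal", "interneuron"):
            raise ValidationError(f"unit {self.unit_id}: unknown label {self.label!r}")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def restrict(self, start: float, stop: float) -> "SpikeTrain":
        """Spikes with start <= t < stop."""
        i0, i1 = np.searchsorted(self.times, [start, stop])
        return SpikeTrain(self.unit_id, self.times[i0:i1], self.label)


@dataclass
class MazeConfig:
    """Geometry of the 150 x 150 cm square maze with optional detour.

    Tracks T1..T4 run along the sides of the square; each is split into a
    first-stationary (50 cm), mobile/middle (50 cm) and last-stationary
    (50 cm) segment.  When a track is detoured, its mobile segment is
    replaced by a 150 cm U-shaped detour, so the track's linearized length
    grows from 150 to 250 cm.  ``track_offsets`` place each track on the
    concatenated 1-D coordinate.
    """

    session_id: str = ""
    detoured_track: int | None = None  # 1-based track index, or None
    side: float = TRACK_LENGTH

    @property
    def n_tracks(self) -> int:
        return 4

    def track_length(self, track: int) -> float:
        if self.detoured_track == track:
            return 2 * SEGMENT_LENGTH + DETOUR_LENGTH
        return TRACK_LENGTH

    @property
    def track_offsets(self) -> np.ndarray:
        lengths = [self.track_length(k) for k in range(1, 5)]
        return np.concatenate([[0.0], np.cumsum(lengths)])

    @property
    def total_length(self) -> float:
        return float(self.track_offsets[-1])

    def corners(self) -> np.ndarray:
        """2-D corner positions of the square, ordered T1 start .. T4 end."""
        s = self.side
        return np.array([[0, 0], [s, 0], [s, s], [0, s], [0, 0]], dtype=float)

    def track_polyline(self, track: int) -> np.ndarray:
        """Vertices of the 2-D path of one track (with detour if present)."""
        c = self.corners()
        a, b = c[track - 1], c[track]
        if self.detoured_track != track:
            return np.vstack([a, b])
        # outward unit normal of the square side
        d = (b - a) / np.linalg.norm(b - a)
        n = np.array([d[1], -d[0]])
        mid = self.side / 2.0
        p1 = a + d * (mid - SEGMENT_LENGTH / 2)  # detour entry
        p2 = p1 + n * SEGMENT_LENGTH
        p3 = p2 + d * SEGMENT_LENGTH
        p4 = a + d * (mid + SEGMENT_LENGTH / 2)  # detour exit
        return np.vstack([a, p1, p2, p3, p4, b])

    def segment_of(self, lin_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map linear positions to (track index 1..4, segment name)."""
        lin_pos = np.asarray(lin_pos, dtype=float)
        offsets = self.track_offsets
        track = np.clip(np.searchsorted(offsets, lin_pos, side="right"), 1, 4)
        within = lin_pos - offsets[track - 1]
        seg = np.empty(lin_pos.shape, dtype=object)
        for k in range(1, 5):
            m = track == k
            if not m.any():
                continue
            w = within[m]
            if self.detoured_track == k:
                names = np.where(
                    w < SEGMENT_LENGTH,
                    "first-stationary",
                    np.where(w < SEGMENT_LENGTH + DETOUR_LENGTH, "detour", "last-stationary"),
                )
            else:
                names = np.where(
                    w < SEGMENT_LENGTH,
                    "first-stationary",
                    np.where(w < 2 * SEGMENT_LENGTH, "mobile", "last-stationary"),
                )
            seg[m] = names
        return track.astype(np.int64), seg.astype(str)

    def point_at(self, lin_pos: np.ndarray) -> np.ndarray:
        """Inverse of linearization: 2-D point at each linear coordinate."""
        lin_pos = np.atleast_1d(np.asarray(lin_pos, dtype=float))
        offsets = self.track_offsets
        out = np.zeros((lin_pos.size, 2))
        track = np.clip(np.searchsorted(offsets, lin_pos, side="right"), 1, 4)
        for k in range(1, 5):
            m = track == k
            if not m.any():
                continue
            poly = self.track_polyline(k)
            seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seglen)])
            w = np.clip(lin_pos[m] - offsets[k - 1], 0, cum[-1])
            j = np.clip(np.searchsorted(cum, w, side="right") - 1, 0, len(seglen) - 1)
            frac = (w - cum[j]) / seglen[j]
            out[m] = poly[j] + frac[:, None] * (poly[j + 1] - poly[j])
        return out

    def segment_bounds(self, track: int, segment: str) -> tuple[float, float]:
        """Linear-coordinate bounds [lo, hi) of one named segment."""
        off = float(self.track_offsets[track - 1])
        detoured = self.detoured_track == track
        mid_len = DETOUR_LENGTH if detoured else SEGMENT_LENGTH
        if segment == "first-stationary":
            return off, off + SEGMENT_LENGTH
        if segment in ("mobile", "detour"):
            if segment == "detour" and not detoured:
                raise ValidationError(f"track {track} has no detour")
            if segment == "mobile" and detoured:
                raise ValidationError(f"track {track} is detoured; no mobile segment")
            return off + SEGMENT_LENGTH, off + SEGMENT_LENGTH + mid_len
        if segment == "last-stationary":
            return off + SEGMENT_LENGTH + mid_len, off + self.track_length(track)
        raise ValidationError(f"unknown segment {segment!r}")


@dataclass
class TrajectorySession:
    """Linearized animal trajectory sampled at 30 Hz."""

    t: np.ndarray
    pos_2d: np.ndarray  # (n, 2) cm; may be empty for sleep sessions
    lin_pos: np.ndarray  # cm on the concatenated coordinate; NaN if off-track
    track_id: np.ndarray  # 1..4, 0 if invalid
    segment_id: np.ndarray  # str labels
    direction: np.ndarray  # 1 (clockwise), 2 (counter-clockwise), 0 undefined
    velocity: np.ndarray  # cm/s, >= 0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("trajectory timestamps not strictly increasing")
        if np.any(self.velocity < -1e-9):
            raise ValidationError("negative velocity")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def velocity_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.velocity)

    def lin_pos_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.lin_pos)

    def direction_at(self, times: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.t, times), 0, self.t.size - 1)
        return self.direction[idx]


@dataclass
class LfpChannel:
    """One wideband LFP channel at a uniform rate (>= 1 kHz)."""

    t: np.ndarray
    samples: np.ndarray  # microvolts
    rate: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate < 1000:
            raise ValidationError("LFP rate must be >= 1000 Hz to resolve ripples")
        if self.t.size != self.samples.size:
            raise ValidationError("LFP t/samples length mismatch")


SESSION_ORDER = ("Sleep1", "Run1", "Sleep2", "Run2", "Sleep3", "Run3", "Sleep4", "Run4")


@dataclass
class Session:
    """One run or sleep session: spikes + trajectory + LFP + maze state."""

    session_id: str
    kind: str  # "run" | "sleep"
    spikes: dict[int, SpikeTrain]
    trajectory: TrajectorySession | None
    lfp: LfpChannel | None
    maze: MazeConfig
    t_stop: float | None = None  # declared session end; else inferred

    def __post_init__(self):
        if self.kind not in ("run", "sleep"):
            raise ValidationError(f"{self.session_id}: kind must be run|sleep")

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.spikes)

    @property
    def duration(self) -> float:
        if self.t_stop is not None:
            return float(self.t_stop)
        stops = [st.times[-1] for st in self.spikes.values() if st.n_spikes]
        if self.trajectory is not None and self.trajectory.t.size:
            stops.append(self.trajectory.t[-1])
        if self.lfp is not None and self.lfp.t.size:
            stops.append(self.lfp.t[-1])
        return float(max(stops)) if stops else 0.0

    @property
    def _bound(self) -> float | None:
        # bound against which spike times are validated: declared end or the
        # extent of the continuously sampled signals
        if self.t_stop is not None:
            return float(self.t_stop)
        stops = []
        if self.trajectory is not None and self.trajectory.t.size:
            stops.append(self.trajectory.t[-1])
        if self.lfp is not None and self.lfp.t.size:
            stops.append(self.lfp.t[-1])
        return float(max(stops)) if stops else None

    def pyramidal_spikes(self) -> dict[int, SpikeTrain]:
        return {u: s for u, s in self.spikes.items() if s.label == "pyramidal"}


@dataclass
class SessionSet:
    """The eight alternating sleep/run sessions of one detour day."""

    sessions: dict[str, Session] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not self.sessions:
            return
        registries = {sid: tuple(s.unit_ids) for sid, s in self.sessions.items()}
        ref_sid, ref = next(iter(registries.items()))
        for sid, reg in registries.items():
            if reg != ref:
                raise ValidationError(
                    f"unit registry mismatch between {ref_sid} and {sid}"
                )
        for sid, s in self.sessions.items():
            dur = s._bound
            if dur is None:
                continue
            for u, st in s.spikes.items():
                if st.n_spikes and (st.times[0] < -1e-9 or st.times[-1] > dur + 1.0):
                    raise ValidationError(
                        f"session {sid} unit {u}: spike time outside session bounds"
                    )

    def __getitem__(self, sid: str) -> Session:
        if sid not in self.sessions:
            raise ValidationError(f"session {sid} absent")
        return self.sessions[sid]

    @property
    def unit_ids(self) -> list[int]:
        first = next(iter(self.sessions.values()))
        return first.unit_ids

    def require(self, names: Iterable[str]):
        for n in names:
            if n not in self.sessions:
                raise ValidationError(f"session {n} absent")


# ---------------------------------------------------------------------------
# Linearization
# ---------------------------------------------------------------------------

def _project_to_polyline(points: np.ndarray, poly: np.ndarray):
    """Perpendicular projection of points to a polyline.

    Returns (arclength along polyline, distance to polyline)."""
    best_d = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    s0 = 0.0
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        L = np.linalg.norm(ab)
        tpar = np.clip((points - a) @ ab / (L * L), 0.0, 1.0)
        proj = a + tpar[:, None] * ab
        d = np.linalg.norm(points - proj, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_s[upd] = s0 + tpar[upd] * L
        s0 += L
    return best_s, best_d


def linearize(
    pos_2d: np.ndarray,
    maze: MazeConfig,
    tolerance: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse 2-D positions to the concatenated linear coordinate.

    Each sample is snapped perpendicular onto the nearest track polyline;
    samples farther than ``tolerance`` (cm) from every track are flagged
    invalid (lin_pos NaN, track 0) and excluded downstream rather than
    clamped.  Ties at corners go to the lower-indexed track.

    Returns
    -------
    lin_pos, track_id, segment_id
    """
    pos_2d = np.asarray(pos_2d, dtype=float)
    n = len(pos_2d)
    lin = np.full(n, np.nan)
    track = np.zeros(n, dtype=np.int64)
    dist = np.full(n, np.inf)
    offsets = maze.track_offsets
    for k in range(1, 5):  # ascending: lower index wins ties via strict <
        s, d = _project_to_polyline(pos_2d, maze.track_polyline(k))
        upd = d < dist - 1e-9
        lin[upd] = offsets[k - 1] + s[upd]
        track[upd] = k
        dist[upd] = d[upd]
    bad = dist > tolerance
    lin[bad] = np.nan
    track[bad] = 0
    seg = np.full(n, "invalid", dtype=object)
    ok = ~bad
    if ok.any():
        _, seg_ok = maze.segment_of(lin[ok])
        seg[ok] = seg_ok
    return lin, track, seg.astype(str)


def make_trajectory(
    t: np.ndarray, pos_2d: np.ndarray, maze: MazeConfig, tolerance: float = 5.0
) -> TrajectorySession:
    """Build a TrajectorySession from raw 30 Hz 2-D tracking samples."""
    lin, track, seg = linearize(pos_2d, maze, tolerance)
    dt = np.gradient(t)
    # velocity from 2-D displacement; invalid samples inherit neighbours via NaN-safe diff
    disp = np.linalg.norm(np.gradient(pos_2d, axis=0), axis=1)
    vel = disp / dt
    vel = np.nan_to_num(vel, nan=0.0)
    # direction from signed linear displacement, ignoring wrap jumps at corners
    dlin = np.gradient(np.nan_to_num(lin, nan=0.0))
    direction = np.where(dlin >= 0, 1, 2).astype(np.int64)
    return TrajectorySession(
        t=t, pos_2d=pos_2d, lin_pos=lin, track_id=track,
        segment_id=seg, direction=direction, velocity=vel,
    )


# ---------------------------------------------------------------------------
# I/O: HDF5 container + YAML config
# ---------------------------------------------------------------------------

def _write_session(g: h5py.Group, s: Session):
    g.attrs["kind"] = s.kind
    g.attrs["detoured_track"] = -1 if s.maze.detoured_track is None else s.maze.detoured_track
    ug = g.create_group("units")
    for u, st in s.spikes.items():
        d = ug.create_group(str(u))
        d.create_dataset("spike_times", data=st.times)
        d.attrs["label"] = st.label
    if s.trajectory is not None:
        p = g.create_group("position")
        tr = s.trajectory
        p.create_dataset("t", data=tr.t)
        p.create_dataset("x", data=tr.pos_2d[:, 0] if tr.pos_2d.size else np.empty(0))
        p.create_dataset("y", data=tr.pos_2d[:, 1] if tr.pos_2d.size else np.empty(0))
        p.create_dataset("lin", data=tr.lin_pos)
        p.create_dataset("track", data=tr.track_id)
        p.create_dataset("segment", data=np.array(tr.segment_id, dtype="S"))
        p.create_dataset("dir", data=tr.direction)
        p.create_dataset("velocity", data=tr.velocity)
    if s.lfp is not None:
        l = g.create_group("lfp")
        l.create_dataset("t", data=s.lfp.t)
        l.create_dataset("samples", data=s.lfp.samples)
        l.attrs["rate"] = s.lfp.rate


def _read_session(g: h5py.Group, sid: str) -> Session:
    det = int(g.attrs["detoured_track"])
    maze = MazeConfig(session_id=sid, detoured_track=None if det < 0 else det)
    spikes = {}
    for u in g["units"]:
        d = g["units"][u]
        spikes[int(u)] = SpikeTrain(int(u), d["spike_times"][...], d.attrs["label"])
    traj = None
    if "position" in g:
        p = g["position"]
        x, y = p["x"][...], p["y"][...]
        traj = TrajectorySession(
            t=p["t"][...],
            pos_2d=np.column_stack([x, y]) if x.size else np.empty((0, 2)),
            lin_pos=p["lin"][...],
            track_id=p["track"][...],
            segment_id=p["segment"][...].astype(str),
            direction=p["dir"][...],
            velocity=p["velocity"][...],
        )
    lfp = None
    if "lfp" in g:
        l = g["lfp"]
        lfp = LfpChannel(t=l["t"][...], samples=l["samples"][...], rate=float(l.attrs["rate"]))
    return Session(sid, str(g.attrs["kind"]), spikes, traj, lfp, maze)


def save_session_set(sset: SessionSet, path: str | Path):
    """Write a SessionSet to one HDF5 container + a YAML sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "sessions.h5", "w") as f:
        for sid, s in sset.sessions.items():
            _write_session(f.create_group(sid), s)
    with open(path / "config.yaml", "w") as f:
        yaml.safe_dump({"sessions": list(sset.sessions), "meta": sset.meta}, f)


def load_session_set(path: str | Path, config: Mapping | None = None) -> SessionSet:
    """Load and validate a SessionSet written by :func:`save_session_set`.

    ``config`` may list ``required_sessions``; a missing one raises
    ``ValidationError('session <name> absent')``.
    """
    path = Path(path)
    cfg_file = path / "config.yaml"
    meta = {}
    if cfg_file.exists():
        with open(cfg_file) as f:
            loaded = yaml.safe_load(f) or {}
        meta = loaded.get("meta", {})
    sessions: dict[str, Session] = {}
    with h5py.File(path / "sessions.h5", "r") as f:
        for sid in f:
            sessions[sid] = _read_session(f[sid], sid)
    sset = SessionSet(sessions=sessions, meta=meta)
    required = (config or {}).get("required_sessions")
    if required:
        sset.require(required)
    return sset


def export_csv(sset: SessionSet, path: str | Path):
    """Plain-text mirrors: one spikes CSV and one position CSV per session."""
    import pandas as pd

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for sid, s in sset.sessions.items():
        rows = [
            (u, t, st.label)
            for u, st in s.spikes.items()
            for t in st.times
        ]
        pd.DataFrame(rows, columns=["unit_id", "time_s", "label"]).to_csv(
            path / f"{sid}_spikes.csv", index=False
        )
        if s.trajectory is not None:
            tr = s.trajectory
            pd.DataFrame(
                {
                    "t": tr.t,
                    "lin_pos": tr.lin_pos,
                    "track": tr.track_id,
                    "segment": tr.segment_id,
                    "direction": tr.direction,
                    "velocity": tr.velocity,
                }
            ).to_csv(path / f"{sid}_position.csv", index=False)
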