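"""Offline frame, ripple and theta-state detection from spikes and LFP.

Frames are brief multi-unit bursts during immobility: the pooled pyramidal
spike train is binned at 1 ms, smoothed with a 15 ms Gaussian, thresholded
at mean + 2 SD (statistics taken over immobility periods) and extended to
the flanking mean crossings; candidates must last 100-1200 ms, contain at
least 5 distinct units, and fall entirely in velocity < 2 cm/s periods.

Theta phase uses a zero-phase 7-10 Hz band-pass and the analytic signal;
phase 0 is the LFP peak and 180 degrees the trough, so cycle boundaries are
consecutive phase peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.ndimage import gaussian_filter1d

from .session import LfpChannel, SpikeTrain, TrajectorySession

__all__ = [
    "Frame",
    "ThetaCycle",
    "RippleEvent",
    "detect_frames",
    "theta_phase",
    "theta_cycles",
    "detect_ripples",
    "classify_theta_state",
    "events_to_table",
]

THETA_BAND = (7.0, 10.0)
RIPPLE_BAND = (140.0, 220.0)
IMMOBILE_SPEED = 2.0  # cm/s
FRAME_DUR = (0.1, 1.2)  # s
RIPPLE_DUR = (0.03, 0.2)  # s
MIN_FRAME_UNITS = 5


@dataclass
class Frame:
    """One offline multi-unit burst (candidate replay/preplay window)."""

    start: float
    stop: float
    member_spikes: list  # (unit_id, time) pairs, time-sorted
    origin: str = "sleep"  # sleep | waking-rest

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def n_distinct_units(self) -> int:
        return len({u for u, _t in self.member_spikes})

    @property
    def unit_ids(self) -> list:
        return sorted({u for u, _t in self.member_spikes})


@dataclass
class ThetaCycle:
    """One peak-to-peak theta cycle with its member spikes."""

    start: float
    stop: float
    member_spikes: list = field(default_factory=list)
    lap: int = -1
    midpoint_pos: float = np.nan
    direction: int = 0

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def n_active_units(self) -> int:
        return len({u for u, _t in self.member_spikes})


@dataclass
class RippleEvent:
    start: float
    stop: float
    peak_power_z: float

    @property
    def duration(self) -> float:
        return self.stop - self.start


# ---------------------------------------------------------------------------


def _collect_member_spikes(spikes: dict[int, SpikeTrain], start: float, stop: float):
    out = []
    for u, st in spikes.items():
        ts = st.times
        i0, i1 = np.searchsorted(ts, [start, stop])
        out.extend((u, float(t)) for t in ts[i0:i1])
    out.sort(key=lambda p: p[1])
    return out


def detect_frames(
    spikes: dict[int, SpikeTrain],
    trajectory: TrajectorySession | None,
    duration: float | None = None,
    bin_ms: float = 1.0,
    smooth_ms: float = 15.0,
    threshold_sd: float = 2.0,
    dur_range: tuple[float, float] = FRAME_DUR,
    min_units: int = MIN_FRAME_UNITS,
    immobile_speed: float = IMMOBILE_SPEED,
    origin: str = "sleep",
) -> list[Frame]:
    """Detect multi-unit activity frames during immobility.

    MUA mean/SD are computed over immobility samples only.  Candidates above
    mean + ``threshold_sd`` SD are extended outward to the nearest crossings
    of the immobility mean, then filtered by duration, distinct-unit count
    and by requiring velocity < ``immobile_speed`` throughout.
    """
    pyramidal = {u: s for u, s in spikes.items() if s.label == "pyramidal"}
    all_times = np.sort(np.concatenate([s.times for s in pyramidal.values()])) \
        if pyramidal else np.empty(0)
    if all_times.size == 0:
        return []
    if duration is None:
        duration = float(all_times[-1]) + 0.1
        if trajectory is not None and trajectory.t.size:
            duration = max(duration, float(trajectory.t[-1]))

    dt = bin_ms / 1000.0
    n = int(np.ceil(duration / dt))
    mua = np.bincount(np.clip((all_times / dt).astype(int), 0, n - 1), minlength=n)
    mua = gaussian_filter1d(mua.astype(float), smooth_ms / bin_ms)

    tgrid = (np.arange(n) + 0.5) * dt
    if trajectory is not None and trajectory.t.size:
        vel = trajectory.velocity_at(tgrid)
    else:
        vel = np.zeros(n)
    immobile = vel < immobile_speed
    if not immobile.any():
        return []
    mu, sd = mua[immobile].mean(), mua[immobile].std()
    if sd == 0:
        return []
    hi = mua > mu + threshold_sd * sd
    above_mean = mua > mu

    frames: list[Frame] = []
    # contiguous super-threshold runs
    d = np.diff(hi.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if hi[0]:
        starts = np.r_[0, starts]
    if hi[-1]:
        stops = np.r_[stops, n]
    last_stop = -1.0
    for a, b in zip(starts, stops):
        # extend to nearest mean crossings flanking the excursion
        a2 = a
        while a2 > 0 and above_mean[a2 - 1]:
            a2 -= 1
        b2 = b
        while b2 < n and above_mean[b2]:
            b2 += 1
        t0, t1 = a2 * dt, b2 * dt
        if t0 < last_stop:  # merged with previous extension; skip duplicate
            continue
        dur = t1 - t0
        if not (dur_range[0] <= dur <= dur_range[1]):
            continue
        seg = immobile[a2:b2]
        if not seg.all():
            continue
        members = _collect_member_spikes(pyramidal, t0, t1)
        if len({u for u, _ in members}) < min_units:
            continue
        frames.append(Frame(t0, t1, members, origin=origin))
        last_stop = t1
    return frames


# ---------------------------------------------------------------------------


def _bandpass_sos(lo: float, hi: float, rate: float, order: int = 3):
    return butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")


def theta_phase(lfp: LfpChannel, band: tuple[float, float] = THETA_BAND):
    """Instantaneous theta phase (radians in [-pi, pi), 0 = LFP peak).

    The LFP is band-passed with a zero-phase forward-backward Butterworth
    filter, then the analytic-signal angle gives the phase.
    """
    if np.allclose(lfp.samples, lfp.samples[0]):
        raise ValueError("flat LFP: theta phase undefined")
    sos = _bandpass_sos(band[0], band[1], lfp.rate)
    filt = sosfiltfilt(sos, lfp.samples)
    analytic = hilbert(filt)
    phase = np.angle(analytic)
    return phase, filt


def theta_cycles(
    lfp: LfpChannel,
    band: tuple[float, float] = THETA_BAND,
    tolerance: float = 0.25,
) -> list[ThetaCycle]:
    """Cycle boundaries at consecutive theta-phase peaks (phase-0 crossings).

    Cycles whose duration deviates more than ``tolerance`` (fractional) from
    the band's period range are dropped.
    """
    phase, _ = theta_phase(lfp, band)
    unwrapped = np.unwrap(phase)
    # peaks are where the unwrapped phase crosses multiples of 2 pi
    k0 = np.ceil(unwrapped[0] / (2 * np.pi))
    k1 = np.floor(unwrapped[-1] / (2 * np.pi))
    targets = 2 * np.pi * np.arange(k0, k1 + 1)
    peak_t = np.interp(targets, unwrapped, lfp.t)
    lo_dur = (1.0 / band[1]) * (1 - tolerance)
    hi_dur = (1.0 / band[0]) * (1 + tolerance)
    cycles = []
    for a, b in zip(peak_t[:-1], peak_t[1:]):
        if lo_dur <= (b - a) <= hi_dur:
            cycles.append(ThetaCycle(float(a), float(b)))
    return cycles


def attach_spikes_to_cycles(
    cycles: list[ThetaCycle],
    spikes: dict[int, SpikeTrain],
    trajectory: TrajectorySession | None = None,
) -> list[ThetaCycle]:
    """Fill member spikes, midpoint position/direction and lap per cycle."""
    for c in cycles:
        c.member_spikes = _collect_member_spikes(spikes, c.start, c.stop)
        if trajectory is not None:
            mid = 0.5 * (c.start + c.stop)
            c.midpoint_pos = float(trajectory.lin_pos_at(np.array([mid]))[0])
            c.direction = int(trajectory.direction_at(np.array([mid]))[0])
    return cycles


def interp_phase(lfp: LfpChannel, phase: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Phase at arbitrary times via unwrapped interpolation."""
    unwrapped = np.unwrap(phase)
    p = np.interp(times, lfp.t, unwrapped)
    return np.angle(np.exp(1j * p))


# ---------------------------------------------------------------------------


def detect_ripples(
    lfp: LfpChannel,
    band: tuple[float, float] = RIPPLE_BAND,
    hi_sd: float = 5.0,
    lo_sd: float = 2.0,
    dur_range: tuple[float, float] = RIPPLE_DUR,
    smooth_ms: float = 2.0,
) -> list[RippleEvent]:
    """Ripple events from the 140-220 Hz power envelope.

    Candidates exceed mean + ``hi_sd`` SD and are extended to the
    mean + ``lo_sd`` SD crossings; 30-200 ms duration filter applies.
    """
    sos = _bandpass_sos(band[0], band[1], lfp.rate)
    filt = sosfiltfilt(sos, lfp.samples)
    power = np.abs(hilbert(filt))
    power = gaussian_filter1d(power, smooth_ms / 1000.0 * lfp.rate)
    mu, sd = power.mean(), power.std()
    if sd == 0:
        return []
    z = (power - mu) / sd
    hi = z > hi_sd
    lo = z > lo_sd
    events: list[RippleEvent] = []
    d = np.diff(hi.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if hi.size and hi[0]:
        starts = np.r_[0, starts]
    if hi.size and hi[-1]:
        stops = np.r_[stops, hi.size]
    last_stop = -1.0
    for a, b in zip(starts, stops):
        a2 = a
        while a2 > 0 and lo[a2 - 1]:
            a2 -= 1
        b2 = b
        while b2 < lo.size and lo[b2]:
            b2 += 1
        t0, t1 = lfp.t[a2], lfp.t[min(b2, lo.size - 1)]
        if t0 <= last_stop:
            continue
        if dur_range[0] <= (t1 - t0) <= dur_range[1]:
            events.append(RippleEvent(float(t0), float(t1), float(z[a:b].max())))
            last_stop = t1
    return events


def classify_theta_state(
    lfp: LfpChannel,
    trajectory: TrajectorySession,
    speed_floor: float = 10.0,
    theta_band: tuple[float, float] = THETA_BAND,
    broad_band: tuple[float, float] = (2.0, 15.0),
) -> np.ndarray:
    """Boolean theta-state series on the LFP time base.

    Theta state requires running speed > ``speed_floor`` and a theta power
    ratio (7-10 Hz)/(2-15 Hz) above its session median.
    """
    sos_t = _bandpass_sos(*theta_band, lfp.rate)
    sos_b = _bandpass_sos(*broad_band, lfp.rate)
    pt = np.abs(hilbert(sosfiltfilt(sos_t, lfp.samples)))
    pb = np.abs(hilbert(sosfiltfilt(sos_b, lfp.samples)))
    # smooth at the theta timescale for a stable instantaneous ratio
    w = int(lfp.rate * 0.5)
    kern = np.ones(w) / w
    pt = np.convolve(pt**2, kern, mode="same")
    pb = np.convolve(pb**2, kern, mode="same")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pb > 0, pt / pb, 0.0)
    med = np.median(ratio)
    vel = trajectory.velocity_at(lfp.t)
    return (vel > speed_floor) & (ratio > med)


def events_to_table(events) -> "pandas.DataFrame":
    """BED-like interval table (start, stop, type, score) for any event list."""
    import pandas as pd

    rows = []
    for e in events:
        if isinstance(e, Frame):
            rows.append((e.start, e.stop, "frame", e.n_distinct_units))
        elif isinstance(e, RippleEvent):
            rows.append((e.start, e.stop, "ripple", e.peak_power_z))
        elif isinstance(e, ThetaCycle):
            rows.append((e.start, e.stop, "theta_cycle", e.n_active_units))
    return pd.DataFrame(rows, columns=["start", "stop", "type", "score"])
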