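"""Synthetic session generator with known ground truth.

Emulates the statistical structure the downstream analyses assume:

* run sessions with Gaussian place fields on the linearized square maze,
  theta-modulated phase-precessing spiking and a sinusoidal theta LFP;
* sleep sessions with low-rate background spiking plus burst "frames" in
  which template unit sequences fire in order (preplay / tuplet motifs);
* remapping plans (stable / plastic / elastic / random) between the
  pre-detour, detour and post-detour maps;
* optional "flicker" epochs during run in which spiking transiently
  follows an alternate (non-local) context's tuning.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
spec, so identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .session import (
    DETOUR_LENGTH,
    SEGMENT_LENGTH,
    LfpChannel,
    MazeConfig,
    Session,
    SessionSet,
    SpikeTrain,
    TrajectorySession,
)

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "gaussian_tuning",
    "generate_run_session",
    "generate_sleep_session",
    "apply_remapping_plan",
    "inject_flicker",
    "make_session_set",
]

BIN_CM = 2.0


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic recording day.

    Defaults emulate the recorded regime: tens of simultaneously held CA1
    pyramidal units, ~10 cm place-field sigma with 5-20 Hz peaks, ~30 cm/s
    running over >= 10 laps, 8 Hz theta with phase precession, and sleep
    frames of 100-1200 ms containing >= 5 distinct units.
    """

    n_units: int = 40
    fields_per_unit: int = 2
    field_sigma_cm: float = 10.0
    peak_rate_range: tuple[float, float] = (5.0, 20.0)
    run_speed: float = 30.0  # cm/s
    n_laps: int = 10  # end-to-end traversals, alternating direction
    pause_s: float = 2.0  # immobility at each end of the maze
    theta_freq: float = 8.0  # Hz, within the 7-10 Hz band
    theta_kappa: float = 2.0  # von Mises phase concentration of spiking
    precession_slope_deg_per_cm: float = -6.0  # ~240 deg across a 40 cm field
    precession_onset_deg: float = 330.0  # field-entry phase; declines through the field
    lfp_rate: float = 1250.0
    lfp_noise_sd: float = 0.3  # relative to unit theta amplitude
    sleep_duration_s: float = 300.0
    # tonic rate between frames; non-REM population activity concentrates in
    # frames (up-state bursts), so the tonic floor is near-silent
    sleep_background_hz: float = 0.05
    frame_rate_per_min: float = 8.0
    frame_duration_range: tuple[float, float] = (0.2, 0.5)  # s, within 0.1-1.2
    frame_spikes_per_unit: float = 3.0
    frame_jitter_ms: float = 8.0
    participation_prob: float = 1.0
    time_compression: float = 10.0  # run sequence -> frame sequence speed-up
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    true_maps: dict = field(default_factory=dict)  # direction -> (n_units, n_bins)
    field_params: list = field(default_factory=list)  # (unit, center, sigma, peak)
    frames: list = field(default_factory=list)  # (start, stop, ordered unit ids)
    unit_labels: dict = field(default_factory=dict)  # unit -> stable|plastic|elastic|remap
    flicker_epochs: list = field(default_factory=list)  # (start, stop)
    theta_epochs: list = field(default_factory=list)  # (start, stop) of running bouts
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Tuning curves
# ---------------------------------------------------------------------------

def gaussian_tuning(
    n_units: int,
    length: float,
    rng: np.random.Generator,
    sigma: float = 10.0,
    peak_range: tuple[float, float] = (5.0, 20.0),
    fields_per_unit: int = 2,
    bin_cm: float = BIN_CM,
) -> tuple[np.ndarray, list]:
    """Sum-of-Gaussians rate maps on [0, length) cm.

    Returns (rates: (n_units, n_bins) Hz, field parameter list).
    """
    n_bins = int(round(length / bin_cm))
    x = (np.arange(n_bins) + 0.5) * bin_cm
    rates = np.zeros((n_units, n_bins))
    params = []
    for i in range(n_units):
        for _ in range(fields_per_unit):
            c = rng.uniform(0, length)
            p = rng.uniform(*peak_range)
            rates[i] += p * np.exp(-0.5 * ((x - c) / sigma) ** 2)
            params.append((i, c, sigma, p))
    return rates, params


def _tuning_at(rates: np.ndarray, pos: np.ndarray, bin_cm: float = BIN_CM) -> np.ndarray:
    """Rates of every unit at each position: (n_units, len(pos))."""
    idx = np.clip((pos / bin_cm).astype(int), 0, rates.shape[1] - 1)
    return rates[:, idx]


# ---------------------------------------------------------------------------
# Run sessions
# ---------------------------------------------------------------------------

def _lap_trajectory(spec: GeneratorSpec, length: float, dt: float):
    """Ping-pong trajectory over [0, length]: odd laps clockwise (direction 1)."""
    sweep = length / spec.run_speed
    seg_t, seg_x, seg_run = [], [], []
    t0 = 0.0
    for lap in range(spec.n_laps):
        n = int(round(sweep / dt))
        tt = t0 + np.arange(n) * dt
        frac = np.arange(n) / n
        x = frac * length if lap % 2 == 0 else (1 - frac) * length
        seg_t.append(tt)
        seg_x.append(x)
        seg_run.append(np.ones(n, bool))
        t0 = tt[-1] + dt
        npause = int(round(spec.pause_s / dt))
        if npause:
            tt = t0 + np.arange(npause) * dt
            seg_t.append(tt)
            seg_x.append(np.full(npause, length if lap % 2 == 0 else 0.0))
            seg_run.append(np.zeros(npause, bool))
            t0 = tt[-1] + dt
    return np.concatenate(seg_t), np.concatenate(seg_x), np.concatenate(seg_run)


def generate_run_session(
    spec: GeneratorSpec,
    maze: MazeConfig,
    session_id: str,
    tuning: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Session, GroundTruth]:
    """Simulate one run session: trajectory, spikes, LFP, and ground truth.

    Spikes are an inhomogeneous Poisson process with rate
    ``place_tuning(x) * vonmises_gain(theta_phase - preferred_phase)``
    where the preferred phase advances linearly with distance travelled into
    the nearest field (phase precession), so phase and position are coupled
    rather than independently jittered.
    """
    rng = spec.rng() if rng is None else rng
    length = maze.total_length
    if tuning is None:
        tuning, params = gaussian_tuning(
            spec.n_units, length, rng, spec.field_sigma_cm,
            spec.peak_rate_range, spec.fields_per_unit,
        )
    else:
        params = []
    if spec.n_laps <= 0:
        raise ValueError("config error: lap count must be positive")
    if not np.any(tuning.sum(axis=0) > 0) and np.any(tuning < 0):
        raise ValueError("config error: invalid tuning")

    dt = 1e-3
    t, x, running = _lap_trajectory(spec, length, dt)
    theta_phase = (2 * np.pi * spec.theta_freq * t) % (2 * np.pi)

    # preferred phase per unit per time: precession through the nearest field
    field_centers = np.zeros(spec.n_units)
    for (i, c, s, p) in params:
        field_centers[i] = c  # last field wins; only used for precession anchor
    slope = np.deg2rad(spec.precession_slope_deg_per_cm)
    onset = np.deg2rad(spec.precession_onset_deg)

    rates = _tuning_at(tuning, x)  # (n_units, n_t)
    rates = rates * running  # no place-driven spiking while paused
    # distance travelled into the field, signed by running direction, so the
    # preferred phase advances with progress through the field either way
    heading = np.sign(np.gradient(x))
    heading[heading == 0] = 1.0
    dist_into = heading[None, :] * (x[None, :] - field_centers[:, None]) \
        + 2 * spec.field_sigma_cm
    pref = onset + slope * dist_into
    # von Mises phase gain, normalized to unit mean so rates are conserved
    from scipy.special import i0

    kappa = spec.theta_kappa
    gain = np.exp(kappa * np.cos(theta_phase[None, :] - pref)) / i0(kappa)
    lam = rates * gain * dt
    spikes_bool = rng.random(lam.shape) < lam

    spike_trains = {}
    for i in range(spec.n_units):
        st = t[spikes_bool[i]]
        # sub-millisecond dither keeps times unique without breaking order
        st = np.sort(st + rng.uniform(0, dt * 0.9, st.size))
        spike_trains[i] = SpikeTrain(i, st)

    # 30 Hz trajectory
    stride = int(round((1 / 30.0) / dt))
    t30 = t[::stride]
    x30 = x[::stride]
    pos2d = maze.point_at(x30)
    vel = np.abs(np.gradient(x30, t30))
    track, seg = maze.segment_of(x30)
    direction = np.where(np.gradient(x30) >= 0, 1, 2).astype(np.int64)
    traj = TrajectorySession(
        t=t30, pos_2d=pos2d, lin_pos=x30, track_id=track,
        segment_id=seg, direction=direction, velocity=vel,
    )

    # LFP: theta sinusoid during running, attenuated while immobile, + noise
    nl = int(round(t[-1] * spec.lfp_rate))
    tl = np.arange(nl) / spec.lfp_rate
    run_l = np.interp(tl, t, running.astype(float)) > 0.5
    amp = np.where(run_l, 1.0, 0.2)
    lfp = amp * np.cos(2 * np.pi * spec.theta_freq * tl)
    lfp = lfp + rng.normal(0, spec.lfp_noise_sd, nl)
    lfp_ch = LfpChannel(t=tl, samples=lfp, rate=spec.lfp_rate)

    # theta (running) epochs ground truth
    edges = np.flatnonzero(np.diff(running.astype(int)))
    bounds = np.concatenate([[0], edges + 1, [len(t)]])
    epochs = [
        (t[a], t[b - 1])
        for a, b in zip(bounds[:-1], bounds[1:])
        if running[a]
    ]

    gt = GroundTruth(
        true_maps={"both": tuning}, field_params=params, theta_epochs=epochs,
        meta={"session_id": session_id, "seed": spec.seed},
    )
    sess = Session(session_id, "run", spike_trains, traj, lfp_ch, maze)
    return sess, gt


# ---------------------------------------------------------------------------
# Sleep sessions
# ---------------------------------------------------------------------------

def generate_sleep_session(
    spec: GeneratorSpec,
    templates: Sequence[Sequence[int]] | None = None,
    rng: np.random.Generator | None = None,
    maze: MazeConfig | None = None,
    session_id: str = "Sleep",
    markov_model=None,
) -> tuple[Session, GroundTruth]:
    """Simulate sleep: low-rate background plus sequential burst frames.

    Each injected frame draws a template (an ordered unit-ID sequence), keeps
    every unit independently with ``participation_prob``, tops the member set
    up to >= 5 distinct units, and places each member's spikes around evenly
    spaced centers of mass spanning the frame, in template order.  If
    ``markov_model`` is a fitted :class:`~placeseq.motifs.MarkovSequenceModel`
    the templates are instead sampled from it per frame.
    """
    rng = spec.rng() if rng is None else rng
    maze = maze or MazeConfig(session_id=session_id)
    dur = spec.sleep_duration_s
    units = np.arange(spec.n_units)
    if templates:
        for tpl in templates:
            if np.any(np.asarray(tpl) >= spec.n_units):
                raise ValueError("config error: template references unknown unit")

    # background homogeneous Poisson
    trains = {}
    for i in range(spec.n_units):
        n = rng.poisson(spec.sleep_background_hz * dur)
        trains[i] = list(rng.uniform(0, dur, n))

    n_frames = rng.poisson(spec.frame_rate_per_min * dur / 60.0)
    starts = np.sort(rng.uniform(2.0, dur - 2.0, n_frames))
    if starts.size:
        # enforce >= 1.5 s separation so frames never merge
        keep = np.concatenate([[True], np.diff(starts) > 1.5])
        starts = starts[keep]
    frames_truth = []
    for s0 in starts:
        d = rng.uniform(*spec.frame_duration_range)
        if markov_model is not None:
            L = int(rng.integers(6, 10))
            seq = list(markov_model.sample_sequence(L, rng))
        elif templates:
            seq = list(templates[rng.integers(len(templates))])
        else:
            seq = list(rng.choice(units, size=8, replace=False))
        part = [u for u in seq if rng.random() < spec.participation_prob]
        if len(part) < 5:  # top up preserving order with unused units
            extra = [u for u in rng.permutation(units) if u not in part]
            part = part + extra[: 5 - len(part)]
        K = len(part)
        coms = s0 + (np.arange(K) + 0.5) / K * d
        jit = spec.frame_jitter_ms / 1000.0
        for u, c in zip(part, coms):
            nsp = max(1, rng.poisson(spec.frame_spikes_per_unit))
            tt = rng.normal(c, jit, nsp)
            trains[int(u)].extend(np.clip(tt, s0, s0 + d))
        frames_truth.append((float(s0), float(s0 + d), [int(u) for u in part]))

    spike_trains = {
        i: SpikeTrain(i, np.sort(np.asarray(ts))) for i, ts in trains.items()
    }

    # immobile trajectory (sleep box) so frame detection has a velocity series
    t30 = np.arange(0, dur, 1 / 30.0)
    traj = TrajectorySession(
        t=t30, pos_2d=np.zeros((t30.size, 2)), lin_pos=np.zeros(t30.size),
        track_id=np.zeros(t30.size, np.int64),
        segment_id=np.full(t30.size, "sleep-box"),
        direction=np.zeros(t30.size, np.int64), velocity=np.zeros(t30.size),
    )

    # broadband LFP with 160 Hz ripple bursts at frame starts
    nl = int(dur * spec.lfp_rate)
    tl = np.arange(nl) / spec.lfp_rate
    lfp = rng.normal(0, 1.0, nl)
    for (s0, s1, _u) in frames_truth:
        m = (tl >= s0) & (tl < s0 + 0.08)
        lfp[m] += 4.0 * np.sin(2 * np.pi * 160.0 * tl[m])
    lfp_ch = LfpChannel(t=tl, samples=lfp, rate=spec.lfp_rate)

    gt = GroundTruth(frames=frames_truth, meta={"session_id": session_id, "seed": spec.seed})
    return Session(session_id, "sleep", spike_trains, traj, lfp_ch, maze), gt


# ---------------------------------------------------------------------------
# Remapping plans
# ---------------------------------------------------------------------------

def apply_remapping_plan(
    maps_pre: np.ndarray,
    plan: dict,
    rng: np.random.Generator,
    sigma: float = 10.0,
    peak_range: tuple[float, float] = (5.0, 20.0),
    fields_per_unit: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive detour and post-detour maps from the pre-detour maps.

    ``plan`` gives fractions ``{"stable": s, "plastic": p, "elastic": e}``
    (sum <= 1; the remainder remaps randomly in both sessions):

    * stable  : pre == det == post
    * plastic : det is a fresh random map, post == det (change persists)
    * elastic : det is a fresh random map, post == pre (change reverts)
    * remap   : det and post are two independent fresh maps

    Returns (maps_det, maps_post, labels).
    """
    fr = {k: plan.get(k, 0.0) for k in ("stable", "plastic", "elastic")}
    if sum(fr.values()) > 1 + 1e-9:
        raise ValueError("plan fractions must sum to <= 1")
    n_units, n_bins = maps_pre.shape
    length = n_bins * BIN_CM

    def fresh(n):
        m, _ = gaussian_tuning(n, length, rng, sigma, peak_range, fields_per_unit)
        return m

    counts = {k: int(round(v * n_units)) for k, v in fr.items()}
    labels = (
        ["stable"] * counts["stable"]
        + ["plastic"] * counts["plastic"]
        + ["elastic"] * counts["elastic"]
    )
    labels += ["remap"] * (n_units - len(labels))
    labels = np.array(labels[:n_units])
    rng.shuffle(labels)

    maps_det = maps_pre.copy()
    maps_post = maps_pre.copy()
    for lab in ("plastic", "elastic", "remap"):
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:
            continue
        new = fresh(idx.size)
        maps_det[idx] = new
        if lab == "plastic":
            maps_post[idx] = new
        elif lab == "remap":
            maps_post[idx] = fresh(idx.size)
        # elastic: post stays at pre
    return maps_det, maps_post, labels


# ---------------------------------------------------------------------------
# Flicker injection
# ---------------------------------------------------------------------------

def inject_flicker(
    session: Session,
    tuning_local: np.ndarray,
    tuning_alt: np.ndarray,
    epochs: Sequence[tuple[float, float]] | None,
    spec: GeneratorSpec,
    rng: np.random.Generator,
    segment_bounds: tuple[float, float] | None = None,
    alt_bounds: tuple[float, float] | None = None,
    n_epochs_per_lap: int = 0,
    epoch_dur: float = 0.1,
    theta_locked: bool = False,
    epoch_gain: float = 3.0,
) -> tuple[Session, GroundTruth]:
    """Replace spiking inside chosen run epochs with alternate-context tuning.

    During each epoch the current position is mapped proportionally onto the
    alternate segment and every unit's spikes are redrawn from its alternate
    tuning there, so a concatenated-template decoder sees the non-local
    context.  If ``epochs`` is None they are placed randomly (optionally with
    midpoints locked to theta-phase 0, the LFP peak).
    """
    traj = session.trajectory
    assert traj is not None
    if epochs is None:
        epochs = []
        on_segment = np.ones(traj.t.size, bool)
        if segment_bounds is not None:
            on_segment = (traj.lin_pos >= segment_bounds[0] + 10) & \
                         (traj.lin_pos < segment_bounds[1] - 10)
        run_t = traj.t[(traj.velocity > 10.0) & on_segment]
        if run_t.size and n_epochs_per_lap > 0:
            n_total = n_epochs_per_lap * spec.n_laps
            cand = np.sort(rng.choice(run_t, size=min(n_total, run_t.size), replace=False))
            for c in cand:
                if theta_locked:
                    # midpoint at a theta peak: phase 0 of cos(2 pi f t)
                    per = 1.0 / spec.theta_freq
                    c = np.round(c / per) * per
                epochs.append((float(c - epoch_dur / 2), float(c + epoch_dur / 2)))
    epochs = sorted(epochs)

    lo_c, hi_c = segment_bounds if segment_bounds else (0.0, traj.lin_pos[np.isfinite(traj.lin_pos)].max())
    lo_a, hi_a = alt_bounds if alt_bounds else (lo_c, hi_c)
    dt = 1e-3
    new_trains = {}
    for u, st in session.spikes.items():
        times = st.times
        keep = np.ones(times.size, bool)
        added = []
        for (e0, e1) in epochs:
            keep &= ~((times >= e0) & (times < e1))
            tt = np.arange(e0, e1, dt)
            x = traj.lin_pos_at(tt)
            frac = np.clip((x - lo_c) / max(hi_c - lo_c, 1e-9), 0, 1)
            x_alt = lo_a + frac * (hi_a - lo_a)
            # flicker events are coordinated population bursts, so the
            # alternate tuning is expressed with elevated gain
            lam = epoch_gain * _tuning_at(tuning_alt[u][None, :], x_alt)[0] * dt
            added.extend(tt[rng.random(tt.size) < lam])
        new_times = np.sort(np.concatenate([times[keep], np.asarray(added)]))
        new_trains[u] = SpikeTrain(u, new_times, st.label)
    gt = GroundTruth(flicker_epochs=list(epochs), meta={"seed": spec.seed})
    out = Session(session.session_id, session.kind, new_trains, traj, session.lfp, session.maze)
    return out, gt


# ---------------------------------------------------------------------------
# Whole-day bundles
# ---------------------------------------------------------------------------

def make_session_set(
    spec: GeneratorSpec,
    detour_track_run2: int = 2,
    detour_track_run3: int = 4,
    remap_plan: dict | None = None,
    preplay_detour: bool = True,
) -> tuple[SessionSet, dict]:
    """Generate the full alternating Sleep1..Run4 day.

    Run1/Run4 use the plain square maze; Run2 and Run3 carry the two detours.
    Sleep2 frames embed forward preplay of the Run2 detour-segment place-map
    sequence when ``preplay_detour`` is set.  Returns the SessionSet plus a
    ground-truth dict keyed by session id.
    """
    rng = spec.rng()
    remap_plan = remap_plan or {"stable": 0.6, "plastic": 0.2, "elastic": 0.2}

    maze_plain = MazeConfig(session_id="plain")
    maze_det2 = MazeConfig(session_id="det2", detoured_track=detour_track_run2)
    maze_det3 = MazeConfig(session_id="det3", detoured_track=detour_track_run3)

    maps_pre, params = gaussian_tuning(
        spec.n_units, maze_plain.total_length, rng, spec.field_sigma_cm,
        spec.peak_rate_range, spec.fields_per_unit,
    )
    maps_det, maps_post, labels = apply_remapping_plan(
        maps_pre, remap_plan, rng, spec.field_sigma_cm,
        spec.peak_rate_range, spec.fields_per_unit,
    )

    def extend(maps, maze):
        """Pad plain-maze maps to the detoured maze length with fresh detour tuning."""
        nb = int(round(maze.total_length / BIN_CM))
        out = np.zeros((spec.n_units, nb))
        det = maze.detoured_track
        lo, hi = maze.segment_bounds(det, "detour")
        blo, bhi = int(lo / BIN_CM), int(hi / BIN_CM)
        det_maps, _ = gaussian_tuning(
            spec.n_units, hi - lo, rng, spec.field_sigma_cm,
            spec.peak_rate_range, 1,
        )
        # copy plain-maze tuning outside the detour, offsetting past it
        plain_lo, plain_hi = maze_plain.segment_bounds(det, "mobile")
        pl, ph = int(plain_lo / BIN_CM), int(plain_hi / BIN_CM)
        out[:, :blo] = maps[:, :pl]
        out[:, blo:bhi] = det_maps
        out[:, bhi:] = maps[:, ph:]
        return out

    maps_run2 = extend(maps_det, maze_det2)
    maps_run3 = extend(maps_det, maze_det3)

    truth: dict[str, GroundTruth] = {}
    sessions: dict[str, Session] = {}

    def run(sid, maze, tuning):
        s, g = generate_run_session(spec, maze, sid, tuning=tuning, rng=rng)
        g.true_maps = {"both": tuning}
        sessions[sid], truth[sid] = s, g

    def sleep(sid, templates):
        s, g = generate_sleep_session(spec, templates, rng=rng, session_id=sid)
        sessions[sid], truth[sid] = s, g

    # preplay template: detour-segment place-map order of Run2 tuning
    det_lo, det_hi = maze_det2.segment_bounds(detour_track_run2, "detour")
    blo, bhi = int(det_lo / BIN_CM), int(det_hi / BIN_CM)
    det_rates = maps_run2[:, blo:bhi]
    active = np.flatnonzero(det_rates.max(axis=1) > 2.0)
    order = active[np.argsort(det_rates[active].argmax(axis=1))]
    preplay_tpl = [list(map(int, order[:10]))] if (preplay_detour and order.size >= 5) else None

    sleep("Sleep1", None)
    run("Run1", maze_plain, maps_pre)
    sleep("Sleep2", preplay_tpl)
    run("Run2", maze_det2, maps_run2)
    sleep("Sleep3", preplay_tpl)
    run("Run3", maze_det3, maps_run3)
    sleep("Sleep4", None)
    run("Run4", maze_plain, maps_post)

    sset = SessionSet(
        sessions=sessions,
        meta={
            "seed": spec.seed,
            "detour_track_run2": detour_track_run2,
            "detour_track_run3": detour_track_run3,
            "remap_plan": remap_plan,
        },
    )
    truth["labels"] = labels
    truth["maps"] = {"pre": maps_pre, "det": maps_det, "post": maps_post,
                     "run2": maps_run2, "run3": maps_run3}
    truth["preplay_template"] = preplay_tpl[0] if preplay_tpl else []
    return sset, truth
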