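"""Theta-sequence statistics: quadrant ratio, phase locking/precession,
spike jittering, CCG temporal bias, and the matched-false-positive
comparison of theta-sequence versus waking-rest replay emergence.

The quadrant ratio scores one theta cycle's decoded posterior after
recentring the spatial axis on the animal's current position (within
+/- 40 cm) and orienting it along the running direction.  With the cycle
split at its temporal midpoint, quadrant 1 holds future-time/ahead mass and
quadrant 3 past-time/behind mass:

    QR = (P(Q1) + P(Q3) - P(Q2) - P(Q4)) / (P(Q1) + P(Q2) + P(Q3) + P(Q4))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, wilcoxon

from .decoding import Posterior
from .session import SpikeTrain

__all__ = [
    "QuadrantResult",
    "CcgBias",
    "quadrant_ratio",
    "theta_sequence_test",
    "phase_locking",
    "rayleigh_test",
    "phase_precession",
    "jitter_spikes",
    "ccg_bias",
    "ccg_curve_similarity",
    "emergence_comparison",
]

QR_WINDOW_CM = 40.0
MIN_CYCLE_UNITS = 3  # "more than 3 neurons" gate applied by callers as > 3


@dataclass
class QuadrantResult:
    qr: float
    n_active_units: int
    lap: int = -1
    position: float = np.nan


@dataclass
class CcgBias:
    unit_i: int
    unit_j: int
    bias_s: float
    window_s: float
    n_pairs: int


# ---------------------------------------------------------------------------


def quadrant_ratio(
    posterior: Posterior | np.ndarray,
    current_pos_cm: float,
    direction: int = 1,
    window_cm: float = QR_WINDOW_CM,
    bin_cm: float = 2.0,
) -> float:
    """Quadrant ratio of one cycle posterior recentred on the animal.

    Spatial bins within +/- ``window_cm`` of ``current_pos_cm`` are kept and
    expressed as ahead/behind along the running direction (direction 2 flips
    the axis).  Time is split at the cycle's temporal midpoint.  Returns NaN
    if no posterior mass falls inside the window.
    """
    if isinstance(posterior, Posterior):
        P = posterior.prob
        bin_cm = posterior.bin_cm
    else:
        P = np.asarray(posterior, float)
    nx, nt = P.shape
    if nt < 2:
        return np.nan
    centers = (np.arange(nx) + 0.5) * bin_cm
    rel = centers - current_pos_cm
    if direction == 2:
        rel = -rel
    inside = np.abs(rel) <= window_cm
    if not inside.any():
        return np.nan
    P = P[inside]
    rel = rel[inside]
    tmid = nt / 2.0
    tt = np.arange(nt) + 0.5
    future = tt >= tmid
    ahead = rel > 0
    q1 = P[np.ix_(ahead, future)].sum()  # ahead, future
    q3 = P[np.ix_(~ahead, ~future)].sum()  # behind, past
    q2 = P[np.ix_(ahead, ~future)].sum()
    q4 = P[np.ix_(~ahead, future)].sum()
    tot = q1 + q2 + q3 + q4
    if tot <= 0:
        return np.nan
    return float((q1 + q3 - q2 - q4) / tot)


def theta_sequence_test(qr_values, alpha: float = 0.05) -> tuple[float, bool]:
    """One-sided Wilcoxon signed-rank test for a positive quadrant-ratio
    population.  Returns (p-value, significant)."""
    qr = np.asarray([q for q in np.ravel(qr_values) if np.isfinite(q)])
    qr = qr[qr != 0]
    if qr.size < 5:
        return np.nan, False
    # continuity-corrected normal approximation: slightly conservative,
    # keeping the empirical false-positive rate at or below alpha
    p = float(wilcoxon(qr, alternative="greater", correction=True).pvalue)
    return p, p < alpha


# ---------------------------------------------------------------------------
# Phase statistics
# ---------------------------------------------------------------------------


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh Z test of circular non-uniformity: returns (Z, p)."""
    phases = np.asarray(phases, float)
    n = phases.size
    if n == 0:
        return np.nan, np.nan
    R = np.abs(np.exp(1j * phases).mean()) * n
    z = R**2 / n
    # Zar's approximation of the Rayleigh p-value
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def phase_locking(phases: np.ndarray, bin_deg: float = 20.0):
    """Rayleigh test + preferred phase from the peak of a 20-degree histogram.

    Returns (Z, p, preferred phase in radians at the peak bin center).
    """
    z, p = rayleigh_test(phases)
    nb = int(round(360.0 / bin_deg))
    edges = np.linspace(-np.pi, np.pi, nb + 1)
    h, _ = np.histogram(np.angle(np.exp(1j * np.asarray(phases))), bins=edges)
    if h.sum() == 0:
        return z, p, np.nan
    k = int(h.argmax())
    pref = 0.5 * (edges[k] + edges[k + 1])
    return z, p, float(pref)


def phase_precession(
    phases: np.ndarray, norm_positions: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of raw theta phase versus normalized in-field
    position (the linear, not circular-linear, variant).  Returns (r, p).

    Phases are expressed on [0, 2 pi) — the descending precession ramp from a
    late entry phase is then monotone and wrap-free across a typical field.
    """
    phases = np.mod(np.asarray(phases, float), 2 * np.pi)
    x = np.asarray(norm_positions, float)
    ok = np.isfinite(phases) & np.isfinite(x)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(phases[ok]) == 0:
        return np.nan, np.nan
    res = pearsonr(x[ok], phases[ok])
    return float(res.statistic), float(res.pvalue)


def circular_linear_precession(phases, norm_positions):
    """Circular-linear alternative: correlation of position with the phase
    projected onto its best-fitting line (exposed as an option)."""
    phases = np.asarray(phases, float)
    x = np.asarray(norm_positions, float)
    best_r, best_p = 0.0, 1.0
    for slope in np.linspace(-2, 2, 81) * 2 * np.pi:
        resid = np.angle(np.exp(1j * (phases - slope * x)))
        r, p = pearsonr(x, np.cos(resid))
        if abs(r) > abs(best_r):
            best_r, best_p = r, p
    return float(best_r), float(best_p)


# ---------------------------------------------------------------------------
# Jitter
# ---------------------------------------------------------------------------


def jitter_spikes(
    spikes: dict[int, SpikeTrain],
    half_range_ms: float,
    rng: np.random.Generator | None = None,
) -> dict[int, SpikeTrain]:
    """Independently shift every spike by U(-h, +h) (h in ms).

    Generate once per half-range and reuse for both the precession and the
    sequence analyses, so both see the same perturbed data.
    """
    rng = rng or np.random.default_rng(0)
    h = half_range_ms / 1000.0
    out = {}
    for u, st in spikes.items():
        if h == 0:
            out[u] = SpikeTrain(u, st.times.copy(), st.label)
        else:
            t = st.times + rng.uniform(-h, h, st.times.size)
            out[u] = SpikeTrain(u, np.sort(t), st.label)
    return out


# ---------------------------------------------------------------------------
# Cross-correlograms
# ---------------------------------------------------------------------------


def _ccg_deltas(ti: np.ndarray, tj: np.ndarray, window: float) -> np.ndarray:
    """All t_j - t_i differences within +/- window (seconds)."""
    out = []
    lo = np.searchsorted(tj, ti - window)
    hi = np.searchsorted(tj, ti + window)
    for a, b, t in zip(lo, hi, ti):
        if b > a:
            out.append(tj[a:b] - t)
    return np.concatenate(out) if out else np.empty(0)


def ccg_bias(
    spikes_i: SpikeTrain,
    spikes_j: SpikeTrain,
    window_s: float = 0.2,
    bin_ms: float = 5.0,
) -> CcgBias:
    """Center of mass of the cross-correlogram of a unit pair.

    Positive bias means unit j tends to fire after unit i.  Computed on a
    histogram with symmetric bins so bias(i, j) = -bias(j, i) exactly.
    """
    # canonical pair order makes bias(i, j) == -bias(j, i) exact (no
    # floating-point asymmetry from reversed accumulation order)
    if spikes_i.unit_id > spikes_j.unit_id:
        flipped = ccg_bias(spikes_j, spikes_i, window_s, bin_ms)
        return CcgBias(spikes_i.unit_id, spikes_j.unit_id,
                       -flipped.bias_s, window_s, flipped.n_pairs)
    d = _ccg_deltas(spikes_i.times, spikes_j.times, window_s)
    nb = int(round(2 * window_s / (bin_ms / 1000.0)))
    edges = np.linspace(-window_s, window_s, nb + 1)
    h, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if h.sum() == 0:
        return CcgBias(spikes_i.unit_id, spikes_j.unit_id, np.nan, window_s, 0)
    bias = float((h * centers).sum() / h.sum())
    return CcgBias(spikes_i.unit_id, spikes_j.unit_id, bias, window_s, int(h.sum()))


def ccg_curve_similarity(
    spikes_i_a, spikes_j_a, spikes_i_b, spikes_j_b,
    window_s: float = 1.0,
    bin_ms: float = 10.0,
    lowpass_hz: float = 0.5,
    min_peak_sd: float = 2.0,
    min_peak_count: float = 2.0,
):
    """Cosine similarity of a pair's low-pass-filtered CCG curves in two
    sessions; NaN unless both curves carry a significant peak
    (> mean + 2 SD and > 2 counts)."""
    from scipy.signal import butter, sosfiltfilt

    def curve(si, sj):
        d = _ccg_deltas(si.times, sj.times, window_s)
        nb = int(round(2 * window_s / (bin_ms / 1000.0)))
        h, _ = np.histogram(d, bins=np.linspace(-window_s, window_s, nb + 1))
        fs = 1000.0 / bin_ms
        sos = butter(2, lowpass_hz / (fs / 2), btype="low", output="sos") \
            if lowpass_hz < fs / 2 else None
        c = sosfiltfilt(sos, h.astype(float)) if sos is not None else h.astype(float)
        ok = h.max() > h.mean() + min_peak_sd * h.std() and h.max() > min_peak_count
        return c, ok

    ca, oka = curve(spikes_i_a, spikes_j_a)
    cb, okb = curve(spikes_i_b, spikes_j_b)
    if not (oka and okb):
        return np.nan
    na, nb_ = np.linalg.norm(ca), np.linalg.norm(cb)
    if na == 0 or nb_ == 0:
        return np.nan
    return float(ca @ cb / (na * nb_))


# ---------------------------------------------------------------------------
# Emergence comparison
# ---------------------------------------------------------------------------


def emergence_comparison(
    cycle_qrs: np.ndarray,
    cycle_times: np.ndarray,
    cycle_laps: np.ndarray,
    frame_times: np.ndarray,
    frame_significant: np.ndarray,
    frame_laps: np.ndarray,
    replay_false_positive_rate: float = 0.01,
    theta_alpha: float | None = None,
) -> dict:
    """First significant time/lap of theta sequences versus replay, at
    matched operating points.

    For every candidate replay frame, the quadrant ratios of all theta
    cycles preceding that frame are tested for positivity (one-sided
    signed-rank) at an alpha no larger than the replay detector's empirical
    false-positive rate, matching the number of tests between phenomena.
    """
    alpha = theta_alpha if theta_alpha is not None else replay_false_positive_rate
    order = np.argsort(frame_times)
    frame_times = np.asarray(frame_times)[order]
    frame_significant = np.asarray(frame_significant)[order]
    frame_laps = np.asarray(frame_laps)[order]

    theta_time = theta_lap = None
    for ft, fl in zip(frame_times, frame_laps):
        prior = cycle_times < ft
        p, sig = theta_sequence_test(np.asarray(cycle_qrs)[prior], alpha=alpha)
        if sig:
            theta_time, theta_lap = float(ft), int(fl)
            break
    replay_time = replay_lap = None
    hit = np.flatnonzero(frame_significant)
    if hit.size:
        replay_time = float(frame_times[hit[0]])
        replay_lap = int(frame_laps[hit[0]])
    return {
        "theta_time": theta_time, "theta_lap": theta_lap,
        "replay_time": replay_time, "replay_lap": replay_lap,
        "alpha_theta": alpha,
        "alpha_replay": replay_false_positive_rate,
    }
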