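"""Occupancy-normalized place maps, spatial information, stability and remapping.

Rate maps are the ratio of Gaussian-smoothed spike counts to Gaussian-smoothed
occupancy in 2 cm bins, restricted to samples with running speed above
10 cm/s; bins with less than 0.1 s of raw occupancy are masked.  Counts and
occupancy are smoothed separately before dividing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr, spearmanr

from .session import SpikeTrain, TrajectorySession, MazeConfig

__all__ = [
    "PlaceMapSet",
    "RemappingResult",
    "PlaceMapEstimator",
    "compute_place_maps",
    "spatial_information",
    "within_session_stability",
    "segment_pair_similarity",
    "population_vector_similarity",
    "sequence_rank_correlation",
    "bidirectionality",
]

SPEED_FLOOR = 10.0  # cm/s
OCC_FLOOR = 0.1  # s
BIN_CM = 2.0
SMOOTH_CM = 2.0
PEAK_GATE_HZ = 2.0


@dataclass
class PlaceMapSet:
    """Per-unit firing-rate maps over spatial bins for one session/direction."""

    rate: np.ndarray  # (n_units, n_bins) Hz
    occupancy: np.ndarray  # (n_bins,) s, raw (pre-smoothing)
    valid: np.ndarray  # (n_bins,) bool
    unit_ids: np.ndarray
    bin_cm: float = BIN_CM
    direction: int = 0
    segment_labels: np.ndarray | None = None
    smoothing_cm: float = SMOOTH_CM
    counts: np.ndarray | None = None  # raw per-unit spike counts per bin

    @property
    def n_units(self) -> int:
        return self.rate.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rate.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_cm

    def peak_rate(self) -> np.ndarray:
        r = np.where(self.valid[None, :], self.rate, 0.0)
        return r.max(axis=1)

    def peak_bin(self) -> np.ndarray:
        r = np.where(self.valid[None, :], self.rate, -np.inf)
        return r.argmax(axis=1)

    def slice_bins(self, lo_bin: int, hi_bin: int) -> "PlaceMapSet":
        return PlaceMapSet(
            rate=self.rate[:, lo_bin:hi_bin],
            occupancy=self.occupancy[lo_bin:hi_bin],
            valid=self.valid[lo_bin:hi_bin],
            unit_ids=self.unit_ids,
            bin_cm=self.bin_cm,
            direction=self.direction,
            segment_labels=None if self.segment_labels is None
            else self.segment_labels[lo_bin:hi_bin],
            smoothing_cm=self.smoothing_cm,
            counts=None if self.counts is None else self.counts[:, lo_bin:hi_bin],
        )

    def slice_segment(self, maze: MazeConfig, track: int, segment: str) -> "PlaceMapSet":
        lo, hi = maze.segment_bounds(track, segment)
        return self.slice_bins(int(round(lo / self.bin_cm)), int(round(hi / self.bin_cm)))


@dataclass
class RemappingResult:
    """Per-unit shifted-correlation values versus a cell-ID shuffle null."""

    correlations: np.ndarray  # per included unit
    shifts: np.ndarray  # bins, the shift achieving each correlation
    shuffle: np.ndarray  # pooled shuffle correlation values
    unit_ids: np.ndarray
    config_label: str = ""
    n_shuffles: int = 0

    def pvalue(self) -> float:
        """Rank-sum p for data correlations exceeding the shuffle null."""
        from scipy.stats import mannwhitneyu

        if self.correlations.size == 0 or self.shuffle.size == 0:
            return np.nan
        return float(
            mannwhitneyu(self.correlations, self.shuffle, alternative="greater").pvalue
        )


# ---------------------------------------------------------------------------


def _spike_positions(spikes: SpikeTrain, traj: TrajectorySession) -> np.ndarray:
    return traj.lin_pos_at(spikes.times)


def compute_place_maps(
    spikes: dict[int, SpikeTrain],
    trajectory: TrajectorySession,
    direction: int = 0,
    n_bins: int | None = None,
    bin_cm: float = BIN_CM,
    smooth_cm: float = SMOOTH_CM,
    speed_floor: float = SPEED_FLOOR,
    occ_floor: float = OCC_FLOOR,
    lap_mask: np.ndarray | None = None,
) -> PlaceMapSet:
    """Occupancy-normalized rate maps from spikes and a linearized trajectory.

    direction 0 pools both running directions; 1/2 restrict to one.
    ``lap_mask`` (optional, per trajectory sample) further restricts which
    samples contribute, used by the split-half stability computation.
    """
    t = trajectory.t
    ok = (trajectory.velocity > speed_floor) & np.isfinite(trajectory.lin_pos)
    if direction:
        ok &= trajectory.direction == direction
    if lap_mask is not None:
        ok &= lap_mask
    if not ok.any():
        raise ValueError("no running samples after velocity/direction filtering")

    if n_bins is None:
        n_bins = int(np.ceil(np.nanmax(trajectory.lin_pos) / bin_cm))
    edges = np.arange(n_bins + 1) * bin_cm
    dt = np.median(np.diff(t))
    occ, _ = np.histogram(trajectory.lin_pos[ok], bins=edges)
    occ = occ * dt

    # per-spike sample index -> apply the same filter to spikes
    unit_ids = np.array(sorted(spikes))
    counts = np.zeros((unit_ids.size, n_bins))
    idx_ok = np.flatnonzero(ok)
    for r, u in enumerate(unit_ids):
        st = spikes[u].times
        samp = np.clip(np.searchsorted(t, st) - 1, 0, t.size - 1)
        keep = np.isin(samp, idx_ok)
        pos = trajectory.lin_pos_at(st[keep])
        counts[r], _ = np.histogram(pos, bins=edges)

    sigma_bins = smooth_cm / bin_cm
    sm_counts = gaussian_filter1d(counts, sigma_bins, axis=1, mode="nearest")
    sm_occ = gaussian_filter1d(occ.astype(float), sigma_bins, mode="nearest")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(sm_occ > 0, sm_counts / sm_occ, 0.0)
    valid = occ >= occ_floor
    _, seg = trajectory.t, None
    return PlaceMapSet(
        rate=rate, occupancy=occ, valid=valid, unit_ids=unit_ids,
        bin_cm=bin_cm, direction=direction, smoothing_cm=smooth_cm, counts=counts,
    )


class PlaceMapEstimator:
    """Scikit-learn style wrapper: fit(spikes, trajectory) -> ``maps_``.

    Parameters mirror :func:`compute_place_maps`; after ``fit`` the
    per-direction maps are available as ``maps_`` (dict direction -> map set).
    """

    def __init__(self, bin_cm=BIN_CM, smooth_cm=SMOOTH_CM,
                 speed_floor=SPEED_FLOOR, occ_floor=OCC_FLOOR, directions=(1, 2)):
        self.bin_cm = bin_cm
        self.smooth_cm = smooth_cm
        self.speed_floor = speed_floor
        self.occ_floor = occ_floor
        self.directions = directions

    def get_params(self, deep=True):
        return {
            "bin_cm": self.bin_cm, "smooth_cm": self.smooth_cm,
            "speed_floor": self.speed_floor, "occ_floor": self.occ_floor,
            "directions": self.directions,
        }

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit(self, spikes, trajectory):
        self.maps_ = {
            d: compute_place_maps(
                spikes, trajectory, direction=d, bin_cm=self.bin_cm,
                smooth_cm=self.smooth_cm, speed_floor=self.speed_floor,
                occ_floor=self.occ_floor,
            )
            for d in self.directions
        }
        return self


# ---------------------------------------------------------------------------


def spatial_information(rate: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs spatial information in bits/spike.

    SI = sum_b p_b (f_b / F) log2(f_b / F) with p_b the occupancy fraction
    and F the occupancy-weighted mean rate.  Returns NaN for silent maps.
    """
    rate = np.asarray(rate, float)
    occupancy = np.asarray(occupancy, float)
    m = occupancy > 0
    p = occupancy[m] / occupancy[m].sum()
    f = rate[m]
    F = float(np.sum(p * f))
    if F <= 0:
        return np.nan
    ratio = f / F
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def _lap_ids(trajectory: TrajectorySession) -> np.ndarray:
    """Lap index per trajectory sample: increments at each direction reversal."""
    d = trajectory.direction.astype(int)
    change = np.concatenate([[0], (np.diff(d) != 0).astype(int)])
    # ignore reversals during immobility jitter: only count when moving
    change = change * (trajectory.velocity > SPEED_FLOOR)
    return np.cumsum(change)


def within_session_stability(
    spikes: dict[int, SpikeTrain],
    trajectory: TrajectorySession,
    n_repeats: int = 100,
    rng: np.random.Generator | None = None,
    **map_kw,
) -> np.ndarray:
    """Mean split-half cosine similarity of lap-wise place maps, per unit.

    Laps are randomly bipartitioned; the cosine similarity between the two
    half-session maps is averaged over ``n_repeats`` random splits.
    """
    rng = rng or np.random.default_rng(0)
    laps = _lap_ids(trajectory)
    uniq = np.unique(laps[trajectory.velocity > SPEED_FLOOR])
    if uniq.size < 2:
        raise ValueError("need >= 2 laps for split-half stability")
    unit_ids = np.array(sorted(spikes))
    sims = np.zeros((n_repeats, unit_ids.size))
    n_bins = int(np.ceil(np.nanmax(trajectory.lin_pos) / map_kw.get("bin_cm", BIN_CM)))
    for r in range(n_repeats):
        perm = rng.permutation(uniq)
        half = perm[: uniq.size // 2]
        m1 = np.isin(laps, half)
        a = compute_place_maps(spikes, trajectory, lap_mask=m1, n_bins=n_bins, **map_kw)
        b = compute_place_maps(spikes, trajectory, lap_mask=~m1, n_bins=n_bins, **map_kw)
        v = a.valid & b.valid
        for i in range(unit_ids.size):
            sims[r, i] = _cosine(a.rate[i, v], b.rate[i, v])
    return np.nanmean(sims, axis=0)


def _shifted_pearson(a: np.ndarray, b: np.ndarray, max_shift: int) -> tuple[float, int]:
    """Max Pearson r of a vs b over relative shifts in [-max_shift, max_shift]."""
    best, best_s = -np.inf, 0
    n = a.size
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            x, y = a[s:], b[: n - s]
        else:
            x, y = a[: n + s], b[-s:]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        r = pearsonr(x, y).statistic
        if r > best:
            best, best_s = r, s
    return (np.nan, 0) if best == -np.inf else (float(best), best_s)


def segment_pair_similarity(
    maps_a: PlaceMapSet,
    maps_b: PlaceMapSet,
    config_label: str = "",
    max_shift_bins: int = 2,
    n_shuffles: int = 1000,
    peak_gate: float = PEAK_GATE_HZ,
    rng: np.random.Generator | None = None,
) -> RemappingResult:
    """Per-unit shifted Pearson correlation between two segment map sets,
    compared against cell-ID shuffles.

    When the segments differ in length (stretched comparison) the caller is
    expected to have re-binned so the bin counts match; a mismatch here is an
    error.  Units require peak rate > ``peak_gate`` on at least one segment.
    """
    rng = rng or np.random.default_rng(0)
    if maps_a.n_bins != maps_b.n_bins:
        raise ValueError(
            f"bin count mismatch after resolution matching: "
            f"{maps_a.n_bins} vs {maps_b.n_bins}"
        )
    gate = (maps_a.peak_rate() > peak_gate) | (maps_b.peak_rate() > peak_gate)
    idx = np.flatnonzero(gate)
    cors = np.full(idx.size, np.nan)
    shifts = np.zeros(idx.size, int)
    for k, i in enumerate(idx):
        cors[k], shifts[k] = _shifted_pearson(maps_a.rate[i], maps_b.rate[i], max_shift_bins)
    # cell-ID shuffle: correlate unit i of A with a random other unit of B
    shuf = []
    for _ in range(n_shuffles):
        j = rng.permutation(idx)
        i = idx[rng.integers(idx.size)]
        jj = j[0] if j[0] != i else j[-1]
        r, _s = _shifted_pearson(maps_a.rate[i], maps_b.rate[jj], max_shift_bins)
        shuf.append(r)
    shuf = np.asarray(shuf)
    return RemappingResult(
        correlations=cors[np.isfinite(cors)],
        shifts=shifts,
        shuffle=shuf[np.isfinite(shuf)],
        unit_ids=maps_a.unit_ids[idx],
        config_label=config_label,
        n_shuffles=n_shuffles,
    )


def rebin_to(maps: PlaceMapSet, n_bins: int) -> PlaceMapSet:
    """Average-rebin a map set to ``n_bins`` (stretched-segment comparison,
    e.g. 150 cm at 6 cm bins versus 50 cm at 2 cm bins)."""
    old = maps.n_bins
    x_old = (np.arange(old) + 0.5) / old
    x_new = (np.arange(n_bins) + 0.5) / n_bins
    rate = np.vstack([np.interp(x_new, x_old, r) for r in maps.rate])
    occ = np.interp(x_new, x_old, maps.occupancy)
    valid = np.interp(x_new, x_old, maps.valid.astype(float)) > 0.5
    return PlaceMapSet(
        rate=rate, occupancy=occ, valid=valid, unit_ids=maps.unit_ids,
        bin_cm=maps.bin_cm * old / n_bins, direction=maps.direction,
    )


def population_vector_similarity(maps_a: PlaceMapSet, maps_b: PlaceMapSet) -> np.ndarray:
    """Cosine similarity between all spatial-bin pairs of two map sets.

    S[i, j] = cos(PV_A(i), PV_B(j)) where a PV is the vector of all units'
    rates at one bin.  Zero-rate bins give NaN (masked downstream).
    """
    if not np.array_equal(maps_a.unit_ids, maps_b.unit_ids):
        raise ValueError("unit registries differ")
    A = maps_a.rate  # (units, bins_a)
    B = maps_b.rate
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = (A.T @ B) / np.outer(na, nb)
    S[na == 0, :] = np.nan
    S[:, nb == 0] = np.nan
    return S


def sequence_rank_correlation(
    maps_ref: PlaceMapSet, maps_test: PlaceMapSet, peak_gate: float = PEAK_GATE_HZ
) -> tuple[float, float]:
    """Spearman rho between the peak-location orderings of two map sets."""
    gate = (maps_ref.peak_rate() > peak_gate) & (maps_test.peak_rate() > peak_gate)
    if gate.sum() < 3:
        return np.nan, np.nan
    pa = maps_ref.peak_bin()[gate]
    pb = maps_test.peak_bin()[gate]
    res = spearmanr(pa, pb)
    return float(res.statistic), float(res.pvalue)


def bidirectionality(maps_dir1: PlaceMapSet, maps_dir2: PlaceMapSet) -> np.ndarray:
    """Cosine similarity of the two directional maps, per unit."""
    v = maps_dir1.valid & maps_dir2.valid
    return np.array([
        _cosine(maps_dir1.rate[i, v], maps_dir2.rate[i, v])
        for i in range(maps_dir1.n_units)
    ])
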