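"""Alternate-context ("flickering") decoding during run.

Five segment templates compete in a concatenated Bayesian decode at 40 ms
bins: the two unchanged stationary segments, the current middle segment, the
alternative (absent) segment, and a length-matched control segment on the
opposite side of the maze.  Epochs where the smoothed summed probability of
one context exceeds 0.5 while the animal runs > 10 cm/s are "representing
epochs"; 40 ms bins with context probability > 0.9 and >= 3 active units
are "strong representations".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .decoding import Posterior, concatenated_decode
from .session import SpikeTrain, TrajectorySession
from .thetaseq import rayleigh_test
from .motifs import MarkovSequenceModel

__all__ = [
    "FlickerEpoch",
    "flicker_decode",
    "find_epochs",
    "strong_representation_bins",
    "phase_modulation",
    "spatiotemporal_pattern",
    "classify_flicker_cells",
    "flicker_sleep_prediction",
]

EPOCH_THRESHOLD = 0.5
STRONG_THRESHOLD = 0.9
STRONG_MIN_UNITS = 3
RUN_SPEED = 10.0


@dataclass
class FlickerEpoch:
    start: float
    stop: float
    context: str
    mean_probability: float
    n_active_units: int
    theta_phase_mid: float = np.nan

    @property
    def duration(self):
        return self.stop - self.start


def flicker_decode(
    spikes: dict[int, SpikeTrain],
    segment_templates: list[tuple[str, np.ndarray]],
    start: float,
    stop: float,
    tau: float = 0.04,
    min_active: int = 3,
    overlap: float = 0.0,
) -> tuple[Posterior, dict]:
    """Concatenated five-segment decode with per-context summed probability.

    ``segment_templates``: ordered (label, rates) for first-stationary,
    current, last-stationary, alternative, control.  Only bins with more
    than ``min_active`` active units enter downstream context probabilities
    (others are NaN-masked).  Returns (posterior, {label: prob series}).
    """
    post = concatenated_decode(
        spikes, segment_templates, start, stop, tau=tau,
        rescale=True, min_spikes=1, overlap=overlap,
    )
    ctx = post.context_probability()
    mask = post.n_active_units > min_active
    ctx = {lab: np.where(mask, p, np.nan) for lab, p in ctx.items()}
    return post, ctx


def find_epochs(
    prob: np.ndarray,
    time_centers: np.ndarray,
    trajectory: TrajectorySession,
    context: str = "alternative",
    threshold: float = EPOCH_THRESHOLD,
    smooth_bins: int = 1,
    speed_floor: float = RUN_SPEED,
    spikes: dict[int, SpikeTrain] | None = None,
) -> list[FlickerEpoch]:
    """Representing epochs: contiguous runs of smoothed probability above
    ``threshold`` with running speed above ``speed_floor``.

    ``smooth_bins`` is the moving-average width in decoding bins (one 40 ms
    bin by default, i.e. the 40 ms moving-average window).  The threshold is
    applied to the smoothed series, so boundary bins below it are excluded.
    """
    p = np.asarray(prob, float)
    if smooth_bins > 1:
        kern = np.ones(smooth_bins) / smooth_bins
        p = np.convolve(np.nan_to_num(p), kern, mode="same")
    vel = trajectory.velocity_at(time_centers)
    good = (p > threshold) & (vel > speed_floor) & np.isfinite(p)
    epochs: list[FlickerEpoch] = []
    d = np.diff(good.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if good.size and good[0]:
        starts = np.r_[0, starts]
    if good.size and good[-1]:
        stops = np.r_[stops, good.size]
    dt = np.median(np.diff(time_centers)) if time_centers.size > 1 else 0.04
    for a, b in zip(starts, stops):
        t0 = float(time_centers[a] - dt / 2)
        t1 = float(time_centers[b - 1] + dt / 2)
        n_act = 0
        if spikes is not None:
            n_act = len({
                u for u, st in spikes.items()
                if np.any((st.times >= t0) & (st.times < t1))
            })
        epochs.append(FlickerEpoch(
            t0, t1, context, float(np.nanmean(p[a:b])), n_act,
        ))
    return epochs


def strong_representation_bins(
    prob: np.ndarray,
    n_active_units: np.ndarray,
    threshold: float = STRONG_THRESHOLD,
    min_units: int = STRONG_MIN_UNITS,
) -> np.ndarray:
    """Boolean mask of 40 ms bins with context probability > 0.9 and at
    least ``min_units`` active units."""
    p = np.asarray(prob, float)
    return (p > threshold) & (np.asarray(n_active_units) >= min_units)


def phase_modulation(
    prob: np.ndarray,
    phases: np.ndarray,
    strong_mask: np.ndarray | None = None,
    n_phase_bins: int = 18,
    dof_fraction: float = 0.1,
) -> dict:
    """Theta-phase modulation of the context probability.

    Probability of each (possibly 90%-overlapping) window is assigned to the
    theta phase at the window midpoint.  Returns the phase-binned mean curve
    with s.e.m. whose degrees of freedom are corrected to ``dof_fraction`` of
    the window count (overlapping windows are not independent), plus a
    Rayleigh uniformity test on the phases of strong-representation bins.
    """
    p = np.asarray(prob, float)
    ph = np.asarray(phases, float)
    ok = np.isfinite(p) & np.isfinite(ph)
    edges = np.linspace(-np.pi, np.pi, n_phase_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = np.full(n_phase_bins, np.nan)
    sem = np.full(n_phase_bins, np.nan)
    idx = np.digitize(ph[ok], edges) - 1
    vals = p[ok]
    for b in range(n_phase_bins):
        v = vals[idx == b]
        if v.size:
            mean[b] = v.mean()
            n_eff = max(1.0, dof_fraction * v.size)
            sem[b] = v.std(ddof=0) / np.sqrt(n_eff)
    out = {"phase_centers": centers, "mean": mean, "sem": sem,
           "rayleigh_z": np.nan, "rayleigh_p": np.nan, "n_strong": 0}
    if strong_mask is not None:
        sp = ph[np.asarray(strong_mask, bool) & np.isfinite(ph)]
        out["n_strong"] = int(sp.size)
        if sp.size:
            z, pval = rayleigh_test(sp)
            out["rayleigh_z"], out["rayleigh_p"] = z, pval
    return out


def spatiotemporal_pattern(
    prob: np.ndarray,
    laps: np.ndarray,
    positions: np.ndarray,
    pos_edges: np.ndarray,
    corner_positions: np.ndarray | None = None,
) -> dict:
    """Lap x position matrix of the non-local probability and its first
    principal component.

    Returns PC1 spatial loadings and per-lap scores, plus (when
    ``corner_positions`` is given) the contrast of mean PC1 loading within
    20 cm of an entry corner versus beyond 40 cm.
    """
    laps = np.asarray(laps)
    uniq = np.unique(laps[laps >= 0])
    if uniq.size < 2:
        raise ValueError("need >= 2 laps for the lap x position pattern")
    nb = pos_edges.size - 1
    M = np.full((uniq.size, nb), np.nan)
    for r, lap in enumerate(uniq):
        m = laps == lap
        idx = np.digitize(positions[m], pos_edges) - 1
        v = np.asarray(prob)[m]
        for b in range(nb):
            sel = (idx == b) & np.isfinite(v)
            if sel.any():
                M[r, b] = v[sel].mean()
    filled = np.nan_to_num(M, nan=np.nanmean(M))
    pca = PCA(n_components=1)
    scores = pca.fit_transform(filled)[:, 0]
    loading = pca.components_[0]
    # deterministic sign: loading correlates positively with the mean profile
    if loading @ filled.mean(axis=0) < 0:
        loading, scores = -loading, -scores
    out = {"matrix": M, "pc1_loading": loading, "pc1_scores": scores,
           "explained_var": float(pca.explained_variance_ratio_[0])}
    if corner_positions is not None:
        centers = 0.5 * (pos_edges[:-1] + pos_edges[1:])
        dist = np.min(np.abs(centers[:, None] - corner_positions[None, :]), axis=1)
        near, far = dist < 20.0, dist > 40.0
        out["corner_contrast"] = (
            float(loading[near].mean() - loading[far].mean())
            if near.any() and far.any() else np.nan
        )
    return out


def classify_flicker_cells(
    spikes: dict[int, SpikeTrain],
    nonlocal_epochs: list[FlickerEpoch],
    local_epochs: list[FlickerEpoch],
) -> dict[int, str]:
    """Per-unit preference by majority of in-epoch spikes.

    Units spiking mostly inside non-local representing epochs are non-local
    class, mostly inside local epochs local class; zero in-epoch spikes
    leaves a unit unclassified.
    """

    def count_in(st, epochs):
        return sum(
            int(np.searchsorted(st.times, e.stop) - np.searchsorted(st.times, e.start))
            for e in epochs
        )

    out = {}
    for u, st in spikes.items():
        n_nl = count_in(st, nonlocal_epochs)
        n_lo = count_in(st, local_epochs)
        if n_nl + n_lo == 0:
            out[u] = "unclassified"
        else:
            out[u] = "non-local" if n_nl > n_lo else "local"
    return out


def flicker_sleep_prediction(
    epoch_sequences_nonlocal,
    epoch_sequences_local,
    model: MarkovSequenceModel,
    n_shuffles: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Normalized Markov probabilities of epoch spike sequences under the
    preceding sleep's model, compared non-local vs local (rank-sum).

    Sequences with fewer than 2 units are excluded.
    """
    from scipy.stats import mannwhitneyu

    rng = rng or np.random.default_rng(0)

    def score(seqs):
        vals = []
        for s in seqs:
            units = tuple(s.units) if hasattr(s, "units") else tuple(s)
            if len(units) < 2:
                continue
            vals.append(model.probability(units, normalized=True))
        return np.asarray(vals)

    a = score(epoch_sequences_nonlocal)
    b = score(epoch_sequences_local)
    p = np.nan
    if a.size and b.size:
        p = float(mannwhitneyu(a, b, alternative="greater").pvalue)
    return {"nonlocal": a, "local": b, "p_greater": p}
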