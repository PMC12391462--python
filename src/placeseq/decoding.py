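"""Memoryless Bayesian decoding of linear position and trajectory statistics.

The decoder is the canonical memoryless Poisson population decoder: for
spike counts n_i in a window of width tau and template rates f_i(x),

    P(x | n) ~ prod_i f_i(x)^{n_i} * exp(-tau * sum_i f_i(x))

with a uniform spatial prior, normalized over the included bins.  A small
floor (per-unit mean rate x 1e-5) is added to each template to avoid zero
probabilities.  Likelihoods accumulate in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .placefields import PlaceMapSet
from .session import SpikeTrain

__all__ = [
    "Posterior",
    "TrajectoryScore",
    "BayesianDecoder",
    "bin_spike_counts",
    "decode",
    "concatenated_decode",
    "weighted_correlation",
    "max_jump",
    "time_bin_shuffle_test",
    "classify_replay_direction",
]

RATE_FLOOR_SCALE = 1e-5
WC_THRESHOLD = 0.6
JUMP_THRESHOLD = 0.4


@dataclass
class Posterior:
    """Decoded posterior: (n_spatial_bins, n_time_bins) column-stochastic."""

    prob: np.ndarray
    time_edges: np.ndarray  # (n_time_bins + 1,) s
    bin_cm: float
    n_active_units: np.ndarray  # per time bin
    track_slices: dict = field(default_factory=dict)  # label -> (lo_bin, hi_bin)

    @property
    def n_time_bins(self) -> int:
        return self.prob.shape[1]

    @property
    def n_space_bins(self) -> int:
        return self.prob.shape[0]

    @property
    def time_centers(self) -> np.ndarray:
        return 0.5 * (self.time_edges[:-1] + self.time_edges[1:])

    def map_estimate(self) -> np.ndarray:
        """Peak decoded bin per time bin."""
        return self.prob.argmax(axis=0)

    def context_probability(self) -> dict:
        """Summed probability per labelled track slice, each (n_time_bins,)."""
        return {
            lab: self.prob[lo:hi].sum(axis=0)
            for lab, (lo, hi) in self.track_slices.items()
        }


@dataclass
class TrajectoryScore:
    weighted_correlation: float
    max_jump_norm: float
    shuffle_percentile: float
    significant: bool
    criterion: str = "wc_jump"


# ---------------------------------------------------------------------------


def bin_spike_counts(
    spikes: dict[int, SpikeTrain],
    start: float,
    stop: float,
    tau: float,
    unit_ids=None,
    overlap: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-count matrix (n_time_bins, n_units) and window edges.

    ``overlap`` in [0, 1) slides windows by ``tau * (1 - overlap)`` (used for
    theta-phase display analyses); 0 gives non-overlapping contiguous bins.
    """
    unit_ids = sorted(spikes) if unit_ids is None else list(unit_ids)
    step = tau * (1.0 - overlap)
    starts = np.arange(start, stop - tau + 1e-12, step)
    if starts.size == 0:
        starts = np.array([start])
    counts = np.zeros((starts.size, len(unit_ids)), dtype=np.int64)
    for j, u in enumerate(unit_ids):
        ts = spikes[u].times
        a = np.searchsorted(ts, starts)
        b = np.searchsorted(ts, starts + tau)
        counts[:, j] = b - a
    edges = np.append(starts, starts[-1] + tau)
    return counts, edges


class BayesianDecoder:
    """Scikit-learn style memoryless Poisson decoder.

    ``fit`` takes the template rates (a PlaceMapSet or a raw (n_units,
    n_bins) array); ``predict_proba`` maps spike-count windows to posterior
    columns; ``predict`` returns the MAP spatial bin.
    """

    def __init__(self, tau: float = 0.02, rate_floor_scale: float = RATE_FLOOR_SCALE):
        self.tau = tau
        self.rate_floor_scale = rate_floor_scale

    def get_params(self, deep=True):
        return {"tau": self.tau, "rate_floor_scale": self.rate_floor_scale}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit(self, templates, y=None):
        """templates: PlaceMapSet, rate array, or list of (label, rates) for
        concatenated multi-track decoding (optionally mean-rate rescaled)."""
        if isinstance(templates, PlaceMapSet):
            rates = templates.rate
            self.bin_cm_ = templates.bin_cm
            self.track_slices_ = {}
        elif isinstance(templates, np.ndarray):
            rates = templates
            self.bin_cm_ = 2.0
            self.track_slices_ = {}
        else:
            raise TypeError("templates must be a PlaceMapSet or ndarray; "
                            "use fit_concatenated for multi-track templates")
        self._finalize(rates)
        return self

    def fit_concatenated(self, labelled_templates, bin_cm: float = 2.0, rescale: bool = True):
        """Concatenate several track templates into one decoding space.

        ``labelled_templates``: sequence of (label, rates (n_units, n_bins)).
        With ``rescale`` each track's template is scaled so its mean firing
        rate matches the global mean, preventing rate-difference bias.
        """
        labels, mats = zip(*labelled_templates)
        mats = [np.asarray(m, float) for m in mats]
        if rescale:
            means = np.array([m.mean() for m in mats])
            target = means[means > 0].mean() if np.any(means > 0) else 1.0
            mats = [m * (target / mu) if mu > 0 else m for m, mu in zip(mats, means)]
        self.track_slices_ = {}
        lo = 0
        for lab, m in zip(labels, mats):
            self.track_slices_[lab] = (lo, lo + m.shape[1])
            lo += m.shape[1]
        self.bin_cm_ = bin_cm
        self._finalize(np.concatenate(mats, axis=1))
        return self

    def _finalize(self, rates: np.ndarray):
        rates = np.asarray(rates, dtype=float)
        mean_rate = rates.mean(axis=1, keepdims=True)
        floor = np.maximum(mean_rate, 1e-3) * self.rate_floor_scale
        self.rates_ = rates + floor
        self.log_rates_ = np.log(self.rates_)
        self.n_units_, self.n_bins_ = rates.shape

    def predict_proba(self, counts: np.ndarray, tau: float | None = None) -> np.ndarray:
        """Posterior matrix (n_space_bins, n_time_bins) from counts
        (n_time_bins, n_units); each column sums to 1."""
        tau = self.tau if tau is None else tau
        counts = np.atleast_2d(np.asarray(counts))
        log_lik = counts @ self.log_rates_ - tau * self.rates_.sum(axis=0)[None, :]
        log_post = log_lik - logsumexp(log_lik, axis=1, keepdims=True)
        return np.exp(log_post).T

    def predict(self, counts: np.ndarray, tau: float | None = None) -> np.ndarray:
        return self.predict_proba(counts, tau).argmax(axis=0)

    def decode_window(
        self,
        spikes: dict[int, SpikeTrain],
        start: float,
        stop: float,
        tau: float | None = None,
        unit_ids=None,
        min_spikes: int = 1,
        overlap: float = 0.0,
    ) -> Posterior:
        """Decode a time window; bins with fewer than ``min_spikes`` total
        spikes are dropped (the uniform-prior-dominated columns)."""
        tau = self.tau if tau is None else tau
        counts, edges = bin_spike_counts(spikes, start, stop, tau, unit_ids, overlap)
        active = (counts > 0).sum(axis=1)
        keep = counts.sum(axis=1) >= min_spikes
        prob = self.predict_proba(counts[keep], tau)
        kept_edges = np.append(edges[:-1][keep], edges[:-1][keep][-1] + tau) \
            if keep.any() else edges[:1]
        return Posterior(
            prob=prob, time_edges=kept_edges, bin_cm=self.bin_cm_,
            n_active_units=active[keep], track_slices=dict(self.track_slices_),
        )


def decode(
    spikes: dict[int, SpikeTrain],
    templates: PlaceMapSet,
    start: float,
    stop: float,
    tau: float = 0.02,
    min_spikes: int = 1,
) -> Posterior:
    """One-shot functional interface over :class:`BayesianDecoder`."""
    dec = BayesianDecoder(tau=tau).fit(templates)
    return dec.decode_window(spikes, start, stop, tau,
                             unit_ids=list(templates.unit_ids), min_spikes=min_spikes)


def concatenated_decode(
    spikes: dict[int, SpikeTrain],
    labelled_templates,
    start: float,
    stop: float,
    tau: float = 0.02,
    rescale: bool = True,
    unit_ids=None,
    min_spikes: int = 1,
    overlap: float = 0.0,
) -> Posterior:
    """Decode against several concatenated track templates competing for
    probability (mean-rate rescaled by default)."""
    dec = BayesianDecoder(tau=tau).fit_concatenated(labelled_templates, rescale=rescale)
    return dec.decode_window(spikes, start, stop, tau, unit_ids=unit_ids,
                             min_spikes=min_spikes, overlap=overlap)


# ---------------------------------------------------------------------------
# Trajectory statistics
# ---------------------------------------------------------------------------


def weighted_correlation(prob: np.ndarray | Posterior) -> float:
    """Linear correlation of time vs decoded location weighted by posterior mass.

    wc = cov_w(t, x) / sqrt(var_w(t) var_w(x)) over the (time-bin index,
    spatial-bin index) grid with the posterior as weights.  NaN when either
    weighted variance vanishes.
    """
    P = prob.prob if isinstance(prob, Posterior) else np.asarray(prob, float)
    if P.size == 0:
        return np.nan
    nx, nt = P.shape
    W = P.sum()
    if W <= 0:
        return np.nan
    x = np.arange(nx, dtype=float)[:, None]
    t = np.arange(nt, dtype=float)[None, :]
    mx = (P * x).sum() / W
    mt = (P * t).sum() / W
    cov = (P * (x - mx) * (t - mt)).sum() / W
    vx = (P * (x - mx) ** 2).sum() / W
    vt = (P * (t - mt) ** 2).sum() / W
    if vx <= 0 or vt <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vt))


def max_jump(prob: np.ndarray | Posterior, track_length_cm: float | None = None,
             bin_cm: float = 2.0) -> float:
    """Largest peak-location step between consecutive time bins, normalized
    by the track length."""
    if isinstance(prob, Posterior):
        bin_cm = prob.bin_cm
        if track_length_cm is None:
            track_length_cm = prob.n_space_bins * bin_cm
        P = prob.prob
    else:
        P = np.asarray(prob, float)
        if track_length_cm is None:
            track_length_cm = P.shape[0] * bin_cm
    if P.shape[1] < 2:
        return 0.0
    peaks = P.argmax(axis=0)
    return float(np.abs(np.diff(peaks)).max() * bin_cm / track_length_cm)


def time_bin_shuffle_test(
    prob: np.ndarray | Posterior,
    n_shuffles: int = 1000,
    criterion: str = "wc_jump",
    wc_threshold: float = WC_THRESHOLD,
    jump_threshold: float = JUMP_THRESHOLD,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    track_length_cm: float | None = None,
) -> TrajectoryScore:
    """Score a frame posterior against time-bin (column permutation) shuffles.

    criterion "wc_jump": significant iff |wc| > ``wc_threshold`` and
    normalized max jump < ``jump_threshold`` (the two-parameter rule).
    criterion "percentile": significant iff |wc| exceeds the (1 - alpha)
    quantile of the shuffled |wc| distribution.
    """
    rng = rng or np.random.default_rng(0)
    P = prob.prob if isinstance(prob, Posterior) else np.asarray(prob, float)
    wc = weighted_correlation(P)
    mj = max_jump(prob if isinstance(prob, Posterior) else P,
                  track_length_cm=track_length_cm)
    shuf = np.empty(n_shuffles)
    nt = P.shape[1]
    for k in range(n_shuffles):
        perm = rng.permutation(nt)
        shuf[k] = abs(weighted_correlation(P[:, perm]))
    pct = float(100.0 * np.mean(abs(wc) > shuf)) if np.isfinite(wc) else np.nan
    if criterion == "wc_jump":
        sig = bool(np.isfinite(wc) and abs(wc) > wc_threshold and mj < jump_threshold)
    elif criterion == "percentile":
        sig = bool(np.isfinite(wc) and pct >= 100 * (1 - alpha))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return TrajectoryScore(
        weighted_correlation=wc if np.isfinite(wc) else np.nan,
        max_jump_norm=mj, shuffle_percentile=pct, significant=sig,
        criterion=criterion,
    )


def classify_replay_direction(
    frame_spikes: dict[int, SpikeTrain],
    start: float,
    stop: float,
    templates_by_track: dict,
    tau: float = 0.02,
    run_direction: int = 1,
    **test_kw,
):
    """Assign a frame to the best track template and a forward/reverse label.

    ``templates_by_track``: {track_label: PlaceMapSet}.  The significant
    template with the highest |wc| wins; ties break toward higher |wc| then
    lower track label.  Positive wc under direction-1 convention is forward.
    Returns (direction_label, track_label, scores dict).
    """
    results = {}
    for lab in sorted(templates_by_track):
        tmpl = templates_by_track[lab]
        post = decode(frame_spikes, tmpl, start, stop, tau=tau)
        score = time_bin_shuffle_test(post, **test_kw)
        results[lab] = score
    sig = {k: v for k, v in results.items() if v.significant}
    if not sig:
        return "none", None, results
    best = max(sorted(sig), key=lambda k: abs(sig[k].weighted_correlation))
    wc = sig[best].weighted_correlation
    forward = (wc > 0) if run_direction == 1 else (wc < 0)
    return ("forward" if forward else "reverse"), best, results
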