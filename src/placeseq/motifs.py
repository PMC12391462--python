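"""First-order Markov sequence models, tuplet motifs and order statistics.

Each offline frame (or theta cycle) is reduced to an ordered sequence of
unit IDs sorted by the center of mass of each unit's spike times within the
event.  A first-order Markov model over these sequences has

    P2(x_i | x_{i-1}) = n(x_{i-1} x_i) / n(x_{i-1})        (transition)
    P1(x)             = n(x) / N                           (unconditional)

with maximum-likelihood counts pooled across frames.  To keep long-sequence
probabilities finite on finite samples, exact zeros in the transition matrix
are reset to its minimum non-zero value and exact ones to its maximum
non-one value.  A sequence x of length n scores

    Pr(x) = P1(x_1) * prod_{i>=2} P2(x_i | x_{i-1})

and the length-normalized score is the geometric mean Pr(x)^(1/n).
Significance compares Pr(x) with same-length random sequences (uniform over
units, no within-sequence repeats); above the 95th percentile is significant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest, spearmanr

from .brainstates import Frame, ThetaCycle

__all__ = [
    "FrameSequence",
    "Tuplet",
    "MarkovSequenceModel",
    "frame_sequence",
    "fit_transition_model",
    "sequence_probability",
    "sequence_significance",
    "predict_theta_cycles",
    "extract_tuplets",
    "tuplet_recruitment",
    "pairwise_order_matrix",
    "score_cycle_orders",
    "frame_cycle_rank_correlation",
]


@dataclass
class FrameSequence:
    """Ordered unit IDs of one event, by spike-time center of mass."""

    units: tuple
    source_id: str = ""

    def __len__(self):
        return len(self.units)


@dataclass
class Tuplet:
    units: tuple  # length 2 or 3
    count: int
    shuffle_p95: float
    significant: bool


def frame_sequence(event: Frame | ThetaCycle, source_id: str = "") -> FrameSequence:
    """Center-of-mass unit ordering of a frame or theta cycle.

    Each unit appears once at the mean of its spike times; center-of-mass
    ties break deterministically by unit ID.
    """
    by_unit: dict = {}
    for u, t in event.member_spikes:
        by_unit.setdefault(u, []).append(t)
    coms = sorted(((float(np.mean(ts)), u) for u, ts in by_unit.items()))
    return FrameSequence(tuple(u for _c, u in coms), source_id)


# ---------------------------------------------------------------------------
# Markov model
# ---------------------------------------------------------------------------


class MarkovSequenceModel:
    """Scikit-learn style first-order Markov model over unit sequences.

    After ``fit``: ``p1_`` (n_units,), ``p2_`` (n_units, n_units) with
    ``p2_[i, j] = P(next = j | current = i)``, plus raw ``counts_`` and a
    ``clipped_`` record of the zero/one resets.
    """

    def __init__(self, n_units: int | None = None):
        self.n_units = n_units

    def get_params(self, deep=True):
        return {"n_units": self.n_units}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit(self, sequences, y=None):
        seqs = [tuple(s.units) if isinstance(s, FrameSequence) else tuple(s)
                for s in sequences]
        if self.n_units is None:
            self.n_units = 1 + max((max(s) for s in seqs if s), default=-1)
        U = self.n_units
        counts1 = np.zeros(U)
        counts2 = np.zeros((U, U))
        n_trans = 0
        for s in seqs:
            for u in s:
                counts1[u] += 1
            for a, b in zip(s[:-1], s[1:]):
                counts2[a, b] += 1
                n_trans += 1
        if n_trans == 0:
            raise ValueError("no transitions: all sequences have length < 2")
        N = counts1.sum()
        self.counts_ = counts2
        self.unit_counts_ = counts1
        self.total_length_ = float(N)
        self.p1_ = counts1 / N
        with np.errstate(divide="ignore", invalid="ignore"):
            p2 = np.where(counts1[:, None] > 0, counts2 / counts1[:, None], 0.0)
        # finite-sample clipping: zeros -> min non-zero, ones -> max non-one
        nz = p2[p2 > 0]
        clipped = {"zeros": int((p2 == 0).sum()), "ones": int((p2 == 1).sum())}
        if nz.size:
            p2 = np.where(p2 == 0, nz.min(), p2)
        non_one = p2[p2 < 1]
        if non_one.size and (p2 == 1).any():
            p2 = np.where(p2 == 1, non_one.max(), p2)
        self.p2_ = p2
        self.clipped_ = clipped
        self.log_p1_ = np.log(np.where(self.p1_ > 0, self.p1_, np.nan))
        self.log_p2_ = np.log(p2)
        return self

    # -- scoring ------------------------------------------------------------

    def log_probability(self, sequence) -> float:
        s = tuple(sequence.units) if isinstance(sequence, FrameSequence) else tuple(sequence)
        lp = self.log_p1_[s[0]]
        for a, b in zip(s[:-1], s[1:]):
            lp += self.log_p2_[a, b]
        return float(lp)

    def probability(self, sequence, normalized: bool = False) -> float:
        s = tuple(sequence.units) if isinstance(sequence, FrameSequence) else tuple(sequence)
        lp = self.log_probability(s)
        if normalized:
            lp /= len(s)
        return float(np.exp(lp))

    def score(self, sequences) -> float:
        """Mean normalized log-probability (sklearn-style goodness)."""
        return float(np.mean([self.log_probability(s) / len(s) for s in sequences]))

    def _random_log_probs(self, length: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Log-probabilities of ``n`` uniformly random no-repeat sequences."""
        U = self.n_units
        # vectorized sampling without replacement via random-key argsort
        keys = rng.random((n, U))
        seqs = np.argsort(keys, axis=1)[:, :length]
        lp = self.log_p1_[seqs[:, 0]]
        for i in range(1, length):
            lp = lp + self.log_p2_[seqs[:, i - 1], seqs[:, i]]
        return lp

    def significance(
        self,
        sequence,
        n_shuffles: int = 500_000,
        rng: np.random.Generator | None = None,
    ) -> float:
        """Percentile (0-100) of the sequence's probability among same-length
        random sequences; > 95 is conventionally significant."""
        rng = rng or np.random.default_rng(0)
        s = tuple(sequence.units) if isinstance(sequence, FrameSequence) else tuple(sequence)
        lp = self.log_probability(s)
        null = self._random_log_probs(len(s), n_shuffles, rng)
        return float(100.0 * np.mean(lp > null))

    def cell_id_shuffled(self, rng: np.random.Generator | None = None) -> "MarkovSequenceModel":
        """Control model with unit identities permuted in P1/P2 (destroys any
        correspondence with tested sequences while keeping the spectrum)."""
        rng = rng or np.random.default_rng(0)
        perm = rng.permutation(self.n_units)
        out = MarkovSequenceModel(self.n_units)
        out.p1_ = self.p1_[perm]
        out.p2_ = self.p2_[np.ix_(perm, perm)]
        out.counts_ = self.counts_[np.ix_(perm, perm)]
        out.unit_counts_ = self.unit_counts_[perm]
        out.total_length_ = self.total_length_
        out.clipped_ = dict(self.clipped_)
        out.log_p1_ = np.log(np.where(out.p1_ > 0, out.p1_, np.nan))
        out.log_p2_ = np.log(out.p2_)
        return out

    def sample_sequence(self, length: int, rng: np.random.Generator) -> list:
        """Draw one no-repeat sequence from the chain (for generators)."""
        p1 = self.p1_ / self.p1_.sum()
        seq = [int(rng.choice(self.n_units, p=p1))]
        for _ in range(length - 1):
            p = self.p2_[seq[-1]].copy()
            p[seq] = 0.0
            if p.sum() <= 0:
                break
            seq.append(int(rng.choice(self.n_units, p=p / p.sum())))
        return seq


def fit_transition_model(sequences, n_units: int | None = None) -> MarkovSequenceModel:
    """Functional wrapper: fit the first-order model on frame sequences."""
    return MarkovSequenceModel(n_units).fit(sequences)


def sequence_probability(model: MarkovSequenceModel, sequence, normalized: bool = True):
    return model.probability(sequence, normalized=normalized)


def sequence_significance(model: MarkovSequenceModel, sequence,
                          n_shuffles: int = 500_000, rng=None) -> float:
    return model.significance(sequence, n_shuffles, rng)


def predict_theta_cycles(
    model: MarkovSequenceModel,
    cycle_sequences,
    n_shuffles: int = 10_000,
    min_units: int = 4,
    rng: np.random.Generator | None = None,
) -> dict:
    """Fraction of theta-cycle sequences significant under the sleep model.

    Cycles with more than ``min_units - 1`` active units (i.e. >= min_units)
    are scored; the population fraction above the 95th percentile is tested
    against the 5% chance level with a one-sided binomial test.
    """
    rng = rng or np.random.default_rng(0)
    seqs = [s for s in cycle_sequences if len(s) >= min_units]
    if not seqs:
        return {"fraction": np.nan, "n": 0, "p": np.nan, "percentiles": np.array([])}
    # group by length so each length's null is sampled once
    pcts = np.empty(len(seqs))
    by_len: dict[int, list[int]] = {}
    for k, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(k)
    for L, idx in by_len.items():
        null = np.sort(model._random_log_probs(L, n_shuffles, rng))
        for k in idx:
            lp = model.log_probability(seqs[k])
            pcts[k] = 100.0 * np.searchsorted(null, lp, side="left") / n_shuffles
    sig = pcts > 95.0
    frac = float(sig.mean())
    p = float(binomtest(int(sig.sum()), len(seqs), 0.05, alternative="greater").pvalue)
    return {"fraction": frac, "n": len(seqs), "p": p, "percentiles": pcts}


# ---------------------------------------------------------------------------
# Tuplets
# ---------------------------------------------------------------------------


def _subsequences(units: tuple, contiguous: bool = True):
    """Ordered 2- and 3-unit sub-sequences of one frame ordering."""
    out = []
    n = len(units)
    if contiguous:
        out.extend(tuple(units[i:i + 2]) for i in range(n - 1))
        out.extend(tuple(units[i:i + 3]) for i in range(n - 2))
    else:
        from itertools import combinations

        out.extend(combinations(units, 2))
        out.extend(combinations(units, 3))
    return out


def _shuffle_sleep(sequences, unit_weights: np.ndarray, rng: np.random.Generator):
    """Shuffle-sleep surrogate: per-frame unit count preserved, units drawn
    by weighted sampling without replacement from overall frame-participation
    frequencies, order random (destroys co-firing and order)."""
    U = unit_weights.size
    p = unit_weights / unit_weights.sum()
    out = []
    for s in sequences:
        k = min(len(s), U)
        out.append(tuple(rng.choice(U, size=k, replace=False, p=p)))
    return out


def extract_tuplets(
    sequences,
    n_units: int,
    n_shuffle_sleeps: int = 500,
    contiguous: bool = True,
    rng: np.random.Generator | None = None,
) -> list[Tuplet]:
    """Significantly repeated 2- and 3-unit ordered motifs in sleep frames.

    Candidates repeat >= 2 times in the real frames; each is significant if
    its repeat count exceeds the count in more than 95% of rate-matched
    shuffle sleeps.  Reversed orders are independently eligible.
    """
    rng = rng or np.random.default_rng(0)
    seqs = [tuple(s.units) if isinstance(s, FrameSequence) else tuple(s) for s in sequences]
    if not seqs:
        return []
    counts = Counter()
    for s in seqs:
        counts.update(_subsequences(s, contiguous))
    candidates = {k: c for k, c in counts.items() if c >= 2}
    if not candidates:
        return []
    weights = np.zeros(n_units)
    for s in seqs:
        for u in s:
            weights[u] += 1
    shuf_counts = {k: np.zeros(n_shuffle_sleeps) for k in candidates}
    for r in range(n_shuffle_sleeps):
        sh = _shuffle_sleep(seqs, weights, rng)
        c = Counter()
        for s in sh:
            c.update(_subsequences(s, contiguous))
        for k in candidates:
            shuf_counts[k][r] = c.get(k, 0)
    out = []
    for k, n in sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0])):
        p95 = float(np.percentile(shuf_counts[k], 95))
        out.append(Tuplet(k, n, p95, bool(n > p95)))
    return out


def tuplet_recruitment(
    tuplets: list[Tuplet],
    cycle_sequences,
    contiguous: bool = True,
) -> float:
    """Fraction of cycle sub-sequences that are significant sleep tuplets."""
    sig = {t.units for t in tuplets if t.significant}
    total = hits = 0
    for s in cycle_sequences:
        units = tuple(s.units) if isinstance(s, FrameSequence) else tuple(s)
        for sub in _subsequences(units, contiguous):
            total += 1
            hits += sub in sig
    return hits / total if total else 0.0


# ---------------------------------------------------------------------------
# Pairwise order consistency
# ---------------------------------------------------------------------------


def pairwise_order_matrix(sequences, n_units: int):
    """Antisymmetric order-probability matrix from frame orderings.

    ``M[i, j]`` = P(i fires before j | both active), with
    ``M[i, j] + M[j, i] = 1`` for observed pairs and NaN for unobserved ones.
    """
    before = np.zeros((n_units, n_units))
    both = np.zeros((n_units, n_units))
    for s in sequences:
        units = tuple(s.units) if isinstance(s, FrameSequence) else tuple(s)
        for a_idx in range(len(units)):
            for b_idx in range(a_idx + 1, len(units)):
                i, j = units[a_idx], units[b_idx]
                before[i, j] += 1
                both[i, j] += 1
                both[j, i] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(both > 0, before / np.maximum(both, 1), np.nan)
    M[both == 0] = np.nan
    return M


def score_cycle_orders(matrix: np.ndarray, cycle_sequences) -> float:
    """Mean order probability of all observed cycle pair orders, minus the
    0.5 chance level.  Positive means cycle orders agree with frame orders."""
    vals = []
    for s in cycle_sequences:
        units = tuple(s.units) if isinstance(s, FrameSequence) else tuple(s)
        for a in range(len(units)):
            for b in range(a + 1, len(units)):
                v = matrix[units[a], units[b]]
                if np.isfinite(v):
                    vals.append(v)
    if not vals:
        return np.nan
    return float(np.mean(vals) - 0.5)


def frame_cycle_rank_correlation(
    frame_sequences,
    cycle_sequences,
    min_common: int = 5,
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
) -> dict:
    """Spearman rank correlation of common-unit orderings between every
    (frame, cycle) pair with >= ``min_common`` shared units.

    A pair is significant when its correlation exceeds 95% of ``n_perm``
    order permutations; the significant fraction is tested against the 5%
    chance level (one-sided binomial).
    """
    rng = rng or np.random.default_rng(0)
    n_sig = n_pairs = 0
    for fs in frame_sequences:
        fu = tuple(fs.units) if isinstance(fs, FrameSequence) else tuple(fs)
        f_rank = {u: k for k, u in enumerate(fu)}
        for cs in cycle_sequences:
            cu = tuple(cs.units) if isinstance(cs, FrameSequence) else tuple(cs)
            common = [u for u in cu if u in f_rank]
            if len(common) < min_common:
                continue
            x = np.array([f_rank[u] for u in common], float)
            y = np.arange(len(common), dtype=float)
            rho = spearmanr(x, y).statistic
            null = np.empty(n_perm)
            for k in range(n_perm):
                null[k] = spearmanr(x, rng.permutation(y)).statistic
            n_pairs += 1
            n_sig += rho > np.percentile(null, 95)
    if n_pairs == 0:
        return {"fraction": np.nan, "n_pairs": 0, "p": np.nan}
    p = float(binomtest(int(n_sig), n_pairs, 0.05, alternative="greater").pvalue)
    return {"fraction": n_sig / n_pairs, "n_pairs": n_pairs, "p": p}
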