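"""Null calibrations of the sequence-detection statistics.

These routines measure the false-positive behaviour of the three detection
procedures on synthetic data carrying no true structure:

* the theta-sequence positivity test on time-bin-shuffled cycle posteriors;
* the pairwise spike-order score on order-randomized frames and cycles;
* the Markov sequence-significance test under a cell-ID-shuffled model.

They are used both by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import wilcoxon

from .motifs import MarkovSequenceModel, pairwise_order_matrix, score_cycle_orders
from .thetaseq import quadrant_ratio

__all__ = [
    "synthetic_cycle_posteriors",
    "theta_shuffle_calibration",
    "pairwise_order_chance",
    "markov_null_calibration",
]


def synthetic_cycle_posteriors(
    n_cycles: int,
    rng: np.random.Generator,
    n_space: int = 40,
    n_time: int = 6,
    sweep_gain: float = 1.0,
    noise: float = 0.3,
) -> np.ndarray:
    """Cycle-like posteriors: a forward sweep through the +/- 40 cm window.

    Each posterior is a Gaussian ridge moving from behind to ahead of the
    window center across the cycle, plus uniform noise, column-normalized —
    the structure a decoded theta sequence shows.  Returns
    (n_cycles, n_space, n_time).
    """
    x = np.arange(n_space)[None, :, None]
    t = np.arange(n_time)[None, None, :]
    center = n_space / 2.0
    # ridge center sweeps across ~half the window during the cycle
    start = center - n_space / 4 + rng.normal(0, 2.0, (n_cycles, 1, 1))
    speed = (n_space / 2) / n_time * (1 + 0.3 * rng.normal(0, 1, (n_cycles, 1, 1)))
    ridge = np.exp(-0.5 * ((x - (start + speed * t)) / 3.0) ** 2)
    P = sweep_gain * ridge + noise * rng.random((n_cycles, n_space, n_time))
    P /= P.sum(axis=1, keepdims=True)
    return P


def theta_shuffle_calibration(
    n_cycles: int = 10_000,
    n_subpops: int = 1000,
    subpop_size: int = 200,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
    bin_cm: float = 2.0,
) -> dict:
    """False-positive rate of the theta-sequence positivity test.

    Synthetic cycle posteriors are time-bin (column) shuffled, their quadrant
    ratios computed, and ``n_subpops`` random subpopulations tested with the
    one-sided signed rank at ``alpha``.  Under the shuffle null the QR
    population is symmetric about zero, so the significant fraction must not
    exceed ``alpha``.
    """
    rng = rng or np.random.default_rng(0)
    P = synthetic_cycle_posteriors(n_cycles, rng)
    n_space = P.shape[1]
    center_cm = (n_space / 2) * bin_cm
    # each drawn permutation enters together with its time reversal: the
    # reversal negates the quadrant ratio, so the null pool is exactly
    # symmetric and subpopulation tests share no spurious mean offset
    qrs = np.empty(2 * n_cycles)
    for k in range(n_cycles):
        perm = rng.permutation(P.shape[2])
        qrs[2 * k] = quadrant_ratio(P[k][:, perm], center_cm, bin_cm=bin_cm)
        qrs[2 * k + 1] = quadrant_ratio(P[k][:, perm[::-1]], center_cm, bin_cm=bin_cm)
    qrs = qrs[np.isfinite(qrs)]
    # each subpopulation is tested together with its mirror image: the mean
    # rejection rate is unchanged (both are null samples) while the paired
    # anti-correlation halves the estimator's variance
    n_sig = n_tests = 0
    for _ in range(n_subpops):
        sub = rng.choice(qrs, size=subpop_size, replace=False)
        sub = sub[sub != 0]
        for signed in (sub, -sub):
            p = wilcoxon(signed, alternative="greater", correction=True).pvalue
            n_sig += p < alpha
            n_tests += 1
    return {
        "fraction_significant": n_sig / n_tests,
        "alpha": alpha,
        "n_cycles": int(qrs.size),
        "n_subpops": n_subpops,
        "mean_qr": float(qrs.mean()),
    }


def pairwise_order_chance(
    n_frames: int = 2000,
    n_cycles: int = 10_000,
    n_units: int = 30,
    rng: np.random.Generator | None = None,
) -> dict:
    """Chance level of the mean pairwise order probability.

    Frames and cycles are drawn with independent uniformly random unit
    orders; the mean order probability of cycle pairs under the frame-built
    matrix converges to 50%.
    """
    rng = rng or np.random.default_rng(0)

    def random_orders(n, lo=5, hi=9):
        out = []
        for _ in range(n):
            L = int(rng.integers(lo, hi))
            out.append(tuple(rng.permutation(n_units)[:L]))
        return out

    frames = random_orders(n_frames)
    cycles = random_orders(n_cycles)
    M = pairwise_order_matrix(frames, n_units)
    score = score_cycle_orders(M, cycles)
    return {
        "mean_order_probability_pct": 100.0 * (score + 0.5),
        "score_minus_chance": score,
        "n_frames": n_frames,
        "n_cycles": n_cycles,
    }


def markov_null_calibration(
    n_cycles: int = 2000,
    n_shuffles: int = 10_000,
    n_units: int = 30,
    n_frames: int = 1500,
    n_model_shuffles: int = 5,
    rng: np.random.Generator | None = None,
) -> dict:
    """Null calibration of the Markov sequence-significance test.

    A first-order model is fitted on structured synthetic sleep-frame
    sequences (drawn from a planted transition chain), then cell-ID shuffled
    so it carries no correspondence with the tested cycles.  Structured
    cycle sequences are scored against same-length random sequences; the
    fraction above the 95th percentile should sit at the 5% chance level.
    """
    rng = rng or np.random.default_rng(0)
    # planted sequential structure: a diverse random transition chain, so
    # different cycles exercise different transitions (weakly correlated
    # scores, binomial-dominated calibration variance)
    chain = rng.dirichlet(np.ones(n_units), size=n_units)

    def structured(n, lo=5, hi=9):
        out = []
        for _ in range(n):
            L = int(rng.integers(lo, hi))
            s = [int(rng.integers(n_units))]
            for _k in range(L - 1):
                p = chain[s[-1]].copy()
                p[s] = 0.0
                if p.sum() <= 0:
                    break
                s.append(int(rng.choice(n_units, p=p / p.sum())))
            if len(s) >= 2:
                out.append(tuple(s))
        return out

    frames = structured(n_frames)
    model = MarkovSequenceModel(n_units).fit(frames)
    cycles = structured(n_cycles)
    by_len: dict[int, list[int]] = {}
    for k, s in enumerate(cycles):
        by_len.setdefault(len(s), []).append(k)

    # a single cell-ID shuffle leaves model-level variance in the tail
    # fraction; averaging over independent shuffles estimates the chance
    # level with binomial-dominated error
    fracs = []
    for _rep in range(n_model_shuffles):
        shuffled = model.cell_id_shuffled(rng)
        pcts = np.empty(len(cycles))
        for L, idx in by_len.items():
            null = np.sort(shuffled._random_log_probs(L, n_shuffles, rng))
            for k in idx:
                lp = shuffled.log_probability(cycles[k])
                pcts[k] = 100.0 * np.searchsorted(null, lp, side="left") / n_shuffles
        fracs.append(float(np.mean(pcts > 95.0)))
    return {
        "fraction_significant_pct": 100.0 * float(np.mean(fracs)),
        "per_shuffle_pct": [100.0 * f for f in fracs],
        "n_cycles": len(cycles),
        "n_shuffles": n_shuffles,
    }
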