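"""Cross-session remapping: plastic/elastic indices, session-pair similarity
groups, PCA cell assemblies with the Marchenko-Pastur bound, regression
variance decomposition, and sleep-based prediction of drift vs stable
sequences.

The plastic/elastic index of a unit (or assembly) compares its post-detour
tuning with its detour and pre-detour tunings on the preserved stationary
segments:

    index = cos(post, det) - cos(post, pre)   in [-1, 1]

+1 means the detour change persisted (plastic), -1 that it reverted
(elastic), ~0 stable or random.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .motifs import MarkovSequenceModel
from .session import SpikeTrain

__all__ = [
    "PlasticElasticResult",
    "AssemblyDetector",
    "plastic_elastic",
    "session_pair_similarity_groups",
    "assembly_activation",
    "assembly_similarity_across_sessions",
    "regression_variance_explained",
    "drift_stable_prediction",
    "bin_zscore",
]

PE_THRESHOLD = 0.3  # |index| above which a unit is classified plastic/elastic
DRIFT_CUT = 0.3  # Run1-vs-Run4 map correlation cut for drift vs stable


def _cos(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


@dataclass
class PlasticElasticResult:
    index: np.ndarray  # per unit
    label: np.ndarray  # plastic | elastic | neutral
    threshold: float


def plastic_elastic(
    pre: np.ndarray, det: np.ndarray, post: np.ndarray,
    threshold: float = PE_THRESHOLD,
) -> PlasticElasticResult:
    """Plastic/elastic index and classification per unit.

    Inputs are nonnegative tuning matrices (n_units, n_features) on the
    concatenated stationary segments.  index > +threshold -> plastic,
    index < -threshold -> elastic, otherwise neutral.
    """
    pre, det, post = (np.atleast_2d(np.asarray(m, float)) for m in (pre, det, post))
    if not (pre.shape == det.shape == post.shape):
        raise ValueError("tuning matrices must share shape")
    idx = np.array([
        _cos(post[i], det[i]) - _cos(post[i], pre[i]) for i in range(pre.shape[0])
    ])
    lab = np.where(idx > threshold, "plastic",
                   np.where(idx < -threshold, "elastic", "neutral"))
    lab = np.where(np.isfinite(idx), lab, "undefined")
    return PlasticElasticResult(index=idx, label=lab, threshold=threshold)


# ---------------------------------------------------------------------------
# Session-pair similarity groups
# ---------------------------------------------------------------------------

GROUPS = ("no-detour", "before-vs-detour", "after-vs-detour", "before-vs-after")


def session_pair_similarity_groups(
    tunings: dict[str, np.ndarray],
    detour_session: str,
    session_order: list[str] | None = None,
) -> "pandas.DataFrame":
    """Per-unit cosine similarity for every session pair, labelled by
    session lag and detour relation.

    ``tunings``: {session: (n_units, n_features)} stationary-segment vectors.
    Groups: pairs not straddling the detour session ("no-detour"),
    pre-detour vs detour, detour vs post, and pre vs post sessions.
    """
    import pandas as pd

    order = session_order or sorted(tunings)
    if len(order) < 2:
        raise ValueError("need >= 2 sessions")
    k_det = order.index(detour_session)
    rows = []
    for a, b in combinations(range(len(order)), 2):
        lag = b - a
        if b < k_det or a > k_det:
            grp = "no-detour"
        elif b == k_det:
            grp = "before-vs-detour"
        elif a == k_det:
            grp = "after-vs-detour"
        else:
            grp = "before-vs-after"
        A, B = tunings[order[a]], tunings[order[b]]
        for i in range(A.shape[0]):
            rows.append((order[a], order[b], lag, grp, i, _cos(A[i], B[i])))
    return pd.DataFrame(
        rows, columns=["session_a", "session_b", "lag", "group", "unit", "cosine"]
    )


# ---------------------------------------------------------------------------
# Cell assemblies
# ---------------------------------------------------------------------------


def bin_zscore(
    spikes: dict[int, SpikeTrain],
    start: float,
    stop: float,
    bin_s: float = 0.02,
    drop_silent: bool = True,
):
    """Z-scored binned spike matrix (n_units, n_bins) and the kept unit IDs.

    Silent (zero-variance) units cannot be z-scored and are dropped.
    """
    unit_ids = np.array(sorted(spikes))
    edges = np.arange(start, stop + bin_s, bin_s)
    n_bins = edges.size - 1
    M = np.zeros((unit_ids.size, n_bins))
    for r, u in enumerate(unit_ids):
        M[r], _ = np.histogram(spikes[u].times, bins=edges)
    sd = M.std(axis=1)
    keep = sd > 0 if drop_silent else np.ones(unit_ids.size, bool)
    Z = (M[keep] - M[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return Z, unit_ids[keep]


class AssemblyDetector:
    """PCA cell assemblies retained above the Marchenko-Pastur bound.

    fit(Z) on a z-scored (n_units, n_bins) matrix computes the correlation
    eigendecomposition; components with eigenvalue above
    ``(1 + sqrt(n_units / n_bins))**2`` are assemblies.  Fitted attributes:
    ``patterns_`` (n_assemblies, n_units; unit-norm, sign fixed so the
    largest-magnitude weight is positive), ``eigenvalues_``, ``mp_bound_``,
    ``members_`` (per assembly, units with weight > mean + 2 SD).
    transform(Z) returns assembly activation time series.
    """

    def __init__(self, member_sd: float = 2.0):
        self.member_sd = member_sd

    def get_params(self, deep=True):
        return {"member_sd": self.member_sd}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit(self, Z: np.ndarray, y=None):
        Z = np.asarray(Z, float)
        n_units, n_bins = Z.shape
        if n_units < 2:
            raise ValueError("need >= 2 units")
        if n_bins < n_units:
            raise ValueError("Marchenko-Pastur bound undefined: fewer bins than units")
        C = (Z @ Z.T) / n_bins
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.mp_bound_ = (1 + np.sqrt(n_units / n_bins)) ** 2
        keep = evals > self.mp_bound_
        pats = evecs[:, keep].T
        # deterministic sign: largest-magnitude weight positive
        for k in range(pats.shape[0]):
            if pats[k, np.argmax(np.abs(pats[k]))] < 0:
                pats[k] = -pats[k]
        self.patterns_ = pats
        self.eigenvalues_ = evals[keep]
        self.all_eigenvalues_ = evals
        self.members_ = [
            np.flatnonzero(w > w.mean() + self.member_sd * w.std()) for w in pats
        ]
        self.n_assemblies_ = pats.shape[0]
        return self

    def transform(self, Z: np.ndarray) -> np.ndarray:
        """Activation strength of each assembly per time bin:
        A_k(t) = z(t)^T (w w^T - diag) z(t); single-unit activity contributes
        nothing because the diagonal is removed."""
        Z = np.asarray(Z, float)
        out = np.empty((self.n_assemblies_, Z.shape[1]))
        for k, w in enumerate(self.patterns_):
            P = np.outer(w, w)
            np.fill_diagonal(P, 0.0)
            out[k] = np.einsum("it,ij,jt->t", Z, P, Z)
        return out

    def fit_transform(self, Z, y=None):
        return self.fit(Z).transform(Z)


def assembly_activation(pattern: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Activation time series for one weight vector (see AssemblyDetector)."""
    P = np.outer(pattern, pattern)
    np.fill_diagonal(P, 0.0)
    return np.einsum("it,ij,jt->t", Z, P, Z)


def assembly_similarity_across_sessions(
    patterns_a: np.ndarray, patterns_b: np.ndarray
) -> float:
    """Mean over assemblies of A of the max Pearson correlation with any
    assembly of B (row-max-then-average matching)."""
    if patterns_a.size == 0 or patterns_b.size == 0:
        return np.nan
    A = np.atleast_2d(patterns_a)
    B = np.atleast_2d(patterns_b)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = Ac @ Bc.T
    den = np.outer(np.linalg.norm(Ac, axis=1), np.linalg.norm(Bc, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(den > 0, num / den, np.nan)
    return float(np.nanmean(np.nanmax(R, axis=1)))


# ---------------------------------------------------------------------------
# Regression variance decomposition
# ---------------------------------------------------------------------------

REGRESSORS = ("Pre", "Det", "OT", "T1", "T3")


def regression_variance_explained(
    post: np.ndarray,
    regressors: dict[str, np.ndarray],
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Leave-one-regressor-out variance shares of the post-detour tunings.

    The post tuning matrix (n_units, n_features) is modeled as
    ``post = c0 + c1*Ave + sum_k beta_k * regressor_k`` with scalar
    coefficients shared across units, fit by least squares over all
    (unit, feature) observations.  ``Ave`` (grand-mean tuning across units)
    is built internally from Pre and Det.  The share of regressor k is

        var_k = (resid_without_k - resid_full) / resid_full

    with residuals as Frobenius norms.  A unit-identity shuffle (response
    rows permuted against regressor rows, ``n_shuffles`` times) gives each
    share's percentile.
    """
    rng = rng or np.random.default_rng(0)
    post = np.asarray(post, float)
    n_units, n_feat = post.shape
    for k in REGRESSORS:
        if k not in regressors:
            raise ValueError(f"missing regressor {k}")
    ave = 0.5 * (regressors["Pre"].mean(axis=0) + regressors["Det"].mean(axis=0))

    def design(perm=None):
        cols = [np.ones(n_units * n_feat), np.tile(ave, n_units)]
        for k in REGRESSORS:
            X = regressors[k]
            if perm is not None:
                X = X[perm]
            cols.append(X.ravel())
        return np.column_stack(cols)

    def resid_norm(X, y, drop=None):
        Xd = np.delete(X, drop, axis=1) if drop is not None else X
        coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        return float(np.linalg.norm(y - Xd @ coef))

    y = post.ravel()
    X = design()
    res_full = resid_norm(X, y)
    if res_full == 0:
        res_full = np.finfo(float).tiny
    shares = {}
    for i, k in enumerate(REGRESSORS):
        res_k = resid_norm(X, y, drop=2 + i)
        shares[k] = (res_k - res_full) / res_full

    shuf = {k: np.empty(n_shuffles) for k in REGRESSORS}
    for r in range(n_shuffles):
        perm = rng.permutation(n_units)
        Xs = design(perm)
        rf = resid_norm(Xs, y)
        rf = rf if rf > 0 else np.finfo(float).tiny
        for i, k in enumerate(REGRESSORS):
            shuf[k][r] = (resid_norm(Xs, y, drop=2 + i) - rf) / rf
    pct = {k: float(100.0 * np.mean(shares[k] > shuf[k])) for k in REGRESSORS}
    return {"shares": shares, "percentiles": pct, "resid_full": res_full}


# ---------------------------------------------------------------------------
# Drift / stable prediction
# ---------------------------------------------------------------------------


def drift_stable_prediction(
    run4_maps: np.ndarray,
    run1_maps: np.ndarray,
    sleep1_model: MarkovSequenceModel,
    sleep3_model: MarkovSequenceModel,
    peak_gate: float = 2.0,
    corr_cut: float = DRIFT_CUT,
    n_shuffles: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Score the Run4 drift and stable place-map sequences under the Sleep1
    and Sleep3 Markov models.

    Units with Run4 peak > ``peak_gate`` split into drift (Run1-Run4 map
    correlation < ``corr_cut``) and stable (> ``corr_cut``); each group,
    sorted by Run4 peak location, forms a sequence whose length-normalized
    probability and random-sequence percentile are computed under each model.
    """
    rng = rng or np.random.default_rng(0)
    run4_maps = np.asarray(run4_maps, float)
    run1_maps = np.asarray(run1_maps, float)
    peak = run4_maps.max(axis=1)
    corr = np.array([
        np.corrcoef(run1_maps[i], run4_maps[i])[0, 1]
        if run1_maps[i].std() > 0 and run4_maps[i].std() > 0 else np.nan
        for i in range(run4_maps.shape[0])
    ])
    eligible = peak > peak_gate
    drift = np.flatnonzero(eligible & (corr < corr_cut))
    stable = np.flatnonzero(eligible & (corr > corr_cut))

    def seq_of(idx):
        if idx.size < 2:
            return None
        return tuple(int(u) for u in idx[np.argsort(run4_maps[idx].argmax(axis=1))])

    out = {}
    for name, idx in (("stable", stable), ("drift", drift)):
        seq = seq_of(idx)
        entry = {"n_units": int(idx.size)}
        if seq is None:
            entry.update({"empty": True})
        else:
            for mname, model in (("Sleep1", sleep1_model), ("Sleep3", sleep3_model)):
                entry[mname] = {
                    "norm_prob": model.probability(seq, normalized=True),
                    "percentile": model.significance(seq, n_shuffles, rng),
                }
        out[name] = entry
    return out
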