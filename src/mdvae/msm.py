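"""Markov-state-model implied timescales from low-dimensional CVs.

CV trajectories (e.g. 2-D domain-angle coordinates) are discretised
with k-means; transitions are counted at a lag time tau with a sliding
window that never crosses concatenated-trajectory joins; the transition
matrix is the non-reversible maximum-likelihood (row-normalised)
estimate over the largest strongly connected set of states; relaxation
timescales follow from its eigenvalues as

    t_i(tau) = -tau / ln(lambda_i(tau)),

with lambda_1 the second-largest eigenvalue (the first is 1 for any
stochastic matrix).  Flat t(tau) across lags indicates Markovian
behaviour of the discretised dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "DiscreteTrajectory",
    "MSMResult",
    "kmeans_discretize",
    "count_transitions",
    "estimate_transition_matrix",
    "transition_eigenvalues",
    "implied_timescales",
    "bootstrap_timescale_ci",
]


@dataclass
class DiscreteTrajectory:
    """Per-frame cluster assignments with trajectory-segment boundaries.

    ``segment_lengths`` partitions the concatenated frame sequence so
    transition counting never crosses joins between trajectories.
    """

    assignments: np.ndarray
    n_clusters: int
    cluster_centers: np.ndarray | None = None
    segment_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.ndim != 1:
            raise ValueError("assignments must be 1-D")
        if self.assignments.size and (
            self.assignments.min() < 0 or self.assignments.max() >= self.n_clusters
        ):
            raise ValueError("assignments out of [0, n_clusters) range")
        if self.segment_lengths is None:
            self.segment_lengths = (self.assignments.size,)
        else:
            self.segment_lengths = tuple(int(n) for n in self.segment_lengths)
        if sum(self.segment_lengths) != self.assignments.size:
            raise ValueError("segment_lengths must partition the frame sequence")

    @property
    def segments(self) -> list[np.ndarray]:
        out, start = [], 0
        for n in self.segment_lengths:
            out.append(self.assignments[start : start + n])
            start += n
        return out


@dataclass
class MSMResult:
    """Transition-matrix estimate at one lag."""

    lag: int
    count_matrix: np.ndarray
    transition_matrix: np.ndarray
    active_states: np.ndarray
    eigenvalues: np.ndarray
    implied_timescales: np.ndarray  # NaN where lambda <= 0 or >= 1


def kmeans_discretize(
    cvs: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    segment_lengths: tuple[int, ...] | None = None,
) -> DiscreteTrajectory:
    """k-means (k-means++ init, 10 restarts, seeded) on the CV points."""
    from sklearn.cluster import KMeans

    cvs = np.atleast_2d(np.asarray(cvs, dtype=float))
    if cvs.shape[0] < n_clusters:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds n_frames={cvs.shape[0]}"
        )
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed)
    assignments = km.fit_predict(cvs)
    return DiscreteTrajectory(
        assignments=assignments,
        n_clusters=n_clusters,
        cluster_centers=km.cluster_centers_,
        segment_lengths=segment_lengths,
    )


def count_transitions(
    dtraj: DiscreteTrajectory, lag: int, mode: str = "sliding"
) -> np.ndarray:
    """Count matrix C[i, j] = number of (t, t+lag) assignment pairs.

    ``sliding`` uses every window; ``strided`` uses non-overlapping
    windows (step = lag).  Windows never cross segment boundaries.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    n = dtraj.n_clusters
    C = np.zeros((n, n), dtype=np.int64)
    any_window = False
    for seg in dtraj.segments:
        if len(seg) <= lag:
            continue
        any_window = True
        step = 1 if mode == "sliding" else lag
        src = seg[:-lag:step]
        dst = seg[lag::step]
        np.add.at(C, (src, dst), 1)
    if not any_window:
        raise ValueError(f"lag {lag} is too large for every trajectory segment")
    return C


def estimate_transition_matrix(
    counts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalised MLE over the largest strongly connected set.

    Returns (T, active_states); states outside the largest strongly
    connected component of the count graph are trimmed.
    """
    C = np.asarray(counts)
    if (C < 0).any():
        raise ValueError("counts must be non-negative")
    n = C.shape[0]
    graph = csr_matrix((C > 0).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    # keep only components with at least one observed transition
    sizes = np.array(
        [
            ((labels == c).sum(), C[np.ix_(labels == c, labels == c)].sum())
            for c in range(n_comp)
        ]
    )
    valid = sizes[:, 1] > 0
    if not valid.any():
        raise ValueError("no connected set with observed transitions")
    order = np.lexsort((sizes[:, 1], sizes[:, 0]))  # size, then counts
    best = order[::-1][np.argmax(valid[order[::-1]])]
    active = np.flatnonzero(labels == best)
    sub = C[np.ix_(active, active)].astype(float)
    rows = sub.sum(axis=1)
    T = sub / rows[:, None]
    return T, active


def transition_eigenvalues(T: np.ndarray) -> np.ndarray:
    """Eigenvalues sorted by descending real part; warns if the spectrum
    has a non-negligible imaginary component."""
    ev = np.linalg.eigvals(T)
    if np.abs(ev.imag).max(initial=0.0) > 1e-8:
        warnings.warn(
            "transition matrix has complex eigenvalues (|imag| > 1e-8)",
            stacklevel=2,
        )
    return ev.real[np.argsort(-ev.real)]


def _timescales_from_T(T: np.ndarray, lag: int, n_timescales: int) -> tuple[np.ndarray, np.ndarray]:
    ev = transition_eigenvalues(T)
    sub = ev[1 : n_timescales + 1]
    ts = np.full(n_timescales, np.nan)
    for i, lam in enumerate(sub):
        if 0.0 < lam < 1.0:
            ts[i] = -lag / np.log(lam)
        # lambda <= 0 or >= 1: undefined, left as NaN (flagged, not dropped)
    return ev, ts


def build_msm(dtraj: DiscreteTrajectory, lag: int, n_timescales: int = 1,
              mode: str = "sliding") -> MSMResult:
    """Count, estimate and diagonalise at a single lag."""
    C = count_transitions(dtraj, lag, mode=mode)
    T, active = estimate_transition_matrix(C)
    ev, ts = _timescales_from_T(T, lag, n_timescales)
    return MSMResult(
        lag=lag,
        count_matrix=C,
        transition_matrix=T,
        active_states=active,
        eigenvalues=ev,
        implied_timescales=ts,
    )


def implied_timescales(
    dtraj: DiscreteTrajectory,
    lags: list[int],
    n_timescales: int = 1,
    mode: str = "sliding",
    frame_time: float = 1.0,
) -> pd.DataFrame:
    """Implied-timescale table over lags.

    t_i(tau) = -tau / ln(lambda_i(tau)) for the i-th largest eigenvalue
    below 1; entries where lambda <= 0 or >= 1 are NaN.  ``frame_time``
    converts frame units to physical time (e.g. ns per frame).
    """
    rows = []
    for lag in lags:
        res = build_msm(dtraj, int(lag), n_timescales, mode=mode)
        row = {"lag": int(lag)}
        for i, t in enumerate(res.implied_timescales):
            row[f"t{i + 1}"] = t * frame_time
        rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_timescale_ci(
    dtraj: DiscreteTrajectory,
    lag: int,
    n_boot: int = 100,
    seed: int = 0,
    n_timescales: int = 1,
    confidence: float = 0.95,
) -> np.ndarray:
    """Percentile bootstrap confidence intervals for the implied
    timescales at one lag.

    With >= 5 trajectory segments, resamples whole segments (block
    bootstrap); otherwise falls back to resampling counted transition
    pairs, with a warning.  Deterministic given the seed.  Returns an
    (n_timescales, 2) array of (low, high); NaN rows where the
    timescale was undefined in too many resamples.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50 for stable percentiles")
    rng = np.random.default_rng(seed)
    segments = dtraj.segments
    use_blocks = len(segments) >= 5
    if not use_blocks:
        warnings.warn(
            "fewer than 5 trajectory segments; falling back to "
            "transition-pair bootstrap",
            stacklevel=2,
        )
        C0 = count_transitions(dtraj, lag)
        pairs = np.array(
            [(i, j) for i in range(C0.shape[0]) for j in range(C0.shape[1])]
        )
        weights = C0.ravel()
        total = int(weights.sum())
    samples = np.full((n_boot, n_timescales), np.nan)
    alpha = (1.0 - confidence) / 2.0
    for b in range(n_boot):
        try:
            if use_blocks:
                pick = rng.integers(0, len(segments), size=len(segments))
                boot = DiscreteTrajectory(
                    assignments=np.concatenate([segments[i] for i in pick]),
                    n_clusters=dtraj.n_clusters,
                    segment_lengths=tuple(len(segments[i]) for i in pick),
                )
                C = count_transitions(boot, lag)
            else:
                idx = rng.choice(len(pairs), size=total, p=weights / total)
                C = np.zeros_like(C0)
                np.add.at(C, (pairs[idx, 0], pairs[idx, 1]), 1)
            T, _ = estimate_transition_matrix(C)
            _, ts = _timescales_from_T(T, lag, n_timescales)
            samples[b] = ts
        except ValueError:
            continue  # disconnected resample; leave NaN
    lo = np.nanpercentile(samples, 100 * alpha, axis=0)
    hi = np.nanpercentile(samples, 100 * (1 - alpha), axis=0)
    return np.stack([lo, hi], axis=1)
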