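"""Encoder/decoder assessment metrics.

Encoder fidelity is measured as distance preservation: Euclidean
distances between frame pairs are computed in the input feature space
and in the latent space, and compared with the Spearman rank
correlation

    rho = 1 - 6 * sum(d_i^2) / (n (n^2 - 1))

(average ranks under ties, with a Pearson-of-ranks fallback because the
shortcut formula is biased when ties exist) and the Pearson correlation
of the paired distance lists.

Decoder fidelity uses the superposition RMSD between each frame and its
decode, plus two two-sample distances between the distributions of
RMSD-to-reference values of real versus decoded frames: the maximum
mean discrepancy (Gaussian kernel, unbiased estimator, median-heuristic
bandwidth) and the first Wasserstein (earth mover's) distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata, wasserstein_distance

from . import models as _models
from .features import FeatureMatrix, FeatureScaler, SplitIndex, inverse_transform
from .geometry import superposition_rmsd

__all__ = [
    "MetricReport",
    "spearman_distance_preservation",
    "pearson_distance_preservation",
    "superposition_rmsd",
    "decoder_rmsd_profile",
    "mmd",
    "emd",
    "benchmark_models",
]

DEFAULT_MAX_PAIRS = 100_000


@dataclass
class MetricReport:
    """All assessment metrics for one trained model (one replicate)."""

    spearman: float
    pearson: float
    mean_rmsd: float
    mmd: float
    emd: float
    per_frame_rmsd: np.ndarray = field(default=None)  # type: ignore[assignment]
    dope: float | None = None  # populated only via an external scorer hook
    metadata: dict = field(default_factory=dict)


def _paired_distances(
    high: np.ndarray, low: np.ndarray, max_pairs: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray]:
    n = high.shape[0]
    if low.shape[0] != n:
        raise ValueError("high- and low-dimensional arrays must have equal frame counts")
    if n < 3:
        raise ValueError("distance preservation needs at least 3 frames")
    n_pairs = n * (n - 1) // 2
    if n_pairs <= max_pairs:
        return pdist(high), pdist(low)
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n - 1, size=max_pairs)
    j = np.where(j >= i, j + 1, j)  # uniform over off-diagonal pairs
    dh = np.linalg.norm(high[i] - high[j], axis=1)
    dl = np.linalg.norm(low[i] - low[j], axis=1)
    return dh, dl


def _as_2d(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.values
    if isinstance(x, _models.LatentEmbedding):
        return x.points
    return np.atleast_2d(np.asarray(x, dtype=float))


def spearman_distance_preservation(
    high_dim, low_dim, max_pairs: int = DEFAULT_MAX_PAIRS, seed: int | None = 0
) -> float:
    """Spearman rho between paired inter-frame distances in the two
    spaces.  Returns NaN (with a warning) if either distance list is
    constant, where the correlation is undefined."""
    dh, dl = _paired_distances(_as_2d(high_dim), _as_2d(low_dim), max_pairs, seed)
    if np.ptp(dh) == 0 or np.ptp(dl) == 0:
        warnings.warn("all pairwise distances equal; Spearman undefined", stacklevel=2)
        return float("nan")
    rh = rankdata(dh)  # average ranks for ties
    rl = rankdata(dl)
    n = len(dh)
    ties = len(np.unique(dh)) < n or len(np.unique(dl)) < n
    if ties:
        # the 6*sum(d^2) shortcut is biased under ties
        return _pearson(rh, rl)
    d = rh - rl
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1.0)))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt(np.sum(x * x))
    sy = np.sqrt(np.sum(y * y))
    return float(np.sum(x * y) / (sx * sy))


def pearson_distance_preservation(
    high_dim, low_dim, max_pairs: int = DEFAULT_MAX_PAIRS, seed: int | None = 0
) -> float:
    """Pearson correlation between the paired distance lists."""
    dh, dl = _paired_distances(_as_2d(high_dim), _as_2d(low_dim), max_pairs, seed)
    if np.ptp(dh) == 0 or np.ptp(dl) == 0:
        warnings.warn("zero distance variance; Pearson undefined", stacklevel=2)
        return float("nan")
    return _pearson(dh, dl)


def pearson_correlation(x, y) -> float:
    """Plain Pearson correlation of two paired value lists."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; Pearson undefined", stacklevel=2)
        return float("nan")
    return _pearson(x, y)


def decoder_rmsd_profile(
    model: "_models.TrainedModel",
    features: FeatureMatrix | np.ndarray,
    scaler: FeatureScaler | None = None,
    allow_untrained: bool = False,
) -> tuple[np.ndarray, float]:
    """decode(encode(x)) reconstruction error per frame.

    Both the original and the reconstruction are inverse-scaled to Å and
    compared by superposition RMSD; returns (per-frame vector, mean).
    """
    if scaler is None:
        scaler = features.scaler if isinstance(features, FeatureMatrix) else model.scaler
    if scaler is None:
        raise ValueError("a FeatureScaler is required to decode to Å")
    values = _as_2d(features)
    z = _models.encode(model, values, allow_untrained=allow_untrained)
    recon = _models.decode(model, z.points, allow_untrained=allow_untrained)
    orig_xyz = inverse_transform(values, scaler)
    recon_xyz = inverse_transform(recon, scaler)
    rmsds = np.array(
        [superposition_rmsd(recon_xyz[i], orig_xyz[i]) for i in range(len(values))]
    )
    return rmsds, float(rmsds.mean())


# ---------------------------------------------------------------------------
# Two-sample distribution distances on the scalar RMSD proxy
# ---------------------------------------------------------------------------


def _median_heuristic(pooled: np.ndarray) -> float:
    d = np.abs(pooled[:, None] - pooled[None, :])
    med = float(np.median(d[np.triu_indices(len(pooled), k=1)]))
    return med if med > 0 else 1.0


def mmd(
    sample_p: np.ndarray,
    sample_q: np.ndarray,
    bandwidth: float | str = "median",
) -> float:
    """Maximum mean discrepancy between two scalar samples.

    Gaussian kernel k(a,b) = exp(-(a-b)^2 / (2 h^2)); h from the median
    pairwise distance of the pooled sample unless given.  Unbiased
    estimator of MMD^2, clamped at zero, square root returned.
    """
    p = np.asarray(sample_p, dtype=float).ravel()
    q = np.asarray(sample_q, dtype=float).ravel()
    if p.size == 0 or q.size == 0:
        raise ValueError("mmd requires non-empty samples")
    if bandwidth == "median":
        h = _median_heuristic(np.concatenate([p, q]))
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")

    def k(a, b):
        return np.exp(-((a[:, None] - b[None, :]) ** 2) / (2.0 * h * h))

    m, n = len(p), len(q)
    kpp = k(p, p)
    kqq = k(q, q)
    kpq = k(p, q)
    if m > 1:
        term_pp = (kpp.sum() - np.trace(kpp)) / (m * (m - 1))
    else:
        term_pp = 0.0
    if n > 1:
        term_qq = (kqq.sum() - np.trace(kqq)) / (n * (n - 1))
    else:
        term_qq = 0.0
    mmd2 = term_pp + term_qq - 2.0 * kpq.mean()
    return float(np.sqrt(max(mmd2, 0.0)))


def emd(sample_p: np.ndarray, sample_q: np.ndarray) -> float:
    """First Wasserstein distance between the empirical distributions
    (1-D sorted-quantile formulation)."""
    p = np.asarray(sample_p, dtype=float).ravel()
    q = np.asarray(sample_q, dtype=float).ravel()
    if p.size == 0 or q.size == 0:
        raise ValueError("emd requires non-empty samples")
    return float(wasserstein_distance(p, q))


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------


def evaluate_model(
    model: "_models.TrainedModel",
    features: FeatureMatrix,
    frame_subset: np.ndarray | None = None,
    reference: np.ndarray | None = None,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
    allow_untrained: bool = False,
) -> MetricReport:
    """Full metric report on a frame subset (default: all frames).

    MMD/EMD compare the RMSD-to-reference distributions of the real and
    the decoded frames (scalar RMSD proxy for tertiary structure); the
    reference defaults to frame 0 of the evaluated set.
    """
    values = features.values if frame_subset is None else features.values[frame_subset]
    emb = _models.encode(model, values, allow_untrained=allow_untrained)
    spearman = spearman_distance_preservation(values, emb.points, max_pairs, seed)
    pearson = pearson_distance_preservation(values, emb.points, max_pairs, seed)
    per_frame, mean_rmsd = decoder_rmsd_profile(
        model, values, features.scaler, allow_untrained=allow_untrained
    )

    orig_xyz = inverse_transform(values, features.scaler)
    recon_xyz = inverse_transform(
        _models.decode(model, emb.points, allow_untrained=allow_untrained),
        features.scaler,
    )
    ref = orig_xyz[0] if reference is None else np.asarray(reference, dtype=float)
    rmsd_real = np.array([superposition_rmsd(x, ref) for x in orig_xyz])
    rmsd_dec = np.array([superposition_rmsd(x, ref) for x in recon_xyz])
    return MetricReport(
        spearman=spearman,
        pearson=pearson,
        mean_rmsd=mean_rmsd,
        mmd=mmd(rmsd_real, rmsd_dec),
        emd=emd(rmsd_real, rmsd_dec),
        per_frame_rmsd=per_frame,
        metadata={"n_frames": int(len(values)), "max_pairs": max_pairs, "seed": seed},
    )


def benchmark_models(
    specs: list["_models.ModelSpec"],
    features: FeatureMatrix,
    split: SplitIndex,
    n_replicates: int = 3,
    reference: np.ndarray | None = None,
    max_pairs: int = DEFAULT_MAX_PAIRS,
) -> "pd.DataFrame":
    """Train each spec ``n_replicates`` times (distinct seeds) and report
    all metrics on the test partition, per replicate plus the mean.

    A failed replicate is recorded as a row with an ``error`` note, never
    silently dropped.
    """
    import pandas as pd

    if not specs:
        raise ValueError("at least one ModelSpec is required")
    rows = []
    for s_i, spec in enumerate(specs):
        label = f"{spec.model_kind}-{len(spec.encoder_layer_sizes)}layer"
        for rep in range(n_replicates):
            rep_spec = _models.ModelSpec.from_dict(
                {**spec.to_dict(), "seed": spec.seed + 1000 * rep}
            )
            try:
                model = _models.build_model(rep_spec)
                if rep_spec.epochs > 0:
                    _models.train(model, features, split)
                else:
                    model.scaler = features.scaler  # untrained baseline
                report = evaluate_model(
                    model,
                    features,
                    frame_subset=split.test_indices,
                    reference=reference,
                    max_pairs=max_pairs,
                    seed=rep_spec.seed,
                    allow_untrained=rep_spec.epochs == 0,
                )
                rows.append(
                    {
                        "model": label,
                        "replicate": rep,
                        "spearman": report.spearman,
                        "pearson": report.pearson,
                        "mean_rmsd": report.mean_rmsd,
                        "mmd": report.mmd,
                        "emd": report.emd,
                        "error": "",
                    }
                )
            except Exception as exc:  # record, do not drop
                rows.append(
                    {
                        "model": label,
                        "replicate": rep,
                        "spearman": np.nan,
                        "pearson": np.nan,
                        "mean_rmsd": np.nan,
                        "mmd": np.nan,
                        "emd": np.nan,
                        "error": str(exc),
                    }
                )
    df = pd.DataFrame(rows)
    means = (
        df.groupby("model", sort=False)[
            ["spearman", "pearson", "mean_rmsd", "mmd", "emd"]
        ]
        .mean()
        .reset_index()
    )
    means["replicate"] = "mean"
    means["error"] = ""
    return pd.concat([df, means], ignore_index=True)
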