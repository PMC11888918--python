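"""Multi-channel correlation (MC) features and time-domain baselines.

The MC feature vector of an M-channel recording concatenates, over all
M(M-1)/2 unordered channel pairs in row-major order
(1,2), (1,3), ..., (1,M), (2,3), ..., (M-1,M):

* Lin's concordance correlation coefficient (CCC) — the *linear* half;
  rho = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with population
  (divide-by-N) moments.  CCC couples correlation with agreement of means
  and variances, so crosstalk between channels shows up directly.
* Copula-entropy mutual information — the *nonlinear* half.  Both series
  are rank-transformed to pseudo-observations u = r/(N+1); the negative
  differential entropy of the resulting empirical copula equals the mutual
  information, estimated here with a Kozachenko-Leonenko k-nearest-neighbor
  entropy estimator (Chebyshev metric, k=3 by default).  Being rank-based,
  the estimate is exactly invariant under strictly monotone transforms of
  either channel, and no joint density ever has to be estimated.

The resulting length-M(M-1) vectors are z-normalized per dimension using
population statistics fitted on a training set.  Four classical
time-domain baselines (MAV, ZC, WL, SSC) are provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors


def pair_order(m: int) -> list[tuple[int, int]]:
    """Row-major unordered channel pairs (0-based): (0,1),(0,2),...,(M-2,M-1)."""
    if m < 2:
        raise ValueError("need at least 2 channels")
    return [(i, j) for i in range(m - 1) for j in range(i + 1, m)]


# ---------------------------------------------------------------------------
# concordance correlation
# ---------------------------------------------------------------------------

def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population moments.

    Returns 0 (with a warning) in the 0/0 degenerate case where both series
    are constant with equal means — no variation is no evidence of
    concordance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        warnings.warn("CCC undefined for two equal constant series; returning 0")
        return 0.0
    return float(2.0 * sxy / denom)


def pairwise_ccc(recording) -> np.ndarray:
    """CCC for every unordered channel pair, in :func:`pair_order` order."""
    v = recording.values
    return np.array([ccc(v[:, i], v[:, j]) for i, j in pair_order(v.shape[1])])


# ---------------------------------------------------------------------------
# copula mutual information
# ---------------------------------------------------------------------------

def pseudo_observations(x) -> np.ndarray:
    """Empirical-copula transform: ranks / (N + 1), ties -> average ranks."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D series of length >= 2")
    return rankdata(x, method="average") / (len(x) + 1)


def _knn_entropy(points: np.ndarray, k: int) -> float:
    """Kozachenko-Leonenko differential entropy, Chebyshev metric (nats)."""
    n, d = points.shape
    nn = NearestNeighbors(n_neighbors=k + 1, metric="chebyshev")
    nn.fit(points)
    dist, _ = nn.kneighbors(points)
    eps = np.maximum(dist[:, k], 1e-15)
    return float(digamma(n) - digamma(k) + d * np.mean(np.log(2.0 * eps)))


def copula_mi(x, y, k_neighbors: int = 3) -> float:
    """Mutual information (nats) as negative copula entropy.

    Both series are mapped to pseudo-observations; the joint differential
    entropy of the pairs (which is <= 0, with equality iff independent)
    is estimated by k-NN and negated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if len(x) < 20:
        raise ValueError("need at least 20 samples for a stable MI estimate")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no copula")
    pts = np.column_stack([pseudo_observations(x), pseudo_observations(y)])
    return -_knn_entropy(pts, k_neighbors)


def pairwise_mi(recording, k_neighbors: int = 3) -> np.ndarray:
    """Copula MI for every unordered channel pair, same order as CCC."""
    v = recording.values
    return np.array(
        [copula_mi(v[:, i], v[:, j], k_neighbors) for i, j in pair_order(v.shape[1])]
    )


# ---------------------------------------------------------------------------
# MC feature assembly and normalization
# ---------------------------------------------------------------------------

@dataclass
class MCFeatureVector:
    """Length-M(M-1) vector: M(M-1)/2 CCC entries then M(M-1)/2 MI entries."""

    values: np.ndarray
    n_channels: int

    def __post_init__(self) -> None:
        m = self.n_channels
        if len(self.values) != m * (m - 1):
            raise ValueError("MC feature vector must have length M(M-1)")

    @property
    def ccc_values(self) -> np.ndarray:
        return self.values[: len(self.values) // 2]

    @property
    def mi_values(self) -> np.ndarray:
        return self.values[len(self.values) // 2:]

    @staticmethod
    def feature_names(m: int) -> list[str]:
        pairs = pair_order(m)
        return [f"ccc_{i + 1}_{j + 1}" for i, j in pairs] + [
            f"mi_{i + 1}_{j + 1}" for i, j in pairs
        ]


def mc_features(recording, k_neighbors: int = 3) -> MCFeatureVector:
    """Concatenate [pairwise CCC, pairwise copula MI] for one recording."""
    return MCFeatureVector(
        np.concatenate([pairwise_ccc(recording), pairwise_mi(recording, k_neighbors)]),
        recording.n_channels,
    )


@dataclass
class NormalizationStats:
    """Per-dimension mean and population std fitted on a training set.

    Zero-variance dimensions are flagged rather than dividing by zero;
    they normalize to 0.
    """

    means: np.ndarray
    stds: np.ndarray
    zero_variance: np.ndarray
    n_fit_samples: int


def fit_normalizer(feature_matrix) -> NormalizationStats:
    f = np.asarray(feature_matrix, dtype=float)
    if f.ndim != 2 or f.shape[0] < 2:
        raise ValueError("need an S x D matrix with S >= 2")
    means = f.mean(axis=0)
    stds = f.std(axis=0)  # population (divide by S)
    return NormalizationStats(means, stds, stds == 0, f.shape[0])


def apply_normalizer(feature_matrix, stats: NormalizationStats) -> np.ndarray:
    f = np.asarray(feature_matrix, dtype=float)
    if f.ndim == 1:
        f = f[None, :]
    if f.shape[1] != len(stats.means):
        raise ValueError(
            f"feature dimension {f.shape[1]} does not match fitted {len(stats.means)}"
        )
    safe = np.where(stats.zero_variance, 1.0, stats.stds)
    out = (f - stats.means) / safe
    out[:, stats.zero_variance] = 0.0
    return out


def extract_mc_features(dataset, k_neighbors: int = 3):
    """(S x M(M-1)) raw MC feature matrix and label vector for a dataset."""
    mat = np.vstack(
        [mc_features(r, k_neighbors).values for r in dataset.recordings]
    )
    return mat, np.asarray(dataset.labels)


# ---------------------------------------------------------------------------
# time-domain baselines
# ---------------------------------------------------------------------------

def time_domain_features(recording, eps: float = 0.0) -> np.ndarray:
    """MAV, ZC, WL, SSC per channel, as one length-4M vector.

    Layout: [mav_1..mav_M, zc_1..zc_M, wl_1..wl_M, ssc_1..ssc_M].
    MAV = mean |x|; ZC counts sign changes whose jump exceeds ``eps``;
    WL = total variation sum |x_{n+1} - x_n|; SSC counts slope-sign
    changes with product threshold ``eps``.
    """
    v = recording.values
    if v.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    mav = np.mean(np.abs(v), axis=0)
    d = np.diff(v, axis=0)
    zc = np.sum((v[:-1] * v[1:] < 0) & (np.abs(d) > eps), axis=0)
    wl = np.sum(np.abs(d), axis=0)
    if v.shape[0] >= 3:
        ssc = np.sum(
            (v[1:-1] - v[:-2]) * (v[1:-1] - v[2:]) > eps, axis=0
        )
    else:
        ssc = np.zeros(v.shape[1])
    return np.concatenate([mav, zc.astype(float), wl, ssc.astype(float)])


def time_domain_feature_names(m: int) -> list[str]:
    return [
        f"{name}_{c + 1}" for name in ("mav", "zc", "wl", "ssc") for c in range(m)
    ]


def extract_time_domain_features(dataset, eps: float = 0.0):
    mat = np.vstack([time_domain_features(r, eps) for r in dataset.recordings])
    return mat, np.asarray(dataset.labels)
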