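"""Consensus K-means with PAC / RCSI model selection.

For each candidate K, K-means is repeated on random subsamples of the
rows; the consensus matrix records, for every sample pair, the fraction of
co-sampled runs in which the pair co-clustered. The empirical CDF C(K, u)
of the off-diagonal consensus values summarises stability, and the
proportion of ambiguously clustered pairs is

    P(K) = C(K, u2) - C(K, u1)          (u1 = 0.1, u2 = 0.9)

— the mass of pairs that sometimes, but not always, co-cluster. Because
PAC alone favours large K, the relative cluster stability index compares
it with PACs of structureless reference data (a single multivariate
Gaussian matching the feature covariance of the input, K = 1 truth):

    RCSI(K) = log10( mean_b P_rf(K, b) ) - log10( P_rl(K) )

Higher RCSI means the observed clustering is more stable than the same
procedure applied to correlated noise; the best K maximises RCSI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .datatypes import LatentRepresentation

DEFAULT_U1 = 0.1
DEFAULT_U2 = 0.9


@dataclass
class ConsensusResult:
    """Consensus matrix and final K-means labels for one K."""

    K: int
    consensus_matrix: np.ndarray
    pair_counts: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def cdf(self, u: float) -> float:
        """Empirical CDF of the upper-triangle off-diagonal consensus values."""
        vals = _upper_triangle(self.consensus_matrix)
        return float((vals <= u).mean())

    @property
    def pac(self) -> float:
        return pac_score(self)


@dataclass
class RCSIResult:
    """PAC of the real data vs the Monte-Carlo reference PACs, for one K."""

    K: int
    p_real: float
    ref_pacs: list[float]
    rcsi: float
    consensus: ConsensusResult | None = field(default=None, repr=False)
    silhouette: float | None = None


def _upper_triangle(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def _as_array(X) -> np.ndarray:
    if isinstance(X, LatentRepresentation):
        return X.values
    return np.asarray(X, dtype=float)


def consensus_kmeans(
    X: LatentRepresentation | np.ndarray,
    K: int,
    reps: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
) -> ConsensusResult:
    """Subsampled consensus K-means.

    Each rep draws ``floor(subsample * n)`` samples without replacement and
    clusters them; co-cluster and co-sample counts accumulate into the
    consensus matrix (pairs never co-sampled get 0; the diagonal is 1).
    Final labels come from K-means on the full data under the same seed
    stream.
    """
    data = _as_array(X)
    n = data.shape[0]
    if not 2 <= K < n:
        raise ValueError(f"K={K} must satisfy 2 <= K < n={n}")
    if not 0.0 < subsample <= 1.0:
        raise ValueError("subsample must lie in (0, 1]")
    m = int(np.floor(subsample * n))
    if m < K:
        raise ValueError("subsample size smaller than K")

    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        km_seed = int(rng.integers(2**31 - 1))
        labels = KMeans(n_clusters=K, n_init=n_init, random_state=km_seed).fit_predict(
            data[idx]
        )
        co_sample[np.ix_(idx, idx)] += 1.0
        for c in range(K):
            members = idx[labels == c]
            if members.size:
                co_cluster[np.ix_(members, members)] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    # final labels always get the full 10 restarts, even when the
    # subsampled reps run with fewer for speed
    final_seed = int(rng.integers(2**31 - 1))
    final = KMeans(n_clusters=K, n_init=max(n_init, 10), random_state=final_seed).fit_predict(data)
    return ConsensusResult(K=K, consensus_matrix=consensus, pair_counts=co_sample, labels=final)


def pac_score(
    result: ConsensusResult | np.ndarray, u1: float = DEFAULT_U1, u2: float = DEFAULT_U2
) -> float:
    """Proportion of ambiguously clustered pairs: C(K, u2) - C(K, u1).

    The CDF runs over the upper-triangle off-diagonal consensus entries, so
    PAC is the fraction of pairs with consensus in (u1, u2].
    """
    if not 0.0 <= u1 < u2 <= 1.0:
        raise ValueError("need 0 <= u1 < u2 <= 1")
    matrix = result.consensus_matrix if isinstance(result, ConsensusResult) else np.asarray(result)
    vals = _upper_triangle(matrix)
    # C(u2) - C(u1) via one integer count, so the subtraction is exact
    n_between = int((vals <= u2).sum()) - int((vals <= u1).sum())
    return n_between / vals.size


def simulate_reference(
    X: LatentRepresentation | np.ndarray, B: int, seed: int = 0
) -> list[np.ndarray]:
    """B structureless datasets matching X's feature covariance (K = 1 truth).

    Draws from a single multivariate Gaussian with the sample mean and
    covariance of X, via eigendecomposition with negative eigenvalues
    floored at zero, so the correlation between dimensions is maintained.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    data = _as_array(X)
    n, d = data.shape
    mu = data.mean(axis=0)
    cov = np.cov(data, rowvar=False)
    cov = np.atleast_2d(cov)
    if not np.any(np.diag(cov) > 0):
        raise ValueError("degenerate covariance: all features constant")
    eigval, eigvec = np.linalg.eigh(cov)
    eigval = np.clip(eigval, 0.0, None)
    transform = eigvec * np.sqrt(eigval)
    rng = np.random.default_rng(seed)
    return [rng.standard_normal((n, d)) @ transform.T + mu for _ in range(B)]


def rcsi_score(p_real: float, ref_pacs: list[float], floor: float = 1e-12) -> float:
    """log10(mean reference PAC) - log10(real PAC), with a zero guard.

    Any PAC below `floor` is replaced by it before taking logs; callers
    working with an n-sample consensus use floor = 1 / (number of pairs).
    """
    ref = np.asarray(ref_pacs, dtype=float)
    if ref.size == 0:
        raise ValueError("need at least one reference PAC")
    mean_ref = max(float(ref.mean()), floor)
    p_real = max(float(p_real), floor)
    return float(np.log10(mean_ref) - np.log10(p_real))


def pair_floor(n: int) -> float:
    """PAC flooring constant: one part per sample pair."""
    return 1.0 / (n * (n - 1) / 2.0)


def select_k(
    X: LatentRepresentation | np.ndarray,
    k_range: range | list[int] = range(2, 21),
    reps: int = 1000,
    subsample: float = 0.8,
    B: int = 25,
    seed: int = 0,
    ref_reps: int | None = None,
    n_init: int = 10,
    u1: float = DEFAULT_U1,
    u2: float = DEFAULT_U2,
) -> tuple[int, list[RCSIResult]]:
    """Scan K, computing PAC on the data and on B shared reference datasets.

    The same B simulated reference datasets are reused across every K.
    `ref_reps` lets desk-scale runs use fewer consensus reps on each
    reference than on the real data (default: same as `reps`). Best K is
    the RCSI argmax; exact ties go to the smaller K.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k_range")
    data = _as_array(X)
    n = data.shape[0]
    floor = pair_floor(n)
    if ref_reps is None:
        ref_reps = reps

    root = np.random.SeedSequence(seed)
    ref_seed, *k_seeds = root.spawn(len(ks) + 1)
    refs = simulate_reference(data, B=B, seed=int(ref_seed.generate_state(1)[0] % (2**31)))

    results: list[RCSIResult] = []
    for k, kseq in zip(ks, k_seeds):
        sub_seeds = kseq.generate_state(B + 1) % (2**31)
        real = consensus_kmeans(
            data, K=k, reps=reps, subsample=subsample, seed=int(sub_seeds[0]), n_init=n_init
        )
        p_real = pac_score(real, u1, u2)
        ref_pacs = []
        for b, ref in enumerate(refs):
            ref_res = consensus_kmeans(
                ref, K=k, reps=ref_reps, subsample=subsample,
                seed=int(sub_seeds[b + 1]), n_init=n_init,
            )
            ref_pacs.append(pac_score(ref_res, u1, u2))
        rcsi = rcsi_score(p_real, ref_pacs, floor=floor)
        sil = average_silhouette(data, real.labels) if k >= 2 else None
        results.append(
            RCSIResult(K=k, p_real=p_real, ref_pacs=ref_pacs, rcsi=rcsi,
                       consensus=real, silhouette=sil)
        )
    best = max(results, key=lambda r: (r.rcsi, -r.K))
    return best.K, results


def average_silhouette(X: LatentRepresentation | np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width (Euclidean); singleton clusters contribute 0."""
    data = _as_array(X)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least two clusters")
    return float(silhouette_samples(data, labels, metric="euclidean").mean())
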