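"""Per-class GMM-GMR trajectory models and Mahalanobis channel assignment.

A Gaussian mixture is fitted to 4-D points (normalized time, ax, ay, az)
pooled over a class's windows.  Conditioning the mixture on time yields a
mean acceleration trajectory with a per-time covariance.  Dynamic
assignment partitions a window and the trajectory into N equal parts and
routes each signal part to the CNN channel whose trajectory part it best
matches under mean (squared) Mahalanobis distance, as a minimum-cost
bijection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = [
    "GmmGmrModel", "ConditionalTrajectory", "ChannelAssignment",
    "fit_gmm_gmr", "condition_on_time", "conditional_trajectory",
    "mahalanobis_distance", "segment_distance", "dynamic_assign",
]


@dataclass
class GmmGmrModel:
    """Joint time-acceleration mixture: weights, 4-D means, 4x4 covariances.

    Index 0 of each mean/covariance is normalized time in [0, 1]; indices
    1..3 are acceleration.
    """

    weights: np.ndarray        # (K,)
    means: np.ndarray          # (K, 4)
    covariances: np.ndarray    # (K, 4, 4)

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def to_json(self) -> str:
        return json.dumps({"weights": self.weights.tolist(),
                           "means": self.means.tolist(),
                           "covariances": self.covariances.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "GmmGmrModel":
        d = json.loads(s)
        return cls(np.asarray(d["weights"]), np.asarray(d["means"]),
                   np.asarray(d["covariances"]))


@dataclass
class ConditionalTrajectory:
    times: np.ndarray          # (T,)
    mean: np.ndarray           # (T, 3)
    cov: np.ndarray            # (T, 3, 3)
    responsibilities: np.ndarray  # (T, K), rows sum to 1


@dataclass
class ChannelAssignment:
    mapping: np.ndarray        # segment index -> channel index (a bijection)
    distances: np.ndarray      # (N, N) mean Mahalanobis cost matrix
    total_cost: float


def fit_gmm_gmr(points: np.ndarray, K_g: int = 5, seed: int = 0,
                reg: float = 1e-6) -> GmmGmrModel:
    """EM fit of a K_g-component full-covariance mixture on (T*, 4) points.

    Deterministic given the seed (k-means init); degenerate fits are
    retried up to 3 times with shifted seeds.
    """
    if K_g < 1:
        raise ValueError("K_g must be >= 1")
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 4:
        raise ValueError("points must be (n, 4): (t, ax, ay, az)")
    if len(points) < 10 * K_g:
        raise ValueError(f"need >= {10 * K_g} points for K_g={K_g}")
    last_err: Exception | None = None
    for attempt in range(3):
        gm = GaussianMixture(n_components=K_g, covariance_type="full",
                             reg_covar=reg, random_state=seed + attempt,
                             n_init=1, max_iter=200)
        gm.fit(points)
        covs = gm.covariances_ + reg * np.eye(4)
        try:
            for c in covs:
                np.linalg.cholesky(c)
        except np.linalg.LinAlgError as e:  # pragma: no cover - rare
            last_err = e
            continue
        return GmmGmrModel(gm.weights_, gm.means_, covs)
    raise RuntimeError("EM produced degenerate components in 3 attempts") \
        from last_err


def condition_on_time(model: GmmGmrModel, t: float):
    """Condition the mixture on a time value.

    Per-component conditional mean mu_k^a + S_k^at (S_k^tt)^-1 (t - mu_k^t)
    and covariance S_k^aa - S_k^at (S_k^tt)^-1 S_k^ta; responsibilities from
    the components' 1-D time marginals, normalized in log-space so they
    never underflow to NaN.  The mixture mean weights components by beta_k,
    the mixture covariance by beta_k^2.
    """
    K = model.n_components
    mu_t = model.means[:, 0]
    mu_a = model.means[:, 1:]
    s_tt = model.covariances[:, 0, 0]
    s_ta = model.covariances[:, 0:1, 1:]
    s_at = model.covariances[:, 1:, 0:1]
    s_aa = model.covariances[:, 1:, 1:]

    logb = np.log(model.weights) + norm.logpdf(t, loc=mu_t, scale=np.sqrt(s_tt))
    logb -= logb.max()
    beta = np.exp(logb)
    beta /= beta.sum()

    cond_mean = mu_a + (s_at[:, :, 0] / s_tt[:, None]) * (t - mu_t)[:, None]
    cond_cov = s_aa - s_at @ s_ta / s_tt[:, None, None]

    mu = (beta[:, None] * cond_mean).sum(axis=0)
    cov = ((beta ** 2)[:, None, None] * cond_cov).sum(axis=0)
    return mu, cov, beta


def conditional_trajectory(model: GmmGmrModel, times: np.ndarray
                           ) -> ConditionalTrajectory:
    times = np.asarray(times, dtype=float)
    mean = np.empty((len(times), 3))
    cov = np.empty((len(times), 3, 3))
    resp = np.empty((len(times), model.n_components))
    for i, t in enumerate(times):
        mean[i], cov[i], resp[i] = condition_on_time(model, t)
    return ConditionalTrajectory(times, mean, cov, resp)


def mahalanobis_distance(x_t: np.ndarray, mu: np.ndarray,
                         Sigma: np.ndarray) -> float:
    """Squared Mahalanobis quadratic form (x-mu)^T Sigma^-1 (x-mu)."""
    d = np.asarray(x_t, dtype=float) - np.asarray(mu, dtype=float)
    try:
        sol = np.linalg.solve(np.asarray(Sigma, dtype=float), d)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular covariance in Mahalanobis distance") from e
    return float(d @ sol)


def segment_distance(segment: np.ndarray, traj_mean: np.ndarray,
                     traj_cov: np.ndarray) -> float:
    """Mean per-sample squared Mahalanobis distance of a feature part against
    the matching trajectory slice."""
    segment = np.asarray(segment, dtype=float)
    if len(segment) != len(traj_mean):
        raise ValueError("segment and trajectory slice lengths differ")
    total = 0.0
    for x, mu, cov in zip(segment, traj_mean, traj_cov):
        total += mahalanobis_distance(x, mu, cov)
    return total / len(segment)


def _pad_to_multiple(values: np.ndarray, n_parts: int) -> np.ndarray:
    W = len(values)
    rem = W % n_parts
    if rem == 0:
        return values
    pad = n_parts - rem
    return np.concatenate([values, np.repeat(values[-1:], pad, axis=0)], axis=0)


def dynamic_assign(feature: np.ndarray, model: GmmGmrModel,
                   N_p: int = 4) -> ChannelAssignment:
    """Partition feature (W, 3) and the model trajectory into N_p contiguous
    parts and assign parts to channels by minimum-total-cost bijection."""
    feature = _pad_to_multiple(np.asarray(feature, dtype=float), N_p)
    W = len(feature)
    times = (np.arange(W) + 0.5) / W
    traj = conditional_trajectory(model, times)
    L = W // N_p
    cost = np.empty((N_p, N_p))
    for i in range(N_p):
        seg = feature[i * L:(i + 1) * L]
        for j in range(N_p):
            sl = slice(j * L, (j + 1) * L)
            cost[i, j] = segment_distance(seg, traj.mean[sl], traj.cov[sl])
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(N_p, dtype=int)
    mapping[rows] = cols
    return ChannelAssignment(mapping=mapping, distances=cost,
                             total_cost=float(cost[rows, cols].sum()))
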