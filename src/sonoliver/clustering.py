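"""Fuzzy, possibilistic and possibilistic-fuzzy c-means, and sample entropy.

These are the four texture descriptors extracted from each (denoised)
ultrasound image:

* **FCM** minimises ``K = sum_l sum_m w_lm^n ||y_l - u_m||^2`` subject to the
  memberships of each point summing to one over clusters, by the standard
  Bezdek alternating optimisation.
* **PCM** drops the sum-to-one constraint: per-cluster *typicalities*
  ``v_ab = 1 / (1 + (||y_b - u_a||^2 / eta_a)^(1/(m-1)))`` make outliers
  typical of nothing.  The per-cluster scales ``eta_a`` are estimated once
  from an FCM initialisation (PCM is initialisation-sensitive).
* **PFCM** blends both: its objective weights memberships and typicalities by
  ``a_weight`` (C_FCM) and ``b_weight`` (C_PCM) and reduces exactly to FCM
  (b=0) or PCM (a=0, b=1, shared scales).
* **Sample entropy** -ln(A/B) with A/B the counts of length-(m+1)/length-m
  template matches under a Chebyshev tolerance r, self-matches excluded; low
  values mean regular texture, high values complex texture.

Per-image feature vectors are built from fitted cluster centers,
cluster-averaged memberships/typicalities, or sample-entropy statistics, then
min-max normalised with bounds fitted on training images only.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.preprocessing import MinMaxScaler

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringConfig",
    "SampEnConfig",
    "MembershipState",
    "FeatureVector",
    "fcm_fit",
    "pcm_fit",
    "pfcm_fit",
    "sample_entropy",
    "extract_features",
    "FeatureNormalizer",
    "FEATURE_METHODS",
]

FEATURE_METHODS = ("fcm", "pcm", "pfcm", "sampen")


@dataclasses.dataclass(frozen=True)
class ClusteringConfig:
    """Shared configuration for FCM / PCM / PFCM.

    ``fuzzifier`` (> 1) is the softness exponent used by all three
    objectives.  ``a_weight``/``b_weight`` are the PFCM membership and
    typicality weights C_FCM and C_PCM.  ``beta`` scales the eta estimator;
    ``force_unit_eta`` pins every per-cluster scale to 1 instead (both
    readings of the scale rule are supported; the estimator is the default).
    """

    c: int = 3
    fuzzifier: float = 2.0
    a_weight: float = 1.0
    b_weight: float = 1.0
    beta: float = 1.0
    force_unit_eta: bool = False
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")
        if self.a_weight < 0 or self.b_weight < 0:
            raise ValueError("a_weight and b_weight must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclasses.dataclass(frozen=True)
class SampEnConfig:
    """Sample-entropy configuration: template length m and tolerance r
    (as a fraction of the series standard deviation)."""

    m_template: int = 2
    r_tolerance: float = 0.2
    series_mapping: str = "row_major"  # or "per_row_mean"

    def __post_init__(self) -> None:
        if self.m_template < 1:
            raise ValueError("m_template must be >= 1")
        if self.r_tolerance <= 0:
            raise ValueError("r_tolerance must be > 0")
        if self.series_mapping not in ("row_major", "per_row_mean"):
            raise ValueError(f"unknown series_mapping {self.series_mapping!r}")


@dataclasses.dataclass
class MembershipState:
    """Result of a clustering fit.

    ``memberships`` (c x N) columns sum to one (FCM/PFCM); ``typicalities``
    (c x N) are unconstrained across clusters (PCM/PFCM).  ``objective_trace``
    holds the objective value after every alternating-optimisation sweep and
    is non-increasing.
    """

    centers: np.ndarray
    memberships: np.ndarray | None
    typicalities: np.ndarray | None
    objective_trace: list[float]
    n_iter: int
    converged: bool
    degenerate: bool = False
    eta: np.ndarray | None = None


def _as_2d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.ndim != 2:
        raise ValueError("data must be 1-D or 2-D")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    return data


def _sqdist(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shape (c, N)."""
    diff = centers[:, None, :] - data[None, :, :]
    return np.einsum("cnd,cnd->cn", diff, diff)


def _fcm_memberships(d2: np.ndarray, fuzzifier: float) -> np.ndarray:
    """Optimal FCM memberships for fixed centers (columns sum to one)."""
    c = d2.shape[0]
    zero = d2 <= 1e-300
    u = np.where(zero, 0.0, 1.0 / np.maximum(d2, 1e-300)) ** (1.0 / (fuzzifier - 1.0))
    # points coincident with >=1 center: share membership among those centers
    hit = zero.any(axis=0)
    if hit.any():
        u[:, hit] = zero[:, hit] / zero[:, hit].sum(axis=0)
    col = u.sum(axis=0)
    return u / np.maximum(col, 1e-300) if c > 1 else np.ones_like(u)


def fcm_fit(data: np.ndarray, cfg: ClusteringConfig) -> MembershipState:
    """Fuzzy c-means by alternating optimisation of the fuzzified objective."""
    X = _as_2d(data)
    n = X.shape[0]
    if n <= cfg.c:
        raise ValueError(f"need more samples ({n}) than clusters ({cfg.c})")
    m = cfg.fuzzifier
    if np.allclose(X, X[0], atol=1e-12):
        centers = np.repeat(X[:1], cfg.c, axis=0)
        u = np.full((cfg.c, n), 1.0 / cfg.c)
        logger.warning("fcm_fit: all data points identical; degenerate fit")
        return MembershipState(centers, u, None, [0.0], 0, True, degenerate=True)
    rng = np.random.default_rng(cfg.seed)
    # seed centers from distinct data values: duplicated points must not
    # collapse two centers onto one another at initialisation
    uniq = np.unique(X, axis=0)
    if uniq.shape[0] >= cfg.c:
        centers = uniq[rng.choice(uniq.shape[0], size=cfg.c, replace=False)]
    else:
        centers = X[rng.choice(n, size=cfg.c, replace=False)]
        centers = centers + rng.normal(0, 1e-6, size=centers.shape)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        u = _fcm_memberships(_sqdist(X, centers), m)
        um = u**m
        centers = (um @ X) / np.maximum(um.sum(axis=1)[:, None], 1e-300)
        obj = float(np.sum(um * _sqdist(X, centers)))
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.tol:
            converged = True
            break
    u = _fcm_memberships(_sqdist(X, centers), m)
    return MembershipState(centers, u, None, trace, it, converged)


def estimate_eta(
    data: np.ndarray, init: MembershipState, cfg: ClusteringConfig
) -> np.ndarray:
    """Per-cluster possibilistic scales eta_a = beta * sum(u^m d^2)/sum(u^m),
    from a (fuzzy) initialisation; optionally forced to 1."""
    if cfg.force_unit_eta:
        return np.ones(init.centers.shape[0])
    X = _as_2d(data)
    u = init.memberships
    if u is None:
        raise ValueError("initialisation must carry memberships")
    um = u**cfg.fuzzifier
    d2 = _sqdist(X, init.centers)
    eta = cfg.beta * (um * d2).sum(axis=1) / np.maximum(um.sum(axis=1), 1e-300)
    if np.any(eta <= 0):
        raise ValueError("degenerate initialisation: non-positive eta scale")
    return eta


def _typicalities(d2: np.ndarray, eta: np.ndarray, m: float, b: float = 1.0) -> np.ndarray:
    """Typicality update 1 / (1 + (b d^2/eta)^(1/(m-1))); exact minimiser of
    the possibilistic objective term for fixed centers."""
    ratio = b * d2 / eta[:, None]
    return 1.0 / (1.0 + np.maximum(ratio, 0.0) ** (1.0 / (m - 1.0)))


def pcm_fit(
    data: np.ndarray, cfg: ClusteringConfig, init: MembershipState
) -> MembershipState:
    """Possibilistic c-means seeded from an FCM fit.

    The objective recorded per sweep is
    ``sum_ab v_ab^m d_ab^2 + sum_a eta_a sum_b (1 - v_ab)^m``, which the
    typicality and center updates minimise coordinate-wise, so the trace is
    non-increasing.
    """
    X = _as_2d(data)
    m = cfg.fuzzifier
    eta = estimate_eta(X, init, cfg)
    centers = init.centers.copy()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        v = _typicalities(_sqdist(X, centers), eta, m)
        vm = v**m
        centers = (vm @ X) / np.maximum(vm.sum(axis=1)[:, None], 1e-300)
        d2 = _sqdist(X, centers)
        obj = float(np.sum(vm * d2) + np.sum(eta[:, None] * (1.0 - v) ** m))
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.tol:
            converged = True
            break
    v = _typicalities(_sqdist(X, centers), eta, m)
    return MembershipState(centers, None, v, trace, it, converged, eta=eta)


def pfcm_fit(
    data: np.ndarray, cfg: ClusteringConfig, init: MembershipState
) -> MembershipState:
    """Possibilistic-fuzzy c-means: memberships as FCM, typicalities as PCM
    (with per-cluster scales gamma estimated from the init), centers weighted
    by ``a_weight * u^m + b_weight * t^m``."""
    if cfg.a_weight + cfg.b_weight <= 0:
        raise ValueError("a_weight + b_weight must be > 0 for PFCM")
    X = _as_2d(data)
    m = cfg.fuzzifier
    a, b = cfg.a_weight, cfg.b_weight
    gamma = estimate_eta(X, init, cfg)
    centers = init.centers.copy()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        d2 = _sqdist(X, centers)
        u = _fcm_memberships(d2, m)
        t = _typicalities(d2, gamma, m, b=b) if b > 0 else np.ones_like(d2)
        w = a * u**m + b * t**m
        centers = (w @ X) / np.maximum(w.sum(axis=1)[:, None], 1e-300)
        d2 = _sqdist(X, centers)
        obj = float(
            np.sum((a * u**m + b * t**m) * d2)
            + np.sum(gamma[:, None] * (1.0 - t) ** m)
        )
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.tol:
            converged = True
            break
    d2 = _sqdist(X, centers)
    u = _fcm_memberships(d2, m)
    t = _typicalities(d2, gamma, m, b=b) if b > 0 else np.ones_like(d2)
    return MembershipState(centers, u, t if b > 0 else None, trace, it, converged,
                           eta=gamma)


def sample_entropy(series: np.ndarray, cfg: SampEnConfig) -> float:
    """Sample entropy -ln(A/B) of a 1-D series.

    A and B count ordered template pairs (i != j) matching to within
    ``r_tolerance * std(series)`` in Chebyshev distance at lengths m+1 and m.
    A constant series returns 0; A == 0 returns +inf.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    m = cfg.m_template
    if n <= m + 1:
        raise ValueError(f"series length {n} must exceed m_template+1 = {m + 1}")
    sd = float(x.std())
    if sd == 0.0:
        return 0.0
    r = cfg.r_tolerance * sd
    # |x_i - x_j| for all pairs, then running Chebyshev match over templates.
    # Both template lengths use the same n-m starting offsets so A/B is a
    # conditional probability (every m+1 match is also an m match).
    within = np.abs(x[:, None] - x[None, :]) <= r
    match = within[: n - m, : n - m].copy()
    for k in range(1, m):
        match &= within[k : n - m + k, k : n - m + k]
    b_count = int(match.sum()) - (n - m)  # drop self-matches (diagonal)
    match &= within[m:n, m:n]
    a_count = int(match.sum()) - (n - m)
    if b_count <= 0 or a_count <= 0:
        return float("inf")
    return float(-np.log(a_count / b_count))


class FeatureNormalizer:
    """Per-coordinate min-max normaliser fitted on training vectors only;
    transform clips to [0, 1] so unseen test values stay in range."""

    def __init__(self) -> None:
        self._scaler = MinMaxScaler(clip=True)
        self.fitted = False

    def fit(self, vectors: np.ndarray) -> "FeatureNormalizer":
        self._scaler.fit(np.asarray(vectors, dtype=float))
        self.fitted = True
        return self

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("normaliser not fitted")
        return self._scaler.transform(np.asarray(vectors, dtype=float))

    def fit_transform(self, vectors: np.ndarray) -> np.ndarray:
        return self.fit(vectors).transform(vectors)


@dataclasses.dataclass
class FeatureVector:
    """Raw (un-normalised) per-image descriptor plus provenance."""

    values: np.ndarray
    method: str
    image_id: str = ""
    label: str = "unknown"
    converged: bool = True
    degenerate: bool = False


def _subsample_pixels(img: np.ndarray, max_pixels: int, seed: int) -> np.ndarray:
    flat = np.asarray(img, dtype=float).ravel()
    if flat.size <= max_pixels:
        return flat
    rng = np.random.default_rng(seed)
    return flat[rng.choice(flat.size, size=max_pixels, replace=False)]


def _central_series(img: np.ndarray, side: int, mapping: str) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    side = min(side, h, w)
    r0, c0 = (h - side) // 2, (w - side) // 2
    patch = img[r0 : r0 + side, c0 : c0 + side]
    if mapping == "per_row_mean":
        return patch.mean(axis=1)
    return patch.ravel()


def extract_features(
    img: np.ndarray,
    method: str,
    cfg: ClusteringConfig | SampEnConfig | None = None,
    *,
    image_id: str = "",
    label: str = "unknown",
    max_pixels: int = 4096,
    patch_side: int = 32,
) -> FeatureVector:
    """Extract the raw per-image descriptor for one feature method.

    Clustering methods cluster a seeded random subsample of at most
    ``max_pixels`` pixel intensities; the descriptor is the sorted centers
    followed by per-cluster mean membership and (when defined) per-cluster
    mean typicality, ordered consistently with the sorted centers.  The
    ``sampen`` method flattens the central ``patch_side`` x ``patch_side``
    patch row-major and reports [SampEn(m=1), SampEn(m=2), mean, std].
    Normalisation to [0, 1] is a separate, training-set-fitted step
    (:class:`FeatureNormalizer`).
    """
    if method not in FEATURE_METHODS:
        raise ValueError(f"unknown feature method {method!r}")
    if method == "sampen":
        scfg = cfg if isinstance(cfg, SampEnConfig) else SampEnConfig()
        series = _central_series(img, patch_side, scfg.series_mapping)
        vals = np.array(
            [
                sample_entropy(series, dataclasses.replace(scfg, m_template=1)),
                sample_entropy(series, dataclasses.replace(scfg, m_template=2)),
                float(series.mean()),
                float(series.std()),
            ]
        )
        # an inf sentinel (no length-m+1 matches) is capped for downstream use
        vals = np.nan_to_num(vals, posinf=10.0, neginf=0.0)
        return FeatureVector(vals, method, image_id, label)

    ccfg = cfg if isinstance(cfg, ClusteringConfig) else ClusteringConfig()
    pixels = _subsample_pixels(img, max_pixels, ccfg.seed)
    fcm = fcm_fit(pixels, ccfg)
    if method == "fcm":
        state = fcm
    elif method == "pcm":
        state = pcm_fit(pixels, ccfg, fcm)
    else:
        state = pfcm_fit(pixels, ccfg, fcm)
    if not state.converged:
        logger.warning(
            "extract_features: %s did not converge in %d iterations (image %s)",
            method, state.n_iter, image_id or "<unnamed>",
        )
    order = np.argsort(state.centers[:, 0])
    parts = [state.centers[order, 0]]
    if state.memberships is not None:
        parts.append(state.memberships.mean(axis=1)[order])
    if state.typicalities is not None:
        parts.append(state.typicalities.mean(axis=1)[order])
    return FeatureVector(
        np.concatenate(parts), method, image_id, label,
        converged=state.converged, degenerate=state.degenerate,
    )
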