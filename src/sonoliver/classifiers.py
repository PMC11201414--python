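"""The eight decision models, under one train/predict contract.

Labels are integers 0 (normal) and 1 (abnormal / cirrhotic).  Regression-
style models work against *target codings*: normal -> 0.1 and abnormal ->
0.85, chosen so the class targets are at least 0.5 apart on the normalized
[0, 1] feature scale; a continuous output is mapped to the nearer target.

Models
------
GMM        per-class Gaussian mixtures fitted by EM (equal priors, argmax
           class log-density).
SDC        softmax discriminant: score_j = log sum_i exp(-lambda ||x - x_i^j||^2)
           over class j's stored training vectors.
SVM        soft-margin kernel SVM (linear / polynomial / RBF), SMO-style dual
           solver behind the scenes.
HS         per-image harmony search fitting a candidate vector to the image's
           normalized features by MSE; class = nearer target to the best
           harmony's mean.  Training-free.
AAO        as HS with the artificial-algae optimizer as the engine.
AAO-GMM    hybrid: AAO searches the EM initialisation (component count and
           starting means) to minimise internal ten-fold output MSE against
           the encoded targets; the winner is refit by EM on the full
           training set.

Ties in any argmax break toward normal (conservative) and are logged.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "TargetScheme",
    "encode_targets",
    "check_target_separation",
    "GMMClassifier",
    "SDCModel",
    "SVMModel",
    "HarmonyConfig",
    "harmony_search",
    "HSClassifier",
    "AlgaeConfig",
    "aao_optimize",
    "AAOClassifier",
    "AAOGMMClassifier",
    "make_classifier",
    "CLASSIFIER_NAMES",
]

NORMAL, ABNORMAL = 0, 1
CLASSIFIER_NAMES = (
    "gmm", "sdc", "hs", "svm-linear", "svm-poly", "svm-rbf", "aao", "aao-gmm",
)


# ---------------------------------------------------------------------------
# Target coding
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TargetScheme:
    """Continuous class targets; separation of at least 0.5 is enforced."""

    t_norm: float = 0.1
    t_abnormal: float = 0.85

    def __post_init__(self) -> None:
        if self.t_abnormal - self.t_norm < 0.5:
            raise ValueError(
                "target separation t_abnormal - t_norm must be >= 0.5, got "
                f"{self.t_abnormal - self.t_norm:.3f}"
            )

    def target(self, label: int) -> float:
        return self.t_abnormal if label == ABNORMAL else self.t_norm

    def nearest_label(self, value: float) -> int:
        d_norm = abs(value - self.t_norm)
        d_ab = abs(value - self.t_abnormal)
        if d_ab < d_norm:
            return ABNORMAL
        if d_ab == d_norm:
            logger.info("target tie at %.6f; breaking toward normal", value)
        return NORMAL


_LABEL_ALIASES = {"normal": NORMAL, "cirrhotic": ABNORMAL, "abnormal": ABNORMAL,
                  0: NORMAL, 1: ABNORMAL}


def as_int_labels(labels) -> np.ndarray:
    """Coerce string or integer class labels to the 0/1 convention."""
    out = []
    for lab in np.asarray(labels).ravel():
        key = lab.item() if hasattr(lab, "item") else lab
        key = key if isinstance(key, int) else str(key)
        if key not in _LABEL_ALIASES:
            raise ValueError(f"non-binary or unknown label {lab!r}")
        out.append(_LABEL_ALIASES[key])
    return np.asarray(out, dtype=int)


def encode_targets(labels, scheme: TargetScheme = TargetScheme()) -> np.ndarray:
    """Map binary labels to their continuous targets (0.1 / 0.85)."""
    y = as_int_labels(labels)
    return np.where(y == ABNORMAL, scheme.t_abnormal, scheme.t_norm)


def check_target_separation(
    features_by_class: dict, scheme: TargetScheme = TargetScheme()
) -> bool:
    """Check the class-mean normalized features against the target bounds.

    Normal-class mean should not exceed t_norm and abnormal-class mean should
    not exceed t_abnormal; violations log a warning (not an error).  Returns
    True when all present classes satisfy their bound.  With fewer than two
    classes the check is vacuous.
    """
    ok = True
    for label, block in features_by_class.items():
        lab = as_int_labels([label])[0]
        mean = float(np.asarray(block, dtype=float).mean())
        bound = scheme.t_abnormal if lab == ABNORMAL else scheme.t_norm
        if mean > bound:
            logger.warning(
                "class %s mean normalized feature %.4f exceeds target bound %.2f",
                label, mean, bound,
            )
            ok = False
    return ok


# ---------------------------------------------------------------------------
# Gaussian mixture EM
# ---------------------------------------------------------------------------

def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    z = np.linalg.solve(L, (X - mean).T)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(z * z, axis=0))


@dataclasses.dataclass
class _Mixture:
    weights: np.ndarray   # (k,)
    means: np.ndarray     # (k, d)
    covs: np.ndarray      # (k, d, d)
    loglik_trace: list[float]

    def log_density(self, X: np.ndarray) -> np.ndarray:
        comp = np.stack(
            [np.log(w) + _log_gauss(X, m, c)
             for w, m, c in zip(self.weights, self.means, self.covs)]
        )
        return logsumexp(comp, axis=0)


def _fit_mixture(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    reg: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-6,
    init_means: np.ndarray | None = None,
    warn_prune: bool = True,
) -> _Mixture:
    """Full-covariance EM with covariance ridge; log-likelihood trace is
    non-decreasing.  Components whose weight collapses are pruned (with a
    warning) after convergence."""
    n, d = X.shape
    if n < 2 * k:
        raise ValueError(f"need >= {2 * k} samples for {k} components, got {n}")
    base_cov = np.cov(X.T).reshape(d, d) if n > 1 else np.eye(d)
    ridge = reg * max(np.trace(base_cov) / d, 1e-12) * np.eye(d)
    if init_means is None:
        means = X[rng.choice(n, size=k, replace=False)].copy()
    else:
        means = np.asarray(init_means, dtype=float).reshape(k, d).copy()
    covs = np.repeat((base_cov + ridge)[None], k, axis=0)
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    for _ in range(max_iter):
        log_comp = np.stack(
            [np.log(np.maximum(w, 1e-300)) + _log_gauss(X, m, c)
             for w, m, c in zip(weights, means, covs)]
        )  # (k, n)
        log_norm = logsumexp(log_comp, axis=0)
        trace.append(float(log_norm.mean()))
        resp = np.exp(log_comp - log_norm)
        nk = resp.sum(axis=1)
        weights = nk / n
        means = (resp @ X) / np.maximum(nk, 1e-300)[:, None]
        for j in range(k):
            diff = X - means[j]
            covs[j] = (resp[j][:, None] * diff).T @ diff / max(nk[j], 1e-300) + ridge
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    keep = weights > 1e-8
    if not keep.all():
        log = logger.warning if warn_prune else logger.debug
        log("pruning %d vanishing mixture component(s)", (~keep).sum())
        weights, means, covs = weights[keep], means[keep], covs[keep]
        weights = weights / weights.sum()
    return _Mixture(weights, means, covs, trace)


class GMMClassifier:
    """One Gaussian mixture per class, equal priors; argmax class density."""

    def __init__(self, n_components: int = 1, seed: int = 0,
                 max_iter: int = 100, scheme: TargetScheme = TargetScheme()):
        self.n_components = n_components
        self.seed = seed
        self.max_iter = max_iter
        self.scheme = scheme
        self.mixtures_: dict[int, _Mixture] = {}

    def fit(self, X: np.ndarray, y) -> "GMMClassifier":
        X = np.asarray(X, dtype=float)
        y = as_int_labels(y)
        rng = np.random.default_rng(self.seed)
        self.mixtures_ = {}
        for label in sorted(np.unique(y)):
            self.mixtures_[int(label)] = _fit_mixture(
                X[y == label], self.n_components, rng, max_iter=self.max_iter
            )
        return self

    def log_densities(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        labels = sorted(self.mixtures_)
        return np.column_stack([self.mixtures_[l].log_density(X) for l in labels])

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.log_densities(X)
        labels = np.asarray(sorted(self.mixtures_))
        # argmax with ties toward the normal class (first listed)
        return labels[np.argmax(scores, axis=1)]

    def predict_outputs(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.scheme.target(p) for p in self.predict(X)])


# ---------------------------------------------------------------------------
# Softmax discriminant classifier
# ---------------------------------------------------------------------------

class SDCModel:
    """Stores training vectors; score_j = log sum_i exp(-lambda ||x-x_i^j||^2)."""

    def __init__(self, lam: float = 0.5, scheme: TargetScheme = TargetScheme()):
        if lam <= 0:
            raise ValueError("lambda must be > 0")
        self.lam = lam
        self.scheme = scheme
        self.class_vectors_: dict[int, np.ndarray] = {}

    def fit(self, X: np.ndarray, y) -> "SDCModel":
        X = np.asarray(X, dtype=float)
        y = as_int_labels(y)
        self.class_vectors_ = {
            int(l): X[y == l].copy() for l in sorted(np.unique(y))
        }
        for label, block in self.class_vectors_.items():
            if block.shape[0] == 0:
                raise ValueError(f"class {label} has no training vectors")
        return self

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = []
        for label in sorted(self.class_vectors_):
            K = self.class_vectors_[label]
            d2 = ((X[:, None, :] - K[None, :, :]) ** 2).sum(axis=2)
            cols.append(logsumexp(-self.lam * d2, axis=1))
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        labels = np.asarray(sorted(self.class_vectors_))
        s = self.scores(X)
        best = np.argmax(s, axis=1)
        ties = (s == s.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            logger.info("SDC: %d tie(s) broken toward first class", ties.sum())
        return labels[best]

    def predict_outputs(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.scheme.target(p) for p in self.predict(X)])


# ---------------------------------------------------------------------------
# Support vector machine (SMO dual solver via scikit-learn)
# ---------------------------------------------------------------------------

class SVMModel:
    """Binary soft-margin SVM with linear / polynomial / RBF kernel.

    ``class_weight`` multiplies the penalty C for the abnormal class.  The
    polynomial kernel is (gamma x.y + 1)^degree; RBF is exp(-gamma ||x-y||^2).
    """

    _DEFAULTS = {
        "linear": dict(C=0.85, gamma=1.0, degree=3, class_weight=0.4),
        "poly": dict(C=0.8, gamma=10.0, degree=2, class_weight=0.5),
        "rbf": dict(C=0.8, gamma=100.0, degree=3, class_weight=0.87),
    }

    def __init__(self, kernel: str = "rbf", C: float | None = None,
                 gamma: float | None = None, degree: int | None = None,
                 class_weight: float | None = None, seed: int = 0,
                 scheme: TargetScheme = TargetScheme()):
        if kernel not in self._DEFAULTS:
            raise ValueError(f"unknown kernel {kernel!r}")
        dft = self._DEFAULTS[kernel]
        self.kernel = kernel
        self.C = dft["C"] if C is None else C
        self.gamma = dft["gamma"] if gamma is None else gamma
        self.degree = dft["degree"] if degree is None else degree
        self.class_weight = (
            dft["class_weight"] if class_weight is None else class_weight
        )
        if self.C <= 0:
            raise ValueError("C must be > 0")
        self.seed = seed
        self.scheme = scheme
        self._svc: SVC | None = None

    def fit(self, X: np.ndarray, y) -> "SVMModel":
        X = np.asarray(X, dtype=float)
        y = as_int_labels(y)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present for SVM training")
        h = np.where(y == ABNORMAL, 1, -1)  # class labels in {-1, +1}
        self._svc = SVC(
            kernel=self.kernel, C=self.C, gamma=self.gamma, degree=self.degree,
            coef0=1.0, tol=1e-4, class_weight={-1: 1.0, 1: self.class_weight},
            random_state=self.seed,
        )
        self._svc.fit(X, h)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise RuntimeError("model not fitted")
        return self._svc.decision_function(np.atleast_2d(np.asarray(X, dtype=float)))

    def kernel_matrix(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Explicit kernel evaluation (used for decision self-consistency)."""
        A = np.atleast_2d(A)
        B = np.atleast_2d(B)
        if self.kernel == "linear":
            return A @ B.T
        if self.kernel == "poly":
            return (self.gamma * (A @ B.T) + 1.0) ** self.degree
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, ABNORMAL, NORMAL)

    def predict_outputs(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.scheme.target(p) for p in self.predict(X)])


# ---------------------------------------------------------------------------
# Harmony search
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class HarmonyConfig:
    """Harmony-search parameters.

    ``bw`` is the initial pitch-adjustment bandwidth; it decays linearly to
    ``delta_w`` over the run.  The search stops when the best fitness drops
    below ``mse_stop`` or after ``max_iter`` improvisations.
    """

    hm_size: int = 16
    hmcr: float = 0.9
    par: float = 0.3
    bw: float = 0.1
    delta_w: float = 0.005
    max_iter: int = 1000
    mse_stop: float = 1e-5
    bounds: tuple[float, float] = (0.1, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.hmcr < 1:
            raise ValueError("hmcr must lie in (0, 1)")
        if not 0 < self.par < 1:
            raise ValueError("par must lie in (0, 1)")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("lower bound must be below upper bound")
        if self.hm_size < 2:
            raise ValueError("hm_size must be >= 2")


def harmony_search(
    objective, dims: int, cfg: HarmonyConfig, seed: int,
    bounds: tuple[float, float] | None = None,
    max_evals: int | None = None,
):
    """Minimise ``objective`` over [low, high]^dims; returns
    (best_vector, best_fitness, fitness_trace).  The trace records the best
    fitness after every improvisation and is non-increasing."""
    low, high = bounds if bounds is not None else cfg.bounds
    rng = np.random.default_rng(seed)
    hm = rng.uniform(low, high, size=(cfg.hm_size, dims))
    fit = np.array([objective(h) for h in hm])
    evals = cfg.hm_size
    trace = [float(fit.min())]
    for it in range(cfg.max_iter):
        if max_evals is not None and evals >= max_evals:
            break
        if trace[-1] <= cfg.mse_stop:
            break
        # improved-HS scheduling: bandwidth decays exponentially from bw to
        # delta_w while the pitch-adjust rate ramps up; pitch adjustment
        # perturbs around the best harmony's value (global-best variant)
        frac = min(it / max(cfg.max_iter - 1, 1), 1.0)
        bw = cfg.bw * (cfg.delta_w / cfg.bw) ** frac
        par = cfg.par + (0.99 - cfg.par) * frac
        gbest = int(np.argmin(fit))
        new = np.empty(dims)
        for d in range(dims):
            if rng.random() < cfg.hmcr:
                new[d] = hm[rng.integers(cfg.hm_size), d]
                if rng.random() < par:
                    new[d] = hm[gbest, d] + rng.uniform(-1.0, 1.0) * bw
            else:
                new[d] = rng.uniform(low, high)
        np.clip(new, low, high, out=new)
        f_new = objective(new)
        evals += 1
        worst = int(np.argmax(fit))
        if f_new < fit[worst]:
            hm[worst] = new
            fit[worst] = f_new
        trace.append(float(fit.min()))
    best = int(np.argmin(fit))
    return hm[best].copy(), float(fit[best]), trace


class HSClassifier:
    """Per-image, training-free harmony-search classifier.

    For each image the search fits a harmony vector to the normalized feature
    vector under MSE; the image is assigned the class whose target is nearer
    to the best harmony's mean.
    """

    def __init__(self, cfg: HarmonyConfig = HarmonyConfig(), seed: int = 0,
                 scheme: TargetScheme = TargetScheme()):
        self.cfg = cfg
        self.seed = seed
        self.scheme = scheme

    def fit(self, X: np.ndarray, y) -> "HSClassifier":
        return self  # training-free by construction

    def predict_outputs(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        outs = np.empty(X.shape[0])
        for i, f in enumerate(X):
            best, _, _ = harmony_search(
                lambda v: float(np.mean((v - f) ** 2)),
                dims=f.size, cfg=self.cfg, seed=self.seed + i,
            )
            outs[i] = float(best.mean())
        return outs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array(
            [self.scheme.nearest_label(o) for o in self.predict_outputs(X)]
        )


# ---------------------------------------------------------------------------
# Artificial algae optimization
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AlgaeConfig:
    """Artificial-algae parameters: shear force (drives step size), energy
    loss per unsuccessful move, adaptation rate of the most-starved colony,
    Monod half-saturation ``half_sat`` for colony growth."""

    n_colonies: int = 20
    shear_force: float = 3.0
    energy_loss: float = 0.4
    adaptation_rate: float = 0.3
    half_sat: float = 0.5
    max_evals: int = 500
    energy_exponent: float = 2.5
    growth_gain: float = 0.5
    shrink_rate: float = 1.05

    def __post_init__(self) -> None:
        if self.n_colonies < 2:
            raise ValueError("need at least 2 colonies")
        if not 0 < self.energy_loss <= 1:
            raise ValueError("energy_loss must lie in (0, 1]")


def _friction(size: np.ndarray, shear: float) -> np.ndarray:
    """Hemisphere-surface friction tau = 2*pi*(3H/4pi)^(2/3), capped below the
    shear force so the movement step (shear - tau) stays positive."""
    tau = 2.0 * np.pi * (3.0 * np.asarray(size, dtype=float) / (4.0 * np.pi)) ** (2.0 / 3.0)
    return np.minimum(tau, 0.98 * shear)


def aao_optimize(
    objective, dims: int, bounds: tuple[float, float], cfg: AlgaeConfig, seed: int
):
    """Artificial algae algorithm minimising ``objective``.

    Returns (best_position, best_fitness, trace); the trace records the
    best-so-far fitness once per generation and is non-increasing.

    One generation: every colony spends its energy (a decreasing function of
    fitness rank) on helical moves in three random planes toward a
    tournament-selected source, with step scaled by (shear - friction(size));
    improving moves cost half the energy of failed ones.  A colony grows by
    its Monod rate e/(half_sat+e) on every successful move and dies back
    slightly on every failed one, so friction — and with it the step size —
    self-adapts to local success: colonies that keep improving take ever
    finer steps while stalled ones regain reach.  Non-improvers starve, and
    with probability ``adaptation_rate`` the most-starved colony is pulled
    toward the biggest one and its starvation reset.
    """
    low, high = bounds
    if low >= high:
        raise ValueError("lower bound must be below upper bound")
    rng = np.random.default_rng(seed)
    n = cfg.n_colonies

    def safe_eval(x: np.ndarray) -> float:
        v = float(objective(x))
        return v

    X = rng.uniform(low, high, size=(n, dims))
    fit = np.empty(n)
    evals = 0
    for i in range(n):
        fit[i] = safe_eval(X[i])
        evals += 1
        for _ in range(20):  # resample non-finite starts
            if np.isfinite(fit[i]):
                break
            X[i] = rng.uniform(low, high, size=dims)
            fit[i] = safe_eval(X[i])
            evals += 1
        if not np.isfinite(fit[i]):
            fit[i] = np.inf  # treated as worst; replaced on first finite move
    sizes = np.ones(n)
    starving = np.zeros(n)
    best_idx = int(np.argmin(fit))
    best_x, best_f = X[best_idx].copy(), float(fit[best_idx])
    trace = [best_f]

    while evals < cfg.max_evals:
        order = np.argsort(np.argsort(fit))  # rank 0 = best
        energy = (1.0 - order / n) ** cfg.energy_exponent
        improved = np.zeros(n, dtype=bool)
        for i in range(n):
            e = energy[i]
            # a colony moves only while it can afford a full (failed) move
            while e >= cfg.energy_loss and evals < cfg.max_evals:
                # tournament source selection
                a, b = rng.choice(n, size=2, replace=False)
                j = a if fit[a] <= fit[b] else b
                if j == i:
                    j = b if j == a else a
                step = cfg.shear_force - _friction(sizes[i], cfg.shear_force)
                cand = X[i].copy()
                d_idx = rng.integers(0, dims, size=3)
                p = rng.uniform(-1, 1)
                alpha = rng.uniform(0, 2 * np.pi)
                beta = rng.uniform(0, 2 * np.pi)
                cand[d_idx[0]] = X[i, d_idx[0]] + (X[j, d_idx[0]] - X[i, d_idx[0]]) * step * p
                cand[d_idx[1]] = X[i, d_idx[1]] + (X[j, d_idx[1]] - X[i, d_idx[1]]) * step * np.cos(alpha)
                cand[d_idx[2]] = X[i, d_idx[2]] + (X[j, d_idx[2]] - X[i, d_idx[2]]) * step * np.sin(beta)
                np.clip(cand, low, high, out=cand)
                f_cand = safe_eval(cand)
                evals += 1
                if not np.isfinite(f_cand):
                    # reject and resample the candidate position
                    continue
                mu = energy[i] / (cfg.half_sat + energy[i])  # Monod growth rate
                if f_cand < fit[i]:
                    X[i], fit[i] = cand, f_cand
                    improved[i] = True
                    e -= cfg.energy_loss / 2.0
                    sizes[i] *= 1.0 + mu * cfg.growth_gain
                else:
                    e -= cfg.energy_loss
                    sizes[i] = max(sizes[i] / cfg.shrink_rate, 1e-2)
            if fit[i] < best_f:
                best_f, best_x = float(fit[i]), X[i].copy()
        # starvation of non-improvers drifts toward (and past) the current max
        biggest = float(starving.max())
        idx = ~improved
        starving[idx] += rng.uniform(0, 1, size=int(idx.sum())) * np.maximum(
            biggest - starving[idx], 1.0
        )
        # adaptation: most starved colony imitates the biggest colony
        if rng.random() < cfg.adaptation_rate:
            s = int(np.argmax(starving))
            g = int(np.argmax(sizes))
            if s != g:
                X[s] = X[s] + (X[g] - X[s]) * rng.uniform(0, 1, size=dims)
                fit[s] = safe_eval(X[s])
                evals += 1
                starving[s] = 0.0
                if fit[s] < best_f:
                    best_f, best_x = float(fit[s]), X[s].copy()
        trace.append(best_f)
    return best_x, best_f, trace


class AAOClassifier:
    """Per-image, training-free artificial-algae classifier (HS analogue)."""

    def __init__(self, cfg: AlgaeConfig | None = None, seed: int = 0,
                 scheme: TargetScheme = TargetScheme(),
                 bounds: tuple[float, float] = (0.1, 1.0)):
        self.cfg = cfg if cfg is not None else AlgaeConfig(max_evals=400)
        self.seed = seed
        self.scheme = scheme
        self.bounds = bounds

    def fit(self, X: np.ndarray, y) -> "AAOClassifier":
        return self

    def predict_outputs(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        outs = np.empty(X.shape[0])
        for i, f in enumerate(X):
            best, _, _ = aao_optimize(
                lambda v: float(np.mean((v - f) ** 2)),
                dims=f.size, bounds=self.bounds, cfg=self.cfg, seed=self.seed + i,
            )
            outs[i] = float(best.mean())
        return outs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array(
            [self.scheme.nearest_label(o) for o in self.predict_outputs(X)]
        )


# ---------------------------------------------------------------------------
# AAO-GMM hybrid
# ---------------------------------------------------------------------------

class AAOGMMClassifier:
    """AAO-tuned Gaussian mixture classifier.

    The algae search explores (component count in {1, 2, 3}, EM starting
    means); each candidate is scored by the internal ten-fold output MSE of
    its predictions against the encoded class targets, and the winning
    configuration is refit by EM on the full training set.  The plain
    seeded-EM configuration is included in the search so the hybrid never
    starts worse than the base GMM.
    """

    K_CHOICES = (1, 2, 3)

    def __init__(self, cfg: AlgaeConfig | None = None, seed: int = 0,
                 scheme: TargetScheme = TargetScheme(), internal_folds: int = 10,
                 search_em_iter: int = 25):
        self.cfg = cfg if cfg is not None else AlgaeConfig(
            n_colonies=6, max_evals=40)
        self.seed = seed
        self.scheme = scheme
        self.internal_folds = internal_folds
        self.search_em_iter = search_em_iter
        self.model_: GMMClassifier | None = None
        self.best_k_: int | None = None
        self.search_trace_: list[float] = []

    # decision vector: [k_raw, mean offsets for each class x component x dim]
    def _decode_k(self, k_raw: float) -> int:
        idx = int(np.clip(np.floor(k_raw), 0, len(self.K_CHOICES) - 1))
        return self.K_CHOICES[idx]

    def _internal_mse(self, X, y, k, mean_offsets, seed) -> float:
        targets = encode_targets(y, self.scheme)
        n_splits = min(self.internal_folds, *np.bincount(y))
        if n_splits < 2:
            return float("inf")
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        errs = []
        for tr, te in skf.split(X, y):
            try:
                model = self._build(X[tr], y[tr], k, mean_offsets, seed,
                                    max_iter=self.search_em_iter)
            except (ValueError, np.linalg.LinAlgError):
                return float("inf")
            out = model.predict_outputs(X[te])
            errs.append(float(np.mean((out - targets[te]) ** 2)))
        return float(np.mean(errs))

    def _build(self, X, y, k, mean_offsets, seed, max_iter) -> GMMClassifier:
        model = GMMClassifier(n_components=k, seed=seed, max_iter=max_iter,
                              scheme=self.scheme)
        X = np.asarray(X, dtype=float)
        y = as_int_labels(y)
        rng = np.random.default_rng(seed)
        model.mixtures_ = {}
        d = X.shape[1]
        for ci, label in enumerate(sorted(np.unique(y))):
            block = X[y == label]
            base = block.mean(axis=0)
            spread = block.std(axis=0) + 1e-12
            if mean_offsets is None:
                init = None
            else:
                off = mean_offsets[ci].reshape(len(self.K_CHOICES), d)[:k]
                init = base + off * spread  # offsets in units of class spread
            model.mixtures_[int(label)] = _fit_mixture(
                block, k, rng, max_iter=max_iter, init_means=init,
                warn_prune=False,
            )
        return model

    def fit(self, X: np.ndarray, y) -> "AAOGMMClassifier":
        X = np.asarray(X, dtype=float)
        y = as_int_labels(y)
        classes = sorted(np.unique(y))
        d = X.shape[1]
        kmax = len(self.K_CHOICES)
        dims = 1 + len(classes) * kmax * d

        def unpack(v: np.ndarray):
            k = self._decode_k(v[0] * kmax)  # v[0] in [0,1) scaled to k index
            offs = v[1:].reshape(len(classes), kmax, d) * 4.0 - 2.0
            return k, offs

        def objective(v: np.ndarray) -> float:
            k, offs = unpack(v)
            return self._internal_mse(X, y, k, offs, self.seed)

        # baseline: plain seeded EM per component count (zero offsets)
        best_v = None
        best_f = np.inf
        for ki in range(kmax):
            v = np.full(dims, 0.5)
            v[0] = (ki + 0.5) / kmax
            f = objective(v)
            if f < best_f:
                best_f, best_v = f, v
        bx, bf, trace = aao_optimize(
            objective, dims=dims, bounds=(0.0, 1.0), cfg=self.cfg, seed=self.seed
        )
        if bf < best_f:
            best_f, best_v = bf, bx
        self.search_trace_ = [min(best_f, t) for t in trace]
        k, offs = unpack(best_v)
        self.best_k_ = k
        self.model_ = self._build(X, y, k, offs, self.seed, max_iter=100)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("model not fitted")
        return self.model_.predict(X)

    def predict_outputs(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.scheme.target(p) for p in self.predict(X)])


# ---------------------------------------------------------------------------
# Factory
# ---------------------------------------------------------------------------

def make_classifier(name: str, seed: int = 0,
                    scheme: TargetScheme = TargetScheme(), **kwargs):
    """Instantiate one of the eight classifiers by name with its defaults."""
    if name == "gmm":
        return GMMClassifier(seed=seed, scheme=scheme, **kwargs)
    if name == "sdc":
        return SDCModel(scheme=scheme, **kwargs)
    if name == "hs":
        return HSClassifier(seed=seed, scheme=scheme, **kwargs)
    if name == "aao":
        return AAOClassifier(seed=seed, scheme=scheme, **kwargs)
    if name == "aao-gmm":
        return AAOGMMClassifier(seed=seed, scheme=scheme, **kwargs)
    if name.startswith("svm-"):
        kernel = {"svm-linear": "linear", "svm-poly": "poly", "svm-rbf": "rbf"}.get(name)
        if kernel is None:
            raise ValueError(f"unknown classifier {name!r}")
        return SVMModel(kernel=kernel, seed=seed, scheme=scheme, **kwargs)
    raise ValueError(f"unknown classifier {name!r}")
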