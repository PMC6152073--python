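"""Relevance vector machine: sparse Bayesian kernel regression on 0/1 labels.

The model places an independent zero-mean Gaussian prior of precision
``alpha_i`` on every kernel weight (plus a bias).  With a Gaussian
likelihood of noise variance ``sigma^2`` over the 0/1 targets, the weight
posterior is Gaussian:

    Sigma = (sigma^-2 Phi^T Phi + A)^-1,    A = diag(alpha)
    u     = sigma^-2 Sigma Phi^T t

Hyperparameters are re-estimated by evidence (type-II) maximization with
the classic fixed-point updates

    gamma_i       = 1 - alpha_i * Sigma_ii
    alpha_i_new   = gamma_i / u_i^2
    sigma^2_new   = ||t - Phi u||^2 / (N - sum_i gamma_i)   [optional]

Basis functions whose precision diverges (alpha above a pruning threshold)
are removed; the training inputs whose basis functions survive are the
relevance vectors.  Prediction is the plain kernel expansion
``y(x) = w0 + sum_j w_j k(x, rv_j)`` with a 0.5 decision threshold.

This is the regression-form RVM trained directly on 0/1 class labels (no
logistic link, no Laplace approximation); the continuous score is
thresholded for classification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

KERNELS = ("poly2", "linear", "rbf")


class RVMConvergenceWarning(UserWarning):
    """Emitted when evidence maximization hits max_iter without converging."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and width.

    ``poly2`` is the inhomogeneous degree-2 polynomial (1 + x.z/width)^2;
    ``rbf`` is exp(-||x-z||^2 / (2 width^2)); ``linear`` is the dot product.
    """

    name: str = "poly2"
    width: float = 1.0

    def __post_init__(self) -> None:
        name = {"ploy2": "poly2"}.get(self.name, self.name)  # toolbox spelling
        object.__setattr__(self, "name", name)
        if self.name not in KERNELS:
            raise ValueError(f"unknown kernel {self.name!r}; choose from {KERNELS}")
        if not self.width > 0:
            raise ValueError("kernel width must be positive")


@dataclass
class TrainingConfig:
    """Hyperparameter initialization and stopping rules for rvm_fit.

    ``init_alpha`` may be the rule ``"1/N"`` (every precision starts at the
    reciprocal of the training-set size) or an explicit positive float.
    ``init_sigma2=None`` applies the rule max(0.1 * var(t), 1e-3).
    Convergence is declared when the largest |change in log alpha| over
    surviving basis functions drops below ``tol``.

    ``update_sigma2`` controls whether the noise variance is re-estimated
    from the residual each iteration.  The default keeps it fixed at its
    initial value: on exactly fittable 0/1 targets the residual-based
    update drives sigma^2 to zero, which defeats pruning and makes the
    model interpolate the training labels (the classic degenerate
    maximum-likelihood variance estimate).  Set it to True for genuinely
    noisy regression targets.
    """

    init_alpha: Union[str, float] = "1/N"
    init_sigma2: Optional[float] = None
    max_iter: int = 1000
    alpha_prune: float = 1e12
    tol: float = 1e-3
    seed: int = 0
    update_sigma2: bool = False

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.alpha_prune > 0:
            raise ValueError("alpha_prune must be positive")
        if not self.tol > 0:
            raise ValueError("tol must be positive")

    def resolve_init_alpha(self, n: int) -> float:
        if isinstance(self.init_alpha, str):
            if self.init_alpha.strip() != "1/N":
                raise ValueError(f"unknown init_alpha rule {self.init_alpha!r}")
            return 1.0 / n
        if not self.init_alpha > 0:
            raise ValueError("init_alpha must be positive")
        return float(self.init_alpha)


@dataclass
class FitState:
    """Diagnostic snapshot of one evidence-maximization iteration."""

    alpha: np.ndarray          # precisions over the active set
    sigma2: float              # noise variance
    Sigma: np.ndarray          # posterior covariance (active set)
    u: np.ndarray              # posterior mean weights (active set)
    gamma: np.ndarray          # well-determinedness, in [0, 1]
    active: np.ndarray         # indices into the full basis (0 = bias)
    log_evidence: float = np.nan


@dataclass
class RVMModel:
    """A trained relevance vector machine."""

    kernel: KernelSpec
    relevance_vectors: np.ndarray     # m x d retained training inputs
    weights: np.ndarray               # m kernel weights
    bias: float                       # w0 (0.0 if the bias was pruned)
    bias_active: bool
    alpha_final: np.ndarray
    sigma2_final: float
    threshold: float = 0.5
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.relevance_vectors = np.atleast_2d(
            np.asarray(self.relevance_vectors, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.relevance_vectors.size and (
                len(self.weights) != self.relevance_vectors.shape[0]):
            raise ValueError("one weight per relevance vector required")

    @property
    def n_relevance_vectors(self) -> int:
        return 0 if self.relevance_vectors.size == 0 else self.relevance_vectors.shape[0]

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({
            "kernel": {"name": self.kernel.name, "width": self.kernel.width},
            "relevance_vectors": self.relevance_vectors.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "bias_active": self.bias_active,
            "alpha_final": np.asarray(self.alpha_final).tolist(),
            "sigma2_final": self.sigma2_final,
            "threshold": self.threshold,
            "metadata": self.metadata,
        }))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RVMModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            kernel=KernelSpec(**obj["kernel"]),
            relevance_vectors=np.array(obj["relevance_vectors"], dtype=float),
            weights=np.array(obj["weights"], dtype=float),
            bias=obj["bias"],
            bias_active=obj["bias_active"],
            alpha_final=np.array(obj["alpha_final"], dtype=float),
            sigma2_final=obj["sigma2_final"],
            threshold=obj["threshold"],
            metadata=obj.get("metadata", {}),
        )


def kernel_value(k: KernelSpec, x: np.ndarray, z: np.ndarray) -> float:
    """Evaluate the kernel on a single pair of vectors."""
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    if k.name == "linear":
        return float(x @ z)
    if k.name == "poly2":
        return float((1.0 + x @ z / k.width) ** 2)
    d2 = float(np.sum((x - z) ** 2))
    return float(np.exp(-d2 / (2.0 * k.width ** 2)))


def kernel_matrix(k: KernelSpec, X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """n x m Gram block of kernel values between rows of X and rows of B."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if X.shape[1] != B.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} features, B has {B.shape[1]}")
    if k.name == "linear":
        return X @ B.T
    if k.name == "poly2":
        return (1.0 + X @ B.T / k.width) ** 2
    d2 = (np.sum(X ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None, :]
          - 2.0 * X @ B.T)
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * k.width ** 2))


def design_matrix(k: KernelSpec, X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """n x (m+1) design matrix: a leading ones column, then kernel columns."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if X.size == 0 or B.size == 0:
        raise ValueError("design_matrix requires non-empty inputs")
    K = kernel_matrix(k, X, B)
    return np.hstack([np.ones((X.shape[0], 1)), K])


def posterior(phi: np.ndarray, t: np.ndarray, alpha: np.ndarray,
              sigma2: float) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian weight posterior (Sigma, u) for fixed hyperparameters.

    Solves Sigma = (sigma^-2 Phi^T Phi + diag(alpha))^-1 and
    u = sigma^-2 Sigma Phi^T t via Cholesky factorization, escalating a
    small diagonal jitter on near-singular systems before failing.
    """
    phi = np.asarray(phi, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    if phi.shape[0] != t.shape[0] or phi.shape[1] != alpha.shape[0]:
        raise ValueError("inconsistent shapes for phi, t, alpha")
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")

    m = phi.shape[1]
    H = phi.T @ phi / sigma2 + np.diag(alpha)
    jitter = 1e-10 * np.trace(H) / m
    for attempt in range(4):
        try:
            c = cho_factor(H if attempt == 0
                           else H + (jitter * 10 ** (attempt - 1)) * np.eye(m),
                           lower=True)
            break
        except LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError(
            f"posterior system singular beyond jitter tolerance "
            f"(cond ~ {np.linalg.cond(H):.3g})")
    Sigma = cho_solve(c, np.eye(m))
    Sigma = 0.5 * (Sigma + Sigma.T)
    u = cho_solve(c, phi.T @ t) / sigma2
    return Sigma, u


def log_marginal_likelihood(phi: np.ndarray, t: np.ndarray, alpha: np.ndarray,
                            sigma2: float) -> float:
    """Log evidence log p(t | alpha, sigma^2) of the active basis.

    Uses Omega = sigma^2 I + Phi A^-1 Phi^T; requires all alpha > 0.
    """
    phi = np.asarray(phi, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    n = t.shape[0]
    omega = sigma2 * np.eye(n) + (phi / alpha) @ phi.T
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    quad = float(t @ np.linalg.solve(omega, t))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def rvm_fit(X: np.ndarray, t: np.ndarray, k: Optional[KernelSpec] = None,
            cfg: Optional[TrainingConfig] = None) -> RVMModel:
    """Train an RVM by iterative evidence maximization with pruning.

    All training inputs seed the basis (plus a bias column).  Each
    iteration recomputes the posterior, re-estimates alpha and sigma^2 from
    the well-determinedness factors, and prunes basis functions whose
    precision exceeds ``cfg.alpha_prune``.  Iteration stops when the
    largest |change in log alpha| over surviving precisions falls below
    ``cfg.tol`` (the posterior from before the sub-tolerance update is
    kept) or at ``cfg.max_iter``, in which case a convergence warning is
    recorded in the model metadata.
    """
    k = k or KernelSpec()
    cfg = cfg or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two training samples")
    if X.shape[0] != t.shape[0]:
        raise ValueError("X and t length mismatch")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(t)):
        raise ValueError("training data contains NaN/Inf")
    classes = np.unique(t)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")

    phi_full = design_matrix(k, X, X)           # n x (n+1), column 0 = bias
    active = np.arange(n + 1)
    alpha = np.full(n + 1, cfg.resolve_init_alpha(n))
    sigma2 = (cfg.init_sigma2 if cfg.init_sigma2 is not None
              else max(0.1 * float(np.var(t)), 1e-3))

    evidence_path: List[float] = []
    converged = False
    Sigma = u = gamma = None
    n_iter = 0

    for n_iter in range(1, cfg.max_iter + 1):
        phi = phi_full[:, active]
        Sigma, u = posterior(phi, t, alpha, sigma2)
        gamma = np.clip(1.0 - alpha * np.diag(Sigma), 0.0, 1.0)
        evidence_path.append(log_marginal_likelihood(phi, t, alpha, sigma2))

        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = gamma / (u ** 2)
        alpha_new[~np.isfinite(alpha_new)] = np.inf

        if cfg.update_sigma2:
            resid = t - phi @ u
            denom = max(n - float(gamma.sum()), 1e-10)
            sigma2_new = max(float(resid @ resid) / denom, 1e-12)
        else:
            sigma2_new = sigma2

        survivors = alpha_new < cfg.alpha_prune
        if not survivors.any():
            survivors[np.argmin(alpha_new)] = True  # never empty the basis
        with np.errstate(divide="ignore"):
            delta = np.abs(np.log(alpha_new[survivors]) - np.log(alpha[survivors]))
        if delta.size and float(delta.max()) < cfg.tol:
            converged = True
            break

        alpha = alpha_new[survivors]
        sigma2 = sigma2_new
        keep_gamma = survivors
        active = active[survivors]
        Sigma = Sigma[np.ix_(survivors, survivors)]
        u = u[survivors]
        gamma = gamma[keep_gamma]

    if not converged:
        warnings.warn(
            f"evidence maximization did not converge in {cfg.max_iter} "
            f"iterations; returning best state", RVMConvergenceWarning)
        phi = phi_full[:, active]
        Sigma, u = posterior(phi, t, alpha, sigma2)
        gamma = np.clip(1.0 - alpha * np.diag(Sigma), 0.0, 1.0)

    bias_active = bool(active[0] == 0)
    rv_mask = active > 0
    rv_idx = active[rv_mask] - 1
    weights = u[rv_mask]
    bias = float(u[0]) if bias_active else 0.0

    return RVMModel(
        kernel=k,
        relevance_vectors=X[rv_idx] if rv_idx.size else np.empty((0, X.shape[1])),
        weights=weights,
        bias=bias,
        bias_active=bias_active,
        alpha_final=alpha,
        sigma2_final=float(sigma2),
        metadata={
            "n_iter": n_iter,
            "converged": converged,
            "log_evidence_path": evidence_path,
            "n_training_samples": n,
            "active_indices": active.tolist(),
            "gamma_final": gamma.tolist(),
        },
    )


def rvm_predict(m: RVMModel, X: np.ndarray) -> np.ndarray:
    """Continuous decision scores y(x) = w0 + sum_j w_j k(x, rv_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = np.full(X.shape[0], m.bias)
    if m.n_relevance_vectors:
        if X.shape[1] != m.relevance_vectors.shape[1]:
            raise ValueError(
                f"query dimension {X.shape[1]} != relevance-vector dimension "
                f"{m.relevance_vectors.shape[1]}")
        scores = scores + kernel_matrix(m.kernel, X, m.relevance_vectors) @ m.weights
    return scores


def rvm_classify(m: RVMModel, X: np.ndarray) -> np.ndarray:
    """Hard 0/1 labels: 1 iff the continuous score >= the model threshold."""
    return (rvm_predict(m, X) >= m.threshold).astype(int)
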