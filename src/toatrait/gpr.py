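"""Anisotropic squared-exponential Gaussian-process regression with uncertainty.

The kernel between two band-reflectance vectors is

    k(x_i, x_j) = sigma_s^2 * exp( -1/2 * sum_b [(x_i(b) - x_j(b)) / sigma_b]^2 )

with one length-scale per band (anisotropic / ARD form).  Training maximizes
the log marginal likelihood over {sigma_s^2, sigma_b, sigma_n^2} by
quasi-Newton optimization on log-hyperparameters with seeded multi-start
restarts.  Prediction at a query x* returns

    mean(x*) = k*^T (K + sigma_n^2 I)^-1 y
    var(x*)  = c* - k*^T (K + sigma_n^2 I)^-1 k*,   c* = k(x*, x*) + sigma_n^2

Inputs are z-scored per band and targets z-scored before training; statistics
are stored in the model and predictions are back-transformed.

:class:`PortableModel` factorizes everything that depends only on the
hyperparameters and training data — the weight vector alpha and the explicit
inverse of (K + sigma_n^2 I) — into a self-contained, human-readable JSON
document so that per-pixel map prediction reduces to elementwise kernel
evaluation plus small matrix products, with no optimizer state attached.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "GPRHyperparams",
    "TrainConfig",
    "GPRModel",
    "PredictionResult",
    "PortableModel",
    "kernel",
    "kernel_matrix",
    "train",
    "predict",
    "export_portable",
    "predict_portable",
]

PORTABLE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GPRHyperparams:
    """Kernel signal variance, per-band length-scales, and noise variance."""

    sigma_s2: float
    sigma_b: np.ndarray
    sigma_n2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_b", np.asarray(self.sigma_b, dtype=float))
        if self.sigma_s2 <= 0 or self.sigma_n2 <= 0 or np.any(self.sigma_b <= 0):
            raise ValueError("all hyperparameters must be strictly positive")

    @property
    def D(self) -> int:
        return self.sigma_b.size


@dataclass(frozen=True)
class TrainConfig:
    """Multi-start optimizer settings for marginal-likelihood maximization."""

    n_restarts: int = 5
    max_iter: int = 200
    # log10 ranges for random restarts (z-scored feature space)
    lengthscale_range: tuple[float, float] = (-1.0, 1.0)
    signal_range: tuple[float, float] = (-0.5, 0.5)
    noise_range: tuple[float, float] = (-4.0, -1.0)
    # natural-log optimizer bounds; on z-scored data the signal variance is
    # O(1), so capping it avoids the flat ridge where sigma_s2 and the
    # length-scales grow jointly without bound (poor variance calibration)
    signal_bounds: tuple[float, float] = (-6.0, 3.0)
    lengthscale_bounds: tuple[float, float] = (-6.0, 5.0)
    noise_bounds: tuple[float, float] = (-12.0, 1.0)


@dataclass
class PredictionResult:
    """Predictive mean, variance and SD in trait units."""

    mean: np.ndarray | float
    variance: np.ndarray | float
    sd: np.ndarray | float


def kernel(xi: np.ndarray, xj: np.ndarray, hyper: GPRHyperparams) -> float:
    """Anisotropic squared-exponential covariance between two vectors."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.ndim != 1 or xi.size != hyper.D:
        raise ValueError("kernel inputs must be D-vectors matching the hyperparameters")
    return float(hyper.sigma_s2 * np.exp(-0.5 * np.sum(((xi - xj) / hyper.sigma_b) ** 2)))


def kernel_matrix(A: np.ndarray, B: np.ndarray, hyper: GPRHyperparams) -> np.ndarray:
    """Covariance matrix between row sets A (n, D) and B (m, D)."""
    As = A / hyper.sigma_b
    Bs = B / hyper.sigma_b
    d2 = (
        np.sum(As**2, axis=1)[:, None]
        + np.sum(Bs**2, axis=1)[None, :]
        - 2.0 * As @ Bs.T
    )
    return hyper.sigma_s2 * np.exp(-0.5 * np.maximum(d2, 0.0))


def _chol_with_jitter(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factorization with adaptive diagonal jitter (1e-10 .. 1e-4)."""
    jitter = 0.0
    for j in [0.0] + [1e-10 * 10**k for k in range(7)]:
        try:
            L = linalg.cholesky(A + j * np.eye(A.shape[0]), lower=True)
            return L, j
        except linalg.LinAlgError:
            jitter = j
            continue
    raise linalg.LinAlgError(f"matrix not positive definite even with jitter {jitter}")


@dataclass
class GPRModel:
    """A trained Gaussian-process regressor with its precomputed solves."""

    hyper: GPRHyperparams
    X_train: np.ndarray          # raw inputs (N, D)
    y_train: np.ndarray          # raw targets (N,)
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    alpha: np.ndarray            # (K + sigma_n2 I)^-1 y_n
    chol_K: np.ndarray           # lower-triangular factor of (K + sigma_n2 I)
    log_marginal_likelihood: float
    jitter: float = 0.0
    trait: str = ""
    units: str = ""
    band_centers: np.ndarray | None = None
    seed: int | None = None

    @property
    def Xn(self) -> np.ndarray:
        return (self.X_train - self.x_mean) / self.x_sd

    @classmethod
    def from_hyperparams(cls, X, y, hyper: GPRHyperparams, *, normalize: bool = True,
                         trait: str = "", units: str = "",
                         band_centers=None, seed=None) -> "GPRModel":
        """Build the linear-algebra terms for fixed hyperparameters (no optimization)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (N, D) with one target per row")
        if X.shape[0] < 2:
            raise ValueError("at least two training samples required")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite entries in training data")
        if normalize:
            x_mean = X.mean(axis=0)
            x_sd = X.std(axis=0)
            x_sd[x_sd == 0] = 1.0
            y_mean = float(y.mean())
            y_sd = float(y.std()) or 1.0
        else:
            x_mean = np.zeros(X.shape[1])
            x_sd = np.ones(X.shape[1])
            y_mean, y_sd = 0.0, 1.0
        Xn = (X - x_mean) / x_sd
        yn = (y - y_mean) / y_sd
        K = kernel_matrix(Xn, Xn, hyper) + hyper.sigma_n2 * np.eye(X.shape[0])
        L, jit = _chol_with_jitter(K)
        alpha = linalg.cho_solve((L, True), yn)
        lml = float(
            -0.5 * yn @ alpha - np.sum(np.log(np.diag(L)))
            - 0.5 * X.shape[0] * np.log(2.0 * np.pi)
        )
        return cls(
            hyper=hyper, X_train=X, y_train=y, x_mean=x_mean, x_sd=x_sd,
            y_mean=y_mean, y_sd=y_sd, alpha=alpha, chol_K=L,
            log_marginal_likelihood=lml, jitter=jit, trait=trait, units=units,
            band_centers=None if band_centers is None else np.asarray(band_centers, float),
            seed=seed,
        )


def _nll_and_grad(log_params: np.ndarray, Xn: np.ndarray, yn: np.ndarray,
                  sqd: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood and its gradient in log-parameters.

    ``sqd`` holds the per-band squared differences, shape (D, N, N).
    """
    D = sqd.shape[0]
    N = Xn.shape[0]
    s2 = np.exp(log_params[0])
    ls2 = np.exp(2.0 * log_params[1 : D + 1])   # sigma_b^2
    sn2 = np.exp(log_params[-1])
    Q = np.tensordot(1.0 / ls2, sqd, axes=(0, 0))
    K = s2 * np.exp(-0.5 * Q)
    A = K + sn2 * np.eye(N)
    try:
        L = linalg.cholesky(A, lower=True)
    except linalg.LinAlgError:
        return 1e25, np.zeros_like(log_params)
    alpha = linalg.cho_solve((L, True), yn)
    nll = 0.5 * yn @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * N * np.log(2 * np.pi)
    Kinv = linalg.cho_solve((L, True), np.eye(N))
    W = np.outer(alpha, alpha) - Kinv
    grad = np.empty_like(log_params)
    grad[0] = -0.5 * np.sum(W * K)
    for b in range(D):
        # d K / d log sigma_b = K * sqd_b / sigma_b^2
        grad[1 + b] = -0.5 * np.sum(W * K * sqd[b]) / ls2[b]
    grad[-1] = -0.5 * np.trace(W) * sn2
    return float(nll), grad


def train(X, y, opts: TrainConfig = TrainConfig(), seed: int = 0, *,
          trait: str = "", units: str = "", band_centers=None,
          init: GPRHyperparams | None = None) -> GPRModel:
    """Fit hyperparameters by maximizing the log marginal likelihood.

    Runs a quasi-Newton (L-BFGS-B) search on log-hyperparameters from
    ``opts.n_restarts`` seeded random starts (plus ``init`` as a warm start
    when given) and keeps the best optimum found.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (N, D) with one target per row")
    if X.shape[0] < 2:
        raise ValueError("at least two training samples required")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in training data")
    if np.ptp(y) == 0.0:
        warnings.warn("constant training targets: model degenerates to the mean",
                      stacklevel=2)
    N, D = X.shape
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean = float(y.mean())
    y_sd = float(y.std()) or 1.0
    Xn = (X - x_mean) / x_sd
    yn = (y - y_mean) / y_sd
    diff = Xn[:, None, :] - Xn[None, :, :]
    sqd = np.ascontiguousarray(np.moveaxis(diff**2, -1, 0))  # (D, N, N)

    rng = np.random.default_rng(seed)
    ln10 = np.log(10.0)
    # ARD median-style heuristic: with z-scored features, typical pairwise
    # distances are ~sqrt(2D), so length-scales of order sqrt(D) put the
    # kernel in its informative regime (sigma_b = 1 would make the Gram
    # matrix near-diagonal and strand the optimizer in the noise-only basin)
    ls0 = 0.5 * np.log(D)
    starts = []
    if init is not None:
        # warm start: refine the supplied hyperparameters (plus the heuristic
        # as a safety net)
        starts.append(np.concatenate([
            [np.log(init.sigma_s2)], np.log(init.sigma_b), [np.log(init.sigma_n2)]
        ]))
        starts.append(np.concatenate([[0.0], np.full(D, ls0), [np.log(1e-1)]]))
    else:
        # the initial noise level decides which basin L-BFGS lands in: from a
        # tiny sigma_n2 the fastest descent direction on misfit data is to
        # inflate the noise, collapsing to the mean-only solution; cover a
        # moderate-noise start in two length-scale regimes plus one
        # near-interpolation start
        for ls, n2 in ((ls0, 1e-1), (0.0, 1e-1), (ls0, 1e-2)):
            starts.append(np.concatenate([[0.0], np.full(D, ls), [np.log(n2)]]))
    n_random = max(0, opts.n_restarts - 1)
    for _ in range(n_random):
        starts.append(np.concatenate([
            [rng.uniform(*opts.signal_range) * ln10],
            ls0 + rng.uniform(*opts.lengthscale_range, D) * ln10,
            [rng.uniform(*opts.noise_range) * ln10],
        ]))

    bounds = ([opts.signal_bounds] + [opts.lengthscale_bounds] * D
              + [opts.noise_bounds])
    best = None
    start_nlls = []
    for x0 in starts:
        start_nlls.append(_nll_and_grad(x0, Xn, yn, sqd)[0])
        res = optimize.minimize(
            _nll_and_grad, x0, args=(Xn, yn, sqd), jac=True,
            method="L-BFGS-B", bounds=bounds, options={"maxiter": opts.max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e24:
        raise linalg.LinAlgError("covariance matrix singular at every start point")
    # optimum can never be worse than the best start we evaluated
    lp = best.x if best.fun <= min(start_nlls) else starts[int(np.argmin(start_nlls))]
    hyper = GPRHyperparams(
        sigma_s2=float(np.exp(lp[0])),
        sigma_b=np.exp(lp[1 : D + 1]),
        sigma_n2=float(np.exp(lp[-1])),
    )
    model = GPRModel.from_hyperparams(
        X, y, hyper, trait=trait, units=units, band_centers=band_centers, seed=seed
    )
    return model


def predict(model: GPRModel, x_star) -> PredictionResult:
    """Predictive mean and variance at one query or a batch of queries."""
    x = np.asarray(x_star, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.X_train.shape[1]:
        raise ValueError("query dimension does not match training inputs")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite query")
    Xs = (X - model.x_mean) / model.x_sd
    Kstar = kernel_matrix(Xs, model.Xn, model.hyper)
    mean_n = Kstar @ model.alpha
    V = linalg.solve_triangular(model.chol_K, Kstar.T, lower=True)
    c_star = model.hyper.sigma_s2 + model.hyper.sigma_n2
    var_n = np.maximum(c_star - np.sum(V**2, axis=0), 0.0)
    mean = model.y_mean + model.y_sd * mean_n
    var = model.y_sd**2 * var_n
    sd = np.sqrt(var)
    if single:
        return PredictionResult(float(mean[0]), float(var[0]), float(sd[0]))
    return PredictionResult(mean, var, sd)


# ---------------------------------------------------------------------------
# Portable (factorized) models
# ---------------------------------------------------------------------------

@dataclass
class PortableModel:
    """Self-contained factorized model: everything prediction needs, nothing else."""

    schema_version: int
    trait: str
    units: str
    band_centers: list[float]
    hyper: GPRHyperparams
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    Xn: np.ndarray               # normalized training inputs (N, D)
    alpha: np.ndarray
    K_inv: np.ndarray            # explicit inverse of (K + sigma_n2 I [+ jitter])
    provenance: dict = field(default_factory=dict)

    @property
    def D(self) -> int:
        return self.Xn.shape[1]

    def to_json(self) -> str:
        doc = {
            "schema_version": self.schema_version,
            "trait": self.trait,
            "units": self.units,
            "band_centers": list(map(float, self.band_centers)),
            "hyperparameters": {
                "sigma_s2": self.hyper.sigma_s2,
                "sigma_b": self.hyper.sigma_b.tolist(),
                "sigma_n2": self.hyper.sigma_n2,
            },
            "normalization": {
                "x_mean": self.x_mean.tolist(),
                "x_sd": self.x_sd.tolist(),
                "y_mean": self.y_mean,
                "y_sd": self.y_sd,
            },
            "X_train": self.Xn.tolist(),
            "alpha": self.alpha.tolist(),
            "K_inv": self.K_inv.tolist(),
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "PortableModel":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupted portable-model document: {exc}") from exc
        version = doc.get("schema_version")
        if version != PORTABLE_SCHEMA_VERSION:
            raise ValueError(f"unsupported portable-model schema version {version!r}")
        hp = doc["hyperparameters"]
        norm = doc["normalization"]
        return cls(
            schema_version=version,
            trait=doc["trait"],
            units=doc["units"],
            band_centers=doc["band_centers"],
            hyper=GPRHyperparams(hp["sigma_s2"], np.array(hp["sigma_b"]), hp["sigma_n2"]),
            x_mean=np.array(norm["x_mean"], dtype=float),
            x_sd=np.array(norm["x_sd"], dtype=float),
            y_mean=float(norm["y_mean"]),
            y_sd=float(norm["y_sd"]),
            Xn=np.array(doc["X_train"], dtype=float),
            alpha=np.array(doc["alpha"], dtype=float),
            K_inv=np.array(doc["K_inv"], dtype=float),
            provenance=doc.get("provenance", {}),
        )

    @classmethod
    def load(cls, path) -> "PortableModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def export_portable(model: GPRModel) -> PortableModel:
    """Precompute alpha and the explicit covariance inverse for lightweight use."""
    N = model.X_train.shape[0]
    K_inv = linalg.cho_solve((model.chol_K, True), np.eye(N))
    train_hash = hashlib.sha256(
        np.ascontiguousarray(model.X_train).tobytes()
        + np.ascontiguousarray(model.y_train).tobytes()
    ).hexdigest()[:16]
    return PortableModel(
        schema_version=PORTABLE_SCHEMA_VERSION,
        trait=model.trait,
        units=model.units,
        band_centers=[] if model.band_centers is None else list(map(float, model.band_centers)),
        hyper=model.hyper,
        x_mean=model.x_mean.copy(),
        x_sd=model.x_sd.copy(),
        y_mean=model.y_mean,
        y_sd=model.y_sd,
        Xn=model.Xn.copy(),
        alpha=model.alpha.copy(),
        K_inv=K_inv,
        provenance={
            "training_hash": train_hash,
            "seed": model.seed,
            "n_train": int(N),
        },
    )


def predict_portable(pm: PortableModel, x_star) -> PredictionResult:
    """Prediction from the factorized terms alone.

    All reductions use fixed-order elementwise summation (einsum without
    BLAS dispatch), so results are bit-identical regardless of how queries
    are batched or tiled.
    """
    x = np.asarray(x_star, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != pm.D:
        raise ValueError("query dimension does not match the portable model")
    Xs = (X - pm.x_mean) / pm.x_sd
    d2 = np.einsum(
        "mjb->mj",
        ((Xs[:, None, :] - pm.Xn[None, :, :]) / pm.hyper.sigma_b) ** 2,
        optimize=False,
    )
    Kstar = pm.hyper.sigma_s2 * np.exp(-0.5 * d2)
    mean_n = np.einsum("mj,j->m", Kstar, pm.alpha, optimize=False)
    q = np.einsum("mj,jk,mk->m", Kstar, pm.K_inv, Kstar, optimize=False)
    c_star = pm.hyper.sigma_s2 + pm.hyper.sigma_n2
    var_n = np.maximum(c_star - q, 0.0)
    mean = pm.y_mean + pm.y_sd * mean_n
    var = pm.y_sd**2 * var_n
    sd = np.sqrt(var)
    if single:
        return PredictionResult(float(mean[0]), float(var[0]), float(sd[0]))
    return PredictionResult(mean, var, sd)
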