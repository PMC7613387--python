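"""Euclidean-distance-based diversity (EBD) active learning for training-set reduction.

Starting from a small random subset of the simulated pool, the loop
repeatedly proposes the pool candidate farthest (in min squared Euclidean
distance over the current training set, computed on z-scored band
reflectances) from the samples already included, tentatively retrains the
regressor with the candidate added, and accepts the candidate only when the
validation RMSE against the in situ table strictly decreases.  Every
candidate is evaluated exactly once; rejected candidates are discarded.
The result is a much smaller training set whose validation error never rose
at any acceptance event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpr import GPRHyperparams, GPRModel, TrainConfig, predict, train
from .lut import TrainingSet

__all__ = ["ALConfig", "ALResult", "ebd_distance", "ebd_select", "al_optimize"]


def ebd_distance(candidate: np.ndarray, training: np.ndarray,
                 aggregation: str = "maximin") -> float:
    """Diversity distance of one candidate from a set of training rows.

    ``maximin`` (default) returns the minimum over training rows of the
    squared Euclidean distance ||x_u - x_l||^2; ``mean`` returns the mean.
    """
    training = np.atleast_2d(np.asarray(training, dtype=float))
    candidate = np.asarray(candidate, dtype=float)
    if training.shape[0] == 0:
        raise ValueError("training set is empty")
    if candidate.shape[-1] != training.shape[1]:
        raise ValueError("dimension mismatch between candidate and training rows")
    d2 = np.sum((training - candidate) ** 2, axis=1)
    if aggregation == "maximin":
        return float(d2.min())
    if aggregation == "mean":
        return float(d2.mean())
    raise ValueError(f"unknown aggregation {aggregation!r}")


def ebd_select(pool: np.ndarray, training: np.ndarray,
               aggregation: str = "maximin") -> int:
    """Index of the pool row farthest from the training set (ties -> lowest index)."""
    pool = np.atleast_2d(np.asarray(pool, dtype=float))
    if pool.shape[0] == 0:
        raise ValueError("candidate pool is empty")
    d = np.array([ebd_distance(row, training, aggregation) for row in pool])
    return int(np.argmax(d))  # argmax returns the first maximum -> lowest index


@dataclass(frozen=True)
class ALConfig:
    """Settings of the EBD active-learning loop."""

    init_fraction: float = 0.05
    max_iterations: int | None = None
    aggregation: str = "maximin"
    force_include_nonveg: bool = False
    train_config: TrainConfig = field(default_factory=lambda: TrainConfig(n_restarts=3))
    reopt_config: TrainConfig = field(default_factory=lambda: TrainConfig(
        n_restarts=0, max_iter=8))


@dataclass
class ALResult:
    """Reduced training set, per-iteration history, and the final model."""

    training_set: TrainingSet
    history: pd.DataFrame
    model: GPRModel
    initial_rmse: float
    final_rmse: float
    selected_indices: np.ndarray
    n_pool: int

    @property
    def reduction_percent(self) -> float:
        """Pool-size reduction achieved, in percent."""
        return 100.0 * (1.0 - len(self.training_set) / self.n_pool)


def _rmse(observed: np.ndarray, estimated: np.ndarray) -> float:
    return float(np.sqrt(np.mean((observed - estimated) ** 2)))


def initial_subset_size(n_pool: int, init_fraction: float = 0.05) -> int:
    """Number of seeded-random rows the loop starts from (ceil of the fraction)."""
    return int(np.ceil(init_fraction * n_pool))


def al_optimize(pool: TrainingSet, validation: pd.DataFrame, trait: str,
                cfg: ALConfig = ALConfig(), seed: int = 0) -> ALResult:
    """Run the RMSE-gated EBD loop for one trait.

    ``validation`` pairs measured trait values (column ``trait``) with the
    band reflectances named as in ``pool.band_names``.  Hyperparameters are
    optimized on the initial subset, then warm-start re-optimized at every
    acceptance; between acceptances only the linear-algebra terms are
    rebuilt.  A hyperparameter update that worsens validation RMSE is
    discarded so the loop's monotonicity guarantee carries to the final model.
    """
    if trait not in validation.columns:
        raise ValueError(f"validation table lacks trait column {trait!r}")
    if trait not in pool.trait_names:
        raise ValueError(f"pool is not labeled for trait {trait!r}")
    missing = [b for b in pool.band_names if b not in validation.columns]
    if missing:
        raise ValueError(f"validation table lacks band column(s) {missing}")

    n_pool = len(pool)
    n_init = initial_subset_size(n_pool, cfg.init_fraction)
    if n_pool < n_init or n_init < 2:
        raise ValueError("pool smaller than the initial fraction")

    rng = np.random.default_rng(seed)
    X_val = validation[pool.band_names].to_numpy(dtype=float)
    y_val = validation[trait].to_numpy(dtype=float)
    y_pool = pool.traits[trait].to_numpy(dtype=float)

    # z-score band space for diversity distances (pool statistics)
    mu = pool.X.mean(axis=0)
    sd = pool.X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (pool.X - mu) / sd

    forced = np.zeros(n_pool, dtype=bool)
    if cfg.force_include_nonveg:
        forced = pool.provenance == "non_vegetated"
    free = np.flatnonzero(~forced)
    init_idx = rng.choice(free, size=n_init, replace=False)
    in_train = np.zeros(n_pool, dtype=bool)
    in_train[init_idx] = True
    in_train[forced] = True

    model = train(pool.X[in_train], y_pool[in_train], cfg.train_config, seed=seed)
    best_rmse = _rmse(y_val, predict(model, X_val).mean)
    initial_rmse = best_rmse

    # running min squared distance of every pool row to the training set
    min_d2 = np.full(n_pool, np.inf)
    for i in np.flatnonzero(in_train):
        min_d2 = np.minimum(min_d2, np.sum((Z - Z[i]) ** 2, axis=1))

    remaining = np.ones(n_pool, dtype=bool)
    remaining[in_train] = False
    records = []
    it = 0
    while remaining.any():
        if cfg.max_iterations is not None and it >= cfg.max_iterations:
            break
        cand_ids = np.flatnonzero(remaining)
        if cfg.aggregation == "maximin":
            cand = int(cand_ids[np.argmax(min_d2[cand_ids])])
            d_e = float(min_d2[cand])
        else:
            local = ebd_select(Z[cand_ids], Z[in_train], cfg.aggregation)
            cand = int(cand_ids[local])
            d_e = ebd_distance(Z[cand], Z[in_train], cfg.aggregation)
        remaining[cand] = False

        trial = in_train.copy()
        trial[cand] = True
        trial_model = GPRModel.from_hyperparams(pool.X[trial], y_pool[trial], model.hyper)
        rmse = _rmse(y_val, predict(trial_model, X_val).mean)
        accepted = rmse < best_rmse
        if accepted:
            in_train = trial
            min_d2 = np.minimum(min_d2, np.sum((Z - Z[cand]) ** 2, axis=1))
            # warm-start hyperparameter re-optimization; keep only if it
            # does not hurt validation accuracy
            reopt = train(pool.X[in_train], y_pool[in_train], cfg.reopt_config,
                          seed=seed + it + 1, init=model.hyper)
            rmse_reopt = _rmse(y_val, predict(reopt, X_val).mean)
            if rmse_reopt <= rmse:
                model, best_rmse = reopt, rmse_reopt
            else:
                model, best_rmse = trial_model, rmse
        records.append((it, cand, d_e, rmse, accepted))
        it += 1

    history = pd.DataFrame(records,
                           columns=["iter", "candidate_id", "d_E", "rmse", "accepted"])
    selected = np.flatnonzero(in_train)
    final = pool.subset(selected)
    model = GPRModel.from_hyperparams(
        pool.X[in_train], y_pool[in_train], model.hyper, trait=trait, seed=seed
    )
    final_rmse = _rmse(y_val, predict(model, X_val).mean)
    return ALResult(
        training_set=final, history=history, model=model,
        initial_rmse=initial_rmse, final_rmse=final_rmse,
        selected_indices=selected, n_pool=n_pool,
    )
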