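"""Cross-validated prediction metrics and the subsampling-proportion sweep.

Predictive performance is measured on pooled out-of-fold predictions from a
k-fold split: Pearson correlation between observed and predicted values
(predictive ability), mean squared prediction error, and the dispersion bias
as the ordinary-least-squares slope of observations on predictions (1 =
unbiased; < 1 means over-dispersed predictions).  Computational cost is
tracked with a deterministic in-bag observation-touch counter (exactly
p * round(psi * n_train) per MCMC round), which is linear in the subsampling
proportion psi; wall-clock minutes are recorded for reporting only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    GenotypeMatrix,
    InvalidConfigError,
    InvalidInputError,
    MCMCConfig,
    PriorSpec,
    compute_prior_shapes,
    predict,
    run_chain,
)


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per individual; folds partition 0..n-1 with sizes
    differing by at most one."""

    fold: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold != fold)


@dataclass(frozen=True)
class PredictionMetrics:
    predictive_ability: float
    mspe: float
    bias_slope: float
    op_count: int
    wall_minutes: float


@dataclass(frozen=True)
class CrossValidationResult:
    per_fold: tuple[PredictionMetrics, ...]
    aggregate: PredictionMetrics
    observed: np.ndarray
    predicted: np.ndarray
    folds: FoldAssignment


@dataclass(frozen=True)
class SweepResult:
    """Per-fold metric rows over the (psi, replacement-mode) grid."""

    table: pd.DataFrame       # psi, mode, fold, metrics (one row per fold x rep)
    aggregate: pd.DataFrame   # psi, mode, pooled metrics (one row per grid point)


def kfold_split(n: int, k: int, seed: int) -> FoldAssignment:
    """Seed-reproducible random partition into k folds of size
    floor(n/k) or ceil(n/k)."""
    if not 2 <= k <= n:
        raise InvalidInputError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=np.int64)
    base, extra = divmod(n, k)
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        fold[perm[start:start + size]] = f
        start += size
    return FoldAssignment(fold=fold, k=k)


def _check_pair(observed, predicted):
    y = np.asarray(observed, dtype=np.float64)
    yhat = np.asarray(predicted, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise InvalidInputError("observed/predicted must be 1-D vectors of equal length")
    return y, yhat


def mspe(observed, predicted) -> float:
    """Mean squared prediction error."""
    y, yhat = _check_pair(observed, predicted)
    if y.size < 1:
        raise InvalidInputError("need at least one observation")
    return float(np.mean((y - yhat) ** 2))


def bias_slope(observed, predicted) -> float:
    """OLS slope of observed on predicted (cov(y, yhat) / var(yhat))."""
    y, yhat = _check_pair(observed, predicted)
    if y.size < 3:
        raise InvalidInputError("need at least 3 observations")
    var_pred = float(np.var(yhat, ddof=1))
    if var_pred == 0:
        raise InvalidInputError("undefined slope: predictions are constant")
    cov = float(np.cov(y, yhat, ddof=1)[0, 1])
    return cov / var_pred


def predictive_ability(observed, predicted) -> float:
    """Pearson correlation between observations and predictions."""
    y, yhat = _check_pair(observed, predicted)
    if y.size < 3:
        raise InvalidInputError("need at least 3 observations")
    if np.var(y) == 0 or np.var(yhat) == 0:
        raise InvalidInputError("undefined correlation: zero variance")
    return float(np.corrcoef(y, yhat)[0, 1])


def _fold_seeds(seed: int, count: int) -> np.ndarray:
    # deterministic child seeds below 2^31
    return np.random.SeedSequence(seed).generate_state(count) % (2**31)


def cross_validate(
    phenotypes,
    genotypes: GenotypeMatrix,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    """k-fold cross-validation of the Bayesian ridge fit.

    Prior shapes and marker sums of squares are recomputed on the training
    rows of each fold (no leakage); metrics are reported per fold and on the
    pooled out-of-fold predictions.  ``priors`` supplies the R^2 and degrees
    of freedom used by the per-fold elicitation.
    """
    y = np.asarray(phenotypes, dtype=np.float64)
    if config is None:
        config = MCMCConfig()
    settings = priors if priors is not None else PriorSpec()
    folds = kfold_split(y.shape[0], k, seed)
    chain_seeds = _fold_seeds(seed, k)
    predicted = np.empty_like(y)
    per_fold = []
    total_ops = 0
    total_wall = 0.0
    for f in range(k):
        tr = folds.train_indices(f)
        te = folds.test_indices(f)
        gtrain = genotypes.subset_rows(tr)
        fold_priors = compute_prior_shapes(
            y[tr], gtrain, settings.r_squared, settings.nu_b, settings.nu_e
        )
        t0 = time.perf_counter()
        summary = run_chain(
            y[tr], gtrain, fold_priors, replace(config, seed=int(chain_seeds[f]))
        )
        wall = (time.perf_counter() - t0) / 60.0
        yhat = predict(genotypes.subset_rows(te), summary)
        predicted[te] = yhat
        ops = summary.diagnostics["op_count"]
        total_ops += ops
        total_wall += wall
        per_fold.append(
            PredictionMetrics(
                predictive_ability=predictive_ability(y[te], yhat),
                mspe=mspe(y[te], yhat),
                bias_slope=bias_slope(y[te], yhat),
                op_count=ops,
                wall_minutes=wall,
            )
        )
    aggregate = PredictionMetrics(
        predictive_ability=predictive_ability(y, predicted),
        mspe=mspe(y, predicted),
        bias_slope=bias_slope(y, predicted),
        op_count=total_ops,
        wall_minutes=total_wall,
    )
    return CrossValidationResult(
        per_fold=tuple(per_fold),
        aggregate=aggregate,
        observed=y,
        predicted=predicted,
        folds=folds,
    )


def subsampling_sweep(
    phenotypes,
    genotypes: GenotypeMatrix,
    priors: PriorSpec | None = None,
    base_config: MCMCConfig | None = None,
    psi_min: float = 0.25,
    psi_max: float = 1.0,
    step: float = 0.01,
    modes: tuple[bool, ...] = (False, True),
    k: int = 10,
    seed: int = 0,
    replicates: int = 1,
) -> SweepResult:
    """Cross-validate over a grid of subsampling proportions and replacement
    modes; single-run psi curves are noisy, so a replicate count over fresh
    CV seeds is available."""
    if not 0.0 < psi_min <= psi_max <= 1.0:
        raise InvalidConfigError("need 0 < psi_min <= psi_max <= 1")
    if step <= 0:
        raise InvalidConfigError("step must be positive")
    if base_config is None:
        base_config = MCMCConfig()
    n_points = int(round((psi_max - psi_min) / step)) + 1
    psis = np.round(psi_min + step * np.arange(n_points), 10)
    psis = psis[psis <= 1.0 + 1e-12]
    if psis.size == 0:
        raise InvalidConfigError("empty psi grid")
    rep_seeds = _fold_seeds(seed, max(replicates, 1))
    rows = []
    agg_rows = []
    for psi in psis:
        for mode in modes:
            cfg = replace(base_config, psi=float(min(psi, 1.0)), with_replacement=mode)
            agg_acc = []
            for r in range(replicates):
                res = cross_validate(
                    phenotypes, genotypes, priors, cfg, k=k, seed=int(rep_seeds[r])
                )
                for f, m in enumerate(res.per_fold):
                    rows.append(
                        {
                            "psi": float(psi),
                            "mode": "wR" if mode else "woR",
                            "replicate": r,
                            "fold": f,
                            "predictive_ability": m.predictive_ability,
                            "mspe": m.mspe,
                            "bias_slope": m.bias_slope,
                            "op_count": m.op_count,
                            "wall_minutes": m.wall_minutes,
                        }
                    )
                agg_acc.append(res.aggregate)
            agg_rows.append(
                {
                    "psi": float(psi),
                    "mode": "wR" if mode else "woR",
                    "predictive_ability": float(
                        np.mean([a.predictive_ability for a in agg_acc])
                    ),
                    "mspe": float(np.mean([a.mspe for a in agg_acc])),
                    "bias_slope": float(np.mean([a.bias_slope for a in agg_acc])),
                    "op_count": int(np.mean([a.op_count for a in agg_acc])),
                    "wall_minutes": float(np.mean([a.wall_minutes for a in agg_acc])),
                }
            )
    return SweepResult(table=pd.DataFrame(rows), aggregate=pd.DataFrame(agg_rows))
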