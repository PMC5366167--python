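"""Bayesian ridge regression for genomic prediction, fitted by a Gibbs
sampler with Gauss-Seidel residual updating (GSRU) and optional per-round
subsampling of observations (the subsampling bootstrap Markov chain, SBMC).

Model
-----
    y = 1*mu + X b + e,   b ~ N(0, I sigma_b^2),   e ~ N(0, I sigma_e^2)

with scaled-inverse-chi-squared priors on both variance components and the
ridge penalty lambda = sigma_e^2 / sigma_b^2.  Marker effects are updated
coordinate-wise; after each coefficient change the full residual vector is
updated incrementally so that e = y - mu - X b holds at all times.

Under subsampling, each MCMC round draws one random bag of
``m = round(psi * n)`` observations (with or without replacement) that is
shared by the intercept update, all p coefficient updates and the residual
variance update.  The marker sum of squares x_j'x_j is precomputed once on
the full data and scaled by psi rather than recomputed per bag, assuming
bag allele frequencies match the full panel.  The genetic variance update
uses the full effect vector and is unaffected by subsampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernels import sweep_coefficients_full, sweep_coefficients_subsampled

VAR_FLOOR = 1e-12


class InvalidInputError(ValueError):
    """Raised when data fail a precondition (shapes, values, variances)."""


class InvalidConfigError(ValueError):
    """Raised when a sampler or experiment configuration is inconsistent."""


class NumericalDegeneracyError(ArithmeticError):
    """Raised when a conditional distribution is undefined (e.g. zero precision)."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x p allele-count matrix with entries in {0, 1, 2}.

    Rows are individuals, columns are markers; entry counts copies of one
    allele (0/1/2 for the two homozygotes and the heterozygote).
    """

    values: np.ndarray
    marker_ids: tuple[str, ...]
    individual_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise InvalidInputError("genotype values must be a 2-D matrix")
        if not np.isin(values, (0, 1, 2)).all():
            raise InvalidInputError("genotype entries must all be 0, 1 or 2")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        n, p = values.shape
        if len(self.marker_ids) != p:
            raise InvalidInputError(f"expected {p} marker IDs, got {len(self.marker_ids)}")
        if len(self.individual_ids) != n:
            raise InvalidInputError(
                f"expected {n} individual IDs, got {len(self.individual_ids)}"
            )
        if len(set(self.marker_ids)) != p:
            raise InvalidInputError("marker IDs must be unique")
        if len(set(self.individual_ids)) != n:
            raise InvalidInputError("individual IDs must be unique")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def as_float(self) -> np.ndarray:
        return np.ascontiguousarray(self.values, dtype=np.float64)

    def subset_rows(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            self.values[rows],
            self.marker_ids,
            tuple(self.individual_ids[i] for i in rows),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Scaled-inverse-chi-squared prior settings for both variance components.

    ``shape_b``/``shape_e`` are the prior scales S_b, S_e (trait units
    squared); ``nu_b``/``nu_e`` the prior degrees of freedom.  ``r_squared``
    is the assumed fraction of phenotypic variance captured by markers, used
    by the elicitation rule and by sampler initialization.
    """

    r_squared: float = 0.5
    nu_b: float = 5.0
    nu_e: float = 5.0
    shape_b: float = 0.0
    shape_e: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.r_squared <= 1.0:
            raise InvalidConfigError("r_squared must be in (0, 1]")
        if self.nu_b <= 0 or self.nu_e <= 0:
            raise InvalidConfigError("prior degrees of freedom must be positive")
        if self.shape_b < 0 or self.shape_e < 0:
            raise InvalidConfigError("prior shapes must be non-negative")


@dataclass(frozen=True)
class MCMCConfig:
    """Gibbs sampler settings.

    psi is the per-round subsampling proportion of observations; psi = 1
    without replacement is the plain full-data sampler.  ``update_order``
    is "fixed" (ascending marker order) or "permuted" (new permutation per
    round).  ``fix_variance_components`` freezes sigma_b^2 / sigma_e^2 at
    their initial values (used for validation against the closed-form ridge
    solution).  ``store_effect_samples`` keeps the full post-burn-in draw
    matrix of b (memory permitting); posterior means are always returned.
    """

    iterations: int = 4000
    burn_in: int = 500
    psi: float = 1.0
    with_replacement: bool = False
    seed: int = 0
    update_order: str = "fixed"
    store_effect_samples: bool = False
    fix_variance_components: bool = False

    def __post_init__(self):
        if self.iterations <= 0:
            raise InvalidConfigError("iterations must be positive")
        if not 0 <= self.burn_in < self.iterations:
            raise InvalidConfigError("burn_in must satisfy 0 <= burn_in < iterations")
        if not 0.0 < self.psi <= 1.0:
            raise InvalidConfigError("psi must be in (0, 1]")
        if self.update_order not in ("fixed", "permuted"):
            raise InvalidConfigError("update_order must be 'fixed' or 'permuted'")


@dataclass(frozen=True)
class SubsampleDraw:
    """One round's bag of observation indices (a multiset when drawn with
    replacement)."""

    indices: np.ndarray
    m: int
    with_replacement: bool


@dataclass
class SamplerState:
    """Current Gibbs state: intercept, effects, full residual, variances.

    ``d`` holds the full-data marker sums of squares x_j'x_j, computed once;
    ``X`` a reference to the genotype matrix the chain is conditioned on.
    The invariant e = y - mu - X b is maintained by every update.
    """

    mu: float
    b: np.ndarray
    e: np.ndarray
    var_b: float
    var_e: float
    lam: float
    d: np.ndarray
    X: np.ndarray | None = None
    round: int = 0


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior means and stored post-burn-in draws from one chain."""

    mu_mean: float
    b_mean: np.ndarray
    var_b_mean: float
    var_e_mean: float
    samples: dict
    marker_ids: tuple[str, ...]
    b_samples: np.ndarray | None
    diagnostics: dict


# ---------------------------------------------------------------------------
# Prior elicitation and initialization


def _genotype_values(genotypes) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.as_float()
    return np.ascontiguousarray(np.asarray(genotypes), dtype=np.float64)


def compute_prior_shapes(
    phenotypes: Sequence[float],
    genotypes,
    r_squared: float = 0.5,
    nu_b: float = 5.0,
    nu_e: float = 5.0,
) -> PriorSpec:
    """Elicit prior scales from the phenotypic variance (the R^2 rule).

    S_b = R^2 * var(y) * (nu_b + 2) / sum_j var(x_j)
    S_e = (1 - R^2) * var(y) * (nu_e + 2)

    Per-marker genotype variances are computed on the whole supplied data.
    """
    y = np.asarray(phenotypes, dtype=np.float64)
    X = _genotype_values(genotypes)
    var_y = float(np.var(y, ddof=1))
    if var_y <= 0:
        raise InvalidInputError("phenotype variance must be positive")
    sum_var_x = float(np.var(X, axis=0, ddof=1).sum())
    if sum_var_x <= 0:
        raise InvalidInputError("all markers are monomorphic")
    shape_b = r_squared * var_y * (nu_b + 2.0) / sum_var_x
    shape_e = (1.0 - r_squared) * var_y * (nu_e + 2.0)
    return PriorSpec(
        r_squared=r_squared, nu_b=nu_b, nu_e=nu_e, shape_b=shape_b, shape_e=shape_e
    )


def initialize_state(phenotypes, genotypes, priors: PriorSpec) -> SamplerState:
    """Start the chain at mu = mean(y), b = 0, with the phenotypic variance
    split by the prior R^2 between genetic and residual components."""
    y = np.asarray(phenotypes, dtype=np.float64)
    X = _genotype_values(genotypes)
    if y.ndim != 1 or y.shape[0] != X.shape[0]:
        raise InvalidInputError(
            f"phenotype length {y.shape} does not match genotype rows {X.shape[0]}"
        )
    mu = float(y.mean())
    b = np.zeros(X.shape[1])
    e = y - mu
    var_y = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
    sum_var_x = float(np.var(X, axis=0, ddof=1).sum()) if y.size > 1 else 0.0
    var_e = max((1.0 - priors.r_squared) * var_y, VAR_FLOOR)
    if sum_var_x > 0:
        var_b = max(priors.r_squared * var_y / sum_var_x, VAR_FLOOR)
    else:
        var_b = VAR_FLOOR
    d = np.einsum("ij,ij->j", X, X)
    return SamplerState(
        mu=mu, b=b, e=e, var_b=var_b, var_e=var_e, lam=var_e / var_b, d=d, X=X
    )


# ---------------------------------------------------------------------------
# Single Gibbs updates (the reference, pure-Python path)


def draw_subsample(n: int, config: MCMCConfig, rng: np.random.Generator) -> SubsampleDraw:
    """Draw one round's bag of m = round(psi * n) observation indices.

    psi = 1 without replacement is the identity bag {0..n-1} and consumes no
    random numbers, so the subsampled chain reduces exactly to the plain one.
    """
    if n < 1:
        raise InvalidInputError("n must be at least 1")
    m = int(round(config.psi * n))
    if m == 0:
        raise InvalidConfigError(f"psi={config.psi} with n={n} gives an empty bag")
    if config.psi == 1.0 and not config.with_replacement:
        idx = np.arange(n, dtype=np.int64)
    elif config.with_replacement:
        idx = rng.integers(0, n, size=m).astype(np.int64)
    else:
        idx = rng.permutation(n)[:m].astype(np.int64)
    return SubsampleDraw(indices=idx, m=m, with_replacement=config.with_replacement)


def sample_coefficient(
    j: int,
    state: SamplerState,
    sub: SubsampleDraw,
    psi: float,
    rng: np.random.Generator,
) -> float:
    """Draw marker effect b_j from its full conditional on the current bag.

    mean = (x~_j'e~ + psi d_j b_j) / (psi d_j + lambda)
    var  = sigma_e^2 / (psi d_j + lambda)

    where x~_j, e~ are the bag rows (multiplicities counted) and psi * d_j
    stands in for the bag sum of squares.  Does not mutate the state; pair
    with :func:`update_residual` to apply the draw.
    """
    dj = float(state.d[j])
    denom = psi * dj + state.lam
    if denom <= 0:
        raise NumericalDegeneracyError(
            f"marker {j}: zero precision (psi*d_j + lambda = {denom})"
        )
    idx = sub.indices
    xe = float(state.X[idx, j] @ state.e[idx])
    mean = (xe + psi * dj * state.b[j]) / denom
    sd = math.sqrt(state.var_e / denom)
    return float(rng.normal(mean, sd))


def update_residual(
    state: SamplerState, j: int, b_old: float, b_new: float
) -> np.ndarray:
    """Apply e <- e - x_j (b_new - b_old) to the FULL residual vector and
    record the new effect.

    Every physical row is updated exactly once regardless of bag
    multiplicity, keeping e = y - mu - X b valid for all n observations.
    """
    delta = b_new - b_old
    if delta != 0.0:
        state.e -= state.X[:, j] * delta
    state.b[j] = b_new
    return state.e


def sample_intercept(
    state: SamplerState, sub: SubsampleDraw, rng: np.random.Generator
) -> float:
    """Flat-prior conjugate draw of the intercept on the bagged residual mean;
    the full residual is shifted to preserve the identity."""
    ebar = float(state.e[sub.indices].mean())
    mu_new = float(rng.normal(state.mu + ebar, math.sqrt(state.var_e / sub.m)))
    state.e -= mu_new - state.mu
    state.mu = mu_new
    return mu_new


def sample_genetic_variance(
    state: SamplerState, priors: PriorSpec, rng: np.random.Generator
) -> float:
    """sigma_b^2 <- (b'b + S_b nu_b) / chi^2_{p + nu_b}, on the full effect
    vector (unaffected by subsampling); lambda is recomputed."""
    p = state.b.shape[0]
    num = float(state.b @ state.b) + priors.shape_b * priors.nu_b
    draw = max(float(rng.chisquare(p + priors.nu_b)), VAR_FLOOR)
    state.var_b = max(num / draw, VAR_FLOOR)
    state.lam = state.var_e / state.var_b
    return state.var_b


def sample_residual_variance(
    state: SamplerState,
    sub: SubsampleDraw,
    priors: PriorSpec,
    psi: float,
    rng: np.random.Generator,
) -> float:
    """sigma_e^2 <- (e~'e~ + S_e nu_e) / chi^2_{psi n + nu_e} on the bag
    (multiplicities counted); lambda is recomputed.  psi = 1 without
    replacement reproduces the full-data update exactly."""
    es = state.e[sub.indices]
    num = float(es @ es) + priors.shape_e * priors.nu_e
    dof = psi * state.e.shape[0] + priors.nu_e
    draw = max(float(rng.chisquare(dof)), VAR_FLOOR)
    state.var_e = max(num / draw, VAR_FLOOR)
    state.lam = state.var_e / state.var_b
    return state.var_e


# ---------------------------------------------------------------------------
# Full chains


def _run_chain_impl(y, X, priors, config, subsampled: bool, initial_state=None):
    y = np.asarray(y, dtype=np.float64)
    Xf = np.ascontiguousarray(X, dtype=np.float64)
    n, p = Xf.shape
    if y.shape[0] != n:
        raise InvalidInputError("phenotype/genotype dimension mismatch")
    state = initial_state if initial_state is not None else initialize_state(y, Xf, priors)
    Xt = np.ascontiguousarray(Xf.T)

    gen = np.random.default_rng(config.seed)
    fixed_order = np.arange(p, dtype=np.int64)
    n_keep = config.iterations - config.burn_in
    mu_s = np.empty(n_keep)
    var_b_s = np.empty(n_keep)
    var_e_s = np.empty(n_keep)
    b_s = np.empty((n_keep, p)) if config.store_effect_samples else None
    b_accum = np.zeros(p)
    touches = 0

    m_full = int(round(config.psi * n))
    if m_full == 0:
        raise InvalidConfigError("psi too small: empty bag")

    for it in range(config.iterations):
        if subsampled:
            sub = draw_subsample(n, config, gen)
            idx = sub.indices
            m = sub.m
            ebar = float(state.e[idx].mean())
        else:
            m = n
            ebar = float(state.e.mean())
        # intercept (flat-prior conjugate draw on the bagged residual mean)
        mu_new = float(gen.normal(state.mu + ebar, math.sqrt(state.var_e / m)))
        state.e -= mu_new - state.mu
        state.mu = mu_new

        order = gen.permutation(p) if config.update_order == "permuted" else fixed_order
        if subsampled:
            touches += sweep_coefficients_subsampled(
                gen, Xt, state.e, state.b, idx, config.psi, state.d,
                state.lam, state.var_e, order,
            )
        else:
            touches += sweep_coefficients_full(
                gen, Xt, state.e, state.b, state.d, state.lam, state.var_e, order
            )

        if not config.fix_variance_components:
            num_b = float(state.b @ state.b) + priors.shape_b * priors.nu_b
            draw = max(float(gen.chisquare(p + priors.nu_b)), VAR_FLOOR)
            state.var_b = max(num_b / draw, VAR_FLOOR)
            es = state.e[idx] if subsampled else state.e
            num_e = float(es @ es) + priors.shape_e * priors.nu_e
            dof = config.psi * n + priors.nu_e
            draw = max(float(gen.chisquare(dof)), VAR_FLOOR)
            state.var_e = max(num_e / draw, VAR_FLOOR)
            state.lam = state.var_e / state.var_b

        if not (np.isfinite(state.var_e) and np.isfinite(state.mu)):
            raise NumericalDegeneracyError(
                f"chain diverged at round {it}: mu={state.mu}, var_e={state.var_e}"
            )

        state.round = it + 1
        k = it - config.burn_in
        if k >= 0:
            mu_s[k] = state.mu
            var_b_s[k] = state.var_b
            var_e_s[k] = state.var_e
            b_accum += state.b
            if b_s is not None:
                b_s[k] = state.b

    return state, mu_s, var_b_s, var_e_s, b_s, b_accum / n_keep, touches


def _summarize(state, mu_s, var_b_s, var_e_s, b_s, b_mean, touches, config,
               marker_ids, n, p):
    return PosteriorSummary(
        mu_mean=float(mu_s.mean()),
        b_mean=b_mean,
        var_b_mean=float(var_b_s.mean()),
        var_e_mean=float(var_e_s.mean()),
        samples={"mu": mu_s, "var_b": var_b_s, "var_e": var_e_s},
        marker_ids=marker_ids,
        b_samples=b_s,
        diagnostics={
            "op_count": int(touches),
            "seed": config.seed,
            "config": config,
            "n": n,
            "p": p,
            "m_per_round": int(round(config.psi * n)),
            "final_mu": state.mu,
            "final_b": state.b.copy(),
            "final_e": state.e.copy(),
        },
    )


def run_chain(
    phenotypes,
    genotypes,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    initial_state: SamplerState | None = None,
) -> PosteriorSummary:
    """Run one SBMC Gibbs chain and return posterior summaries.

    Each round: draw one observation bag, update the intercept, sweep all p
    marker effects (Gauss-Seidel residual updating with bagged dot products),
    then update both variance components.  The diagnostics record carries
    the in-bag observation-touch counter (m per marker dot product per
    round), the seed and a config echo, plus the final state for invariant
    checks.  Fully deterministic given config.seed.
    """
    y = np.asarray(phenotypes, dtype=np.float64)
    X = _genotype_values(genotypes)
    marker_ids = (
        genotypes.marker_ids
        if isinstance(genotypes, GenotypeMatrix)
        else tuple(f"m{j + 1}" for j in range(X.shape[1]))
    )
    if config is None:
        config = MCMCConfig()
    if priors is None:
        priors = compute_prior_shapes(y, X)
    out = _run_chain_impl(y, X, priors, config, subsampled=True,
                          initial_state=initial_state)
    return _summarize(*out, config, marker_ids, X.shape[0], X.shape[1])


def gsru_reference_chain(
    phenotypes,
    genotypes,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    initial_state: SamplerState | None = None,
) -> PosteriorSummary:
    """Plain full-data GSRU Gibbs chain (no subsampling machinery at all).

    Kept as an independent code path: the SBMC chain at psi = 1 without
    replacement must reproduce it draw for draw.
    """
    y = np.asarray(phenotypes, dtype=np.float64)
    X = _genotype_values(genotypes)
    marker_ids = (
        genotypes.marker_ids
        if isinstance(genotypes, GenotypeMatrix)
        else tuple(f"m{j + 1}" for j in range(X.shape[1]))
    )
    if config is None:
        config = MCMCConfig()
    if config.psi != 1.0 or config.with_replacement:
        raise InvalidConfigError("the reference chain is full-data only (psi=1)")
    out = _run_chain_impl(y, X, priors if priors is not None
                          else compute_prior_shapes(y, X),
                          config, subsampled=False, initial_state=initial_state)
    return _summarize(*out, config, marker_ids, X.shape[0], X.shape[1])


def predict(genotypes, summary: PosteriorSummary) -> np.ndarray:
    """Genomic estimated breeding values: y_hat = mu_mean + X b_mean."""
    X = _genotype_values(genotypes)
    if isinstance(genotypes, GenotypeMatrix):
        if genotypes.marker_ids != summary.marker_ids:
            raise InvalidInputError(
                "prediction markers do not match the training marker set"
            )
    elif X.shape[1] != summary.b_mean.shape[0]:
        raise InvalidInputError("marker count mismatch")
    return summary.mu_mean + X @ summary.b_mean


def ridge_closed_form_oracle(phenotypes, genotypes, lam: float) -> np.ndarray:
    """Direct solve of the ridge normal equations (X'X + lambda I) b = X'y
    for an already-centered response; validation oracle, not the fitting path."""
    y = np.asarray(phenotypes, dtype=np.float64)
    X = _genotype_values(genotypes)
    n, p = X.shape
    if lam < 0:
        raise InvalidInputError("lambda must be non-negative")
    if lam == 0 and p > n:
        raise InvalidInputError("singular system: lambda=0 with p > n")
    A = X.T @ X + lam * np.eye(p)
    try:
        return np.linalg.solve(A, X.T @ y)
    except np.linalg.LinAlgError as exc:
        raise InvalidInputError(f"singular ridge system: {exc}") from exc
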