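"""CMA-ES search over the CLAHE parameter pair.

The clip limit C is searched continuously on [0.01, 0.5]; the tile size T
is restricted to {8, 16, 32, 64} and is handled through a continuous
exponent coordinate z2 in [2.5, 6.5] with T = 2**round(z2) snapped at
evaluation time, so both parameters are sampled jointly from one
multivariate normal.  The optimizer is a standard (mu/mu_w, lambda)
covariance matrix adaptation evolution strategy with canonical constants
for dimension 2: weighted recombination of the better half, cumulative
step-size adaptation, and rank-1 plus rank-mu covariance updates.  Only
the objective — the composite PSNR/SSIM/NRMSE fitness averaged over a
calibration set — is task-specific.

Because the clip limit only enters CLAHE through the integer cap
round(C * T * T), objective values are cached per (T, cap) pair during a
search, which makes the 2-D run cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .enhance import CLAHE, EnhanceParams, _round_half_away
from .quality import ObjectiveConfig, evaluate_params

__all__ = [
    "SearchSpace",
    "CmaState",
    "OptimResult",
    "CLAHETuner",
    "sample_population",
    "decode",
    "update_state",
    "optimize_clahe",
]


@dataclass(frozen=True)
class SearchSpace:
    """Feasible region: C in [c_lo, c_hi], T drawn from powers of two."""

    c_lo: float = 0.01
    c_hi: float = 0.5
    t_values: tuple = (8, 16, 32, 64)
    exp_lo: float = 2.5
    exp_hi: float = 6.5

    def __post_init__(self):
        if not self.c_lo < self.c_hi:
            raise ValueError("clip-limit bounds must be ordered")
        for t in self.t_values:
            if t < 2 or (t & (t - 1)) != 0:
                raise ValueError("tile sizes must be powers of two >= 2")

    @property
    def exponents(self):
        return tuple(int(np.log2(t)) for t in self.t_values)


@dataclass
class CmaState:
    """Full state of the evolution strategy (dimension 2).

    ``mean`` and ``cov`` parameterize the sampling distribution
    N(mean, step_size^2 * cov); ``p_sigma`` and ``p_c`` are the evolution
    paths for step-size and covariance adaptation.
    """

    mean: np.ndarray
    cov: np.ndarray
    step_size: float
    p_sigma: np.ndarray = field(default_factory=lambda: np.zeros(2))
    p_c: np.ndarray = field(default_factory=lambda: np.zeros(2))
    generation: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).copy()
        self.cov = np.asarray(self.cov, dtype=float).copy()
        if self.mean.shape != (2,) or self.cov.shape != (2, 2):
            raise ValueError("state is 2-dimensional")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")


@dataclass(frozen=True)
class OptimResult:
    """Outcome of one search: theta*, f(theta*), and bookkeeping."""

    best_params: EnhanceParams
    best_score: float
    history: tuple  # best-ever score after each generation
    evaluations: int


def initial_state(space: SearchSpace = SearchSpace(), seed: int = 0) -> CmaState:
    """Center start with per-coordinate scales of 0.3x each coordinate range.

    The two coordinates have very different ranges (0.49 for C, 4.0 for the
    tile exponent), so the anisotropy is carried by the initial diagonal
    covariance with a unit global step size.
    """
    mean = np.array([
        0.5 * (space.c_lo + space.c_hi),
        0.5 * (space.exp_lo + space.exp_hi),
    ])
    scales = np.array([
        0.3 * (space.c_hi - space.c_lo),
        0.3 * (space.exp_hi - space.exp_lo),
    ])
    return CmaState(mean=mean, cov=np.diag(scales**2), step_size=1.0,
                    rng_seed=int(seed))


def _repaired_eigh(cov: np.ndarray):
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    floor = 1e-20 * max(1.0, vals.max())
    vals = np.maximum(vals, floor)
    return vals, vecs


def sample_population(state: CmaState, pop_size: int) -> list[np.ndarray]:
    """Draw pop_size candidates from N(mean, step_size^2 * cov).

    The draws are seeded by (rng_seed, generation) so a generation's sample
    is reproducible; a non-positive-definite covariance is repaired by
    flooring its eigenvalues before sampling.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    vals, vecs = _repaired_eigh(state.cov)
    sqrt_c = vecs @ np.diag(np.sqrt(vals)) @ vecs.T
    rng = np.random.default_rng([state.rng_seed, state.generation])
    z = rng.standard_normal((pop_size, 2))
    return [state.mean + state.step_size * (sqrt_c @ zi) for zi in z]


def decode(candidate, space: SearchSpace = SearchSpace()) -> EnhanceParams:
    """Map an unconstrained 2-vector to feasible (C, T).

    C clamps to its bounds; the tile exponent clamps to [exp_lo, exp_hi],
    rounds half to even, and is finally clipped onto the available
    exponents so T always lands in t_values.
    """
    z1, z2 = float(candidate[0]), float(candidate[1])
    c = min(max(z1, space.c_lo), space.c_hi)
    exps = space.exponents
    e = int(np.clip(np.round(np.clip(z2, space.exp_lo, space.exp_hi)),
                    min(exps), max(exps)))
    return EnhanceParams(clip_fraction=c, tile_size=2**e)


# canonical CMA-ES constants for dimension n and population lam
def _cma_constants(n: int, lam: int):
    mu = lam // 2
    raw = np.log((lam + 1) / 2.0) - np.log(np.arange(1, mu + 1))
    weights = raw / raw.sum()
    mueff = 1.0 / np.sum(weights**2)
    cs = (mueff + 2) / (n + mueff + 5)
    ds = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    c1 = 2.0 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    chi_n = np.sqrt(n) * (1 - 1.0 / (4 * n) + 1.0 / (21 * n**2))
    return mu, weights, mueff, cs, ds, cc, c1, cmu, chi_n


def update_state(state: CmaState, ranked) -> CmaState:
    """One CMA-ES generation update from score-ranked candidates.

    ``ranked`` is a sequence of (candidate 2-vector, score) pairs; they are
    (re-)sorted by descending score, the better half is recombined into the
    new mean with logarithmic weights, and the step size and covariance are
    adapted along the evolution paths.
    """
    ranked = sorted(ranked, key=lambda cs_pair: -cs_pair[1])
    lam = len(ranked)
    if lam < 2:
        raise ValueError("need at least 2 ranked candidates")
    n = 2
    mu, weights, mueff, cs, ds, cc, c1, cmu, chi_n = _cma_constants(n, lam)

    sigma = state.step_size
    xs = np.array([np.asarray(c, dtype=float) for c, _ in ranked[:mu]])
    ys = (xs - state.mean) / sigma
    yw = weights @ ys
    new_mean = state.mean + sigma * yw

    vals, vecs = _repaired_eigh(state.cov)
    inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T

    p_sigma = (1 - cs) * state.p_sigma + np.sqrt(
        cs * (2 - cs) * mueff
    ) * (inv_sqrt @ yw)
    gen1 = state.generation + 1
    denom = np.sqrt(1 - (1 - cs) ** (2 * gen1))
    h_sigma = float(
        np.linalg.norm(p_sigma) / denom / chi_n < 1.4 + 2.0 / (n + 1)
    )
    p_c = (1 - cc) * state.p_c + h_sigma * np.sqrt(cc * (2 - cc) * mueff) * yw

    rank_mu = sum(w * np.outer(y, y) for w, y in zip(weights, ys))
    cov = (
        (1 - c1 - cmu) * state.cov
        + c1 * (np.outer(p_c, p_c) + (1 - h_sigma) * cc * (2 - cc) * state.cov)
        + cmu * rank_mu
    )
    cov = (cov + cov.T) / 2.0
    step = sigma * np.exp((cs / ds) * (np.linalg.norm(p_sigma) / chi_n - 1))
    # flat-fitness handling (reference CMA-ES behavior): when the selected
    # parents are indistinguishable the selection gradient is zero, so
    # inflate the step size to escape plateaus of the objective
    top_scores = [s for _, s in ranked[:mu]]
    if abs(top_scores[0] - top_scores[-1]) < 1e-12 * max(1.0, abs(top_scores[0])):
        step *= np.exp(0.2 + cs / ds)
    return CmaState(
        mean=new_mean,
        cov=cov,
        step_size=float(step),
        p_sigma=p_sigma,
        p_c=p_c,
        generation=gen1,
        rng_seed=state.rng_seed,
    )


class CLAHETuner(TransformerMixin, BaseEstimator):
    """Select CLAHE parameters by CMA-ES on a calibration image set.

    ``fit(X)`` runs the search on the stack/list of [0, 1] images ``X`` and
    stores the best decoded parameters; ``transform(X)`` applies CLAHE with
    those parameters.  The search stops at the evaluation budget or after
    the best score stagnates (change < ``stagnation_tol``) for
    ``stagnation_generations`` consecutive generations.

    Fitted attributes: ``best_params_``, ``best_score_``, ``history_``,
    ``n_evaluations_``, ``result_``.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        beta: float = 1.0,
        gamma: float = 1.0,
        psnr_cap: float = 100.0,
        budget: int = 240,
        pop_size: int = 6,
        seed: int = 0,
        levels: int = 256,
        space: SearchSpace = SearchSpace(),
        stagnation_generations: int = 25,
        stagnation_tol: float = 1e-6,
        exponent_std_floor: float = 0.5,
        boundary_penalty: float = 10.0,
    ):
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.psnr_cap = psnr_cap
        self.budget = budget
        self.pop_size = pop_size
        self.seed = seed
        self.levels = levels
        self.space = space
        self.stagnation_generations = stagnation_generations
        self.stagnation_tol = stagnation_tol
        self.exponent_std_floor = exponent_std_floor
        self.boundary_penalty = boundary_penalty

    def fit(self, X, y=None):
        images = [np.asarray(img, dtype=float) for img in X]
        if not images:
            raise ValueError("calibration set must be non-empty")
        if self.budget < 2 * self.pop_size:
            raise ValueError(
                f"budget {self.budget} too small for pop_size {self.pop_size}"
            )
        config = ObjectiveConfig(
            alpha=self.alpha, beta=self.beta, gamma=self.gamma,
            psnr_cap=self.psnr_cap,
        )
        space = self.space
        state = initial_state(space, seed=self.seed)
        cache: dict = {}
        best_score = -np.inf
        best_params = None
        history = []
        evaluations = 0
        since_improved = 0

        max_generations = 10 * max(1, self.budget // self.pop_size)
        for _generation in range(max_generations):
            if evaluations + self.pop_size > self.budget:
                break
            candidates = sample_population(
                self._floored(state), self.pop_size)
            scored = []
            gen_best = -np.inf
            for cand in candidates:
                params = decode(cand, space)
                n_pix = params.tile_size**2
                cap = max(1, int(_round_half_away(
                    params.clip_fraction * n_pix)))
                key = (params.tile_size, cap)
                if key not in cache:
                    cache[key] = evaluate_params(
                        images, params, config, levels=self.levels
                    )
                    evaluations += 1
                score = cache[key]
                # rank by score minus a quadratic penalty on the distance
                # to the feasible box (per-coordinate, range-normalized);
                # without it the clamped plateau lets the genotype mean
                # drift arbitrarily far outside the search space
                clamped = np.array([
                    np.clip(cand[0], space.c_lo, space.c_hi),
                    np.clip(cand[1], space.exp_lo, space.exp_hi),
                ])
                rel = (np.asarray(cand, dtype=float) - clamped) / np.array(
                    [space.c_hi - space.c_lo, space.exp_hi - space.exp_lo]
                )
                scored.append(
                    (cand, score - self.boundary_penalty * float(rel @ rel))
                )
                if score > gen_best:
                    gen_best = score
                    if score > best_score + self.stagnation_tol:
                        since_improved = -1  # reset below
                    if score > best_score:
                        best_score = score
                        best_params = params
            # a generation whose selected parents are indistinguishable is
            # plateau escape in progress, not convergence: it does not
            # count toward the stagnation window
            top = sorted((s for _, s in scored), reverse=True)
            mu = self.pop_size // 2
            flat = abs(top[0] - top[mu - 1]) < 1e-12 * max(1.0, abs(top[0]))
            if not flat:
                since_improved += 1
            history.append(best_score)
            state = update_state(state, scored)
            if since_improved >= self.stagnation_generations:
                break

        self.best_params_ = best_params
        self.best_score_ = float(best_score)
        self.history_ = tuple(history)
        self.n_evaluations_ = evaluations
        self.result_ = OptimResult(
            best_params=best_params,
            best_score=float(best_score),
            history=tuple(history),
            evaluations=evaluations,
        )
        return self

    def _floored(self, state: CmaState) -> CmaState:
        """Floor the tile-exponent sampling std at half a discretization cell.

        The tile size only changes when the exponent coordinate crosses an
        integer boundary, so once its sampling std falls well below the
        cell width the search can no longer move between tile sizes; the
        floor keeps neighboring cells reachable throughout the run.
        """
        std_t = state.step_size * np.sqrt(max(state.cov[1, 1], 0.0))
        if std_t >= self.exponent_std_floor:
            return state
        cov = state.cov.copy()
        cov[1, 1] = (self.exponent_std_floor / state.step_size) ** 2
        return CmaState(
            mean=state.mean, cov=cov, step_size=state.step_size,
            p_sigma=state.p_sigma, p_c=state.p_c,
            generation=state.generation, rng_seed=state.rng_seed,
        )

    def transform(self, X):
        if not hasattr(self, "best_params_"):
            raise RuntimeError("CLAHETuner must be fitted before transform")
        est = CLAHE(
            clip_fraction=self.best_params_.clip_fraction,
            tile_size=self.best_params_.tile_size,
            levels=self.levels,
        )
        return est.transform(X)


def optimize_clahe(
    images,
    space: SearchSpace = SearchSpace(),
    config: ObjectiveConfig = ObjectiveConfig(),
    budget: int = 240,
    seed: int = 0,
    pop_size: int = 6,
    levels: int = 256,
) -> OptimResult:
    """Run the CMA-ES search and return the best parameters and score."""
    tuner = CLAHETuner(
        alpha=config.alpha, beta=config.beta, gamma=config.gamma,
        psnr_cap=config.psnr_cap, budget=budget, pop_size=pop_size,
        seed=seed, levels=levels, space=space,
    )
    tuner.fit(images)
    return tuner.result_
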