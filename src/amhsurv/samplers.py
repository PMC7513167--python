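"""MCMC algorithms for the AMH-Weibull posterior.

Three chain flavours differ only in how the Weibull shapes ``alpha_j``
are updated:

* ``A1`` / ``IMH``  -- independent Metropolis-Hastings with the Gamma
  prior as proposal; the acceptance ratio reduces to a likelihood ratio.
* ``A2`` / ``RWM``  -- random-walk Metropolis, Gaussian perturbation with
  variance ``sigma2_rwm`` (default 1, chosen from pilot runs); the
  acceptance ratio is the likelihood-times-prior ratio, and proposals
  ``alpha* <= 0`` are rejected through their zero prior density.
* ``A3`` / ``SS``   -- slice sampling on the conditional kernel
  ``kappa(alpha_j)`` with a stepping-out width ``slice_lambda``
  (default 0.01).

In every flavour the scales ``beta_j`` are updated by
Metropolis-Hastings with the natural Gamma candidate
``Gamma(b_j1 + r_j, b_j2 + sum_i t_ij**alpha_j)`` -- the exact
conditional when ``phi = 0``, so that update is then a Gibbs draw -- and
``phi`` is updated by an independence sampler proposing uniformly from
the current or an adjacent cell of a fixed grid on (-1, 1), with the
exact Hastings correction for the edge cells.

Per iteration the update order is ``alpha1, beta1, alpha2, beta2, phi``;
each ``beta_j`` update uses the same-iteration value of ``alpha_j``.
All acceptance ratios are computed as differences of log kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    BivariateSurvivalData,
    Hyperparams,
    ModelParams,
    _PsiIndex,
    _log_psi_sum,
    log_posterior,
)

__all__ = [
    "MCMCConfig",
    "ChainState",
    "ChainOutput",
    "imh_update_alpha",
    "rwm_update_alpha",
    "slice_update_alpha",
    "slice_sample_1d",
    "mh_update_beta",
    "grid_imh_update_phi",
    "grid_imh_step",
    "run_chain",
    "run_chains",
    "posterior_summary",
    "auto_init",
]

PARAM_NAMES = ("alpha1", "beta1", "alpha2", "beta2", "phi")

_ALGORITHM_ALIASES = {
    "A1": "IMH",
    "A2": "RWM",
    "A3": "SS",
    "IMH": "IMH",
    "RWM": "RWM",
    "SS": "SS",
}


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-length and tuning constants.

    Defaults are the reference settings used throughout: ``L`` = 55,000
    iterations, burn-in ``B`` = 5000, thinning stride ``J`` = 10 (so
    ``S = (L - B) // J`` draws are kept), RWM proposal variance 1, slice
    step width 0.01 and a phi-proposal grid of width-0.1 cells.
    """

    L: int = 55_000
    B: int = 5_000
    J: int = 10
    alpha_algorithm: str = "SS"
    sigma2_rwm: float = 1.0
    slice_lambda: float = 0.01
    slice_mode: str = "shrinkage"
    phi_grid_step: float = 0.1
    seed: int | None = None
    n_chains: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.B < self.L):
            raise ValueError("need 0 <= B < L")
        if self.J < 1:
            raise ValueError("thinning stride J must be >= 1")
        if self.S < 1:
            raise ValueError("kept sample count (L - B) // J must be >= 1")
        if self.sigma2_rwm <= 0:
            raise ValueError("sigma2_rwm must be > 0")
        if self.slice_lambda <= 0:
            raise ValueError("slice_lambda must be > 0")
        if self.slice_mode not in ("shrinkage", "paper"):
            raise ValueError("slice_mode must be 'shrinkage' or 'paper'")
        if self.alpha_algorithm not in _ALGORITHM_ALIASES:
            raise ValueError(
                f"alpha_algorithm must be one of {sorted(_ALGORITHM_ALIASES)}"
            )
        step = self.phi_grid_step
        if not (0 < step <= 1) or abs(round(2.0 / step) - 2.0 / step) > 1e-9:
            raise ValueError("phi_grid_step must evenly divide (-1, 1)")

    @property
    def S(self) -> int:
        return (self.L - self.B) // self.J

    @property
    def algorithm(self) -> str:
        """Canonical alpha-update algorithm name (IMH / RWM / SS)."""
        return _ALGORITHM_ALIASES[self.alpha_algorithm]


class ChainState:
    """Mutable chain state with cached per-margin arrays.

    Caches ``t_j**alpha_j`` and the marginal CDF values ``F_j`` so each
    block update recomputes only what its parameter touches.  The state
    is bound to the dataset it was initialized with.
    """

    __slots__ = (
        "data", "t1", "t2", "logt1", "logt2", "d1", "d2", "r1", "r2",
        "sdlogt1", "sdlogt2", "pidx",
        "alpha1", "beta1", "alpha2", "beta2", "phi",
        "ta1", "ta2", "sum_ta1", "sum_ta2", "F1", "F2",
        "iteration", "accept_counts", "update_counts",
    )

    def __init__(self, params: ModelParams, data: BivariateSurvivalData) -> None:
        self.data = data
        self.t1, self.d1 = data.t1, data.delta1
        self.t2, self.d2 = data.t2, data.delta2
        self.logt1 = np.log(self.t1)
        self.logt2 = np.log(self.t2)
        self.r1, self.r2 = data.r1, data.r2
        self.sdlogt1 = float((self.d1 * self.logt1).sum())
        self.sdlogt2 = float((self.d2 * self.logt2).sum())
        self.pidx = _PsiIndex.from_data(data)
        self.iteration = 0
        self.accept_counts = dict.fromkeys(PARAM_NAMES, 0)
        self.update_counts = dict.fromkeys(PARAM_NAMES, 0)
        self.set_params(params)

    # -- parameter access -------------------------------------------------
    @property
    def params(self) -> ModelParams:
        return ModelParams(
            self.alpha1, self.beta1, self.alpha2, self.beta2, self.phi
        )

    def set_params(self, params: ModelParams) -> None:
        self.alpha1, self.beta1 = params.alpha1, params.beta1
        self.alpha2, self.beta2 = params.alpha2, params.beta2
        self.phi = params.phi
        self.ta1 = self.t1 ** self.alpha1
        self.ta2 = self.t2 ** self.alpha2
        self.sum_ta1 = float(self.ta1.sum())
        self.sum_ta2 = float(self.ta2.sum())
        self.F1 = -np.expm1(-self.beta1 * self.ta1)
        self.F2 = -np.expm1(-self.beta2 * self.ta2)

    def _margin(self, margin: int):
        if margin == 1:
            return (self.t1, self.logt1, self.d1, self.r1, self.sdlogt1,
                    self.alpha1, self.beta1, self.ta1, self.F1, self.F2)
        if margin == 2:
            return (self.t2, self.logt2, self.d2, self.r2, self.sdlogt2,
                    self.alpha2, self.beta2, self.ta2, self.F2, self.F1)
        raise ValueError(f"margin must be 1 or 2, got {margin!r}")

    def _set_alpha(self, margin, alpha, ta, F) -> None:
        if margin == 1:
            self.alpha1 = alpha
            self.ta1, self.sum_ta1, self.F1 = ta, float(ta.sum()), F
        else:
            self.alpha2 = alpha
            self.ta2, self.sum_ta2, self.F2 = ta, float(ta.sum()), F

    def _set_beta(self, margin, beta, F) -> None:
        if margin == 1:
            self.beta1, self.F1 = beta, F
        else:
            self.beta2, self.F2 = beta, F

    def _log_psi(self, F_self, F_other, margin, phi=None):
        phi = self.phi if phi is None else phi
        if margin == 1:
            return _log_psi_sum(F_self, F_other, phi, self.pidx)
        return _log_psi_sum(F_other, F_self, phi, self.pidx)


def _alpha_kernel_block(state: ChainState, margin: int, hyper: Hyperparams,
                        alphas: np.ndarray):
    """Evaluate ``log kappa`` at a vector of shape values.

    Returns ``(values, ta_matrix, F_matrix)``; rows with ``alpha <= 0``
    or numerical overflow get ``-inf``.
    """
    t, logt, d, r, sdlogt, _, beta, _, _, F_other = state._margin(margin)
    a1h, a2h = hyper.alpha_prior(margin)
    al = np.atleast_1d(np.asarray(alphas, dtype=float))
    valid = al > 0
    al_safe = np.where(valid, al, 1.0)
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        ta = np.exp(al_safe[:, None] * logt[None, :])
        F = -np.expm1(-beta * ta)
        lpsi = state._log_psi(F, F_other, margin)
        val = (
            (a1h + r - 1.0) * np.log(al_safe)
            + al_safe * (sdlogt - a2h)
            - beta * ta.sum(axis=1)
            + lpsi
        )
    val = np.where(valid & ~np.isnan(val), val, -np.inf)
    return val, ta, F


def _log_uniform(rng) -> float:
    # log of U in (0, 1]; avoids log(0)
    return math.log1p(-rng.random())


# ---------------------------------------------------------------------------
# block updates for alpha
# ---------------------------------------------------------------------------

def imh_update_alpha(state: ChainState, margin: int,
                     data: BivariateSurvivalData, hyper: Hyperparams,
                     rng: np.random.Generator) -> ChainState:
    """Independent MH update of ``alpha_j`` with the Gamma prior proposal.

    Prior and proposal cancel, so the acceptance ratio is the likelihood
    ratio alone.
    """
    a1h, a2h = hyper.alpha_prior(margin)
    cur = state.alpha1 if margin == 1 else state.alpha2
    prop = rng.gamma(a1h, 1.0 / a2h)
    name = "alpha1" if margin == 1 else "alpha2"
    state.update_counts[name] += 1
    if prop <= 0:
        return state
    val, ta, F = _alpha_kernel_block(state, margin, hyper,
                                     np.array([prop, cur]))
    # strip the Gamma prior kernel: IMH accepts on the likelihood ratio
    prior_prop = (a1h - 1.0) * math.log(prop) - a2h * prop
    prior_cur = (a1h - 1.0) * math.log(cur) - a2h * cur
    delta = (val[0] - prior_prop) - (val[1] - prior_cur)
    if _log_uniform(rng) <= delta:
        state._set_alpha(margin, prop, ta[0], F[0])
        state.accept_counts[name] += 1
    return state


def rwm_update_alpha(state: ChainState, margin: int,
                     data: BivariateSurvivalData, hyper: Hyperparams,
                     rng: np.random.Generator,
                     sigma2: float = 1.0) -> ChainState:
    """Random-walk Metropolis update of ``alpha_j``.

    ``alpha* = alpha + eps`` with ``eps ~ N(0, sigma2)``; the symmetric
    proposal cancels and the ratio is likelihood times prior, which is
    zero for ``alpha* <= 0`` (automatic rejection, preserving detailed
    balance without reflection).
    """
    return _rwm_update_alpha(state, margin, hyper, rng, math.sqrt(sigma2))


def _rwm_update_alpha(state, margin, hyper, rng, sigma):
    cur = state.alpha1 if margin == 1 else state.alpha2
    prop = cur + sigma * rng.standard_normal()
    name = "alpha1" if margin == 1 else "alpha2"
    state.update_counts[name] += 1
    if prop <= 0:
        return state
    val, ta, F = _alpha_kernel_block(state, margin, hyper,
                                     np.array([prop, cur]))
    if _log_uniform(rng) <= val[0] - val[1]:
        state._set_alpha(margin, prop, ta[0], F[0])
        state.accept_counts[name] += 1
    return state


def slice_sample_1d(log_kernel, x0: float, lam: float,
                    rng: np.random.Generator, mode: str = "shrinkage",
                    max_steps: int = 10 ** 6) -> float:
    """One slice-sampling update of a scalar with kernel ``log_kernel``.

    The auxiliary level is drawn in log space
    (``log u = log kappa(x0) + log U(0, 1]``), mathematically identical
    to drawing ``u ~ U(0, kappa(x0))`` but immune to underflow of the
    kernel over many subjects.  The slice bracket is found by stepping
    outward in increments of ``lam`` from the current point until the
    kernel drops below the level; the current point is always part of the
    bracket, so a degenerate (width-zero) bracket returns the current
    point rather than failing.

    ``mode="paper"`` then draws uniformly on the bracket and returns it
    unconditionally (the verbatim stepping construction, which can land
    outside the slice when the kernel is multimodal on the bracket).
    ``mode="shrinkage"`` (default) rejects points outside the slice and
    shrinks the bracket toward the current point, which targets the
    conditional exactly.

    ``log_kernel`` must accept a 1-D array and return a 1-D array.
    """
    if mode not in ("shrinkage", "paper"):
        raise ValueError("mode must be 'shrinkage' or 'paper'")
    logf0 = float(log_kernel(np.array([x0]))[0])
    if not np.isfinite(logf0):
        raise ValueError("slice sampler started at a zero-density point")
    logu = logf0 + _log_uniform(rng)

    block = 32

    def _step_out(direction: int) -> tuple[float, float]:
        # returns (last point inside the slice, first point below the level)
        inside = x0
        m = 1
        while True:
            ms = m + np.arange(block)
            xs = x0 + direction * ms * lam
            vals = log_kernel(xs)
            below = vals <= logu
            if below.any():
                k = int(np.argmax(below))
                if k > 0:
                    inside = xs[k - 1]
                return inside, xs[k]
            inside = xs[-1]
            m += block
            if m > max_steps:
                raise RuntimeError(
                    "slice stepping exceeded max_steps; unbounded slice?"
                )

    in_lo, out_lo = _step_out(-1)
    in_hi, out_hi = _step_out(+1)
    if mode == "paper":
        # verbatim construction: uniform over the accepted step points'
        # span (degenerate when both immediate neighbours fail)
        return float(rng.uniform(in_lo, in_hi)) if in_hi > in_lo else x0
    # shrinkage: the bracket covers the slice (both ends below the level),
    # so reject-and-shrink targets the conditional exactly
    lo, hi = out_lo, out_hi
    for _ in range(1000):
        if hi <= lo:
            return x0
        x = float(rng.uniform(lo, hi))
        if float(log_kernel(np.array([x]))[0]) > logu:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0


def slice_update_alpha(state: ChainState, margin: int,
                       data: BivariateSurvivalData, hyper: Hyperparams,
                       rng: np.random.Generator, lam: float = 0.01,
                       mode: str = "shrinkage") -> ChainState:
    """Slice-sampling update of ``alpha_j`` on the conditional kernel."""
    cur = state.alpha1 if margin == 1 else state.alpha2

    def kernel(xs):
        return _alpha_kernel_block(state, margin, hyper, xs)[0]

    new = slice_sample_1d(kernel, cur, lam, rng, mode=mode)
    name = "alpha1" if margin == 1 else "alpha2"
    state.update_counts[name] += 1
    state.accept_counts[name] += 1
    if new != cur:
        _, ta, F = _alpha_kernel_block(state, margin, hyper, np.array([new]))
        state._set_alpha(margin, new, ta[0], F[0])
    return state


# ---------------------------------------------------------------------------
# beta and phi updates
# ---------------------------------------------------------------------------

def mh_update_beta(state: ChainState, margin: int,
                   data: BivariateSurvivalData, hyper: Hyperparams,
                   rng: np.random.Generator) -> ChainState:
    """MH update of ``beta_j`` with its natural Gamma candidate.

    Proposes ``beta* ~ Gamma(b_j1 + r_j, b_j2 + sum t**alpha)`` using the
    *current-iteration* ``alpha_j``; the Gamma kernels cancel and the
    acceptance ratio is the ratio of the copula correction
    ``eta(beta) = prod_i Psi_i`` alone.  For ``phi = 0``, ``eta`` is
    constant in ``beta`` and the update is an exact Gibbs draw.
    """
    t, logt, d, r, sdlogt, alpha, beta, ta, F, F_other = state._margin(margin)
    b1h, b2h = hyper.beta_prior(margin)
    rate = b2h + (state.sum_ta1 if margin == 1 else state.sum_ta2)
    prop = rng.gamma(b1h + r, 1.0 / rate)
    name = "beta1" if margin == 1 else "beta2"
    state.update_counts[name] += 1
    if prop <= 0:
        return state
    with np.errstate(under="ignore"):
        F_new = -np.expm1(-prop * ta)
    delta = float(state._log_psi(F_new, F_other, margin)) - float(
        state._log_psi(F, F_other, margin)
    )
    if _log_uniform(rng) <= delta:
        state._set_beta(margin, prop, F_new)
        state.accept_counts[name] += 1
    return state


def _phi_interval(phi: float, step: float, n_cells: int) -> int:
    a = int(math.floor((phi + 1.0) / step))
    return min(max(a, 0), n_cells - 1)


def grid_imh_step(phi: float, log_target, rng: np.random.Generator,
                  step: float = 0.1) -> tuple[float, bool]:
    """One grid-based independence-sampler step for ``phi``.

    The grid splits (-1, 1) into ``2/step`` half-open cells
    ``[I_a, I_a + step)``.  From an interior cell the proposal is uniform
    on one of the three cells {left, own, right} with probability 1/3
    each; from an edge cell, on one of the two available cells with
    probability 1/2 each.  The Hastings factor is the ratio of mixture
    arities (1 between like cells, 2/3 moving edge -> interior, 3/2
    moving interior -> edge).  Returns ``(new_phi, accepted)``.
    """
    n_cells = int(round(2.0 / step))
    a = _phi_interval(phi, step, n_cells)

    def _choices(c: int) -> tuple:
        if c == 0:
            return (0, 1)
        if c == n_cells - 1:
            return (n_cells - 2, n_cells - 1)
        return (c - 1, c, c + 1)

    fwd = _choices(a)
    b = fwd[rng.integers(len(fwd))]
    lo = -1.0 + b * step
    prop = float(rng.uniform(lo, lo + step))
    if prop <= -1.0:
        prop = math.nextafter(-1.0, 0.0)
    log_p = math.log(len(fwd)) - math.log(len(_choices(b)))
    delta = float(log_target(prop)) - float(log_target(phi)) + log_p
    if _log_uniform(rng) <= delta:
        return prop, True
    return phi, False


def grid_imh_update_phi(state: ChainState, data: BivariateSurvivalData,
                        rng: np.random.Generator,
                        step: float = 0.1) -> ChainState:
    """Grid IMH update of the dependence parameter ``phi``.

    Only the copula factors depend on ``phi`` (the uniform prior is flat),
    so the acceptance ratio is the ``Psi``-product ratio times the
    Hastings grid factor.
    """
    def target(p):
        return _log_psi_sum(state.F1, state.F2, p, state.pidx)

    new, accepted = grid_imh_step(state.phi, target, rng, step=step)
    state.update_counts["phi"] += 1
    if accepted:
        state.phi = new
        state.accept_counts["phi"] += 1
    return state


# ---------------------------------------------------------------------------
# chain drivers
# ---------------------------------------------------------------------------

@dataclass
class ChainOutput:
    """Thinned post-burn-in draws plus posterior summaries."""

    draws: np.ndarray                      # (S, 5)
    iterations: np.ndarray                 # kept iteration indices
    acceptance_rates: dict
    estimates: dict                        # posterior means per parameter
    ci_lower: dict                         # 2.5% quantiles
    ci_upper: dict                         # 97.5% quantiles
    config: MCMCConfig
    seed: int | None
    param_names: tuple = field(default=PARAM_NAMES)

    @property
    def S(self) -> int:
        return self.draws.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df.insert(0, "iter", self.iterations)
        return df

    def estimate_params(self) -> ModelParams:
        return ModelParams(**self.estimates)


def auto_init(data: BivariateSurvivalData) -> ModelParams:
    """Default initialization: unit shapes, exponential moment-matched
    rates ``beta_j = r_j / sum t_ij`` (1 if no events), ``phi = 0``."""
    betas = []
    for j in (1, 2):
        t, d = data.margin(j)
        r = float(d.sum())
        betas.append(r / float(t.sum()) if r > 0 else 1.0)
    return ModelParams(1.0, betas[0], 1.0, betas[1], 0.0)


def _summaries(draws: np.ndarray):
    est = dict(zip(PARAM_NAMES, draws.mean(axis=0)))
    q = np.quantile(draws, [0.025, 0.975], axis=0)
    lo = dict(zip(PARAM_NAMES, q[0]))
    hi = dict(zip(PARAM_NAMES, q[1]))
    return est, lo, hi


def run_chain(data: BivariateSurvivalData,
              hyper: Hyperparams | None = None,
              config: MCMCConfig | None = None,
              init: ModelParams | str = "auto") -> ChainOutput:
    """Run one MCMC chain and return thinned draws and summaries.

    Iterations ``B + J, B + 2J, ..., <= L`` are kept
    (``S = (L - B) // J`` rows); estimates are the column means of the
    kept draws and intervals are equal-tailed 2.5%/97.5% quantiles.
    Bit-for-bit reproducible for a fixed seed and config.
    """
    hyper = Hyperparams() if hyper is None else hyper
    config = MCMCConfig() if config is None else config
    if data.r1 + data.r2 == 0:
        raise ValueError(
            "cannot fit: every observation is censored on both margins"
        )
    params0 = auto_init(data) if isinstance(init, str) else init
    if isinstance(init, str) and init != "auto":
        raise ValueError(f"init must be ModelParams or 'auto', got {init!r}")
    lp0 = log_posterior(data, params0, hyper)
    if not np.isfinite(lp0):
        raise ValueError("log posterior is not finite at the initial point")

    rng = np.random.default_rng(config.seed)
    state = ChainState(params0, data)
    algorithm = config.algorithm
    sigma = math.sqrt(config.sigma2_rwm)

    def update_alpha(margin):
        if algorithm == "IMH":
            imh_update_alpha(state, margin, data, hyper, rng)
        elif algorithm == "RWM":
            _rwm_update_alpha(state, margin, hyper, rng, sigma)
        else:
            slice_update_alpha(state, margin, data, hyper, rng,
                               lam=config.slice_lambda,
                               mode=config.slice_mode)

    S = config.S
    draws = np.empty((S, 5))
    kept = np.empty(S, dtype=int)
    k = 0
    for l in range(1, config.L + 1):
        update_alpha(1)
        mh_update_beta(state, 1, data, hyper, rng)
        update_alpha(2)
        mh_update_beta(state, 2, data, hyper, rng)
        grid_imh_update_phi(state, data, rng, step=config.phi_grid_step)
        state.iteration = l
        if l > config.B and (l - config.B) % config.J == 0 and k < S:
            draws[k] = (state.alpha1, state.beta1, state.alpha2,
                        state.beta2, state.phi)
            kept[k] = l
            k += 1

    acc = {
        name: state.accept_counts[name] / max(state.update_counts[name], 1)
        for name in PARAM_NAMES
    }
    est, lo, hi = _summaries(draws)
    return ChainOutput(draws=draws, iterations=kept, acceptance_rates=acc,
                       estimates=est, ci_lower=lo, ci_upper=hi,
                       config=config, seed=config.seed)


def run_chains(data: BivariateSurvivalData,
               hyper: Hyperparams | None = None,
               config: MCMCConfig | None = None,
               n_chains: int | None = None) -> list[ChainOutput]:
    """Run several chains with overdispersed starts for convergence checks.

    Chain 0 starts at the default initialization; subsequent chains scale
    the Weibull parameters by 0.5 or 2 and set ``phi`` to -0.5 or +0.5.
    Per-chain seeds are derived deterministically from ``config.seed``.
    """
    hyper = Hyperparams() if hyper is None else hyper
    config = MCMCConfig() if config is None else config
    m = config.n_chains if n_chains is None else n_chains
    if m < 1:
        raise ValueError("n_chains must be >= 1")
    base = auto_init(data)
    scales = [1.0, 0.5, 2.0]
    phis = [0.0, -0.5, 0.5]
    seeds = np.random.SeedSequence(config.seed).generate_state(m)
    outputs = []
    for i in range(m):
        s = scales[i % len(scales)]
        init = ModelParams(base.alpha1 * s, base.beta1 * s,
                           base.alpha2 * s, base.beta2 * s,
                           phis[i % len(phis)])
        cfg = replace(config, seed=int(seeds[i]) % (2 ** 31))
        outputs.append(run_chain(data, hyper, cfg, init=init))
    return outputs


def posterior_summary(chain: ChainOutput) -> dict:
    """Posterior means and equal-tailed 95% intervals from kept draws."""
    if chain.draws.shape[0] < 1:
        raise ValueError("empty chain")
    est, lo, hi = _summaries(chain.draws)
    return {"estimates": est, "ci_lower": lo, "ci_upper": hi}
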