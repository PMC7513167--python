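"""Ali-Mikhail-Haq (AMH) copula survival model with Weibull margins.

The joint survival function of a pair of lifetimes ``(T1, T2)`` is

.. math::

    S(t_1, t_2) = \\frac{S_1(t_1)\\,S_2(t_2)}
                       {1 - \\varphi\\,(1 - S_1(t_1))\\,(1 - S_2(t_2))},
    \\qquad \\varphi \\in [-1, 1),

with Weibull margins :math:`S_j(t) = \\exp(-\\beta_j t^{\\alpha_j})`.

.. warning::

   **Scale convention.**  ``beta_j`` multiplies ``t**alpha_j`` directly
   (a rate-type scale).  Most libraries (``scipy.stats.weibull_min``,
   ``numpy.random.weibull``) use a scale ``lambda = beta**(-1/alpha)``;
   convert before comparing parameter values.

The AMH family admits only weak dependence: Kendall's tau ranges over
roughly (-0.18, 1/3) and Spearman's rho over roughly (-0.27, 0.48) as
``phi`` sweeps its domain, making the model appropriate for bivariate
lifetimes with modest association (e.g. paired-organ data).

All likelihood computation is carried out in log space.  Products of the
copula correction factors (``Psi`` below) over ``n`` subjects underflow
in linear space for even moderate ``n``; any non-positive factor arising
from numerical underflow yields an explicit ``-inf`` log-likelihood,
never a silent NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import gammaln

__all__ = [
    "ModelParams",
    "BivariateSurvivalData",
    "Hyperparams",
    "joint_survival",
    "joint_density",
    "partial_survival",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "log_kappa_alpha",
    "kendall_tau",
    "spearman_rho",
]

_LOG_HALF = math.log(0.5)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the AMH-Weibull survival model.

    Parameters
    ----------
    alpha1, alpha2 : float
        Weibull shape parameters of margins 1 and 2 (dimensionless, > 0).
    beta1, beta2 : float
        Weibull rate-type scale parameters (units ``time**-alpha_j``, > 0);
        the marginal survival function is ``exp(-beta_j * t**alpha_j)``.
    phi : float
        AMH dependence parameter, ``-1 <= phi < 1``.  ``phi = 0`` gives
        independent margins.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not (-1.0 <= self.phi < 1.0):
            raise ValueError(f"phi must lie in [-1, 1), got {self.phi!r}")

    def margin(self, j: int) -> tuple[float, float]:
        """Return ``(alpha_j, beta_j)`` for margin ``j`` in {1, 2}."""
        if j == 1:
            return self.alpha1, self.beta1
        if j == 2:
            return self.alpha2, self.beta2
        raise ValueError(f"margin must be 1 or 2, got {j!r}")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.alpha1, self.beta1, self.alpha2, self.beta2, self.phi]
        )

    @classmethod
    def from_array(cls, arr) -> "ModelParams":
        a1, b1, a2, b2, phi = (float(v) for v in arr)
        return cls(a1, b1, a2, b2, phi)

    names: tuple = field(
        default=("alpha1", "beta1", "alpha2", "beta2", "phi"),
        init=False,
        repr=False,
    )


@dataclass(frozen=True, eq=False)
class BivariateSurvivalData:
    """Right-censored bivariate survival data.

    Each subject contributes an observed time and an event indicator per
    margin: ``delta = 1`` means the event was observed (``T = t``),
    ``delta = 0`` means the lifetime is right-censored (``T > t``).
    """

    t1: np.ndarray
    t2: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t1", np.asarray(self.t1, dtype=float))
        object.__setattr__(self, "t2", np.asarray(self.t2, dtype=float))
        object.__setattr__(self, "delta1", np.asarray(self.delta1, dtype=int))
        object.__setattr__(self, "delta2", np.asarray(self.delta2, dtype=int))
        n = self.t1.shape[0]
        if n < 1:
            raise ValueError("data must contain at least one subject")
        for name in ("t2", "delta1", "delta2"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        for name in ("t1", "t2"):
            t = getattr(self, name)
            if not np.all(np.isfinite(t) & (t > 0)):
                raise ValueError(f"{name} must be strictly positive and finite")
        for name in ("delta1", "delta2"):
            d = getattr(self, name)
            if not np.all((d == 0) | (d == 1)):
                raise ValueError(f"{name} entries must be 0 or 1")

    @property
    def n(self) -> int:
        return self.t1.shape[0]

    @property
    def r1(self) -> int:
        """Number of uncensored observations on margin 1."""
        return int(self.delta1.sum())

    @property
    def r2(self) -> int:
        """Number of uncensored observations on margin 2."""
        return int(self.delta2.sum())

    def margin(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(times, indicators)`` for margin ``j``."""
        if j == 1:
            return self.t1, self.delta1
        if j == 2:
            return self.t2, self.delta2
        raise ValueError(f"margin must be 1 or 2, got {j!r}")

    def censoring_fractions(self) -> tuple[float, float]:
        return (1.0 - self.r1 / self.n, 1.0 - self.r2 / self.n)


@dataclass(frozen=True)
class Hyperparams:
    """Gamma prior constants (shape, rate) for the Weibull parameters.

    The priors are independent: ``alpha_j ~ Gamma(a_j1, a_j2)`` and
    ``beta_j ~ Gamma(b_j1, b_j2)`` in the shape/rate parameterization
    (mean ``a1/a2``, variance ``a1/a2**2``); ``phi ~ U(-1, 1)`` carries no
    free hyperparameter.  The defaults (all 0.01) give vague priors with
    mean 1 and variance 100.
    """

    a11: float = 0.01
    a12: float = 0.01
    a21: float = 0.01
    a22: float = 0.01
    b11: float = 0.01
    b12: float = 0.01
    b21: float = 0.01
    b22: float = 0.01

    def __post_init__(self) -> None:
        for name in ("a11", "a12", "a21", "a22", "b11", "b12", "b21", "b22"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def alpha_prior(self, j: int) -> tuple[float, float]:
        return (self.a11, self.a12) if j == 1 else (self.a21, self.a22)

    def beta_prior(self, j: int) -> tuple[float, float]:
        return (self.b11, self.b12) if j == 1 else (self.b21, self.b22)


# ---------------------------------------------------------------------------
# Weibull margin helpers (rate-type scale)
# ---------------------------------------------------------------------------

def weibull_survival(t, alpha: float, beta: float):
    """Marginal survival ``exp(-beta * t**alpha)``."""
    t = np.asarray(t, dtype=float)
    return np.exp(-beta * t ** alpha)


def weibull_cdf(t, alpha: float, beta: float):
    """Marginal CDF ``1 - exp(-beta * t**alpha)``, computed stably."""
    t = np.asarray(t, dtype=float)
    return -np.expm1(-beta * t ** alpha)


def weibull_density(t, alpha: float, beta: float):
    t = np.asarray(t, dtype=float)
    return beta * alpha * t ** (alpha - 1.0) * np.exp(-beta * t ** alpha)


# ---------------------------------------------------------------------------
# copula factors
# ---------------------------------------------------------------------------

class _PsiIndex:
    """Precomputed index sets for the censoring-pattern factors Psi_i.

    The likelihood contribution of subject i factors into
    ``Psi_i1**(d1 d2) * Psi_i2**(d1(1-d2)) * Psi_i3**(d2(1-d1))
    * Psi_i4**-(d1+d2+1)``; only the subjects whose exponent is nonzero
    need the corresponding log term, so the index sets are built once per
    dataset.
    """

    __slots__ = ("idx11", "idx10", "idx01", "w4")

    def __init__(self, delta1: np.ndarray, delta2: np.ndarray) -> None:
        d1 = np.asarray(delta1, dtype=int)
        d2 = np.asarray(delta2, dtype=int)
        self.idx11 = np.flatnonzero(d1 & d2)
        self.idx10 = np.flatnonzero(d1 & (1 - d2))
        self.idx01 = np.flatnonzero(d2 & (1 - d1))
        self.w4 = (d1 + d2 + 1).astype(float)

    @classmethod
    def from_data(cls, data: BivariateSurvivalData) -> "_PsiIndex":
        return cls(data.delta1, data.delta2)


def _log_psi_sum(F1, F2, phi: float, pidx: _PsiIndex):
    """Sum over subjects of ``log Psi_i`` for CDF arrays ``F1``, ``F2``.

    ``F1`` and ``F2`` may carry leading batch axes (broadcast against each
    other); the subject axis is the last one.  Rows where the double-event
    numerator is non-positive (possible only at the numerical boundary)
    return ``-inf``.
    """
    D = 1.0 - phi * (F1 * F2)
    out = -(np.log(D) * pidx.w4).sum(axis=-1)
    if pidx.idx10.size:
        out = out + np.log(
            1.0 - phi * np.take(F2, pidx.idx10, axis=-1)
        ).sum(axis=-1)
    if pidx.idx01.size:
        out = out + np.log(
            1.0 - phi * np.take(F1, pidx.idx01, axis=-1)
        ).sum(axis=-1)
    if pidx.idx11.size:
        a = np.take(F1, pidx.idx11, axis=-1)
        b = np.take(F2, pidx.idx11, axis=-1)
        A = (1.0 + phi) * (1.0 + phi * a * b) - 2.0 * phi * (a + b)
        pos = A > 0.0
        logA = np.where(pos, np.log(np.where(pos, A, 1.0)), -np.inf)
        out = out + logA.sum(axis=-1)
    return out


# ---------------------------------------------------------------------------
# joint survival / density / partials
# ---------------------------------------------------------------------------

def joint_survival(t1, t2, params: ModelParams):
    """AMH joint survival function ``S(t1, t2)``.

    Reduces to ``S1(t1) * S2(t2)`` at ``phi = 0`` and to the opposite
    margin's survival when one argument is 0.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("times must be nonnegative")
    S1 = weibull_survival(t1, params.alpha1, params.beta1)
    S2 = weibull_survival(t2, params.alpha2, params.beta2)
    return S1 * S2 / (1.0 - params.phi * (1.0 - S1) * (1.0 - S2))


def joint_density(t1, t2, params: ModelParams):
    """Joint density ``f(t1, t2)``, the mixed partial of the survival function.

    ``f = f1 f2 [(1+phi)(1+phi F1 F2) - 2 phi (F1+F2)] / (1-phi F1 F2)**3``
    with ``F_j = 1 - S_j``.  Nonnegative on the positive quadrant for all
    valid ``phi``.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("times must be strictly positive")
    phi = params.phi
    f1 = weibull_density(t1, params.alpha1, params.beta1)
    f2 = weibull_density(t2, params.alpha2, params.beta2)
    F1 = weibull_cdf(t1, params.alpha1, params.beta1)
    F2 = weibull_cdf(t2, params.alpha2, params.beta2)
    num = (1.0 + phi) * (1.0 + phi * F1 * F2) - 2.0 * phi * (F1 + F2)
    den = (1.0 - phi * F1 * F2) ** 3
    return f1 * f2 * num / den


def partial_survival(t1, t2, params: ModelParams, margin: int):
    """Negative single partial derivative of the joint survival function.

    ``margin=1`` returns ``-dS/dt1 = f1 S2 (1-phi F2)/(1-phi F1 F2)**2``
    (the likelihood factor when margin 1 is an event and margin 2 is
    censored); ``margin=2`` is the mirror image.
    """
    if margin not in (1, 2):
        raise ValueError(f"margin must be 1 or 2, got {margin!r}")
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    phi = params.phi
    F1 = weibull_cdf(t1, params.alpha1, params.beta1)
    F2 = weibull_cdf(t2, params.alpha2, params.beta2)
    den = (1.0 - phi * F1 * F2) ** 2
    if margin == 1:
        f1 = weibull_density(t1, params.alpha1, params.beta1)
        return f1 * (1.0 - F2) * (1.0 - phi * F2) / den
    f2 = weibull_density(t2, params.alpha2, params.beta2)
    return f2 * (1.0 - F1) * (1.0 - phi * F1) / den


# ---------------------------------------------------------------------------
# likelihood / prior
# ---------------------------------------------------------------------------

def log_likelihood(
    data: BivariateSurvivalData,
    params: ModelParams,
    _pidx: _PsiIndex | None = None,
) -> float:
    """Exact censored-data log-likelihood of the AMH-Weibull model.

    Each subject contributes the joint density, a negative partial, or the
    joint survival according to its censoring pattern.  At ``phi = 0``
    this is the sum of two independent censored Weibull log-likelihoods;
    with all events observed it equals ``sum(log joint_density)``.
    Returns ``-inf`` if a double-event numerator underflows to a
    non-positive value.
    """
    pidx = _pidx if _pidx is not None else _PsiIndex.from_data(data)
    total = 0.0
    Fs = []
    for j in (1, 2):
        t, d = data.margin(j)
        a, b = params.margin(j)
        with np.errstate(over="ignore", under="ignore"):
            ta = t ** a
        r = float(d.sum())
        total += (
            r * math.log(a * b)
            + (a - 1.0) * float((d * np.log(t)).sum())
            - b * float(ta.sum())
        )
        Fs.append(-np.expm1(-b * ta))
    total += float(_log_psi_sum(Fs[0], Fs[1], params.phi, pidx))
    if np.isnan(total):
        return -np.inf
    return total


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -np.inf
    return (
        shape * math.log(rate)
        - float(gammaln(shape))
        + (shape - 1.0) * math.log(x)
        - rate * x
    )


def log_prior(params: ModelParams, hyper: Hyperparams) -> float:
    """Log prior density: independent Gammas on the Weibull parameters and
    ``U(-1, 1)`` on ``phi`` (open at both ends, so ``phi = -1`` has prior
    density zero even though the model itself admits it)."""
    if not (-1.0 < params.phi < 1.0):
        return -np.inf
    out = _LOG_HALF
    for j in (1, 2):
        a, b = params.margin(j)
        out += _gamma_logpdf(a, *hyper.alpha_prior(j))
        out += _gamma_logpdf(b, *hyper.beta_prior(j))
    return out


def log_posterior(
    data: BivariateSurvivalData, params: ModelParams, hyper: Hyperparams
) -> float:
    """Unnormalized log posterior ``log L + log prior``."""
    lp = log_prior(params, hyper)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(data, params)


def log_kappa_alpha(
    alpha,
    margin: int,
    data: BivariateSurvivalData,
    other_params: ModelParams,
    hyper: Hyperparams,
):
    """Log conditional-posterior kernel ``log kappa(alpha_j)``.

    For margin 1:
    ``kappa(a) = a**(a11+r1-1) exp{a [sum d log t - a12] - b1 sum t**a}
    prod_i Psi_i``; this equals ``log_likelihood + log_prior`` up to an
    additive constant that does not depend on ``alpha_j``.  Vectorized
    over ``alpha``; non-positive shapes map to ``-inf``.
    """
    if margin not in (1, 2):
        raise ValueError(f"margin must be 1 or 2, got {margin!r}")
    al = np.asarray(alpha, dtype=float)
    scalar = al.ndim == 0
    al = np.atleast_1d(al)
    if np.any(~np.isfinite(al)):
        raise ValueError("alpha must be finite")
    t, d = data.margin(margin)
    a1h, a2h = hyper.alpha_prior(margin)
    beta = other_params.margin(margin)[1]
    r = float(d.sum())
    sdlogt = float((d * np.log(t)).sum())
    to, do_ = data.margin(3 - margin)
    ao, bo = other_params.margin(3 - margin)
    F_other = -np.expm1(-bo * to ** ao)
    pidx = _PsiIndex.from_data(data)

    valid = al > 0
    al_safe = np.where(valid, al, 1.0)
    with np.errstate(over="ignore", under="ignore"):
        ta = np.exp(np.outer(al_safe, np.log(t)))
        F = -np.expm1(-beta * ta)
        if margin == 1:
            lpsi = _log_psi_sum(F, F_other, other_params.phi, pidx)
        else:
            lpsi = _log_psi_sum(F_other, F, other_params.phi, pidx)
        val = (
            (a1h + r - 1.0) * np.log(al_safe)
            + al_safe * (sdlogt - a2h)
            - beta * ta.sum(axis=1)
            + lpsi
        )
    val = np.where(valid & ~np.isnan(val), val, -np.inf)
    return float(val[0]) if scalar else val


# ---------------------------------------------------------------------------
# dependence measures
# ---------------------------------------------------------------------------

def amh_copula(u, v, phi: float):
    """AMH copula ``C(u, v) = u v / [1 - phi (1-u)(1-v)]``."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return u * v / (1.0 - phi * (1.0 - u) * (1.0 - v))


def _check_phi(phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if np.any((phi < -1.0) | (phi >= 1.0)):
        raise ValueError("phi must lie in [-1, 1)")
    return phi


def kendall_tau(phi):
    """Kendall's tau of the AMH copula.

    Closed form ``tau = 1 - 2[phi + (1-phi)^2 ln(1-phi)] / (3 phi^2)``,
    with the removable singularity at ``phi = 0`` handled by its Taylor
    series ``2 phi/9 + phi^2/18 + phi^3/45``.  Monotone increasing from
    ``(5 - 8 ln 2)/3 ~ -0.1817`` at ``phi = -1`` to ``1/3`` as
    ``phi -> 1``.
    """
    phi = _check_phi(phi)
    scalar = phi.ndim == 0
    phi = np.atleast_1d(phi)
    out = np.empty_like(phi)
    small = np.abs(phi) < 1e-4
    p = phi[small]
    out[small] = 2.0 * p / 9.0 + p ** 2 / 18.0 + p ** 3 / 45.0
    p = phi[~small]
    out[~small] = 1.0 - 2.0 * (p + (1.0 - p) ** 2 * np.log1p(-p)) / (
        3.0 * p ** 2
    )
    return float(out[0]) if scalar else out


def spearman_rho(phi, epsabs: float = 1e-10):
    """Spearman's rho of the AMH copula via adaptive 2-D quadrature.

    ``rho = 12 * double-integral of C_phi(u, v) - 3``; ranges from about
    -0.2711 at ``phi = -1`` to about 0.4784 as ``phi -> 1``.
    """
    phi = _check_phi(phi)
    scalar = phi.ndim == 0
    phi = np.atleast_1d(phi)
    out = np.empty_like(phi)
    for i, p in enumerate(phi):
        val, _ = integrate.dblquad(
            lambda v, u: u * v / (1.0 - p * (1.0 - u) * (1.0 - v)),
            0.0,
            1.0,
            0.0,
            1.0,
            epsabs=epsabs,
            epsrel=1e-10,
        )
        out[i] = 12.0 * val - 3.0
    return float(out[0]) if scalar else out
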