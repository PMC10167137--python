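"""Parametric response families and maximum-likelihood node fits.

Three families are provided:

* ``exgaussian`` — the exponentially modified Gaussian, the standard
  right-skewed model for reaction times.  Parameterised as
  ``(mu, sigma, nu)`` where ``mu``/``sigma`` are the Gaussian location and
  scale and ``nu`` is the mean of the exponential component, so that
  ``E[X] = mu + nu`` and ``Var[X] = sigma**2 + nu**2``.
* ``gb1`` — the generalized beta distribution of the first kind on the open
  unit interval, used for accuracy rates.  Parameterised as
  ``(mu, sigma, nu, tau)`` with ``mu, sigma`` in (0, 1) and ``nu, tau > 0``;
  at ``nu = tau = 1`` it reduces to the Beta distribution with mean ``mu``
  and dispersion ``sigma`` (``a = mu(1-sigma^2)/sigma^2``,
  ``b = (1-mu)(1-sigma^2)/sigma^2``).
* ``normal`` — included as the classical reference family.

Each family exposes a vectorised log-density; :func:`fit_mle` maximises the
sample log-likelihood on the link scale (identity for unbounded, log for
positive, logit for unit-interval parameters) and returns a
:class:`FittedNodeModel` carrying the per-observation score matrix that the
distributional tree uses for its parameter-instability tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "DistributionSpec",
    "FittedNodeModel",
    "EXGAUSSIAN",
    "GB1",
    "NORMAL",
    "get_family",
    "exgauss_logpdf",
    "exgauss_scores",
    "exgauss_rvs",
    "exgauss_median",
    "gb1_logpdf",
    "normal_logpdf",
    "fit_mle",
    "squeeze_unit",
]

_SQRT2 = math.sqrt(2.0)
_LOG2PI = math.log(2.0 * math.pi)

# link-scale magnitude beyond which a fit is declared to sit on the boundary
BOUNDARY_ETA = 15.0
# relative log-likelihood convergence tolerance
LOGLIK_RTOL = 1e-8


# --------------------------------------------------------------------------
# links
# --------------------------------------------------------------------------

class _Link:
    name = "identity"

    @staticmethod
    def to_eta(theta):
        return theta

    @staticmethod
    def to_theta(eta):
        return eta

    @staticmethod
    def dtheta_deta(eta):
        return np.ones_like(eta)


class _LogLink(_Link):
    name = "log"

    @staticmethod
    def to_eta(theta):
        return np.log(theta)

    @staticmethod
    def to_theta(eta):
        return np.exp(np.clip(eta, -700, 700))

    @staticmethod
    def dtheta_deta(eta):
        return np.exp(np.clip(eta, -700, 700))


class _LogitLink(_Link):
    name = "logit"

    @staticmethod
    def to_eta(theta):
        return special.logit(theta)

    @staticmethod
    def to_theta(eta):
        return special.expit(eta)

    @staticmethod
    def dtheta_deta(eta):
        p = special.expit(eta)
        return p * (1.0 - p)


LINKS = {"identity": _Link, "log": _LogLink, "logit": _LogitLink}


# --------------------------------------------------------------------------
# family specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A parametric family: names, links and support.

    ``support`` is a pair of open-interval endpoints for the observations
    (``(-inf, inf)`` for the real line, ``(0, 1)`` for rates).
    """

    family: str
    parameter_names: tuple
    links: tuple
    support: tuple = (-np.inf, np.inf)

    def __post_init__(self):
        if len(self.parameter_names) != len(self.links):
            raise ValueError("one link per parameter required")

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    def link_objs(self):
        return [LINKS[name] for name in self.links]

    def parameter_supports(self):
        """Natural-scale open domains implied by the links."""
        doms = {"identity": (-np.inf, np.inf), "log": (0.0, np.inf),
                "logit": (0.0, 1.0)}
        return [doms[name] for name in self.links]

    def logpdf(self, x, theta):
        return _LOGPDFS[self.family](x, *theta)

    def scores(self, x, theta):
        """Per-observation derivatives of the log-density w.r.t. the
        natural-scale parameters (n x p)."""
        fn = _SCORES.get(self.family)
        if fn is not None:
            return fn(x, *theta)
        return _fd_scores(self, x, theta)

    def check_support(self, x):
        lo, hi = self.support
        x = np.asarray(x, dtype=float)
        if np.any(~np.isfinite(x)) or np.any(x <= lo) or np.any(x >= hi):
            raise ValueError(
                f"observations outside the open support ({lo}, {hi}) "
                f"of family {self.family!r}"
            )


EXGAUSSIAN = DistributionSpec(
    "exgaussian", ("mu", "sigma", "nu"), ("identity", "log", "log")
)
GB1 = DistributionSpec(
    "gb1", ("mu", "sigma", "nu", "tau"), ("logit", "logit", "log", "log"),
    support=(0.0, 1.0),
)
NORMAL = DistributionSpec("normal", ("mu", "sigma"), ("identity", "log"))

_FAMILIES = {"exgaussian": EXGAUSSIAN, "gb1": GB1, "normal": NORMAL}


def get_family(name: str) -> DistributionSpec:
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; choose from {sorted(_FAMILIES)}")


# --------------------------------------------------------------------------
# Ex-Gaussian
# --------------------------------------------------------------------------

def exgauss_logpdf(x, mu, sigma, nu):
    """Log-density of the exponentially modified Gaussian.

    Two numerically stable branches are combined.  In and left of the bulk
    (``(x - mu)/sigma <= sigma/nu``) the scaled complementary error
    function keeps the expression finite for arbitrarily small ``nu``:

        log f(x) = -log(2 nu) - (x - mu)^2 / (2 sigma^2)
                   + log erfcx((sigma/nu - (x - mu)/sigma) / sqrt(2))

    In the exponential right tail (where erfcx of a large negative argument
    would overflow) the log-Phi form is exact and cancellation-free:

        log f(x) = -log nu + sigma^2/(2 nu^2) - (x - mu)/nu
                   + log Phi((x - mu)/sigma - sigma/nu)
    """
    x = np.asarray(x, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(sigma <= 0) or np.any(nu <= 0):
        raise ValueError("sigma and nu must be positive")
    d = (x - mu) / sigma
    z = d - sigma / nu
    with np.errstate(over="ignore"):
        left = -np.log(2.0 * nu) - 0.5 * d * d + np.log(special.erfcx(-z / _SQRT2))
    right = (-np.log(nu) + 0.5 * (sigma / nu) ** 2 - (x - mu) / nu
             + special.log_ndtr(z))
    return np.where(z <= 0.0, left, right)


def _exgauss_hratio(z):
    # phi(z) / Phi(z) = exp(log phi - log Phi), stable in both tails;
    # extreme optimizer excursions may overflow harmlessly to 0 or inf
    with np.errstate(over="ignore", invalid="ignore"):
        return np.exp(-0.5 * z * z - 0.5 * _LOG2PI - special.log_ndtr(z))


def exgauss_scores(x, mu, sigma, nu):
    """Per-observation gradient of ``exgauss_logpdf`` in (mu, sigma, nu)."""
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma - sigma / nu
    r = _exgauss_hratio(z)
    d_mu = 1.0 / nu - r / sigma
    d_sigma = sigma / nu**2 + r * (-(x - mu) / sigma**2 - 1.0 / nu)
    d_nu = (-1.0 / nu - sigma**2 / nu**3 + (x - mu) / nu**2) + r * (sigma / nu**2)
    return np.column_stack([d_mu, d_sigma, d_nu])


def exgauss_rvs(mu, sigma, nu, size, rng):
    return mu + sigma * rng.standard_normal(size) + rng.exponential(nu, size)


def exgauss_median(mu, sigma, nu):
    """Median of the Ex-Gaussian (via the exponnorm quantile function)."""
    return mu + stats.exponnorm.ppf(0.5, nu / sigma, loc=0.0, scale=sigma)


# --------------------------------------------------------------------------
# Generalized beta type 1
# --------------------------------------------------------------------------

def _gb1_ab(mu, sigma):
    c = (1.0 - sigma**2) / sigma**2
    return mu * c, (1.0 - mu) * c


def gb1_logpdf(x, mu, sigma, nu, tau):
    """Log-density of the generalized beta type 1 on (0, 1).

    With ``a = mu (1 - sigma^2)/sigma^2`` and
    ``b = (1 - mu)(1 - sigma^2)/sigma^2``:

        f(y) = tau nu^b y^(tau a - 1) (1 - y^tau)^(b - 1)
               / ( B(a, b) (nu + (1 - nu) y^tau)^(a + b) )

    At ``nu = tau = 1`` this is the Beta(a, b) density, i.e. the
    mean-``mu`` / dispersion-``sigma`` Beta of the location-scale
    convention for rates.
    """
    x = np.asarray(x, dtype=float)
    mu, sigma, nu, tau = (np.asarray(v, dtype=float) for v in (mu, sigma, nu, tau))
    if (np.any(mu <= 0) or np.any(mu >= 1) or np.any(sigma <= 0)
            or np.any(sigma >= 1) or np.any(nu <= 0) or np.any(tau <= 0)):
        raise ValueError("gb1 requires mu, sigma in (0,1) and nu, tau > 0")
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("gb1 observations must lie strictly inside (0, 1); "
                         "squeeze boundary values first")
    a, b = _gb1_ab(mu, sigma)
    logx = np.log(x)
    w = np.exp(tau * logx)              # y^tau in (0,1)
    return (
        np.log(tau)
        + b * np.log(nu)
        + (tau * a - 1.0) * logx
        + (b - 1.0) * np.log1p(-w)
        - special.betaln(a, b)
        - (a + b) * np.log(nu + (1.0 - nu) * w)
    )


def gb1_scores(x, mu, sigma, nu, tau):
    """Per-observation gradient of ``gb1_logpdf`` in (mu, sigma, nu, tau).

    Derivatives are taken via the shape pair ``(a, b)`` and chained back to
    the location/dispersion parameterisation.
    """
    x = np.asarray(x, dtype=float)
    mu, sigma, nu, tau = (np.asarray(v, dtype=float) for v in (mu, sigma, nu, tau))
    c = (1.0 - sigma**2) / sigma**2
    a = mu * c
    b = (1.0 - mu) * c
    logx = np.log(x)
    w = np.exp(tau * logx)
    denom = nu + (1.0 - nu) * w
    psi_ab = special.digamma(a + b)
    d_a = tau * logx - special.digamma(a) + psi_ab - np.log(denom)
    d_b = np.log(nu) + np.log1p(-w) - special.digamma(b) + psi_ab - np.log(denom)
    d_nu = b / nu - (a + b) * (1.0 - w) / denom
    d_tau = (1.0 / tau + a * logx - (b - 1.0) * w * logx / (1.0 - w)
             - (a + b) * (1.0 - nu) * w * logx / denom)
    dc_dsigma = -2.0 / sigma**3
    d_mu = c * (d_a - d_b)
    d_sigma = dc_dsigma * (mu * d_a + (1.0 - mu) * d_b)
    return np.column_stack([np.broadcast_to(d_mu, x.shape),
                            np.broadcast_to(d_sigma, x.shape),
                            np.broadcast_to(d_nu, x.shape),
                            np.broadcast_to(d_tau, x.shape)])


def normal_logpdf(x, mu, sigma):
    x = np.asarray(x, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    d = (x - mu) / sigma
    return -0.5 * d * d - np.log(sigma) - 0.5 * _LOG2PI


def _normal_scores(x, mu, sigma):
    x = np.asarray(x, dtype=float)
    d = (x - mu) / sigma
    return np.column_stack([d / sigma, (d * d - 1.0) / sigma])


_LOGPDFS = {
    "exgaussian": exgauss_logpdf,
    "gb1": gb1_logpdf,
    "normal": normal_logpdf,
}
_SCORES = {
    "exgaussian": exgauss_scores,
    "gb1": gb1_scores,
    "normal": _normal_scores,
}


def _fd_scores(spec, x, theta, rel_h=1e-5):
    """Central finite-difference scores on the natural scale.

    Step sizes are shrunk near a parameter-domain boundary so the
    perturbed parameters stay admissible.
    """
    x = np.asarray(x, dtype=float)
    p = len(theta)
    doms = spec.parameter_supports()
    out = np.empty((x.size, p))
    for j in range(p):
        lo, hi = doms[j]
        h = rel_h * max(abs(theta[j]), 1e-3)
        if np.isfinite(hi):
            h = min(h, 0.5 * (hi - theta[j]))
        if np.isfinite(lo):
            h = min(h, 0.5 * (theta[j] - lo))
        h = max(h, 1e-300)
        tp = list(theta)
        tm = list(theta)
        tp[j] += h
        tm[j] -= h
        out[:, j] = (spec.logpdf(x, tp) - spec.logpdf(x, tm)) / (2.0 * h)
    return out


# --------------------------------------------------------------------------
# squeeze to the open unit interval
# --------------------------------------------------------------------------

def squeeze_unit(values, epsilon=0.005):
    """Compress [0, 1] values into (epsilon, 1 - epsilon).

    ``v -> v (1 - 2 eps) + eps``: strictly monotone, maps 0 to ``eps`` and
    1 to ``1 - eps`` with 0.5 a fixed point.  Needed because GB1 has open
    support while perfect accuracies occur.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    v = np.asarray(values, dtype=float)
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise ValueError("values must lie in [0, 1]")
    return v * (1.0 - 2.0 * epsilon) + epsilon


# --------------------------------------------------------------------------
# ML fitting
# --------------------------------------------------------------------------

@dataclass
class FittedNodeModel:
    """A maximum-likelihood fit of one family to one sample."""

    spec: DistributionSpec
    theta_hat: np.ndarray
    loglik: float
    n: int
    score_matrix: np.ndarray = field(repr=False)
    converged: bool = True
    boundary: bool = False

    def to_json(self) -> str:
        return json.dumps({
            "family": self.spec.family,
            "theta_hat": dict(zip(self.spec.parameter_names,
                                  np.asarray(self.theta_hat).tolist())),
            "loglik": float(self.loglik),
            "n": int(self.n),
            "converged": bool(self.converged),
        })


def _moment_start(x, spec):
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x))
    s = float(np.std(x))
    if spec.family == "normal":
        return np.array([m, max(s, 1e-8)])
    if spec.family == "exgaussian":
        g1 = float(stats.skew(x)) if x.size > 2 else 0.0
        g1 = min(max(g1, 1e-3), 10.0)
        nu0 = s * (g1 / 2.0) ** (1.0 / 3.0)
        nu0 = min(max(nu0, 0.05 * s, 1e-6), 0.95 * s * 3)
        sigma0 = math.sqrt(max(s**2 - nu0**2, (0.05 * s) ** 2, 1e-12))
        return np.array([m - nu0, sigma0, nu0])
    if spec.family == "gb1":
        v = max(float(np.var(x)), 1e-8)
        mu0 = min(max(m, 0.02), 0.98)
        sig0 = math.sqrt(min(max(v / (mu0 * (1.0 - mu0)), 1e-4), 0.9))
        return np.array([mu0, sig0, 1.0, 1.0])
    raise ValueError(spec.family)


def fit_mle(sample, spec, init=None, seed=0, n_restarts=3, max_iter=500,
            polish=True):
    """Maximum-likelihood fit of ``spec`` to ``sample``.

    Optimisation runs on the link scale (L-BFGS-B within a wide box),
    starting from the method-of-moments estimate (or ``init`` on the
    natural scale), with jittered restarts on failure (seeded, so the fit
    is deterministic).  Non-convergence is reported honestly via
    ``converged=False``; a link-scale parameter beyond ``+-15`` raises the
    separate ``boundary`` flag (e.g. families on the unit interval chasing
    an atom of identical observations).
    """
    x = np.asarray(sample, dtype=float)
    spec.check_support(x)
    p = spec.n_params
    if x.size < 2:
        raise ValueError("need at least two observations")
    links = spec.link_objs()

    if x.size >= 2 and np.ptp(x) == 0.0 and spec.family != "normal":
        # degenerate constant sample: scale parameters run to the boundary
        theta = _moment_start(x + 0.0, spec)
        ll = float(np.sum(spec.logpdf(x, theta)))
        return FittedNodeModel(spec, theta, ll, x.size,
                               np.zeros((x.size, p)), converged=False,
                               boundary=True)

    def unpack(eta):
        return [lk.to_theta(eta[j]) for j, lk in enumerate(links)]

    def negll(eta):
        theta = unpack(eta)
        try:
            lp = spec.logpdf(x, theta)
        except (ValueError, FloatingPointError):
            return np.inf
        if not np.all(np.isfinite(lp)):
            return np.inf
        return -float(np.sum(lp))

    def negll_grad(eta):
        theta = unpack(eta)
        try:
            sc = spec.scores(x, theta)      # natural scale
        except (ValueError, FloatingPointError):
            return np.zeros(p)
        d = np.array([lk.dtheta_deta(eta[j]) for j, lk in enumerate(links)])
        g = -(sc.sum(axis=0) * d)
        return np.nan_to_num(g, nan=0.0, posinf=1e12, neginf=-1e12)

    theta0 = np.asarray(init, dtype=float) if init is not None else _moment_start(x, spec)
    eta0 = np.array([lk.to_eta(theta0[j]) for j, lk in enumerate(links)])

    rng = np.random.default_rng(seed)
    best = None
    starts = [eta0]
    for _ in range(n_restarts):
        starts.append(eta0 + rng.normal(scale=0.3, size=p))

    ll0 = -negll(eta0)
    box = [(-BOUNDARY_ETA - 3.0, BOUNDARY_ETA + 3.0)] * p
    for k, e0 in enumerate(starts):
        res = optimize.minimize(
            negll, np.clip(e0, box[0][0], box[0][1]), jac=negll_grad,
            method="L-BFGS-B", bounds=box,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.success and np.isfinite(best.fun):
            break
    if not best.success and polish:
        # simplex polish: families with near-degenerate ridges (GB1 fitting
        # an atom of identical rates) defeat curvature-based line searches
        nm = optimize.minimize(negll, best.x if np.isfinite(best.fun) else eta0,
                               method="Nelder-Mead",
                               options={"maxiter": 400 * p, "fatol": 1e-10,
                                        "xatol": 1e-8})
        nm.x = np.clip(nm.x, box[0][0], box[0][1])
        nm.fun = negll(nm.x)
        if nm.fun <= best.fun or not np.isfinite(best.fun):
            best = nm

    eta_hat = best.x
    theta_hat = np.array(unpack(eta_hat))
    ll = -float(best.fun)
    boundary = bool(np.any(np.abs(eta_hat) > BOUNDARY_ETA))
    converged = bool(best.success) and np.isfinite(ll)
    # the optimiser must never lose to its initialiser
    if np.isfinite(ll0) and ll < ll0 - abs(ll0) * LOGLIK_RTOL - 1e-9:
        converged = False
    try:
        scores = spec.scores(x, theta_hat) if np.all(np.isfinite(theta_hat)) \
            else np.zeros((x.size, p))
        if not np.all(np.isfinite(scores)):
            # a degenerate (boundary) optimum: no usable score information
            scores = np.zeros((x.size, p))
    except (ValueError, FloatingPointError):
        scores = np.zeros((x.size, p))
    return FittedNodeModel(spec, theta_hat, ll, int(x.size), scores,
                           converged=converged, boundary=boundary)
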