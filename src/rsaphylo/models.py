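"""Ecological RSA models for protein-domain abundances.

Three candidate Relative Species Abundance distributions arise from a
birth-death-innovation diffusion with environmental and demographic
noise (Engen-Lande framework):

* **Poisson Log-Normal** (PLN) - Gompertzian density regulation
  g(x) = gamma*ln(x + eps); the Poisson mixing rate is log-normally
  distributed with mu = r/gamma and sigma^2 = sigma_e^2 / (2*gamma).
* **Negative Binomial** (NB) - linear regulation g(x) = eta*x; the
  mixing rate is Gamma with shape alpha = 2(r + eta*eps)/sigma_e^2 and
  the NB success rate is q = sigma_e^2 / (2*eta + sigma_e^2).
* **Log-Series** (LS) - the alpha -> 0 limit of the NB.

All models are fitted zero-truncated (the zero-abundance class is
unobservable), by maximum likelihood, and compared by AIC.  Fit quality
is additionally summarised by an R^2 over Preston octaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .profiles import RSAHistogram

MODEL_ORDER = ("PLN", "NB", "LS")  # deterministic tie-break order


class ModelError(ValueError):
    """Invalid model parameters or unusable input."""


class UnfittableRSAError(ModelError):
    """RSA too degenerate to fit (mirrors genomes excluded upstream)."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLNParams:
    """Poisson Log-Normal: mu location, sigma2 variance of log rate."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and np.isfinite(self.sigma2)):
            raise ModelError("non-finite PLN parameters")
        if self.sigma2 <= 0:
            raise ModelError(f"PLN sigma2 must be > 0, got {self.sigma2}")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)


@dataclass(frozen=True)
class NBParams:
    """Negative Binomial: dispersion alpha > 0, success rate q in (0,1)."""

    dispersion: float
    q: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dispersion) and np.isfinite(self.q)):
            raise ModelError("non-finite NB parameters")
        if self.dispersion <= 0:
            raise ModelError(f"NB dispersion must be > 0, got {self.dispersion}")
        if not 0 < self.q < 1:
            raise ModelError(f"NB q must lie in (0,1), got {self.q}")


@dataclass(frozen=True)
class LSParams:
    """Log-Series: q in (0,1)."""

    q: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.q) or not 0 < self.q < 1:
            raise ModelError(f"LS q must lie in (0,1), got {self.q}")


@dataclass(frozen=True)
class EcologicalParams:
    """Rates of the stochastic growth model.

    r = b - d is the net per-copy growth rate; sigma_e2 and sigma_d2 the
    environmental and demographic variances; epsilon = sigma_d2/sigma_e2.
    Exactly one of gamma (Gompertz regulation strength) or eta (linear
    regulation strength) is set, fixing the regulation mode.
    """

    r: float
    sigma_e2: float
    sigma_d2: float = 0.0
    gamma: float | None = None
    eta: float | None = None
    omega0: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_e2 <= 0:
            raise ModelError("sigma_e2 must be > 0")
        if self.sigma_d2 < 0:
            raise ModelError("sigma_d2 must be >= 0")
        if self.omega0 <= 0:
            raise ModelError("omega0 must be > 0")
        if (self.gamma is None) == (self.eta is None):
            raise ModelError("set exactly one of gamma (Gompertz) or eta (linear)")
        if self.gamma is not None and self.gamma <= 0:
            raise ModelError("gamma must be > 0")
        if self.eta is not None and self.eta <= 0:
            raise ModelError("eta must be > 0")

    @property
    def epsilon(self) -> float:
        return self.sigma_d2 / self.sigma_e2

    @property
    def regulation(self) -> str:
        return "gompertz" if self.gamma is not None else "linear"


def eco_to_dist_params(eco: EcologicalParams, regulation: str | None = None):
    """Map ecological rates to the implied RSA distribution parameters.

    Gompertz regulation -> PLNParams(mu=r/gamma, sigma2=sigma_e2/(2 gamma));
    linear regulation  -> NBParams(alpha=2(r+eta*eps)/sigma_e2,
                                   q=sigma_e2/(2 eta + sigma_e2)).
    """
    regulation = regulation or eco.regulation
    if regulation != eco.regulation:
        raise ModelError(
            f"requested {regulation!r} regulation but parameters are {eco.regulation}"
        )
    if regulation == "gompertz":
        return PLNParams(mu=eco.r / eco.gamma, sigma2=eco.sigma_e2 / (2.0 * eco.gamma))
    alpha = 2.0 * (eco.r + eco.eta * eco.epsilon) / eco.sigma_e2
    if alpha <= 0:
        raise ModelError("linear regulation requires r + eta*epsilon > 0")
    q = eco.sigma_e2 / (2.0 * eco.eta + eco.sigma_e2)
    return NBParams(dispersion=alpha, q=q)


def lambda_rate(x, eco: EcologicalParams, regulation: str | None = None):
    """Closed-form intensity lambda(x) of the abundance point process.

    Gompertz: lambda(x) = alpha*omega0/(x+eps) *
        exp(-[ln(x+eps) - r/gamma]^2 / (sigma_e^2/gamma)),
        alpha = (2/sigma_e^2) exp{(gamma/sigma_e^2)[ln(1+eps) - r/gamma]^2}.
    Linear:   lambda(x) = a*omega0 (x+eps)^{2(r+eta*eps)/sigma_e^2 - 1}
        exp(-2 eta (x+eps)/sigma_e^2),
        a = 2 e^{2(1+eps)eta/sigma_e^2} / (sigma_e^2 (1+eps)^{2(r+eta*eps)/sigma_e^2}).
    """
    regulation = regulation or eco.regulation
    if regulation != eco.regulation:
        raise ModelError("regulation mode does not match parameters")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ModelError("lambda_rate requires x > 0")
    eps = eco.epsilon
    se2 = eco.sigma_e2
    if regulation == "gompertz":
        g = eco.gamma
        pref = (2.0 / se2) * np.exp((g / se2) * (np.log1p(eps) - eco.r / g) ** 2)
        z = np.log(x + eps) - eco.r / g
        return pref * eco.omega0 / (x + eps) * np.exp(-0.5 * z**2 / (se2 / (2.0 * g)))
    eta = eco.eta
    expo = 2.0 * (eco.r + eta * eps) / se2
    a = 2.0 * np.exp(2.0 * (1.0 + eps) * eta / se2) / (se2 * (1.0 + eps) ** expo)
    return a * eco.omega0 * (x + eps) ** (expo - 1.0) * np.exp(-2.0 * eta * (x + eps) / se2)


# ---------------------------------------------------------------------------
# probability mass functions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _simpson_logweights(npts: int) -> np.ndarray:
    w = np.ones(npts)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return np.log(w / 3.0)


def pln_logpmf(x, params: PLNParams, nodes: int = 801, span: float = 25.0) -> np.ndarray:
    """log PMF of the Poisson Log-Normal.

    P(x) = int_0^inf Poisson(x; lam) LogNormal(lam; mu, sigma2) dlam,
    integrated in u = log(lam) by Simpson's rule on a per-x grid centred
    at the integrand's mode (found by Newton) and scaled by its local
    curvature width, so narrow integrands (large x, or sigma2 -> 0) are
    resolved as well as wide ones.  `nodes` is the number of quadrature
    points (odd); all arithmetic is in log space.
    """
    x = np.atleast_1d(np.asarray(x))
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ModelError("PLN pmf requires integer x >= 0")
    x = x.astype(float)
    mu, s2 = params.mu, params.sigma2
    if nodes % 2 == 0:
        nodes += 1
    if x.size > 4096:  # chunk to bound the (len(x), nodes) work array
        return np.concatenate(
            [pln_logpmf(chunk, params, nodes=nodes, span=span)
             for chunk in np.array_split(x, math.ceil(x.size / 4096))]
        )
    # mode of g(u) = x*u - e^u - (u-mu)^2/(2 s2)
    u = np.where(x > 0, np.log(np.maximum(x, 1e-300)), mu - s2)
    for _ in range(80):
        eu = np.exp(np.clip(u, -700.0, 700.0))
        step = np.clip((x - eu - (u - mu) / s2) / (-eu - 1.0 / s2), -5.0, 5.0)
        u = u - step
        if np.max(np.abs(step)) < 1e-13:
            break
    width = 1.0 / np.sqrt(np.exp(np.clip(u, -700.0, 700.0)) + 1.0 / s2)
    tgrid = np.linspace(-span, span, nodes)
    un = u[:, None] + width[:, None] * tgrid[None, :]
    g = (x[:, None] * un - np.exp(np.clip(un, -700.0, 700.0))
         - (un - mu) ** 2 / (2.0 * s2))
    terms = _simpson_logweights(nodes)[None, :] + g
    du = width * (2.0 * span / (nodes - 1))
    return (logsumexp(terms, axis=1) + np.log(du)
            - gammaln(x + 1.0) - 0.5 * math.log(2.0 * math.pi * s2))


def pln_pmf(x, params: PLNParams, nodes: int = 801) -> np.ndarray:
    """Poisson Log-Normal probability mass at integer x >= 0."""
    return np.exp(pln_logpmf(x, params, nodes=nodes))


def nb_logpmf(x, params: NBParams) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x))
    if np.any(x < 0):
        raise ModelError("NB pmf requires x >= 0")
    # scipy's nbinom: pmf(k) = C(k+n-1, k) p^n (1-p)^k, so p = 1 - q
    return stats.nbinom.logpmf(x, params.dispersion, 1.0 - params.q)


def nb_pmf(x, params: NBParams) -> np.ndarray:
    """Negative Binomial pmf Gamma(x+a)/(x! Gamma(a)) (1-q)^a q^x."""
    return np.exp(nb_logpmf(x, params))


def ls_logpmf(x, params: LSParams) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x))
    if np.any(x < 1):
        raise ModelError("Log-Series support starts at x = 1")
    return stats.logser.logpmf(x, params.q)


def ls_pmf(x, params: LSParams) -> np.ndarray:
    """Log-Series pmf  -q^x / (x ln(1-q)), support x >= 1."""
    return np.exp(ls_logpmf(x, params))


def _logpmf(model: str, params, x, nodes: int = 801) -> np.ndarray:
    if model == "PLN":
        return pln_logpmf(x, params, nodes=nodes)
    if model == "NB":
        return nb_logpmf(x, params)
    if model == "LS":
        return ls_logpmf(x, params)
    raise ModelError(f"unknown model {model!r}")


def _pmf_at_zero(model: str, params, nodes: int = 801) -> float:
    if model == "LS":
        return 0.0
    return float(np.exp(_logpmf(model, params, [0], nodes=nodes))[0])


def zt_logpmf(model: str, params, x, nodes: int = 801) -> np.ndarray:
    """log of the zero-truncated pmf; LS passes through (already truncated)."""
    x = np.atleast_1d(np.asarray(x))
    if np.any(x < 1):
        raise ModelError("zero-truncated pmf defined for x >= 1")
    if model == "LS":
        return ls_logpmf(x, params)
    p0 = _pmf_at_zero(model, params, nodes=nodes)
    if p0 >= 1.0 - 1e-15:
        raise ModelError("degenerate truncation: P(X=0) = 1 numerically")
    return _logpmf(model, params, x, nodes=nodes) - math.log1p(-p0)


def zt_pmf(model: str, params, x, nodes: int = 801) -> np.ndarray:
    """Zero-truncated pmf  p(x) / (1 - p(0)) on x >= 1."""
    return np.exp(zt_logpmf(model, params, x, nodes=nodes))


def model_x_max(model: str, params, observed_max: int) -> int:
    """Support cap for truncated infinite sums.

    max(4 * observed max, the 1 - 1e-9 quantile of the untruncated model).
    """
    if model == "NB":
        q = int(stats.nbinom.ppf(1 - 1e-9, params.dispersion, 1.0 - params.q))
    elif model == "LS":
        # geometric tail bound: sum_{k>x} q^k/(k(-ln(1-q))) <= q^{x+1}/((1-q)(-ln(1-q)))
        norm = (1.0 - params.q) * (-math.log1p(-params.q))
        q = 16
        while params.q ** (q + 1) / norm > 1e-9 and q < 10**8:
            q *= 2
    else:
        lam_hi = math.exp(min(params.mu + 6.0 * params.sigma, 700.0))
        q = int(stats.poisson.ppf(1 - 1e-9, lam_hi)) if lam_hi < 1e15 else 4 * observed_max
    return int(max(4 * observed_max, q, 16))


# ---------------------------------------------------------------------------
# Preston octaves and R^2
# ---------------------------------------------------------------------------

def preston_binning(rsa: RSAHistogram) -> np.ndarray:
    """Observed family counts per doubling octave [2^k, 2^{k+1}), k=0,1,..."""
    max_x = int(rsa.abundances.max())
    n_oct = int(math.floor(math.log2(max_x))) + 1
    out = np.zeros(n_oct, dtype=int)
    for x, n in rsa.counts.items():
        out[int(math.floor(math.log2(x)))] += n
    return out


def expected_octave_counts(model: str, params, rsa: RSAHistogram,
                           nodes: int = 801) -> np.ndarray:
    """Expected octave counts S * sum_{x in octave} zt_pmf(x).

    The residual mass beyond the support cap is folded into the last octave
    so the expectations sum to S.
    """
    obs = preston_binning(rsa)
    n_oct = len(obs)
    xs = np.arange(1, 2 ** n_oct)  # exact sums over the observed octaves
    p = zt_pmf(model, params, xs, nodes=nodes)
    octs = np.floor(np.log2(xs)).astype(int)
    exp_counts = np.zeros(n_oct)
    np.add.at(exp_counts, octs, p)
    exp_counts[-1] += 1.0 - p.sum()  # tail mass folded into the last octave
    return rsa.n_species * exp_counts


def r_squared(model: str, params, rsa: RSAHistogram, nodes: int = 801) -> float:
    """Preston-octave R^2 = 1 - SS_res/SS_tot (observed vs expected counts).

    Returns nan for a single-octave RSA, where SS_tot = 0.
    """
    obs = preston_binning(rsa).astype(float)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    exp = expected_octave_counts(model, params, rsa, nodes=nodes)
    return 1.0 - float(np.sum((obs - exp) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# maximum-likelihood fitting (statsmodels-style model/results objects)
# ---------------------------------------------------------------------------

@dataclass
class RSAFit:
    """Results of one zero-truncated MLE fit.

    aic = 2k - 2*loglik with k free parameters (PLN 2, NB 2, LS 1).
    bse are standard errors from the observed information (numerical
    Hessian in the natural parameter space); None if not invertible.
    """

    model: str
    params: PLNParams | NBParams | LSParams
    loglik: float
    aic: float
    r2: float
    n_species: int
    converged: bool
    bse: tuple[float, ...] | None = None

    @property
    def k_params(self) -> int:
        return 1 if self.model == "LS" else 2

    def param_values(self) -> tuple[float, ...]:
        if self.model == "PLN":
            return (self.params.mu, self.params.sigma2)
        if self.model == "NB":
            return (self.params.dispersion, self.params.q)
        return (self.params.q,)

    def param_names(self) -> tuple[str, ...]:
        if self.model == "PLN":
            return ("mu", "sigma2")
        if self.model == "NB":
            return ("dispersion", "q")
        return ("q",)

    def summary(self) -> str:
        lines = [
            f"Zero-truncated {self.model} fit (S = {self.n_species})",
            f"  log-likelihood: {self.loglik:.4f}",
            f"  AIC:            {self.aic:.4f}",
            f"  Preston R^2:    {self.r2:.4f}",
            f"  converged:      {self.converged}",
        ]
        ses = self.bse or (float("nan"),) * self.k_params
        for name, val, se in zip(self.param_names(), self.param_values(), ses):
            lines.append(f"  {name:<11}{val: .6g}  (se {se:.3g})")
        return "\n".join(lines)


class _ZTModel:
    """Base class: zero-truncated count model over an RSA histogram."""

    name: str = ""
    k_params: int = 0

    def __init__(self, rsa: RSAHistogram, min_species: int = 10, nodes: int = 801):
        self.rsa = rsa
        self.nodes = nodes
        self.xs = rsa.abundances.astype(float)
        self.ns = np.array([rsa.counts[int(x)] for x in self.xs], dtype=float)
        if rsa.n_species < min_species:
            raise UnfittableRSAError(
                f"unfittable RSA: S = {rsa.n_species} < minimum {min_species}"
            )

    # subclasses: natural params <-> unconstrained optimizer params
    def _to_params(self, theta: np.ndarray):
        raise NotImplementedError

    def _start(self) -> np.ndarray:
        raise NotImplementedError

    def _at_boundary(self, theta: np.ndarray) -> bool:
        return False

    def loglike(self, params) -> float:
        """Zero-truncated log-likelihood sum_x n_x log ztpmf(x)."""
        try:
            lp = zt_logpmf(self.name, params, self.xs, nodes=self.nodes)
        except ModelError:
            return -np.inf
        val = float(np.dot(self.ns, lp))
        return val if np.isfinite(val) else -np.inf

    def _negloglike_theta(self, theta: np.ndarray) -> float:
        try:
            params = self._to_params(theta)
        except ModelError:
            return np.inf
        return -self.loglike(params)

    def fit(self, maxiter: int = 2000, ftol: float = 1e-8,
            compute_se: bool = True) -> RSAFit:
        """MLE via Nelder-Mead followed by quasi-Newton polish.

        The zero-truncated likelihood surface is a curved, nearly flat
        ridge in (mu, sigma2)-like parameter pairs; the simplex gets the
        neighbourhood right and L-BFGS-B (numerical gradient) climbs the
        ridge.  The better of the two is kept, plus an independent
        quasi-Newton run from the moment start as a safeguard.
        """
        theta0 = self._start()
        candidates = []
        with np.errstate(invalid="ignore", over="ignore"):
            res = optimize.minimize(
                self._negloglike_theta, theta0, method="Nelder-Mead",
                options={"maxiter": min(maxiter, 300), "xatol": 1e-4, "fatol": ftol},
            )
            candidates.append(res)
            for start in (res.x, theta0):
                try:
                    polish = optimize.minimize(
                        self._negloglike_theta, start, method="L-BFGS-B",
                        options={"maxiter": maxiter},
                    )
                    candidates.append(polish)
                except (ValueError, FloatingPointError):  # pragma: no cover
                    continue
        finite = [c for c in candidates if np.isfinite(c.fun)]
        res = min(finite, key=lambda c: c.fun) if finite else res
        theta = res.x
        converged = np.isfinite(res.fun) and not self._at_boundary(theta)
        try:
            params = self._to_params(theta)
        except ModelError:
            params = self._to_params(theta0)
            converged = False
        loglik = self.loglike(params)
        aic = 2.0 * self.k_params - 2.0 * loglik
        bse = self._std_errors(params) if (compute_se and converged) else None
        return RSAFit(
            model=self.name, params=params, loglik=loglik, aic=aic,
            r2=r_squared(self.name, params, self.rsa, nodes=self.nodes),
            n_species=self.rsa.n_species, converged=converged, bse=bse,
        )

    # --- observed information ------------------------------------------------
    def _natural_values(self, params) -> np.ndarray:
        raise NotImplementedError

    def _from_natural(self, vals: np.ndarray):
        raise NotImplementedError

    def _std_errors(self, params) -> tuple[float, ...] | None:
        v0 = self._natural_values(params)
        k = len(v0)

        def nll(v: np.ndarray) -> float:
            try:
                return -self.loglike(self._from_natural(v))
            except ModelError:
                return np.inf

        h = 1e-4 * (1.0 + np.abs(v0))
        H = np.zeros((k, k))
        f0 = nll(v0)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    H[i, i] = (nll(v0 + ei) - 2 * f0 + nll(v0 - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        nll(v0 + ei + ej) - nll(v0 + ei - ej)
                        - nll(v0 - ei + ej) + nll(v0 - ei - ej)
                    ) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            return None
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        diag = np.diag(cov)
        if np.any(diag <= 0):
            return None
        return tuple(float(s) for s in np.sqrt(diag))


class PoissonLogNormal(_ZTModel):
    """Zero-truncated Poisson Log-Normal over an RSA histogram."""

    name = "PLN"
    k_params = 2

    def _to_params(self, theta: np.ndarray) -> PLNParams:
        return PLNParams(mu=float(theta[0]), sigma2=float(np.exp(theta[1])))

    def _start(self) -> np.ndarray:
        logs = np.log(self.xs)
        m = float(np.average(logs, weights=self.ns))
        v = float(np.average((logs - m) ** 2, weights=self.ns))
        return np.array([m - 0.5, math.log(max(v + 0.5, 0.1))])

    def _at_boundary(self, theta: np.ndarray) -> bool:
        return not (-16.0 < theta[1] < 16.0) or abs(theta[0]) > 50.0

    def _natural_values(self, params: PLNParams) -> np.ndarray:
        return np.array([params.mu, params.sigma2])

    def _from_natural(self, vals: np.ndarray) -> PLNParams:
        return PLNParams(mu=float(vals[0]), sigma2=float(vals[1]))


class NegativeBinomial(_ZTModel):
    """Zero-truncated Negative Binomial over an RSA histogram."""

    name = "NB"
    k_params = 2

    def _to_params(self, theta: np.ndarray) -> NBParams:
        return NBParams(
            dispersion=float(np.exp(np.clip(theta[0], -500.0, 500.0))),
            q=float(1.0 / (1.0 + np.exp(-np.clip(theta[1], -500.0, 500.0)))),
        )

    def _start(self) -> np.ndarray:
        m = float(np.average(self.xs, weights=self.ns))
        v = float(np.average((self.xs - m) ** 2, weights=self.ns))
        q0 = min(max(1.0 - m / v, 0.05), 0.95) if v > m else 0.5
        a0 = max(m * (1.0 - q0) / q0, 1e-3)
        return np.array([math.log(a0), math.log(q0 / (1.0 - q0))])

    def _at_boundary(self, theta: np.ndarray) -> bool:
        return not (-30.0 < theta[0] < 30.0) or not (-30.0 < theta[1] < 30.0)

    def _natural_values(self, params: NBParams) -> np.ndarray:
        return np.array([params.dispersion, params.q])

    def _from_natural(self, vals: np.ndarray) -> NBParams:
        return NBParams(dispersion=float(vals[0]), q=float(vals[1]))


class LogSeries(_ZTModel):
    """Log-Series over an RSA histogram (inherently zero-truncated)."""

    name = "LS"
    k_params = 1

    def _to_params(self, theta: np.ndarray) -> LSParams:
        return LSParams(q=float(1.0 / (1.0 + np.exp(-np.clip(theta[0], -500.0, 500.0)))))

    def _start(self) -> np.ndarray:
        m = float(np.average(self.xs, weights=self.ns))
        q0 = min(max(1.0 - 1.0 / m, 0.05), 0.95) if m > 1.0 else 0.05
        return np.array([math.log(q0 / (1.0 - q0))])

    def _at_boundary(self, theta: np.ndarray) -> bool:
        return not (-13.0 < theta[0] < 30.0)

    def _natural_values(self, params: LSParams) -> np.ndarray:
        return np.array([params.q])

    def _from_natural(self, vals: np.ndarray) -> LSParams:
        return LSParams(q=float(vals[0]))


_MODEL_CLASSES = {"PLN": PoissonLogNormal, "NB": NegativeBinomial, "LS": LogSeries}


def fit_mle(model: str, rsa: RSAHistogram, min_species: int = 10,
            nodes: int = 801, **fit_kw) -> RSAFit:
    """Fit one zero-truncated model to an RSA histogram by MLE."""
    if model not in _MODEL_CLASSES:
        raise ModelError(f"unknown model {model!r}")
    return _MODEL_CLASSES[model](rsa, min_species=min_species, nodes=nodes).fit(**fit_kw)


def fit_all(rsa: RSAHistogram, models: Sequence[str] = MODEL_ORDER,
            min_species: int = 10, nodes: int = 801, **fit_kw) -> list[RSAFit]:
    """Fit all candidate models to one RSA histogram."""
    return [fit_mle(m, rsa, min_species=min_species, nodes=nodes, **fit_kw)
            for m in models]


def select_model(fits: Iterable[RSAFit]) -> RSAFit:
    """Pick the converged fit with minimal AIC.

    Ties (|dAIC| < 1e-9) go to fewer parameters, then fixed order
    PLN < NB < LS, so selection is deterministic.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ModelError("no converged fits to select from")
    best_aic = min(f.aic for f in converged)
    tied = [f for f in converged if abs(f.aic - best_aic) < 1e-9]
    return min(tied, key=lambda f: (f.k_params, MODEL_ORDER.index(f.model)))
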