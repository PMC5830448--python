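"""Per-site model fits: Gaussian, independent mixture, and the
pedigree-coupled ("Mendelian") mixture, all sharing fixed group weights.

Each site's M-values x₁…x_n are modelled three ways:

* ``GaussianModel`` — a single normal distribution (closed-form MLE);
* ``MixtureModel`` — a two-component normal mixture with *fixed* weights
  (α₀, α₁) = (0.99, 0.01), fitted by the standard EM algorithm;
* ``MendelianModel`` — the same two components, but group membership is the
  carrier status of a rare autosomal variant segregating in the pedigrees,
  so memberships are dependent within families.  Fitted by a generalised EM
  whose E-step sums over all carrier vectors of each family's typed members
  (weighted by the cached segregation prior) and whose M-step is the usual
  responsibility-weighted update.

The screening statistic Δl = l_Mendel − l_mix compares the maximised
log-likelihoods; because the two models have the same number of free
parameters (μ₀, μ₁, σ₀, σ₁), ranking by Δl coincides with ranking by AIC or
BIC differences.  Component 1 is always the rare (carrier) component; each
fitter tries both orientations (carriers = upper mode, carriers = lower
mode) and keeps the higher-likelihood fit, breaking exact ties toward
"upper".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .pedigree import Pedigree
from .segregation import FamilyPriorTable, precompute_family_priors

__all__ = [
    "Theta",
    "DeltaL",
    "GaussianModel",
    "MixtureModel",
    "MendelianModel",
    "fit_gaussian",
    "fit_mixture_em",
    "fit_mendelian_em",
    "delta_l",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _logsumexp(a: np.ndarray) -> float:
    """log Σ exp(a) for a 1-D array; tolerates -inf entries.  Local and
    minimal because it sits in the E-step's innermost loop."""
    m = a.max()
    if m == -np.inf:
        return -np.inf
    return float(m + np.log(np.exp(a - m).sum()))


class Theta(NamedTuple):
    """Mixture parameters; α₀ + α₁ = 1 and α is never re-estimated."""

    alpha0: float
    alpha1: float
    mu0: float
    mu1: float
    sigma0: float
    sigma1: float

    def swapped(self) -> "Theta":
        """The opposite carrier orientation (components exchanged)."""
        return Theta(self.alpha0, self.alpha1, self.mu1, self.mu0, self.sigma1, self.sigma0)

    @property
    def orientation(self) -> str:
        return "upper" if self.mu1 >= self.mu0 else "lower"


@dataclass(frozen=True)
class DeltaL:
    """The per-site screening statistic and its two ingredients."""

    probe_id: str
    delta_l: float
    l_mendel: float
    l_mix: float


def _norm_logpdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI


def _as_site_vector(X) -> np.ndarray:
    x = np.asarray(X, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("M-values must be finite")
    return x


def _two_means_split(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D 2-means: the sorted-order split minimising total
    within-cluster sum of squares.  Returns (lower cluster, upper cluster)."""
    xs = np.sort(x)
    n = xs.size
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    best_j, best_ss = 1, np.inf
    for j in range(1, n):
        sl, ql = csum[j - 1], csq[j - 1]
        sr, qr = csum[-1] - sl, csq[-1] - ql
        ss = (ql - sl * sl / j) + (qr - sr * sr / (n - j))
        if ss < best_ss - 1e-15:
            best_ss, best_j = ss, j
    return xs[:best_j], xs[best_j:]


def _initial_thetas(x: np.ndarray, alpha1: float, floor: float) -> list[Theta]:
    """Both carrier orientations of the 2-means initialisation."""
    lo, hi = _two_means_split(x)
    m_lo, m_hi = float(lo.mean()), float(hi.mean())
    s_lo = max(float(lo.std()), floor)
    s_hi = max(float(hi.std()), floor)
    upper = Theta(1 - alpha1, alpha1, m_lo, m_hi, s_lo, s_hi)  # carriers = upper mode
    return [upper, upper.swapped()]


class GaussianModel(BaseEstimator):
    """Single-normal fit of one site's M-values (closed-form MLE).

    The Gaussian model is nested in both mixture models (set μ₀ = μ₁,
    σ₀ = σ₁); its log-likelihood is reported for reference but does not
    enter Δl.
    """

    def __init__(self, variance_floor: float = 1e-3):
        self.variance_floor = variance_floor

    def fit(self, X, y=None):
        x = _as_site_vector(X)
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        self.mean_ = float(x.mean())
        sd = float(x.std())  # MLE: divisor n
        if sd < self.variance_floor:
            warnings.warn("degenerate site (near-constant values); variance floored")
            sd = self.variance_floor
        self.sd_ = sd
        self.loglik_ = float(_norm_logpdf(x, self.mean_, self.sd_).sum())
        self.n_ = x.size
        return self


def _mixture_em(
    x: np.ndarray, theta: Theta, tol: float, max_iter: int, floor: float
) -> tuple[Theta, float, list[float], bool]:
    """Fixed-weight two-component EM from one starting point."""
    log_a0, log_a1 = np.log(theta.alpha0), np.log(theta.alpha1)
    path: list[float] = []
    converged = False
    for _ in range(max_iter):
        l0 = log_a0 + _norm_logpdf(x, theta.mu0, theta.sigma0)
        l1 = log_a1 + _norm_logpdf(x, theta.mu1, theta.sigma1)
        tot = np.logaddexp(l0, l1)
        loglik = float(tot.sum())
        path.append(loglik)
        if len(path) > 1 and abs(path[-1] - path[-2]) < tol * (1.0 + abs(path[-1])):
            converged = True
            break
        r1 = np.exp(l1 - tot)
        r0 = 1.0 - r1
        theta = Theta(
            theta.alpha0,
            theta.alpha1,
            *_weighted_update(x, r0, r1, theta, floor),
        )
    return theta, path[-1], path, converged


def _weighted_update(
    x: np.ndarray, q0: np.ndarray, q1: np.ndarray, prev: Theta, floor: float
) -> tuple[float, float, float, float]:
    """Responsibility-weighted means/sds (the shared M-step).  A component
    whose total responsibility vanishes keeps its previous parameters."""
    out = []
    for q, mu_prev, s_prev in ((q0, prev.mu0, prev.sigma0), (q1, prev.mu1, prev.sigma1)):
        tot = q.sum()
        if tot <= 1e-300:
            warnings.warn("component responsibility collapsed; keeping previous parameters")
            out.append((mu_prev, max(s_prev, floor)))
            continue
        w = q / tot
        mu = float(w @ x)
        sd = float(np.sqrt(w @ (x - mu) ** 2))
        out.append((mu, max(sd, floor)))
    (mu0, s0), (mu1, s1) = out
    return mu0, mu1, s0, s1


class MixtureModel(BaseEstimator):
    """Two-component normal mixture with fixed weights (α₁ rare), standard EM.

    Parameters
    ----------
    alpha1 : rare-component weight (default 0.01, matching a rare dominant
        variant's expected carrier frequency).
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap; non-convergence returns the best-so-far fit
        with ``converged_ = False``.
    variance_floor : lower bound on component standard deviations, in
        M-value units, preventing singular likelihoods.
    """

    def __init__(
        self,
        alpha1: float = 0.01,
        tol: float = 1e-8,
        max_iter: int = 500,
        variance_floor: float = 1e-3,
    ):
        self.alpha1 = alpha1
        self.tol = tol
        self.max_iter = max_iter
        self.variance_floor = variance_floor

    def fit(self, X, y=None):
        x = _as_site_vector(X)
        if x.size < 4:
            raise ValueError("mixture fit requires at least 4 observations")
        candidates = []
        for theta0 in _initial_thetas(x, self.alpha1, self.variance_floor):
            candidates.append(
                _mixture_em(x, theta0, self.tol, self.max_iter, self.variance_floor)
            )
        theta, loglik, path, converged = _pick_orientation(candidates)
        self.theta_ = theta
        self.loglik_ = loglik
        self.loglik_path_ = path
        self.n_iter_ = len(path)
        self.converged_ = converged
        self.orientation_ = theta.orientation
        self.n_ = x.size
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-observation responsibilities, columns (non-carrier, carrier)."""
        x = _as_site_vector(X)
        t = self.theta_
        l0 = np.log(t.alpha0) + _norm_logpdf(x, t.mu0, t.sigma0)
        l1 = np.log(t.alpha1) + _norm_logpdf(x, t.mu1, t.sigma1)
        tot = np.logaddexp(l0, l1)
        r1 = np.exp(l1 - tot)
        return np.column_stack([1.0 - r1, r1])


def _pick_orientation(candidates):
    """Highest log-likelihood wins; exact ties go to carrier = upper mode."""
    def key(c):
        theta, loglik = c[0], c[1]
        return (loglik, 1 if theta.orientation == "upper" else 0)

    return max(candidates, key=key)


_BITS_CACHE: dict[int, np.ndarray] = {}


def _bits_matrix(k: int) -> np.ndarray:
    """(2^k, k) matrix of carrier-vector bits; cached, shared, read-only."""
    if k not in _BITS_CACHE:
        vecs = np.arange(1 << k)[:, None]
        bits = ((vecs >> np.arange(k)) & 1).astype(float)
        bits.setflags(write=False)
        _BITS_CACHE[k] = bits
    return _BITS_CACHE[k]


class _FamilyBlock:
    """Per-family precomputed pieces for the generalised E-step."""

    def __init__(self, table: FamilyPriorTable, idx: np.ndarray):
        k = len(table.typed_members)
        self.k = k
        self.idx = idx  # positions of this family's typed members in x
        self.log_prior = table.log_probs
        self.bits = _bits_matrix(k)


def _mendelian_estep(
    blocks: Sequence[_FamilyBlock], x: np.ndarray, theta: Theta
) -> tuple[float, np.ndarray]:
    """One E-step: total log-likelihood and per-individual carrier
    probabilities q_{i1} at the supplied parameters."""
    lp0 = _norm_logpdf(x, theta.mu0, theta.sigma0)
    lp1 = _norm_logpdf(x, theta.mu1, theta.sigma1)
    q1 = np.empty_like(x)
    loglik = 0.0
    for blk in blocks:
        d = lp1[blk.idx] - lp0[blk.idx]
        base = lp0[blk.idx].sum()
        logjoint = blk.log_prior + base + blk.bits @ d
        lse = _logsumexp(logjoint)
        loglik += lse
        post = np.exp(logjoint - lse)
        q1[blk.idx] = post @ blk.bits
    return float(loglik), q1


def _mendelian_em(
    blocks: Sequence[_FamilyBlock],
    x: np.ndarray,
    theta: Theta,
    tol: float,
    max_iter: int,
    floor: float,
) -> tuple[Theta, float, list[float], bool, np.ndarray]:
    path: list[float] = []
    converged = False
    q1 = np.full_like(x, np.nan)
    for _ in range(max_iter):
        loglik, q1 = _mendelian_estep(blocks, x, theta)
        path.append(loglik)
        if len(path) > 1 and abs(path[-1] - path[-2]) < tol * (1.0 + abs(path[-1])):
            converged = True
            break
        theta = Theta(
            theta.alpha0,
            theta.alpha1,
            *_weighted_update(x, 1.0 - q1, q1, theta, floor),
        )
    return theta, path[-1], path, converged, q1


class MendelianModel(BaseEstimator):
    """Pedigree-coupled two-component mixture fitted by generalised EM.

    Group membership is the carrier status of a rare autosomal variant:
    within a family the memberships are dependent, with joint prior given
    by the segregation model (at most one carrier founder, Mendelian
    transmission).  The E-step computes, for every family, the exact
    posterior over all 2^k carrier vectors of its k typed members —

        P(y^f | x^f, θ) ∝ [∏_i φ(x_i | μ_{y_i}, σ_{y_i})] · P(y^f)

    — and the per-person carrier probabilities q_{i1} by marginalisation;
    the M-step is the standard weighted Gaussian update with the weights
    (α₀, α₁) held fixed.  The observed log-likelihood never decreases.

    ``pedigrees`` must have their typed members attached; ``X`` passed to
    :meth:`fit` is the site's M-value vector aligned to the concatenation
    of ``ped.typed_members`` across pedigrees (or a mapping / pandas Series
    indexed by individual id).

    By default the fit is seeded with the fixed-weight mixture MLE (both
    carrier orientations), which makes the two models coincide exactly on
    cohorts of singleton families.
    """

    def __init__(
        self,
        pedigrees: Sequence[Pedigree] | None = None,
        prior_tables: dict[str, FamilyPriorTable] | None = None,
        alpha1: float = 0.01,
        tol: float = 1e-8,
        max_iter: int = 500,
        variance_floor: float = 1e-3,
        theta_init: Theta | None = None,
    ):
        self.pedigrees = pedigrees
        self.prior_tables = prior_tables
        self.alpha1 = alpha1
        self.tol = tol
        self.max_iter = max_iter
        self.variance_floor = variance_floor
        self.theta_init = theta_init

    def _setup(self) -> tuple[list[_FamilyBlock], list[str]]:
        if not self.pedigrees:
            raise ValueError("pedigrees are required")
        tables = self.prior_tables
        if tables is None:
            tables = precompute_family_priors(self.pedigrees, self.alpha1)
        order: list[str] = []
        blocks: list[_FamilyBlock] = []
        for ped in self.pedigrees:
            if not ped.typed_members:
                continue
            if ped.family_id not in tables:
                raise ValueError(f"no prior table for family {ped.family_id!r}")
            table = tables[ped.family_id]
            if table.typed_members != ped.typed_members:
                raise ValueError(
                    f"prior table for family {ped.family_id!r} does not match "
                    "its typed members"
                )
            idx = np.arange(len(order), len(order) + len(ped.typed_members))
            order.extend(ped.typed_members)
            blocks.append(_FamilyBlock(table, idx))
        if not order:
            raise ValueError("no typed members in any pedigree; nothing to fit")
        return blocks, order

    def _align(self, X, order: list[str]) -> np.ndarray:
        if hasattr(X, "reindex"):  # pandas Series
            vals = X.reindex(order)
            if vals.isna().any():
                missing = [o for o, v in zip(order, vals) if np.isnan(v)]
                raise ValueError(f"missing M-values for typed members: {missing[:5]}")
            return vals.to_numpy(dtype=float)
        if isinstance(X, dict):
            try:
                return np.array([X[o] for o in order], dtype=float)
            except KeyError as exc:
                raise ValueError(f"missing M-value for typed member {exc}") from exc
        x = _as_site_vector(X)
        if x.size != len(order):
            raise ValueError(
                f"expected {len(order)} M-values (one per typed member), got {x.size}"
            )
        return x

    def fit(self, X, y=None):
        blocks, order = self._setup()
        x = self._align(X, order)
        if x.size < 4:
            raise ValueError("Mendelian fit requires at least 4 typed observations")
        if self.theta_init is not None:
            seeds = [self.theta_init]
        else:
            seeds = []
            for theta0 in _initial_thetas(x, self.alpha1, self.variance_floor):
                theta_m, *_ = _mixture_em(
                    x, theta0, self.tol, self.max_iter, self.variance_floor
                )
                seeds.append(theta_m)
        candidates = [
            _mendelian_em(blocks, x, s, self.tol, self.max_iter, self.variance_floor)
            for s in seeds
        ]
        theta, loglik, path, converged, q1 = _pick_orientation(candidates)
        # final E-step so the stored posteriors match the returned theta
        loglik, q1 = _mendelian_estep(blocks, x, theta)
        self.theta_ = theta
        self.loglik_ = loglik
        self.loglik_path_ = path
        self.n_iter_ = len(path)
        self.converged_ = converged
        self.orientation_ = theta.orientation
        self.typed_order_ = tuple(order)
        self.carrier_prob_ = q1
        self.n_ = x.size
        return self

    def predict_proba(self, X=None) -> np.ndarray:
        """Posterior carrier probabilities for the typed members, columns
        (non-carrier, carrier).  ``X`` defaults to the fitted site."""
        if X is None:
            q1 = self.carrier_prob_
        else:
            blocks, order = self._setup()
            x = self._align(X, order)
            _, q1 = _mendelian_estep(blocks, x, self.theta_)
        return np.column_stack([1.0 - q1, q1])


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_gaussian(x, variance_floor: float = 1e-3) -> GaussianModel:
    return GaussianModel(variance_floor=variance_floor).fit(x)


def fit_mixture_em(x, **options) -> MixtureModel:
    return MixtureModel(**options).fit(x)


def fit_mendelian_em(x, pedigrees, prior_tables=None, **options) -> MendelianModel:
    return MendelianModel(
        pedigrees=pedigrees, prior_tables=prior_tables, **options
    ).fit(x)


def delta_l(
    x,
    pedigrees,
    prior_tables=None,
    probe_id: str = "",
    **options,
) -> DeltaL:
    """Δl = l_Mendel − l_mix for one site, from orientation-maximised fits."""
    mix = MixtureModel(**options).fit(x)
    mendel = MendelianModel(
        pedigrees=pedigrees, prior_tables=prior_tables, **options
    ).fit(x)
    return DeltaL(
        probe_id=probe_id,
        delta_l=mendel.loglik_ - mix.loglik_,
        l_mendel=mendel.loglik_,
        l_mix=mix.loglik_,
    )
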