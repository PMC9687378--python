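"""Pooled Gaussian mixture modelling and Bayes-posterior normalization.

The analysis substrate is the pooled distribution of log-transformed
expression values of all genes and samples of a dataset.  A Gaussian
mixture model (GMM)

    GMM(x) = sum_i w_i * N(x | m_i, s_i)

is fitted to that pooled distribution by expectation--maximization, the
number of components M is chosen by the Akaike information criterion,
and each expression value is then replaced by the Bayes posterior
probability that it belongs to the high-expression ("expressed")
component.  Posteriors live on [0, 1]: 0 means definitive
underexpression, 1 definitive overexpression.  The decision border is
the log-expression value at which that posterior equals 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = [
    "GaussianComponent",
    "GaussianMixtureModel",
    "DecisionBorder",
    "GofResult",
    "FitError",
    "log_transform",
    "back_transform",
    "gmm_density",
    "fit_gmm",
    "posterior",
    "posterior_high",
    "decision_border",
    "normalize_to_posteriors",
    "chi_square_gof",
]

_LOG_2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    """EM failed to produce a non-degenerate mixture."""


@dataclass(frozen=True)
class GaussianComponent:
    """One weighted Gaussian: weight ``w``, mean ``m``, standard deviation ``s``."""

    w: float
    m: float
    s: float

    def __post_init__(self) -> None:
        if not (0.0 < self.w <= 1.0):
            raise ValueError(f"component weight must be in (0, 1], got {self.w}")
        if not self.s > 0.0:
            raise ValueError(f"component sd must be positive, got {self.s}")


@dataclass(frozen=True)
class GaussianMixtureModel:
    """A fitted mixture with components ordered by ascending mean.

    ``log_base`` and ``pseudocount`` record the transform under which
    the model lives, so that decision borders can be mapped back to the
    raw expression scale.
    """

    components: tuple[GaussianComponent, ...]
    log_base: float = 10.0
    pseudocount: float = 0.0
    loglik: float = float("nan")
    aic: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("model needs at least one component")
        means = [c.m for c in self.components]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("components must be sorted by ascending mean")
        total = sum(c.w for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total!r}")

    @property
    def M(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.w for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.m for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.s for c in self.components])

    @property
    def split_index(self) -> int:
        """Index of the first component on the "expressed" side.

        For M = 2 this is component 1.  For M > 2 the expressed /
        unexpressed split is placed at the largest gap between adjacent
        component means.
        """
        if self.M < 2:
            raise ValueError("split undefined for a single-component model")
        gaps = np.diff(self.means)
        return int(np.argmax(gaps)) + 1

    # -- densities -----------------------------------------------------
    def component_logpdf(self, x) -> np.ndarray:
        """log(w_i * N(x|m_i, s_i)) with shape (..., M)."""
        x = np.asarray(x, dtype=float)[..., np.newaxis]
        w, m, s = self.weights, self.means, self.sds
        return np.log(w) - np.log(s) - 0.5 * _LOG_2PI - 0.5 * ((x - m) / s) ** 2

    def logpdf(self, x) -> np.ndarray:
        return logsumexp(self.component_logpdf(x), axis=-1)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., np.newaxis]
        return np.sum(self.weights * stats.norm.cdf((x - self.means) / self.sds), axis=-1)

    def quantile(self, q: float) -> float:
        """Inverse mixture CDF by bracketed root-finding."""
        if not 0.0 < q < 1.0:
            raise ValueError("quantile level must be in (0, 1)")
        lo = float(np.min(self.means - 12.0 * self.sds))
        hi = float(np.max(self.means + 12.0 * self.sds))
        return float(optimize.brentq(lambda v: self.cdf(v) - q, lo, hi, xtol=1e-12))

    def responsibilities(self, x) -> np.ndarray:
        """Posterior p(c_i | x) over components, shape (..., M); rows sum to 1."""
        lp = self.component_logpdf(x)
        return np.exp(lp - logsumexp(lp, axis=-1, keepdims=True))


@dataclass(frozen=True)
class DecisionBorder:
    """Log-scale location where the expressed-component posterior is 0.5."""

    x_log: float
    x_raw: float


@dataclass(frozen=True)
class GofResult:
    """Binned chi-square goodness of fit of a mixture to pooled data."""

    chi2_stat: float
    dof: int
    p_value: float
    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log_transform(values, log_base: float = 10.0, pseudocount: float = 0.0):
    """Elementwise log of (value + pseudocount); monotone in the input."""
    values = np.asarray(values, dtype=float)
    if np.any(values + pseudocount <= 0):
        raise ValueError("log_transform requires value + pseudocount > 0")
    out = np.log(values + pseudocount) / math.log(log_base)
    return float(out) if out.ndim == 0 else out


def back_transform(x_log, log_base: float = 10.0, pseudocount: float = 0.0):
    """Inverse of :func:`log_transform`: base**x minus the pseudocount."""
    x_log = np.asarray(x_log, dtype=float)
    out = np.power(log_base, x_log) - pseudocount
    return float(out) if out.ndim == 0 else out


def gmm_density(model: GaussianMixtureModel, x):
    """Mixture density GMM(x) = sum_i w_i N(x|m_i, s_i)."""
    return model.pdf(x)


# ---------------------------------------------------------------------------
# EM fitting with AIC model selection
# ---------------------------------------------------------------------------

def _quantile_split_init(x_sorted: np.ndarray, M: int, rng: np.random.Generator | None):
    """Moments of M contiguous quantile blocks, optionally jittered."""
    blocks = np.array_split(x_sorted, M)
    w = np.array([b.size for b in blocks], dtype=float)
    w /= w.sum()
    m = np.array([b.mean() for b in blocks])
    s = np.array([max(b.std(), 1e-3) for b in blocks])
    if rng is not None:
        m = m + rng.normal(scale=s)
        s = s * np.exp(rng.normal(scale=0.3, size=M))
    return w, m, s


def em_fit(
    x: np.ndarray,
    w: np.ndarray,
    m: np.ndarray,
    s: np.ndarray,
    s_floor: float,
    tol: float = 1e-8,
    max_iter: int = 500,
):
    """Run EM from a given start; return (w, m, s, loglik_trace).

    The per-iteration log-likelihood trace is non-decreasing (standard
    EM guarantee); callers may assert this.  Raises :class:`FitError`
    when a component collapses below ``s_floor`` or empties out.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    w, m, s = map(np.array, (w, m, s))
    xx = x[:, None]
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        # E step in density space: the data lie within a few sd of the
        # components during fitting, so no underflow protection is needed
        # beyond a tiny floor on the mixture density.
        z = (xx - m) / s
        dens = (w / (s * math.sqrt(2.0 * math.pi))) * np.exp(-0.5 * z * z)
        total = dens.sum(axis=1)
        np.maximum(total, 1e-300, out=total)
        loglik = float(np.log(total).sum())
        trace.append(loglik)
        if loglik - prev < tol:
            break
        prev = loglik
        r = dens / total[:, None]
        nk = r.sum(axis=0)
        if np.any(nk < 1e-10):
            raise FitError("component emptied out during EM")
        w = nk / n
        m = (r * xx).sum(axis=0) / nk
        var = (r * (xx - m) ** 2).sum(axis=0) / nk
        s = np.sqrt(var)
        if np.any(s < s_floor):
            raise FitError("component sd collapsed below the floor")
    return w, m, s, np.array(trace)


def _fit_single_m(x, M, seed, n_restarts, tol, max_iter, s_floor, burn_iter=25):
    """Best-of-restarts EM for one component count.

    Each restart is burned in for a few iterations; only the most
    promising start is then run to full convergence (the usual
    short-runs strategy, which leaves the selected optimum unchanged
    while avoiding full convergence of hopeless starts).
    """
    rng = np.random.default_rng(seed)
    x_sorted = np.sort(x)
    candidates = []
    for restart in range(n_restarts):
        init_rng = None if restart == 0 else rng
        w0, m0, s0 = _quantile_split_init(x_sorted, M, init_rng)
        try:
            w, m, s, trace = em_fit(x, w0, m0, s0, s_floor, tol=tol, max_iter=burn_iter)
        except FitError:
            continue
        candidates.append((trace[-1], w, m, s))
    candidates.sort(key=lambda c: -c[0])
    for _, w0, m0, s0 in candidates:
        try:
            w, m, s, trace = em_fit(x, w0, m0, s0, s_floor, tol=tol, max_iter=max_iter)
        except FitError:
            continue
        return w, m, s, trace
    return None


def fit_gmm(
    pooled,
    m_candidates=(1, 2, 3, 4, 5),
    seed: int | None = None,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 300,
    log_base: float = 10.0,
    pseudocount: float = 0.0,
) -> GaussianMixtureModel:
    """Fit mixtures for each candidate M and return the AIC-best model.

    AIC = 2k - 2 loglik with k = 3M - 1 free parameters (the weights
    lose one degree of freedom to the sum-to-one constraint).  Each M is
    fitted by EM from a quantile-split start plus randomly perturbed
    restarts; the best restart by log-likelihood wins.
    """
    x = np.asarray(pooled, dtype=float).ravel()
    m_candidates = [int(M) for M in m_candidates]
    if x.size < 50:
        raise ValueError("need at least 50 pooled points to fit a mixture")
    if not all(1 <= M <= 6 for M in m_candidates):
        raise ValueError("candidate component counts must lie in 1..6")
    s_floor = 1e-4 * float(np.ptp(x)) if np.ptp(x) > 0 else 1e-8
    ss = np.random.SeedSequence(seed)
    best_model = None
    for M, child in zip(m_candidates, ss.spawn(len(m_candidates))):
        fit = _fit_single_m(
            x, M, child, n_restarts if M > 1 else 1, tol, max_iter, s_floor
        )
        if fit is None:
            continue
        w, m, s, trace = fit
        order = np.argsort(m)
        comps = tuple(
            GaussianComponent(float(w[i]), float(m[i]), float(s[i])) for i in order
        )
        k = 3 * M - 1
        loglik = float(trace[-1])
        model = GaussianMixtureModel(
            components=comps,
            log_base=log_base,
            pseudocount=pseudocount,
            loglik=loglik,
            aic=2.0 * k - 2.0 * loglik,
            n_points=x.size,
        )
        if best_model is None or model.aic < best_model.aic:
            best_model = model
    if best_model is None:
        raise FitError("all EM restarts degenerated for every candidate M")
    return best_model


# ---------------------------------------------------------------------------
# posteriors and decision borders
# ---------------------------------------------------------------------------

def posterior(model: GaussianMixtureModel, x, component_index: int):
    """Bayes posterior p(c_i | x) = w_i N(x|m_i,s_i) / GMM(x), log-space safe."""
    if not 0 <= component_index < model.M:
        raise IndexError("component index out of range")
    r = model.responsibilities(x)[..., component_index]
    return float(r) if r.ndim == 0 else r


def posterior_high(model: GaussianMixtureModel, x):
    """Posterior mass of the expressed (high-mean) side of the mixture."""
    r = model.responsibilities(x)[..., model.split_index :].sum(axis=-1)
    return float(r) if r.ndim == 0 else r


def decision_border(model: GaussianMixtureModel) -> DecisionBorder:
    """Locate the log-expression value where the expressed posterior is 0.5.

    The root is bracketed between the component means adjacent to the
    split and refined to |dx| < 1e-10, so the posterior at the border
    equals 0.5 to well within 1e-8.
    """
    lo = float(model.means[model.split_index - 1])
    hi = float(model.means[model.split_index])
    f = lambda v: posterior_high(model, v) - 0.5
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        root = lo
    elif fhi == 0.0:
        root = hi
    elif flo * fhi > 0:
        raise ValueError(
            "no posterior-0.5 crossing between the adjacent component means "
            f"({lo:.4g}, {hi:.4g}); posterior values {flo + 0.5:.4g}, {fhi + 0.5:.4g}"
        )
    else:
        root = float(optimize.brentq(f, lo, hi, xtol=1e-10))
    return DecisionBorder(
        x_log=root,
        x_raw=float(back_transform(root, model.log_base, model.pseudocount)),
    )


def normalize_to_posteriors(model: GaussianMixtureModel, log_values):
    """Map log expression elementwise to the expressed-component posterior.

    Returns an array of the same shape with entries in [0, 1]; 0 means
    definitive underexpression, 1 definitive overexpression.
    """
    arr = np.asarray(log_values, dtype=float)
    return posterior_high(model, arr)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def chi_square_gof(
    model: GaussianMixtureModel,
    pooled,
    min_expected: float = 5.0,
    n_bins: int = 50,
) -> GofResult:
    """Binned chi-square test of the fitted mixture against the pooled data.

    Bins are equal-probability under the model (edges at model
    quantiles) and adjacent bins are merged until every expected count
    reaches ``min_expected``.  Degrees of freedom are reduced by the
    3M - 1 fitted parameters.
    """
    x = np.asarray(pooled, dtype=float).ravel()
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 points for the goodness-of-fit test")
    inner = np.array([model.quantile(i / n_bins) for i in range(1, n_bins)])
    edges = np.concatenate(([-np.inf], inner, [np.inf]))
    observed = np.histogram(x, bins=np.concatenate(([-1e300], inner, [1e300])))[0].astype(float)
    expected = np.full(n_bins, n / n_bins, dtype=float)

    # merge adjacent bins until each expected count is large enough
    obs_list, exp_list, edge_list = list(observed), list(expected), list(edges)
    i = 0
    while i < len(exp_list):
        if exp_list[i] < min_expected and len(exp_list) > 1:
            j = i + 1 if i + 1 < len(exp_list) else i - 1
            lo_idx, hi_idx = min(i, j), max(i, j)
            exp_list[lo_idx] += exp_list[hi_idx]
            obs_list[lo_idx] += obs_list[hi_idx]
            del exp_list[hi_idx], obs_list[hi_idx], edge_list[hi_idx]
            i = 0
        else:
            i += 1
    observed = np.array(obs_list)
    expected = np.array(exp_list)
    if observed.size < 3:
        raise ValueError("fewer than 3 usable bins for the chi-square test")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    dof = observed.size - 1 - (3 * model.M - 1)
    if dof < 1:
        warnings.warn("chi-square dof fell below 1 after parameter correction; using 1")
        dof = 1
    p = float(stats.chi2.sf(chi2, dof))
    return GofResult(
        chi2_stat=chi2,
        dof=dof,
        p_value=p,
        bin_edges=np.array(edge_list),
        observed=observed,
        expected=expected,
    )
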