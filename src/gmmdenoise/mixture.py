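"""Univariate Gaussian mixtures on log10 ASV abundances, fitted by EM.

The statistical idea: on the log10 read-count scale, true biological variants
and PCR artefacts form (at least) two overlapping abundance modes.  A
k-component Gaussian mixture is fitted by expectation-maximisation; with
components ordered by ascending mean, the uppermost component represents true
variants and the lower component(s) represent artefacts.  The upper one-sided
confidence limit (default 95%) of the *second-uppermost* component — the
upper tail of the error-abundance distribution — is a statistically grounded
abundance filtering threshold: ASVs whose log10 total falls below it are
inferred to be artefacts.

:class:`GMMDenoiser` is a scikit-learn style estimator wrapping the fit; the
module-level functions (:func:`em_fit`, :func:`component_cl`,
:func:`filtering_threshold`, ...) are the underlying primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateDataError, NoErrorComponentError
from .io import ASVTable

__all__ = [
    "GMMFit",
    "ComponentCL",
    "GMMDenoiser",
    "log_abundance",
    "em_fit",
    "responsibilities",
    "mixture_logpdf",
    "mixture_loglik",
    "sample_mixture",
    "component_cl",
    "filtering_threshold",
]

# Default lower bound on component SDs, in log10 units. Read counts are
# discrete: many ASVs share the exact value log10(1) = 0, and an
# unconstrained (or nearly so) component can collapse onto such an atom,
# hijacking the likelihood and producing a meaningless threshold.  A floor
# of about a third of the spacing between the 1-read and 2-read atoms
# (log10 2 ~ 0.30) rules those spikes out without constraining genuine
# abundance modes, whose spread is far larger.
DEFAULT_SD_FLOOR = 0.1


@dataclass(frozen=True)
class GMMFit:
    """Parameters and diagnostics of a fitted k-component univariate mixture.

    Components are stored in canonical order (means ascending).  Means, SDs
    and the confidence limits derived from them are on the log10 read-count
    scale.
    """

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    data_n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if not (len(self.means) == len(self.sds) == len(self.weights) == self.k):
            raise ValueError("component vectors must all have length k")
        if abs(self.weights.sum() - 1.0) > 1e-10 or (self.weights <= 0).any():
            raise ValueError("weights must be positive and sum to one")
        if (np.diff(self.means) < 0).any():
            raise ValueError("components must be sorted by mean")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood is not finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("means", "sds", "weights"):
            d[key] = [float(v) for v in d[key]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GMMFit":
        return cls(**d)


@dataclass(frozen=True)
class ComponentCL:
    """Per-component upper one-sided confidence limits at a given level."""

    level: float
    cls: np.ndarray


def log_abundance(table: ASVTable) -> np.ndarray:
    """log10 of per-ASV totals; every retained ASV must have at least one read."""
    totals = table.total
    if (totals < 1).any():
        bad = table.asv_ids[int(np.argmax(totals < 1))]
        raise ValueError(f"ASV {bad!r} has total < 1; drop unobserved rows first")
    return np.log10(totals.astype(float))


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _log_weighted_components(x: np.ndarray, means, sds, weights) -> np.ndarray:
    """(n, k) matrix of log(w_j * phi((x - mu_j)/sigma_j)/sigma_j)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    z = (x[:, None] - means) / sds
    return -0.5 * z * z - np.log(sds) - _LOG_SQRT_2PI + np.log(np.asarray(weights))


def mixture_logpdf(x: np.ndarray, means, sds, weights) -> np.ndarray:
    """Pointwise log density of the mixture."""
    x = np.asarray(x, dtype=float).ravel()
    return logsumexp(_log_weighted_components(x, means, sds, weights), axis=1)


def mixture_loglik(fit: GMMFit, x: np.ndarray) -> float:
    """Total observed-data log-likelihood of ``x`` under a fitted mixture."""
    return float(mixture_logpdf(x, fit.means, fit.sds, fit.weights).sum())


def sample_mixture(fit: GMMFit, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` observations from a fitted mixture (used by the bootstrap)."""
    comp = rng.choice(fit.k, size=n, p=fit.weights)
    return rng.normal(fit.means[comp], fit.sds[comp])


def _quantile_init(x_sorted: np.ndarray, k: int, sd_floor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    blocks = np.array_split(x_sorted, k)
    means = np.array([b.mean() for b in blocks])
    sds = np.array([max(b.std(), sd_floor) for b in blocks])
    weights = np.full(k, 1.0 / k)
    return means, sds, weights


def _em_run(x, means, sds, weights, tol, max_iter, sd_floor, history=None):
    """One EM run from a given start; returns (means, sds, weights, ll, it, conv).

    ``history``, if a list, collects the observed-data log-likelihood at every
    iteration (it must be non-decreasing — the EM guarantee).
    """
    n = x.size
    k = means.size
    ll_prev = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step, in log space for numerical safety
        logc = _log_weighted_components(x, means, sds, weights)
        lognorm = logsumexp(logc, axis=1)
        ll = float(lognorm.sum())
        if history is not None:
            history.append(ll)
        resp = np.exp(logc - lognorm[:, None])
        # M step: weighted maximum-likelihood updates
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            raise DegenerateDataError("a mixture component lost all responsibility")
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), sd_floor)
        weights = nk / n
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_prev = ll
    # final log-likelihood under the last parameter update
    ll = float(mixture_logpdf(x, means, sds, weights).sum())
    return means, sds, weights, ll, it, converged


def em_fit(
    x: np.ndarray,
    k: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int | np.random.Generator | None = None,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> GMMFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    A deterministic quantile-slicing initialisation (sorted data split into k
    contiguous blocks) is always tried; ``restarts`` additional runs start
    from randomly chosen observations as means.  The best final
    log-likelihood wins, and components are returned sorted by mean.

    Raises
    ------
    ValueError
        Fewer than ``5 * k`` observations.
    DegenerateDataError
        All observations identical with ``k >= 2``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size < 5 * k:
        raise ValueError(f"need at least {5 * k} observations for k={k}, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("abundances must be finite")
    if k >= 2 and np.ptp(x) == 0:
        raise DegenerateDataError("all observations are equal; no mixture is identifiable")

    if k == 1:
        # closed-form Gaussian MLE; EM's fixed point
        mu = float(x.mean())
        sd = max(float(x.std()), sd_floor)
        ll = float(mixture_logpdf(x, [mu], [sd], [1.0]).sum())
        return GMMFit(1, np.array([mu]), np.array([sd]), np.array([1.0]),
                      ll, 1, True, x.size)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_sorted = np.sort(x)
    starts = [_quantile_init(x_sorted, k, sd_floor)]
    sd_all = max(float(x.std()), sd_floor)
    for _ in range(restarts):
        means0 = np.sort(rng.choice(x, size=k, replace=False))
        starts.append((means0, np.full(k, sd_all), np.full(k, 1.0 / k)))

    best = None
    for means0, sds0, w0 in starts:
        try:
            res = _em_run(x, means0.copy(), sds0.copy(), w0.copy(), tol, max_iter, sd_floor)
        except DegenerateDataError:
            continue
        if best is None or res[3] > best[3]:
            best = res
    if best is None:
        raise DegenerateDataError(f"EM failed for every initialisation at k={k}")
    means, sds, weights, ll, it, conv = best
    order = np.argsort(means, kind="stable")
    return GMMFit(k, means[order], sds[order], weights[order] / weights.sum(),
                  ll, it, conv, x.size)


def responsibilities(fit: GMMFit, x: np.ndarray) -> np.ndarray:
    """Posterior component membership probabilities (the E step), rows sum to 1."""
    x = np.asarray(x, dtype=float).ravel()
    logc = _log_weighted_components(x, fit.means, fit.sds, fit.weights)
    return np.exp(logc - logsumexp(logc, axis=1)[:, None])


def component_cl(fit: GMMFit, level: float = 0.95) -> ComponentCL:
    """Upper one-sided confidence limits mu_j + z(level) * sigma_j per component."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(level)
    return ComponentCL(level=level, cls=fit.means + z * fit.sds)


def filtering_threshold(fit: GMMFit, level: float = 0.95) -> float:
    """Abundance threshold: the CL of the second-uppermost component.

    With components sorted by ascending mean this is ``cls[k - 2]`` — the
    upper tail of the highest error component, regardless of k.
    """
    if fit.k < 2:
        raise NoErrorComponentError(
            "k=1 fit has no error component; no filtering threshold is defined"
        )
    return float(component_cl(fit, level).cls[fit.k - 2])


class GMMDenoiser(BaseEstimator):
    """Gaussian-mixture abundance model with a filtering threshold.

    Fit on a vector of log10 ASV abundances (shape ``(n,)`` or ``(n, 1)``).
    After fitting, ``threshold_`` holds the upper one-sided ``level``
    confidence limit of the second-uppermost component; ASVs whose log10
    abundance is below it are inferred to be PCR/sequencing artefacts.

    Parameters
    ----------
    n_components : int
        Number of mixture components k.
    level : float
        One-sided confidence level for the component CLs.
    tol, max_iter, restarts, random_state
        EM controls; see :func:`em_fit`.

    Attributes
    ----------
    means_, sds_, weights_ : ndarray of shape (k,)
        Component parameters on the log10 scale, means ascending.
    loglik_ : float
        Final observed-data log-likelihood.
    threshold_ : float or None
        Filtering threshold (None when ``n_components == 1``).
    fit_ : GMMFit
        The full fit object.
    """

    def __init__(self, n_components: int = 2, level: float = 0.95,
                 tol: float = 1e-8, max_iter: int = 1000, restarts: int = 5,
                 sd_floor: float = DEFAULT_SD_FLOOR,
                 random_state: int | None = None):
        self.n_components = n_components
        self.level = level
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts
        self.sd_floor = sd_floor
        self.random_state = random_state

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected a 1-d vector of log10 abundances")
        return X

    def fit(self, X, y=None) -> "GMMDenoiser":
        x = self._validate(X)
        fit = em_fit(x, self.n_components, tol=self.tol, max_iter=self.max_iter,
                     restarts=self.restarts, seed=self.random_state,
                     sd_floor=self.sd_floor)
        self.fit_ = fit
        self.means_ = fit.means
        self.sds_ = fit.sds
        self.weights_ = fit.weights
        self.loglik_ = fit.loglik
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.confidence_limits_ = component_cl(fit, self.level).cls
        self.threshold_ = (filtering_threshold(fit, self.level)
                           if fit.k >= 2 else None)
        return self

    def predict(self, X) -> np.ndarray:
        """Most probable mixture component per observation."""
        check_is_fitted(self, "fit_")
        return np.argmax(responsibilities(self.fit_, self._validate(X)), axis=1)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "fit_")
        return responsibilities(self.fit_, self._validate(X))

    def score_samples(self, X) -> np.ndarray:
        check_is_fitted(self, "fit_")
        return mixture_logpdf(self._validate(X), self.means_, self.sds_, self.weights_)

    def score(self, X, y=None) -> float:
        """Mean per-observation log-likelihood."""
        return float(self.score_samples(X).mean())

    def retain_mask(self, X) -> np.ndarray:
        """True where an observation is at or above the filtering threshold."""
        check_is_fitted(self, "fit_")
        if self.threshold_ is None:
            raise NoErrorComponentError("no threshold for a single-component fit")
        return self._validate(X) >= self.threshold_
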