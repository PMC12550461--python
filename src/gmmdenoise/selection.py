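"""Choosing the number of mixture components k.

Two approaches are provided, mirroring standard practice for mixtures fitted
to read-count distributions:

* **two-fold cross-validation** — for each candidate k, the data are split
  randomly in half, the mixture is fitted on each half and its held-out
  log-likelihood evaluated on the other half; the two directions (and any
  repeats) are averaged.  The chosen k maximises the mean held-out
  log-likelihood, with a parsimony rule: the smallest k within one
  log-likelihood unit of the maximum wins.

* **sequential parametric bootstrap testing** — for k = 1, 2, ... the
  likelihood-ratio statistic T = 2(loglik_{k+1} - loglik_k) is compared with
  its null distribution obtained by simulating datasets from the fitted
  k-component model and refitting both models.  The add-one p-value
  (1 + #{T_b >= T}) / (B + 1) never returns zero; the procedure stops at the
  first k whose test is non-significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DegenerateDataError
from .mixture import GMMDenoiser, em_fit, mixture_loglik, sample_mixture

logger = logging.getLogger(__name__)

__all__ = ["KSelection", "cv_loglik", "bootstrap_seq_test", "GMMDenoiserCV"]


@dataclass
class KSelection:
    """Result of a k-selection procedure.

    ``cv_loglik`` maps k to the mean held-out log-likelihood (CV method);
    ``bs_pvalues`` maps k to the p-value of the test H0: k vs H1: k+1
    (bootstrap method).  ``method`` is "cv", "bootstrap" or "visual-override"
    when the user forced a k after inspecting the abundance histogram.
    """

    k_grid: list[int]
    chosen_k: int
    method: str
    cv_loglik: dict[int, float] = field(default_factory=dict)
    bs_pvalues: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chosen_k not in self.k_grid:
            raise ValueError("chosen_k must lie in k_grid")
        if any(not 0.0 <= p <= 1.0 for p in self.bs_pvalues.values()):
            raise ValueError("p-values must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "k_grid": list(self.k_grid),
            "chosen_k": int(self.chosen_k),
            "method": self.method,
            "cv_loglik": {int(k): float(v) for k, v in self.cv_loglik.items()},
            "bs_pvalues": {int(k): float(v) for k, v in self.bs_pvalues.items()},
        }


def _held_out_loglik(train: np.ndarray, test: np.ndarray, k: int,
                     rng: np.random.Generator, **em_kw) -> float:
    fit = em_fit(train, k, seed=rng, **em_kw)
    return mixture_loglik(fit, test)


def cv_loglik(
    x: np.ndarray,
    k_grid,
    seed: int | None = None,
    n_repeats: int = 1,
    **em_kw,
) -> KSelection:
    """Two-fold cross-validated log-likelihood over a grid of k values.

    For each repeat the data are permuted and split in half; each half is
    fitted and scored on the other, and all half-scores are averaged per k.
    A fold on which EM fails is dropped with a warning; a k for which every
    fold failed is removed from the grid.
    """
    x = np.asarray(x, dtype=float).ravel()
    k_grid = sorted(int(k) for k in k_grid)
    if x.size < 10 * max(k_grid):
        raise ValueError(f"need at least {10 * max(k_grid)} observations "
                         f"for k up to {max(k_grid)}")
    rng = np.random.default_rng(seed)
    scores: dict[int, list[float]] = {k: [] for k in k_grid}
    for _ in range(n_repeats):
        perm = rng.permutation(x.size)
        half = x.size // 2
        folds = (x[perm[:half]], x[perm[half:]])
        for k in k_grid:
            for a, b in ((0, 1), (1, 0)):
                try:
                    scores[k].append(
                        _held_out_loglik(folds[a], folds[b], k, rng, **em_kw))
                except (DegenerateDataError, ValueError) as exc:
                    warnings.warn(f"EM failed on a CV fold for k={k}: {exc}")
    mean_ll = {k: float(np.mean(v)) for k, v in scores.items() if v}
    if not mean_ll:
        raise DegenerateDataError("cross-validation failed for every k")
    best = max(mean_ll.values())
    chosen = min(k for k, v in mean_ll.items() if v >= best - 1.0)
    return KSelection(k_grid=sorted(mean_ll), chosen_k=chosen, method="cv",
                      cv_loglik=mean_ll)


def bootstrap_seq_test(
    x: np.ndarray,
    k_max: int,
    B: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    max_redraws: int = 10,
    **em_kw,
) -> KSelection:
    """Sequential parametric bootstrap likelihood-ratio tests of k vs k+1.

    Starting at k=1, the observed statistic T = 2(loglik_{k+1} - loglik_k) is
    referred to B parametric-bootstrap replicates simulated from the fitted
    k-component model.  Testing stops at the first non-significant p-value
    (chosen_k = that k); if every test up to k_max - 1 is significant,
    chosen_k = k_max.  A bootstrap replicate on which either refit fails to
    converge is redrawn (up to ``max_redraws`` times, then scored as
    T_b = +inf, which is conservative).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 10 * k_max:
        raise ValueError(f"need at least {10 * k_max} observations for k_max={k_max}")
    if B < 19:
        raise ValueError("B must be at least 19")
    rng = np.random.default_rng(seed)
    # The observed statistic and its bootstrap null must come from fits with
    # an IDENTICAL search budget: a deeper search on the observed data alone
    # would bias T upward relative to T_b and inflate the test.  The shared
    # budget defaults to one random restart and a 1e-6 tolerance (overridable
    # through em_kw), which the LRT decisions are insensitive to.
    em_kw = dict(em_kw)
    em_kw.setdefault("restarts", 1)
    em_kw.setdefault("tol", 1e-6)
    pvalues: dict[int, float] = {}
    chosen = k_max
    for k in range(1, k_max):
        fit_k = em_fit(x, k, seed=rng, **em_kw)
        fit_k1 = em_fit(x, k + 1, seed=rng, **em_kw)
        T = 2.0 * (fit_k1.loglik - fit_k.loglik)
        n_ge = 0
        for _ in range(B):
            t_b = np.inf
            for _attempt in range(max_redraws):
                xb = sample_mixture(fit_k, x.size, rng)
                try:
                    fb_k = em_fit(xb, k, seed=rng, **em_kw)
                    fb_k1 = em_fit(xb, k + 1, seed=rng, **em_kw)
                except (DegenerateDataError, ValueError):
                    continue
                if fb_k.converged and fb_k1.converged:
                    t_b = 2.0 * (fb_k1.loglik - fb_k.loglik)
                    break
            n_ge += t_b >= T
        p = (1.0 + n_ge) / (B + 1.0)
        pvalues[k] = p
        if p > alpha:
            chosen = k
            break
    return KSelection(k_grid=list(range(1, k_max + 1)), chosen_k=chosen,
                      method="bootstrap", bs_pvalues=pvalues)


class GMMDenoiserCV(BaseEstimator):
    """GMMDenoiser with the number of components chosen from the data.

    Runs the requested k-selection procedure over ``k_grid`` and then fits a
    final :class:`~gmmdenoise.mixture.GMMDenoiser` with the chosen k.

    Attributes
    ----------
    selection_ : KSelection
    chosen_k_ : int
    estimator_ : GMMDenoiser
        The final fitted model; ``threshold_``, ``means_`` etc. are mirrored
        on this object.
    """

    def __init__(self, k_grid=(1, 2, 3, 4, 5), method: str = "cv",
                 level: float = 0.95, B: int = 100, alpha: float = 0.05,
                 n_repeats: int = 1, restarts: int = 5,
                 random_state: int | None = None):
        self.k_grid = k_grid
        self.method = method
        self.level = level
        self.B = B
        self.alpha = alpha
        self.n_repeats = n_repeats
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X, y=None) -> "GMMDenoiserCV":
        x = GMMDenoiser._validate(X)
        if self.method == "cv":
            sel = cv_loglik(x, self.k_grid, seed=self.random_state,
                            n_repeats=self.n_repeats, restarts=self.restarts)
        elif self.method == "bootstrap":
            sel = bootstrap_seq_test(x, max(self.k_grid), B=self.B,
                                     alpha=self.alpha, seed=self.random_state,
                                     restarts=self.restarts)
        else:
            raise ValueError(f"unknown selection method {self.method!r}")
        est = GMMDenoiser(n_components=sel.chosen_k, level=self.level,
                          restarts=self.restarts,
                          random_state=self.random_state).fit(x)
        self.selection_ = sel
        self.chosen_k_ = sel.chosen_k
        self.estimator_ = est
        self.fit_ = est.fit_
        self.means_ = est.means_
        self.sds_ = est.sds_
        self.weights_ = est.weights_
        self.loglik_ = est.loglik_
        self.threshold_ = est.threshold_
        return self

    def predict(self, X):
        return self.estimator_.predict(X)

    def retain_mask(self, X):
        return self.estimator_.retain_mask(X)
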