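"""Expressed-gene gating by a two-component Gaussian mixture on log2 counts.

Per-sample histograms of log2(count + 1) are bimodal: a low "non-expressed"
mode and a high "expressed" mode.  A two-component unequal-variance mixture
is fitted by EM per sample; a gene is called expressed in a condition when
its posterior probability of the non-expressed component is below alpha
(default 1%) in every sample of that condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .types import SampleSheet


class DegenerateFitError(ValueError):
    """The data cannot support a two-component fit (e.g. all values equal)."""


class DesignError(ValueError):
    pass


@dataclass
class MixtureFit:
    mean_off: float
    mean_on: float
    sd_off: float
    sd_on: float
    weight_on: float
    responsibilities: np.ndarray  # P(off component | x), per input value
    converged: bool
    n_iter: int
    loglik_path: np.ndarray


class TwoComponentGaussianMixture(BaseEstimator):
    """EM fit of a 1-D two-component Gaussian mixture with unequal variances.

    Deterministic initialisation at the 25th/75th percentiles with equal
    weights; components are relabelled after fitting so mean_on > mean_off.

    Parameters
    ----------
    tol : relative log-likelihood change for convergence.
    max_iter : EM iteration cap.
    min_sd : lower bound on component standard deviations (collapse guard).
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 500, min_sd: float = 1e-3):
        self.tol = tol
        self.max_iter = max_iter
        self.min_sd = min_sd

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < 20:
            raise DegenerateFitError(f"need >= 20 finite values, got {x.size}")
        if np.ptp(x) == 0:
            raise DegenerateFitError("all values identical; no mixture structure")
        mu = np.percentile(x, [25, 75]).astype(float)
        if mu[0] == mu[1]:
            mu = np.array([x.min(), x.max()], dtype=float)
        sd = np.full(2, max(x.std(), self.min_sd))
        w = np.array([0.5, 0.5])
        loglik_path = []
        prev = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # E step
            logp = np.stack(
                [np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)]
            )
            tot = np.logaddexp(logp[0], logp[1])
            loglik = float(tot.sum())
            loglik_path.append(loglik)
            resp = np.exp(logp - tot)  # 2 x n
            # M step
            nk = resp.sum(axis=1)
            if np.any(nk < 1e-10):
                raise DegenerateFitError("a component collapsed to zero weight")
            w = nk / x.size
            mu = (resp @ x) / nk
            var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
            sd = np.sqrt(np.maximum(var, self.min_sd**2))
            if np.isfinite(prev) and abs(loglik - prev) <= self.tol * (abs(prev) + 1e-12):
                converged = True
                break
            prev = loglik
        order = np.argsort(mu)  # off first, on second
        mu, sd, w = mu[order], sd[order], w[order]
        logp = np.stack([np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)])
        resp_off = np.exp(logp[0] - np.logaddexp(logp[0], logp[1]))
        self.means_ = mu
        self.sds_ = sd
        self.weights_ = w
        self.responsibilities_ = resp_off
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.loglik_path_ = np.asarray(loglik_path)
        return self

    def predict_proba_off(self, X) -> np.ndarray:
        """Posterior probability of the non-expressed component per value."""
        x = np.asarray(X, dtype=float).ravel()
        mu, sd, w = self.means_, self.sds_, self.weights_
        logp = np.stack([np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)])
        return np.exp(logp[0] - np.logaddexp(logp[0], logp[1]))

    def to_fit(self) -> MixtureFit:
        return MixtureFit(
            mean_off=float(self.means_[0]),
            mean_on=float(self.means_[1]),
            sd_off=float(self.sds_[0]),
            sd_on=float(self.sds_[1]),
            weight_on=float(self.weights_[1]),
            responsibilities=self.responsibilities_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            loglik_path=self.loglik_path_,
        )


def fit_two_component_mixture(values, seed: int = 0) -> MixtureFit:
    """Functional wrapper over :class:`TwoComponentGaussianMixture`.

    Initialisation is deterministic (quantile-based); the seed is accepted
    for interface stability and reserved for optional random restarts.
    """
    est = TwoComponentGaussianMixture().fit(np.asarray(values, dtype=float))
    return est.to_fit()


def log2_counts(counts) -> np.ndarray:
    """log2(count + 1): a pseudocount of one before the log transform."""
    return np.log2(np.asarray(counts, dtype=float) + 1.0)


def call_expressed(matrix: pd.DataFrame, samples, alpha: float = 0.01):
    """Per-condition expressed gene sets from per-sample mixture fits.

    ``matrix``: genes x samples log2 expression.  ``samples`` is either a
    :class:`SampleSheet` or a pd.Series mapping sample id -> condition
    label.  A gene is expressed in a condition iff its off-component
    posterior is < alpha in EVERY sample of that condition.  Returns
    (dict condition -> set, union set, per-sample fits).
    """
    key = samples.condition_key() if isinstance(samples, SampleSheet) else pd.Series(samples)
    sample_ids = list(key.index)
    missing = [s for s in sample_ids if s not in matrix.columns]
    if missing:
        raise DesignError(f"matrix lacks samples: {missing}")
    fits = {}
    off_prob = pd.DataFrame(index=matrix.index, dtype=float)
    for sid in sample_ids:
        est = TwoComponentGaussianMixture().fit(matrix[sid].to_numpy())
        fits[sid] = est.to_fit()
        off_prob[sid] = est.predict_proba_off(matrix[sid].to_numpy())
    by_condition = {}
    for cond in sorted(key.unique()):
        cols = key.index[key == cond].tolist()
        if not cols:
            raise DesignError(f"condition {cond} has no samples")
        ok = (off_prob[cols] < alpha).all(axis=1)
        by_condition[cond] = set(matrix.index[ok])
    union = set().union(*by_condition.values()) if by_condition else set()
    return by_condition, union, fits
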