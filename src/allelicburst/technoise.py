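"""Estimate technical-noise parameters {alpha, beta, kappa, tau} from spike-ins.

Spike-ins are present in a fixed, known amount in every cell and do not burst,
so any spread between their known molecule counts and the observed counts is
technical.  Estimation is two-stage, shared across all cells of a batch:

1. ``alpha`` (capture/sequencing efficiency) and ``beta`` (amplification
   bias) by Poisson log-linear regression of the *non-zero* observations on
   log true molecules: log E[Q] = log(alpha) + beta * log(Y).
2. ``kappa``, ``tau`` (dropout logistic) by maximising the zero-decomposing
   mixture likelihood with multi-start Nelder-Mead: a zero count is either a
   dropout or a Poisson zero,

   L = prod_{c,g} [ Pois(Q; alpha*Y^beta) * expit(kappa + tau log Y)
                    + (1 - expit(kappa + tau log Y)) * 1{Q = 0} ].
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, log_expit
from sklearn.base import BaseEstimator

from .containers import NoiseParams

__all__ = ["TechnicalNoiseModel", "fit_alpha_beta", "fit_kappa_tau"]

KAPPA_BOUNDS = (-20.0, 20.0)
TAU_BOUNDS = (-10.0, 10.0)
_NM_STARTS = [(k, t) for k in (-2.0, 0.0, 2.0) for t in (0.0, 0.5, 1.5)]


def _pooled(true_molecules, observed_molecules):
    y = np.asarray(true_molecules, dtype=float)
    q = np.asarray(observed_molecules, dtype=float)
    if q.ndim == 1:
        q = q[:, None]
    if y.shape[0] != q.shape[0]:
        raise ValueError("one true molecule level per spike-in row is required")
    keep = y > 0
    return y[keep], q[keep]


def fit_alpha_beta(true_molecules, observed_molecules):
    """Fit (alpha, beta) by Poisson regression on the non-zero observations.

    Returns ``(alpha, beta, se_log_alpha, se_beta)``.  Requires at least two
    distinct true levels, otherwise the design is collinear.
    """
    import statsmodels.api as sm

    y, q = _pooled(true_molecules, observed_molecules)
    if np.unique(y).size < 2:
        raise ValueError(
            "alpha/beta are not identifiable from fewer than 2 distinct "
            "spike-in levels"
        )
    logy = np.repeat(np.log(y), q.shape[1])
    qq = q.ravel()
    nz = qq > 0
    if not np.any(nz):
        raise ValueError("all spike-in observations are zero; nothing to regress")
    if np.unique(logy[nz]).size < 2:
        raise ValueError("non-zero observations cover fewer than 2 spike-in levels")
    X = sm.add_constant(logy[nz])
    with warnings.catch_warnings():
        # molecule-scale responses are continuous; Poisson quasi-likelihood
        warnings.simplefilter("ignore")
        res = sm.GLM(qq[nz], X, family=sm.families.Poisson()).fit()
    log_alpha, beta = res.params
    se = res.bse
    return float(np.exp(log_alpha)), float(beta), float(se[0]), float(se[1])


def _make_dropout_negloglik(logy, logpois, zero):
    def negloglik(params):
        kappa, tau = params
        if not (KAPPA_BOUNDS[0] <= kappa <= KAPPA_BOUNDS[1]) or not (
            TAU_BOUNDS[0] <= tau <= TAU_BOUNDS[1]
        ):
            return np.inf
        x = kappa + tau * logy
        ll_detected = logpois + log_expit(x)
        # zeros: dropout OR detected-but-sampled-zero
        ll = np.where(zero, np.logaddexp(log_expit(-x), ll_detected), ll_detected)
        return -np.sum(ll)

    return negloglik


def fit_kappa_tau(true_molecules, observed_molecules, alpha, beta):
    """Fit the dropout logistic (kappa, tau) by multi-start Nelder-Mead.

    The likelihood decomposes each zero count into a dropout event or a
    Poisson sampling zero at mean alpha*Y^beta.  If no observation is zero
    the dropout probability is indistinguishable from 0 and kappa is
    reported at the upper box bound + 10 with a warning.
    """
    y, q = _pooled(true_molecules, observed_molecules)
    logy = np.repeat(np.log(y), q.shape[1])
    lam = alpha * np.exp(beta * np.log(np.repeat(y, q.shape[1])))
    qq = q.ravel()
    if not np.any(qq == 0):
        warnings.warn(
            "no zero spike-in observations: dropout indistinguishable from "
            "none; kappa fixed at the no-dropout boundary",
            UserWarning,
        )
        return KAPPA_BOUNDS[1] + 10.0, 0.0
    logpois = stats.poisson.logpmf(np.round(qq), lam)
    negloglik = _make_dropout_negloglik(logy, logpois, qq == 0)

    best = None
    for start in _NM_STARTS:
        res = optimize.minimize(
            negloglik,
            np.asarray(start, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    kappa, tau = best.x
    return float(np.clip(kappa, *KAPPA_BOUNDS)), float(np.clip(tau, *TAU_BOUNDS))


class TechnicalNoiseModel(BaseEstimator):
    """Batch-level scRNA-seq technical-noise model fitted from spike-ins.

    Parameters
    ----------
    fit_dropout : bool, default True
        Whether to fit the dropout logistic after the alpha/beta regression.

    Attributes
    ----------
    alpha_, beta_, kappa_, tau_ : float
        Fitted noise parameters.
    alpha_se_log_, beta_se_ : float
        Standard errors from the Poisson regression (alpha on the log scale).
    """

    def __init__(self, fit_dropout: bool = True):
        self.fit_dropout = fit_dropout

    def fit(self, true_molecules, observed_molecules):
        """Fit from spike-in truth (per spike-in) and observed molecule matrix."""
        alpha, beta, se_la, se_b = fit_alpha_beta(true_molecules, observed_molecules)
        self.alpha_, self.beta_ = alpha, beta
        self.alpha_se_log_, self.beta_se_ = se_la, se_b
        if self.fit_dropout:
            self.kappa_, self.tau_ = fit_kappa_tau(
                true_molecules, observed_molecules, alpha, beta
            )
        else:
            self.kappa_, self.tau_ = NoiseParams.identity().kappa, 0.0
        return self

    def to_noise_params(self) -> NoiseParams:
        return NoiseParams(self.alpha_, self.beta_, self.kappa_, self.tau_)

    def predict_detection_probability(self, y) -> np.ndarray:
        """Fitted P(detected | true expression y)."""
        return expit(self.kappa_ + self.tau_ * np.log(np.asarray(y, dtype=float)))
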