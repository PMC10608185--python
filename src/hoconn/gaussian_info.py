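"""Gaussian entropy and mutual information through linear regression.

For jointly Gaussian blocks ``X`` (t1 channels) and ``Y`` (t2 channels)
related by the zero-lag regression ``X = A Y + U``, the mutual information
is ``I(X;Y) = 1/2 ln(|Sigma_X| / |Sigma_U|)`` in nats, where ``Sigma_X`` is
the covariance of the predicted block and ``Sigma_U`` the covariance of the
regression residuals. All covariances use the unbiased (M-1) denominator;
determinants are evaluated in log space from a symmetric eigendecomposition
and a condition number above 1e12 raises a singularity error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import (
    HoconnError,
    InfiniteInformationError,
    InsufficientSamplesError,
    Multiplet,
    SingularityError,
    TimeSeriesSet,
    ValidationError,
    as_multiplet,
)

__all__ = [
    "GaussianFit",
    "MIEstimate",
    "sample_covariance",
    "gaussian_entropy",
    "fit_linear_regression",
    "mutual_information",
    "LN_2PI_E",
]

LN_2PI_E = float(np.log(2.0 * np.pi * np.e))

#: covariance condition number beyond which matrices are treated as singular
COND_LIMIT = 1e12

#: negative MI values above this magnitude indicate an internal inconsistency
_NEG_CLIP = 1e-10


def _logdet_pd(cov: np.ndarray, what: str = "covariance",
               error: type[SingularityError] = SingularityError) -> float:
    """Log-determinant of a symmetric positive-definite matrix.

    Raises ``error`` when the matrix is indefinite or its condition number
    exceeds :data:`COND_LIMIT`.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape[0] != cov.shape[1]:
        raise ValidationError(f"{what} must be square, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValidationError(f"{what} must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w[0] <= 0.0 or w[0] < w[-1] / COND_LIMIT:
        raise error(f"{what} is singular or ill-conditioned "
                    f"(eigenvalue range [{w[0]:.3e}, {w[-1]:.3e}])")
    return float(np.sum(np.log(w)))


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class GaussianFit:
    """Result of an ordinary-least-squares block regression ``X = A Y + U``."""

    coeffs: np.ndarray     # (t1, t2)
    resid_cov: np.ndarray  # Sigma_U, (t1, t1)
    pred_cov: np.ndarray   # Sigma_X, (t1, t1)
    predicted: Multiplet | None = None
    predictors: Multiplet | None = None


@dataclass
class MIEstimate:
    """A mutual information value in nats with optional significance metadata."""

    value: float
    x: Multiplet
    y: Multiplet
    significant: bool | None = None
    threshold: float | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_covariance(ts: TimeSeriesSet, subset: Multiplet | None = None) -> np.ndarray:
    """Unbiased sample covariance of the selected channels (all by default)."""
    idx = list(range(ts.n_channels)) if subset is None else list(as_multiplet(subset))
    n = len(idx)
    if ts.n_samples <= n:
        raise InsufficientSamplesError(
            f"need more samples than variables: M={ts.n_samples}, N={n}")
    block = ts.data[:, idx]
    centered = block - block.mean(axis=0)
    return centered.T @ centered / (ts.n_samples - 1)


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy ``1/2 ln((2 pi e)^t |cov|)`` in nats."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    t = cov.shape[0]
    return 0.5 * (t * LN_2PI_E + _logdet_pd(cov))


def _partition(cov: np.ndarray, t1: int):
    sxx = cov[:t1, :t1]
    syy = cov[t1:, t1:]
    sxy = cov[:t1, t1:]
    return sxx, syy, sxy


def fit_linear_regression(ts: TimeSeriesSet, predicted, predictors) -> GaussianFit:
    """OLS fit of the predicted block on the predictor block (zero lag).

    Data are mean-removed; ``coeffs`` solves the normal equations and
    ``resid_cov`` is the covariance of ``X - A Y``.
    """
    x = as_multiplet(predicted)
    y = as_multiplet(predictors)
    if set(x.indices) & set(y.indices):
        raise ValidationError("predicted and predictor blocks must be disjoint")
    t1, t2 = x.order, y.order
    if ts.n_samples <= t1 + t2:
        raise InsufficientSamplesError(
            f"need M > t1 + t2 = {t1 + t2}, got M={ts.n_samples}")
    xd = ts.data[:, list(x)] - ts.data[:, list(x)].mean(axis=0)
    yd = ts.data[:, list(y)] - ts.data[:, list(y)].mean(axis=0)
    m = ts.n_samples
    syy = yd.T @ yd / (m - 1)
    try:
        _logdet_pd(syy, what="predictor covariance")
    except SingularityError:
        raise SingularityError(
            "rank-deficient predictor covariance for channels "
            f"{y.labelled(ts.labels)}") from None
    sxy = xd.T @ yd / (m - 1)
    coeffs = np.linalg.solve(syy, sxy.T).T
    resid = xd - yd @ coeffs.T
    resid_cov = resid.T @ resid / (m - 1)
    pred_cov = xd.T @ xd / (m - 1)
    return GaussianFit(coeffs=coeffs, resid_cov=resid_cov, pred_cov=pred_cov,
                       predicted=x, predictors=y)


def mutual_information(ts: TimeSeriesSet, x, y) -> MIEstimate:
    """Mutual information between two disjoint channel blocks, in nats.

    ``value = 1/2 ln(|Sigma_X| / |Sigma_U|) >= 0``; tiny negative rounding
    (magnitude <= 1e-10) is clipped to zero and recorded in ``meta``.
    A singular residual covariance (deterministic linear dependence between
    the blocks) raises :class:`InfiniteInformationError`.
    """
    xm = as_multiplet(x)
    ym = as_multiplet(y)
    if set(xm.indices) & set(ym.indices):
        raise ValidationError("the two blocks must be disjoint")
    joint = Multiplet(xm.indices + ym.indices)
    cov = sample_covariance(ts, joint)
    # the joint multiplet is sorted; re-order to [x block, y block]
    order = [joint.indices.index(i) for i in xm.indices] + \
            [joint.indices.index(i) for i in ym.indices]
    cov = cov[np.ix_(order, order)]
    sxx, syy, sxy = _partition(cov, xm.order)
    _logdet_pd(syy, what="predictor covariance")
    resid_cov = sxx - sxy @ np.linalg.solve(syy, sxy.T)
    ld_x = _logdet_pd(sxx, what="predicted covariance")
    ld_u = _logdet_pd(resid_cov, what="residual covariance",
                      error=InfiniteInformationError)
    value = 0.5 * (ld_x - ld_u)
    meta: dict = {}
    if value < 0.0:
        if value < -_NEG_CLIP:
            raise HoconnError(
                f"mutual information came out {value:.3e} < -1e-10; "
                "internal inconsistency")
        meta["clipped_from"] = value
        value = 0.0
    return MIEstimate(value=value, x=xm, y=ym, meta=meta)


def mi_from_covariance(cov: np.ndarray, t1: int) -> float:
    """MI in nats between the first ``t1`` and remaining variables of ``cov``.

    Population-level counterpart of :func:`mutual_information`, used as a
    closed-form oracle on known covariances.
    """
    cov = np.asarray(cov, dtype=float)
    sxx, syy, sxy = _partition(cov, t1)
    resid = sxx - sxy @ np.linalg.solve(syy, sxy.T)
    return 0.5 * (_logdet_pd(sxx) - _logdet_pd(resid, error=InfiniteInformationError))
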