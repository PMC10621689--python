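"""Parameter-recovery measures.

Reliability is the squared Pearson correlation between estimated and true
trait scores; RMSE is the root mean squared deviation on the z-scale;
intertrait-correlation bias is the signed difference between estimated and
true trait intercorrelations; and the person-mean correlation — the
correlation between each person's mean estimated and mean true trait —
diagnoses (partial) ipsativity: under fully ipsative scores the estimated
person means have zero variance and the correlation is undefined.

``UNDEFINED`` quantities are represented as ``None`` and stored as NaN with
an explicit ``defined`` flag; they are never silently mapped to zero outside
display layers.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "reliability",
    "rmse",
    "intercorrelation_bias",
    "person_mean_correlation",
    "approx_ci",
    "score_interval_halfwidth",
    "population_coverage",
]


def reliability(theta_hat: np.ndarray, theta: np.ndarray) -> Optional[float]:
    """Squared Pearson correlation of estimated with true scores.

    Returns ``None`` (UNDEFINED) if either column has zero variance.
    """
    theta_hat = np.asarray(theta_hat, float)
    theta = np.asarray(theta, float)
    if theta_hat.shape != theta.shape or theta.size < 3:
        raise ValueError("columns must have equal length >= 3")
    if theta_hat.std() == 0 or theta.std() == 0:
        return None
    r = np.corrcoef(theta_hat, theta)[0, 1]
    return float(r**2)


def rmse(theta_hat: np.ndarray, theta: np.ndarray) -> float:
    """Root mean squared deviation (absolute fit on the scale of the inputs)."""
    theta_hat = np.asarray(theta_hat, float)
    theta = np.asarray(theta, float)
    if theta_hat.shape != theta.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((theta_hat - theta) ** 2)))


def intercorrelation_bias(
    estimated: np.ndarray, true: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Signed bias of estimated trait intercorrelations.

    Parameters are square matrices of equal dimension (score correlations or
    an EAP of Phi versus the generating Phi).  Returns the per-pair biases
    over the unique off-diagonal pairs and their signed mean.
    """
    estimated = np.asarray(estimated, float)
    true = np.asarray(true, float)
    if estimated.shape != true.shape or estimated.ndim != 2:
        raise ValueError("matrices must have identical square shape")
    iu = np.triu_indices(estimated.shape[0], k=1)
    per_pair = estimated[iu] - true[iu]
    return per_pair, float(per_pair.mean())


def person_mean_correlation(
    theta_hat: np.ndarray, theta: np.ndarray
) -> Optional[float]:
    """Correlation between estimated and true person means over traits.

    ``None`` (UNDEFINED) when either side's person means have zero variance
    — in particular for fully ipsative scores, where every person's total is
    identical by construction.
    """
    theta_hat = np.asarray(theta_hat, float)
    theta = np.asarray(theta, float)
    if theta_hat.shape != theta.shape:
        raise ValueError("shape mismatch")
    mh = theta_hat.mean(axis=1)
    mt = theta.mean(axis=1)
    if np.isclose(mh.std(), 0) or np.isclose(mt.std(), 0):
        return None
    return float(np.corrcoef(mh, mt)[0, 1])


def approx_ci(values: Sequence[float]) -> Tuple[float, Optional[float]]:
    """Mean and 1.96 * SD / sqrt(k) half-width over k replication results.

    The half-width is ``None`` (UNDEFINED) for k < 2.  NaNs are not skipped:
    callers decide how to treat undefined replication values.
    """
    vals = np.asarray(list(values), float)
    k = vals.size
    mean = float(vals.mean()) if k else math.nan
    if k < 2:
        return mean, None
    return mean, float(1.96 * vals.std(ddof=1) / math.sqrt(k))


def score_interval_halfwidth(rmse_value: float, level_z: float = 1.96) -> float:
    """Half-width of the normal-theory score interval implied by an RMSE.

    With estimation errors treated as N(0, RMSE^2), an individual's
    two-sided interval at the given z level is ``+- level_z * RMSE`` on the
    z-scale.
    """
    return float(level_z * rmse_value)


def population_coverage(rmse_value: float, level_z: float = 1.96) -> float:
    """Share of a standard-normal population inside the implied interval.

    The interval ``+- level_z * RMSE`` covers
    ``2 * Phi(level_z * RMSE) - 1`` of a standard-normal trait distribution;
    returned as a percentage.
    """
    from scipy.stats import norm

    return float((2.0 * norm.cdf(level_z * rmse_value) - 1.0) * 100.0)
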