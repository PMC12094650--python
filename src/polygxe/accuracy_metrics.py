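"""Discrimination and liability-scale variance-explained metrics.

Under the liability threshold model, disease occurs when a latent standard
normal liability exceeds ``t = Phi^{-1}(1 - K)``, K the population
lifetime risk.  A predictor explaining a fraction ``rho2`` of liability
variance implies a population AUC of

    AUC(rho2) = Phi( rho2 (i - v) / sqrt( rho2 (1 - rho2 i (i - t))
                                        + rho2 (1 - rho2 v (v - t)) ) )

with ``i = phi(t) / K`` the mean liability of cases and
``v = -i K / (1 - K)`` that of controls (truncated-normal means).  The
inverse map, evaluated by bisection, converts an observed AUC back to
liability-scale R^2.  A second route converts Nagelkerke's pseudo-R^2 via
the threshold-model correction with ascertainment adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "LiabilityParams",
    "auc",
    "liability_auc",
    "auc_to_liability_r2",
    "nagelkerke_to_liability_r2",
]


@dataclass
class LiabilityParams:
    """Population lifetime risk K and sample case proportion P.

    Derived truncated-normal quantities (threshold, case and control mean
    liabilities) are recomputed on access so they can never go stale.
    """

    K: float = 0.01
    P: float = 0.5

    def __post_init__(self):
        if not (0 < self.K < 1):
            raise ValueError("K must lie in (0, 1)")
        if not (0 < self.P < 1):
            raise ValueError("P must lie in (0, 1)")

    @property
    def threshold(self) -> float:
        return float(norm.ppf(1.0 - self.K))

    @property
    def case_mean(self) -> float:
        """Mean liability of cases, i = phi(t) / K."""
        return float(norm.pdf(self.threshold) / self.K)

    @property
    def control_mean(self) -> float:
        """Mean liability of controls, v = -i K / (1 - K)."""
        return -self.case_mean * self.K / (1.0 - self.K)


def auc(scores, labels) -> float:
    """Mann–Whitney AUC with midrank tie handling.

    ``labels`` is binary with 1 = case; returns the probability that a
    random case outscores a random control (ties count half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case = labels == 1
    n1 = int(case.sum())
    n0 = scores.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = ranks[case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def liability_auc(rho2: float, params: LiabilityParams) -> float:
    """Forward map: liability variance explained -> expected AUC."""
    if not (0 <= rho2 < 1):
        raise ValueError("rho2 must lie in [0, 1)")
    if rho2 == 0:
        return 0.5
    t = params.threshold
    i = params.case_mean
    v = params.control_mean
    num = rho2 * (i - v)
    den = np.sqrt(rho2 * (1 - rho2 * i * (i - t)) + rho2 * (1 - rho2 * v * (v - t)))
    return float(norm.cdf(num / den))


def auc_to_liability_r2(
    auc_value: float, params: LiabilityParams, tol: float = 1e-8
) -> float:
    """Invert the truncated-normal AUC map by bisection on rho2 in [0, 1)."""
    if auc_value < 0.5:
        raise ValueError(
            "AUC below 0.5: flip the score direction before converting"
        )
    if auc_value >= 1.0:
        raise ValueError("AUC must be < 1")
    if auc_value == 0.5:
        return 0.0
    lo, hi = 0.0, 1.0 - 1e-12
    if liability_auc(hi, params) < auc_value:
        raise ValueError("AUC not attainable under the liability model")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if liability_auc(mid, params) < auc_value:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def nagelkerke_to_liability_r2(r2_nagelkerke: float, params: LiabilityParams) -> float:
    """Observed-scale pseudo-R^2 -> liability R^2 with ascertainment.

    Threshold-model conversion: with t = Phi^{-1}(1-K), z = phi(t),
    m = z / K the mean case liability, C = K^2 (1-K)^2 / (z^2 P (1-P)) and
    theta = m (P-K)/(1-K) * ( m (P-K)/(1-K) - t ),
    the liability-scale value is C * R2 / (1 + C * theta * R2).  With
    P = K (no ascertainment) this reduces to R2 * K(1-K) / z^2.  Using the
    Nagelkerke R^2 as the observed-scale input is an approximation kept as
    a cross-check of the AUC route.
    """
    if not (0 <= r2_nagelkerke < 1):
        raise ValueError("input R^2 must lie in [0, 1)")
    K, P = params.K, params.P
    t = params.threshold
    z = float(norm.pdf(t))
    m = z / K
    C = K**2 * (1 - K) ** 2 / (z**2 * P * (1 - P))
    d = m * (P - K) / (1 - K)
    theta = d * (d - t)
    return float(C * r2_nagelkerke / (1 + C * theta * r2_nagelkerke))
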