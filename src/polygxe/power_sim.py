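"""Monte-Carlo power and minimum-sample-size estimation for G×E tests.

Post hoc power is simulated from standardized coefficients: per replicate,
standardized genetic and environmental scores are drawn as independent
standard normals, case status follows the logistic model
``logit P(case) = b0 + b_G G + b_E E + b_GE G E`` (intercept calibrated to
the target case fraction), the interaction model is refit, and success is
either a Wald p-value below alpha on the product term (multiplicative
test) or a delta-method RERI interval excluding zero (additive test).
A liability-scale mechanism mirroring the cohort generator is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .association_models import (
    SeparationError,
    ConvergenceError,
    fit_logistic,
)
from .interaction_metrics import reri_delta

__all__ = ["PowerConfig", "PowerResult", "estimate_power", "min_n_for_power"]

_TERMS = ["const", "g", "e", "g:e"]


@dataclass
class PowerConfig:
    """Simulation settings for one power estimate."""

    b_g: float = 0.7
    b_e: float = 1.0
    b_ge: float = 0.3
    n: int = 1073
    case_fraction: float = 717 / 1073
    intercept: Optional[float] = None  # overrides case_fraction calibration
    n_reps: int = 500
    alpha: float = 0.05
    test: str = "multiplicative"
    mechanism: str = "logit"
    seed: int = 0

    def __post_init__(self):
        for name in ("b_g", "b_e", "b_ge"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100 for reported results")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.test not in ("multiplicative", "additive"):
            raise ValueError("test must be 'multiplicative' or 'additive'")
        if self.mechanism not in ("logit", "liability"):
            raise ValueError("mechanism must be 'logit' or 'liability'")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.mechanism == "liability":
            if self.b_g**2 + self.b_e**2 + self.b_ge**2 >= 1:
                raise ValueError("liability coefficient load leaves no residual")


@dataclass
class PowerResult:
    power: float
    mc_se: float
    n: int
    test: str
    n_reps: int
    n_failed: int
    alpha: float

    def __post_init__(self):
        if not (0 <= self.power <= 1):
            raise ValueError("power must lie in [0, 1]")


def _calibrate(config: PowerConfig, rng: np.random.Generator) -> float:
    """Intercept (logit) or threshold (liability) hitting case_fraction."""
    n_cal = 200_000
    g = rng.standard_normal(n_cal)
    e = rng.standard_normal(n_cal)
    eta = config.b_g * g + config.b_e * e + config.b_ge * g * e
    if config.mechanism == "liability":
        resid = np.sqrt(1 - config.b_g**2 - config.b_e**2
                        - config.b_ge**2 * float(np.var(g * e)))
        liab = eta + resid * rng.standard_normal(n_cal)
        return float(np.quantile(liab, 1 - config.case_fraction))
    lo, hi = -40.0, 15.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if float(expit(mid + eta).mean()) > config.case_fraction:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def estimate_power(config: PowerConfig) -> PowerResult:
    """Monte-Carlo power of the chosen interaction test.

    Replicates with a degenerate outcome or a failed refit are counted as
    failures (reported, never silently dropped); a failure rate above 10%
    raises with diagnostics.
    """
    rng = np.random.default_rng(config.seed)
    b0 = config.intercept if config.intercept is not None else _calibrate(config, rng)
    if config.mechanism == "liability":
        resid_sd = np.sqrt(1 - config.b_g**2 - config.b_e**2 - config.b_ge**2)

    successes, failed = 0, 0
    for _ in range(config.n_reps):
        g = rng.standard_normal(config.n)
        e = rng.standard_normal(config.n)
        eta = config.b_g * g + config.b_e * e + config.b_ge * g * e
        if config.mechanism == "logit":
            y = (rng.random(config.n) < expit(b0 + eta)).astype(float)
        else:
            liab = eta + resid_sd * rng.standard_normal(config.n)
            y = (liab > b0).astype(float)
        if y.min() == y.max():
            failed += 1
            continue
        X = np.column_stack([np.ones(config.n), g, e, g * e])
        try:
            fit = fit_logistic(X, y, _TERMS)
        except (SeparationError, ConvergenceError):
            failed += 1
            continue
        if config.test == "multiplicative":
            hit = fit.wald_p("g:e") < config.alpha
        else:
            res = reri_delta(fit, "g", "e", "g:e")
            hit = res.significant
        successes += int(hit)

    if failed > 0.10 * config.n_reps:
        raise RuntimeError(
            f"{failed}/{config.n_reps} power replicates failed to refit at "
            f"n={config.n}; effects {config.b_g}/{config.b_e}/{config.b_ge}"
        )
    n_ok = config.n_reps - failed
    p_hat = successes / n_ok if n_ok else 0.0
    mc_se = float(np.sqrt(p_hat * (1 - p_hat) / n_ok)) if n_ok else float("nan")
    return PowerResult(
        power=float(p_hat), mc_se=mc_se, n=config.n, test=config.test,
        n_reps=config.n_reps, n_failed=failed, alpha=config.alpha,
    )


def min_n_for_power(
    config: PowerConfig, target_power: float = 0.8, n_grid=None
):
    """Smallest grid sample size reaching the target power.

    Brackets the target by doubling through the sorted grid, then bisects
    on grid indices (power is monotone in n up to Monte-Carlo error).
    Returns ``(n_min, curve)`` where ``curve`` lists every evaluated
    (n, power, mc_se) point; raises if even the largest grid n falls short.
    """
    if not (0 < target_power < 1):
        raise ValueError("target_power must lie in (0, 1)")
    if n_grid is None:
        n_grid = [250, 500, 1000, 2000, 4000, 8000, 16000]
    n_grid = sorted(int(n) for n in n_grid)
    if n_grid[0] < 10:
        raise ValueError("grid sample sizes must be >= 10")

    from dataclasses import replace

    cache = {}

    def power_at(n):
        if n not in cache:
            cache[n] = estimate_power(replace(config, n=n, seed=config.seed + n))
        return cache[n].power

    # doubling bracket over grid indices
    hi = 0
    while power_at(n_grid[hi]) < target_power:
        if hi == len(n_grid) - 1:
            best = max(cache.values(), key=lambda r: r.power)
            raise ValueError(
                f"target power {target_power} unreachable on grid; max achieved "
                f"{best.power:.3f} at n={best.n}"
            )
        hi = min(2 * hi + 1, len(n_grid) - 1)
    lo = -1  # n_grid[lo] known (or assumed) below target
    lo_known = [i for i in range(hi) if n_grid[i] in cache and
                cache[n_grid[i]].power < target_power]
    if lo_known:
        lo = max(lo_known)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(n_grid[mid]) >= target_power:
            hi = mid
        else:
            lo = mid
    curve = [
        {"n": n, "power": cache[n].power, "mc_se": cache[n].mc_se}
        for n in sorted(cache)
    ]
    return n_grid[hi], curve
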