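"""Synthetic generation of every input the G×E pipeline consumes.

This module fabricates, under a single master seed and with known ground
truth, the three datasets an applied polygenic gene–environment interaction
study starts from:

* an LD reference panel of additive genotype dosages with block-structured
  linkage disequilibrium (first-order autoregressive latent Gaussian within
  fixed-size blocks, independent across blocks);
* GWAS summary statistics whose true standardized effects follow a
  point-normal prior — zero with probability ``1 - p_causal``, otherwise
  ``N(0, h2 / (M * p_causal))`` — with marginal estimates sampled
  analytically as ``N(D @ beta, D / N)`` per LD block;
* an ascertained case–control cohort (default 717 cases / 356 controls)
  with six binary environmental risk domains, a trauma questionnaire
  analogue, covariates, and optional symptom phenotypes, where case status
  is generated from the standardized genetic score, standardized aggregate
  environmental score and their product on either the logit or the
  liability scale at population lifetime risk ``K``.

Exposures are generated independently of genotypes by default, so the
gene–environment correlation screen downstream has a true null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "GenotypePanel",
    "CohortTable",
    "EXPOSURE_DOMAINS",
    "ETI_SUBDOMAINS",
    "stream_rng",
    "simulate_panel",
    "simulate_sumstats",
    "simulate_exposures",
    "simulate_population",
    "simulate_cohort",
    "GeneratorState",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_sumstats_tsv",
    "read_sumstats_tsv",
    "write_truth_json",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


EXPOSURE_DOMAINS = (
    "paternal_age",
    "pses",
    "obstetric_complications",
    "urbanicity",
    "childhood_adversity",
    "recent_life_events",
)

#: Trauma-questionnaire subdomains; positive schemas are reverse-scored
#: downstream (env_scores.eti_total).
ETI_SUBDOMAINS = (
    "eti_neg_self",
    "eti_neg_others",
    "eti_pos_self",
    "eti_pos_others",
)

# Plausible population exposure rates for the six domains.  The source
# instrument's population prevalence table is not public; these are
# generator configuration, not claims about any population.
DEFAULT_EXPOSURE_PREVALENCES = {
    "paternal_age": 0.15,
    "pses": 0.20,
    "obstetric_complications": 0.10,
    "urbanicity": 0.50,
    "childhood_adversity": 0.25,
    "recent_life_events": 0.30,
}

# Log relative-risk scale weights used to aggregate domains into the
# generating environmental score (mirrors the shipped placeholder weight
# table in env_scores).
DEFAULT_EXPOSURE_WEIGHTS = {
    "paternal_age": 0.262,
    "pses": 0.470,
    "obstetric_complications": 0.336,
    "urbanicity": 0.182,
    "childhood_adversity": 0.693,
    "recent_life_events": 0.405,
}

_STREAMS = {
    "panel": 11,
    "sumstats": 12,
    "exposures": 13,
    "cohort": 14,
    "calibration": 15,
}


def stream_rng(master_seed: int, name: str) -> np.random.Generator:
    """Named, order-independent random substream of the master seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown random stream {name!r}")
    return np.random.default_rng([_STREAMS[name], int(master_seed)])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the target study design: 717 cases vs 356 controls
    ascertained from a population with lifetime risk K = 1%, SNP
    heritability 0.3 with 3% causal variants, and standardized
    case-status coefficients (0.7, 1.0, 0.3) for G, E and G×E.
    """

    master_seed: int = 20260921
    M: int = 800
    n_ref: int = 1500
    block_size: int = 40
    rho: object = (0.2, 0.9)  # scalar, or (low, high) for per-block draw
    maf_range: tuple = (0.05, 0.5)
    h2: float = 0.3
    p_causal: float = 0.03
    N_gwas: int = 50_000
    K: float = 0.01
    n_case: int = 717
    n_control: int = 356
    exposure_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_PREVALENCES)
    )
    exposure_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_WEIGHTS)
    )
    exposure_corr: Optional[np.ndarray] = None
    coef_G: float = 0.7
    coef_E: float = 1.0
    coef_GE: float = 0.3
    mechanism: str = "logit"
    # trauma questionnaire analogue
    eti_max: int = 24
    eti_p_neg: float = 0.10
    eti_p_pos: float = 0.50
    eti_adversity_shift: float = 0.15
    # sampling machinery
    n_calibration: int = 200_000
    batch_size: int = 20_000
    max_draws: int = 5_000_000

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ConfigurationError("M must be >= 1")
        if self.n_ref < 2:
            raise ConfigurationError("n_ref must be >= 2")
        if self.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")
        rhos = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if rhos.size not in (1, 2) or np.any(rhos < 0) or np.any(rhos >= 1):
            raise ConfigurationError("rho must lie in [0, 1) (scalar or (low, high))")
        if rhos.size == 2 and rhos[0] > rhos[1]:
            raise ConfigurationError("rho range must be ordered (low, high)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.h2 < 1):
            raise ConfigurationError("h2 must lie in [0, 1)")
        if not (0 < self.p_causal <= 1):
            raise ConfigurationError("p_causal must lie in (0, 1]")
        if self.N_gwas <= 0:
            raise ConfigurationError("N_gwas must be positive")
        if not (0 < self.K < 1):
            raise ConfigurationError("K must lie in (0, 1)")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ConfigurationError("n_case and n_control must be positive")
        if set(self.exposure_prevalences) != set(EXPOSURE_DOMAINS):
            raise ConfigurationError(
                "exposure_prevalences must cover exactly the six domains"
            )
        for name, p in self.exposure_prevalences.items():
            if not (0 < p < 1):
                raise ConfigurationError(f"prevalence for {name!r} outside (0, 1)")
        if self.mechanism not in ("logit", "liability"):
            raise ConfigurationError("mechanism must be 'logit' or 'liability'")
        if self.mechanism == "liability":
            # conservative check with Var(zG*zE) ~ 1; exact residual variance
            # is recomputed from the calibration sample at generation time
            load = self.coef_G**2 + self.coef_E**2 + self.coef_GE**2
            if load >= 1:
                raise ConfigurationError(
                    "liability mechanism: coefficient variance load >= 1 leaves "
                    "no residual variance"
                )
        if self.exposure_corr is not None:
            C = np.asarray(self.exposure_corr, dtype=float)
            if C.shape != (6, 6) or not np.allclose(C, C.T):
                raise ConfigurationError("exposure_corr must be symmetric 6x6")
            if not np.allclose(np.diag(C), 1.0):
                raise ConfigurationError("exposure_corr must have unit diagonal")


@dataclass
class GenotypePanel:
    """Individuals × variants dosage matrix plus per-variant metadata.

    ``variants`` columns: id, block, block_rho, a1, a2, freq (design
    effect-allele frequency of a1).
    """

    dosages: np.ndarray
    variants: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class CohortTable:
    """Per-individual cohort data with optional genotype rows.

    ``data`` holds id, status (1=case), true standardized genetic and
    environmental scores (g_true_z, e_true_z), the six exposure domains,
    trauma subdomain counts, covariates and phenotypes.  ``genotypes`` is
    the cohort dosage matrix aligned to ``variant_ids`` when the cohort was
    generated in genotype mode.
    """

    data: pd.DataFrame
    genotypes: Optional[np.ndarray] = None
    variant_ids: Optional[list] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return int((self.data["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["status"] == 0).sum())


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def _block_partition(M: int, block_size: int) -> list:
    """Contiguous block slices; the final block may be partial."""
    edges = list(range(0, M, block_size)) + [M]
    return [slice(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _ar1_latent(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    z = rng.standard_normal((n, m))
    if rho > 0 and m > 1:
        c = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + c * z[:, j]
    return z


def _draw_block_dosages(
    rng: np.random.Generator, n: int, freqs: np.ndarray, rho: float
) -> np.ndarray:
    """Hardy–Weinberg dosages from two thresholded AR(1) latent haplotypes."""
    thresholds = norm.ppf(1.0 - freqs)
    h1 = _ar1_latent(rng, n, freqs.size, rho) > thresholds
    h2 = _ar1_latent(rng, n, freqs.size, rho) > thresholds
    return (h1.astype(np.int8) + h2.astype(np.int8))


def _draw_genotypes(
    rng: np.random.Generator, variants: pd.DataFrame, n: int
) -> np.ndarray:
    X = np.empty((n, len(variants)), dtype=np.int8)
    for _, idx in variants.groupby("block", sort=True).indices.items():
        idx = np.asarray(idx)
        freqs = variants["freq"].to_numpy()[idx]
        rho = float(variants["block_rho"].to_numpy()[idx[0]])
        X[:, idx] = _draw_block_dosages(rng, n, freqs, rho)
    return X


def simulate_panel(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GenotypePanel:
    """Draw the LD reference panel under block-AR(1) latent-Gaussian LD."""
    rng = rng if rng is not None else stream_rng(config.master_seed, "panel")
    blocks = _block_partition(config.M, config.block_size)
    rho_spec = np.atleast_1d(np.asarray(config.rho, dtype=float))
    if rho_spec.size == 1:
        block_rhos = np.full(len(blocks), rho_spec[0])
    else:
        block_rhos = rng.uniform(rho_spec[0], rho_spec[1], size=len(blocks))
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.M)

    ids = [f"rs{i + 1:07d}" for i in range(config.M)]
    a1 = [_ALLELE_PAIRS[i % 4][0] for i in range(config.M)]
    a2 = [_ALLELE_PAIRS[i % 4][1] for i in range(config.M)]
    block_ids = np.empty(config.M, dtype=int)
    rho_col = np.empty(config.M, dtype=float)
    X = np.empty((config.n_ref, config.M), dtype=np.int8)
    for b, sl in enumerate(blocks):
        block_ids[sl] = b
        rho_col[sl] = block_rhos[b]
        X[:, sl] = _draw_block_dosages(rng, config.n_ref, freqs[sl], block_rhos[b])

    variants = pd.DataFrame(
        {
            "id": ids,
            "block": block_ids,
            "block_rho": rho_col,
            "a1": a1,
            "a2": a2,
            "freq": freqs,
        }
    )
    return GenotypePanel(dosages=X, variants=variants)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def _block_corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation of dosage columns; monomorphic columns are
    treated as uncorrelated with everything (unit diagonal preserved)."""
    sd = X.std(axis=0)
    bad = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.corrcoef(X, rowvar=False)
    D = np.atleast_2d(D)
    if bad.any():
        D[bad, :] = 0.0
        D[:, bad] = 0.0
    np.fill_diagonal(D, 1.0)
    D[~np.isfinite(D)] = 0.0
    np.fill_diagonal(D, 1.0)
    return D


def _chol_psd(D: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(12):
        try:
            return np.linalg.cholesky(D + jitter * np.eye(D.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
    raise np.linalg.LinAlgError("LD block not positive definite after jitter")


def simulate_sumstats(
    panel: GenotypePanel,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Analytic GWAS summary statistics plus the true effect vector.

    True standardized effects are point-normal; marginal estimates are
    drawn per block as ``beta_hat ~ N(D @ beta, D / N)`` with D the
    empirical panel LD, so no raw training cohort is ever materialized.

    Returns ``(sumstats, truth)`` where ``sumstats`` is a DataFrame with
    columns snp, a1, a2, beta, se, n, freq and ``truth`` carries the true
    effects and causal mask.
    """
    if not (0 <= config.h2 < 1):
        raise ConfigurationError("h2 leaves no residual variance")
    rng = rng if rng is not None else stream_rng(config.master_seed, "sumstats")
    M = panel.n_variants
    causal = rng.random(M) < config.p_causal
    beta = np.zeros(M)
    if config.h2 > 0 and causal.any():
        beta[causal] = rng.normal(
            0.0, np.sqrt(config.h2 / (M * config.p_causal)), size=int(causal.sum())
        )

    beta_hat = np.empty(M)
    N = config.N_gwas
    for _, idx in panel.variants.groupby("block", sort=True).indices.items():
        idx = np.asarray(idx)
        D = _block_corr(panel.dosages[:, idx].astype(float))
        L = _chol_psd(D)
        mean = D @ beta[idx]
        beta_hat[idx] = mean + (L @ rng.standard_normal(idx.size)) / np.sqrt(N)

    freq_emp = panel.dosages.mean(axis=0) / 2.0
    freq_emp = np.clip(freq_emp, 1.0 / (2 * panel.n_individuals), 1 - 1.0 / (2 * panel.n_individuals))
    sumstats = pd.DataFrame(
        {
            "snp": panel.variants["id"].to_numpy(),
            "a1": panel.variants["a1"].to_numpy(),
            "a2": panel.variants["a2"].to_numpy(),
            "beta": beta_hat,
            "se": np.full(M, 1.0 / np.sqrt(N)),
            "n": np.full(M, N, dtype=int),
            "freq": freq_emp,
        }
    )
    truth = {
        "beta_true": beta,
        "causal": causal,
        "h2": config.h2,
        "p_causal": config.p_causal,
    }
    return sumstats, truth


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------


def simulate_exposures(
    n: int, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Six binary exposure domains plus trauma subdomain counts.

    Domains are independent Bernoulli draws by default; a Gaussian-copula
    correlation matrix may be supplied via ``config.exposure_corr``.  The
    trauma counts are positively skewed binomial sums whose negative
    subdomains shift upward (and positive subdomains downward) with the
    childhood-adversity indicator, so the trauma total is a noisy proxy of
    one causal domain.  Exposures never see genotypes.
    """
    rng = rng if rng is not None else stream_rng(config.master_seed, "exposures")
    prev = np.array([config.exposure_prevalences[d] for d in EXPOSURE_DOMAINS])
    if config.exposure_corr is None:
        x = (rng.random((n, 6)) < prev).astype(np.int8)
    else:
        L = _chol_psd(np.asarray(config.exposure_corr, dtype=float))
        z = rng.standard_normal((n, 6)) @ L.T
        x = (z > norm.ppf(1.0 - prev)).astype(np.int8)
    out = pd.DataFrame(x, columns=list(EXPOSURE_DOMAINS))

    ca = out["childhood_adversity"].to_numpy()
    p_neg = np.clip(config.eti_p_neg + config.eti_adversity_shift * ca, 0.01, 0.99)
    p_pos = np.clip(config.eti_p_pos - config.eti_adversity_shift * ca, 0.01, 0.99)
    out["eti_neg_self"] = rng.binomial(config.eti_max, p_neg)
    out["eti_neg_others"] = rng.binomial(config.eti_max, p_neg)
    out["eti_pos_self"] = rng.binomial(config.eti_max, p_pos)
    out["eti_pos_others"] = rng.binomial(config.eti_max, p_pos)
    return out


def _env_raw(exposures: pd.DataFrame, weights: dict) -> np.ndarray:
    total = np.zeros(len(exposures))
    for d in EXPOSURE_DOMAINS:
        total += weights[d] * exposures[d].to_numpy()
    return total


# ---------------------------------------------------------------------------
# case-status mechanism and cohort ascertainment
# ---------------------------------------------------------------------------


def _calibrate_logit_intercept(eta: np.ndarray, K: float) -> float:
    """Bisection on b0 so that mean(expit(b0 + eta)) == K."""
    lo, hi = -45.0, 15.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(expit(mid + eta).mean()) > K:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


class GeneratorState:
    """Calibrated moments and intercept/threshold shared by population and
    cohort sampling.  All calibration draws come from the dedicated
    'calibration' stream, so the cohort stream is untouched."""

    def __init__(
        self,
        config: SimulationConfig,
        panel: Optional[GenotypePanel] = None,
        truth: Optional[dict] = None,
    ):
        self.config = config
        cal = stream_rng(config.master_seed, "calibration")
        n_cal = config.n_calibration

        # environmental score moments
        cal_exp = simulate_exposures(n_cal, config, rng=cal)
        raw_e = _env_raw(cal_exp, config.exposure_weights)
        self.mu_e = float(raw_e.mean())
        self.sd_e = float(raw_e.std())
        if self.sd_e == 0:
            raise ConfigurationError("environmental score is degenerate")

        # genetic score moments (genotype mode standardizes against the panel)
        self.panel = panel
        self.beta_true = None if truth is None else np.asarray(truth["beta_true"])
        if panel is not None:
            if self.beta_true is None:
                raise ValueError("genotype mode requires the sumstats truth vector")
            s = self._raw_genetic(panel.dosages.astype(float))
            self.mu_g = float(s.mean())
            sd = float(s.std())
            self.sd_g = sd if sd > 0 else 1.0
        else:
            self.mu_g, self.sd_g = 0.0, 1.0

        zg = cal.standard_normal(n_cal)
        ze = (raw_e - self.mu_e) / self.sd_e
        eta = config.coef_G * zg + config.coef_E * ze + config.coef_GE * zg * ze
        if config.mechanism == "logit":
            self.b0 = _calibrate_logit_intercept(eta, config.K)
            self.sd_resid = None
            self.threshold = None
        else:
            var_int = float(np.var(zg * ze))
            resid_var = (
                1.0
                - config.coef_G**2
                - config.coef_E**2
                - config.coef_GE**2 * var_int
            )
            if resid_var <= 0:
                raise ConfigurationError(
                    "liability mechanism: residual variance non-positive"
                )
            self.sd_resid = float(np.sqrt(resid_var))
            liab = eta + self.sd_resid * cal.standard_normal(n_cal)
            self.threshold = float(np.quantile(liab, 1.0 - config.K))
            self.b0 = None

    def _raw_genetic(self, X: np.ndarray) -> np.ndarray:
        f = self.panel.variants["freq"].to_numpy()
        denom = np.sqrt(2.0 * f * (1.0 - f))
        return ((X - 2.0 * f) / denom) @ self.beta_true

    def genetic_z(self, X: np.ndarray) -> np.ndarray:
        return (self._raw_genetic(X) - self.mu_g) / self.sd_g

    def status(
        self, zg: np.ndarray, ze: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        c = self.config
        eta = c.coef_G * zg + c.coef_E * ze + c.coef_GE * zg * ze
        if c.mechanism == "logit":
            return (rng.random(zg.size) < expit(self.b0 + eta)).astype(np.int8)
        liab = eta + self.sd_resid * rng.standard_normal(zg.size)
        return (liab > self.threshold).astype(np.int8)


def simulate_population(
    config: SimulationConfig,
    n: int,
    rng: Optional[np.random.Generator] = None,
    state: Optional[GeneratorState] = None,
) -> pd.DataFrame:
    """Unascertained population draws on the score level (no genotypes).

    Returns a DataFrame with g_true_z, e_true_z and status; useful for
    prevalence-calibration checks and score-level simulation studies.
    """
    rng = rng if rng is not None else stream_rng(config.master_seed, "cohort")
    state = state if state is not None else GeneratorState(config)
    zg = rng.standard_normal(n)
    exp = simulate_exposures(n, config, rng=rng)
    ze = (_env_raw(exp, config.exposure_weights) - state.mu_e) / state.sd_e
    y = state.status(zg, ze, rng)
    out = exp.copy()
    out.insert(0, "g_true_z", zg)
    out.insert(1, "e_true_z", ze)
    out.insert(2, "status", y)
    return out


def _phenotypes(
    rng: np.random.Generator, zg: np.ndarray, ze: np.ndarray, status: np.ndarray
) -> pd.DataFrame:
    """Symptom phenotypes with modest G/E/G×E signal (cases only for the
    positive-and-negative-syndrome scale; schema scales for everyone)."""
    n = zg.size
    base = 5.0 * zg + 4.0 * ze + 2.0 * zg * ze
    panss_total = 75.0 + base + rng.normal(0, 10, n)
    df = pd.DataFrame(
        {
            "panss_total": panss_total,
            "panss_positive": 18.0 + 0.25 * (panss_total - 75.0) + rng.normal(0, 3, n),
            "panss_negative": 19.0 + 0.30 * (panss_total - 75.0) + rng.normal(0, 3, n),
            "panss_general": 38.0 + 0.45 * (panss_total - 75.0) + rng.normal(0, 4, n),
            "bcss_negative_self": 6.0 + 1.2 * ze + 0.8 * zg + rng.normal(0, 3, n),
            "bcss_negative_others": 6.0 + 1.0 * ze + 0.6 * zg + rng.normal(0, 3, n),
        }
    )
    df.loc[status == 0, ["panss_total", "panss_positive", "panss_negative", "panss_general"]] = np.nan
    return df


def simulate_cohort(
    config: SimulationConfig,
    panel: Optional[GenotypePanel] = None,
    truth: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
    state: Optional[GeneratorState] = None,
) -> CohortTable:
    """Ascertain exactly ``n_case`` cases and ``n_control`` controls.

    Rejection sampling in batches: each batch draws fresh exposures (and
    genotypes when a panel plus truth vector are supplied), forms the
    standardized genetic and environmental scores, generates status under
    the configured mechanism with the calibrated intercept/threshold, and
    keeps individuals until both quotas are filled.  Raises with a
    draw-count diagnostic if ``max_draws`` population draws are exhausted.
    """
    rng = rng if rng is not None else stream_rng(config.master_seed, "cohort")
    if state is None:
        state = GeneratorState(config, panel=panel, truth=truth)
    genotype_mode = state.panel is not None

    need_case, need_control = config.n_case, config.n_control
    rows, geno_rows = [], []
    total_draws = 0
    while need_case > 0 or need_control > 0:
        if total_draws >= config.max_draws:
            raise RuntimeError(
                f"case/control quota unreachable: {config.n_case - need_case}/"
                f"{config.n_case} cases and {config.n_control - need_control}/"
                f"{config.n_control} controls after {total_draws} draws"
            )
        bs = min(config.batch_size, config.max_draws - total_draws)
        exp = simulate_exposures(bs, config, rng=rng)
        if genotype_mode:
            X = _draw_genotypes(rng, panel.variants, bs)
            zg = state.genetic_z(X.astype(float))
        else:
            X = None
            zg = rng.standard_normal(bs)
        ze = (_env_raw(exp, config.exposure_weights) - state.mu_e) / state.sd_e
        y = state.status(zg, ze, rng)
        total_draws += bs

        case_idx = np.flatnonzero(y == 1)[:need_case]
        control_idx = np.flatnonzero(y == 0)[:need_control]
        keep = np.concatenate([case_idx, control_idx])
        need_case -= case_idx.size
        need_control -= control_idx.size
        if keep.size:
            batch = exp.iloc[keep].reset_index(drop=True)
            batch.insert(0, "g_true_z", zg[keep])
            batch.insert(1, "e_true_z", ze[keep])
            batch.insert(2, "status", y[keep])
            rows.append(batch)
            if genotype_mode:
                geno_rows.append(X[keep])

    data = pd.concat(rows, ignore_index=True)
    n = len(data)
    # covariates independent of status by default (clean adjustment null)
    data["age"] = np.clip(rng.normal(38.0, 11.0, n), 18, 70)
    data["sex"] = rng.integers(0, 2, n).astype(np.int8)
    data["education"] = np.clip(rng.normal(13.0, 3.0, n), 6, 22)
    pheno = _phenotypes(
        rng, data["g_true_z"].to_numpy(), data["e_true_z"].to_numpy(),
        data["status"].to_numpy(),
    )
    data = pd.concat([data, pheno], axis=1)

    order = rng.permutation(n)
    data = data.iloc[order].reset_index(drop=True)
    data.insert(0, "id", [f"ind{i + 1:05d}" for i in range(n)])
    genotypes = np.concatenate(geno_rows)[order] if genotype_mode else None

    meta = {
        "mechanism": config.mechanism,
        "draws_used": total_draws,
        "intercept": state.b0,
        "liability_threshold": state.threshold,
        "sd_resid": state.sd_resid,
        "mu_e": state.mu_e,
        "sd_e": state.sd_e,
        "mu_g": state.mu_g,
        "sd_g": state.sd_g,
    }
    return CohortTable(
        data=data,
        genotypes=genotypes,
        variant_ids=list(panel.variants["id"]) if genotype_mode else None,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------


def write_genotype_tsv(dosages, variant_ids, path, individual_ids=None) -> None:
    """Rows = individuals, header = variant ids, dosage values 0-2."""
    df = pd.DataFrame(np.asarray(dosages), columns=list(variant_ids))
    if individual_ids is not None:
        df.insert(0, "id", list(individual_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_genotype_tsv(path):
    df = pd.read_csv(path, sep="\t")
    individual_ids = None
    if df.columns[0] == "id":
        individual_ids = df.pop("id").tolist()
    return df.to_numpy(dtype=float), list(df.columns), individual_ids


def write_sumstats_tsv(sumstats: pd.DataFrame, path) -> None:
    sumstats.to_csv(path, sep="\t", index=False, na_rep=".")


def read_sumstats_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=".")
    required = {"snp", "a1", "a2", "beta", "se", "n", "freq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics file missing columns: {sorted(missing)}")
    return df


def write_truth_json(truth: dict, config: SimulationConfig, path) -> None:
    payload = {
        "beta_true": np.asarray(truth["beta_true"]).tolist(),
        "causal": np.asarray(truth["causal"]).astype(int).tolist(),
        "h2": truth["h2"],
        "p_causal": truth["p_causal"],
        "coefficients": {
            "coef_G": config.coef_G,
            "coef_E": config.coef_E,
            "coef_GE": config.coef_GE,
        },
        "master_seed": config.master_seed,
        "mechanism": config.mechanism,
        "K": config.K,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))
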