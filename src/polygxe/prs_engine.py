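"""Polygenic score construction from GWAS summary statistics.

Implements the summary-statistic reweighting pipeline: allele alignment
against a reference panel, blockwise LD estimation, posterior-mean effect
sizes under the infinitesimal model (a ridge-type solve against the LD
matrix) and under the point-normal prior (per-variant Gibbs sampler),
individual scoring, AUC-based selection of the causal-fraction
hyperparameter over the standard grid, covariate residualization of
scores, and a compact LD-score-regression heritability estimator.

All effect sizes live on the standardized-genotype scale; dosages are
standardized empirically before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .accuracy_metrics import auc

__all__ = [
    "LDMatrix",
    "WeightVector",
    "LdscFit",
    "DEFAULT_P_GRID",
    "align_alleles",
    "estimate_ld",
    "ldpred_inf_weights",
    "ldpred_gibbs_weights",
    "score_individuals",
    "select_p_by_auc",
    "residualize_covariates",
    "ldsc_h2",
    "write_weights_tsv",
    "write_scores_csv",
]

#: Causal-fraction grid searched when tuning the point-normal prior.
DEFAULT_P_GRID = (1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3, 1.0)

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class LDMatrix:
    """Per-block LD correlation matrices aligned to variant order."""

    blocks: list
    block_index: np.ndarray  # variant -> block
    variant_ids: list

    def __post_init__(self):
        for b, D in enumerate(self.blocks):
            if not np.allclose(D, D.T, atol=1e-8):
                raise ValueError(f"LD block {b} is not symmetric")
            if not np.allclose(np.diag(D), 1.0, atol=1e-6):
                raise ValueError(f"LD block {b} does not have unit diagonal")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def ld_scores(self) -> np.ndarray:
        """Per-variant LD scores: sum of squared correlations within block."""
        out = np.empty(self.n_variants)
        start = 0
        for D in self.blocks:
            m = D.shape[0]
            out[start : start + m] = (D**2).sum(axis=1)
            start += m
        return out


@dataclass
class WeightVector:
    """Posterior-mean per-variant effects plus the hyperparameters used."""

    values: np.ndarray
    variant_ids: list
    method: str  # 'inf' or 'gibbs'
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.variant_ids):
            raise ValueError("weight length does not match variant count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite weights")


@dataclass
class LdscFit:
    h2: float
    se: float
    intercept: float
    n_blocks: int

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("jackknife SE must be non-negative")


# ---------------------------------------------------------------------------
# allele alignment
# ---------------------------------------------------------------------------


def align_alleles(
    sumstats: pd.DataFrame,
    panel,
    drop_ambiguous: bool = True,
):
    """Match summary statistics to the panel's variants and allele coding.

    Effects are flipped in sign when the effect/other alleles are swapped
    relative to the panel; variants whose allele pair does not match are
    dropped, as are strand-ambiguous (A/T, C/G) pairs when
    ``drop_ambiguous`` is set.  Returns the aligned sumstats (in panel
    variant order, restricted to matches) and a count report.
    """
    pv = panel.variants
    merged = pv[["id", "a1", "a2"]].merge(
        sumstats, left_on="id", right_on="snp", suffixes=("_panel", "")
    )
    if merged.empty:
        raise ValueError("no overlapping variants between sumstats and panel")

    report = {"n_input": len(sumstats), "n_overlap": len(merged),
              "n_flipped": 0, "n_mismatch": 0, "n_ambiguous": 0}
    keep_rows = []
    for row in merged.itertuples(index=False):
        pair_panel = {row.a1_panel, row.a2_panel}
        pair_ss = {row.a1, row.a2}
        if drop_ambiguous and (pair_ss in _AMBIGUOUS or pair_panel in _AMBIGUOUS):
            report["n_ambiguous"] += 1
            continue
        if pair_panel != pair_ss:
            report["n_mismatch"] += 1
            continue
        flip = row.a1 != row.a1_panel
        if flip:
            report["n_flipped"] += 1
        keep_rows.append(
            {
                "snp": row.id,
                "a1": row.a1_panel,
                "a2": row.a2_panel,
                "beta": -row.beta if flip else row.beta,
                "se": row.se,
                "n": row.n,
                "freq": 1.0 - row.freq if flip else row.freq,
            }
        )
    if not keep_rows:
        raise ValueError("no variants survived allele alignment")
    aligned = pd.DataFrame(keep_rows)
    # restore panel order
    order = {vid: i for i, vid in enumerate(pv["id"])}
    aligned = aligned.sort_values("snp", key=lambda s: s.map(order)).reset_index(drop=True)
    report["n_aligned"] = len(aligned)
    return aligned, report


# ---------------------------------------------------------------------------
# LD estimation
# ---------------------------------------------------------------------------


def estimate_ld(
    panel,
    window: Optional[int] = None,
    shrinkage: float = 0.0,
) -> LDMatrix:
    """Blockwise Pearson LD of standardized dosages.

    Blocks default to the panel's own block annotation; a fixed-size
    ``window`` (in variants) is used instead when given or when the panel
    carries no block column.  ``shrinkage`` moves each block toward the
    identity by ``(1 - lambda) * D + lambda * I`` for invertibility.
    """
    X = panel.dosages.astype(float)
    n, M = X.shape
    if n < 2:
        raise ValueError("LD estimation needs at least 2 individuals")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = panel.variants["id"].to_numpy()[sd == 0]
        raise ValueError(f"zero-variance variant(s) in panel: {bad[:5].tolist()}")

    if window is None and "block" in panel.variants.columns:
        block_index = panel.variants["block"].to_numpy()
    else:
        w = int(window) if window is not None else 100
        if w < 1:
            raise ValueError("window must be >= 1")
        block_index = np.arange(M) // w

    blocks = []
    for b in np.unique(block_index):
        idx = np.flatnonzero(block_index == b)
        D = np.atleast_2d(np.corrcoef(X[:, idx], rowvar=False))
        if shrinkage > 0:
            D = (1.0 - shrinkage) * D + shrinkage * np.eye(D.shape[0])
        blocks.append(D)
    return LDMatrix(
        blocks=blocks,
        block_index=block_index,
        variant_ids=list(panel.variants["id"]),
    )


# ---------------------------------------------------------------------------
# posterior-mean effect sizes
# ---------------------------------------------------------------------------


def ldpred_inf_weights(
    sumstats: pd.DataFrame, ld: LDMatrix, h2: float, M: int, N: float
) -> WeightVector:
    """Infinitesimal-model posterior means: per block solve
    ``(D + (M / (N h2)) I) w = beta_hat``.  Deterministic."""
    if h2 <= 0:
        raise ValueError("h2 must be positive for the infinitesimal solve")
    if N <= 0:
        raise ValueError("N must be positive")
    beta = np.asarray(sumstats["beta"], dtype=float)
    if beta.size != ld.n_variants:
        raise ValueError("sumstats not aligned to LD matrix")
    lam = M / (N * h2)
    w = np.empty_like(beta)
    start = 0
    for D in ld.blocks:
        m = D.shape[0]
        A = D + lam * np.eye(m)
        try:
            w[start : start + m] = np.linalg.solve(A, beta[start : start + m])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular LD system in block starting at variant {start}"
            ) from exc
        start += m
    return WeightVector(
        values=w, variant_ids=list(ld.variant_ids), method="inf",
        params={"h2": h2, "M": M, "N": N},
    )


def ldpred_gibbs_weights(
    sumstats: pd.DataFrame,
    ld: LDMatrix,
    h2: float,
    p: float,
    M: int,
    N: float,
    n_iter: int = 500,
    burn_in: int = 100,
    seed: int = 0,
    max_abs_weight: float = 2.0,
) -> WeightVector:
    """Point-normal-prior posterior means via a per-variant Gibbs sampler.

    Each sweep samples, for every variant, the causal-inclusion indicator
    from the point-normal posterior odds and the effect given inclusion
    from its normal conditional (prior variance h2 / (M p), sampling noise
    1/N).  The returned weights are the average of the sampled vectors
    over post-burn-in sweeps; fully reproducible given ``seed``.
    """
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    if h2 <= 0 or N <= 0:
        raise ValueError("h2 and N must be positive")
    beta = np.asarray(sumstats["beta"], dtype=float)
    if beta.size != ld.n_variants:
        raise ValueError("sumstats not aligned to LD matrix")

    rng = np.random.default_rng(seed)
    sigma2 = h2 / (M * p)  # prior effect variance given causal
    s2 = 1.0 / (N + 1.0 / sigma2)  # posterior variance given causal
    sd_post = math.sqrt(s2)
    v0 = 1.0 / N
    v1 = sigma2 + v0
    log_prior_odds = math.inf if p == 1.0 else math.log(p) - math.log1p(-p)
    half_log_vr = 0.5 * math.log(v0 / v1)
    prec_diff = 0.5 * (1.0 / v0 - 1.0 / v1)

    w = np.zeros_like(beta)
    acc = np.zeros_like(beta)
    start = 0
    for D in ld.blocks:
        m = D.shape[0]
        b = beta[start : start + m]
        wb = np.zeros(m)
        accb = np.zeros(m)
        r = np.zeros(m)  # D @ wb, maintained incrementally
        for sweep in range(n_iter):
            unif = rng.random(m)
            noise = rng.standard_normal(m)
            for j in range(m):
                bt = b[j] - r[j] + wb[j]
                if log_prior_odds is math.inf:
                    include = True
                else:
                    lo = log_prior_odds + half_log_vr + bt * bt * prec_diff
                    include = unif[j] < 1.0 / (1.0 + math.exp(-lo)) if abs(lo) < 35 else lo > 0
                new_w = s2 * N * bt + sd_post * noise[j] if include else 0.0
                if abs(new_w) > max_abs_weight:
                    raise RuntimeError(
                        f"Gibbs divergence guard: |weight| {abs(new_w):.3g} exceeds "
                        f"{max_abs_weight} at variant {start + j}"
                    )
                if new_w != wb[j]:
                    r += D[:, j] * (new_w - wb[j])
                    wb[j] = new_w
            if sweep >= burn_in:
                accb += wb
        acc[start : start + m] = accb / (n_iter - burn_in)
        start += m
    return WeightVector(
        values=acc, variant_ids=list(ld.variant_ids), method="gibbs",
        params={"h2": h2, "p": p, "M": M, "N": N, "n_iter": n_iter,
                "burn_in": burn_in, "seed": seed},
    )


# ---------------------------------------------------------------------------
# scoring and adjustment
# ---------------------------------------------------------------------------


def score_individuals(panel, weights: WeightVector):
    """Weighted sum of empirically standardized dosages.

    Returns ``(raw, standardized)`` score vectors; the standardized vector
    has mean 0 and SD 1 over the scored individuals.  Monomorphic variants
    contribute zero.
    """
    X = panel.dosages.astype(float) if hasattr(panel, "dosages") else np.asarray(panel, dtype=float)
    if X.shape[1] != weights.values.size:
        raise ValueError(
            f"panel has {X.shape[1]} variants but weights have {weights.values.size}"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, sd == 0] = 0.0
    raw = Z @ weights.values
    spread = raw.std(ddof=1) if raw.size > 1 else 0.0
    standardized = (raw - raw.mean()) / spread if spread > 0 else np.zeros_like(raw)
    return raw, standardized


def select_p_by_auc(candidates: Sequence[WeightVector], panel, labels):
    """Score every candidate weight vector and keep the AUC argmax.

    Ties break toward the smaller causal fraction ``p``.  Returns the best
    candidate and the full (p, auc) table.
    """
    labels = np.asarray(labels)
    if len(candidates) == 0:
        raise ValueError("no candidate weight vectors")
    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class")
    rows = []
    for cand in candidates:
        _, z = score_individuals(panel, cand)
        rows.append({"p": cand.params.get("p", 1.0), "method": cand.method,
                     "auc": auc(z, labels)})
    table = pd.DataFrame(rows)
    order = table.sort_values(["auc", "p"], ascending=[False, True]).index
    best = candidates[order[0]]
    return best, table


def residualize_covariates(scores, covariates):
    """Least-squares residuals of scores on covariates (plus intercept),
    re-standardized to mean 0 / SD 1."""
    y = np.asarray(scores, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std(ddof=1)
    # exact linear dependence leaves only float noise; report true zeros
    if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
        return np.zeros_like(resid)
    return (resid - resid.mean()) / sd


# ---------------------------------------------------------------------------
# LD score regression
# ---------------------------------------------------------------------------


def ldsc_h2(
    sumstats: pd.DataFrame,
    ld: LDMatrix,
    M: int,
    N: float,
    n_jackknife: int = 20,
) -> LdscFit:
    """Heritability from the regression of chi-square on LD scores.

    Fits ``chi2_j = intercept + slope * l_j`` by two-step weighted least
    squares — a first pass with weights ``1 / l_j``, then weights
    ``1 / (l_j (intercept + slope l_j)^2)`` accounting for the chi-square
    variance under the first-pass fit — and reports ``h2 = slope * M / N``.
    The standard error comes from a delete-one block jackknife over
    contiguous variant chunks.
    """
    beta = np.asarray(sumstats["beta"], dtype=float)
    se = np.asarray(sumstats["se"], dtype=float)
    if beta.size != ld.n_variants:
        raise ValueError("sumstats not aligned to LD matrix")
    if beta.size < n_jackknife:
        raise ValueError(
            f"{beta.size} variants is fewer than {n_jackknife} jackknife blocks"
        )
    chi2 = (beta / se) ** 2
    ell = ld.ld_scores()

    def _pass(mask, wts):
        X = np.column_stack([np.ones(mask.sum()), ell[mask]])
        W = wts[mask]
        XtW = X.T * W
        return np.linalg.solve(XtW @ X, XtW @ chi2[mask])  # (intercept, slope)

    ell_safe = np.maximum(ell, 1.0)
    w0 = 1.0 / ell_safe
    first = _pass(np.ones(beta.size, dtype=bool), w0)
    mean_chi2 = np.maximum(first[0] + first[1] * ell, 0.1)
    wts = 1.0 / (ell_safe * mean_chi2**2)

    def _wls(mask):
        return _pass(mask, wts)

    full = _wls(np.ones(beta.size, dtype=bool))
    h2_full = full[1] * M / N

    chunks = np.array_split(np.arange(beta.size), n_jackknife)
    pseudo = []
    for chunk in chunks:
        mask = np.ones(beta.size, dtype=bool)
        mask[chunk] = False
        pseudo.append(_wls(mask)[1] * M / N)
    pseudo = np.asarray(pseudo)
    B = n_jackknife
    se_jk = float(np.sqrt((B - 1) / B * np.sum((pseudo - pseudo.mean()) ** 2)))
    return LdscFit(h2=float(h2_full), se=se_jk, intercept=float(full[0]), n_blocks=B)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------


def write_weights_tsv(weights: WeightVector, sumstats: pd.DataFrame, path) -> None:
    df = pd.DataFrame(
        {
            "snp": weights.variant_ids,
            "a1": np.asarray(sumstats["a1"]),
            "weight": weights.values,
            "p": weights.params.get("p", 1.0),
            "method": weights.method,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_scores_csv(ids, raw, standardized, adjusted, path) -> None:
    pd.DataFrame(
        {"id": ids, "raw": raw, "standardized": standardized, "adjusted": adjusted}
    ).to_csv(path, index=False)
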