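"""Configuration-driven end-to-end orchestration.

A single YAML config drives the whole analysis: simulate the reference
panel, summary statistics and cohort; build polygenic scores over the
causal-fraction grid and pick the AUC-best; compute environmental scores;
fit the four case-control model types for each environmental measure; test
multiplicative and additive interaction; build subgroup odds-ratio tables
at the 75/50/25% control-quantile thresholds; convert discrimination to
liability-scale R²; and run the post hoc power simulation.

Every stage writes plain-text artifacts into the output directory and
contributes to a single ``report.json``.  All randomness descends from the
master seed through named substreams, so an identical config produces a
byte-identical report.  Disabled stages are loaded from their on-disk
artifacts when present; a missing upstream artifact fails fast with a
named dependency error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .accuracy_metrics import (
    LiabilityParams,
    auc,
    auc_to_liability_r2,
    nagelkerke_to_liability_r2,
)
from .association_models import (
    ModelSpec,
    dichotomize_by_control_quantile,
    fit_model,
    ge_correlation_screen,
    information_criteria,
    nagelkerke_r2,
    results_table,
    subgroup_or_table,
)
from .env_scores import (
    eti_total,
    load_weight_table,
    pers_total,
    standardize_scores,
)
from .interaction_metrics import multiplicative_interaction, reri_bootstrap, reri_delta
from .power_sim import PowerConfig, estimate_power, min_n_for_power
from .prs_engine import (
    align_alleles,
    estimate_ld,
    ldpred_gibbs_weights,
    ldsc_h2,
    residualize_covariates,
    score_individuals,
    select_p_by_auc,
    write_weights_tsv,
    DEFAULT_P_GRID,
)
from .synthetic_cohort import (
    CohortTable,
    EXPOSURE_DOMAINS,
    ETI_SUBDOMAINS,
    GenotypePanel,
    SimulationConfig,
    read_genotype_tsv,
    read_sumstats_tsv,
    simulate_cohort,
    simulate_panel,
    simulate_sumstats,
    write_genotype_tsv,
    write_sumstats_tsv,
    write_truth_json,
)

__all__ = [
    "PipelineConfig",
    "DependencyError",
    "validate_config",
    "default_demo_config_path",
    "run_pipeline",
    "STAGES",
]

log = logging.getLogger("polygxe")

STAGES = (
    "simulate", "prs", "env_score", "associate",
    "interact", "subgroup", "metrics", "power",
)


class DependencyError(RuntimeError):
    """A stage needs an artifact that no enabled stage produced."""


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(payload, path) -> None:
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=1, default=_json_default)
    )


class StagesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: bool = True
    prs: bool = True
    env_score: bool = True
    associate: bool = True
    interact: bool = True
    subgroup: bool = True
    metrics: bool = True
    power: bool = True


class SimulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    M: int = 800
    n_ref: int = 1500
    block_size: int = 40
    rho: Union[float, Tuple[float, float]] = (0.2, 0.9)
    maf_range: Tuple[float, float] = (0.05, 0.5)
    h2: float = 0.3
    p_causal: float = 0.03
    N_gwas: int = 50_000
    K: float = 0.01
    n_case: int = 717
    n_control: int = 356
    coef_G: float = 0.7
    coef_E: float = 1.0
    coef_GE: float = 0.3
    mechanism: str = "logit"
    n_calibration: int = 200_000
    batch_size: int = 20_000


class PrsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_grid: List[float] = list(DEFAULT_P_GRID)
    n_iter: int = 500
    burn_in: int = 100
    shrinkage: float = 0.01
    h2_override: Optional[float] = None
    adjust_covariates: List[str] = ["age", "sex"]


class EnvSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    weight_table: Optional[str] = None  # None -> shipped placeholder


class InteractionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bootstrap: bool = False
    B: int = 2000


class SubgroupSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    quantiles: List[float] = [0.75, 0.50, 0.25]


class PowerSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_reps: int = 200
    alpha: float = 0.05
    run_min_n: bool = False
    n_grid: Optional[List[int]] = None


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    master_seed: int = 20260921
    output_dir: str = "scratch/pipeline_run"
    log_level: str = "INFO"
    stages: StagesSection = StagesSection()
    simulation: SimulationSection = SimulationSection()
    prs: PrsSection = PrsSection()
    env: EnvSection = EnvSection()
    interaction: InteractionSection = InteractionSection()
    subgroup: SubgroupSection = SubgroupSection()
    power: PowerSection = PowerSection()

    def simulation_config(self) -> SimulationConfig:
        d = self.simulation.model_dump()
        if isinstance(d["rho"], (list, tuple)):
            d["rho"] = tuple(d["rho"])
        d["maf_range"] = tuple(d["maf_range"])
        return SimulationConfig(master_seed=self.master_seed, **d)


def default_demo_config_path() -> Path:
    from importlib import resources

    return Path(resources.files("polygxe").joinpath("data/demo_config.yaml"))


def validate_config(path) -> PipelineConfig:
    """Parse, schema-check and default-fill a YAML pipeline config.

    Unknown keys and type mismatches raise with the offending key path; a
    missing master seed is filled with the default and echoed in the
    report.
    """
    payload = yaml.safe_load(Path(path).read_text())
    if payload is None:
        payload = {}
    cfg = PipelineConfig.model_validate(payload)
    if cfg.env.weight_table is not None and not Path(cfg.env.weight_table).exists():
        raise FileNotFoundError(
            f"env.weight_table path does not exist: {cfg.env.weight_table}"
        )
    return cfg


# ---------------------------------------------------------------------------
# artifact round-tripping for disabled stages
# ---------------------------------------------------------------------------


def _require(outdir: Path, stage: str, artifact: str) -> Path:
    path = outdir / artifact
    if not path.exists():
        raise DependencyError(
            f"stage dependency unmet: artifact {artifact!r} (produced by stage "
            f"{stage!r}) is missing from {outdir}"
        )
    return path


def _load_simulate(outdir: Path):
    variants = pd.read_csv(_require(outdir, "simulate", "panel_variants.tsv"), sep="\t")
    X, vids, _ = read_genotype_tsv(_require(outdir, "simulate", "panel_genotypes.tsv"))
    panel = GenotypePanel(dosages=X.astype(np.int8), variants=variants)
    sumstats = read_sumstats_tsv(_require(outdir, "simulate", "sumstats.tsv"))
    truth_raw = json.loads(_require(outdir, "simulate", "truth.json").read_text())
    truth = {
        "beta_true": np.asarray(truth_raw["beta_true"]),
        "causal": np.asarray(truth_raw["causal"], dtype=bool),
        "h2": truth_raw["h2"],
        "p_causal": truth_raw["p_causal"],
    }
    data = pd.read_csv(_require(outdir, "simulate", "cohort.csv"))
    Xc, cvids, ids = read_genotype_tsv(
        _require(outdir, "simulate", "cohort_genotypes.tsv")
    )
    cohort = CohortTable(
        data=data, genotypes=Xc.astype(np.int8), variant_ids=cvids, meta={}
    )
    return panel, sumstats, truth, cohort


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, outdir: Path, report: dict):
    sim = cfg.simulation_config()
    log.info("simulate: M=%d n_ref=%d cohort=%d/%d", sim.M, sim.n_ref,
             sim.n_case, sim.n_control)
    panel = simulate_panel(sim)
    sumstats, truth = simulate_sumstats(panel, sim)
    cohort = simulate_cohort(sim, panel=panel, truth=truth)

    panel.variants.to_csv(outdir / "panel_variants.tsv", sep="\t", index=False)
    write_genotype_tsv(panel.dosages, panel.variants["id"], outdir / "panel_genotypes.tsv")
    write_sumstats_tsv(sumstats, outdir / "sumstats.tsv")
    write_truth_json(truth, sim, outdir / "truth.json")
    cohort.data.to_csv(outdir / "cohort.csv", index=False)
    write_genotype_tsv(
        cohort.genotypes, cohort.variant_ids, outdir / "cohort_genotypes.tsv",
        individual_ids=cohort.data["id"],
    )
    report["simulate"] = {
        "M": sim.M,
        "n_ref": sim.n_ref,
        "n_case": cohort.n_cases,
        "n_control": cohort.n_controls,
        "draws_used": cohort.meta.get("draws_used"),
        "mechanism": sim.mechanism,
        "intercept": cohort.meta.get("intercept"),
    }
    return sim, panel, sumstats, truth, cohort


def _stage_prs(cfg: PipelineConfig, outdir: Path, report: dict, sim, panel,
               sumstats, cohort):
    pc = cfg.prs
    aligned, align_report = align_alleles(sumstats, panel)
    if len(aligned) != panel.n_variants:
        keep = panel.variants["id"].isin(aligned["snp"]).to_numpy()
        panel = GenotypePanel(
            dosages=panel.dosages[:, keep],
            variants=panel.variants.loc[keep].reset_index(drop=True),
        )
    M = panel.n_variants
    N = float(np.median(aligned["n"]))

    ld_raw = estimate_ld(panel, shrinkage=0.0)
    ldsc = ldsc_h2(aligned, ld_raw, M=M, N=N, n_jackknife=min(20, max(2, M // 50)))
    h2_use = pc.h2_override if pc.h2_override is not None else float(
        np.clip(ldsc.h2, 0.02, 0.8)
    )
    ld = estimate_ld(panel, shrinkage=pc.shrinkage)

    candidates = []
    for i, p in enumerate(pc.p_grid):
        seed = (cfg.master_seed + 1_000_003 * (i + 1)) % (2**31)
        candidates.append(
            ldpred_gibbs_weights(
                aligned, ld, h2=h2_use, p=p, M=M, N=N,
                n_iter=pc.n_iter, burn_in=pc.burn_in, seed=seed,
            )
        )
    labels = cohort.data["status"].to_numpy()
    best, auc_table = select_p_by_auc(candidates, cohort.genotypes, labels)
    raw, std = score_individuals(cohort.genotypes, best)
    cov = cohort.data[list(pc.adjust_covariates)].to_numpy(dtype=float)
    adjusted = residualize_covariates(std, cov)

    scores = pd.DataFrame(
        {"id": cohort.data["id"], "prs_raw": raw, "prs_z": std, "prs_adj": adjusted}
    )
    scores.to_csv(outdir / "scores.csv", index=False)
    write_weights_tsv(best, aligned, outdir / "weights_best.tsv")
    auc_table.to_csv(outdir / "prs_auc_grid.tsv", sep="\t", index=False)
    _dump_json(
        {"h2": ldsc.h2, "se": ldsc.se, "intercept": ldsc.intercept,
         "n_blocks": ldsc.n_blocks},
        outdir / "ldsc.json",
    )
    report["prs"] = {
        "alignment": align_report,
        "ldsc_h2": ldsc.h2,
        "ldsc_se": ldsc.se,
        "ldsc_intercept": ldsc.intercept,
        "h2_used": h2_use,
        "selected_p": best.params["p"],
        "auc_grid": auc_table.to_dict(orient="records"),
    }
    return scores


def _stage_env(cfg: PipelineConfig, outdir: Path, report: dict, cohort):
    table = load_weight_table(cfg.env.weight_table)
    pers = pers_total(cohort.data[list(EXPOSURE_DOMAINS)], table)
    eti = eti_total(cohort.data[list(ETI_SUBDOMAINS)])
    env = pd.DataFrame(
        {
            "id": cohort.data["id"],
            "pers_total": pers["pers_total"],
            "eti_total": eti["eti_total"],
        }
    )
    env["pers_total_z"] = standardize_scores(env["pers_total"])
    env["eti_total_z"] = standardize_scores(env["eti_total"])
    env.to_csv(outdir / "env_scores.csv", index=False)
    report["env_score"] = {
        "weight_table": cfg.env.weight_table or "placeholder",
        "pers_mean": float(env["pers_total"].mean()),
        "eti_mean": float(env["eti_total"].mean()),
    }
    return env


def _merge_analysis_frame(cohort, scores, env) -> pd.DataFrame:
    df = cohort.data.merge(scores, on="id").merge(env, on="id")
    return df


_ENV_MEASURES = {"pers": "pers_total_z", "eti": "eti_total_z"}


def _stage_associate(cfg: PipelineConfig, outdir: Path, report: dict, df):
    summary = {}
    for label, term in _ENV_MEASURES.items():
        fits = {}
        for mt in ("genetic", "environmental", "independent", "interaction"):
            spec = ModelSpec(model_type=mt, genetic_term="prs_adj",
                             environmental_term=term)
            fits[mt] = fit_model(df, spec)
        table = results_table(fits, {})
        table.to_csv(outdir / f"association_{label}.tsv", sep="\t", index=False)

        base = fits["interaction"]
        ext = fit_model(
            df,
            ModelSpec(
                model_type="interaction", genetic_term="prs_adj",
                environmental_term=term,
                covariate_interactions=("age", "sex", "education"),
            ),
        )
        ic = {
            "base": dict(zip(("aic", "bic"), information_criteria(base))),
            "covariate_interactions": dict(zip(("aic", "bic"),
                                               information_criteria(ext))),
        }
        summary[label] = {
            "nagelkerke_r2": {mt: nagelkerke_r2(f) for mt, f in fits.items()},
            "interaction_or": fits["interaction"].or_ci(f"prs_adj:{term}"),
            "information_criteria": ic,
        }

    screen = ge_correlation_screen(
        df[df["status"] == 1], "prs_adj", list(EXPOSURE_DOMAINS)
    )
    screen.to_csv(outdir / "ge_screen.tsv", sep="\t", index=False)
    summary["ge_screen_min_fdr_p"] = (
        float(screen["fdr_p"].min()) if len(screen) else None
    )
    report["associate"] = summary


def _stage_interact(cfg: PipelineConfig, outdir: Path, report: dict, df):
    rows, summary = [], {}
    for label, term in _ENV_MEASURES.items():
        spec = ModelSpec(model_type="interaction", genetic_term="prs_adj",
                         environmental_term=term)
        fit = fit_model(df, spec)
        ge_term = f"prs_adj:{term}"
        orv, (olo, ohi), op = multiplicative_interaction(fit, ge_term)
        delta = reri_delta(fit, "prs_adj", term, ge_term)
        row = {
            "measure": label,
            "mult_or": orv, "mult_ci_low": olo, "mult_ci_high": ohi, "mult_p": op,
            "reri": delta.estimate, "reri_ci_low": delta.ci[0],
            "reri_ci_high": delta.ci[1], "reri_p": delta.p,
            "reri_method": delta.method,
            "contrast_dG": delta.contrast[0], "contrast_dE": delta.contrast[1],
        }
        if cfg.interaction.bootstrap:
            boot = reri_bootstrap(
                df, spec, B=cfg.interaction.B,
                seed=(cfg.master_seed + 77_003) % (2**31),
            )
            row.update(
                {"reri_boot_ci_low": boot.ci[0], "reri_boot_ci_high": boot.ci[1],
                 "reri_boot_dropped": boot.n_dropped}
            )
        rows.append(row)
        summary[label] = {
            "multiplicative_or": orv, "multiplicative_p": op,
            "reri": delta.estimate, "reri_ci": list(delta.ci),
            "reri_significant": delta.significant,
        }
    pd.DataFrame(rows).to_csv(outdir / "interaction.tsv", sep="\t", index=False)
    report["interact"] = summary


def _stage_subgroup(cfg: PipelineConfig, outdir: Path, report: dict, df):
    from .association_models import SeparationError

    controls = (df["status"] == 0).to_numpy()
    frames, summary = [], {}
    for q in cfg.subgroup.quantiles:
        g_high, _ = dichotomize_by_control_quantile(df["prs_adj"], controls, q)
        for label, term in _ENV_MEASURES.items():
            e_high, _ = dichotomize_by_control_quantile(df[term], controls, q)
            try:
                tab = subgroup_or_table(df, g_high, e_high, quantile=q)
            except (SeparationError, ValueError) as exc:
                # sparse cells at extreme thresholds: record, keep the rest
                log.warning("subgroup %s q=%.2f degenerate: %s", label, q, exc)
                summary.setdefault("degenerate", []).append(
                    {"measure": label, "quantile": q, "reason": str(exc)}
                )
                continue
            frame = tab.to_frame()
            frame.insert(0, "measure", label)
            frames.append(frame)
            if q == max(cfg.subgroup.quantiles):
                summary[label] = {
                    cell: tab.cells[cell]["or"] for cell in tab.cells
                }
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "subgroup.tsv", sep="\t", index=False
        )
    report["subgroup"] = summary


def _stage_metrics(cfg: PipelineConfig, outdir: Path, report: dict, df, sim):
    y = df["status"].to_numpy()
    params = LiabilityParams(K=sim.K, P=float(y.mean()))
    out = {"K": params.K, "P": params.P}

    prs_auc = auc(df["prs_adj"], y)
    out["prs"] = {
        "auc": prs_auc,
        "liability_r2_from_auc": auc_to_liability_r2(max(prs_auc, 0.5), params),
    }
    for label, term in _ENV_MEASURES.items():
        spec = ModelSpec(model_type="independent", genetic_term="prs_adj",
                         environmental_term=term, covariates=())
        fit = fit_model(df, spec)
        from .association_models import build_design

        X, yy, _ = build_design(df, spec)
        lin = X.to_numpy() @ fit.params
        a = auc(lin, yy)
        out[f"prs_plus_{label}"] = {
            "auc": a,
            "liability_r2_from_auc": auc_to_liability_r2(max(a, 0.5), params),
            "liability_r2_from_nagelkerke": nagelkerke_to_liability_r2(
                nagelkerke_r2(fit), params
            ),
        }
    _dump_json(out, outdir / "metrics.json")
    report["metrics"] = out


def _stage_power(cfg: PipelineConfig, outdir: Path, report: dict, df, sim):
    spec = ModelSpec(model_type="interaction", genetic_term="prs_adj",
                     environmental_term="pers_total_z")
    fit = fit_model(df, spec)
    b_g = fit.coef("prs_adj")
    b_e = fit.coef("pers_total_z")
    b_ge = fit.coef("prs_adj:pers_total_z")
    out = {"coefficients": {"b_g": b_g, "b_e": b_e, "b_ge": b_ge}}
    for test in ("multiplicative", "additive"):
        pcfg = PowerConfig(
            b_g=b_g, b_e=b_e, b_ge=b_ge, n=len(df),
            case_fraction=float(df["status"].mean()),
            n_reps=cfg.power.n_reps, alpha=cfg.power.alpha, test=test,
            seed=(cfg.master_seed + 88_007) % (2**31),
        )
        res = estimate_power(pcfg)
        out[test] = {"power": res.power, "mc_se": res.mc_se, "n": res.n,
                     "n_failed": res.n_failed}
        if cfg.power.run_min_n:
            try:
                n_min, curve = min_n_for_power(pcfg, 0.8, cfg.power.n_grid)
                out[test]["min_n_for_80pct"] = n_min
                out[test]["curve"] = curve
            except ValueError as exc:
                out[test]["min_n_for_80pct"] = None
                out[test]["min_n_note"] = str(exc)
    _dump_json(out, outdir / "power.json")
    report["power"] = out


def run_pipeline(cfg: PipelineConfig, output_dir: Optional[str] = None) -> dict:
    """Execute the enabled stages in order and return the report dict.

    Identical configs yield byte-identical ``report.json`` files: every
    stage draws from named substreams of the master seed and the report
    carries no timestamps.
    """
    outdir = Path(output_dir if output_dir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    report = {
        "package_version": __version__,
        "master_seed": cfg.master_seed,
        "config": cfg.model_dump(mode="json"),
    }

    sim = cfg.simulation_config()
    state = {}
    if cfg.stages.simulate:
        sim, panel, sumstats, truth, cohort = _stage_simulate(cfg, outdir, report)
        state.update(panel=panel, sumstats=sumstats, truth=truth, cohort=cohort)

    def ensure_sim():
        if "cohort" not in state:
            panel, sumstats, truth, cohort = _load_simulate(outdir)
            state.update(panel=panel, sumstats=sumstats, truth=truth, cohort=cohort)
        return state["panel"], state["sumstats"], state["truth"], state["cohort"]

    scores = env = None
    if cfg.stages.prs:
        panel, sumstats, truth, cohort = ensure_sim()
        scores = _stage_prs(cfg, outdir, report, sim, panel, sumstats, cohort)
    if cfg.stages.env_score:
        _, _, _, cohort = ensure_sim()
        env = _stage_env(cfg, outdir, report, cohort)

    downstream = [s for s in ("associate", "interact", "subgroup", "metrics", "power")
                  if getattr(cfg.stages, s)]
    if downstream:
        _, _, _, cohort = ensure_sim()
        if scores is None:
            scores = pd.read_csv(_require(outdir, "prs", "scores.csv"))
        if env is None:
            env = pd.read_csv(_require(outdir, "env_score", "env_scores.csv"))
        df = _merge_analysis_frame(cohort, scores, env)
        if cfg.stages.associate:
            _stage_associate(cfg, outdir, report, df)
        if cfg.stages.interact:
            _stage_interact(cfg, outdir, report, df)
        if cfg.stages.subgroup:
            _stage_subgroup(cfg, outdir, report, df)
        if cfg.stages.metrics:
            _stage_metrics(cfg, outdir, report, df, sim)
        if cfg.stages.power:
            _stage_power(cfg, outdir, report, df, sim)

    _dump_json(report, outdir / "report.json")
    return report
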