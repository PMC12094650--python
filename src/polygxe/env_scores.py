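"""Aggregate environmental risk scores.

Two scores are computed per individual: a polyenvironmental risk total —
a weighted sum over six exposure domains (paternal age, parental
socioeconomic status, obstetric complications, urbanicity, childhood
adversity, recent life events), each observed level contributing its log
relative-risk weight — and a trauma-questionnaire total in which the
positive-schema subdomains are reverse-scored (``max - raw``) before being
added to the negative subdomains.

The domain weight table is data, not code: a placeholder fixture ships
with the package (clearly labeled non-canonical) and substantive analyses
should supply their own table via YAML or TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EnvWeightTable",
    "load_weight_table",
    "default_weight_table_path",
    "write_weight_table",
    "pers_total",
    "eti_total",
    "standardize_scores",
    "DEFAULT_ETI_MAXIMA",
    "POSITIVE_ETI_SUBDOMAINS",
]

#: Per-subdomain maximum raw scores for the trauma questionnaire analogue.
DEFAULT_ETI_MAXIMA = {
    "eti_neg_self": 24,
    "eti_neg_others": 24,
    "eti_pos_self": 24,
    "eti_pos_others": 24,
}

POSITIVE_ETI_SUBDOMAINS = ("eti_pos_self", "eti_pos_others")


class WeightTableError(ValueError):
    """Schema violation in an environmental weight table."""


@dataclass
class EnvWeightTable:
    """Ordered exposure levels and log relative-risk weights per domain.

    ``domains`` maps domain name -> {"levels": [...], "weights": {level: w},
    "reference": level, "note": str}.  The reference level always carries
    weight 0.
    """

    domains: dict = field(default_factory=dict)
    source_note: str = ""

    def __post_init__(self):
        seen = set()
        for name, d in self.domains.items():
            if name in seen:
                raise WeightTableError(f"duplicate domain {name!r}")
            seen.add(name)
            levels = d.get("levels", [])
            if len(levels) != len(set(levels)):
                raise WeightTableError(f"duplicate level in domain {name!r}")
            ref = d.get("reference")
            if ref is None or ref not in levels:
                raise WeightTableError(f"missing reference level in domain {name!r}")
            weights = d.get("weights", {})
            for lvl in levels:
                if lvl not in weights:
                    raise WeightTableError(
                        f"domain {name!r} level {lvl!r} has no weight"
                    )
                if not np.isfinite(weights[lvl]):
                    raise WeightTableError(
                        f"non-finite weight for domain {name!r} level {lvl!r}"
                    )
            if weights[ref] != 0:
                raise WeightTableError(
                    f"reference level weight must be 0 in domain {name!r}"
                )

    @property
    def domain_names(self):
        return list(self.domains)

    def weight(self, domain: str, level) -> float:
        d = self.domains.get(domain)
        if d is None:
            raise KeyError(f"unknown domain {domain!r}")
        try:
            return float(d["weights"][level])
        except KeyError:
            raise KeyError(
                f"unknown level {level!r} for domain {domain!r}"
            ) from None


def default_weight_table_path() -> Path:
    """Path of the shipped placeholder weight table (non-canonical)."""
    return Path(resources.files("polygxe").joinpath("data/env_weights_placeholder.yaml"))


def load_weight_table(path=None) -> EnvWeightTable:
    """Read and validate a weight table from YAML or TSV.

    YAML schema: ``source_note`` plus ``domains`` — a list of entries with
    ``name``, ``reference`` and ``levels`` (each level: ``level`` plus
    either ``weight`` on the log scale or ``odds_ratio``, which is
    log-transformed on load).  TSV columns: domain, level, weight,
    is_reference.
    """
    path = Path(path) if path is not None else default_weight_table_path()
    if path.suffix.lower() in (".yaml", ".yml"):
        payload = yaml.safe_load(path.read_text())
        domains = {}
        for entry in payload.get("domains", []):
            name = entry["name"]
            if name in domains:
                raise WeightTableError(f"duplicate domain {name!r}")
            levels, weights = [], {}
            for lvl in entry.get("levels", []):
                value = lvl["level"]
                levels.append(value)
                if "weight" in lvl:
                    weights[value] = float(lvl["weight"])
                elif "odds_ratio" in lvl:
                    orv = float(lvl["odds_ratio"])
                    if orv <= 0:
                        raise WeightTableError(
                            f"odds ratio must be positive in domain {name!r}"
                        )
                    weights[value] = float(np.log(orv))
                else:
                    raise WeightTableError(
                        f"level {value!r} of domain {name!r} has neither "
                        "weight nor odds_ratio"
                    )
            domains[name] = {
                "levels": levels,
                "weights": weights,
                "reference": entry.get("reference"),
                "note": entry.get("note", ""),
            }
        return EnvWeightTable(domains=domains, source_note=payload.get("source_note", ""))
    # TSV route
    df = pd.read_csv(path, sep="\t")
    required = {"domain", "level", "weight", "is_reference"}
    if not required.issubset(df.columns):
        raise WeightTableError(f"TSV weight table needs columns {sorted(required)}")
    domains = {}
    for name, grp in df.groupby("domain", sort=False):
        refs = grp.loc[grp["is_reference"].astype(bool), "level"].tolist()
        if len(refs) != 1:
            raise WeightTableError(f"missing reference level in domain {name!r}")
        domains[name] = {
            "levels": grp["level"].tolist(),
            "weights": dict(zip(grp["level"], grp["weight"].astype(float))),
            "reference": refs[0],
            "note": "",
        }
    return EnvWeightTable(domains=domains)


def write_weight_table(table: EnvWeightTable, path) -> None:
    """Round-trippable YAML writer."""
    payload = {
        "source_note": table.source_note,
        "domains": [
            {
                "name": name,
                "reference": d["reference"],
                "note": d.get("note", ""),
                "levels": [
                    {"level": lvl, "weight": float(d["weights"][lvl])}
                    for lvl in d["levels"]
                ],
            }
            for name, d in table.domains.items()
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def pers_total(
    exposures: pd.DataFrame,
    table: EnvWeightTable,
    domains: Optional[Sequence[str]] = None,
    rescale_missing: bool = False,
) -> pd.DataFrame:
    """Weighted polyenvironmental total per individual.

    ``exposures`` holds one column per domain with the observed level.
    Complete-case by default: individuals missing any domain get a NaN
    total and a positive ``n_missing``; with ``rescale_missing`` the total
    over observed domains is rescaled by (all-domain weight count /
    observed count) instead.

    Returns a DataFrame with per-domain contribution columns
    (``contrib_<domain>``), ``pers_total`` and ``n_missing``.
    """
    domains = list(domains) if domains is not None else table.domain_names
    missing_cols = [d for d in domains if d not in exposures.columns]
    if missing_cols:
        raise KeyError(f"exposure columns missing: {missing_cols}")
    n = len(exposures)
    contrib = pd.DataFrame(index=exposures.index)
    for d in domains:
        col = exposures[d]
        vals = np.full(n, np.nan)
        obs = col.notna().to_numpy()
        for i in np.flatnonzero(obs):
            vals[i] = table.weight(d, col.iloc[i])
        contrib[f"contrib_{d}"] = vals
    n_missing = contrib.isna().sum(axis=1)
    if rescale_missing:
        k = len(domains)
        observed = k - n_missing
        total = contrib.sum(axis=1, min_count=1) * (k / observed.replace(0, np.nan))
    else:
        total = contrib.sum(axis=1, min_count=len(domains))
    out = contrib.copy()
    out["pers_total"] = total
    out["n_missing"] = n_missing
    return out


def eti_total(
    subdomain_scores: pd.DataFrame,
    max_by_subdomain: Optional[dict] = None,
    positive_subdomains: Sequence[str] = POSITIVE_ETI_SUBDOMAINS,
) -> pd.DataFrame:
    """Trauma total with reverse-scored positive subdomains.

    ``reversed = max - raw`` for each positive subdomain; the total is the
    sum of raw negative subdomains and reversed positive subdomains.
    Raises if any raw score falls outside [0, max].
    """
    maxima = dict(DEFAULT_ETI_MAXIMA if max_by_subdomain is None else max_by_subdomain)
    out = pd.DataFrame(index=subdomain_scores.index)
    total = np.zeros(len(subdomain_scores))
    for sub, mx in maxima.items():
        if sub not in subdomain_scores.columns:
            raise KeyError(f"subdomain column missing: {sub!r}")
        raw = subdomain_scores[sub].to_numpy(dtype=float)
        if np.nanmin(raw) < 0 or np.nanmax(raw) > mx:
            raise ValueError(f"raw scores for {sub!r} outside [0, {mx}]")
        adj = mx - raw if sub in positive_subdomains else raw
        out[f"adj_{sub}"] = adj
        total = total + adj
    out["eti_total"] = total
    return out


def standardize_scores(values, reference_mask=None):
    """(x - mean) / SD over non-missing values.

    With ``reference_mask`` the mean and SD come from the masked subset
    (e.g. controls) but are applied to everyone.  Sample SD (ddof=1).
    """
    x = np.asarray(values, dtype=float)
    ref = x if reference_mask is None else x[np.asarray(reference_mask, dtype=bool)]
    ref = ref[np.isfinite(ref)]
    if ref.size < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; cannot standardize")
    return (x - ref.mean()) / sd
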