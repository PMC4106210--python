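"""File formats, run configuration and pipeline orchestration.

The canonical on-disk form of trial data is a long (tidy) CSV with header
``year,environment,block,genotype,value`` (order-free, case-insensitive):
one row per plot.  Marker panels are a wide CSV (``line`` column plus one
column per marker, -1/+1 coded) accompanied by a map CSV
(``marker,chromosome,position_cM``).  Reports are written as CSV tables
(percentages to 2 decimals) plus a JSON bundle with every sum of squares,
degree of freedom and setting in force; reports are byte-reproducible
given the same inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .families import FREE_PARAMS, Family
from .fitting import CellMeansTable, compute_environment_index, fit_all_genotypes
from .partition import (
    anova_partition,
    classify_stability,
    partition_gxe,
    _complete_case,
)
from .scan import (
    ElasticNetConfig,
    EnvClass,
    MarkerPanel,
    genome_scan,
    representative_phenotypes,
)

__all__ = [
    "TRIAL_COLUMNS",
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_panel",
    "write_panel",
    "write_report",
    "run_pipeline",
]

logger = logging.getLogger("nlgxe")

TRIAL_COLUMNS = ("year", "environment", "block", "genotype", "value")


# ---------------------------------------------------------------------------
# trial records
# ---------------------------------------------------------------------------

def read_trials(path) -> pd.DataFrame:
    """Read and validate a long-format trial CSV.

    Columns may appear in any order and case.  Duplicate
    (year, environment, block, genotype) keys and non-numeric values are
    errors naming the offending keys / line numbers.
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[list(TRIAL_COLUMNS)]

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric value on line(s) {lines}")
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite trait values")
    df["value"] = values

    key_cols = ["year", "environment", "block", "genotype"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, key_cols].drop_duplicates().head(5).to_records(index=False)
        )
        raise ValueError(
            f"{path}: duplicate (year, environment, block, genotype) keys: "
            + "; ".join(map(str, offenders))
        )
    return df


def write_trials(records: pd.DataFrame, path) -> None:
    records.loc[:, list(TRIAL_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------

def read_panel(panel_path, map_path) -> MarkerPanel:
    """Read a line x marker genotype CSV plus its genetic-map CSV."""
    wide = pd.read_csv(panel_path)
    wide.columns = [str(c).strip() for c in wide.columns]
    first = wide.columns[0]
    if first.lower() != "line":
        raise ValueError(f"{panel_path}: first column must be 'line', got {first!r}")
    gmap = pd.read_csv(map_path)
    gmap.columns = [str(c).strip() for c in gmap.columns]
    markers = list(gmap["marker"].astype(str))
    missing = [m for m in markers if m not in wide.columns]
    if missing:
        raise ValueError(f"{panel_path}: markers missing from panel: {missing[:5]}")
    geno = wide[markers].to_numpy()
    return MarkerPanel(
        lines=list(wide[first].astype(str)),
        markers=gmap[["marker", "chromosome", "position_cM"]],
        genotypes=geno,
    )


def write_panel(panel: MarkerPanel, panel_path, map_path) -> None:
    wide = pd.DataFrame(
        panel.genotypes, columns=list(panel.markers["marker"]),
    )
    wide.insert(0, "line", panel.lines)
    wide.to_csv(panel_path, index=False)
    panel.markers.to_csv(map_path, index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Settings of one full analysis run."""

    families: Tuple[Family, ...] = tuple(Family)
    alpha_level: float = 0.05
    enet: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    enet_alphas: Tuple[float, ...] = (0.5, 1.0)
    seed: int = 0
    out_dir: Optional[str] = None
    verbose: bool = False

    def __post_init__(self) -> None:
        self.families = tuple(Family.coerce(f) for f in self.families)
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        enet = ElasticNetConfig(**raw.pop("enet", {}))
        return cls(enet=enet, **raw)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(report: Dict, path) -> None:
    """Write the JSON report bundle, byte-reproducible for identical inputs."""
    with open(path, "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: RunConfig,
    trial_path,
    panel_path=None,
    map_path=None,
) -> Dict:
    """Full analysis: ANOVA, per-family G x E partition, stability, and
    (when a panel is given) the environment-stratified marker scan.

    Writes ``partition.csv``, ``stability.csv``, ``report.json`` and, per
    penalty mixing value, ``scan_alpha<alpha>.csv`` into
    ``config.out_dir`` when set, and returns the report dict.
    """
    records = read_trials(trial_path)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    report: Dict = {
        "seed": config.seed,
        "settings": {
            "families": [f.value for f in config.families],
            "alpha_level": config.alpha_level,
            "enet_alphas": list(config.enet_alphas),
            "n_folds": config.enet.n_folds,
            "n_lambda": config.enet.n_lambda,
        },
        "years": {},
    }
    logger.info(
        "pipeline seed=%d families=%s", config.seed,
        ",".join(f.value for f in config.families),
    )

    pct_rows = []
    stab_rows = []
    for year in sorted(records["year"].unique(), key=str):
        sub = _complete_case(records[records["year"] == year])
        anova = anova_partition(sub)
        table = compute_environment_index(sub)
        ydict: Dict = {"anova": anova.as_dict(), "families": {}}
        for fam in config.families:
            sweep = fit_all_genotypes(table, fam, seed=config.seed)
            part = partition_gxe(table, sweep, anova)
            pct_rows.append(
                {
                    "year": str(year), "family": fam.value,
                    "pct_explained": part.pct_explained,
                    "ss_GxE": anova.ss_GxE,
                    "ss_explained": part.ss_explained,
                    "ss_residual": part.ss_residual,
                    "n_genotypes": len(table.genotypes),
                    "n_environments": len(table.environments),
                }
            )
            ydict["families"][fam.value] = {
                "pct_explained": part.pct_explained,
                "ss_explained": part.ss_explained,
                "ss_residual": part.ss_residual,
                "floored": part.floored,
            }
            if fam is Family.LINEAR:
                reps = classify_stability(
                    sweep, table, alpha_level=config.alpha_level,
                    pooled_error_ms=(
                        anova.ss_error / anova.df_error
                        if anova.df_error > 0 else None
                    ),
                    pooled_error_df=anova.df_error or None,
                )
                for rep in reps:
                    stab_rows.append(
                        {
                            "year": str(year), "genotype": rep.genotype,
                            "slope": rep.slope, "se_slope": rep.se_slope,
                            "dev_ms": rep.dev_ms, "mean_yield": rep.mean_yield,
                            "fw_class": rep.fw_class.value,
                            "er_stable": rep.er_stable,
                        }
                    )
        report["years"][str(year)] = ydict

    pct = pd.DataFrame(pct_rows)
    if pct["year"].nunique() > 1:
        avg = pct.groupby("family", sort=False)["pct_explained"].mean().reset_index()
        avg.insert(0, "year", "average")
        pct = pd.concat([pct, avg], ignore_index=True)

    stability = pd.DataFrame(stab_rows)
    if out_dir:
        out = pct.copy()
        out["pct_explained"] = out["pct_explained"].round(2)
        out.to_csv(out_dir / "partition.csv", index=False)
        if not stability.empty:
            stability.round(6).to_csv(out_dir / "stability.csv", index=False)

    if panel_path is not None:
        if map_path is None:
            raise ValueError("a marker panel requires its map CSV")
        panel = read_panel(panel_path, map_path)
        if records["year"].nunique() > 1:
            raise ValueError("marker scans expect single-year trial records")
        table = compute_environment_index(records)
        if list(table.genotypes) != list(panel.lines):
            raise ValueError("trial genotypes do not match panel lines")
        sweep = fit_all_genotypes(table, Family.LINEAR, seed=config.seed)
        if sweep.skipped:
            raise ValueError(f"lines not fittable linearly: {sweep.skipped}")
        pheno = representative_phenotypes(table, sweep)
        report["scan"] = {}
        for alpha in config.enet_alphas:
            cfg = dataclasses.replace(config.enet, alpha=alpha, seed=config.seed)
            scans = genome_scan(panel, pheno, cfg)
            scan_df = panel.markers.copy()
            for cls in EnvClass:
                scan_df[f"effect_{cls.value}"] = scans[cls].effects
            if out_dir:
                scan_df.to_csv(out_dir / f"scan_alpha{alpha:g}.csv", index=False)
            report["scan"][f"alpha_{alpha:g}"] = {
                cls.value: {
                    "n_nonzero": scans[cls].n_nonzero,
                    "lambda_selected": scans[cls].lambda_selected,
                    "mean_abs_effect": float(np.mean(np.abs(scans[cls].effects))),
                }
                for cls in EnvClass
            }

    if out_dir:
        write_report(report, out_dir / "report.json")
    return report
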