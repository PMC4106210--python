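"""Two-way G x E variance partitioning and stability classification.

The total sum of squares of a balanced replicated trial is split into
genotype (G), environment (E), interaction (G x E) and within-cell error
components.  The interaction component is then partitioned further, per
response family, into the part explained by the fitted per-genotype
response curves and a residual:

1. compute per-cell deviations  d_ij = ybar_ij - fhat_i(x_j),
2. double-center them          d_ij - dbar_i. - dbar_.j + dbar_..,
3. ss_residual = n_reps * sum(centered d^2),  ss_explained = ss_GxE - ss_residual.

The double-centering removes whatever additive (G + E) structure the
curves failed to absorb, so only genuine interaction is credited to a
family.  In the LINEAR case this construction reduces exactly to the
classical joint-regression heterogeneity-of-regressions sum of squares
``n_reps * sum_i (b_i - 1)^2 * S_xx``, and for every family the identity
``ss_explained + ss_residual = ss_GxE`` holds before flooring.

Stability classification follows the three Finlay-Wilkinson groups on the
linear slope (b = 1 average, b > 1 low stability, b < 1 high stability),
decided by a two-sided t-test of H0: b = 1 rather than the raw comparison,
plus the Eberhart-Russell refinement (average slope, low deviation mean
square, high mean yield).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .families import Family
from .fitting import (
    CellMeansTable,
    FitSweep,
    GenotypeFit,
    compute_environment_index,
    fit_all_genotypes,
)

__all__ = [
    "AnovaPartition",
    "GxEPartition",
    "StabilityClass",
    "StabilityReport",
    "UnbalancedDataError",
    "anova_partition",
    "partition_gxe",
    "percent_table",
    "classify_stability",
]

logger = logging.getLogger("nlgxe")


class UnbalancedDataError(ValueError):
    """Layout not balanced after the complete-case genotype rule."""


@dataclass
class AnovaPartition:
    """Two-way (genotype x environment) sums of squares with replication."""

    ss_total: float
    ss_G: float
    ss_E: float
    ss_GxE: float
    ss_error: float
    df_total: int
    df_G: int
    df_E: int
    df_GxE: int
    df_error: int
    n_reps: int

    def as_dict(self) -> Dict[str, float]:
        return {
            "ss_total": self.ss_total, "ss_G": self.ss_G, "ss_E": self.ss_E,
            "ss_GxE": self.ss_GxE, "ss_error": self.ss_error,
            "df_total": self.df_total, "df_G": self.df_G, "df_E": self.df_E,
            "df_GxE": self.df_GxE, "df_error": self.df_error,
            "n_reps": self.n_reps,
        }


@dataclass
class GxEPartition:
    """Share of the interaction sum of squares explained by one family."""

    family: Family
    ss_explained: float
    ss_residual: float
    pct_explained: Optional[float]
    floored: bool = False
    df_explained: Optional[int] = None


class StabilityClass(str, enum.Enum):
    AVERAGE = "average"
    LOW_STABILITY = "low_stability"
    HIGH_STABILITY = "high_stability"


@dataclass
class StabilityReport:
    """Joint-regression stability summary for one genotype."""

    genotype: str
    slope: float
    se_slope: Optional[float]
    dev_ms: Optional[float]
    mean_yield: float
    fw_class: StabilityClass
    er_stable: bool
    t_stat: Optional[float] = None
    p_value: Optional[float] = None


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _complete_case(df: pd.DataFrame) -> pd.DataFrame:
    """Restrict to genotypes observed in every environment (no imputation)."""
    envs = df["environment"].unique()
    per_geno = df.groupby("genotype")["environment"].nunique()
    keep = per_geno[per_geno == len(envs)].index
    dropped = sorted(set(df["genotype"]) - set(keep))
    if dropped:
        logger.warning(
            "excluding genotypes absent from some environments: %s", dropped
        )
    return df[df["genotype"].isin(keep)]


def anova_partition(raw: pd.DataFrame) -> AnovaPartition:
    """Two-way sums of squares (G, E, G x E, error) from replicated records.

    Blocks act as replicates: the error stratum has GE(r - 1) degrees of
    freedom.  Genotypes missing from some environments are excluded first
    (complete-case rule); remaining unequal per-cell replication is an
    error listing the offending cells.
    """
    df = raw.copy()
    df.columns = [str(c).lower() for c in df.columns]
    if "year" in df.columns and df["year"].nunique() > 1:
        raise ValueError("records span multiple years; stratify by year first")
    df = _complete_case(df)
    if df.empty:
        raise UnbalancedDataError("no complete-case genotypes remain")

    counts = df.groupby(["genotype", "environment"])["value"].size()
    if counts.nunique() > 1:
        r = int(counts.mode().iloc[0])
        bad = counts[counts != r]
        raise UnbalancedDataError(
            "unequal replication in cells: "
            + ", ".join(f"{g}/{e} (n={n})" for (g, e), n in bad.items())
        )
    r = int(counts.iloc[0])

    cell = df.groupby(["genotype", "environment"])["value"].mean().unstack()
    M = cell.to_numpy(float)
    G, E = M.shape
    grand = M.mean()
    gm = M.mean(axis=1)
    em = M.mean(axis=0)

    ss_G = E * r * float(np.sum((gm - grand) ** 2))
    ss_E = G * r * float(np.sum((em - grand) ** 2))
    inter = M - gm[:, None] - em[None, :] + grand
    ss_GxE = r * float(np.sum(inter ** 2))
    y = df["value"].to_numpy(float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    cell_of = cell.stack()
    fitted = df.set_index(["genotype", "environment"]).index.map(cell_of)
    ss_error = float(np.sum((y - np.asarray(fitted, float)) ** 2))

    return AnovaPartition(
        ss_total=ss_total, ss_G=ss_G, ss_E=ss_E, ss_GxE=ss_GxE, ss_error=ss_error,
        df_total=G * E * r - 1, df_G=G - 1, df_E=E - 1,
        df_GxE=(G - 1) * (E - 1), df_error=G * E * (r - 1), n_reps=r,
    )


# ---------------------------------------------------------------------------
# G x E partition by family
# ---------------------------------------------------------------------------

def partition_gxe(
    table: CellMeansTable,
    fits: Sequence[GenotypeFit] | FitSweep,
    anova: AnovaPartition,
) -> GxEPartition:
    """Split ss_GxE into the part explained by the fitted curves and a residual.

    Requires a complete table and one fit per genotype.  A fit worse than
    the additive model would give negative ss_explained; that is floored
    at 0 and flagged.  ``pct_explained`` is None when ss_GxE is zero.
    """
    fit_list = list(fits.fits) if isinstance(fits, FitSweep) else list(fits)
    by_geno = {f.genotype: f for f in fit_list}
    missing = [g for g in table.genotypes if g not in by_geno]
    if missing:
        raise ValueError(f"no fit for genotypes: {missing}")
    if not table.is_complete:
        raise ValueError("partitioning requires a complete cell-means table")

    family = fit_list[0].params.family
    pred = np.vstack(
        [by_geno[g].predict(table.env_index) for g in table.genotypes]
    )
    delta = table.means - pred
    centered = (
        delta
        - delta.mean(axis=1, keepdims=True)
        - delta.mean(axis=0, keepdims=True)
        + delta.mean()
    )
    ss_residual = anova.n_reps * float(np.sum(centered ** 2))
    ss_explained = anova.ss_GxE - ss_residual
    floored = False
    if ss_explained < 0:
        # possible only when a fit is worse than the additive model
        if ss_explained < -1e-8 * max(anova.ss_GxE, 1.0):
            floored = True
            logger.warning(
                "%s explained SS negative (%.3g); floored at 0",
                family.value, ss_explained,
            )
        ss_explained = 0.0
        ss_residual = anova.ss_GxE
    pct = (
        100.0 * ss_explained / anova.ss_GxE if anova.ss_GxE > 0 else None
    )
    df_exp = sum(f.n_params - 1 for f in fit_list)
    return GxEPartition(
        family=family, ss_explained=ss_explained, ss_residual=ss_residual,
        pct_explained=pct, floored=floored, df_explained=df_exp,
    )


def percent_table(
    raw: pd.DataFrame,
    families: Sequence[Family | str],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-year, per-family percentage of G x E explained (tidy frame).

    Runs the full chain — environmental index, per-genotype fits for each
    family, interaction partition — separately within each year stratum,
    and appends an across-year ``average`` row per family when several
    years are present.  Columns: year, family, pct_explained, ss_GxE,
    ss_explained, ss_residual, n_genotypes, n_environments.
    """
    df = raw.copy()
    df.columns = [str(c).lower() for c in df.columns]
    if "year" not in df.columns:
        df["year"] = "all"
    families = [Family.coerce(f) for f in families]
    rows = []
    for year in sorted(df["year"].unique(), key=str):
        sub = _complete_case(df[df["year"] == year])
        anova = anova_partition(sub)
        table = compute_environment_index(sub)
        for fam in families:
            sweep = fit_all_genotypes(table, fam, seed=seed)
            if sweep.skipped:
                raise ValueError(
                    f"year {year}: genotypes not fittable under "
                    f"{fam.value}: {sweep.skipped}"
                )
            part = partition_gxe(table, sweep, anova)
            rows.append(
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
    out = pd.DataFrame(rows)
    if out["year"].nunique() > 1:
        avg = (
            out.groupby("family", sort=False)["pct_explained"]
            .mean()
            .reset_index()
        )
        avg.insert(0, "year", "average")
        out = pd.concat([out, avg], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def classify_stability(
    fits: Sequence[GenotypeFit] | FitSweep,
    table: CellMeansTable,
    alpha_level: float = 0.05,
    pooled_error_ms: Optional[float] = None,
    pooled_error_df: Optional[int] = None,
) -> List[StabilityReport]:
    """Finlay-Wilkinson / Eberhart-Russell stability summary per genotype.

    The slope's standard error comes from the usual OLS formula
    ``sqrt(dev_ms / S_xx)`` with ``dev_ms = rss/(n - 2)``; the class is
    decided by a two-sided t-test of H0: b = 1 at ``alpha_level``.  A
    genotype is Eberhart-Russell stable when its class is AVERAGE, its
    deviation mean square is low (not significantly above the pooled error
    mean square by an F-test when replicates provide one, otherwise at or
    below the across-genotype median), and its mean yield exceeds the
    median genotype mean.  Genotypes with fewer than 4 environments get a
    null dev_ms and default to AVERAGE with a warning.
    """
    fit_list = list(fits.fits) if isinstance(fits, FitSweep) else list(fits)
    for f in fit_list:
        if f.params.family is not Family.LINEAR:
            raise ValueError("stability classification requires LINEAR fits")

    mean_yields = {
        g: float(np.nanmean(table.means[table.row(g)])) for g in table.genotypes
    }
    median_yield = float(np.median(list(mean_yields.values())))

    prelim = []
    for f in fit_list:
        x, _ = table.xy(f.genotype)
        sxx = float(np.sum((x - x.mean()) ** 2))
        if f.n_obs >= 4:
            dev_ms = f.rss / (f.n_obs - 2)
            se = float(np.sqrt(dev_ms / sxx)) if sxx > 0 else None
        else:
            dev_ms = se = None
            logger.warning(
                "genotype %s: n_obs=%d < 4, deviation MS undefined",
                f.genotype, f.n_obs,
            )
        prelim.append((f, dev_ms, se, f.n_obs - 2))

    dev_values = [d for _, d, _, _ in prelim if d is not None]
    median_dev = float(np.median(dev_values)) if dev_values else np.inf

    reports = []
    for f, dev_ms, se, df_dev in prelim:
        b = f.params.b
        t = p = None
        fw = StabilityClass.AVERAGE
        if se is not None and se > 0:
            t = (b - 1.0) / se
            p = 2.0 * float(stats.t.sf(abs(t), df_dev))
            if p <= alpha_level:
                fw = (
                    StabilityClass.LOW_STABILITY
                    if b > 1
                    else StabilityClass.HIGH_STABILITY
                )
        elif se is not None:  # perfect fit: slope known exactly
            if b != 1.0:
                fw = (
                    StabilityClass.LOW_STABILITY
                    if b > 1
                    else StabilityClass.HIGH_STABILITY
                )
        if dev_ms is None:
            low_dev = False
        elif pooled_error_ms is not None and pooled_error_df:
            mean_ms = pooled_error_ms / table.n_reps  # error MS on a cell-mean basis
            fstat = dev_ms / mean_ms if mean_ms > 0 else np.inf
            low_dev = float(stats.f.sf(fstat, df_dev, pooled_error_df)) > alpha_level
        else:
            low_dev = dev_ms <= median_dev
        er = (
            fw is StabilityClass.AVERAGE
            and low_dev
            and mean_yields[f.genotype] > median_yield
        )
        reports.append(
            StabilityReport(
                genotype=f.genotype, slope=b, se_slope=se, dev_ms=dev_ms,
                mean_yield=mean_yields[f.genotype], fw_class=fw, er_stable=er,
                t_stat=t, p_value=p,
            )
        )
    return reports
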