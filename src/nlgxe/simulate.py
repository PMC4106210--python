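"""Seeded generators for multi-environment trials and DH marker panels.

Two study designs are emulated:

* A replicated multi-environment trial (MET) in a randomized complete
  block design: each genotype's expected response to a latent environment
  quality follows one of the six response families, with genotype-specific
  parameters drawn from configured distributions, additive block effects,
  and i.i.d. Gaussian plot error.  The latent quality plays the role the
  environmental index estimates; the analysis chain re-derives the index
  from the simulated data, so index-estimation error is part of every
  end-to-end check.

* A doubled-haploid (DH) biparental mapping population: one gamete per
  chromosome is generated by a Markov walk along the marker map, with the
  recombination fraction between adjacent markers given by Haldane's map
  function r = (1 - exp(-2d/100))/2 for a spacing of d cM (no
  interference); chromosome doubling makes lines fully homozygous (-1/+1
  coding).  Line-by-environment phenotypes carry planted QTL whose
  additive effects scale linearly with environment quality, so that
  marker effects are larger in good than in poor environments — the
  generating model behind QTL-by-environment interaction as a change of
  effect size.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .families import FREE_PARAMS, Family, ResponseParams, _eval
from .fitting import _POSITIVE_FAMILIES
from .scan import MarkerPanel

__all__ = [
    "MetSimConfig",
    "DhSimConfig",
    "SimulatedMet",
    "SimulatedDhTrial",
    "default_param_distributions",
    "haldane",
    "simulate_met",
    "simulate_dh_population",
    "simulate_dh_phenotypes",
]

_MAX_REDRAWS = 1000


def haldane(d_cM) -> np.ndarray:
    """Recombination fraction between loci d centimorgans apart (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


def default_param_distributions(family: Family) -> Dict[str, Tuple[float, float]]:
    """Per-parameter (mean, sd) across genotypes, on a cereal-yield scale.

    Chosen so that responses over an index range of roughly 2-8 t/ha look
    like realistic trial data: linear slopes centered on 1 with sd 0.3,
    peaked families with optima near the middle of the range, peak yields
    near 6 t/ha and response-range scales of about 2 t/ha.
    """
    family = Family.coerce(family)
    return {
        Family.LINEAR: {"a": (0.0, 0.5), "b": (1.0, 0.3)},
        Family.PARABOLA: {"a": (0.0, 0.5), "b": (1.0, 0.2), "c": (0.0, 0.05)},
        Family.RECIP_QUAD: {
            "a": (0.45, 0.05), "b": (-0.085, 0.01), "c": (0.0085, 0.001),
        },
        Family.CAUCHY: {"k": (6.0, 0.8), "x_max": (5.0, 1.5), "r": (2.0, 0.5)},
        Family.LOGISTIC: {"a": (0.15, 0.02), "b": (1.0, 0.3), "c": (0.5, 0.1)},
        Family.NORMAL: {"k": (40.0, 5.0), "x_max": (5.0, 1.5), "r": (2.0, 0.5)},
    }[family]


@dataclass
class MetSimConfig:
    """Settings of one simulated multi-environment trial.

    Defaults emulate a provincial cultivar-trial series: 30 genotypes in
    20 environments with 3 RCBD blocks, environment qualities spanning
    2-8 t/ha, plot noise of 0.3 t/ha, and Cauchy reaction norms.
    """

    n_genotypes: int = 30
    n_environments: int = 20
    n_blocks: int = 3
    family: Family = Family.CAUCHY
    parameter_distributions: Optional[Dict[str, Tuple[float, float]]] = None
    env_quality: Optional[np.ndarray] = None
    noise_sd: float = 0.3
    seed: int = 0
    year: str = "sim"

    def __post_init__(self) -> None:
        self.family = Family.coerce(self.family)
        if self.n_genotypes < 2 or self.n_environments < 2 or self.n_blocks < 1:
            raise ValueError("counts must be >= 2 genotypes/environments, >= 1 block")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.parameter_distributions is None:
            self.parameter_distributions = default_param_distributions(self.family)
        if self.env_quality is None:
            self.env_quality = np.linspace(2.0, 8.0, self.n_environments)
        self.env_quality = np.asarray(self.env_quality, float)
        if self.env_quality.shape != (self.n_environments,):
            raise ValueError("env_quality length must equal n_environments")


@dataclass
class SimulatedMet:
    """Replicated long-format records plus the generating truth."""

    records: pd.DataFrame
    true_params: List[ResponseParams]
    env_quality: np.ndarray
    config: MetSimConfig


def _draw_params(
    family: Family,
    dists: Dict[str, Tuple[float, float]],
    rng: np.random.Generator,
    x: np.ndarray,
    floor: float,
) -> ResponseParams:
    """Draw one genotype's parameters, redrawing draws that violate the
    family constraints or whose expected curve dips below ``floor`` over
    the simulated environments (keeps yields in the positive domain the
    non-linear fitters require)."""
    names = FREE_PARAMS[family]
    for name in names:
        if name not in dists:
            raise ValueError(f"no distribution given for parameter {name!r}")
    for _ in range(_MAX_REDRAWS):
        theta = {n: rng.normal(*dists[n]) for n in names}
        try:
            params = ResponseParams(family=family, **theta)
        except ValueError:
            continue
        try:
            curve = _eval(family, params.free_values, x)
        except ValueError:
            continue
        if np.min(curve) > floor:
            return params
    raise ValueError(
        f"could not draw valid {family.value} parameters in {_MAX_REDRAWS} tries; "
        "check parameter_distributions"
    )


def simulate_met(config: MetSimConfig) -> SimulatedMet:
    """Simulate an RCBD multi-environment trial under one response family.

    Each plot value is ``f_i(x*_j) + block_k + e_ijk`` with latent
    environment quality x*, block effects ~ N(0, (noise_sd/2)^2) and plot
    error ~ N(0, noise_sd^2).  The generating parameters are returned so
    recovery can be checked downstream.
    """
    rng = np.random.default_rng(config.seed)
    x = config.env_quality
    # positive-response families must stay clear of zero despite plot noise
    floor = (
        4.0 * config.noise_sd
        if config.family in _POSITIVE_FAMILIES
        else -np.inf
    )
    params = [
        _draw_params(config.family, config.parameter_distributions, rng, x, floor)
        for _ in range(config.n_genotypes)
    ]
    expected = np.vstack(
        [_eval(p.family, p.free_values, x) for p in params]
    )  # (G, E)
    blocks = rng.normal(0.0, config.noise_sd / 2.0, size=config.n_blocks)

    g_idx, e_idx, b_idx = np.meshgrid(
        np.arange(config.n_genotypes),
        np.arange(config.n_environments),
        np.arange(config.n_blocks),
        indexing="ij",
    )
    g_idx, e_idx, b_idx = g_idx.ravel(), e_idx.ravel(), b_idx.ravel()
    noise = rng.normal(0.0, config.noise_sd, size=g_idx.size)
    values = expected[g_idx, e_idx] + blocks[b_idx] + noise

    records = pd.DataFrame(
        {
            "year": config.year,
            "environment": [f"E{j+1:02d}" for j in e_idx],
            "block": [f"B{k+1}" for k in b_idx],
            "genotype": [f"G{i+1:02d}" for i in g_idx],
            "value": values,
        }
    )
    return SimulatedMet(
        records=records, true_params=params,
        env_quality=x.copy(), config=config,
    )


# ---------------------------------------------------------------------------
# DH population
# ---------------------------------------------------------------------------

@dataclass
class DhSimConfig:
    """Settings for a simulated DH biparental mapping population.

    Defaults mirror a classic barley mapping panel: 150 lines, 223
    markers over 7 chromosomes (37/37/31/33/29/22/34), 150 cM per
    chromosome, three planted yield QTL whose effects grow with
    environment quality, and line-mean heritability 0.7 at the median
    environment.
    """

    chrom_marker_counts: Sequence[int] = (37, 37, 31, 33, 29, 22, 34)
    chrom_lengths_cM: Optional[Sequence[float]] = None
    n_lines: int = 150
    qtl: Sequence[Tuple[int, float, float]] = (
        (15, 0.25, 0.05),   # (marker index, base effect, per-index scaling)
        (100, 0.15, 0.08),
        (170, 0.0, 0.06),
    )
    h2: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_lengths_cM is None:
            self.chrom_lengths_cM = [150.0] * len(self.chrom_marker_counts)
        if len(self.chrom_lengths_cM) != len(self.chrom_marker_counts):
            raise ValueError("chromosome lengths/counts mismatch")
        n_markers = sum(self.chrom_marker_counts)
        for idx, _, _ in self.qtl:
            if not 0 <= idx < n_markers:
                raise ValueError(f"QTL marker index {idx} out of range")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")


def simulate_dh_population(config: DhSimConfig) -> MarkerPanel:
    """Simulate DH line genotypes by meiosis along the marker map.

    Per line and chromosome, the first marker allele is +-1 with equal
    probability and each subsequent marker recombines with probability
    given by Haldane's map function of the adjacent spacing; doubling the
    gamete yields a fully homozygous line.
    """
    rng = np.random.default_rng(config.seed)
    marker_rows = []
    columns = []
    for c, (count, length) in enumerate(
        zip(config.chrom_marker_counts, config.chrom_lengths_cM), start=1
    ):
        pos = (
            np.linspace(0.0, float(length), count)
            if count > 1
            else np.array([0.0])
        )
        rec = haldane(np.diff(pos))
        first = rng.choice((-1, 1), size=config.n_lines)
        chrom = np.empty((config.n_lines, count), dtype=np.int8)
        chrom[:, 0] = first
        for m in range(1, count):
            flip = rng.random(config.n_lines) < rec[m - 1]
            chrom[:, m] = np.where(flip, -chrom[:, m - 1], chrom[:, m - 1])
        columns.append(chrom)
        for m in range(count):
            marker_rows.append(
                {
                    "marker": f"C{c}M{m+1:02d}",
                    "chromosome": c,
                    "position_cM": float(pos[m]),
                }
            )
    genotypes = np.hstack(columns)
    lines = [f"DH{i+1:03d}" for i in range(config.n_lines)]
    return MarkerPanel(
        lines=lines, markers=pd.DataFrame(marker_rows), genotypes=genotypes
    )


@dataclass
class SimulatedDhTrial:
    """Line x environment phenotypes plus the planted QTL truth."""

    table: pd.DataFrame          # lines x environments
    env_quality: np.ndarray
    qtl: Sequence[Tuple[int, float, float]]
    noise_sd: float
    config: DhSimConfig


def simulate_dh_phenotypes(
    panel: MarkerPanel,
    config: DhSimConfig,
    env_quality: Optional[np.ndarray] = None,
    mu: float = 0.0,
) -> SimulatedDhTrial:
    """Simulate line-by-environment phenotypes with environment-scaled QTL.

    ``y_ij = mu + x*_j + sum_q g_iq (base_q + scale_q x*_j) + e_ij``; the
    residual sd is set so that broad-sense heritability across lines
    equals ``config.h2`` at the median environment.  Positive scaling
    coefficients make QTL effects (and between-line variance) grow with
    environment quality.  Defaults to 16 environments with quality 3-7.
    """
    if env_quality is None:
        env_quality = np.linspace(3.0, 7.0, 16)
    env_quality = np.asarray(env_quality, float)
    rng = np.random.default_rng(config.seed + 1)

    G = panel.genotypes.astype(float)
    genetic = np.zeros((panel.n_lines, env_quality.size))
    for idx, base, scale in config.qtl:
        genetic += np.outer(G[:, idx], base + scale * env_quality)

    x_med = float(np.median(env_quality))
    g_med = np.zeros(panel.n_lines)
    for idx, base, scale in config.qtl:
        g_med += G[:, idx] * (base + scale * x_med)
    var_g = float(np.var(g_med))
    if config.h2 >= 1.0:
        if var_g == 0:
            raise ValueError("h2 = 1 requires nonzero genetic variance")
        noise_sd = 0.0
    elif config.h2 <= 0.0:
        raise ValueError("h2 must be positive to scale the residual variance")
    else:
        noise_sd = float(np.sqrt(var_g * (1.0 - config.h2) / config.h2))
        if var_g == 0:
            noise_sd = 1.0  # pure-noise trait; arbitrary unit scale

    values = (
        mu
        + env_quality[None, :]
        + genetic
        + rng.normal(0.0, noise_sd, size=genetic.shape)
    )
    table = pd.DataFrame(
        values,
        index=list(panel.lines),
        columns=[f"E{j+1:02d}" for j in range(env_quality.size)],
    )
    return SimulatedDhTrial(
        table=table, env_quality=env_quality.copy(), qtl=tuple(config.qtl),
        noise_sd=noise_sd, config=config,
    )
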