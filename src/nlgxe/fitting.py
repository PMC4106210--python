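"""Per-genotype response-curve estimation against the environmental index.

The environmental index of environment *j* is the mean trait value of all
genotypes tested there; each genotype's cell means are then regressed on
that index under one of the six response families.  LINEAR, PARABOLA and
RECIP_QUAD are fitted in closed form (ordinary / polynomial least squares,
the latter on the reciprocal scale).  CAUCHY, LOGISTIC and NORMAL use the
natural linearizing transform of each family to initialize, followed by
damped (trust-region) non-linear least squares on the original scale with
the analytic Jacobian:

* CAUCHY — ``1/y`` is quadratic in x; the quadratic coefficients give
  ``x_max = -b/(2c)``, then ``k`` and ``r``.
* LOGISTIC — for a fixed base ``c``, ``1/y`` is linear in ``c**x``; the
  base is profiled over a log-spaced grid and refined by bounded scalar
  minimization before the full refinement.
* NORMAL — ``log y`` is quadratic in x with a negative leading
  coefficient.

If an initializing transform is infeasible (e.g. the reciprocal quadratic
opens downward), a seeded multi-start over the observed x-range takes over.
Refinement never increases the residual sum of squares relative to its
initializer, and reported ``rss`` is always on the original trait scale so
families are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .families import (
    FREE_PARAMS,
    Family,
    ResponseParams,
    _eval,
    _jac,
)

__all__ = [
    "CellMeansTable",
    "GenotypeFit",
    "FitSweep",
    "DegenerateIndexError",
    "NonPositiveResponseError",
    "compute_environment_index",
    "fit_linear",
    "fit_parabola",
    "fit_reciprocal_quadratic",
    "fit_cauchy",
    "fit_logistic",
    "fit_normal",
    "fit_genotype",
    "fit_all_genotypes",
]

logger = logging.getLogger("nlgxe")

# convergence contract for the non-linear refinements
_GTOL = 1e-8
_XTOL = 1e-10
_FTOL = 1e-12
_MAX_NFEV = 500
_N_MULTISTART = 20

#: families whose responses must be strictly positive to be fitted
_POSITIVE_FAMILIES = frozenset(
    {Family.RECIP_QUAD, Family.CAUCHY, Family.LOGISTIC, Family.NORMAL}
)


class DegenerateIndexError(ValueError):
    """Environmental index carries no variation (or too few environments)."""


class NonPositiveResponseError(ValueError):
    """A family requiring y > 0 was given a non-positive response."""


@dataclass
class CellMeansTable:
    """Genotype x environment table of trait cell means.

    ``means[i, j]`` is the mean (over blocks) of genotype i in environment
    j; missing cells are NaN.  ``env_index[j]`` is the mean of column j
    over the genotypes observed there — the environmental index used as
    the regressor by every fitting routine.
    """

    genotypes: List[str]
    environments: List[str]
    means: np.ndarray
    env_index: np.ndarray
    n_reps: int = 1

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.env_index = np.asarray(self.env_index, float)
        if self.means.shape != (len(self.genotypes), len(self.environments)):
            raise ValueError("means shape does not match genotype/environment labels")
        if self.env_index.shape != (len(self.environments),):
            raise ValueError("env_index length does not match environments")

    @classmethod
    def from_means(
        cls,
        means,
        genotypes: Optional[Sequence[str]] = None,
        environments: Optional[Sequence[str]] = None,
        n_reps: int = 1,
    ) -> "CellMeansTable":
        """Build directly from a cell-means matrix; the environmental index
        is the per-column mean over non-missing genotypes."""
        means = np.asarray(means, float)
        g, e = means.shape
        genotypes = list(genotypes) if genotypes is not None else [f"G{i+1:02d}" for i in range(g)]
        environments = (
            list(environments) if environments is not None else [f"E{j+1:02d}" for j in range(e)]
        )
        with np.errstate(invalid="ignore"):
            env_index = np.nanmean(means, axis=0)
        return cls(genotypes, environments, means, env_index, n_reps=n_reps)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.means).any()

    def row(self, genotype: str) -> int:
        try:
            return self.genotypes.index(genotype)
        except ValueError:
            raise KeyError(f"unknown genotype {genotype!r}") from None

    def xy(self, genotype: str) -> Tuple[np.ndarray, np.ndarray]:
        """(env_index, cell mean) pairs for one genotype, missing cells dropped."""
        y = self.means[self.row(genotype)]
        keep = ~np.isnan(y)
        return self.env_index[keep], y[keep]


@dataclass
class GenotypeFit:
    """One genotype's fitted response curve."""

    genotype: str
    params: ResponseParams
    rss: float
    n_obs: int
    converged: bool
    n_params: int
    rss_init: Optional[float] = None  # rss of the initializer, for diagnostics

    def predict(self, x) -> np.ndarray:
        return _eval(self.params.family, self.params.free_values, np.asarray(x, float))


@dataclass
class FitSweep:
    """Result of fitting one family across all genotypes of a table."""

    family: Family
    fits: List[GenotypeFit]
    skipped: Dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.fits)

    def by_genotype(self) -> Dict[str, GenotypeFit]:
        return {f.genotype: f for f in self.fits}


# ---------------------------------------------------------------------------
# environmental index
# ---------------------------------------------------------------------------

def compute_environment_index(
    raw: Union[pd.DataFrame, CellMeansTable]
) -> CellMeansTable:
    """Aggregate replicated trial records to cell means and derive the
    environmental index as the per-environment mean over genotypes.

    ``raw`` is either a long-format record frame (columns environment,
    genotype, value, optionally block/year — a multi-year frame must be
    split by year first) or an existing :class:`CellMeansTable` whose
    index is recomputed from its means.  Requires at least 2 genotypes and
    3 environments; genotypes observed in no environment are dropped with
    a warning.
    """
    if isinstance(raw, CellMeansTable):
        table = raw
        keep = ~np.all(np.isnan(table.means), axis=1)
        if not keep.all():
            dropped = [g for g, k in zip(table.genotypes, keep) if not k]
            logger.warning("dropping genotypes with no observations: %s", dropped)
        means = table.means[keep]
        return CellMeansTable.from_means(
            means,
            [g for g, k in zip(table.genotypes, keep) if k],
            table.environments,
            n_reps=table.n_reps,
        )

    df = raw.copy()
    df.columns = [str(c).lower() for c in df.columns]
    for col in ("environment", "genotype", "value"):
        if col not in df.columns:
            raise ValueError(f"trial records need a {col!r} column")
    if "year" in df.columns and df["year"].nunique() > 1:
        raise ValueError(
            "records span multiple years; stratify by year before indexing"
        )
    cell = df.groupby(["genotype", "environment"], sort=True)["value"].mean()
    wide = cell.unstack("environment")
    if wide.shape[1] < 3:
        raise DegenerateIndexError(
            f"need >= 3 environments, got {wide.shape[1]}"
        )
    if wide.shape[0] < 2:
        raise ValueError(f"need >= 2 genotypes, got {wide.shape[0]}")
    counts = df.groupby(["genotype", "environment"])["value"].size()
    n_reps = int(counts.mode().iloc[0])
    return CellMeansTable.from_means(
        wide.to_numpy(float),
        [str(g) for g in wide.index],
        [str(e) for e in wide.columns],
        n_reps=n_reps,
    )


# ---------------------------------------------------------------------------
# closed-form fits
# ---------------------------------------------------------------------------

def _require_obs(x: np.ndarray, genotype: str, n_min: int) -> None:
    if x.size < n_min:
        raise ValueError(
            f"genotype {genotype!r}: needs >= {n_min} environments, has {x.size}"
        )


def _polyfit(x: np.ndarray, z: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares polynomial coefficients in ascending order."""
    V = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(V) < degree + 1:
        raise DegenerateIndexError(
            f"design is rank-deficient: fewer than {degree + 1} distinct index values"
        )
    coef, *_ = np.linalg.lstsq(V, z, rcond=None)
    return coef


def fit_linear(table: CellMeansTable, genotype: str) -> GenotypeFit:
    """Joint-regression (Finlay-Wilkinson) fit y = a + b x for one genotype."""
    x, y = table.xy(genotype)
    _require_obs(x, genotype, 3)
    if np.ptp(x) == 0:
        raise DegenerateIndexError("environmental index has zero variance")
    a, b = _polyfit(x, y, 1)
    resid = y - (a + b * x)
    params = ResponseParams(Family.LINEAR, a=a, b=b)
    return GenotypeFit(genotype, params, float(resid @ resid), x.size, True, 2)


def fit_parabola(table: CellMeansTable, genotype: str) -> GenotypeFit:
    x, y = table.xy(genotype)
    _require_obs(x, genotype, 4)
    a, b, c = _polyfit(x, y, 2)
    resid = y - (a + (b + c * x) * x)
    params = ResponseParams(Family.PARABOLA, a=a, b=b, c=c)
    return GenotypeFit(genotype, params, float(resid @ resid), x.size, True, 3)


def _require_positive(y: np.ndarray, genotype: str, family: Family) -> None:
    if np.any(y <= 0):
        raise NonPositiveResponseError(
            f"genotype {genotype!r}: {family.value} requires strictly positive "
            f"responses; found min {y.min():g}"
        )


def fit_reciprocal_quadratic(table: CellMeansTable, genotype: str) -> GenotypeFit:
    """Fit 1/y = a + b x + c x^2 by OLS on the reciprocal scale.

    Coefficients are the transform-scale least-squares solution; ``rss``
    is reported on the original trait scale for comparability (the
    transform-scale rss is kept in ``fit.transform_rss``).
    """
    x, y = table.xy(genotype)
    _require_obs(x, genotype, 4)
    _require_positive(y, genotype, Family.RECIP_QUAD)
    a, b, c = _polyfit(x, 1.0 / y, 2)
    den = a + (b + c * x) * x
    t_resid = 1.0 / y - den
    resid = y - 1.0 / den
    params = ResponseParams(Family.RECIP_QUAD, a=a, b=b, c=c)
    fit = GenotypeFit(genotype, params, float(resid @ resid), x.size, True, 3)
    fit.transform_rss = float(t_resid @ t_resid)
    return fit


# ---------------------------------------------------------------------------
# non-linear refinement machinery
# ---------------------------------------------------------------------------

def _rss(family: Family, theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    try:
        r = _eval(family, theta, x) - y
    except ValueError:
        return np.inf
    return float(r @ r)


def _refine(
    family: Family,
    theta0: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    bounds: Tuple[np.ndarray, np.ndarray],
    max_nfev: int = _MAX_NFEV,
) -> Tuple[np.ndarray, float, bool]:
    """Damped least squares from theta0; never returns a worse rss."""
    theta0 = np.clip(theta0, bounds[0], bounds[1])
    rss0 = _rss(family, theta0, x, y)

    def fun(t):
        return _eval(family, t, x) - y

    def jac(t):
        return _jac(family, t, x)

    try:
        # trust-region internals can probe negative discriminants; the
        # solver handles those itself, so silence the numpy warnings
        with np.errstate(invalid="ignore", divide="ignore"):
            res = least_squares(
                fun, theta0, jac=jac, bounds=bounds, method="trf",
                xtol=_XTOL, gtol=_GTOL, ftol=_FTOL, max_nfev=max_nfev,
            )
    except ValueError:
        return theta0, rss0, False
    rss1 = float(res.fun @ res.fun)
    if rss1 <= rss0:
        return res.x, rss1, bool(res.success)
    return theta0, rss0, False  # monotone acceptance


def _multistart(
    family: Family,
    x: np.ndarray,
    y: np.ndarray,
    bounds: Tuple[np.ndarray, np.ndarray],
    seed: int,
) -> Tuple[np.ndarray, float, bool]:
    """20 seeded random starts over the observed data range; best rss wins,
    ties broken by smaller scale parameter r.  Each start gets a cheap
    refinement pass; only the winner is polished at full tolerance."""
    rng = np.random.default_rng(seed)
    span = max(np.ptp(x), 1e-6)
    best = None
    for _ in range(_N_MULTISTART):
        x_max0 = rng.uniform(x.min(), x.max())
        r0 = rng.uniform(0.1, 2.0) * span
        peak0 = rng.uniform(0.5, 2.0) * y.max()
        if family is Family.CAUCHY:
            theta0 = np.array([peak0, x_max0, r0])
        else:  # NORMAL: k is the density scale, not the peak
            theta0 = np.array([peak0 * _SQRT_2PI_ * r0, x_max0, r0])
        theta, rss, _ = _refine(family, theta0, x, y, bounds, max_nfev=30)
        key = (rss, theta[2])
        if best is None or key < best[0]:
            best = (key, theta)
    return _refine(family, best[1], x, y, bounds)


_SQRT_2PI_ = float(np.sqrt(2.0 * np.pi))
_TINY = 1e-10
_INF = np.inf


def _degenerate_fit(
    genotype: str, family: Family, x: np.ndarray, y: np.ndarray
) -> GenotypeFit:
    """Flat response: scale parameters unidentifiable, flagged unconverged."""
    span = max(np.ptp(x), 1.0)
    ybar = float(np.mean(y))
    if family is Family.CAUCHY:
        theta = np.array([ybar, float(np.mean(x)), span])
    else:
        theta = np.array([ybar * _SQRT_2PI_ * span, float(np.mean(x)), span])
    params = ResponseParams.from_free(family, theta)
    return GenotypeFit(
        genotype, params, _rss(family, theta, x, y), x.size, False, 3
    )


def fit_cauchy(table: CellMeansTable, genotype: str, seed: int = 0) -> GenotypeFit:
    """Fit y = k / (1 + ((x - x_max)/r)^2).

    Initialized from the reciprocal-scale quadratic (1/y is quadratic in x
    for an exact Cauchy curve), refined on the original scale.  If the
    reciprocal quadratic opens downward the seeded multi-start takes over.
    """
    x, y = table.xy(genotype)
    _require_obs(x, genotype, 4)
    _require_positive(y, genotype, Family.CAUCHY)
    if np.ptp(y) == 0:
        return _degenerate_fit(genotype, Family.CAUCHY, x, y)

    bounds = (np.array([_TINY, -_INF, _TINY]), np.array([_INF, _INF, _INF]))
    theta0 = None
    try:
        qa, qb, qc = _polyfit(x, 1.0 / y, 2)
    except DegenerateIndexError:
        qc = -1.0
    if qc > 0:
        x_max0 = -qb / (2.0 * qc)
        inv_k = qa - qb * qb / (4.0 * qc)  # 1/k
        if inv_k > 0:
            k0 = 1.0 / inv_k
            theta0 = np.array([k0, x_max0, np.sqrt(1.0 / (k0 * qc))])
    if theta0 is not None:
        theta, rss, ok = _refine(Family.CAUCHY, theta0, x, y, bounds)
        rss_init = _rss(Family.CAUCHY, np.clip(theta0, *bounds), x, y)
    else:
        theta, rss, ok = _multistart(Family.CAUCHY, x, y, bounds, seed)
        rss_init = None
    fit = GenotypeFit(
        genotype, ResponseParams.from_free(Family.CAUCHY, theta), rss,
        x.size, ok, 3, rss_init=rss_init,
    )
    return fit


def fit_normal(table: CellMeansTable, genotype: str, seed: int = 0) -> GenotypeFit:
    """Fit the Gaussian response y = k/sqrt(2 pi r^2) exp(-(x-x_max)^2/(2 r^2)).

    ``log y`` is quadratic in x with negative curvature; that quadratic
    initializes (k, x_max, r) before the original-scale refinement.
    """
    x, y = table.xy(genotype)
    _require_obs(x, genotype, 4)
    _require_positive(y, genotype, Family.NORMAL)
    if np.ptp(y) == 0:
        return _degenerate_fit(genotype, Family.NORMAL, x, y)
    if len(np.unique(x)) < 3:
        raise DegenerateIndexError("NORMAL needs >= 3 distinct index values")

    bounds = (np.array([_TINY, -_INF, _TINY]), np.array([_INF, _INF, _INF]))
    c0, c1, c2 = _polyfit(x, np.log(y), 2)
    theta0 = None
    if c2 < 0:
        r2 = -1.0 / (2.0 * c2)
        x_max0 = c1 * r2
        k0 = _SQRT_2PI_ * np.sqrt(r2) * np.exp(c0 + x_max0 * x_max0 / (2.0 * r2))
        theta0 = np.array([k0, x_max0, np.sqrt(r2)])
    if theta0 is not None and np.all(np.isfinite(theta0)):
        theta, rss, ok = _refine(Family.NORMAL, theta0, x, y, bounds)
        rss_init = _rss(Family.NORMAL, np.clip(theta0, *bounds), x, y)
    else:
        theta, rss, ok = _multistart(Family.NORMAL, x, y, bounds, seed)
        rss_init = None
    return GenotypeFit(
        genotype, ResponseParams.from_free(Family.NORMAL, theta), rss,
        x.size, ok, 3, rss_init=rss_init,
    )


_LOGISTIC_C_GRID = np.geomspace(0.01, 0.99, 50)


def _logistic_profile(x: np.ndarray, z: np.ndarray, c: float):
    """OLS of z = 1/y on (1, c**x); returns (a, b, transform rss)."""
    u = np.power(c, x)
    X = np.column_stack([np.ones_like(x), u])
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ coef
    return coef[0], coef[1], float(resid @ resid)


def fit_logistic(table: CellMeansTable, genotype: str, seed: int = 0) -> GenotypeFit:
    """Fit y = 1/(a + b c^x) with a > 0, b >= 0, 0 < c < 1.

    For fixed c the model is linear in 1/y; c is profiled over a log-spaced
    grid, refined by bounded scalar minimization, then the full parameter
    set is refined by original-scale non-linear least squares.  A best
    profile slope b < 0 (monotone-decreasing response) violates the family
    constraints and is reported unconverged with b projected to 0.
    """
    x, y = table.xy(genotype)
    _require_obs(x, genotype, 4)
    _require_positive(y, genotype, Family.LOGISTIC)
    z = 1.0 / y

    prof = [(_logistic_profile(x, z, c), c) for c in _LOGISTIC_C_GRID]
    (a0, b0, t_rss), c_best = min(prof, key=lambda t: t[0][2])
    i = int(np.argmin([p[0][2] for p in prof]))
    lo = _LOGISTIC_C_GRID[max(i - 1, 0)]
    hi = _LOGISTIC_C_GRID[min(i + 1, len(_LOGISTIC_C_GRID) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda c: _logistic_profile(x, z, c)[2],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        c_best = float(res.x)
        a0, b0, t_rss = _logistic_profile(x, z, c_best)

    constrained = b0 < 0 or a0 <= 0
    a0 = max(a0, _TINY)
    b0 = max(b0, 0.0)
    eps_c = 1e-9
    bounds = (
        np.array([_TINY, 0.0, eps_c]),
        np.array([_INF, _INF, 1.0 - eps_c]),
    )
    theta0 = np.array([a0, b0, min(max(c_best, eps_c), 1.0 - eps_c)])
    theta, rss, ok = _refine(Family.LOGISTIC, theta0, x, y, bounds)
    rss_init = _rss(Family.LOGISTIC, np.clip(theta0, *bounds), x, y)
    if constrained:
        ok = False
    # b on the zero boundary is a flat curve, not a converged logistic shape
    params = ResponseParams(
        Family.LOGISTIC, a=theta[0], b=theta[1],
        c=min(max(theta[2], eps_c), 1.0 - eps_c),
    )
    return GenotypeFit(genotype, params, rss, x.size, ok, 3, rss_init=rss_init)


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------

_FITTERS = {
    Family.LINEAR: fit_linear,
    Family.PARABOLA: fit_parabola,
    Family.RECIP_QUAD: fit_reciprocal_quadratic,
    Family.CAUCHY: fit_cauchy,
    Family.LOGISTIC: fit_logistic,
    Family.NORMAL: fit_normal,
}

_SEEDED = {Family.CAUCHY, Family.LOGISTIC, Family.NORMAL}


def fit_genotype(
    table: CellMeansTable, genotype: str, family: Family, seed: int = 0
) -> GenotypeFit:
    """Fit one genotype under one family (dispatch over the six fitters)."""
    family = Family.coerce(family)
    fitter = _FITTERS[family]
    if family in _SEEDED:
        return fitter(table, genotype, seed=seed)
    return fitter(table, genotype)


def fit_all_genotypes(
    table: CellMeansTable, family: Family, seed: int = 0
) -> FitSweep:
    """Fit every genotype of the table under one family.

    Genotypes failing a family precondition (too few environments,
    non-positive responses, degenerate design) are skipped and listed with
    the reason.  Multi-start draws are seeded per genotype from ``seed``,
    so the sweep is deterministic.
    """
    family = Family.coerce(family)
    fits: List[GenotypeFit] = []
    skipped: Dict[str, str] = {}
    for i, genotype in enumerate(table.genotypes):
        try:
            fits.append(
                fit_genotype(table, genotype, family, seed=int(seed) + i)
            )
        except (ValueError, KeyError) as exc:
            skipped[genotype] = str(exc)
            logger.warning("skipping %s under %s: %s", genotype, family.value, exc)
    return FitSweep(family=family, fits=fits, skipped=skipped)
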