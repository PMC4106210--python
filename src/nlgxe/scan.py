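"""Environment-stratified marker-effect scans by elastic-net regression.

Marker effects of a doubled-haploid (DH) biparental panel are estimated at
three representative environments — poor (minimum environmental index),
average (mean index) and good (maximum index) — to expose QTL-by-
environment interaction as a change in the size, sign or position of
estimated effects along the environmental gradient.

Per-line phenotypes at the three evaluation points come from each line's
fitted linear reaction norm (``a + b * x_class``), or optionally from the
observed values at the extreme environments.  Effects are then estimated
by minimizing the elastic-net objective

    (1/2n) ||y - X beta||^2 + lambda * (alpha ||beta||_1
                                        + (1 - alpha)/2 ||beta||^2)

by cyclic coordinate descent with the univariate soft-threshold update,
warm-started along a decreasing log-spaced lambda path from
``lambda_max = max_k |x_k' y| / (n alpha)`` (the smallest penalty at which
every coefficient is zero).  ``alpha = 1`` is the LASSO, ``alpha = 0.5``
the elastic-net compromise used alongside it; lambda is chosen by seeded
k-fold cross-validation (minimum mean squared error).

Markers are coded -1/+1 for the two homozygous DH classes, standardized to
unit variance for the fit, and effects are reported back on the allele
coding scale (trait units per allele substitution).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numba
import numpy as np
import pandas as pd

from .fitting import CellMeansTable, FitSweep, GenotypeFit

__all__ = [
    "EnvClass",
    "MarkerPanel",
    "ElasticNetConfig",
    "EffectScan",
    "representative_phenotypes",
    "elastic_net_fit",
    "kkt_residual",
    "lambda_path",
    "fit_path",
    "genome_scan",
]

logger = logging.getLogger("nlgxe")

_SWEEP_TOL = 1e-9       # max coefficient change per sweep
_KKT_TOL = 1e-9         # stationarity residual at convergence
_MAX_SWEEPS = 10_000


class EnvClass(str, enum.Enum):
    POOR = "poor"
    AVERAGE = "average"
    GOOD = "good"


@dataclass
class MarkerPanel:
    """Line x marker genotypes of a DH biparental population.

    ``genotypes`` is coded -1/+1 for the two homozygous classes;
    ``markers`` carries marker, chromosome and position (cM) columns with
    positions non-decreasing within each chromosome.
    """

    lines: List[str]
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.shape != (len(self.lines), len(self.markers)):
            raise ValueError("genotype matrix shape mismatch")
        if not np.isin(self.genotypes, (-1, 1)).all():
            raise ValueError("DH genotypes must be coded -1/+1")
        for col in ("marker", "chromosome", "position_cM"):
            if col not in self.markers.columns:
                raise ValueError(f"marker map needs column {col!r}")
        for _, grp in self.markers.groupby("chromosome", sort=False):
            if not grp["position_cM"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within chromosome")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class ElasticNetConfig:
    """Settings of one penalized scan.

    ``alpha`` mixes the LASSO (1) and ridge (0) penalties; ``lambda_grid``
    overrides the automatic path when given (positive, decreasing);
    ``n_lambda`` and the fixed ratio 1e-3 shape the automatic path.
    """

    alpha: float = 0.5
    lambda_grid: Optional[np.ndarray] = None
    n_lambda: int = 50
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, float)
            if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
                raise ValueError("lambda_grid must be positive and decreasing")
            self.lambda_grid = grid


@dataclass
class EffectScan:
    """Per-marker effect estimates at one representative environment."""

    environment_class: EnvClass
    alpha: float
    effects: np.ndarray          # allele-coding scale, trait units per substitution
    n_nonzero: int
    lambda_selected: float
    intercept: float = 0.0


# ---------------------------------------------------------------------------
# representative phenotypes
# ---------------------------------------------------------------------------

def representative_phenotypes(
    table: CellMeansTable,
    fits: Sequence[GenotypeFit] | FitSweep,
    mode: str = "fitted",
) -> pd.DataFrame:
    """Per-line trait values at the poor/average/good index points.

    ``mode='fitted'`` (default) evaluates each line's linear fit at the
    minimum, mean and maximum of the environmental index.  ``mode=
    'observed'`` takes the observed cell means at the extreme-index
    environments and the across-environment mean for the average class.
    """
    fit_list = list(fits.fits) if isinstance(fits, FitSweep) else list(fits)
    by_geno = {f.genotype: f for f in fit_list}
    missing = [g for g in table.genotypes if g not in by_geno]
    if missing:
        raise ValueError(f"no fit for lines: {missing}")

    x = table.env_index
    points = {
        EnvClass.POOR: float(x.min()),
        EnvClass.AVERAGE: float(x.mean()),
        EnvClass.GOOD: float(x.max()),
    }
    if mode == "fitted":
        data = {
            cls.value: [
                float(by_geno[g].predict(pt)) for g in table.genotypes
            ]
            for cls, pt in points.items()
        }
    elif mode == "observed":
        j_poor, j_good = int(np.argmin(x)), int(np.argmax(x))
        data = {
            EnvClass.POOR.value: table.means[:, j_poor],
            EnvClass.AVERAGE.value: np.nanmean(table.means, axis=1),
            EnvClass.GOOD.value: table.means[:, j_good],
        }
    else:
        raise ValueError(f"mode must be 'fitted' or 'observed', got {mode!r}")
    return pd.DataFrame(data, index=list(table.genotypes))


# ---------------------------------------------------------------------------
# coordinate descent
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _cd_kernel(X, y, lam, alpha, beta, max_sweeps, sweep_tol, kkt_tol):  # pragma: no cover
    n, p = X.shape
    r = y - X @ beta
    nrm = np.empty(p)
    for k in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, k] * X[i, k]
        nrm[k] = s / n
    thr = lam * alpha
    ridge = lam * (1.0 - alpha)
    sweeps = 0
    while sweeps < max_sweeps:
        # one full cyclic sweep
        max_delta = 0.0
        for k in range(p):
            if nrm[k] == 0.0:
                continue
            bk = beta[k]
            rho = 0.0
            for i in range(n):
                rho += X[i, k] * r[i]
            rho = rho / n + nrm[k] * bk
            if rho > thr:
                bnew = (rho - thr) / (nrm[k] + ridge)
            elif rho < -thr:
                bnew = (rho + thr) / (nrm[k] + ridge)
            else:
                bnew = 0.0
            d = bnew - bk
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, k] * d
                beta[k] = bnew
                if abs(d) > max_delta:
                    max_delta = abs(d)
        sweeps += 1
        # active-set sweeps on the nonzero coefficients
        while max_delta >= sweep_tol and sweeps < max_sweeps:
            max_delta = 0.0
            for k in range(p):
                if beta[k] == 0.0 or nrm[k] == 0.0:
                    continue
                bk = beta[k]
                rho = 0.0
                for i in range(n):
                    rho += X[i, k] * r[i]
                rho = rho / n + nrm[k] * bk
                if rho > thr:
                    bnew = (rho - thr) / (nrm[k] + ridge)
                elif rho < -thr:
                    bnew = (rho + thr) / (nrm[k] + ridge)
                else:
                    bnew = 0.0
                d = bnew - bk
                if d != 0.0:
                    for i in range(n):
                        r[i] -= X[i, k] * d
                    beta[k] = bnew
                    if abs(d) > max_delta:
                        max_delta = abs(d)
            sweeps += 1
        # stationarity check over all coordinates
        viol = 0.0
        for k in range(p):
            if nrm[k] == 0.0:
                continue
            g = 0.0
            for i in range(n):
                g += X[i, k] * r[i]
            g /= n
            if beta[k] == 0.0:
                v = abs(g) - thr
                if v < 0.0:
                    v = 0.0
            else:
                sgn = 1.0 if beta[k] > 0.0 else -1.0
                v = abs(g - ridge * beta[k] - thr * sgn)
            if v > viol:
                viol = v
        if viol <= kkt_tol:
            break
    return beta


def _check_standardized(X: np.ndarray) -> None:
    mu = X.mean(axis=0)
    var = X.var(axis=0)
    if np.any(np.abs(mu) > 1e-8) or np.any(np.abs(var - 1.0) > 1e-6):
        raise ValueError("X columns must be standardized (mean 0, variance 1)")


def elastic_net_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    beta0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Elastic-net coefficients at one penalty by cyclic coordinate descent.

    ``X`` must have standardized columns (mean 0, unit variance) and ``y``
    must be centered; at convergence the Karush-Kuhn-Tucker stationarity
    conditions hold to 1e-7 (checked by :func:`kkt_residual`).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes are inconsistent")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    _check_standardized(X)
    Xf = np.asfortranarray(X)
    if beta0 is not None:
        beta = np.array(beta0, float)
    else:
        beta = np.zeros(X.shape[1])
        # warm-start down a short internal path: a cold start at a small
        # penalty converges very slowly when p >> n
        if lam > 0 and alpha > 0:
            lam_max = float(np.max(np.abs(X.T @ y)) / (X.shape[0] * alpha))
            if lam < lam_max:
                for step in np.geomspace(lam_max, lam, 8)[:-1]:
                    beta = _cd_kernel(
                        Xf, y, float(step), float(alpha), beta,
                        _MAX_SWEEPS, 1e-6, 1e-6,
                    )
    return _cd_kernel(
        Xf, y, float(lam), float(alpha), beta,
        _MAX_SWEEPS, _SWEEP_TOL, _KKT_TOL,
    )


def kkt_residual(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, alpha: float, lam: float
) -> float:
    """Max violation of the elastic-net stationarity conditions.

    For zero coefficients ``|x_k'(y - X beta)/n| <= lam*alpha``; for
    nonzero ones the subgradient equality must hold with the sign of the
    coefficient.
    """
    n = X.shape[0]
    g = X.T @ (y - X @ beta) / n
    thr = lam * alpha
    ridge = lam * (1.0 - alpha)
    zero = beta == 0
    viol_zero = np.maximum(np.abs(g[zero]) - thr, 0.0)
    viol_nz = np.abs(g[~zero] - ridge * beta[~zero] - thr * np.sign(beta[~zero]))
    pieces = np.concatenate([viol_zero, viol_nz])
    return float(pieces.max()) if pieces.size else 0.0


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    ceiling: float = 1e3,
) -> np.ndarray:
    """Decreasing log-spaced penalty grid starting at the all-zero solution.

    ``lambda_max = max_k |x_k' y| / (n * alpha)`` and the grid descends to
    ``lambda_max * 1e-3``.  For ``alpha = 0`` (pure ridge) lambda_max is
    unbounded; the configured ``ceiling`` is used instead.
    """
    n = X.shape[0]
    if alpha > 0:
        lam_max = float(np.max(np.abs(X.T @ y)) / (n * alpha))
        if lam_max <= 0:
            lam_max = 1e-3
    else:
        lam_max = ceiling
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    df_max: Optional[int] = None,
    sweep_tol: float = _SWEEP_TOL,
    kkt_tol: float = _KKT_TOL,
) -> np.ndarray:
    """Warm-started coefficient path, one row per lambda (decreasing).

    ``df_max`` stops the descent once the active set exceeds that size
    (the saturated tail of a p > n path is a gross overfit that would
    never be selected by cross-validation but converges very slowly);
    remaining rows repeat the last computed solution.
    """
    p = X.shape[1]
    Xf = np.asfortranarray(X)
    betas = np.empty((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = _cd_kernel(
            Xf, y, float(lam), float(alpha), beta.copy(),
            _MAX_SWEEPS, sweep_tol, kkt_tol,
        )
        betas[i] = beta
        if df_max is not None and np.count_nonzero(beta) > df_max:
            betas[i + 1 :] = beta
            break
    return betas


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def _standardize_cols(G: np.ndarray):
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    ok = sd > 0
    X = np.zeros_like(G, dtype=float)
    X[:, ok] = (G[:, ok] - mu[ok]) / sd[ok]
    return X, mu, sd, ok


def _cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
) -> int:
    """Index of the minimum cross-validated MSE lambda (seeded folds)."""
    n = X.shape[0]
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    mse = np.zeros(len(lambdas))
    for val in folds:
        mask = np.ones(n, bool)
        mask[val] = False
        Xtr_raw, ytr_raw = X[mask], y[mask]
        # re-standardize within the training fold
        mu = Xtr_raw.mean(axis=0)
        sd = Xtr_raw.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr_raw - mu) / sd
        ybar = ytr_raw.mean()
        ytr = ytr_raw - ybar
        betas = fit_path(
            Xtr, ytr, alpha, lambdas,
            df_max=int(0.6 * Xtr.shape[0]), sweep_tol=1e-6, kkt_tol=1e-6,
        )
        Xval = (X[val] - mu) / sd
        pred = Xval @ betas.T + ybar
        mse += ((pred - y[val][:, None]) ** 2).sum(axis=0)
    mse /= n
    return int(np.argmin(mse))


def genome_scan(
    panel: MarkerPanel,
    phenotypes: pd.DataFrame,
    config: ElasticNetConfig,
) -> Dict[EnvClass, EffectScan]:
    """Marker-effect scan at the poor/average/good evaluation points.

    ``phenotypes`` is the frame produced by
    :func:`representative_phenotypes` (index = line labels, columns poor/
    average/good).  For each class, the penalty is chosen by seeded
    ``n_folds``-fold cross-validated MSE on the full lambda path, the
    final coefficients are refitted on all lines at the selected penalty,
    and effects are reported on the -1/+1 allele coding scale.
    Deterministic given ``config.seed``.
    """
    if list(phenotypes.index) != list(panel.lines):
        raise ValueError("phenotype lines do not match the panel lines")
    if panel.n_lines < config.n_folds:
        raise ValueError(
            f"{panel.n_lines} lines < {config.n_folds} folds"
        )
    G = panel.genotypes.astype(float)
    X, _, sd, ok = _standardize_cols(G)
    if not ok.all():
        logger.warning("%d monomorphic markers carry no signal", int((~ok).sum()))

    scans: Dict[EnvClass, EffectScan] = {}
    for cls in EnvClass:
        y_raw = phenotypes[cls.value].to_numpy(float)
        ybar = float(y_raw.mean())
        y = y_raw - ybar
        lambdas = (
            config.lambda_grid
            if config.lambda_grid is not None
            else lambda_path(X, y, config.alpha, config.n_lambda)
        )
        rng = np.random.default_rng(config.seed)
        if np.allclose(y, 0):
            i_best, beta = 0, np.zeros(X.shape[1])
            lambdas = np.atleast_1d(lambdas)
        else:
            i_best = _cv_lambda(X, y, config.alpha, lambdas, config.n_folds, rng)
            beta = fit_path(
                X, y, config.alpha, lambdas[: i_best + 1],
                df_max=int(0.8 * X.shape[0]),
            )[-1]
        effects = np.zeros(panel.n_markers)
        effects[ok] = beta[ok] / sd[ok]
        scans[cls] = EffectScan(
            environment_class=cls,
            alpha=config.alpha,
            effects=effects,
            n_nonzero=int(np.count_nonzero(beta)),
            lambda_selected=float(lambdas[i_best]),
            intercept=ybar,
        )
    return scans
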