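"""Parametric response-function families for genotype reaction norms.

A reaction norm describes how one genotype's mean performance (e.g. grain
yield) changes along an environmental gradient.  Here the gradient is the
*environmental index*: the mean performance of all genotypes tested in an
environment, so index and trait share units.  Six families are supported:

=============  ================================================  ===========
family         model                                             parameters
=============  ================================================  ===========
LINEAR         y = a + b x                                       a, b
PARABOLA       y = a + b x + c x**2                              a, b, c
RECIP_QUAD     y = 1 / (a + b x + c x**2)                        a, b, c
CAUCHY         y = k / (1 + ((x - x_max) / r)**2)                k, x_max, r
LOGISTIC       y = 1 / (a + b c**x)          (0 < c < 1)         a, b, c
NORMAL         y = k / sqrt(2 pi r**2)
                 * exp(-(x - x_max)**2 / (2 r**2))               k, x_max, r
=============  ================================================  ===========

LINEAR is the classical joint-regression (Finlay-Wilkinson) model whose
slope ``b`` measures stability: ``b = 1`` average response, ``b > 1`` high
sensitivity, ``b < 1`` high stability.  The non-linear families describe
rise-peak-decline responses over environmental ranges wide enough to span
sub-optimal through super-optimal conditions; near the optimum all of them
are locally quadratic and therefore mutually indistinguishable
(see :func:`quadratic_approx_error`).

For the peaked families (CAUCHY, NORMAL) ``k`` sets the peak scale,
``x_max`` locates the optimum on the index axis and ``r > 0`` is the scale
of the response range.  Standardizing a Cauchy curve to
``x' = (x - x_max)/r`` and ``y' = y/k`` gives the unit form
``y' = 1/(1 + x'**2)`` with peak 1 at ``x' = 0``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "Family",
    "ResponseParams",
    "StandardizedPoint",
    "ResponseDomainError",
    "UnsupportedFamilyError",
    "FREE_PARAMS",
    "evaluate_response",
    "response_gradient",
    "standardize",
    "quadratic_approx_error",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

ArrayLike = Union[float, Sequence[float], np.ndarray]


class Family(str, enum.Enum):
    """The six supported response families."""

    LINEAR = "linear"
    PARABOLA = "parabola"
    RECIP_QUAD = "recip_quad"
    CAUCHY = "cauchy"
    LOGISTIC = "logistic"
    NORMAL = "normal"

    @classmethod
    def coerce(cls, value: "Family | str") -> "Family":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


#: free parameters of each family, in canonical order
FREE_PARAMS = {
    Family.LINEAR: ("a", "b"),
    Family.PARABOLA: ("a", "b", "c"),
    Family.RECIP_QUAD: ("a", "b", "c"),
    Family.CAUCHY: ("k", "x_max", "r"),
    Family.LOGISTIC: ("a", "b", "c"),
    Family.NORMAL: ("k", "x_max", "r"),
}

_ALL_FIELDS = ("a", "b", "c", "k", "x_max", "r")


class ResponseDomainError(ValueError):
    """Model undefined at the requested x (non-positive denominator)."""

    def __init__(self, family: Family, x) -> None:
        self.family = family
        self.x = x
        super().__init__(
            f"{family.value} response undefined at x={x!r}: non-positive denominator"
        )


class UnsupportedFamilyError(ValueError):
    """Operation not defined for the given family."""


@dataclass(frozen=True)
class ResponseParams:
    """Parameter set of one genotype's response curve.

    Only the fields used by ``family`` may be set (see :data:`FREE_PARAMS`);
    the rest must be ``None``.  Scale parameters ``k`` and ``r`` must be
    positive, and the LOGISTIC base must satisfy ``0 < c < 1`` so that the
    curve rises monotonically toward its asymptote ``1/a``.
    """

    family: Family
    a: Optional[float] = None
    b: Optional[float] = None
    c: Optional[float] = None
    k: Optional[float] = None
    x_max: Optional[float] = None
    r: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family.coerce(self.family))
        used = FREE_PARAMS[self.family]
        for name in _ALL_FIELDS:
            val = getattr(self, name)
            if name in used:
                if val is None:
                    raise ValueError(f"{self.family.value} requires parameter {name!r}")
                object.__setattr__(self, name, float(val))
            elif val is not None:
                raise ValueError(
                    f"parameter {name!r} is not used by family {self.family.value}"
                )
        if self.r is not None and not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.k is not None and not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.family is Family.LOGISTIC and not 0.0 < self.c < 1.0:
            raise ValueError(f"LOGISTIC base c must lie in (0, 1), got {self.c}")

    @property
    def n_params(self) -> int:
        return len(FREE_PARAMS[self.family])

    @property
    def free_values(self) -> np.ndarray:
        """Free parameters as an array in canonical order."""
        return np.array([getattr(self, n) for n in FREE_PARAMS[self.family]], float)

    @classmethod
    def from_free(cls, family: Family, theta: Sequence[float]) -> "ResponseParams":
        family = Family.coerce(family)
        names = FREE_PARAMS[family]
        if len(theta) != len(names):
            raise ValueError(f"{family.value} takes {len(names)} parameters")
        return cls(family=family, **dict(zip(names, map(float, theta))))


@dataclass(frozen=True)
class StandardizedPoint:
    """A (x, y) observation in the standardized Cauchy coordinates.

    ``x_std = (x - x_max)/r`` and ``y_std = y/k``; an exact Cauchy curve
    satisfies ``y_std = 1/(1 + x_std**2)``.
    """

    x_std: float
    y_std: float


# ---------------------------------------------------------------------------
# raw evaluation kernels (unvalidated theta vectors; used by the fitters)
# ---------------------------------------------------------------------------

def _eval(family: Family, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    a = theta  # alias, indexed positionally
    if family is Family.LINEAR:
        return a[0] + a[1] * x
    if family is Family.PARABOLA:
        return a[0] + (a[1] + a[2] * x) * x
    if family is Family.RECIP_QUAD:
        den = a[0] + (a[1] + a[2] * x) * x
        if np.any(den <= 0):
            raise ResponseDomainError(family, np.asarray(x)[np.asarray(den) <= 0])
        return 1.0 / den
    if family is Family.CAUCHY:
        u = (x - a[1]) / a[2]
        return a[0] / (1.0 + u * u)
    if family is Family.LOGISTIC:
        den = a[0] + a[1] * np.power(a[2], x)
        if np.any(den <= 0):
            raise ResponseDomainError(family, np.asarray(x)[np.asarray(den) <= 0])
        return 1.0 / den
    if family is Family.NORMAL:
        u = (x - a[1]) / a[2]
        return a[0] / (_SQRT_2PI * a[2]) * np.exp(-0.5 * u * u)
    raise UnsupportedFamilyError(family)


def _jac(family: Family, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Jacobian of the model wrt its free parameters, shape (len(x), p)."""
    x = np.atleast_1d(np.asarray(x, float))
    a = theta
    one = np.ones_like(x)
    if family is Family.LINEAR:
        return np.column_stack([one, x])
    if family is Family.PARABOLA:
        return np.column_stack([one, x, x * x])
    if family is Family.RECIP_QUAD:
        den = a[0] + (a[1] + a[2] * x) * x
        if np.any(den <= 0):
            raise ResponseDomainError(family, x[den <= 0])
        g = -1.0 / (den * den)
        return np.column_stack([g, g * x, g * x * x])
    if family is Family.CAUCHY:
        u = (x - a[1]) / a[2]
        q = 1.0 + u * u
        dk = 1.0 / q
        common = 2.0 * a[0] * u / (a[2] * q * q)
        return np.column_stack([dk, common, common * u])
    if family is Family.LOGISTIC:
        cx = np.power(a[2], x)
        den = a[0] + a[1] * cx
        if np.any(den <= 0):
            raise ResponseDomainError(family, x[den <= 0])
        g = -1.0 / (den * den)
        return np.column_stack([g, g * cx, g * a[1] * x * np.power(a[2], x - 1.0)])
    if family is Family.NORMAL:
        u = (x - a[1]) / a[2]
        y = a[0] / (_SQRT_2PI * a[2]) * np.exp(-0.5 * u * u)
        return np.column_stack([y / a[0], y * u / a[2], y * (u * u - 1.0) / a[2]])
    raise UnsupportedFamilyError(family)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def evaluate_response(params: ResponseParams, x: ArrayLike):
    """Predicted trait value(s) of a genotype's response curve at index x.

    Scalar in, scalar out; array in, array out.  Raises
    :class:`ResponseDomainError` where RECIP_QUAD or LOGISTIC denominators
    are non-positive.
    """
    xa = np.asarray(x, float)
    y = _eval(params.family, params.free_values, xa)
    return float(y) if np.isscalar(x) or xa.ndim == 0 else y


def response_gradient(params: ResponseParams, x: ArrayLike) -> np.ndarray:
    """Partial derivatives of the response wrt the family's free parameters.

    Returns shape ``(n_params,)`` for scalar x, else ``(n_params, len(x))``,
    ordered as :data:`FREE_PARAMS` for the family.
    """
    xa = np.asarray(x, float)
    jac = _jac(params.family, params.free_values, xa)
    return jac[0] if (np.isscalar(x) or xa.ndim == 0) else jac.T


def standardize(params: ResponseParams, x: float, y: float) -> StandardizedPoint:
    """Map a (x, y) observation to the standardized Cauchy coordinates.

    Only defined for a CAUCHY parameter set; returns
    ``x_std = (x - x_max)/r`` and ``y_std = y/k`` so that points on the
    curve itself satisfy ``y_std = 1/(1 + x_std**2)`` with peak 1 at 0.
    """
    if params.family is not Family.CAUCHY:
        raise UnsupportedFamilyError(
            f"standardize is defined for CAUCHY only, got {params.family.value}"
        )
    return StandardizedPoint(
        x_std=(float(x) - params.x_max) / params.r, y_std=float(y) / params.k
    )


def quadratic_approx_error(x_std: ArrayLike):
    """Absolute error of the small-|x'| quadratic approximation of the
    standardized Cauchy curve:

        | 1/(1 + x'^2)  -  (1 - x'^2) |  =  x'^4 / (1 + x'^2)

    It vanishes at the optimum ``x' = 0``, is bounded above by ``x'^4``,
    and grows without bound at extreme standardized environments.
    """
    x2 = np.square(np.asarray(x_std, float))
    err = x2 * x2 / (1.0 + x2)
    return float(err) if np.isscalar(x_std) or err.ndim == 0 else err
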