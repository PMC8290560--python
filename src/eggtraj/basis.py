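"""Normalized Legendre polynomial basis over weeks of lay.

The trajectory models in this package express each animal's genetic and
permanent environmental effect as a linear combination of normalized
Legendre polynomials phi_k evaluated on the week-of-lay grid.  The
normalization phi_k(x) = sqrt((2k+1)/2) * P_k(x) makes the basis
orthonormal under the continuous inner product on [-1, 1]; the week grid is
mapped linearly so that the first week lands on x = -1 and the last on
x = +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as _leg

__all__ = ["LegendreBasis", "legendre_design"]


@dataclass(frozen=True)
class LegendreBasis:
    """Normalized Legendre covariates on an integer week grid.

    Attributes
    ----------
    order
        Maximum polynomial order k_max (order 3 means 4 covariates).
    weeks
        Integer grid of weeks of lay, e.g. 1..24.
    Phi
        ``len(weeks) x (order + 1)`` matrix with Phi[t, k] = phi_k(x(t)).
    """

    order: int
    weeks: np.ndarray
    Phi: np.ndarray = field(repr=False)

    @property
    def n_coeff(self) -> int:
        return self.order + 1

    def row(self, week: int) -> np.ndarray:
        """Covariate row phi(week) for a single week of lay."""
        idx = np.flatnonzero(self.weeks == week)
        if idx.size == 0:
            raise ValueError(f"week {week} is not on the basis grid")
        return self.Phi[idx[0]]


def _scaled_abscissa(weeks: np.ndarray) -> np.ndarray:
    lo, hi = weeks.min(), weeks.max()
    return -1.0 + 2.0 * (weeks - lo) / (hi - lo)


def legendre_design(order: int = 3, weeks=None) -> LegendreBasis:
    """Build the normalized Legendre design for the given week grid.

    Parameters
    ----------
    order
        Polynomial order (>= 0).
    weeks
        Iterable of integer weeks; defaults to 1..24.

    Returns
    -------
    LegendreBasis
        With ``Phi[t, k] = sqrt((2k+1)/2) * P_k(x_t)`` and x mapping the
        week-range endpoints onto -1 and +1.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    if weeks is None:
        weeks = np.arange(1, 25)
    weeks = np.asarray(list(weeks), dtype=int)
    if weeks.size < 2:
        if order > 0:
            raise ValueError("at least two weeks are required for order > 0")
        x = np.zeros(weeks.size)
    else:
        x = _scaled_abscissa(weeks)
    Phi = np.empty((weeks.size, order + 1))
    for k in range(order + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        Phi[:, k] = np.sqrt((2 * k + 1) / 2.0) * _leg.legval(x, coef)
    return LegendreBasis(order=order, weeks=weeks, Phi=Phi)
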