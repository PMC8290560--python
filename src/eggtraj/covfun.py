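"""Covariance functions on the lay trajectory.

A covariance function represents the (co)variance of a longitudinal effect
as a quadratic form Phi * K * Phi' of a small coefficient covariance matrix
K (additive genetic C or permanent environmental P) in a Legendre basis.
This module expands coefficient matrices to weekly (co)variance matrices,
derives weekly heritabilities and genetic/phenotypic correlations, fits
reduced-order covariance functions to an observed covariance matrix, and
summarises variances of partial sums of weekly production.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .basis import LegendreBasis, legendre_design

__all__ = [
    "CovFunction",
    "ResidualSpec",
    "TrajectoryParameters",
    "expand_covariance",
    "trajectory_parameters",
    "fit_covariance_function",
    "partial_sum_covariance",
    "partial_sum_correlation",
    "nearest_pd",
]


@dataclass(frozen=True)
class CovFunction:
    """Coefficient covariance matrix together with its basis.

    ``coeff`` is the (order+1) x (order+1) symmetric covariance matrix of
    random-regression coefficients; ``label`` distinguishes the additive
    genetic ("additive") from the permanent environmental ("pe") function.
    """

    coeff: np.ndarray
    basis: LegendreBasis
    label: str = "additive"

    def __post_init__(self):
        coeff = np.asarray(self.coeff, dtype=float)
        object.__setattr__(self, "coeff", coeff)
        if coeff.ndim != 2 or coeff.shape[0] != coeff.shape[1]:
            raise ValueError("coeff must be square")
        if coeff.shape[0] != self.basis.n_coeff:
            raise ValueError(
                f"coeff is {coeff.shape[0]}x{coeff.shape[0]} but the basis "
                f"has {self.basis.n_coeff} covariates"
            )
        if not np.allclose(coeff, coeff.T, atol=1e-10):
            raise ValueError("coeff must be symmetric")


@dataclass(frozen=True)
class ResidualSpec:
    """Heterogeneous residual variances over contiguous periods of lay.

    ``periods`` is a sequence of (week_lo, week_hi, variance) triples that
    must be contiguous, non-overlapping and cover the whole week grid.
    """

    periods: tuple

    def __post_init__(self):
        periods = tuple((int(lo), int(hi), float(v)) for lo, hi, v in self.periods)
        object.__setattr__(self, "periods", periods)
        if not periods:
            raise ValueError("at least one residual period is required")
        prev_hi = periods[0][0] - 1
        for lo, hi, v in periods:
            if lo != prev_hi + 1:
                raise ValueError("residual periods must be contiguous and ordered")
            if hi < lo:
                raise ValueError(f"period ({lo},{hi}) is empty")
            if v <= 0:
                raise ValueError("residual variances must be positive")
            prev_hi = hi

    @property
    def week_lo(self) -> int:
        return self.periods[0][0]

    @property
    def week_hi(self) -> int:
        return self.periods[-1][1]

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def variances(self) -> np.ndarray:
        return np.array([v for _, _, v in self.periods])

    def period_of(self, weeks) -> np.ndarray:
        """0-based period index for each week."""
        weeks = np.asarray(weeks, dtype=int)
        out = np.full(weeks.shape, -1, dtype=int)
        for i, (lo, hi, _) in enumerate(self.periods):
            out[(weeks >= lo) & (weeks <= hi)] = i
        if (out < 0).any():
            bad = np.unique(weeks[out < 0])
            raise ValueError(f"weeks {bad.tolist()} outside residual periods")
        return out

    def variance_of(self, weeks) -> np.ndarray:
        """Residual variance applying to each week."""
        return self.variances[self.period_of(weeks)]


def default_residual_spec() -> ResidualSpec:
    from .params import RESIDUAL_PERIODS

    return ResidualSpec(tuple(RESIDUAL_PERIODS))


def expand_covariance(cf: CovFunction) -> np.ndarray:
    """Expand a coefficient covariance matrix to the weekly grid.

    Returns the ``n_weeks x n_weeks`` matrix Phi * coeff * Phi', whose
    diagonal holds the weekly variances of the effect and whose rank is at
    most order + 1.
    """
    Phi = cf.basis.Phi
    K = Phi @ cf.coeff @ Phi.T
    return 0.5 * (K + K.T)


@dataclass(frozen=True)
class TrajectoryParameters:
    """Weekly variance components and derived genetic parameters."""

    weeks: np.ndarray
    var_additive: np.ndarray
    var_pe: np.ndarray
    var_residual: np.ndarray
    heritability: np.ndarray
    genetic_corr: np.ndarray
    phenotypic_corr: np.ndarray
    cov_additive: np.ndarray
    cov_phenotypic: np.ndarray

    @property
    def var_phenotypic(self) -> np.ndarray:
        return self.var_additive + self.var_pe + self.var_residual

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "week": self.weeks,
                "var_additive": self.var_additive,
                "var_pe": self.var_pe,
                "var_residual": self.var_residual,
                "var_phenotypic": self.var_phenotypic,
                "heritability": self.heritability,
            }
        )


def trajectory_parameters(
    add: CovFunction, pe: CovFunction, res: ResidualSpec
) -> TrajectoryParameters:
    """Weekly variances, heritabilities and correlation matrices.

    The phenotypic covariance between two distinct weeks is the sum of the
    genetic and permanent environmental covariances (residuals are
    independent across weeks); the within-week phenotypic variance
    additionally includes the period residual variance.
    """
    weeks = add.basis.weeks
    Kg = expand_covariance(add)
    Kp = expand_covariance(pe)
    var_a = np.diag(Kg).copy()
    var_p = np.diag(Kp).copy()
    var_e = res.variance_of(weeks)
    total = var_a + var_p + var_e
    if np.any(total <= 0):
        raise ValueError("total phenotypic variance must be positive at every week")
    h2 = var_a / total
    sd_a = np.sqrt(np.clip(var_a, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        rg = Kg / np.outer(sd_a, sd_a)
    Kph = Kg + Kp + np.diag(var_e)
    sd_ph = np.sqrt(np.diag(Kph))
    rp = Kph / np.outer(sd_ph, sd_ph)
    np.fill_diagonal(rg, 1.0)
    np.fill_diagonal(rp, 1.0)
    return TrajectoryParameters(
        weeks=weeks,
        var_additive=var_a,
        var_pe=var_p,
        var_residual=var_e,
        heritability=h2,
        genetic_corr=rg,
        phenotypic_corr=rp,
        cov_additive=Kg,
        cov_phenotypic=Kph,
    )


def fit_covariance_function(
    K: np.ndarray, order: int, basis: LegendreBasis | None = None, label: str = "fit"
) -> tuple[CovFunction, float]:
    """Fit a reduced-order covariance function to a weekly covariance matrix.

    Least-squares projection with identity weights:
    ``coeff = (Phi'Phi)^-1 Phi' K Phi (Phi'Phi)^-1``.  The goodness of fit is
    ``1 - ||K - Phi coeff Phi'||_F / ||K||_F``.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    if basis is None:
        basis = legendre_design(order, np.arange(1, K.shape[0] + 1))
    if basis.Phi.shape[0] != K.shape[0]:
        raise ValueError("basis grid does not match K")
    if order + 1 > K.shape[0]:
        raise ValueError("order + 1 may not exceed the number of weeks")
    Phi = basis.Phi
    PtP = Phi.T @ Phi
    if np.linalg.matrix_rank(PtP) < Phi.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient basis design")
    Pinv = np.linalg.solve(PtP, Phi.T)
    coeff = Pinv @ K @ Pinv.T
    coeff = 0.5 * (coeff + coeff.T)
    cf = CovFunction(coeff=coeff, basis=basis, label=label)
    resid = K - Phi @ coeff @ Phi.T
    gof = 1.0 - np.linalg.norm(resid, "fro") / np.linalg.norm(K, "fro")
    return cf, gof


def partial_sum_covariance(K: np.ndarray, weeks_a: Sequence[int], weeks_b=None,
                           week_grid=None) -> float:
    """Covariance of partial sums of weekly values: 1_a' K 1_b.

    ``weeks_a`` / ``weeks_b`` are subsets of the week grid (defaults 1..n);
    with ``weeks_b`` omitted, returns the variance of the ``weeks_a`` sum.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    grid = np.arange(1, n + 1) if week_grid is None else np.asarray(week_grid)
    if weeks_b is None:
        weeks_b = weeks_a

    def indicator(sub):
        sub = np.asarray(list(sub), dtype=int)
        if sub.size == 0:
            raise ValueError("week subset must be non-empty")
        v = np.isin(grid, sub).astype(float)
        if v.sum() != sub.size:
            missing = sorted(set(sub.tolist()) - set(grid.tolist()))
            raise ValueError(f"weeks {missing} not on the grid")
        return v

    va, vb = indicator(weeks_a), indicator(weeks_b)
    return float(va @ K @ vb)


def partial_sum_correlation(K, weeks_a, weeks_b, week_grid=None) -> float:
    """Correlation between the sums of two week subsets under covariance K."""
    cab = partial_sum_covariance(K, weeks_a, weeks_b, week_grid)
    va = partial_sum_covariance(K, weeks_a, None, week_grid)
    vb = partial_sum_covariance(K, weeks_b, None, week_grid)
    return cab / np.sqrt(va * vb)


def nearest_pd(M: np.ndarray, min_eig: float = 1e-4) -> np.ndarray:
    """Repair a nearly-PD symmetric matrix by clipping its eigenvalues.

    Published coefficient covariance matrices rounded to two decimals can be
    slightly indefinite; simulation and MME assembly require strictly
    positive definite inputs.
    """
    M = 0.5 * (np.asarray(M, float) + np.asarray(M, float).T)
    w, V = np.linalg.eigh(M)
    # small slack keeps the repair idempotent (clipping lands within
    # rounding of min_eig)
    if w.min() >= min_eig * (1 - 1e-6):
        return M
    w = np.clip(w, min_eig, None)
    out = (V * w) @ V.T
    return 0.5 * (out + out.T)
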