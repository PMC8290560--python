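"""Bayesian variance-component estimation for the RR model by Gibbs sampling.

A systematic-scan sampler: location effects from their Gaussian full
conditionals (fixed effects as scalars, regression-coefficient blocks per
animal), the additive and permanent environmental coefficient covariance
matrices from inverse-Wishart full conditionals, and the four period
residual variances from scaled inverse chi-square full conditionals.

Priors are near-flat: improper uniform for the fixed effects,
inverse-Wishart with identity scale and minimal proper degrees of freedom
(dim + 2) for C and P, and the flat improper limit (df = -2 equivalent) for
the residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats

from ._gibbs_kernels import location_sweep
from .basis import LegendreBasis
from .covfun import ResidualSpec
from .model import Designs, ModelError
from .pedigree import RelMatrix

__all__ = [
    "ChainConfig",
    "PosteriorChain",
    "run_gibbs",
    "posterior_summary",
    "hpd_interval",
    "diagnostics",
]


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings; defaults follow common practice for this model
    class (a long single chain with a 10% burn-in and 1:50 thinning)."""

    rounds: int = 200_000
    burn_in: int = 20_000
    thin: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.rounds:
            raise ValueError("burn_in must be smaller than rounds")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_saved(self) -> int:
        return (self.rounds - self.burn_in) // self.thin


@dataclass
class PosteriorChain:
    """Saved Gibbs samples of C, P and the period residual variances."""

    C: np.ndarray               # (S, k, k)
    P: np.ndarray               # (S, k, k)
    residual: np.ndarray        # (S, n_periods)
    config: ChainConfig
    basis: LegendreBasis
    residual_spec: ResidualSpec
    structure: str              # "Ainv" or "Hinv"
    n_jitter: int = 0

    @property
    def n_saved(self) -> int:
        return self.C.shape[0]

    @property
    def k(self) -> int:
        return self.C.shape[1]

    def parameter_frame(self) -> pd.DataFrame:
        """All scalar parameters as columns of a tidy frame."""
        cols = {}
        k = self.k
        for i in range(k):
            for j in range(i, k):
                cols[f"C_{i}{j}"] = self.C[:, i, j]
        for i in range(k):
            for j in range(i, k):
                cols[f"P_{i}{j}"] = self.P[:, i, j]
        for p in range(self.residual.shape[1]):
            lo, hi, _ = self.residual_spec.periods[p]
            cols[f"res_w{lo}_{hi}"] = self.residual[:, p]
        return pd.DataFrame(cols)

    def weekly_samples(self):
        """Per-sample weekly genetic/PE variances and heritability."""
        Phi = self.basis.Phi
        var_a = np.einsum("tk,skl,tl->st", Phi, self.C, Phi)
        var_p = np.einsum("tk,skl,tl->st", Phi, self.P, Phi)
        period = self.residual_spec.period_of(self.basis.weeks)
        var_e = self.residual[:, period]
        h2 = var_a / (var_a + var_p + var_e)
        return var_a, var_p, h2

    def to_csv(self, outdir) -> list:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        k = self.k
        written = []
        for name, arr in (("chain_C.csv", self.C), ("chain_P.csv", self.P)):
            flat = arr.reshape(self.n_saved, k * k)
            labels = [f"{name[6]}_{i}{j}" for i in range(k) for j in range(k)]
            path = outdir / name
            pd.DataFrame(flat, columns=labels).to_csv(path, index=False)
            written.append(path)
        res_labels = [f"res_w{lo}_{hi}" for lo, hi, _ in self.residual_spec.periods]
        path = outdir / "chain_res.csv"
        pd.DataFrame(self.residual, columns=res_labels).to_csv(path, index=False)
        written.append(path)
        return written


def _csc_columns(X: sparse.csr_matrix):
    Xc = X.tocsc()
    return (
        Xc.indptr.astype(np.int64),
        Xc.indices.astype(np.int64),
        Xc.data.astype(np.float64),
    )


def run_gibbs(
    designs: Designs,
    Kinv: RelMatrix,
    res: ResidualSpec,
    cfg: ChainConfig,
    c_init: np.ndarray | None = None,
    p_init: np.ndarray | None = None,
    prior_df: int | None = None,
    progress_every: int = 0,
) -> PosteriorChain:
    """Run the Gibbs sampler for the RR model and return the saved chain.

    ``Kinv`` selects the relationship structure (pedigree A^-1 or
    single-step H^-1).  Sampling is seeded and bit-reproducible through
    ``cfg.seed``.
    """
    if designs.n_records == 0:
        raise ModelError("Gibbs sampling requires phenotype records")
    k = designs.basis.n_coeff
    n_animals, n_hens = designs.n_animals, designs.n_hens
    nf = designs.X.shape[1]
    K = Kinv.values
    if not sparse.issparse(K):
        K = sparse.csr_matrix(K)
    K = K.tocsr()
    if K.shape[0] != n_animals:
        raise ModelError("relationship inverse does not match the pedigree size")

    C = np.eye(k) * 0.5 if c_init is None else np.asarray(c_init, float).copy()
    P = np.eye(k) * 0.5 if p_init is None else np.asarray(p_init, float).copy()
    n_periods = res.n_periods
    rvar = np.ones(n_periods)
    prior_df = k + 2 if prior_df is None else prior_df
    S0 = np.eye(k)

    rec_period = res.period_of(designs.rec_week).astype(np.int64)
    week_pos = {int(w): i for i, w in enumerate(designs.basis.weeks)}
    wrow = np.array([week_pos[int(w)] for w in designs.rec_week], dtype=np.int64)
    xcol_indptr, xcol_rec, xcol_val = _csc_columns(designs.X)
    astart = np.searchsorted(designs.rec_animal, np.arange(n_animals)).astype(np.int64)
    aend = np.searchsorted(
        designs.rec_animal, np.arange(n_animals), side="right"
    ).astype(np.int64)
    hen_index = designs.hen_index.astype(np.int64)
    period_counts = np.bincount(rec_period, minlength=n_periods).astype(float)
    if (period_counts < 5).any():
        raise ModelError(
            "every residual period needs at least 5 records for the flat "
            f"prior; counts {period_counts.astype(int).tolist()}"
        )

    theta_fix = np.zeros(nf)
    alpha = np.zeros((n_animals, k))
    pe = np.zeros((n_hens, k))
    e = designs.y.copy()

    rng = np.random.default_rng(cfg.seed)
    n_loc = nf + (n_animals + n_hens) * k
    S = cfg.n_saved
    C_save = np.empty((S, k, k))
    P_save = np.empty((S, k, k))
    r_save = np.empty((S, n_periods))
    n_jitter = 0
    isave = 0
    for rnd in range(1, cfg.rounds + 1):
        Cinv = np.linalg.inv(C)
        Pinv = np.linalg.inv(P)
        z = rng.standard_normal(n_loc)
        n_jitter += location_sweep(
            theta_fix, alpha, pe, e,
            rec_period, wrow,
            xcol_indptr, xcol_rec, xcol_val,
            astart, aend, hen_index,
            designs.basis.Phi, K.indptr.astype(np.int64),
            K.indices.astype(np.int64), K.data,
            Cinv, Pinv, rvar, z,
        )
        # --- variance components ---
        Sa = alpha.T @ (K @ alpha)
        Sp = pe.T @ pe
        C = _draw_invwishart(rng, prior_df + n_animals, S0 + Sa)
        P = _draw_invwishart(rng, prior_df + n_hens, S0 + Sp)
        sse = np.bincount(rec_period, weights=e * e, minlength=n_periods)
        df_res = period_counts - 2.0
        rvar = sse / rng.chisquare(df_res)
        if rnd > cfg.burn_in and (rnd - cfg.burn_in) % cfg.thin == 0:
            C_save[isave] = C
            P_save[isave] = P
            r_save[isave] = rvar
            isave += 1
        if progress_every and rnd % progress_every == 0:
            print(f"gibbs round {rnd}/{cfg.rounds}, saved {isave}")

    return PosteriorChain(
        C=C_save[:isave],
        P=P_save[:isave],
        residual=r_save[:isave],
        config=cfg,
        basis=designs.basis,
        residual_spec=res,
        structure=Kinv.kind,
        n_jitter=n_jitter,
    )


def _draw_invwishart(rng, df, scale):
    scale = 0.5 * (scale + scale.T)
    for attempt in range(5):
        try:
            return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
        except np.linalg.LinAlgError:
            scale = scale + np.eye(scale.shape[0]) * 10.0 ** (-8 + attempt)
    raise ModelError("inverse-Wishart scale remained singular after jitter")


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, float))
    n = x.size
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def posterior_summary(chain: PosteriorChain, prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean, SD and HPD bounds for every scalar parameter.

    Includes the elements of C and P, the period residual variances, and
    the derived weekly genetic/PE variances and heritabilities (computed
    per sample, then summarised).
    """
    if chain.n_saved < 100:
        raise ModelError(
            f"posterior summary requires >= 100 saved samples, got {chain.n_saved}"
        )
    frames = [chain.parameter_frame()]
    var_a, var_p, h2 = chain.weekly_samples()
    weeks = chain.basis.weeks
    frames.append(
        pd.DataFrame(
            {
                **{f"var_a_w{w}": var_a[:, i] for i, w in enumerate(weeks)},
                **{f"var_pe_w{w}": var_p[:, i] for i, w in enumerate(weeks)},
                **{f"h2_w{w}": h2[:, i] for i, w in enumerate(weeks)},
            }
        )
    )
    wide = pd.concat(frames, axis=1)
    rows = []
    for col in wide.columns:
        x = wide[col].to_numpy()
        lo, hi = hpd_interval(x, prob)
        rows.append((col, x.mean(), x.std(ddof=1), lo, hi))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "hpd_lo", "hpd_hi"])


def diagnostics(chain: PosteriorChain, outdir=None) -> pd.DataFrame:
    """Effective sample sizes (and optional trace CSV export) per parameter."""
    import arviz as az

    wide = chain.parameter_frame()
    rows = []
    for col in wide.columns:
        x = wide[col].to_numpy()
        ess = float(az.ess(x)) if np.std(x) > 0 else float(x.size)
        rows.append((col, ess))
    if outdir is not None:
        chain.to_csv(outdir)
    return pd.DataFrame(rows, columns=["parameter", "ess"])
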