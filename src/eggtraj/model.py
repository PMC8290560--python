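"""Random-regression mixed-model equations for egg-production trajectories.

The observation model for hen j in week of lay t is

    y = (hatch-week x week) + (week x AFE-class) + b_t * bodyweight
        + phi(t)' alpha_j + phi(t)' p_j + e,

with alpha_j ~ N(0, A (x) C) (or H (x) C in the single-step case),
p_j ~ N(0, I (x) P), and heterogeneous residual variances by period of lay.
This module builds the incidence matrices, assembles and solves the MME for
RR-PBLUP / RR-ssGBLUP, and turns coefficient solutions into weekly EBV
trajectories, cumulative EBVs and persistency slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as spla

from .basis import LegendreBasis
from .covfun import ResidualSpec
from .params import AFE_CLASSES, PERSISTENCY_DIVISOR, PERSISTENCY_END_WEEK, \
    PERSISTENCY_PEAK_WEEK
from .pedigree import Pedigree, RelMatrix

__all__ = [
    "PhenotypeTable",
    "FixedEffectsSpec",
    "Designs",
    "MMESystem",
    "MMESolution",
    "BreedingValues",
    "ModelError",
    "build_design",
    "assemble_mme",
    "solve_mme",
    "ebv_trajectory",
    "persistency",
]


class ModelError(ValueError):
    pass


class PhenotypeTable:
    """Long-format weekly egg records.

    Columns: animal, week (1..24), eggs, afe_class, hatch_week,
    body_weight.  At most one record per animal-week.
    """

    REQUIRED = ("animal", "week", "eggs", "afe_class", "hatch_week", "body_weight")

    def __init__(self, df: pd.DataFrame, afe_classes=AFE_CLASSES):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ModelError(f"phenotype table lacks columns {missing}")
        df = df.copy().reset_index(drop=True)
        df["week"] = df["week"].astype(int)
        if df["week"].min() < 1 or df["week"].max() > 24:
            raise ModelError("weeks of lay must be within 1..24")
        if df.duplicated(subset=["animal", "week"]).any():
            dup = df[df.duplicated(subset=["animal", "week"])].iloc[0]
            raise ModelError(
                f"duplicate record for animal {dup['animal']} week {dup['week']}"
            )
        bad_afe = set(df["afe_class"].astype(str)) - set(afe_classes)
        if bad_afe:
            raise ModelError(
                f"unknown age-at-first-egg classes {sorted(bad_afe)}; "
                f"expected {list(afe_classes)}"
            )
        if (df["eggs"] < 0).any():
            warnings.warn("negative egg counts present", stacklevel=2)
        self.df = df
        self.afe_classes = tuple(afe_classes)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> np.ndarray:
        return self.df["animal"].unique()

    def subset(self, animals) -> "PhenotypeTable":
        keep = self.df["animal"].isin(set(animals))
        return PhenotypeTable(self.df[keep], self.afe_classes)


@dataclass
class FixedEffectsSpec:
    """Fixed-effect layout: H x W cells, W x AFE cells, weekly BW slopes.

    Levels are enumerated from a (training) phenotype table.  Reference
    levels dropped for estimability are listed in ``dropped_levels``: the
    first observed AFE class within every week of lay.
    """

    hw_levels: list            # [(hatch_week, week), ...] -> one dummy each
    wafe_levels: list          # [(week, afe_class), ...] kept dummies
    bw_weeks: list             # weeks with a body-weight slope column
    bw_center: float
    afe_classes: tuple
    dropped_levels: list = field(default_factory=list)

    @classmethod
    def from_table(cls, ph: PhenotypeTable) -> "FixedEffectsSpec":
        df = ph.df
        hw = sorted(set(zip(df["hatch_week"].tolist(), df["week"].tolist())))
        wafe_all = sorted(
            set(zip(df["week"].tolist(), df["afe_class"].astype(str).tolist()))
        )
        kept, dropped = [], []
        for week in sorted({w for w, _ in wafe_all}):
            classes = [c for w, c in wafe_all if w == week]
            dropped.append((week, classes[0]))
            kept.extend((week, c) for c in classes[1:])
        bw_weeks = sorted(df["week"].unique().tolist())
        return cls(
            hw_levels=hw,
            wafe_levels=kept,
            bw_weeks=bw_weeks,
            bw_center=float(df["body_weight"].mean()),
            afe_classes=ph.afe_classes,
            dropped_levels=dropped,
        )

    @property
    def n_columns(self) -> int:
        return len(self.hw_levels) + len(self.wafe_levels) + len(self.bw_weeks)

    def column_labels(self) -> list:
        return (
            [f"hw:{h}|wk:{w}" for h, w in self.hw_levels]
            + [f"wk:{w}|afe:{c}" for w, c in self.wafe_levels]
            + [f"bw:wk:{w}" for w in self.bw_weeks]
        )


@dataclass
class Designs:
    """Incidence matrices and record bookkeeping for one model fit."""

    X: sparse.csr_matrix
    Q: sparse.csr_matrix
    Z: sparse.csr_matrix
    y: np.ndarray
    rec_animal: np.ndarray      # pedigree index per record
    rec_hen: np.ndarray         # index into hen_index per record
    rec_week: np.ndarray        # week of lay per record
    hen_index: np.ndarray       # pedigree indices of hens with records
    basis: LegendreBasis
    fixed_spec: FixedEffectsSpec
    n_animals: int
    dropped_records: int = 0

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_hens(self) -> int:
        return self.hen_index.shape[0]


def build_design(
    ph: PhenotypeTable,
    spec: FixedEffectsSpec,
    basis: LegendreBasis,
    ped: Pedigree,
    drop_unseen: bool = False,
) -> Designs:
    """Build X (fixed), Q (additive) and Z (permanent environment).

    Every record must reference a pedigree animal; fixed-effect levels not
    present in ``spec`` are fatal unless ``drop_unseen`` (used when applying
    a training-data spec to validation records) drops them with a warning.
    """
    df = ph.df
    animal_ix = ped.index_of(df["animal"].tolist())
    order = np.lexsort((df["week"].to_numpy(), animal_ix))
    df = df.iloc[order].reset_index(drop=True)
    animal_ix = animal_ix[order]

    hw_col = {lv: k for k, lv in enumerate(spec.hw_levels)}
    wafe_col = {lv: k + len(spec.hw_levels) for k, lv in enumerate(spec.wafe_levels)}
    bw_col = {
        w: k + len(spec.hw_levels) + len(spec.wafe_levels)
        for k, w in enumerate(spec.bw_weeks)
    }
    dropped_wafe = set(spec.dropped_levels)

    keep = np.ones(len(df), dtype=bool)
    rows, cols, vals = [], [], []
    for r in range(len(df)):
        week = int(df.at[r, "week"])
        hw = (df.at[r, "hatch_week"], week)
        afe = (week, str(df.at[r, "afe_class"]))
        unseen = hw not in hw_col or (
            afe not in wafe_col and afe not in dropped_wafe
        ) or week not in bw_col
        if unseen:
            if drop_unseen:
                keep[r] = False
                continue
            raise ModelError(
                f"record {df.at[r, 'animal']}/week {week}: fixed-effect level "
                f"unseen in the training specification"
            )
        rows.append(r)
        cols.append(hw_col[hw])
        vals.append(1.0)
        if afe in wafe_col:
            rows.append(r)
            cols.append(wafe_col[afe])
            vals.append(1.0)
        rows.append(r)
        cols.append(bw_col[week])
        vals.append(float(df.at[r, "body_weight"]) - spec.bw_center)

    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} records with fixed-effect levels unseen in "
            "the training data",
            stacklevel=2,
        )
        old_rows = np.flatnonzero(keep)
        remap = {int(r): k for k, r in enumerate(old_rows)}
        rows = [remap[r] for r in rows]
        df = df[keep].reset_index(drop=True)
        animal_ix = animal_ix[keep]

    nrec = len(df)
    X = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(nrec, spec.n_columns)
    ).tocsr()

    weeks = df["week"].to_numpy()
    week_pos = {int(w): i for i, w in enumerate(basis.weeks)}
    try:
        wrow = np.array([week_pos[int(w)] for w in weeks])
    except KeyError as e:
        raise ModelError(f"week {e.args[0]} not on the basis grid") from None
    Phi_rec = basis.Phi[wrow]  # nrec x k

    k = basis.n_coeff
    hen_index = np.unique(animal_ix)
    hen_pos = {int(a): i for i, a in enumerate(hen_index)}
    rec_hen = np.array([hen_pos[int(a)] for a in animal_ix])

    rr = np.repeat(np.arange(nrec), k)
    qc = (animal_ix[:, None] * k + np.arange(k)[None, :]).ravel()
    zc = (rec_hen[:, None] * k + np.arange(k)[None, :]).ravel()
    Q = sparse.coo_matrix(
        (Phi_rec.ravel(), (rr, qc)), shape=(nrec, ped.n * k)
    ).tocsr()
    Z = sparse.coo_matrix(
        (Phi_rec.ravel(), (rr, zc)), shape=(nrec, hen_index.size * k)
    ).tocsr()

    return Designs(
        X=X,
        Q=Q,
        Z=Z,
        y=df["eggs"].to_numpy(dtype=float),
        rec_animal=animal_ix,
        rec_hen=rec_hen,
        rec_week=weeks,
        hen_index=hen_index,
        basis=basis,
        fixed_spec=spec,
        n_animals=ped.n,
        dropped_records=n_dropped,
    )


def _chol_or_report(M: np.ndarray, name: str) -> np.ndarray:
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        eig = np.linalg.eigvalsh(M)
        raise ModelError(
            f"{name} is not positive definite; eigenvalues {np.round(eig, 6)}"
        ) from None
    return np.linalg.inv(M)


@dataclass
class MMESystem:
    """Assembled mixed-model equations, kept in structured (unmerged) form.

    The coefficient matrix is W' R^-1 W plus the prior blocks
    blockdiag(0, Kinv (x) C^-1, I (x) P^-1); it is applied matrix-free for
    iterative solves and materialised for direct factorisation.
    """

    designs: Designs
    Kinv: sparse.csr_matrix
    Cinv: np.ndarray
    Pinv: np.ndarray
    rweights: np.ndarray        # 1 / residual variance per record
    kind: str                   # "Ainv" or "Hinv"
    _W: sparse.csr_matrix = field(default=None, repr=False)
    _WT: sparse.csr_matrix = field(default=None, repr=False)

    def __post_init__(self):
        if self._W is None:
            d = self.designs
            self._W = sparse.hstack([d.X, d.Q, d.Z]).tocsr()
            self._WT = self._W.T.tocsr()

    @property
    def n_fixed(self) -> int:
        return self.designs.X.shape[1]

    @property
    def k(self) -> int:
        return self.designs.basis.n_coeff

    @property
    def n_unknowns(self) -> int:
        return self._W.shape[1]

    def _split(self, v):
        d, k = self.designs, self.k
        nf = self.n_fixed
        na = d.n_animals * k
        return v[:nf], v[nf:nf + na], v[nf + na:]

    def rhs(self) -> np.ndarray:
        return self._WT @ (self.rweights * self.designs.y)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        d, k = self.designs, self.k
        out = self._WT @ (self.rweights * (self._W @ v))
        _, va, vp = self._split(v)
        U = va.reshape(d.n_animals, k)
        out[self.n_fixed:self.n_fixed + va.size] += ((self.Kinv @ U) @ self.Cinv).ravel()
        V = vp.reshape(d.n_hens, k)
        out[self.n_fixed + va.size:] += (V @ self.Pinv).ravel()
        return out

    def to_sparse(self) -> sparse.csr_matrix:
        d, k = self.designs, self.k
        data = self._WT @ sparse.diags(self.rweights) @ self._W
        prior = sparse.block_diag(
            [
                sparse.csr_matrix((self.n_fixed, self.n_fixed)),
                sparse.kron(self.Kinv, sparse.csr_matrix(self.Cinv)),
                sparse.kron(sparse.eye(d.n_hens), sparse.csr_matrix(self.Pinv)),
            ]
        )
        return (data + prior).tocsc()

    def block_preconditioner(self):
        """Block-Jacobi preconditioner: scalar fixed diag, 4x4 random blocks."""
        d, k = self.designs, self.k
        Phi = d.basis.Phi
        week_pos = {int(w): i for i, w in enumerate(d.basis.weeks)}
        wrow = np.array([week_pos[int(w)] for w in d.rec_week])
        Prec = Phi[wrow]
        outer = np.einsum("ri,rj,r->rij", Prec, Prec, self.rweights)
        blocks_a = np.zeros((d.n_animals, k, k))
        np.add.at(blocks_a, d.rec_animal, outer)
        diagK = np.asarray(self.Kinv.diagonal())
        blocks_a += diagK[:, None, None] * self.Cinv
        blocks_p = np.zeros((d.n_hens, k, k))
        np.add.at(blocks_p, d.rec_hen, outer)
        blocks_p += self.Pinv
        inv_a = np.linalg.inv(blocks_a)
        inv_p = np.linalg.inv(blocks_p)
        Xd = np.asarray(
            (self.designs.X.multiply(self.designs.X))
            .T.dot(self.rweights)
        ).ravel()
        Xd[Xd <= 0] = 1.0

        def apply(v):
            vf, va, vp = self._split(v)
            out = np.empty_like(v)
            out[: self.n_fixed] = vf / Xd
            Ua = va.reshape(d.n_animals, k)
            out[self.n_fixed:self.n_fixed + va.size] = np.einsum(
                "nij,nj->ni", inv_a, Ua
            ).ravel()
            Up = vp.reshape(d.n_hens, k)
            out[self.n_fixed + va.size:] = np.einsum(
                "nij,nj->ni", inv_p, Up
            ).ravel()
            return out

        return apply


def assemble_mme(
    designs: Designs,
    Kinv: RelMatrix,
    C: np.ndarray,
    P: np.ndarray,
    res: ResidualSpec,
) -> MMESystem:
    """Assemble the MME for given variance components.

    ``Kinv`` is the sparse A^-1 (RR-PBLUP) or H^-1 (RR-ssGBLUP); C and P are
    the coefficient covariance matrices (must be positive definite, checked
    by Cholesky with an eigenvalue report on failure); residual weighting
    uses the period variance of each record's week.
    """
    C = np.asarray(C, float)
    P = np.asarray(P, float)
    Cinv = _chol_or_report(C, "additive coefficient covariance C")
    Pinv = _chol_or_report(P, "permanent environmental covariance P")
    K = Kinv.values
    if not sparse.issparse(K):
        K = sparse.csr_matrix(K)
    if K.shape[0] != designs.n_animals:
        raise ModelError(
            f"{Kinv.kind} has dimension {K.shape[0]} but the pedigree "
            f"has {designs.n_animals} animals"
        )
    if designs.n_records:
        rweights = 1.0 / res.variance_of(designs.rec_week)
    else:
        rweights = np.zeros(0)
    return MMESystem(
        designs=designs,
        Kinv=K.tocsr(),
        Cinv=Cinv,
        Pinv=Pinv,
        rweights=rweights,
        kind=Kinv.kind,
    )


@dataclass
class MMESolution:
    fixed: np.ndarray
    alpha: np.ndarray           # n_animals x k additive coefficients
    pe: np.ndarray              # n_hens x k permanent environmental coefficients
    method: str
    relative_residual: float
    iterations: int = 0

    def fixed_frame(self, spec: FixedEffectsSpec) -> pd.DataFrame:
        return pd.DataFrame({"effect": spec.column_labels(), "solution": self.fixed})


def solve_mme(
    sys: MMESystem,
    method: str = "auto",
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> MMESolution:
    """Solve the assembled equations.

    ``direct`` uses a sparse LU factorisation of the materialised
    coefficient matrix (intended for systems up to ~20k unknowns with a
    sparse relationship inverse); ``pcg`` runs preconditioned conjugate
    gradients with a block-Jacobi preconditioner and is the default for
    large or dense-block (single-step) systems.  Non-convergence raises
    with the residual history attached.
    """
    n = sys.n_unknowns
    if method == "auto":
        dense_block = sys.Kinv.nnz > 4 * n
        method = "pcg" if (n > 20000 or dense_block) else "direct"
    rhs = sys.rhs()
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm == 0:
        sol = np.zeros(n)
        rel = 0.0
        iters = 0
    elif method == "direct":
        lhs = sys.to_sparse()
        lu = spla.splu(lhs)
        sol = lu.solve(rhs)
        rel = np.linalg.norm(sys.matvec(sol) - rhs) / rhs_norm
        iters = 0
    elif method == "pcg":
        precond = sys.block_preconditioner()
        sol = np.zeros(n)
        r = rhs.copy()
        z = precond(r)
        p = z.copy()
        rz = r @ z
        history = []
        for it in range(1, max_iter + 1):
            Ap = sys.matvec(p)
            alpha = rz / (p @ Ap)
            sol += alpha * p
            r -= alpha * Ap
            rel = np.linalg.norm(r) / rhs_norm
            history.append(rel)
            if rel < tol:
                break
            z = precond(r)
            rz_new = r @ z
            p = z + (rz_new / rz) * p
            rz = rz_new
        else:
            raise ModelError(
                f"PCG did not converge in {max_iter} iterations; last "
                f"relative residuals {history[-5:]}"
            )
        iters = it
    else:
        raise ValueError(f"unknown method {method!r}")

    d, k = sys.designs, sys.k
    nf = sys.n_fixed
    na = d.n_animals * k
    return MMESolution(
        fixed=sol[:nf],
        alpha=sol[nf:nf + na].reshape(d.n_animals, k),
        pe=sol[nf + na:].reshape(d.n_hens, k),
        method=method,
        relative_residual=rel,
        iterations=iters,
    )


@dataclass
class BreedingValues:
    """Weekly EBV trajectories derived from additive coefficient solutions."""

    ids: np.ndarray
    alpha: np.ndarray           # n x k
    weekly: np.ndarray          # n x n_weeks, = alpha @ Phi'
    cumulative: np.ndarray      # n, = sum of weekly
    persistency: np.ndarray     # n, slope peak -> end week
    genomic: bool = False

    def to_frame(self, weeks) -> pd.DataFrame:
        df = pd.DataFrame(self.weekly, columns=[f"week_{w}" for w in weeks])
        df.insert(0, "animal", self.ids)
        df["cumulative"] = self.cumulative
        df["persistency"] = self.persistency
        return df


def persistency(
    weekly_values: np.ndarray,
    week_grid=None,
    peak_week: int = PERSISTENCY_PEAK_WEEK,
    end_week: int = PERSISTENCY_END_WEEK,
    divisor: float = PERSISTENCY_DIVISOR,
):
    """Persistency slope: (value at peak week - value at end week) / divisor.

    A smaller slope means a flatter trajectory, i.e. a more persistent
    layer.  Works on a single trajectory (1-D) or a matrix of trajectories
    (rows = animals).  The conventional divisor of 16 for the week 3 -> 18
    slope is kept as the default.
    """
    weekly_values = np.asarray(weekly_values, dtype=float)
    grid = np.arange(1, weekly_values.shape[-1] + 1) if week_grid is None \
        else np.asarray(week_grid)
    if peak_week == end_week:
        raise ValueError("peak and end week must differ")
    for w in (peak_week, end_week):
        if w not in grid:
            raise ValueError(f"week {w} not on the grid")
    ip = int(np.flatnonzero(grid == peak_week)[0])
    ie = int(np.flatnonzero(grid == end_week)[0])
    return (weekly_values[..., ip] - weekly_values[..., ie]) / divisor


def ebv_trajectory(
    sol: MMESolution,
    basis: LegendreBasis,
    ids: np.ndarray,
    genomic: bool = False,
    peak_week: int = PERSISTENCY_PEAK_WEEK,
    end_week: int = PERSISTENCY_END_WEEK,
    divisor: float = PERSISTENCY_DIVISOR,
) -> BreedingValues:
    """Expand additive coefficient solutions into weekly EBV trajectories."""
    weekly = sol.alpha @ basis.Phi.T
    return BreedingValues(
        ids=np.asarray(ids),
        alpha=sol.alpha,
        weekly=weekly,
        cumulative=weekly.sum(axis=1),
        persistency=persistency(
            weekly, basis.weeks, peak_week=peak_week, end_week=end_week,
            divisor=divisor,
        ),
        genomic=genomic,
    )
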