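"""Random-regression MME tests: design structure, solver correctness
against dense GLS, single-step null equivalence, EBV trajectories and
persistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from eggtraj.covfun import ResidualSpec
from eggtraj.model import (
    Designs,
    FixedEffectsSpec,
    ModelError,
    PhenotypeTable,
    assemble_mme,
    build_design,
    ebv_trajectory,
    persistency,
    solve_mme,
)
from eggtraj.pedigree import Pedigree, RelMatrix, build_A, build_A_inverse
from eggtraj.simulate import SimConfig, simulate_dataset


def toy_table(n_hens=5, weeks=(1, 2, 3, 4), seed=0):
    # hatch week and AFE class crossed so the fixed design is full rank
    rng = np.random.default_rng(seed)
    rows = []
    for h in range(n_hens):
        for w in weeks:
            rows.append(
                (f"h{h}", w, rng.normal(5, 1),
                 "29-31" if (h // 2) % 2 == 0 else "32-34",
                 10 + h % 2, rng.normal(10.5, 0.8))
            )
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["animal", "week", "eggs", "afe_class",
                                    "hatch_week", "body_weight"])
    )


def toy_pedigree(labels):
    n = len(labels)
    return Pedigree(sire=[-1] * n, dam=[-1] * n, labels=np.asarray(labels),
                    hatch_week=np.full(n, np.nan))


@pytest.fixture()
def toy(basis):
    ph = toy_table()
    ped = toy_pedigree(sorted(ph.animals))
    spec = FixedEffectsSpec.from_table(ph)
    return ph, ped, spec, build_design(ph, spec, basis, ped)


SMALL_C = np.array([[0.5, 0.1, 0.0, 0.0], [0.1, 0.3, 0.0, 0.0],
                    [0.0, 0.0, 0.2, 0.05], [0.0, 0.0, 0.05, 0.1]])
SMALL_P = np.diag([0.6, 0.3, 0.2, 0.1])
RES = ResidualSpec(((1, 4, 1.33), (5, 12, 1.38), (13, 17, 1.21), (18, 24, 1.1)))


class TestDesign:
    def test_single_hen_Q_structure(self, basis):
        ph = toy_table(n_hens=1, weeks=range(1, 25))
        ped = toy_pedigree(["h0"])
        d = build_design(ph, FixedEffectsSpec.from_table(ph), basis, ped)
        assert d.Q.shape == (24, 4)
        assert (np.abs(d.Q.toarray()) > 0).all()
        assert np.allclose(d.Q.toarray(), basis.Phi)

    def test_shared_cell_rows_differ_only_in_bodyweight(self, toy, basis):
        ph, ped, spec, d = toy
        # hens h0 and h4 share hatch week and AFE class
        rows = d.X.toarray()
        r0 = np.flatnonzero((d.rec_animal == ped.index_of(["h0"])[0])
                            & (d.rec_week == 2))[0]
        r2 = np.flatnonzero((d.rec_animal == ped.index_of(["h4"])[0])
                            & (d.rec_week == 2))[0]
        diff_cols = np.flatnonzero(rows[r0] != rows[r2])
        labels = np.array(spec.column_labels())[diff_cols]
        assert all(l.startswith("bw:") for l in labels)

    def test_XtX_matches_enumeration_oracle(self, toy):
        ph, ped, spec, d = toy
        X = d.X.toarray()
        # brute-force cross-tabulation over records
        oracle = np.zeros((X.shape[1], X.shape[1]))
        for r in range(X.shape[0]):
            oracle += np.outer(X[r], X[r])
        assert np.allclose((d.X.T @ d.X).toarray(), oracle)

    def test_unknown_animal_fatal(self, basis):
        ph = toy_table()
        ped = toy_pedigree(["h0", "h1"])  # h2 missing
        with pytest.raises(Exception, match="h2"):
            build_design(ph, FixedEffectsSpec.from_table(ph), basis, ped)

    def test_unknown_afe_class_fatal(self):
        df = toy_table().df
        df.loc[0, "afe_class"] = "28"
        with pytest.raises(ModelError, match="age-at-first-egg"):
            PhenotypeTable(df)

    def test_duplicate_record_fatal(self):
        df = toy_table().df
        with pytest.raises(ModelError, match="duplicate"):
            PhenotypeTable(pd.concat([df, df.iloc[[0]]]))


class TestAssemble:
    def test_no_records_prior_only(self, basis):
        ph = toy_table(n_hens=1, weeks=(1,))
        ped = toy_pedigree(["h0", "x1"])
        spec = FixedEffectsSpec.from_table(ph)
        d = build_design(ph, spec, basis, ped)
        empty = Designs(
            X=sparse.csr_matrix((0, d.X.shape[1])),
            Q=sparse.csr_matrix((0, d.Q.shape[1])),
            Z=sparse.csr_matrix((0, 0)),
            y=np.zeros(0), rec_animal=np.zeros(0, int),
            rec_hen=np.zeros(0, int), rec_week=np.zeros(0, int),
            hen_index=np.zeros(0, int), basis=basis, fixed_spec=spec,
            n_animals=2,
        )
        sys = assemble_mme(empty, build_A_inverse(ped), SMALL_C, SMALL_P, RES)
        lhs = sys.to_sparse().toarray()
        prior = sparse.kron(
            build_A_inverse(ped).values, np.linalg.inv(SMALL_C)
        ).toarray()
        nf = sys.n_fixed
        assert np.allclose(lhs[nf:nf + 8, nf:nf + 8], prior)

    def test_non_pd_covariance_fatal_with_eigenvalues(self, toy):
        ph, ped, spec, d = toy
        bad = np.diag([1.0, 1.0, 1.0, -0.5])
        with pytest.raises(ModelError, match="eigenvalues"):
            assemble_mme(d, build_A_inverse(ped), bad, SMALL_P, RES)

    def test_wrong_relationship_dimension_fatal(self, toy):
        ph, ped, spec, d = toy
        small = RelMatrix(np.eye(2), np.array(["a", "b"]), "Ainv")
        with pytest.raises(ModelError, match="dimension"):
            assemble_mme(d, small, SMALL_C, SMALL_P, RES)


class TestSolve:
    def test_solution_satisfies_normal_equations(self, toy):
        ph, ped, spec, d = toy
        sys = assemble_mme(d, build_A_inverse(ped), SMALL_C, SMALL_P, RES)
        sol = solve_mme(sys, method="direct")
        assert sol.relative_residual < 1e-8

    def test_direct_and_pcg_agree(self, toy):
        ph, ped, spec, d = toy
        sys = assemble_mme(d, build_A_inverse(ped), SMALL_C, SMALL_P, RES)
        a = solve_mme(sys, method="direct")
        b = solve_mme(sys, method="pcg", tol=1e-12)
        assert np.abs(a.alpha - b.alpha).max() < 1e-6
        assert np.abs(a.fixed - b.fixed).max() < 1e-6

    def test_single_record_closed_form(self, basis):
        """One animal, one record, no fixed effects: BLUP collapses to
        alpha_hat = C phi y / (phi'C phi + phi'P phi + sigma2_e)."""
        week = 7
        phi = basis.row(week)
        y = 2.5
        ped = toy_pedigree(["h0"])
        spec = FixedEffectsSpec(hw_levels=[], wafe_levels=[], bw_weeks=[],
                                bw_center=0.0, afe_classes=("29-31",))
        d = Designs(
            X=sparse.csr_matrix((1, 0)),
            Q=sparse.csr_matrix(phi[None, :]),
            Z=sparse.csr_matrix(phi[None, :]),
            y=np.array([y]), rec_animal=np.array([0]),
            rec_hen=np.array([0]), rec_week=np.array([week]),
            hen_index=np.array([0]), basis=basis, fixed_spec=spec,
            n_animals=1,
        )
        sys = assemble_mme(d, build_A_inverse(ped), SMALL_C, SMALL_P, RES)
        sol = solve_mme(sys, method="direct")
        g = phi @ SMALL_C @ phi
        p = phi @ SMALL_P @ phi
        r = RES.variance_of([week])[0]
        assert np.allclose(sol.alpha[0], SMALL_C @ phi * y / (g + p + r),
                           atol=1e-10)
        assert np.allclose(sol.pe[0], SMALL_P @ phi * y / (g + p + r),
                           atol=1e-10)

    def test_matches_dense_gls_oracle(self, basis):
        """Fixed effects and BLUPs from the MME equal direct GLS with the
        full covariance of y inverted densely (30 hens)."""
        cfg = SimConfig(n_generations=3, n_sires=2, n_dams=5,
                        progeny_per_dam=3, n_snp=50, seed=13,
                        missing_week_rate=0.2)
        ds = simulate_dataset(cfg)
        ped, ph = ds.pedigree, ds.phenotypes
        spec = FixedEffectsSpec.from_table(ph)
        d = build_design(ph, spec, basis, ped)
        C, P = SMALL_C, SMALL_P
        sys = assemble_mme(d, build_A_inverse(ped), C, P, RES)
        sol = solve_mme(sys, method="direct")

        A = build_A(ped).toarray()
        Q, Z, X = d.Q.toarray(), d.Z.toarray(), d.X.toarray()
        V = (
            Q @ np.kron(A, C) @ Q.T
            + Z @ np.kron(np.eye(d.n_hens), P) @ Z.T
            + np.diag(1.0 / sys.rweights)
        )
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        b = np.linalg.lstsq(XtVi @ X, XtVi @ d.y, rcond=None)[0]
        resid = d.y - X @ b
        a_hat = (np.kron(A, C) @ Q.T @ Vi @ resid).reshape(ped.n, 4)
        p_hat = (np.kron(np.eye(d.n_hens), P) @ Z.T @ Vi @ resid).reshape(
            d.n_hens, 4
        )
        assert np.abs(sol.alpha - a_hat).max() < 1e-6
        assert np.abs(sol.pe - p_hat).max() < 1e-6
        assert np.abs(X @ sol.fixed - X @ b).max() < 1e-6

    def test_duplicated_records_equal_doubled_weights(self, toy, basis):
        """Storing every record twice is the same sufficient statistic as
        one copy with its residual weight doubled."""
        ph, ped, spec, d = toy
        sys = assemble_mme(d, build_A_inverse(ped), SMALL_C, SMALL_P, RES)
        sys.rweights = 2.0 * sys.rweights
        base = solve_mme(sys, method="direct")
        dup = Designs(
            X=sparse.vstack([d.X, d.X]).tocsr(),
            Q=sparse.vstack([d.Q, d.Q]).tocsr(),
            Z=sparse.vstack([d.Z, d.Z]).tocsr(),
            y=np.concatenate([d.y, d.y]),
            rec_animal=np.concatenate([d.rec_animal, d.rec_animal]),
            rec_hen=np.concatenate([d.rec_hen, d.rec_hen]),
            rec_week=np.concatenate([d.rec_week, d.rec_week]),
            hen_index=d.hen_index, basis=basis, fixed_spec=spec,
            n_animals=ped.n,
        )
        sys2 = assemble_mme(dup, build_A_inverse(ped), SMALL_C, SMALL_P, RES)
        doubled = solve_mme(sys2, method="direct")
        assert np.abs(base.alpha - doubled.alpha).max() < 1e-8
        assert np.abs(base.pe - doubled.pe).max() < 1e-8

    def test_bodyweight_shift_changes_only_fixed_solutions(self, basis):
        ph = toy_table(n_hens=4, weeks=range(1, 9), seed=2)
        ped = toy_pedigree(sorted(ph.animals))
        Ainv = build_A_inverse(ped)

        def fit(table):
            spec = FixedEffectsSpec.from_table(table)
            d = build_design(table, spec, basis, ped)
            return solve_mme(
                assemble_mme(d, Ainv, SMALL_C, SMALL_P, RES), method="direct"
            )

        base = fit(ph)
        shifted_df = ph.df.copy()
        shifted_df["body_weight"] += 3.0
        shifted = fit(PhenotypeTable(shifted_df))
        assert np.abs(base.alpha - shifted.alpha).max() < 1e-8
        assert np.abs(base.pe - shifted.pe).max() < 1e-8


class TestSingleStepNull:
    def test_empty_genotype_set_reproduces_pblup(self, small_dataset, basis):
        """With G = A22 the single-step correction vanishes and ssGBLUP
        EBVs equal PBLUP EBVs."""
        from eggtraj.genomic import (
            HStructure, build_H_inverse, genotyped_positions, invert_dense,
        )

        ds = small_dataset
        ped, ph = ds.pedigree, ds.phenotypes
        spec = FixedEffectsSpec.from_table(ph)
        d = build_design(ph, spec, basis, ped)
        C, P, res = ds.config.C_true, ds.config.P_true, ds.config.residual_spec
        Ainv = build_A_inverse(ped)
        sol_p = solve_mme(assemble_mme(d, Ainv, C, P, res), method="direct")
        gi = genotyped_positions(ped, ds.genotypes.animal_ids)
        A22 = build_A(ped, subset=[str(l) for l in ped.labels[gi]])
        Hinv = build_H_inverse(
            HStructure(Ainv=Ainv, Ginv=invert_dense(A22, "Ginv"),
                       A22inv=invert_dense(A22, "A22inv"), genotyped_index=gi)
        )
        sol_h = solve_mme(assemble_mme(d, Hinv, C, P, res), method="direct")
        assert np.abs(sol_h.alpha - sol_p.alpha).max() < 1e-8


class TestTrajectories:
    def test_zero_coefficients_flat_zero(self, basis):
        from eggtraj.model import MMESolution

        sol = MMESolution(fixed=np.zeros(0), alpha=np.zeros((2, 4)),
                          pe=np.zeros((2, 4)), method="direct",
                          relative_residual=0.0)
        bv = ebv_trajectory(sol, basis, np.array(["a", "b"]))
        assert np.all(bv.weekly == 0) and np.all(bv.cumulative == 0)

    def test_constant_basis_coefficient(self, basis):
        from eggtraj.model import MMESolution

        sol = MMESolution(fixed=np.zeros(0),
                          alpha=np.array([[1.0, 0, 0, 0]]),
                          pe=np.zeros((1, 4)), method="direct",
                          relative_residual=0.0)
        bv = ebv_trajectory(sol, basis, np.array(["a"]))
        assert np.allclose(bv.weekly, np.sqrt(0.5))

    def test_cumulative_is_sum_of_weeks(self, basis):
        from eggtraj.model import MMESolution

        rng = np.random.default_rng(3)
        sol = MMESolution(fixed=np.zeros(0),
                          alpha=rng.standard_normal((5, 4)),
                          pe=np.zeros((5, 4)), method="direct",
                          relative_residual=0.0)
        bv = ebv_trajectory(sol, basis, np.array(list("abcde")))
        assert np.allclose(bv.cumulative, bv.weekly.sum(axis=1))


class TestPersistency:
    def test_flat_trajectory_zero_slope(self):
        assert persistency(np.full(24, 4.2)) == 0.0

    def test_reference_weekly_means(self):
        """Peak-week (3) minus week-18 mean over the conventional divisor
        16: (5.30 - 3.91) / 16 = 0.086875."""
        from eggtraj.params import WEEKLY_EGG_MEAN

        assert persistency(WEEKLY_EGG_MEAN) == pytest.approx(0.086875)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        v = rng.normal(4, 1, size=24)
        assert persistency(2 * v) == pytest.approx(2 * persistency(v))

    def test_equal_weeks_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            persistency(np.ones(24), peak_week=5, end_week=5)


def test_ssgblup_beats_pblup_on_true_values(ten_seed_fits):
    """Among genotyped validation hens, correlation between true and
    estimated weekly genetic values is higher for RR-ssGBLUP than RR-PBLUP
    in at least 8 of 10 independent populations."""
    wins = sum(r["acc_ssgblup"] > r["acc_pblup"] for r in ten_seed_fits)
    assert wins >= 8, [
        (round(r["acc_pblup"], 3), round(r["acc_ssgblup"], 3))
        for r in ten_seed_fits
    ]
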