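"""Validation statistics: age-based split, fixed-effect correction,
correlation accuracy, Mendelian sampling and the variance-ratio nu."""

import numpy as np
import pandas as pd
import pytest

from eggtraj.model import (
    BreedingValues,
    FixedEffectsSpec,
    ModelError,
    PhenotypeTable,
    persistency,
)
from eggtraj.pedigree import Pedigree
from eggtraj.validate import (
    correlation_accuracy,
    corrected_phenotypes,
    mendelian_sampling,
    ms_variance_ratio,
    split_by_age,
)


def hens_table(n, hatch=None, seed=0):
    rng = np.random.default_rng(seed)
    hatch = hatch if hatch is not None else (np.arange(n) // 10 + 1)
    rows = []
    for h in range(n):
        rows.append((f"h{h:04d}", 1, rng.normal(5, 1), "29-31", hatch[h],
                     rng.normal(10.5, 0.8)))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["animal", "week", "eggs", "afe_class",
                                    "hatch_week", "body_weight"])
    )


def founder_ped(labels, hatch):
    n = len(labels)
    return Pedigree(sire=[-1] * n, dam=[-1] * n, labels=np.asarray(labels),
                    hatch_week=np.asarray(hatch, dtype=float))


class TestSplitByAge:
    def test_youngest_ten_percent(self):
        ph = hens_table(100)
        ped = founder_ped(sorted(ph.animals), np.arange(100) // 10 + 1)
        ref, val = split_by_age(ph, ped, 0.10)
        assert len(val) == 10
        # the ten youngest all come from the last hatch week
        hw = ped.hatch_week[ped.index_of(val.tolist())]
        assert (hw == 10).all()

    def test_ties_broken_by_id_deterministically(self):
        ph = hens_table(40, hatch=np.ones(40))
        ped = founder_ped(sorted(ph.animals), np.ones(40))
        ref1, val1 = split_by_age(ph, ped, 0.25)
        ref2, val2 = split_by_age(ph, ped, 0.25)
        assert len(val1) == 10
        assert np.array_equal(val1, val2)

    def test_cohort_scale_floor(self):
        """10% of a 7422-hen cohort gives 742 validation animals."""
        assert int(np.floor(0.10 * 7422)) == 742

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2])
    def test_bad_fraction_rejected(self, f):
        ph = hens_table(10)
        ped = founder_ped(sorted(ph.animals), np.ones(10))
        with pytest.raises(ValueError):
            split_by_age(ph, ped, f)


class TestCorrectedPhenotypes:
    def _setup(self):
        from eggtraj.basis import legendre_design

        ph = hens_table(20)
        ped = founder_ped(sorted(ph.animals), np.arange(20) // 10 + 1)
        spec = FixedEffectsSpec.from_table(ph)
        return ph, ped, spec, legendre_design(3)

    def test_zero_solution_returns_raw_phenotypes(self):
        ph, ped, spec, basis = self._setup()
        out = corrected_phenotypes(ph, np.zeros(spec.n_columns), spec, ped,
                                   basis)
        merged = out.merge(ph.df, on=["animal", "week"])
        assert np.allclose(merged["ystar"], merged["eggs"])

    def test_cell_constant_absorbed(self):
        """Adding a constant to one hatch-week cell's records and the same
        constant to that cell's fixed solution leaves y* unchanged."""
        ph, ped, spec, basis = self._setup()
        sol = np.zeros(spec.n_columns)
        cell = spec.hw_levels.index((1, 1))
        sol[cell] = 7.0
        df = ph.df.copy()
        in_cell = df["hatch_week"] == 1
        df.loc[in_cell, "eggs"] += 7.0
        out = corrected_phenotypes(PhenotypeTable(df), sol, spec, ped, basis)
        base = corrected_phenotypes(ph, np.zeros(spec.n_columns), spec, ped,
                                    basis)
        assert np.allclose(
            out.sort_values("animal")["ystar"].to_numpy(),
            base.sort_values("animal")["ystar"].to_numpy(),
        )

    def test_cell_mean_oracle(self):
        """With solutions equal to the cell means, y* are the within-cell
        deviations (two-cell hand computation)."""
        from eggtraj.basis import legendre_design

        rows = [("a", 1, 4.0, "29-31", 1, 10.0), ("b", 1, 6.0, "29-31", 1, 10.0),
                ("c", 1, 9.0, "29-31", 2, 10.0), ("d", 1, 11.0, "29-31", 2, 10.0)]
        ph = PhenotypeTable(pd.DataFrame(
            rows, columns=["animal", "week", "eggs", "afe_class", "hatch_week",
                           "body_weight"]))
        ped = founder_ped(["a", "b", "c", "d"], [1, 1, 2, 2])
        spec = FixedEffectsSpec.from_table(ph)
        sol = np.zeros(spec.n_columns)
        sol[spec.hw_levels.index((1, 1))] = 5.0
        sol[spec.hw_levels.index((2, 1))] = 10.0
        out = corrected_phenotypes(ph, sol, spec, ped, legendre_design(3))
        assert np.allclose(sorted(out["ystar"]), [-1.0, -1.0, 1.0, 1.0])

    def test_unseen_level_dropped_with_warning(self):
        ph, ped, spec, basis = self._setup()
        df = ph.df.copy()
        df.loc[0, "hatch_week"] = 99
        extra = PhenotypeTable(df)
        with pytest.warns(UserWarning, match="unseen"):
            out = corrected_phenotypes(extra, np.zeros(spec.n_columns), spec,
                                       ped, basis)
        assert len(out) == len(df) - 1


def make_bv(weekly, ids):
    weekly = np.asarray(weekly, dtype=float)
    return BreedingValues(
        ids=np.asarray(ids), alpha=np.zeros((weekly.shape[0], 4)),
        weekly=weekly, cumulative=weekly.sum(1),
        persistency=persistency(weekly),
    )


class TestCorrelationAccuracy:
    def test_arithmetic(self):
        """cor = 0.2 at h2 = 0.16 gives accuracy 0.5."""
        rng = np.random.default_rng(8)
        n = 4000
        pred = rng.standard_normal(n)
        obs = 0.2 * pred + np.sqrt(1 - 0.04) * rng.standard_normal(n)
        weekly = np.tile(pred[:, None], (1, 24))
        ids = [f"h{i}" for i in range(n)]
        ystar = pd.DataFrame({"animal": ids, "week": 1, "ystar": obs})
        acc = correlation_accuracy(make_bv(weekly, ids), ystar,
                                   np.full(24, 0.16))
        r = np.corrcoef(pred, obs)[0, 1]
        assert acc.loc[acc["week"] == 1, "accuracy"].iloc[0] == pytest.approx(
            r / 0.4
        )
        assert abs(acc.loc[0, "accuracy"] - 0.5) < 0.1

    def test_constant_ebv_reported_missing(self):
        ids = ["a", "b", "c", "d"]
        weekly = np.ones((4, 24))
        ystar = pd.DataFrame({"animal": ids, "week": 1,
                              "ystar": [1.0, 2.0, 3.0, 4.0]})
        acc = correlation_accuracy(make_bv(weekly, ids), ystar,
                                   np.full(24, 0.2))
        assert np.isnan(acc.loc[acc["week"] == 1, "accuracy"].iloc[0])

    def test_too_few_animals_missing(self):
        ids = ["a", "b"]
        weekly = np.random.default_rng(0).normal(size=(2, 24))
        ystar = pd.DataFrame({"animal": ids, "week": 3, "ystar": [1.0, 2.0]})
        acc = correlation_accuracy(make_bv(weekly, ids), ystar,
                                   np.full(24, 0.2))
        assert np.isnan(acc.loc[acc["week"] == 3, "accuracy"].iloc[0])
        assert acc.loc[acc["week"] == 3, "n_validation"].iloc[0] == 2

    def test_invariant_to_constant_ebv_shift(self):
        rng = np.random.default_rng(2)
        n = 50
        ids = [f"h{i}" for i in range(n)]
        weekly = rng.normal(size=(n, 24))
        ystar = pd.DataFrame({"animal": ids * 1, "week": 5,
                              "ystar": rng.normal(size=n)})
        h2 = np.full(24, 0.2)
        a = correlation_accuracy(make_bv(weekly, ids), ystar, h2)
        b = correlation_accuracy(make_bv(weekly + 11.0, ids), ystar, h2)
        pd.testing.assert_frame_equal(a, b)


TRIO_PED = Pedigree(
    sire=[-1, -1, 0, 0], dam=[-1, -1, 1, 1],
    labels=np.array(["s", "d", "o1", "o2"]), hatch_week=[np.nan] * 4,
)


class TestMendelianSampling:
    def test_parent_average_offspring_zero(self):
        weekly = np.vstack([np.full(24, 2.0), np.full(24, 4.0),
                            np.full(24, 3.0), np.full(24, 3.0)])
        labels, ms = mendelian_sampling(
            make_bv(weekly, TRIO_PED.labels), TRIO_PED, ["o1", "o2"]
        )
        assert np.allclose(ms, 0.0)

    def test_arithmetic(self):
        weekly = np.vstack([np.full(24, 2.0), np.full(24, 2.0),
                            np.full(24, 3.0), np.full(24, 1.0)])
        labels, ms = mendelian_sampling(
            make_bv(weekly, TRIO_PED.labels), TRIO_PED, ["o1", "o2"]
        )
        by = dict(zip(labels, ms[:, 0]))
        assert by["o1"] == pytest.approx(1.0)
        assert by["o2"] == pytest.approx(-1.0)

    def test_only_full_trios_eligible(self):
        ped = Pedigree(sire=[-1, -1, 0, -1], dam=[-1, -1, 1, 1],
                       labels=np.array(["s", "d", "o1", "o2"]),
                       hatch_week=[np.nan] * 4)
        weekly = np.random.default_rng(0).normal(size=(4, 24))
        labels, ms = mendelian_sampling(
            make_bv(weekly, ped.labels), ped, ["o1", "o2"]
        )
        assert list(labels) == ["o1"]

    def test_no_eligible_animals_fatal(self):
        weekly = np.zeros((4, 24))
        with pytest.raises(ModelError, match="parents"):
            mendelian_sampling(make_bv(weekly, TRIO_PED.labels), TRIO_PED,
                               ["s", "d"])


class TestNu:
    def test_zero_ebvs_zero_nu(self):
        ms = np.zeros((20, 24))
        nu = ms_variance_ratio(ms, np.ones(24))
        assert np.allclose(nu, 0.0)

    def test_constructed_unit_ratio(self):
        rng = np.random.default_rng(0)
        ms = rng.standard_normal((5000, 24))
        sigma2 = np.full(24, 2.0)  # 0.5 * sigma2 = 1 = Var(ms)
        nu = ms_variance_ratio(ms, sigma2)
        assert np.allclose(nu, 1.0, atol=0.08)

    def test_too_few_animals_fatal(self):
        with pytest.raises(ModelError, match="10"):
            ms_variance_ratio(np.zeros((5, 24)), np.ones(24))

    def test_soft_warning_above_one(self):
        rng = np.random.default_rng(1)
        ms = rng.standard_normal((2000, 24)) * 2.0
        with pytest.warns(UserWarning, match="1.05"):
            ms_variance_ratio(ms, np.full(24, 2.0))


class TestTruthConsistency:
    def test_nu_of_true_breeding_values_near_one(self):
        """Substituting true breeding values for EBVs, nu estimates the
        realised Mendelian-sampling fraction and approaches 1 with many
        eligible trios."""
        from eggtraj.basis import legendre_design
        from eggtraj.simulate import SimConfig, simulate_dataset

        cfg = SimConfig(n_generations=6, n_sires=8, n_dams=60,
                        progeny_per_dam=5, n_snp=800, seed=31)
        ds = simulate_dataset(cfg)
        ped = ds.pedigree
        basis = legendre_design(3)
        bv = make_bv(ds.truth.weekly_genetic, ped.labels)
        hens = ds.phenotypes.animals
        _, ms = mendelian_sampling(bv, ped, hens)
        sigma2 = np.diag(basis.Phi @ ds.config.C_true @ basis.Phi.T)
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            nu = ms_variance_ratio(ms, sigma2)
        assert ms.shape[0] > 500
        assert np.nanmean(nu) == pytest.approx(1.0, abs=0.1)


def test_ssgblup_nu_exceeds_pblup_nu(ten_seed_fits):
    """The Mendelian-sampling variance ratio is larger under the
    single-step genomic structure in at least 8 of 10 populations."""
    wins = sum(r["nu_ssgblup"] >= r["nu_pblup"] for r in ten_seed_fits)
    assert wins >= 8, [
        (round(r["nu_pblup"], 3), round(r["nu_ssgblup"], 3))
        for r in ten_seed_fits
    ]
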