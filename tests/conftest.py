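"""Shared fixtures: study parameter objects and the two expensive
simulation-based fixtures (a Gibbs recovery chain and a ten-seed panel of
PBLUP/ssGBLUP fits) reused across test modules."""

import numpy as np
import pytest

from eggtraj import params
from eggtraj.basis import legendre_design
from eggtraj.covfun import CovFunction, ResidualSpec, trajectory_parameters
from eggtraj.genomic import (
    HStructure,
    blend_G,
    build_G_vanraden1,
    build_H_inverse,
    genotyped_positions,
    invert_dense,
    qc_genotypes,
)
from eggtraj.model import (
    FixedEffectsSpec,
    assemble_mme,
    build_design,
    ebv_trajectory,
    solve_mme,
)
from eggtraj.pedigree import build_A, build_A_inverse
from eggtraj.simulate import SimConfig, simulate_dataset
from eggtraj.validate import mendelian_sampling, ms_variance_ratio, split_by_age


@pytest.fixture(scope="session")
def basis():
    return legendre_design(3)


@pytest.fixture(scope="session")
def study(basis):
    """Reference coefficient covariances and residual spec."""
    return {
        "add": CovFunction(params.ADDITIVE_COEFF_COV, basis, "additive"),
        "pe": CovFunction(params.PE_COEFF_COV, basis, "pe"),
        "res": ResidualSpec(tuple(params.RESIDUAL_PERIODS)),
    }


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic dataset for structural tests."""
    cfg = SimConfig(
        n_generations=4, n_sires=4, n_dams=12, progeny_per_dam=4, n_snp=300,
        seed=3,
    )
    return simulate_dataset(cfg)


def align_genotypes_to_pedigree(geno, ped):
    """QC and reorder dosage rows into pedigree order; returns (geno, gi)."""
    qcg = qc_genotypes(geno)
    gi = genotyped_positions(ped, qcg.animal_ids)
    row_of = {str(a): i for i, a in enumerate(qcg.animal_ids)}
    qcg.dosages = qcg.dosages[[row_of[str(l)] for l in ped.labels[gi]]]
    qcg.animal_ids = ped.labels[gi]
    return qcg, gi


def fit_both_structures(ds, mask_fraction=0.10, tol=1e-8):
    """Fit RR-PBLUP and RR-ssGBLUP on one dataset with the youngest hens
    masked; returns everything the accuracy statistics need."""
    ped, ph = ds.pedigree, ds.phenotypes
    basis = legendre_design(ds.config.basis_order)
    ref, val = split_by_age(ph, ped, mask_fraction)
    train = ph.subset(ref)
    spec = FixedEffectsSpec.from_table(train)
    designs = build_design(train, spec, basis, ped)
    C, P, res = ds.config.C_true, ds.config.P_true, ds.config.residual_spec
    Ainv = build_A_inverse(ped)
    sol_p = solve_mme(assemble_mme(designs, Ainv, C, P, res), tol=tol)
    qcg, gi = align_genotypes_to_pedigree(ds.genotypes, ped)
    A22 = build_A(ped, subset=ped.labels[gi])
    Gb = blend_G(build_G_vanraden1(qcg), A22, 0.95)
    Hinv = build_H_inverse(
        HStructure(
            Ainv=Ainv,
            Ginv=invert_dense(Gb, "Ginv"),
            A22inv=invert_dense(A22, "A22inv"),
            genotyped_index=gi,
        )
    )
    sol_g = solve_mme(assemble_mme(designs, Hinv, C, P, res), tol=tol)
    return {
        "ped": ped, "ph": ph, "train": train, "spec": spec,
        "designs": designs, "basis": basis, "ref": ref, "val": val,
        "sol_p": sol_p, "sol_g": sol_g, "gi": gi,
        "C": C, "P": P, "res": res,
    }


@pytest.fixture(scope="session")
def ten_seed_fits():
    """PBLUP vs ssGBLUP on ten independent synthetic populations.

    ~1580 hens each, 45% genotyped youngest-first, genomic trait mode.
    Records per seed: mean correlation between true and estimated weekly
    genetic values among validation hens, and the mean Mendelian-sampling
    variance ratio, for both relationship structures.
    """
    out = []
    for seed in range(10):
        cfg = SimConfig(
            n_generations=8, n_sires=8, n_dams=90, progeny_per_dam=5,
            n_snp=1000, genotyped_fraction=0.45, seed=100 + seed,
        )
        ds = simulate_dataset(cfg)
        fit = fit_both_structures(ds)
        ped, basis = fit["ped"], fit["basis"]
        val_ix = ped.index_of(fit["val"].tolist())
        true_w = ds.truth.weekly_genetic[val_ix]
        tp = trajectory_parameters(
            CovFunction(fit["C"], basis, "additive"),
            CovFunction(fit["P"], basis, "pe"),
            fit["res"],
        )
        rec = {"n_hens": len(ds.phenotypes.animals), "n_val": len(val_ix)}
        for tag, sol in (("pblup", fit["sol_p"]), ("ssgblup", fit["sol_g"])):
            ebvw = (sol.alpha @ basis.Phi.T)[val_ix]
            rec[f"acc_{tag}"] = np.mean(
                [np.corrcoef(true_w[:, t], ebvw[:, t])[0, 1] for t in range(24)]
            )
            ebv = ebv_trajectory(sol, basis, ped.labels)
            _, ms = mendelian_sampling(ebv, ped, fit["ref"])
            rec[f"nu_{tag}"] = np.nanmean(
                ms_variance_ratio(ms, tp.var_additive)
            )
        out.append(rec)
    return out


@pytest.fixture(scope="session")
def recovery_run():
    """Gibbs parameter recovery at ~1250 hens, 20k rounds (desk scale)."""
    from eggtraj.gibbs import ChainConfig, run_gibbs

    cfg = SimConfig(
        n_generations=8, n_sires=8, n_dams=70, progeny_per_dam=5, n_snp=1000,
        seed=11,
    )
    ds = simulate_dataset(cfg)
    ped, ph = ds.pedigree, ds.phenotypes
    basis = legendre_design(3)
    designs = build_design(ph, FixedEffectsSpec.from_table(ph), basis, ped)
    chain = run_gibbs(
        designs,
        build_A_inverse(ped),
        ds.config.residual_spec,
        ChainConfig(rounds=20_000, burn_in=2_000, thin=10, seed=1),
    )
    return {"ds": ds, "chain": chain, "basis": basis}
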