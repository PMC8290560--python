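"""Synthetic turkey egg-production data with known generating truth.

Generates a discrete-generation pedigree under random mating, SNP
genotypes by gene dropping over unlinked loci (with planted low-MAF,
high-missingness and sex-chromosome SNPs so QC has real work to do), and
24-week egg-count trajectories with the exact covariance structure the
random-regression model assumes: additive coefficients transmitted through
the pedigree with Mendelian-sampling variance d_i * C, iid permanent
environmental coefficients, hatch-week-by-week and week-by-AFE fixed
effects, per-week body-weight slopes, and four-period heterogeneous
residuals.

Defaults reproduce the covariance structure estimated for a commercial
turkey female line (see :mod:`eggtraj.params`), so parameter-recovery runs
have published-scale generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import params
from .basis import legendre_design
from .covfun import ResidualSpec, nearest_pd
from .genomic import GenotypeData
from .model import PhenotypeTable
from .pedigree import Pedigree, UNKNOWN, inbreeding

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_trajectories",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class SimConfig:
    """Generator settings; scale parameters are per generation.

    The population structure emulates a pedigreed breeding nucleus: 8
    discrete generations, a limited sire team, hatch-week contemporary
    groups within generation, and genotyping concentrated in the youngest
    generations.
    """

    n_generations: int = 8
    n_sires: int = 10
    n_dams: int = 40
    progeny_per_dam: int = 5
    n_hatch_weeks: int = 4          # contemporary groups per generation
    genotyped_fraction: float = 0.45
    n_snp: int = 2000
    n_autosomes: int = 10
    frac_sex_chrom: float = 0.05    # SNPs placed on the sex chromosome
    frac_low_maf: float = 0.05      # founder MAF planted below the QC floor
    frac_high_missing: float = 0.05
    high_missing_rate: float = 0.20
    base_missing_rate: float = 0.01
    C_true: np.ndarray = field(
        default_factory=lambda: nearest_pd(params.ADDITIVE_COEFF_COV)
    )
    P_true: np.ndarray = field(
        default_factory=lambda: nearest_pd(params.PE_COEFF_COV)
    )
    residual_periods: tuple = field(
        default_factory=lambda: tuple(params.RESIDUAL_PERIODS)
    )
    afe_probs: tuple = (0.35, 0.45, 0.20)
    bodyweight_mean: float = 10.5   # kg at start of lay
    bodyweight_sd: float = 0.8
    bw_slope_sd: float = 0.10       # eggs per kg, per-week slopes ~ N(0, sd^2)
    hatch_effect_sd: float = 0.30
    afe_effect_sd: float = 0.20
    missing_week_rate: float = 0.03
    basis_order: int = 3
    #: "genomic": additive coefficients are polygenic sums of per-SNP
    #: effects over the autosomal panel (markers are the causal loci, so
    #: genomic relationships carry real information);
    #: "pedigree": coefficients transmitted through the pedigree with
    #: Mendelian sampling independent of the genomes (markers neutral).
    trait_mode: str = "genomic"
    seed: int = 0

    def __post_init__(self):
        self.C_true = nearest_pd(np.asarray(self.C_true, float))
        self.P_true = nearest_pd(np.asarray(self.P_true, float))
        if abs(sum(self.afe_probs) - 1.0) > 1e-9:
            raise ValueError("AFE class probabilities must sum to 1")
        if self.trait_mode not in ("genomic", "pedigree"):
            raise ValueError("trait_mode must be 'genomic' or 'pedigree'")
        if self.n_sires < 1 or self.n_dams < 1:
            raise ValueError("at least one sire and one dam are required")

    @property
    def residual_spec(self) -> ResidualSpec:
        return ResidualSpec(self.residual_periods)


@dataclass
class TruthRecord:
    """Generating truth: per-animal coefficients and dataset parameters."""

    alpha: np.ndarray               # n_animals x k additive coefficients
    pe: np.ndarray                  # per recorded hen (aligned to pe_ids)
    pe_ids: np.ndarray
    weekly_genetic: np.ndarray      # n_animals x 24, Phi alpha
    C: np.ndarray
    P: np.ndarray
    residual_periods: tuple
    hw_means: dict                  # (hatch_week, week) -> mean
    afe_means: dict                 # (afe_class, week) -> mean
    bw_slopes: np.ndarray           # per week


def simulate_pedigree(cfg: SimConfig, rng=None) -> Pedigree:
    """Discrete-generation random-mating pedigree without selfing.

    Generation 0 holds unrelated founders; each later generation draws its
    sire and dam teams from the previous generation's animals (falling back
    to founders in generation 1), mates each dam to one random sire, and
    assigns each dam's brood to one hatch week within the generation.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    sire_ix, dam_ix, sex, gen, hatch = [], [], [], [], []

    def add(s, d, sx, g, hw):
        sire_ix.append(s)
        dam_ix.append(d)
        sex.append(sx)
        gen.append(g)
        hatch.append(hw)
        return len(sire_ix) - 1

    males = [add(UNKNOWN, UNKNOWN, 0, 0, np.nan) for _ in range(cfg.n_sires)]
    females = [add(UNKNOWN, UNKNOWN, 1, 0, np.nan) for _ in range(cfg.n_dams)]

    for g in range(1, cfg.n_generations):
        sires = rng.choice(males, size=min(cfg.n_sires, len(males)), replace=False)
        dams = rng.choice(females, size=min(cfg.n_dams, len(females)), replace=False)
        new_m, new_f = [], []
        for d in dams:
            s = int(rng.choice(sires))
            hw = (g - 1) * cfg.n_hatch_weeks + int(
                rng.integers(1, cfg.n_hatch_weeks + 1)
            )
            for _ in range(cfg.progeny_per_dam):
                sx = int(rng.integers(0, 2))
                i = add(s, int(d), sx, g, hw)
                (new_f if sx else new_m).append(i)
        if new_m:
            males = new_m
        if new_f:
            females = new_f

    n = len(sire_ix)
    return Pedigree(
        sire=np.array(sire_ix),
        dam=np.array(dam_ix),
        labels=np.array([f"T{i + 1:05d}" for i in range(n)]),
        hatch_week=np.array(hatch, dtype=float),
        sex=np.array(sex),
        generation=np.array(gen),
    )


def genotyped_animals(ped: Pedigree, cfg: SimConfig) -> np.ndarray:
    """Youngest-first genotyping scheme: latest hatch weeks until the
    configured fraction of the pedigree is genotyped (founders last)."""
    n_geno = int(round(cfg.genotyped_fraction * ped.n))
    hw = np.where(np.isnan(ped.hatch_week), -1.0, ped.hatch_week)
    order = np.lexsort((ped.labels, -hw))
    return np.sort(order[:n_geno])


def _drop_genomes(ped: Pedigree, cfg: SimConfig, rng=None):
    """Gene dropping over unlinked biallelic loci for the WHOLE pedigree.

    Founder haplotype alleles are Bernoulli draws at per-SNP frequencies ~
    U(0.05, 0.5); a planted fraction of SNPs gets sub-threshold MAF or a
    sex-chromosome label so that QC removals are verifiable.  Returns
    (dosages n x m, founder_freq, chrom, pos, low_ix, sex_ix).
    """
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    m = cfg.n_snp
    freq = rng.uniform(0.05, 0.5, size=m)
    n_low = int(round(cfg.frac_low_maf * m))
    low_ix = rng.choice(m, size=n_low, replace=False)
    freq[low_ix] = rng.uniform(0.005, 0.035, size=n_low)

    chrom = rng.integers(1, cfg.n_autosomes + 1, size=m).astype(object)
    n_sex = int(round(cfg.frac_sex_chrom * m))
    sex_ix = rng.choice(np.setdiff1d(np.arange(m), low_ix), size=n_sex, replace=False)
    chrom[sex_ix] = "Z"
    pos = rng.integers(1, 10_000_000, size=m)

    n = ped.n
    hap = np.empty((n, 2, m), dtype=np.int8)
    cols = np.arange(m)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN:
            hap[i, 0] = rng.random(m) < freq
        else:
            hap[i, 0] = hap[s, rng.integers(0, 2, size=m), cols]
        if d == UNKNOWN:
            hap[i, 1] = rng.random(m) < freq
        else:
            hap[i, 1] = hap[d, rng.integers(0, 2, size=m), cols]
    dosages = hap.sum(axis=1).astype(float)
    return dosages, freq, chrom, pos, low_ix, sex_ix


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig, rng=None, _genomes=None
) -> GenotypeData:
    """Observed SNP panel for the genotyped (youngest-first) subset.

    Adds missingness on top of the dropped genomes: a base rate
    everywhere plus a planted high-missingness SNP fraction that fails the
    call-rate filter.
    """
    if _genomes is None:
        _genomes = _drop_genomes(ped, cfg, rng)
    dosages, freq, chrom, pos, low_ix, sex_ix = _genomes
    # a dedicated stream so the shared-genomes and standalone paths agree
    rng = np.random.default_rng(cfg.seed + 3)
    m = cfg.n_snp

    geno_ix = genotyped_animals(ped, cfg)
    M = dosages[geno_ix].copy()

    miss_rate = np.full(m, cfg.base_missing_rate)
    n_hm = int(round(cfg.frac_high_missing * m))
    hm_ix = rng.choice(
        np.setdiff1d(np.arange(m), np.concatenate([low_ix, sex_ix])),
        size=n_hm,
        replace=False,
    )
    miss_rate[hm_ix] = cfg.high_missing_rate
    mask = rng.random(M.shape) < miss_rate[None, :]
    M[mask] = np.nan

    snp_map = pd.DataFrame(
        {
            "snp": [f"snp{j + 1:05d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "planted": np.where(
                np.isin(np.arange(m), low_ix), "low_maf",
                np.where(
                    np.isin(np.arange(m), sex_ix), "sex_chrom",
                    np.where(np.isin(np.arange(m), hm_ix), "high_missing", ""),
                ),
            ),
        }
    )
    return GenotypeData(
        dosages=M, snp_map=snp_map, animal_ids=ped.labels[geno_ix]
    )


def simulate_trajectories(
    ped: Pedigree, cfg: SimConfig, rng=None, _genomes=None
) -> tuple[PhenotypeTable, TruthRecord]:
    """Simulate weekly egg counts for all non-founder females.

    In the default genomic trait mode every autosomal SNP carries a
    4-vector effect on the regression coefficients, drawn iid
    N(0, C / (2 sum p(1-p))) so that founder coefficients have covariance
    C; an animal's additive coefficients are the centred dosage-weighted
    sums, and Mendelian sampling arises from actual segregation.  In
    "pedigree" mode coefficients are transmitted directly: founders
    alpha ~ N(0, C); descendants alpha_i = 0.5 (alpha_s + alpha_d) + m_i
    with m_i ~ N(0, d_i C), d_i = 0.5 - 0.25 (F_s + F_d).

    Records add hatch-week x week and week x AFE-class means, a per-week
    body-weight slope, the PE trajectory and a period-specific residual;
    the weekly phenotypic mean curve is anchored at the reference
    population's weekly means.
    """
    rng = np.random.default_rng(cfg.seed + 2 if rng is None else rng)
    basis = legendre_design(cfg.basis_order)
    k = basis.n_coeff
    C, P = cfg.C_true, cfg.P_true
    Lc = np.linalg.cholesky(C)
    Lp = np.linalg.cholesky(P)

    n = ped.n
    if cfg.trait_mode == "genomic":
        if _genomes is None:
            _genomes = _drop_genomes(ped, cfg)
        dosages, freq, chrom, _, _, _ = _genomes
        causal = np.flatnonzero(chrom != "Z")
        p = freq[causal]
        denom = 2.0 * np.sum(p * (1.0 - p))
        beta = rng.standard_normal((causal.size, k)) @ Lc.T / np.sqrt(denom)
        alpha = (dosages[:, causal] - 2.0 * p) @ beta
    else:
        F = inbreeding(ped)
        alpha = np.zeros((n, k))
        for i in range(n):
            s, d = ped.sire[i], ped.dam[i]
            di = 0.5
            base = np.zeros(k)
            if s == UNKNOWN:
                di += 0.25
            else:
                di -= 0.25 * F[s]
                base += 0.5 * alpha[s]
            if d == UNKNOWN:
                di += 0.25
            else:
                di -= 0.25 * F[d]
                base += 0.5 * alpha[d]
            alpha[i] = base + np.sqrt(di) * (Lc @ rng.standard_normal(k))

    is_hen = (ped.sex == 1) & (ped.generation > 0) if ped.sex is not None \
        else ~ped.is_founder()
    hen_ix = np.flatnonzero(is_hen)
    pe = rng.standard_normal((hen_ix.size, k)) @ Lp.T

    res = cfg.residual_spec
    weeks = basis.weeks
    period = res.period_of(weeks)
    sd_e = np.sqrt(res.variances)[period]

    base_curve = params.WEEKLY_EGG_MEAN
    hw_levels = sorted(set(ped.hatch_week[hen_ix][~np.isnan(ped.hatch_week[hen_ix])]))
    hw_dev = {h: rng.normal(0.0, cfg.hatch_effect_sd) for h in hw_levels}
    hw_means = {
        (h, int(w)): base_curve[iw] + hw_dev[h]
        for h in hw_levels
        for iw, w in enumerate(weeks)
    }
    afe_means = {
        (c, int(w)): rng.normal(0.0, cfg.afe_effect_sd) if ci > 0 else 0.0
        for ci, c in enumerate(params.AFE_CLASSES)
        for w in weeks
    }
    bw_slopes = rng.normal(0.0, cfg.bw_slope_sd, size=weeks.size)

    afe_class = rng.choice(
        len(params.AFE_CLASSES), size=hen_ix.size, p=list(cfg.afe_probs)
    )
    bw = rng.normal(cfg.bodyweight_mean, cfg.bodyweight_sd, size=hen_ix.size)

    rows = []
    for hi, i in enumerate(hen_ix):
        h = ped.hatch_week[i]
        cls = params.AFE_CLASSES[afe_class[hi]]
        keep = rng.random(weeks.size) >= cfg.missing_week_rate
        gvals = basis.Phi @ alpha[i]
        pvals = basis.Phi @ pe[hi]
        e = rng.standard_normal(weeks.size) * sd_e
        for iw, w in enumerate(weeks):
            if not keep[iw]:
                continue
            y = (
                hw_means[(h, int(w))]
                + afe_means[(cls, int(w))]
                + bw_slopes[iw] * (bw[hi] - cfg.bodyweight_mean)
                + gvals[iw]
                + pvals[iw]
                + e[iw]
            )
            rows.append(
                (ped.labels[i], int(w), y, cls, h, bw[hi])
            )
    ph = PhenotypeTable(
        pd.DataFrame(
            rows,
            columns=["animal", "week", "eggs", "afe_class", "hatch_week",
                     "body_weight"],
        )
    )
    truth = TruthRecord(
        alpha=alpha,
        pe=pe,
        pe_ids=ped.labels[hen_ix],
        weekly_genetic=alpha @ basis.Phi.T,
        C=C,
        P=P,
        residual_periods=cfg.residual_periods,
        hw_means=hw_means,
        afe_means=afe_means,
        bw_slopes=bw_slopes,
    )
    return ph, truth


@dataclass
class SimulatedDataset:
    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeData
    phenotypes: PhenotypeTable
    truth: TruthRecord


def simulate_dataset(cfg: SimConfig | None = None, seed: int | None = None
                     ) -> SimulatedDataset:
    """Generate pedigree, genotypes and trajectories under one config."""
    cfg = SimConfig() if cfg is None else cfg
    if seed is not None:
        cfg = SimConfig(**{**asdict(cfg), "seed": seed})
    ped = simulate_pedigree(cfg)
    genomes = _drop_genomes(ped, cfg)
    geno = simulate_genotypes(ped, cfg, _genomes=genomes)
    ph, truth = simulate_trajectories(ped, cfg, _genomes=genomes)
    return SimulatedDataset(
        config=cfg, pedigree=ped, genotypes=geno, phenotypes=ph, truth=truth
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write pedigree/phenotype/genotype/truth files and the config used."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "genotypes": outdir / "genotypes.txt",
        "snp_map": outdir / "snp_map.csv",
        "truth_alpha": outdir / "truth_alpha.csv",
        "truth_pe": outdir / "truth_pe.csv",
        "config": outdir / "sim_config.yaml",
    }
    _io.write_pedigree(ds.pedigree, paths["pedigree"])
    _io.write_phenotypes(ds.phenotypes, paths["phenotypes"])
    _io.write_genotypes(ds.genotypes, paths["genotypes"], paths["snp_map"])
    k = ds.truth.alpha.shape[1]
    pd.DataFrame(
        ds.truth.alpha, columns=[f"alpha_{i}" for i in range(k)]
    ).assign(animal=ds.pedigree.labels).to_csv(paths["truth_alpha"], index=False)
    pd.DataFrame(
        ds.truth.pe, columns=[f"pe_{i}" for i in range(k)]
    ).assign(animal=ds.truth.pe_ids).to_csv(paths["truth_pe"], index=False)
    _io.write_sim_config(ds.config, paths["config"])
    return paths
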