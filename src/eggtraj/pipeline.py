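"""Stage runner tying simulation, fitting, sampling and validation together.

Each stage reads its inputs from, and writes its artifacts to, one run
directory.  Artifacts carry the configuration hash; a stage refuses to mix
artifacts written under a different configuration.  Stage order:
simulate -> qc -> fit-pblup / fit-ssgblup -> gibbs -> validate -> report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from . import params
from .basis import legendre_design
from .covfun import (
    CovFunction,
    ResidualSpec,
    nearest_pd,
    trajectory_parameters,
)
from .genomic import (
    HStructure,
    blend_G,
    build_G_vanraden1,
    build_H_inverse,
    genotyped_positions,
    invert_dense,
    qc_genotypes,
)
from .gibbs import ChainConfig, diagnostics, posterior_summary, run_gibbs
from .model import (
    FixedEffectsSpec,
    ModelError,
    assemble_mme,
    build_design,
    ebv_trajectory,
    solve_mme,
)
from .pedigree import build_A, build_A_inverse, read_pedigree
from .simulate import SimConfig, simulate_dataset, write_dataset
from .validate import (
    ValidationResult,
    correlation_accuracy,
    corrected_phenotypes,
    mendelian_sampling,
    ms_variance_ratio,
    split_by_age,
)

log = logging.getLogger("eggtraj")

STAGES = ("simulate", "qc", "fit-pblup", "fit-ssgblup", "gibbs", "validate",
          "report")

#: Weeks shown in the selected-week correlation report table.
REPORT_WEEKS = (1, 4, 8, 12, 16, 20, 24)


@dataclass
class RunConfig:
    """One run's full configuration; defaults follow the reference study
    settings (order-3 basis, 0.95 blend, 5% MAF, 95% call rate, 10%
    validation fraction, four-period residuals)."""

    outdir: str = "eggtraj_run"
    pedigree: str | None = None
    phenotypes: str | None = None
    genotypes: str | None = None
    snp_map: str | None = None
    basis_order: int = params.DEFAULT_ORDER
    blend_weight: float = params.DEFAULT_BLEND_WEIGHT
    maf_min: float = params.DEFAULT_MAF_MIN
    callrate_min: float = params.DEFAULT_CALLRATE_MIN
    validation_fraction: float = params.DEFAULT_VALIDATION_FRACTION
    residual_periods: tuple = field(
        default_factory=lambda: tuple(params.RESIDUAL_PERIODS)
    )
    additive_cov: list = field(
        default_factory=lambda: params.ADDITIVE_COEFF_COV.tolist()
    )
    pe_cov: list = field(default_factory=lambda: params.PE_COEFF_COV.tolist())
    gibbs_rounds: int = 200_000
    gibbs_burn_in: int = 20_000
    gibbs_thin: int = 50
    sim: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def hash(self) -> str:
        return _io.config_hash(self)


class PipelineError(RuntimeError):
    pass


class Runner:
    """Executes stages against one run directory."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.basis = legendre_design(cfg.basis_order)
        self.res = ResidualSpec(cfg.residual_periods)

    # -- helpers -------------------------------------------------------
    def _artifact(self, name: str, needed_by: str, producer: str) -> Path:
        path = self.outdir / name
        if not path.exists():
            raise PipelineError(
                f"stage '{needed_by}' needs {name}; run stage '{producer}' first"
            )
        prov = _io.read_provenance(path)
        if prov is not None and prov != self.cfg.hash:
            raise PipelineError(
                f"{name} was produced under configuration {prov}, current "
                f"configuration is {self.cfg.hash}; refusing to mix artifacts"
            )
        return path

    def _pedigree_path(self, stage):
        if self.cfg.pedigree:
            return Path(self.cfg.pedigree)
        return self._artifact("pedigree.csv", stage, "simulate")

    def _phenotype_path(self, stage):
        if self.cfg.phenotypes:
            return Path(self.cfg.phenotypes)
        return self._artifact("phenotypes.csv", stage, "simulate")

    def _genotype_paths(self, stage):
        if self.cfg.genotypes:
            if not self.cfg.snp_map:
                raise PipelineError("genotypes given without snp_map")
            return Path(self.cfg.genotypes), Path(self.cfg.snp_map)
        qc_path = self.outdir / "genotypes_qc.txt"
        if qc_path.exists():
            return (
                self._artifact("genotypes_qc.txt", stage, "qc"),
                self._artifact("snp_map_qc.csv", stage, "qc"),
            )
        return (
            self._artifact("genotypes.txt", stage, "simulate"),
            self._artifact("snp_map.csv", stage, "simulate"),
        )

    def _variance_components(self):
        """Posterior means if the gibbs stage ran, else configured values."""
        summ = self.outdir / "posterior_summary.csv"
        C = nearest_pd(np.asarray(self.cfg.additive_cov, float))
        P = nearest_pd(np.asarray(self.cfg.pe_cov, float))
        res = self.res
        if summ.exists():
            df = pd.read_csv(summ, comment="#").set_index("parameter")["mean"]
            k = self.basis.n_coeff
            Cm = np.empty((k, k))
            Pm = np.empty((k, k))
            for i in range(k):
                for j in range(i, k):
                    Cm[i, j] = Cm[j, i] = df[f"C_{i}{j}"]
                    Pm[i, j] = Pm[j, i] = df[f"P_{i}{j}"]
            C, P = nearest_pd(Cm), nearest_pd(Pm)
            res = ResidualSpec(
                tuple(
                    (lo, hi, float(df[f"res_w{lo}_{hi}"]))
                    for lo, hi, _ in res.periods
                )
            )
        return C, P, res

    def _fit(self, structure: str, mask_validation: bool = False):
        ped = read_pedigree(self._pedigree_path(structure))
        ph = _io.read_phenotypes(self._phenotype_path(structure))
        val_ids = np.array([])
        if mask_validation:
            _, val_ids = split_by_age(ph, ped, self.cfg.validation_fraction)
            train = ph.subset(set(ph.animals) - set(val_ids))
        else:
            train = ph
        spec = FixedEffectsSpec.from_table(train)
        designs = build_design(train, spec, self.basis, ped)
        C, P, res = self._variance_components()
        Ainv = build_A_inverse(ped)
        gi = None
        if structure == "fit-pblup":
            Kinv = Ainv
        else:
            gpath, mpath = self._genotype_paths(structure)
            geno = _io.read_genotypes(gpath, mpath)
            if not geno.qc_done:
                geno = qc_genotypes(geno, self.cfg.maf_min, self.cfg.callrate_min)
            gi = genotyped_positions(ped, geno.animal_ids)
            geno_labels = ped.labels[gi]
            # reorder dosage rows into pedigree order
            row_of = {str(a): i for i, a in enumerate(geno.animal_ids)}
            order = [row_of[str(l)] for l in geno_labels]
            geno.dosages = geno.dosages[order]
            geno.animal_ids = geno_labels
            G = build_G_vanraden1(geno)
            A22 = build_A(ped, subset=geno_labels)
            Gb = blend_G(G, A22, self.cfg.blend_weight)
            Kinv = build_H_inverse(
                HStructure(
                    Ainv=Ainv,
                    Ginv=invert_dense(Gb, "Ginv"),
                    A22inv=invert_dense(A22, "A22inv"),
                    genotyped_index=gi,
                )
            )
        sys = assemble_mme(designs, Kinv, C, P, res)
        sol = solve_mme(sys)
        ebv = ebv_trajectory(sol, self.basis, ped.labels,
                             genomic=structure != "fit-pblup")
        return ped, ph, train, spec, designs, sol, ebv, (C, P, res), val_ids, gi

    # -- stages --------------------------------------------------------
    def simulate(self):
        sim_cfg = SimConfig(**{"seed": self.cfg.seed, **self.cfg.sim})
        ds = simulate_dataset(sim_cfg)
        paths = write_dataset(ds, self.outdir)
        for name in ("pedigree", "phenotypes"):
            df = pd.read_csv(paths[name])
            _io._write_with_provenance(df, paths[name], self.cfg.hash)
        log.info("simulated %d animals, %d records", ds.pedigree.n,
                 ds.phenotypes.n_records)
        return paths

    def qc(self):
        gpath, mpath = self._genotype_paths("qc")
        geno = _io.read_genotypes(gpath, mpath)
        out = qc_genotypes(geno, self.cfg.maf_min, self.cfg.callrate_min)
        _io._write_with_provenance(
            out.qc_log, self.outdir / "qc_report.csv", self.cfg.hash
        )
        _io.write_genotypes(
            out, self.outdir / "genotypes_qc.txt",
            self.outdir / "snp_map_qc.csv", provenance=self.cfg.hash,
        )
        log.info("QC kept %d of %d SNPs", out.n_snps, geno.n_snps)
        return out

    def fit(self, structure: str):
        if structure == "fit-ssgblup" and not self.cfg.genotypes:
            # fail early with a clear message if no genotypes exist at all
            if not (self.outdir / "genotypes.txt").exists() and not (
                self.outdir / "genotypes_qc.txt"
            ).exists():
                raise PipelineError(
                    "fit-ssgblup requires genotypes; none configured and none "
                    "found in the run directory (run 'simulate' or 'qc' first)"
                )
        ped, ph, train, spec, designs, sol, ebv, _, _, _ = self._fit(structure)
        tag = "pblup" if structure == "fit-pblup" else "ssgblup"
        _io._write_with_provenance(
            sol.fixed_frame(spec), self.outdir / f"solutions_fixed_{tag}.csv",
            self.cfg.hash,
        )
        _io._write_with_provenance(
            ebv.to_frame(self.basis.weeks), self.outdir / f"ebv_{tag}.csv",
            self.cfg.hash,
        )
        return sol, ebv

    def gibbs(self):
        ped = read_pedigree(self._pedigree_path("gibbs"))
        ph = _io.read_phenotypes(self._phenotype_path("gibbs"))
        spec = FixedEffectsSpec.from_table(ph)
        designs = build_design(ph, spec, self.basis, ped)
        Kinv = build_A_inverse(ped)
        cfg = ChainConfig(
            rounds=self.cfg.gibbs_rounds,
            burn_in=self.cfg.gibbs_burn_in,
            thin=self.cfg.gibbs_thin,
            seed=self.cfg.seed,
        )
        chain = run_gibbs(designs, Kinv, self.res, cfg)
        chain.to_csv(self.outdir)
        summary = posterior_summary(chain)
        _io._write_with_provenance(
            summary, self.outdir / "posterior_summary.csv", self.cfg.hash
        )
        _io._write_with_provenance(
            diagnostics(chain), self.outdir / "chain_diagnostics.csv",
            self.cfg.hash,
        )
        return chain

    def validate(self):
        results = []
        have_geno = bool(self.cfg.genotypes) or (
            self.outdir / "genotypes.txt"
        ).exists() or (self.outdir / "genotypes_qc.txt").exists()
        structures = ["fit-pblup"] + (["fit-ssgblup"] if have_geno else [])
        # weekly h2 on the genomic (preferred) scale for both methods
        h2 = None
        for structure in structures:
            (ped, ph, train, spec, designs, sol, ebv, (C, P, res), val_ids,
             designs_gi) = self._fit(structure, mask_validation=True)
            tp = trajectory_parameters(
                CovFunction(C, self.basis, "additive"),
                CovFunction(P, self.basis, "pe"),
                res,
            )
            if h2 is None or structure == "fit-ssgblup":
                h2 = tp.heritability
            ystar = corrected_phenotypes(
                ph.subset(val_ids), sol.fixed, spec, ped, self.basis
            )
            acc = correlation_accuracy(ebv, ystar, h2, self.basis.weeks)
            _, ms = mendelian_sampling(ebv, ped, train.animals)
            nu = ms_variance_ratio(ms, tp.var_additive)
            label = "RR-PBLUP" if structure == "fit-pblup" else "RR-ssGBLUP"
            nu_geno, n_geno_trios = None, 0
            if structure == "fit-ssgblup":
                geno_set = set(str(l) for l in ped.labels[designs_gi])
                recorded_geno = [a for a in train.animals if str(a) in geno_set]
                if recorded_geno:
                    try:
                        _, ms_g = mendelian_sampling(ebv, ped, recorded_geno)
                        nu_geno = ms_variance_ratio(ms_g, tp.var_additive)
                        n_geno_trios = ms_g.shape[0]
                    except ModelError:
                        pass
            results.append(
                ValidationResult(
                    method=label, accuracy=acc, nu=nu, n_trios=ms.shape[0],
                    nu_genotyped=nu_geno, n_trios_genotyped=n_geno_trios,
                )
            )
        out = pd.concat([r.to_frame() for r in results], ignore_index=True)
        _io._write_with_provenance(
            out, self.outdir / "accuracy_by_week.csv", self.cfg.hash
        )
        return results

    def report(self):
        ph = _io.read_phenotypes(self._phenotype_path("report"))
        df = ph.df
        desc = (
            df.groupby("week")["eggs"]
            .agg(n="count", mean="mean", sd="std")
            .reset_index()
        )
        desc["cv_percent"] = desc["sd"] / desc["mean"] * 100.0
        C, P, res = self._variance_components()
        tp = trajectory_parameters(
            CovFunction(C, self.basis, "additive"),
            CovFunction(P, self.basis, "pe"),
            res,
        )
        traj = tp.to_frame()
        resid = pd.DataFrame(
            [(f"weeks {lo} to {hi}", v) for lo, hi, v in res.periods],
            columns=["period", "residual_variance"],
        )
        sel = [int(np.flatnonzero(self.basis.weeks == w)[0]) for w in REPORT_WEEKS]
        corr = np.zeros((len(sel), len(sel)))
        for a, ia in enumerate(sel):
            for b, ib in enumerate(sel):
                if a < b:
                    corr[a, b] = tp.genetic_corr[ia, ib]
                elif a > b:
                    corr[a, b] = tp.phenotypic_corr[ia, ib]
                else:
                    corr[a, b] = tp.heritability[ia]
        corr_df = pd.DataFrame(
            corr, columns=[f"week_{w}" for w in REPORT_WEEKS]
        )
        corr_df.insert(0, "week", list(REPORT_WEEKS))
        tables = {
            "report_descriptive.csv": desc,
            "report_trajectory.csv": traj,
            "report_residual.csv": resid,
            "report_correlations.csv": corr_df,
        }
        for name, table in tables.items():
            _io._write_with_provenance(table, self.outdir / name, self.cfg.hash)
        return tables


def run_pipeline(cfg: RunConfig, stages) -> dict:
    """Run the requested stages in canonical order; returns stage outputs."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    runner = Runner(cfg)
    out = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        if stage == "simulate":
            out[stage] = runner.simulate()
        elif stage == "qc":
            out[stage] = runner.qc()
        elif stage in ("fit-pblup", "fit-ssgblup"):
            out[stage] = runner.fit(stage)
        elif stage == "gibbs":
            out[stage] = runner.gibbs()
        elif stage == "validate":
            out[stage] = runner.validate()
        elif stage == "report":
            out[stage] = runner.report()
    return out
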