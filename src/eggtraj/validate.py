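"""Prediction-accuracy statistics for RR-PBLUP vs RR-ssGBLUP.

Two statistics quantify the benefit of genomic information:

* a forward-validation accuracy: the youngest ~10% of hens have their
  records masked during training, and the weekly accuracy is the Pearson
  correlation between their EBVs and their phenotypes corrected for fixed
  effects, divided by sqrt(h2) of the week;

* a Mendelian-sampling variance ratio: nu(t) = Var(ms_hat(t)) /
  (0.5 * sigma2_a(t)), with ms_hat_i = EBV_i - 0.5 (EBV_sire + EBV_dam)
  over animals that have records and both parents known.  nu approaches 1
  as predictions of the Mendelian sampling terms become perfectly accurate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    BreedingValues,
    FixedEffectsSpec,
    ModelError,
    PhenotypeTable,
    build_design,
)
from .pedigree import Pedigree, UNKNOWN

__all__ = [
    "ValidationResult",
    "split_by_age",
    "corrected_phenotypes",
    "correlation_accuracy",
    "mendelian_sampling",
    "ms_variance_ratio",
]


def split_by_age(
    ph: PhenotypeTable, ped: Pedigree, fraction: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Assign the youngest ``fraction`` of recorded hens to validation.

    Youth is judged by hatch week (largest = youngest), ties broken
    deterministically by animal id.  Returns (reference_ids,
    validation_ids); the validation count is floor(fraction * n_hens).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("validation fraction must be in (0, 1)")
    hens = ph.animals
    ix = ped.index_of(hens.tolist())
    hw = ped.hatch_week[ix]
    order = sorted(
        range(len(hens)), key=lambda i: (-(hw[i]), str(hens[i]))
    )
    n_val = int(np.floor(fraction * len(hens)))
    val = sorted((hens[i] for i in order[:n_val]), key=str)
    ref = sorted(set(hens.tolist()) - set(val), key=str)
    return np.asarray(ref), np.asarray(val)


def corrected_phenotypes(
    ph: PhenotypeTable,
    fixed_solution: np.ndarray,
    spec: FixedEffectsSpec,
    ped: Pedigree,
    basis,
) -> pd.DataFrame:
    """y* = y - X b_hat for every record whose fixed levels were trained.

    ``fixed_solution`` and ``spec`` come from the reference-data fit;
    records with levels unseen in the reference data are dropped with a
    warning.  Returns a frame (animal, week, ystar).
    """
    designs = build_design(ph, spec, basis, ped, drop_unseen=True)
    ystar = designs.y - designs.X @ fixed_solution
    labels = ped.labels[designs.rec_animal]
    return pd.DataFrame(
        {"animal": labels, "week": designs.rec_week, "ystar": ystar}
    )


def correlation_accuracy(
    ebv: BreedingValues,
    ystar: pd.DataFrame,
    h2: np.ndarray,
    weeks=None,
    min_animals: int = 3,
) -> pd.DataFrame:
    """Weekly validation accuracy cor(EBV_t, y*_t) / sqrt(h2_t).

    ``ebv`` must cover the validation animals (masked-data fit); ``ystar``
    holds their observed corrected phenotypes.  Weeks with fewer than
    ``min_animals`` records, zero EBV variance, or h2 = 0 are reported as
    missing.
    """
    weeks = np.arange(1, 25) if weeks is None else np.asarray(weeks)
    h2 = np.asarray(h2, float)
    if h2.shape[0] != weeks.shape[0]:
        raise ValueError("h2 must be given per week")
    pos = {str(a): i for i, a in enumerate(ebv.ids)}
    rows = []
    for iw, w in enumerate(weeks):
        sub = ystar[ystar["week"] == w]
        sub = sub[sub["animal"].astype(str).isin(pos)]
        n = len(sub)
        acc = np.nan
        if n >= min_animals and h2[iw] > 0:
            idx = [pos[str(a)] for a in sub["animal"]]
            pred = ebv.weekly[idx, iw]
            obs = sub["ystar"].to_numpy()
            if np.std(pred) > 0 and np.std(obs) > 0:
                r = np.corrcoef(pred, obs)[0, 1]
                acc = r / np.sqrt(h2[iw])
        rows.append((int(w), acc, n))
    return pd.DataFrame(rows, columns=["week", "accuracy", "n_validation"])


def mendelian_sampling(
    ebv: BreedingValues, ped: Pedigree, recorded_ids
) -> tuple[np.ndarray, np.ndarray]:
    """BLUP-predicted Mendelian sampling terms per eligible animal and week.

    Eligible: the animal has at least one record and both parents are
    known.  Returns (eligible_labels, ms) with ms of shape
    (n_eligible, n_weeks) on the weekly EBV scale.
    """
    pos = {str(a): i for i, a in enumerate(ebv.ids)}
    recorded = set(str(a) for a in recorded_ids)
    elig_ix, elig_lab = [], []
    for lab in recorded:
        i = ped.index_of([lab])[0]
        if ped.sire[i] != UNKNOWN and ped.dam[i] != UNKNOWN:
            elig_ix.append(i)
            elig_lab.append(lab)
    if not elig_ix:
        raise ModelError("no animals with records and both parents known")
    elig_order = np.argsort(np.asarray(elig_ix))
    elig_ix = np.asarray(elig_ix)[elig_order]
    elig_lab = np.asarray(elig_lab)[elig_order]

    def weekly_of(pedigree_index):
        lab = str(ped.labels[pedigree_index])
        return ebv.weekly[pos[lab]]

    ms = np.array(
        [
            weekly_of(i)
            - 0.5 * (weekly_of(ped.sire[i]) + weekly_of(ped.dam[i]))
            for i in elig_ix
        ]
    )
    return elig_lab, ms


def ms_variance_ratio(
    ms: np.ndarray, sigma2_a: np.ndarray, min_animals: int = 10
) -> np.ndarray:
    """nu(t) = Var(ms predictions at week t) / (0.5 sigma2_a(t)).

    The variance is the n-1 sample variance over eligible animals;
    sigma2_a comes from the fitted model's expanded additive covariance.
    Soft range check: values above 1.05 trigger a warning (sampling noise
    can exceed 1 slightly, a larger excess indicates a mis-scaled model).
    """
    ms = np.asarray(ms, float)
    if ms.shape[0] < min_animals:
        raise ModelError(
            f"nu requires >= {min_animals} eligible animals, got {ms.shape[0]}"
        )
    sigma2_a = np.asarray(sigma2_a, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = ms.var(axis=0, ddof=1) / (0.5 * sigma2_a)
    nu[sigma2_a <= 0] = np.nan
    if np.nanmax(nu) > 1.05:
        warnings.warn(
            f"nu exceeds 1.05 (max {np.nanmax(nu):.3f}); check variance scale",
            stacklevel=2,
        )
    return nu


@dataclass
class ValidationResult:
    """Per-week accuracy table for one method (RR-PBLUP or RR-ssGBLUP).

    ``nu_genotyped`` optionally reports nu over the genotyped eligible
    subset only (relevant for the single-step structure).
    """

    method: str
    accuracy: pd.DataFrame          # week, accuracy, n_validation
    nu: np.ndarray                  # per week
    n_trios: int
    nu_genotyped: np.ndarray | None = None
    n_trios_genotyped: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = self.accuracy.copy()
        df["nu"] = self.nu
        df["n_trios"] = self.n_trios
        if self.nu_genotyped is not None:
            df["nu_genotyped"] = self.nu_genotyped
            df["n_trios_genotyped"] = self.n_trios_genotyped
        df.insert(1, "method", self.method)
        return df
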