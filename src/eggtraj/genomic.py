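"""Genotype QC, genomic relationship matrix, and single-step H inverse.

QC removes SNPs with low call rate, non-autosomal location, or low minor
allele frequency (in that order, with MAF computed on the post-call-rate
panel), then mean-imputes remaining missing dosages.  G follows VanRaden's
first method with observed allele frequencies; a blended
``w*G + (1-w)*A22`` guards against singularity.  The single-step inverse is
``H^-1 = A^-1 + [[0,0],[0, G^-1 - A22^-1]]`` over the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import Pedigree, RelMatrix

__all__ = [
    "GenotypeData",
    "HStructure",
    "QCError",
    "qc_genotypes",
    "build_G_vanraden1",
    "blend_G",
    "build_H_inverse",
    "genotyped_positions",
    "invert_dense",
]

#: Chromosome labels treated as non-autosomal (sex chromosomes, mitochondria).
NON_AUTOSOMAL_LABELS = {"X", "Y", "Z", "W", "MT", "M"}


class QCError(ValueError):
    pass


@dataclass
class GenotypeData:
    """Dosage matrix (animals x SNPs, 0/1/2 with NaN missing) plus SNP map.

    ``snp_map`` has columns snp, chrom, pos; ``qc_log`` records per-SNP
    removals with a reason once :func:`qc_genotypes` has run.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    animal_ids: np.ndarray
    qc_log: pd.DataFrame | None = None
    qc_done: bool = False

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise QCError("dosages must be a 2-D matrix")
        if self.dosages.shape[1] != len(self.snp_map):
            raise QCError("snp_map length does not match dosage columns")
        if self.dosages.shape[0] != len(self.animal_ids):
            raise QCError("animal_ids length does not match dosage rows")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if self.qc_done:
            valid = np.isnan(self.dosages) | (
                (self.dosages >= 0) & (self.dosages <= 2)
            )
        if not valid.all():
            raise QCError("raw dosages must be coded 0/1/2 or missing")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted allele per SNP."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


def qc_genotypes(
    g: GenotypeData,
    maf_min: float = 0.05,
    callrate_min: float = 0.95,
    non_autosomal=None,
    animal_callrate_min: float | None = None,
) -> GenotypeData:
    """Filter SNPs and mean-impute the survivors.

    Removal reasons (applied in order, each SNP logged under the first
    criterion it fails): ``call_rate``, ``non_autosomal``, ``maf``.  Missing
    dosages of retained SNPs are imputed to twice the observed allele
    frequency.  Removing every SNP is fatal.

    ``animal_callrate_min`` optionally drops animals below a per-animal
    call rate before the SNP filters; it is off by default.
    """
    if non_autosomal is None:
        non_autosomal = NON_AUTOSOMAL_LABELS
    non_autosomal = {str(c).upper() for c in non_autosomal}
    M = g.dosages
    animal_ids = g.animal_ids
    if animal_callrate_min is not None:
        acall = 1.0 - np.isnan(M).sum(axis=1) / M.shape[1]
        keep_a = acall >= animal_callrate_min
        if not keep_a.any():
            raise QCError("per-animal call-rate filter removed every animal")
        M = M[keep_a]
        animal_ids = np.asarray(animal_ids)[keep_a]
    n = M.shape[0]
    callrate = 1.0 - np.isnan(M).sum(axis=0) / n
    chrom = g.snp_map["chrom"].astype(str).str.upper().to_numpy()
    reasons = np.full(g.n_snps, "", dtype=object)
    reasons[callrate < callrate_min] = "call_rate"
    auto_fail = np.isin(chrom, list(non_autosomal)) & (reasons == "")
    reasons[auto_fail] = "non_autosomal"
    # MAF on the panel that survives the first two filters
    candidate = reasons == ""
    freq = np.full(g.n_snps, np.nan)
    if candidate.any():
        with np.errstate(invalid="ignore"):
            freq[candidate] = np.nanmean(M[:, candidate], axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    maf_fail = candidate & ((maf < maf_min) | np.isnan(maf))
    reasons[maf_fail] = "maf"
    keep = reasons == ""
    if not keep.any():
        raise QCError("quality control removed every SNP")
    kept = M[:, keep].copy()
    p = np.nanmean(kept, axis=0) / 2.0
    miss = np.isnan(kept)
    if miss.any():
        fill = np.broadcast_to(2.0 * p, kept.shape)
        kept[miss] = fill[miss]
    log = pd.DataFrame(
        {"snp": g.snp_map["snp"].to_numpy(), "reason": reasons}
    )
    return GenotypeData(
        dosages=kept,
        snp_map=g.snp_map.loc[keep].reset_index(drop=True),
        animal_ids=np.asarray(animal_ids).copy(),
        qc_log=log[log["reason"] != ""].reset_index(drop=True),
        qc_done=True,
    )


def build_G_vanraden1(g: GenotypeData) -> RelMatrix:
    """VanRaden method-1 genomic relationship matrix.

    ``G = Z Z' / (2 sum_k p_k (1 - p_k))`` with ``Z = M - 2p`` and p the
    observed allele frequencies of the genotyped set.  Requires a QC'd,
    polymorphic panel with at least two animals and two SNPs.
    """
    if g.n_animals < 2 or g.n_snps < 2:
        raise QCError("G requires at least 2 animals and 2 SNPs")
    M = g.dosages
    if np.isnan(M).any():
        raise QCError("missing dosages present; run qc_genotypes first")
    p = M.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise QCError("monomorphic SNP present; run qc_genotypes first")
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    return RelMatrix(values=0.5 * (G + G.T), ids=np.asarray(g.animal_ids), kind="G")


def blend_G(G: RelMatrix, A22: RelMatrix, weight: float = 0.95) -> RelMatrix:
    """Blend G with the pedigree block: ``w*G + (1-w)*A22`` (0 < w < 1)."""
    if not (0.0 < weight < 1.0):
        raise ValueError("blend weight must be strictly between 0 and 1")
    Gv, Av = G.toarray(), A22.toarray()
    if Gv.shape != Av.shape:
        raise ValueError(
            f"dimension mismatch: G is {Gv.shape}, A22 is {Av.shape}"
        )
    return RelMatrix(values=weight * Gv + (1 - weight) * Av, ids=G.ids, kind="Gblend")


@dataclass
class HStructure:
    """Components of the single-step inverse relationship matrix.

    ``genotyped_index`` holds the (strictly increasing) positions of the
    genotyped animals within the full pedigree ordering.
    """

    Ainv: RelMatrix
    Ginv: RelMatrix
    A22inv: RelMatrix
    genotyped_index: np.ndarray

    def __post_init__(self):
        gi = np.asarray(self.genotyped_index, dtype=np.int64)
        if gi.size and not np.all(np.diff(gi) > 0):
            raise ValueError("genotyped_index must be strictly increasing")
        if self.Ginv.n != gi.size or self.A22inv.n != gi.size:
            raise ValueError("Ginv/A22inv dimension must equal the genotyped count")
        self.genotyped_index = gi


def genotyped_positions(ped: Pedigree, genotyped_ids) -> np.ndarray:
    """Sorted pedigree positions of the genotyped animals (fatal if absent)."""
    ix = ped.index_of(list(genotyped_ids))
    return np.sort(ix)


def build_H_inverse(h: HStructure) -> RelMatrix:
    """Assemble the sparse single-step inverse.

    Equal to A^-1 everywhere except the genotyped x genotyped block, which
    gains the dense correction ``G^-1 - A22^-1``.  Returned as a sparse CSR
    matrix (the correction block is dense within the sparse pattern).
    """
    Ainv = h.Ainv.values
    if not sparse.issparse(Ainv):
        Ainv = sparse.csr_matrix(Ainv)
    n = Ainv.shape[0]
    gi = h.genotyped_index
    if gi.size == 0:
        return RelMatrix(values=Ainv.copy(), ids=h.Ainv.ids, kind="Hinv")
    delta = h.Ginv.toarray() - h.A22inv.toarray()
    rows = np.repeat(gi, gi.size)
    cols = np.tile(gi, gi.size)
    corr = sparse.coo_matrix((delta.ravel(), (rows, cols)), shape=(n, n))
    Hinv = (Ainv + corr.tocsr()).tocsr()
    return RelMatrix(values=Hinv, ids=h.Ainv.ids, kind="Hinv")


def invert_dense(rel: RelMatrix, kind: str) -> RelMatrix:
    """Dense inverse of a (blended) relationship matrix block."""
    vals = rel.toarray()
    try:
        inv = np.linalg.inv(vals)
    except np.linalg.LinAlgError as e:
        raise QCError(
            f"{rel.kind} is singular and cannot be inverted: {e}"
        ) from None
    return RelMatrix(values=0.5 * (inv + inv.T), ids=rel.ids, kind=kind)
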