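"""Tabular readers and writers for the pipeline's file formats.

All CSV artifacts carry a provenance comment line ``# eggtraj-run: <hash>``
derived from the run configuration, so artifacts from different runs are
detectable when mixed.  Readers skip comment lines and validate headers
with line-numbered messages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from .genomic import GenotypeData, QCError
from .model import ModelError, PhenotypeTable
from .pedigree import Pedigree, RelMatrix

__all__ = [
    "config_hash",
    "read_provenance",
    "write_pedigree",
    "write_phenotypes",
    "read_phenotypes",
    "write_genotypes",
    "read_genotypes",
    "write_relmatrix",
    "write_sim_config",
    "read_sim_config",
]

PROVENANCE_PREFIX = "# eggtraj-run:"


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(cfg) -> str:
    """Stable short hash of a configuration object."""
    payload = json.dumps(_jsonable(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_with_provenance(df: pd.DataFrame, path, provenance: str | None):
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"{PROVENANCE_PREFIX} {provenance}\n")
        df.to_csv(fh, index=False)


def read_provenance(path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(PROVENANCE_PREFIX):
        return first[len(PROVENANCE_PREFIX):].strip()
    return None


def write_pedigree(ped: Pedigree, path, provenance: str | None = None):
    _write_with_provenance(ped.to_frame(), path, provenance)


def write_phenotypes(ph: PhenotypeTable, path, provenance: str | None = None):
    _write_with_provenance(ph.df, path, provenance)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PhenotypeTable.REQUIRED if c not in df.columns]
    if missing:
        raise ModelError(
            f"{path}, line 1: phenotype header lacks columns {missing}"
        )
    return PhenotypeTable(df)


def write_genotypes(g: GenotypeData, path, map_path, provenance: str | None = None):
    """Whitespace-delimited dosage matrix, animal id first; NA = missing."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"{PROVENANCE_PREFIX} {provenance}\n")
        if g.qc_done:
            fh.write("# qc: done\n")
        for i, aid in enumerate(g.animal_ids):
            row = " ".join(
                "NA" if np.isnan(v) else f"{v:g}" for v in g.dosages[i]
            )
            fh.write(f"{aid} {row}\n")
    _write_with_provenance(
        g.snp_map[["snp", "chrom", "pos"]], map_path, provenance
    )


def read_genotypes(path, map_path, transposed: bool = False) -> GenotypeData:
    """Read a dosage matrix plus SNP map (``snp,chrom,pos``).

    With ``transposed`` the file holds one SNP per row (first column the
    SNP id) rather than one animal per row.
    """
    snp_map = pd.read_csv(map_path, comment="#")
    for col in ("snp", "chrom", "pos"):
        if col not in snp_map.columns:
            raise QCError(f"{map_path}, line 1: SNP map lacks column {col!r}")
    ids, rows = [], []
    qc_done = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#"):
                if line.strip() == "# qc: done":
                    qc_done = True
                continue
            if not line.strip():
                continue
            parts = line.split()
            ids.append(parts[0])
            try:
                rows.append(
                    [np.nan if p.upper() == "NA" else float(p) for p in parts[1:]]
                )
            except ValueError as e:
                raise QCError(f"{path}, line {ln}: {e}") from None
    M = np.asarray(rows, dtype=float)
    if transposed:
        if len(ids) != len(snp_map):
            raise QCError(
                f"{path}: {len(ids)} SNP rows but map lists {len(snp_map)}"
            )
        order = {s: i for i, s in enumerate(snp_map["snp"].astype(str))}
        try:
            perm = [order[str(s)] for s in ids]
        except KeyError as e:
            raise QCError(f"{path}: SNP {e.args[0]!r} missing from map") from None
        Mt = np.empty_like(M)
        Mt[perm] = M
        M = Mt.T
        animal_ids = np.array([f"A{i + 1}" for i in range(M.shape[0])])
        return GenotypeData(dosages=M, snp_map=snp_map, animal_ids=animal_ids,
                            qc_done=qc_done)
    if M.shape[1] != len(snp_map):
        raise QCError(
            f"{path}: rows have {M.shape[1]} dosages but map lists "
            f"{len(snp_map)} SNPs"
        )
    return GenotypeData(dosages=M, snp_map=snp_map, animal_ids=np.array(ids),
                        qc_done=qc_done)


def write_relmatrix(rel: RelMatrix, path, id_path=None, provenance=None):
    """Coordinate-format text export: header naming the kind, then i j value."""
    path = Path(path)
    vals = rel.values
    coo = vals.tocoo() if sparse.issparse(vals) else sparse.coo_matrix(vals)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"{PROVENANCE_PREFIX} {provenance}\n")
        fh.write(f"# kind={rel.kind} n={rel.n} ids={id_path or '-'}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {v:.10g}\n")
    if id_path is not None:
        pd.DataFrame({"index": np.arange(1, rel.n + 1), "animal": rel.ids}).to_csv(
            id_path, index=False
        )


def write_sim_config(cfg, path):
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(cfg), fh, sort_keys=True)


def read_sim_config(path):
    from .simulate import SimConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["C_true"] = np.asarray(raw["C_true"])
    raw["P_true"] = np.asarray(raw["P_true"])
    raw["residual_periods"] = tuple(tuple(p) for p in raw["residual_periods"])
    raw["afe_probs"] = tuple(raw["afe_probs"])
    return SimConfig(**raw)
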