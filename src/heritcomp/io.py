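"""File formats: TSV tables, PLINK .bed/.bim/.fam, GCTA GRM, model JSON.

Subject alignment is inner-join by id; silent misalignment is the classic
failure mode of GRM pipelines, so an overlap below half of the larger input
is a hard error rather than a warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GeneticRelationshipMatrix, RawGenotypeMatrix
from .sqp import TraitModel

__all__ = [
    "read_table",
    "align_tables",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_plink",
    "write_plink",
    "read_gcta_grm",
    "write_gcta_grm",
    "read_grm_tsv",
    "write_grm_tsv",
    "write_model",
    "read_model",
]

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


def read_table(path, kind: str = "features") -> pd.DataFrame:
    """Read a TSV with a header row and subject ids in the first column."""
    if kind not in ("features", "covariates", "trait"):
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject ids in {path}: {dup[:5]}")
    return df


def align_tables(reference_ids, *frames):
    """Inner-join frames on subject id, ordered by ``reference_ids``.

    Subjects missing from any input are dropped (count logged).  Raises if
    there is no overlap, or if the overlap is below 50% of the largest input.
    """
    reference_ids = [str(s) for s in reference_ids]
    common = [s for s in reference_ids
              if all(s in f.index for f in frames)]
    sizes = [len(reference_ids)] + [len(f) for f in frames]
    if len(common) == 0:
        raise ValueError("zero overlapping subjects across inputs")
    if len(common) < 0.5 * max(sizes):
        raise ValueError(
            f"only {len(common)} of up to {max(sizes)} subjects overlap "
            "(< 50%); refusing to align"
        )
    dropped = max(sizes) - len(common)
    if dropped:
        logger.info("dropped %d subject(s) missing from some input", dropped)
    return [f.loc[common] for f in frames]


# -- genotype TSV (rows = subjects, first column id, integer counts) --------

def read_genotype_tsv(path, allele_freqs=None) -> RawGenotypeMatrix:
    df = read_table(path, kind="features")
    return RawGenotypeMatrix(
        counts=df.to_numpy(dtype=float),
        subject_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
        allele_freqs=allele_freqs,
    )


def write_genotype_tsv(raw: RawGenotypeMatrix, path):
    df = pd.DataFrame(raw.counts, index=raw.subject_ids,
                      columns=raw.marker_ids)
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA")


# -- PLINK .bed/.bim/.fam (variant-major bed) -------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes -> copies of the first (.bim column 5) allele
_BED_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix) -> RawGenotypeMatrix:
    """Read a variant-major PLINK fileset; counts are copies of the .bim
    first allele (taken as the reference/counted allele)."""
    prefix = Path(prefix)
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    data = Path(f"{prefix}.bed").read_bytes()
    if data[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a variant-major PLINK bed file")
    bpv = (n + 3) // 4  # bytes per variant
    body = np.frombuffer(data[3:], dtype=np.uint8)
    if body.size != bpv * m:
        raise ValueError(f"{prefix}.bed has unexpected size")
    body = body.reshape(m, bpv)
    # unpack the four 2-bit genotypes per byte, low bits first
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, bpv * 4)[:, :n]
    counts = _BED_CODE_TO_COUNT[codes].T  # subjects x markers
    logger.info("read %s.bed: counting .bim allele-1 copies for %d markers",
                prefix.name, m)
    return RawGenotypeMatrix(
        counts=counts,
        subject_ids=fam[1].astype(str).to_numpy(dtype=object),
        marker_ids=bim[1].astype(str).to_numpy(dtype=object),
    )


def write_plink(raw: RawGenotypeMatrix, prefix):
    """Write a minimal variant-major PLINK fileset (A/B placeholder alleles)."""
    prefix = Path(prefix)
    n, m = raw.counts.shape
    with open(f"{prefix}.fam", "w") as fh:
        for sid in raw.subject_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for j, mid in enumerate(raw.marker_ids):
            fh.write(f"1 {mid} 0 {j + 1} A B\n")
    count_to_code = {2.0: 0, 1.0: 2, 0.0: 3}
    bpv = (n + 3) // 4
    out = bytearray(_BED_MAGIC)
    for j in range(m):
        col = raw.counts[:, j]
        bts = np.zeros(bpv, dtype=np.uint8)
        for i in range(n):
            code = 1 if np.isnan(col[i]) else count_to_code[col[i]]
            bts[i // 4] |= code << (2 * (i % 4))
        out += bts.tobytes()
    Path(f"{prefix}.bed").write_bytes(bytes(out))


# -- GCTA GRM binary dialect and square TSV ---------------------------------

def write_gcta_grm(grm: GeneticRelationshipMatrix, prefix):
    """Write .grm.bin (float32 lower triangle incl. diagonal) and .grm.id."""
    prefix = Path(prefix)
    n = grm.n
    tri = grm.G[np.tril_indices(n)].astype("<f4")
    Path(f"{prefix}.grm.bin").write_bytes(tri.tobytes())
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in grm.subject_ids:
            fh.write(f"{sid}\t{sid}\n")
    if grm.m_used:
        nvals = np.full(tri.shape, grm.m_used, dtype="<f4")
        Path(f"{prefix}.grm.N.bin").write_bytes(nvals.tobytes())


def read_gcta_grm(prefix) -> GeneticRelationshipMatrix:
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)
    n = len(ids)
    tri = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin size does not match {n} ids")
    G = np.zeros((n, n))
    G[np.tril_indices(n)] = tri
    G = G + np.tril(G, -1).T
    m_used = 0
    npath = Path(f"{prefix}.grm.N.bin")
    if npath.exists():
        m_used = int(np.frombuffer(npath.read_bytes(), dtype="<f4")[0])
    return GeneticRelationshipMatrix(
        G=G, subject_ids=ids[1].astype(str).to_numpy(dtype=object),
        m_used=m_used,
    )


def write_grm_tsv(grm: GeneticRelationshipMatrix, path):
    df = pd.DataFrame(grm.G, index=grm.subject_ids, columns=grm.subject_ids)
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def read_grm_tsv(path) -> GeneticRelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneticRelationshipMatrix(
        G=df.to_numpy(dtype=float),
        subject_ids=df.index.astype(str).to_numpy(dtype=object),
    )


# -- model JSON --------------------------------------------------------------

def write_model(model: TraitModel, path):
    """Serialize a fitted trait model to JSON (full float precision)."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "w": [float(x) for x in model.w],
        "lambda": float(model.lam),
        "beta": None if model.beta is None else [float(x) for x in model.beta],
        "feature_names": model.feature_names,
        "data_min": None if model.data_min is None
        else [float(x) for x in model.data_min],
        "data_max": None if model.data_max is None
        else [float(x) for x in model.data_max],
        "objective_value": float(model.objective_value),
        "constraint_residual": float(model.constraint_residual),
        "converged": bool(model.converged),
        "n_iter": int(model.n_iter),
        "kkt_residual": float(model.kkt_residual),
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path) -> TraitModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {doc.get('schema_version')} != "
            f"{MODEL_SCHEMA_VERSION}"
        )
    return TraitModel(
        w=np.array(doc["w"], dtype=float),
        lam=doc["lambda"],
        beta=None if doc["beta"] is None else np.array(doc["beta"]),
        feature_names=doc["feature_names"],
        data_min=None if doc["data_min"] is None
        else np.array(doc["data_min"]),
        data_max=None if doc["data_max"] is None
        else np.array(doc["data_max"]),
        objective_value=doc["objective_value"],
        constraint_residual=doc["constraint_residual"],
        converged=doc["converged"],
        n_iter=doc["n_iter"],
        kkt_residual=doc["kkt_residual"],
        provenance=doc.get("provenance", {}),
    )
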