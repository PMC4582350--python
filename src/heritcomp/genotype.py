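"""Genotype standardization and the genetic relationship matrix (GRM).

Genotypes are reference-allele copy numbers r_ij in {0, 1, 2}.  With f_j the
reference-allele frequency at marker j, the standardized genotype is

    z_ij = (r_ij - 2 f_j) / sqrt(2 f_j (1 - f_j)),

which has mean 0 and unit variance under Hardy-Weinberg sampling.  The GRM
between n subjects over m markers is G = Z Z^T / m; its diagonal averages to
about 1 for sample-standardized genotypes, and off-diagonal entries estimate
pairwise relatedness on the scale where 0.025 corresponds to roughly second
cousins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawGenotypeMatrix",
    "StandardizedGenotypeMatrix",
    "GeneticRelationshipMatrix",
    "MonomorphicMarkerError",
    "standardize_genotypes",
    "compute_grm",
    "prune_related",
    "grm_principal_components",
]


class MonomorphicMarkerError(ValueError):
    """A marker has reference-allele frequency 0 or 1 and cannot be standardized."""


def _as_ids(ids, n, prefix):
    if ids is None:
        return np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
    ids = np.asarray(ids, dtype=object)
    if ids.shape != (n,):
        raise ValueError(f"expected {n} {prefix} ids, got shape {ids.shape}")
    return ids


@dataclass
class RawGenotypeMatrix:
    """Reference-allele counts for subjects x markers, possibly with missing entries.

    ``counts`` is a float array with NaN marking missing genotypes.
    ``allele_freqs`` holds the per-marker reference-allele frequency f_j; when
    not supplied it is estimated in-sample as column-mean(counts)/2 over
    non-missing entries.
    """

    counts: np.ndarray
    subject_ids: np.ndarray = None
    marker_ids: np.ndarray = None
    allele_freqs: np.ndarray = None
    freqs_in_sample: bool = field(default=True)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.size == 0:
            raise ValueError("genotype matrix must be a non-empty 2-D array")
        valid = np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"genotype counts must be 0/1/2 or missing; offending entry at "
                f"(subject {bad[0]}, marker {bad[1]})"
            )
        self.counts = counts
        n, m = counts.shape
        self.subject_ids = _as_ids(self.subject_ids, n, "S")
        self.marker_ids = _as_ids(self.marker_ids, m, "M")
        if self.allele_freqs is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                self.allele_freqs = np.nanmean(counts, axis=0) / 2.0
            self.freqs_in_sample = True
        else:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if self.allele_freqs.shape != (m,):
                raise ValueError("allele_freqs length must match marker count")
            self.freqs_in_sample = False

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    def monomorphic_mask(self) -> np.ndarray:
        """Markers whose frequency is 0 or 1 (or undefined), flagged as monomorphic."""
        f = self.allele_freqs
        return ~np.isfinite(f) | (f <= 0.0) | (f >= 1.0)

    def drop_monomorphic(self) -> "RawGenotypeMatrix":
        """Return a copy without monomorphic markers, warning if any were dropped."""
        mask = self.monomorphic_mask()
        if not mask.any():
            return self
        dropped = list(self.marker_ids[mask])
        warnings.warn(
            f"dropping {mask.sum()} monomorphic marker(s): {dropped[:5]}"
            + (" ..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
        keep = ~mask
        return RawGenotypeMatrix(
            counts=self.counts[:, keep],
            subject_ids=self.subject_ids,
            marker_ids=self.marker_ids[keep],
            allele_freqs=None if self.freqs_in_sample else self.allele_freqs[keep],
        )


@dataclass
class StandardizedGenotypeMatrix:
    """Standardized genotypes Z (no missing entries) plus identifiers."""

    Z: np.ndarray
    subject_ids: np.ndarray = None
    marker_ids: np.ndarray = None

    def __post_init__(self):
        Z = np.asarray(self.Z, dtype=float)
        if Z.ndim != 2 or Z.size == 0:
            raise ValueError("Z must be a non-empty 2-D array")
        if not np.isfinite(Z).all():
            raise ValueError("Z contains non-finite entries")
        self.Z = Z
        self.subject_ids = _as_ids(self.subject_ids, Z.shape[0], "S")
        self.marker_ids = _as_ids(self.marker_ids, Z.shape[1], "M")

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]


@dataclass
class GeneticRelationshipMatrix:
    """Symmetric n x n relationship matrix with subject identifiers."""

    G: np.ndarray
    subject_ids: np.ndarray = None
    m_used: int = 0

    def __post_init__(self):
        G = np.asarray(self.G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1] or G.size == 0:
            raise ValueError("G must be a non-empty square matrix")
        if not np.allclose(G, G.T, atol=1e-8 * max(1.0, np.abs(G).max())):
            raise ValueError("G must be symmetric")
        self.G = (G + G.T) / 2.0
        self.subject_ids = _as_ids(self.subject_ids, G.shape[0], "S")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    def subset(self, idx) -> "GeneticRelationshipMatrix":
        """GRM restricted to the given subject indices (order preserved)."""
        idx = np.asarray(idx)
        return GeneticRelationshipMatrix(
            G=self.G[np.ix_(idx, idx)],
            subject_ids=self.subject_ids[idx],
            m_used=self.m_used,
        )


def standardize_genotypes(raw: RawGenotypeMatrix) -> StandardizedGenotypeMatrix:
    """Standardize allele counts to z = (r - 2f)/sqrt(2f(1-f)).

    Missing entries are mean-imputed to 2 f_j before standardization, i.e. they
    contribute exactly 0 to the standardized column.  All markers must be
    polymorphic; use :meth:`RawGenotypeMatrix.drop_monomorphic` first if the
    data may contain fixed markers.
    """
    mono = raw.monomorphic_mask()
    if mono.any():
        raise MonomorphicMarkerError(
            f"monomorphic marker(s) present: {list(raw.marker_ids[mono][:5])}"
        )
    f = raw.allele_freqs
    counts = raw.counts
    r = np.where(np.isnan(counts), 2.0 * f, counts)
    Z = (r - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    return StandardizedGenotypeMatrix(
        Z=Z, subject_ids=raw.subject_ids, marker_ids=raw.marker_ids
    )


def compute_grm(Z: StandardizedGenotypeMatrix) -> GeneticRelationshipMatrix:
    """G = Z Z^T / m, the genetic relationship matrix."""
    if Z.m < 1:
        raise ValueError("need at least one marker")
    G = Z.Z @ Z.Z.T / Z.m
    return GeneticRelationshipMatrix(G=G, subject_ids=Z.subject_ids, m_used=Z.m)


def prune_related(grm: GeneticRelationshipMatrix, threshold: float):
    """Greedily remove subjects until all pairwise relatedness is <= threshold.

    Repeatedly drops the subject involved in the largest number of
    over-threshold pairs; ties are broken by larger mean relatedness to the
    remaining subjects, then by lexicographic subject id.  Returns
    ``(kept_indices, removed_indices)``, a partition of ``range(n)`` with the
    kept block maximal under this greedy rule.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    G = grm.G
    n = grm.n
    over = (G > threshold) & ~np.eye(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    removed = []
    while True:
        deg = (over & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        dmax = deg.max() if active.any() else 0
        if dmax == 0:
            break
        cand = np.flatnonzero(deg == dmax)
        if len(cand) > 1:
            other = active.copy()
            means = np.array(
                [G[i, other & (np.arange(n) != i)].mean() for i in cand]
            )
            cand = cand[means == means.max()]
            if len(cand) > 1:
                cand = cand[np.argsort(grm.subject_ids[cand].astype(str))]
        drop = int(cand[0])
        active[drop] = False
        removed.append(drop)
    kept = np.flatnonzero(active)
    return kept, np.array(removed, dtype=int)


def grm_principal_components(grm: GeneticRelationshipMatrix, k: int):
    """Top-k eigenvectors of G, for use as ancestry covariates.

    Columns are unit-norm eigenvectors ordered by decreasing eigenvalue, with
    sign fixed so each column's largest-magnitude loading is positive.
    Returns ``(components, eigenvalues)`` with shapes (n, k) and (k,).
    """
    n = grm.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    from scipy.linalg import eigh

    vals, vecs = eigh(grm.G, subset_by_index=(n - k, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs, vals
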