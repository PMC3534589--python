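"""Genotype quality control and the standardized design matrix.

Covers the edit steps applied before model fitting — minor-allele-frequency
filtering, pruning of adjacent markers in complete LD, intersection of marker
panels across populations — plus the centered/scaled design matrix W used by
the samplers and, for the residual polygenic term, the pedigree-based
additive relationship matrix A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FormatError, GenotypeMatrix, MarkerMap

__all__ = [
    "StandardizedGenotypes",
    "RelationshipMatrix",
    "allele_frequencies",
    "filter_maf",
    "prune_complete_ld",
    "intersect_markers",
    "standardize",
    "build_A_from_pedigree",
    "read_pedigree",
]


@dataclass
class StandardizedGenotypes:
    """Centered and scaled genotype matrix W.

    Under Hardy-Weinberg equilibrium each column j of W is
    ``(x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))`` where ``p_j`` is the second
    (ALT) allele frequency, so columns have mean ~0 and variance ~1 when
    frequencies come from the same data.

    ``freq_provenance`` records which population's frequencies were used
    (validation animals are standardized with reference frequencies).
    """

    W: np.ndarray
    freqs: np.ndarray
    source_map: MarkerMap
    freq_provenance: str = "own"

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]

    @property
    def n_markers(self) -> int:
        return self.W.shape[1]


@dataclass
class RelationshipMatrix:
    """Pedigree-based additive (numerator) relationship matrix."""

    A: np.ndarray
    ids: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.A.shape != (len(self.ids), len(self.ids)):
            raise ValueError("A dimensions do not match ids")
        if not np.allclose(self.A, self.A.T, atol=1e-12):
            raise ValueError("A must be symmetric")

    def submatrix(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return self.A[np.ix_(idx, idx)]


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Second-allele frequency per marker: p_j = mean dosage / 2."""
    return G.X.mean(axis=0) / 2.0


def filter_maf(G: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Remove markers with minor allele frequency strictly below ``threshold``.

    The default 0.01 is the conventional edit for dense SNP panels. A marker
    with MAF exactly equal to the threshold is retained.
    """
    if not (0 <= threshold < 0.5):
        raise ValueError("threshold must be in [0, 0.5)")
    p = allele_frequencies(G)
    maf = np.minimum(p, 1 - p)
    keep = np.where(maf >= threshold)[0]
    if keep.size == 0:
        raise ValueError("MAF filter removed all markers")
    return G.subset_markers(keep)


def prune_complete_ld(G: GenotypeMatrix, tol: float = 1e-12) -> GenotypeMatrix:
    """Drop the later of any adjacent marker pair in complete LD (r^2 = 1).

    Scans markers in map order; each marker is compared with the previously
    *retained* marker and dropped when the squared Pearson correlation of
    dosages equals 1 within ``tol``. Monomorphic columns have undefined r^2
    and must have been removed by :func:`filter_maf` first.
    """
    X = G.X
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(
            f"monomorphic marker {G.map.marker_id[j]!r}: r^2 undefined; "
            "run filter_maf first"
        )
    keep = [0]
    prev = 0
    for j in range(1, G.n_markers):
        r = np.corrcoef(X[:, prev], X[:, j])[0, 1]
        if r * r >= 1.0 - tol:
            continue
        keep.append(j)
        prev = j
    return G.subset_markers(np.array(keep))


def intersect_markers(
    G1: GenotypeMatrix, G2: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two panels to their shared markers, in a common order.

    Cross-population prior transfer is only meaningful on a shared marker
    panel; both outputs carry the shared marker ids in G1's map order.
    Shared ids whose chromosome/position disagree between the maps are a
    map conflict and raise.
    """
    ids1 = {m: j for j, m in enumerate(G1.map.marker_id)}
    ids2 = {m: j for j, m in enumerate(G2.map.marker_id)}
    shared = [m for m in G1.map.marker_id if m in ids2]
    if not shared:
        raise ValueError("no markers in common between the panels")
    for m in shared:
        j1, j2 = ids1[m], ids2[m]
        if (G1.map.chrom[j1] != G2.map.chrom[j2]
                or G1.map.pos_bp[j1] != G2.map.pos_bp[j2]):
            raise FormatError(
                f"marker {m!r} maps to {G1.map.chrom[j1]}:{G1.map.pos_bp[j1]} "
                f"vs {G2.map.chrom[j2]}:{G2.map.pos_bp[j2]}"
            )
    idx1 = np.array([ids1[m] for m in shared])
    idx2 = np.array([ids2[m] for m in shared])
    return G1.subset_markers(idx1), G2.subset_markers(idx2)


def standardize(
    G: GenotypeMatrix, p: np.ndarray | None = None, freq_provenance: str = "own"
) -> StandardizedGenotypes:
    """Center and scale dosages to the design matrix W.

    When ``p`` is omitted it is computed from ``G`` itself (the reference-
    population case). Pass the reference frequencies explicitly to
    standardize validation animals on the reference scale.
    """
    if p is None:
        p = allele_frequencies(G)
        freq_provenance = "own"
    p = np.asarray(p, dtype=float)
    if p.shape != (G.n_markers,):
        raise ValueError("frequency vector length does not match marker count")
    if np.any((p <= 0) | (p >= 1)):
        j = int(np.argmax((p <= 0) | (p >= 1)))
        raise ValueError(
            f"p = {p[j]} at marker {G.map.marker_id[j]!r}: fixed allele, "
            "standardization undefined (filter first)"
        )
    denom = np.sqrt(2.0 * p * (1.0 - p))
    W = (G.X - 2.0 * p) / denom
    return StandardizedGenotypes(W, p, G.map, freq_provenance)


def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree TSV with columns id, sire, dam ("0" or empty = unknown)."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise FormatError(f"{path}: pedigree missing column {col!r}")
    return df


def build_A_from_pedigree(ped: pd.DataFrame) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method.

    ``ped`` has columns id, sire, dam with "0", "" or NaN for unknown
    parents. Individuals are topologically sorted so parents precede
    offspring; a pedigree cycle (an individual among its own ancestors)
    raises. Entries follow the recursion
    ``a_ii = 1 + 0.5 a(sire, dam)`` and ``a_ij = 0.5 (a_j,sire(i) + a_j,dam(i))``.
    """

    def norm(v):
        if v is None:
            return None
        v = str(v).strip()
        return None if v in ("", "0", "nan", "NA") else v

    ids = [str(i).strip() for i in ped["id"]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate id in pedigree")
    sire = {i: norm(s) for i, s in zip(ids, ped["sire"])}
    dam = {i: norm(d) for i, d in zip(ids, ped["dam"])}
    for i in ids:
        for par in (sire[i], dam[i]):
            if par is not None and par == i:
                raise ValueError(f"individual {i!r} is its own parent")
            if par is not None and par not in sire:
                # founder parent not listed: treat as unknown founder entry
                sire[par] = None
                dam[par] = None
    all_ids = list(sire.keys())

    # topological sort (parents first); cycle detection via DFS state
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(i, stack):
        st = state.get(i, 0)
        if st == 1:
            raise ValueError(f"pedigree cycle involving {i!r}")
        if st == 2:
            return
        state[i] = 1
        for par in (sire[i], dam[i]):
            if par is not None:
                visit(par, stack)
        state[i] = 2
        order.append(i)

    for i in all_ids:
        visit(i, [])

    q = len(order)
    pos = {s: k for k, s in enumerate(order)}
    A = np.zeros((q, q))
    for i_name in order:
        i = pos[i_name]
        s = pos.get(sire[i_name]) if sire[i_name] is not None else None
        d = pos.get(dam[i_name]) if dam[i_name] is not None else None
        for j in range(i):
            a = 0.0
            if s is not None:
                a += 0.5 * A[j, s]
            if d is not None:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
    return RelationshipMatrix(A, np.array(order, dtype=object))
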