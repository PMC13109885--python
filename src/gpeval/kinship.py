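"""Relationship matrices: pedigree A, genomic G, blended Gw and the
single-step H-inverse.

All algebra is dense: at desk scale (a few thousand animals) explicit
inversion is fast, and every construction can be cross-checked against
a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, Pedigree

__all__ = [
    "RelationshipMatrix",
    "a_matrix",
    "a22",
    "g_matrix",
    "blend_gw",
    "blend_identity",
    "h_inverse",
    "make_h_inverse",
    "inv_psd",
]


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    ids: list[str]
    kind: str  # one of A, A22, G, Gw, Hinv

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square")
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for a {n}x{n} matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric to 1e-10")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=np.int64)
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.kind)


def inv_psd(M: np.ndarray, jitter_scale: float = 1e-8) -> np.ndarray:
    """Invert a PSD matrix via Cholesky, with a jitter fallback.

    If the factorization fails, ``jitter_scale * mean(diag)`` is added
    to the diagonal before retrying once.
    """
    M = np.asarray(M, dtype=np.float64)
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        bump = jitter_scale * float(np.mean(np.diag(M)))
        if bump <= 0:
            bump = jitter_scale
        try:
            L = np.linalg.cholesky(M + bump * np.eye(M.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "matrix is not positive definite even after jitter; "
                "blend with the pedigree matrix or identity first"
            ) from exc
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv


def a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Processing animals in pedigree (topological) order:
    ``A[i,j] = (A[j,s] + A[j,d]) / 2`` for earlier j and
    ``A[i,i] = 1 + A[s,d] / 2``; an unknown parent contributes 0.
    """
    sire, dam = ped.parent_indices()
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(A, ped.ids, "A")


def a22(A: RelationshipMatrix, genotyped_ids: list[str]) -> RelationshipMatrix:
    """Pedigree relationships among the genotyped subset."""
    out = A.subset(genotyped_ids)
    out.kind = "A22"
    return out


def g_matrix(
    geno: GenotypeMatrix, weights: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix, optionally SNP-weighted.

    ``G = Z D Z' / sum_i 2 p_i (1 - p_i)`` with ``Z`` the dosage matrix
    column-centered by twice the observed counted-allele frequency and
    ``D`` the diagonal weight matrix (identity by default).  Weights are
    expected to be trace-normalized to the marker count; the denominator
    is unweighted, so rescaling-plus-renormalization leaves G unchanged.
    """
    if geno.n_markers < 1:
        raise ValueError("need at least one marker")
    dos = geno.dosages
    if np.isnan(dos).any():
        raise ValueError("missing dosages: impute (e.g. impute_mean) before G")
    p = dos.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = geno.markers["marker"].iloc[int(np.flatnonzero(mono)[0])]
        raise ValueError(
            f"monomorphic marker {bad!r} (p in {{0,1}}); run QC/MAF filtering first"
        )
    Z = dos - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if weights is None:
        G = (Z @ Z.T) / denom
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (geno.n_markers,):
            raise ValueError(
                f"weight vector length {w.shape} does not match {geno.n_markers} markers"
            )
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            bad = geno.markers["marker"].iloc[
                int(np.flatnonzero(~np.isfinite(w) | (w < 0))[0])
            ]
            raise ValueError(f"non-finite or negative weight at marker {bad!r}")
        G = (Z * w) @ Z.T / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(G, list(geno.ids), "G")


def blend_gw(G: RelationshipMatrix, A22m: RelationshipMatrix, g_weight: float = 0.95) -> RelationshipMatrix:
    """Blend genomic and pedigree relationships: Gw = 0.95 G + 0.05 A22."""
    if G.ids != A22m.ids:
        raise ValueError("id order of G and A22 must match for blending")
    Gw = g_weight * G.values + (1.0 - g_weight) * A22m.values
    return RelationshipMatrix(Gw, list(G.ids), "Gw")


def blend_identity(G: RelationshipMatrix, g_weight: float = 0.95) -> RelationshipMatrix:
    """Blend G with the identity (used when no pedigree is modeled)."""
    Gw = g_weight * G.values + (1.0 - g_weight) * np.eye(G.n)
    return RelationshipMatrix(Gw, list(G.ids), "Gw")


def h_inverse(
    Ainv: RelationshipMatrix,
    A22inv: np.ndarray,
    Gwinv: np.ndarray,
    genotyped_ids: list[str],
) -> RelationshipMatrix:
    """Single-step H-inverse.

    ``H^{-1} = A^{-1} + [[0, 0], [0, Gw^{-1} - A22^{-1}]]`` with the
    nonzero block on the genotyped individuals.
    """
    pos = {i: k for k, i in enumerate(Ainv.ids)}
    try:
        idx = np.array([pos[i] for i in genotyped_ids], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"genotyped id {exc.args[0]!r} not in pedigree matrix") from None
    ng = len(idx)
    A22inv = np.asarray(A22inv, dtype=np.float64)
    Gwinv = np.asarray(Gwinv, dtype=np.float64)
    if A22inv.shape != (ng, ng) or Gwinv.shape != (ng, ng):
        raise ValueError("A22inv/Gwinv shapes do not match the genotyped id list")
    if not (np.all(np.isfinite(A22inv)) and np.all(np.isfinite(Gwinv))):
        raise ValueError("non-finite entries in A22inv or Gwinv")
    H = Ainv.values.copy()
    H[np.ix_(idx, idx)] += Gwinv - A22inv
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(H, list(Ainv.ids), "Hinv")


def make_h_inverse(
    ped: Pedigree,
    geno: GenotypeMatrix,
    weights: np.ndarray | None = None,
    g_weight: float = 0.95,
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Convenience assembly of (H^{-1}, Gw) from pedigree + genotypes."""
    A = a_matrix(ped)
    A22m = a22(A, list(geno.ids))
    G = g_matrix(geno, weights=weights)
    Gw = blend_gw(G, A22m, g_weight=g_weight)
    Ainv = RelationshipMatrix(inv_psd(A.values), A.ids, "Ainv")
    Hinv = h_inverse(Ainv, inv_psd(A22m.values), inv_psd(Gw.values), list(geno.ids))
    return Hinv, Gw
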