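"""Iterative SNP weighting (weighted single-step GWAS).

Starting from uniform weights, each iteration (i) fits single-step
GBLUP with the current weighted genomic relationship matrix, (ii)
backsolves the genotyped animals' GEBVs to per-marker effects
``u = D Z' Gw^{-1} a_g / lambda`` with ``lambda = sum_i 2 p_i (1-p_i)``,
(iii) converts squared effects to variance weights
``d_i* = u_i^2 2 p_i (1 - p_i)`` and (iv) renormalizes the weights to
trace M.  Two iterations are the recommended default.  Per-window
genetic-variance shares over non-overlapping 20-SNP windows summarize
where the weight mass (and hence putative QTL signal) sits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Pedigree
from .kinship import RelationshipMatrix, a22, a_matrix, blend_gw, h_inverse, inv_psd
from .mixedmodel import VarianceComponents, build_design, em_reml, solve_mme

__all__ = ["WssgwasState", "iterate_weights", "window_variance"]


@dataclass
class WssgwasState:
    t: int
    weights: np.ndarray  # D at iteration t, trace-normalized to M
    u_hat: np.ndarray  # marker effects backsolved at the last iteration
    lambda_norm: float  # sum_i 2 p_i (1 - p_i)
    weights_history: list[np.ndarray] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)


def _check_finite(vec: np.ndarray, marker_ids: list[str], what: str) -> None:
    bad = ~np.isfinite(vec)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite {what} at marker {marker_ids[j]!r}")


def iterate_weights(
    pheno: pd.DataFrame,
    ped: Pedigree,
    geno: GenotypeMatrix,
    vc: VarianceComponents | None = None,
    n_iter: int = 2,
    trait: str = "trait",
    fixed: tuple[str, ...] = ("batch",),
    covariates: tuple[str, ...] = (),
    train_ids: list[str] | None = None,
) -> WssgwasState:
    """Run the iterative weighting procedure and return the final state.

    ``train_ids`` restricts the phenotype records entering the
    single-step fits, so weights can be learned on a training fold only.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    geno = geno.impute_mean()
    m = geno.n_markers
    marker_ids = geno.markers["marker"].tolist()
    p = geno.allele_freqs()
    if np.any((p <= 0) | (p >= 1)):
        j = int(np.flatnonzero((p <= 0) | (p >= 1))[0])
        raise ValueError(f"monomorphic marker {marker_ids[j]!r}; run QC first")
    Z = geno.dosages - 2.0 * p
    two_pq = 2.0 * p * (1.0 - p)
    lam = float(two_pq.sum())

    y, X, rec_ids, names = build_design(pheno, trait, fixed, covariates)
    if train_ids is not None:
        keep = [k for k, i in enumerate(rec_ids) if i in set(train_ids)]
        y, X = y[keep], X[keep]
        live = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
        X = X[:, live]
        names = [names[j] for j in live]
        rec_ids = [rec_ids[k] for k in keep]
    rec_idx = ped.subset_index(rec_ids)

    A = a_matrix(ped)
    A22m = a22(A, list(geno.ids))
    Ainv = RelationshipMatrix(inv_psd(A.values), A.ids, "Ainv")
    A22inv = inv_psd(A22m.values)
    g_pos = {i: k for k, i in enumerate(A.ids)}
    g_rows = [g_pos[i] for i in geno.ids]

    D = np.ones(m)
    history: list[np.ndarray] = []
    u_hat = np.zeros(m)
    for _t in range(n_iter):
        G = (Z * D) @ Z.T / lam
        G = 0.5 * (G + G.T)
        Gw = blend_gw(
            RelationshipMatrix(G, list(geno.ids), "G"), A22m
        )
        Gwinv = inv_psd(Gw.values)
        Hinv = h_inverse(Ainv, A22inv, Gwinv, list(geno.ids))
        if vc is None:
            H = inv_psd(Hinv.values)
            vc = em_reml(y, X, H[np.ix_(rec_idx, rec_idx)])
        fit = solve_mme(y, X, vc, Kinv=Hinv, record_idx=rec_idx, fixed_names=names)
        a_g = fit.a_hat.to_numpy()[g_rows]
        u_hat = D * (Z.T @ (Gwinv @ a_g)) / lam
        _check_finite(u_hat, marker_ids, "marker effect")
        d_star = u_hat**2 * two_pq
        _check_finite(d_star, marker_ids, "weight")
        total = d_star.sum()
        if total <= 0:
            warnings.warn(
                "all backsolved marker effects are zero; keeping uniform weights",
                stacklevel=2,
            )
            D = np.ones(m)
        else:
            D = m * d_star / total
        history.append(D.copy())
    return WssgwasState(
        t=n_iter,
        weights=D,
        u_hat=u_hat,
        lambda_norm=lam,
        weights_history=history,
        marker_ids=marker_ids,
    )


def window_variance(
    state: WssgwasState, geno: GenotypeMatrix, window_snps: int = 20
) -> pd.DataFrame:
    """Genetic-variance share of non-overlapping marker windows.

    For each window w of ``window_snps`` consecutive markers (map
    order; the final window may be shorter) the share is
    ``var(Z_w u_w) / var(Z u)`` over the genotyped individuals.  Shares
    need not sum to 1 because window contributions covary.
    """
    geno = geno.impute_mean()
    m = geno.n_markers
    if m < window_snps:
        warnings.warn(
            f"{m} markers is less than one {window_snps}-SNP window; using a single window",
            stacklevel=2,
        )
        window_snps = m
    p = geno.allele_freqs()
    Z = geno.dosages - 2.0 * p
    u = state.u_hat
    total = float((Z @ u).var())
    rows = []
    w = 0
    for start in range(0, m, window_snps):
        end = min(m, start + window_snps)
        gv = float((Z[:, start:end] @ u[start:end]).var())
        share = gv / total if total > 0 else 0.0
        rows.append(
            {
                "window": w,
                "chrom": geno.markers["chrom"].iloc[start],
                "first_marker": geno.markers["marker"].iloc[start],
                "last_marker": geno.markers["marker"].iloc[end - 1],
                "first_index": start,
                "last_index": end - 1,
                "variance_share": share,
            }
        )
        w += 1
    return pd.DataFrame(rows)
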