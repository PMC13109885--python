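"""Variance components, Henderson mixed-model equations and the linear
predictors: pedigree ABLUP (for corrected phenotypes), GBLUP, ssGBLUP
and weighted GBLUP.

The animal model throughout is

    y = X b + Z a + e,   a ~ N(0, K sigma_g^2),   e ~ N(0, I sigma_e^2)

with K one of A (pedigree), G (genomic), Gw (blended) or H (single
step).  Covariates such as genomic PCs enter through extra columns of
X.  Corrected phenotypes are yc = y - X b_hat = a_hat + e_hat, the
response used by every genomic predictor so parental information is not
double counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Pedigree
from .kinship import (
    RelationshipMatrix,
    a22,
    a_matrix,
    blend_gw,
    blend_identity,
    g_matrix,
    inv_psd,
    make_h_inverse,
)

__all__ = [
    "VarianceComponents",
    "MixedModelFit",
    "em_reml",
    "solve_mme",
    "build_design",
    "ablup_corrected_phenotypes",
    "gblup",
    "wgblup",
    "ssgblup",
]


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    converged: bool = True
    identifiable: bool = True
    n_iter: int = 0

    def __post_init__(self):
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0

    @property
    def lam(self) -> float:
        """Shrinkage ratio sigma_e^2 / sigma_g^2 entering the MME."""
        if self.sigma_g2 <= 0:
            return np.inf
        return self.sigma_e2 / self.sigma_g2


@dataclass
class MixedModelFit:
    b_hat: np.ndarray  # fixed-effect estimates, order of fixed_names
    fixed_names: list[str]
    a_hat: pd.Series  # breeding values for every individual in K
    e_hat: pd.Series  # residuals, record-bearing individuals only
    vc: VarianceComponents
    record_ids: list[str]

    @property
    def gebv(self) -> pd.Series:
        return self.a_hat


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
    start: tuple[float, float] | None = None,
) -> VarianceComponents:
    """EM-REML for the single-random-effect animal model.

    K is the relationship matrix over the record-bearing individuals.
    Iterates the expectation-maximization updates on (sigma_g^2,
    sigma_e^2) until the relative change of both components falls below
    ``tol`` or ``max_iter`` is reached; returns a convergence flag
    rather than raising on non-convergence.  With K = I the two
    components are not separable; the result is flagged
    ``identifiable=False``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X rows must match y length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("X is rank deficient; drop aliased fixed-effect columns")
    K = np.asarray(K, dtype=np.float64)
    if K.shape != (n, n):
        raise ValueError("K must be square over the record-bearing individuals")

    vary = float(np.var(y))
    if vary < 1e-12:
        return VarianceComponents(0.0, 0.0, converged=True, n_iter=0)
    identifiable = not np.allclose(K, np.eye(n), atol=1e-12)

    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    sg, se = start if start is not None else (vary / 2.0, vary / 2.0)
    floor = 1e-12 * vary
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = S * sg + se
        d = np.maximum(d, 1e-300)
        Xd = Xt / d[:, None]
        B = np.linalg.inv(Xt.T @ Xd)
        py = yt / d - Xd @ (B @ (Xd.T @ yt))
        tr_P = float(np.sum(1.0 / d) - np.einsum("ij,jk,ik->", Xd, B, Xd))
        XdS = Xd * S[:, None]
        tr_KP = float(np.sum(S / d) - np.einsum("ij,jk,ik->", XdS, B, Xd))
        yPKPy = float(np.sum(S * py**2))
        yPPy = float(np.sum(py**2))

        sg_new = sg + sg**2 * (yPKPy - tr_KP) / n
        se_new = se + se**2 * (yPPy - tr_P) / n
        sg_new = max(sg_new, floor)
        se_new = max(se_new, floor)
        rel = max(
            abs(sg_new - sg) / max(sg, floor), abs(se_new - se) / max(se, floor)
        )
        sg, se = sg_new, se_new
        if rel < tol:
            converged = True
            break
    return VarianceComponents(
        sigma_g2=sg,
        sigma_e2=se,
        converged=converged,
        identifiable=identifiable,
        n_iter=it,
    )


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    vc: VarianceComponents,
    K: RelationshipMatrix | None = None,
    Kinv: RelationshipMatrix | None = None,
    record_idx: np.ndarray | None = None,
    fixed_names: list[str] | None = None,
) -> MixedModelFit:
    """Solve Henderson's mixed-model equations.

    Either K or its inverse may be supplied.  ``record_idx[r]`` gives
    the K row of the individual carrying record r; by default records
    align one-to-one with K.  BLUPs are returned for every individual
    in K, with or without records.
    """
    if (K is None) == (Kinv is None):
        raise ValueError("supply exactly one of K or Kinv")
    rel = K if K is not None else Kinv
    ids = list(rel.ids)
    q = rel.n
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    r = y.size
    if record_idx is None:
        if r != q:
            raise ValueError("record_idx required when records do not align with K")
        record_idx = np.arange(q)
    record_idx = np.asarray(record_idx, dtype=np.int64)
    if vc.sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive to form the MME")
    names = fixed_names if fixed_names is not None else [f"b{j}" for j in range(X.shape[1])]

    if not np.isfinite(vc.lam):  # no genetic variance: plain least squares
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        a = np.zeros(q)
        e = y - X @ b
        return MixedModelFit(
            b, names, pd.Series(a, index=ids), pd.Series(e, index=[ids[i] for i in record_idx]),
            vc, [ids[i] for i in record_idx],
        )

    Z = np.zeros((r, q))
    Z[np.arange(r), record_idx] = 1.0
    if Kinv is None:
        evals = np.linalg.eigvalsh(K.values)
        if evals[0] <= 1e-10 * max(evals[-1], 1e-300):
            # singular K (e.g. VanRaden G, which annihilates the ones
            # vector): the MME needs K^{-1}, so solve the equivalent
            # GLS/BLUP system on the variance scale instead
            return _solve_gls_blup(y, X, vc, K, Z, record_idx, names)
        Kinv_vals = inv_psd(K.values)
    else:
        Kinv_vals = Kinv.values
    lam = vc.lam
    if X.shape[1] == 0:  # no fixed part: pure shrinkage system
        C = Z.T @ Z + Kinv_vals * lam
        rhs = Z.T @ y
    else:
        C = np.block(
            [
                [X.T @ X, X.T @ Z],
                [Z.T @ X, Z.T @ Z + Kinv_vals * lam],
            ]
        )
        rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular MME coefficient matrix (cond ~ {np.linalg.cond(C):.3e}); "
            "check fixed-effect coding and relationship-matrix invertibility"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError(
            f"non-finite MME solution (cond ~ {np.linalg.cond(C):.3e})"
        )
    p = X.shape[1]
    b = sol[:p]
    a = sol[p:]
    e = y - X @ b - a[record_idx]
    rec_ids = [ids[i] for i in record_idx]
    return MixedModelFit(
        b, names, pd.Series(a, index=ids), pd.Series(e, index=rec_ids), vc, rec_ids
    )


def _solve_gls_blup(y, X, vc, K, Z, record_idx, names) -> MixedModelFit:
    """Variance-scale equivalent of the MME, valid for singular K."""
    ids = list(K.ids)
    V = (Z @ K.values @ Z.T) * vc.sigma_g2 + np.eye(len(y)) * vc.sigma_e2
    Vi = inv_psd(V)
    if X.shape[1]:
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        resid_fixed = y - X @ b
    else:
        b = np.zeros(0)
        resid_fixed = y
    a = vc.sigma_g2 * K.values @ Z.T @ (Vi @ resid_fixed)
    e = y - X @ b - a[record_idx]
    rec_ids = [ids[i] for i in record_idx]
    return MixedModelFit(
        b, names, pd.Series(a, index=ids), pd.Series(e, index=rec_ids), vc, rec_ids
    )


def build_design(
    pheno: pd.DataFrame,
    trait: str = "trait",
    fixed: tuple[str, ...] = ("batch",),
    covariates: tuple[str, ...] = (),
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Design matrix with intercept, factor dummies and covariates.

    Rows with a missing trait value or missing covariate are dropped.
    Returns (y, X, record ids, fixed-effect column names).
    """
    cols = [trait, *fixed, *covariates]
    sub = pheno[["id", *cols]].dropna(subset=[trait, *covariates])
    y = sub[trait].to_numpy(dtype=float)
    parts = [np.ones((len(sub), 1))]
    names = ["intercept"]
    for f in fixed:
        levels = pd.unique(sub[f])
        counts = sub[f].value_counts()
        lonely = counts[counts == 1]
        if len(lonely):
            warnings.warn(
                f"fixed factor {f!r} has levels with a single record: "
                f"{list(lonely.index)[:5]}",
                stacklevel=2,
            )
        dummies = pd.get_dummies(sub[f], prefix=f, drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
        names.extend(dummies.columns.tolist())
    for c in covariates:
        parts.append(sub[c].to_numpy(dtype=float)[:, None])
        names.append(c)
    X = np.hstack(parts)
    return y, X, sub["id"].tolist(), names


def ablup_corrected_phenotypes(
    pheno: pd.DataFrame,
    ped: Pedigree,
    trait: str = "trait",
    fixed: tuple[str, ...] = ("batch",),
    covariates: tuple[str, ...] = (),
    vc: VarianceComponents | None = None,
    A: RelationshipMatrix | None = None,
) -> tuple[pd.Series, MixedModelFit]:
    """Corrected phenotypes from a pedigree animal model.

    Fits ABLUP with the numerator relationship matrix and returns
    ``yc = y - X b_hat`` (equivalently EBV + residual) for the record-
    bearing individuals, together with the full fit.
    """
    if A is None:
        A = a_matrix(ped)
    y, X, rec_ids, names = build_design(pheno, trait, fixed, covariates)
    missing = [i for i in rec_ids if i not in set(ped.ids)]
    if missing:
        raise ValueError(f"phenotyped individuals not in pedigree: {missing[:5]}")
    rec_idx = ped.subset_index(rec_ids)
    if vc is None:
        K_rec = A.values[np.ix_(rec_idx, rec_idx)]
        vc = em_reml(y, X, K_rec)
    fit = solve_mme(y, X, vc, K=A, record_idx=rec_idx, fixed_names=names)
    yc = pd.Series(y - X @ fit.b_hat, index=rec_ids, name="yc")
    return yc, fit


def gblup(
    yc: pd.Series,
    G: RelationshipMatrix,
    vc: VarianceComponents | None = None,
    train_ids: list[str] | None = None,
) -> MixedModelFit:
    """GBLUP on corrected phenotypes with an intercept-only fixed part.

    ``G`` must be invertible (blend beforehand); GEBVs are returned for
    every individual in G, so candidates without records are predicted
    through their genomic relationships to the training set.
    """
    in_g = set(G.ids)
    if train_ids is None:
        train_ids = [i for i in G.ids if i in set(yc.index)]
    else:
        train_ids = [i for i in train_ids if i in in_g]
    if not train_ids:
        raise ValueError("no training individuals present in G")
    y = yc.loc[train_ids].to_numpy(dtype=float)
    X = np.ones((len(train_ids), 1))
    rec_idx = np.array([G.ids.index(i) for i in train_ids], dtype=np.int64)
    if vc is None:
        K_rec = G.values[np.ix_(rec_idx, rec_idx)]
        vc = em_reml(y, X, K_rec)
    return solve_mme(y, X, vc, K=G, record_idx=rec_idx, fixed_names=["intercept"])


def wgblup(
    yc: pd.Series,
    geno: GenotypeMatrix,
    weights: np.ndarray,
    vc: VarianceComponents | None = None,
    train_ids: list[str] | None = None,
    A22m: RelationshipMatrix | None = None,
) -> MixedModelFit:
    """GBLUP with a SNP-weighted G; identical to :func:`gblup` when the
    weights are all ones."""
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (geno.n_markers,):
        raise ValueError(
            f"weight vector length {w.size} does not match {geno.n_markers} markers"
        )
    G = g_matrix(geno, weights=w)
    Gb = blend_gw(G, A22m) if A22m is not None else blend_identity(G)
    return gblup(yc, Gb, vc=vc, train_ids=train_ids)


def ssgblup(
    pheno: pd.DataFrame,
    ped: Pedigree,
    geno: GenotypeMatrix | None,
    trait: str = "trait",
    fixed: tuple[str, ...] = ("batch",),
    covariates: tuple[str, ...] = (),
    vc: VarianceComponents | None = None,
    weights: np.ndarray | None = None,
    train_ids: list[str] | None = None,
    A: RelationshipMatrix | None = None,
    Hinv: RelationshipMatrix | None = None,
) -> MixedModelFit:
    """Single-step GBLUP on raw phenotypes over the full pedigree.

    Builds H^{-1} from the pedigree and the genotyped block (blended
    Gw = 0.95 G + 0.05 A22) and solves the animal model with the same
    fixed effects as ABLUP.  With no genotyped individuals this reduces
    exactly to ABLUP.  ``train_ids`` restricts the records used (for
    cross-validation); predictions still cover every animal.  ``A`` and
    ``Hinv`` may be precomputed to avoid rebuilding them per fold.
    """
    y, X, rec_ids, names = build_design(pheno, trait, fixed, covariates)
    if train_ids is not None:
        keep = [k for k, i in enumerate(rec_ids) if i in set(train_ids)]
        y, X = y[keep], X[keep]
        # a factor level may vanish from the training records
        live = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
        X = X[:, live]
        names = [names[j] for j in live]
        rec_ids = [rec_ids[k] for k in keep]
    rec_idx = ped.subset_index(rec_ids)
    if geno is None or geno.n_individuals == 0:
        if A is None:
            A = a_matrix(ped)
        if vc is None:
            vc = em_reml(y, X, A.values[np.ix_(rec_idx, rec_idx)])
        return solve_mme(y, X, vc, K=A, record_idx=rec_idx, fixed_names=names)
    if Hinv is None:
        Hinv, _ = make_h_inverse(ped, geno, weights=weights)
    if vc is None:
        H = inv_psd(Hinv.values)
        vc = em_reml(y, X, H[np.ix_(rec_idx, rec_idx)])
    return solve_mme(y, X, vc, Kinv=Hinv, record_idx=rec_idx, fixed_names=names)
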