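"""Repeated k-fold cross-validation and evaluation statistics.

Accuracy is the Pearson correlation between corrected phenotypes and
GEBVs in the validation fold; bias is the slope of regressing corrected
phenotypes on GEBVs (1 = neither inflated nor deflated); MSE and MAE
are the usual per-round prediction errors.  Bland-Altman statistics
quantify agreement between two paired measurement methods.  Models are
compared across rounds by one-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldPlan",
    "CVReport",
    "make_folds",
    "accuracy",
    "bias",
    "mse_mae",
    "bland_altman",
    "run_cv",
]


@dataclass
class FoldPlan:
    """Validation-id sets for ``n_repeats`` random k-fold partitions."""

    k: int
    n_repeats: int
    seed: int
    rounds: list[tuple[int, int, list[str]]] = field(default_factory=list)
    # rounds: (repeat, fold, validation ids)

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


def make_folds(ids: list[str], k: int = 5, repeats: int = 10, seed: int = 0) -> FoldPlan:
    """Uniform random partition of ids into k folds, repeated.

    Fold sizes differ by at most one; partitioning 3,737 ids into five
    folds gives sizes 748/748/747/747/747.
    """
    ids = list(ids)
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} ids into {k} folds")
    rng = np.random.default_rng(seed)
    rounds = []
    for rep in range(repeats):
        perm = rng.permutation(len(ids))
        for fold, chunk in enumerate(np.array_split(perm, k)):
            rounds.append((rep, fold, [ids[i] for i in chunk]))
    return FoldPlan(k=k, n_repeats=repeats, seed=seed, rounds=rounds)


def accuracy(yc_val: np.ndarray, gebv_val: np.ndarray) -> float:
    """Pearson correlation between corrected phenotypes and GEBVs."""
    yc_val = np.asarray(yc_val, dtype=float)
    gebv_val = np.asarray(gebv_val, dtype=float)
    if yc_val.size < 3:
        raise ValueError("need at least 3 pairs")
    if yc_val.std() == 0 or gebv_val.std() == 0:
        raise ValueError("zero variance on one side; correlation undefined")
    return float(np.corrcoef(yc_val, gebv_val)[0, 1])


def bias(yc_val: np.ndarray, gebv_val: np.ndarray) -> float:
    """OLS slope of corrected phenotype on GEBV; 1 means unbiased."""
    yc_val = np.asarray(yc_val, dtype=float)
    gebv_val = np.asarray(gebv_val, dtype=float)
    v = gebv_val.var()
    if v == 0:
        raise ValueError("zero GEBV variance; slope undefined")
    return float(np.cov(gebv_val, yc_val, ddof=0)[0, 1] / v)


def mse_mae(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mean squared and mean absolute prediction error."""
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=float)
    if f.shape != y.shape:
        raise ValueError("prediction and response lengths differ")
    d = f - y
    return float(np.mean(d**2)), float(np.mean(np.abs(d)))


@dataclass
class BlandAltman:
    bias: float
    lower: float
    upper: float
    pct_within: float
    degenerate: bool  # zero difference SD collapses the limits


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Agreement between two paired measurements.

    Limits of agreement are bias +/- 1.96 SD of the differences;
    ``pct_within`` is the percentage of pairs strictly inside them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired points")
    d = x - y
    b = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = b - 1.96 * sd, b + 1.96 * sd
    degenerate = sd == 0.0
    if degenerate:
        # all differences equal the bias: perfect agreement, collapsed limits
        warnings.warn("zero difference SD: limits of agreement collapse", stacklevel=2)
        within = 100.0
    else:
        within = 100.0 * float(np.mean((d > lower) & (d < upper)))
    return BlandAltman(b, lower, upper, within, degenerate)


@dataclass
class CVReport:
    rounds: pd.DataFrame  # model, repeat, fold, accuracy, bias, mse, mae
    summary: pd.DataFrame  # per-model mean and SE of each metric
    anova: pd.DataFrame | None = None  # pairwise Tukey comparisons on accuracy
    anova_p: float | None = None
    failures: list[tuple[str, int, int, str]] = field(default_factory=list)


def _summarize(rounds: pd.DataFrame) -> pd.DataFrame:
    out = []
    for model, grp in rounds.groupby("model", sort=False):
        row = {"model": model, "n_rounds": len(grp)}
        for metric in ("accuracy", "bias", "mse", "mae"):
            vals = grp[metric].to_numpy()
            row[f"{metric}_mean"] = float(np.mean(vals))
            row[f"{metric}_se"] = (
                float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            )
        out.append(row)
    return pd.DataFrame(out)


def run_cv(models: dict, yc: pd.Series, plan: FoldPlan, compare: bool = True) -> CVReport:
    """Run every model through every CV round and score the predictions.

    ``models`` maps a model name to a callable
    ``predict(train_ids, val_ids) -> pd.Series`` returning GEBVs indexed
    by (at least) the validation ids; training uses only the training
    ids, which is the callable's responsibility (including fold-local
    variance components or SNP weights).  ``yc`` holds the corrected
    phenotypes of every individual in the plan.  A model failure in a
    round is recorded and the round excluded from that model's summary.
    """
    all_ids = set(yc.index)
    records = []
    failures = []
    for model_name, predictor in models.items():
        for rep, fold, val_ids in plan.rounds:
            train_ids = [i for i in yc.index if i not in set(val_ids)]
            val_ids = [i for i in val_ids if i in all_ids]
            try:
                pred = predictor(train_ids, val_ids)
                pv = pred.loc[val_ids].to_numpy(dtype=float)
                truth = yc.loc[val_ids].to_numpy(dtype=float)
                acc = accuracy(truth, pv)
                slope = bias(truth, pv)
                mse, mae = mse_mae(pv, truth)
            except Exception as exc:  # noqa: BLE001 - round-level fault isolation
                failures.append((model_name, rep, fold, str(exc)))
                continue
            records.append(
                {
                    "model": model_name,
                    "repeat": rep,
                    "fold": fold,
                    "accuracy": acc,
                    "bias": slope,
                    "mse": mse,
                    "mae": mae,
                }
            )
    rounds = pd.DataFrame(records)
    if rounds.empty:
        raise RuntimeError(f"every CV round failed: {failures[:3]}")
    summary = _summarize(rounds)
    report = CVReport(rounds=rounds, summary=summary, failures=failures)
    if compare and rounds["model"].nunique() >= 2:
        groups = [grp["accuracy"].to_numpy() for _, grp in rounds.groupby("model", sort=False)]
        if all(len(g) >= 2 for g in groups) and any(np.std(g) > 0 for g in groups):
            report.anova_p = float(stats.f_oneway(*groups).pvalue)
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            tk = pairwise_tukeyhsd(
                rounds["accuracy"].to_numpy(), rounds["model"].to_numpy(), alpha=0.05
            )
            report.anova = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
    return report
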