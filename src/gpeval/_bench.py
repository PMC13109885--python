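"""Reproducibility experiments used by tests and scripts/acceptance.py.

Each function regenerates its data from a seed and recomputes the
quantity from scratch through the public API.  Problem sizes are chosen
for a desktop-scale single-core run; the methods note records them.
"""

from __future__ import annotations

import numpy as np

from .evaluate import accuracy, make_folds
from .genio import qc_filter
from .kinship import blend_identity, g_matrix
from .mixedmodel import (
    ablup_corrected_phenotypes,
    em_reml,
    gblup,
    wgblup,
)
from .simdata import Architecture, SimConfig, simulate_dataset
from .wssgwas import iterate_weights

__all__ = [
    "h2_recovery",
    "realized_h2_calibration",
    "directional_cv_experiment",
]


def h2_recovery(seed: int = 0, n_reps: int = 10, true_h2: float = 0.30) -> dict:
    """Mean EM-REML heritability estimate on simulated genomic data.

    Per replicate: ~550-animal three-generation pedigree, 2,000 markers,
    polygenic trait at the given heritability; K is the blended VanRaden
    G of the post-QC panel.
    """
    ests = []
    for rep in range(n_reps):
        cfg = SimConfig(
            n_founders=150,
            n_generations=3,
            matings_per_generation=(100, 100),
            offspring_per_mating=2,
            n_markers=2000,
            n_chromosomes=5,
            h2=true_h2,
            seed=seed * 1000 + rep,
        )
        ped, geno, pheno, _ = simulate_dataset(cfg)
        geno, _ = qc_filter(geno)
        G = blend_identity(g_matrix(geno.impute_mean()))
        sub = pheno.dropna(subset=["trait"])
        ids = [i for i in sub["id"] if i in set(geno.ids)]
        y = sub.set_index("id").loc[ids, "trait"].to_numpy()
        idx = [G.ids.index(i) for i in ids]
        vc = em_reml(y, np.ones((len(y), 1)), G.values[np.ix_(idx, idx)])
        ests.append(vc.h2)
    return {"h2_mean": float(np.mean(ests)), "h2_per_rep": ests, "n": n_reps}


def realized_h2_calibration(
    seed: int = 0, n_reps: int = 20, target_h2: float = 0.264
) -> dict:
    """Realized var(TBV)/var(y) of the generator at n=1,000 animals."""
    ratios = []
    for rep in range(n_reps):
        cfg = SimConfig(
            n_founders=250,
            n_generations=3,
            matings_per_generation=(190, 185),
            offspring_per_mating=2,
            n_markers=500,
            n_chromosomes=5,
            h2=target_h2,
            trait_mean=1.905,
            trait_sd=0.228,
            seed=seed * 1000 + rep,
        )
        _, _, pheno, truth = simulate_dataset(cfg)
        ratios.append(float(truth.tbv.var(ddof=0) / pheno["trait"].var(ddof=0)))
    return {"realized_h2_mean": float(np.mean(ratios)), "n": n_reps}


def _one_directional_run(seed: int) -> dict:
    """One seeded run of the model-comparison CV experiment.

    800-animal pedigree, 800 markers, oligogenic trait (10 QTL carrying
    60% of the genetic variance, h2 = 0.30, small batch effect).  GBLUP,
    WGBLUP (full-data wssGWAS weights, two iterations) and GBLUP on a
    random 10% marker subsample are scored on 3x5-fold CV against
    corrected phenotypes, with run-level variance components.
    """
    cfg = SimConfig(
        n_founders=200,
        n_generations=3,
        matings_per_generation=(150, 150),
        offspring_per_mating=2,
        n_markers=800,
        n_chromosomes=5,
        h2=0.3,
        architecture=Architecture("oligogenic", 10, 0.6),
        n_batches=4,
        batch_effect_sd=0.2,
        seed=seed,
    )
    ped, geno, pheno, _ = simulate_dataset(cfg)
    geno, _ = qc_filter(geno)
    yc, ab_fit = ablup_corrected_phenotypes(pheno, ped)
    yc = yc[yc.index.isin(geno.ids)]
    gi = geno.impute_mean()
    Gb = blend_identity(g_matrix(gi))
    idx = [Gb.ids.index(i) for i in yc.index]
    vc = em_reml(yc.to_numpy(), np.ones((len(yc), 1)), Gb.values[np.ix_(idx, idx)])
    state = iterate_weights(pheno, ped, gi, vc=ab_fit.vc, n_iter=2)
    rng = np.random.default_rng(seed)
    sparse_idx = np.sort(rng.choice(gi.n_markers, gi.n_markers // 10, replace=False))
    Gs = blend_identity(g_matrix(gi.subset(markers=sparse_idx)))
    plan = make_folds(list(yc.index), k=5, repeats=3, seed=seed)
    accs: dict[str, list[float]] = {"gblup": [], "wgblup": [], "sparse": []}
    for _rep, _fold, val in plan.rounds:
        tr = [i for i in yc.index if i not in set(val)]
        fg = gblup(yc, Gb, vc=vc, train_ids=tr)
        accs["gblup"].append(accuracy(yc.loc[val], fg.a_hat.loc[val]))
        fw = wgblup(yc, gi, state.weights, vc=vc, train_ids=tr)
        accs["wgblup"].append(accuracy(yc.loc[val], fw.a_hat.loc[val]))
        fs = gblup(yc, Gs, vc=vc, train_ids=tr)
        accs["sparse"].append(accuracy(yc.loc[val], fs.a_hat.loc[val]))
    return {k: float(np.mean(v)) for k, v in accs.items()}


def directional_cv_experiment(seed: int = 0, n_runs: int = 10) -> dict:
    """Repeat the model-comparison run over seeds and summarize."""
    runs = [_one_directional_run(seed * 1000 + r) for r in range(n_runs)]
    wins = sum(r["wgblup"] > r["gblup"] for r in runs)
    out = {
        "runs": runs,
        "wgblup_wins": int(wins),
        "n_runs": n_runs,
        "gblup_mean": float(np.mean([r["gblup"] for r in runs])),
        "wgblup_mean": float(np.mean([r["wgblup"] for r in runs])),
        "sparse_mean": float(np.mean([r["sparse"] for r in runs])),
    }
    return out
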