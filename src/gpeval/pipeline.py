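"""Configuration-driven orchestration: simulate/load -> QC -> prune ->
corrected phenotypes -> predictors -> repeated cross-validation.

A run directory holds the inputs, a manifest (package version, config,
config hash, master seed), per-stage outputs and the tidy CV report.
Reruns with an identical config reproduce identical numbers; with
``resume=True`` stages whose outputs exist under a matching config hash
are loaded instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import GenotypeMatrix, Pedigree
from .evaluate import CVReport, make_folds, run_cv
from .genio import compute_pcs, ld_prune, qc_filter, read_dataset, write_dataset
from .kinship import blend_identity, g_matrix, make_h_inverse
from .mixedmodel import (
    ablup_corrected_phenotypes,
    gblup,
    ssgblup,
    wgblup,
)
from .mlpredict import (
    DEFAULT_GRIDS,
    KernelSpec,
    RFSpec,
    grid_search,
    krr_fit_predict,
    rf_fit_predict,
    svr_fit_predict,
)
from .simdata import SimConfig, simulate_dataset, wenchang_config
from .wssgwas import iterate_weights

log = logging.getLogger("gpeval")

VALID_MODELS = ("ablup", "gblup", "ssgblup", "wgblup", "krr", "svr", "rf")


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs."""

    out_dir: str
    input_dir: str | None = None  # read an existing dataset ...
    preset: str | None = None  # ... or simulate one ("wenchang" or "small")
    trait: str = "trait"
    preset_trait: str = "32w-BW"
    sim_overrides: dict = field(default_factory=dict)
    models: tuple[str, ...] = ("gblup",)
    ld_threshold: float | None = None
    cv_k: int = 5
    cv_repeats: int = 10
    seed: int = 0
    weights_source: str = "fold"  # fold | full
    wssgwas_iters: int = 2
    n_pcs: int = 3
    tune: str = "none"  # none | once (grid search on the first training fold)
    fixed: tuple[str, ...] = ("batch",)

    def __post_init__(self):
        if not self.models:
            raise ValueError("model list must be nonempty")
        unknown = set(self.models) - set(VALID_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.ld_threshold is not None and not 0 < self.ld_threshold <= 1:
            raise ValueError("ld_threshold must be in (0, 1] or null")
        if self.weights_source not in ("fold", "full", "ones"):
            raise ValueError("weights_source must be 'fold', 'full' or 'ones'")
        if (self.input_dir is None) == (self.preset is None):
            raise ValueError("set exactly one of input_dir or preset")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _simulate(cfg: RunConfig) -> tuple[Pedigree, GenotypeMatrix, pd.DataFrame]:
    if cfg.preset == "wenchang":
        sim = wenchang_config(trait=cfg.preset_trait, seed=cfg.seed, **cfg.sim_overrides)
    elif cfg.preset == "small":
        sim = SimConfig(seed=cfg.seed, **cfg.sim_overrides)
    else:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    ped, geno, pheno, _ = simulate_dataset(sim)
    return ped, geno, pheno


def build_predictors(
    cfg: RunConfig,
    ped: Pedigree,
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    yc: pd.Series,
) -> dict:
    """Per-model closures with the ``predict(train_ids, val_ids)`` contract.

    Every closure trains only on the training ids: variance components
    are re-estimated per fold and, with ``weights_source='fold'``, the
    wssGWAS weights are learned inside the fold as well.
    """
    geno_i = geno.impute_mean()
    Gb = blend_identity(g_matrix(geno_i))
    features = geno_i.dosages
    feat_pos = {i: k for k, i in enumerate(geno_i.ids)}
    predictors: dict = {}

    if "ablup" in cfg.models or "ssgblup" in cfg.models:
        from .kinship import a_matrix

        A = a_matrix(ped)
    if "ssgblup" in cfg.models or ("wgblup" in cfg.models and cfg.weights_source == "full"):
        Hinv, _ = make_h_inverse(ped, geno_i)

    def _series(fit):
        return fit.a_hat

    if "ablup" in cfg.models:
        predictors["ablup"] = lambda tr, va: _series(
            ssgblup(pheno, ped, None, trait=cfg.trait, fixed=cfg.fixed, train_ids=tr, A=A)
        )
    if "gblup" in cfg.models:
        predictors["gblup"] = lambda tr, va: _series(gblup(yc, Gb, train_ids=tr))
    if "ssgblup" in cfg.models:
        predictors["ssgblup"] = lambda tr, va: _series(
            ssgblup(
                pheno, ped, geno_i, trait=cfg.trait, fixed=cfg.fixed, train_ids=tr, Hinv=Hinv
            )
        )
    if "wgblup" in cfg.models:
        if cfg.weights_source == "ones":
            # forced uniform weights: reduces exactly to GBLUP
            ones = np.ones(geno_i.n_markers)
            predictors["wgblup"] = lambda tr, va: _series(
                wgblup(yc, geno_i, ones, train_ids=tr)
            )
        elif cfg.weights_source == "full":
            state = iterate_weights(
                pheno, ped, geno_i, n_iter=cfg.wssgwas_iters, trait=cfg.trait, fixed=cfg.fixed
            )
            full_w = state.weights

            predictors["wgblup"] = lambda tr, va: _series(
                wgblup(yc, geno_i, full_w, train_ids=tr)
            )
        else:

            def _wgblup(tr, va):
                state = iterate_weights(
                    pheno,
                    ped,
                    geno_i,
                    n_iter=cfg.wssgwas_iters,
                    trait=cfg.trait,
                    fixed=cfg.fixed,
                    train_ids=tr,
                )
                return _series(wgblup(yc, geno_i, state.weights, train_ids=tr))

            predictors["wgblup"] = _wgblup

    ml_specs = {
        "krr": (krr_fit_predict, KernelSpec(kind="rbf", lam=0.1, gamma=1e-4)),
        "svr": (svr_fit_predict, KernelSpec(kind="rbf", C=1.0, gamma=1e-4)),
        "rf": (rf_fit_predict, RFSpec(seed=cfg.seed)),
    }
    for name in ("krr", "svr", "rf"):
        if name not in cfg.models:
            continue
        fit_predict, spec = ml_specs[name]

        def _ml(tr, va, _fp=fit_predict, _spec=spec, _name=name):
            tr = [i for i in tr if i in feat_pos and i in yc.index]
            Xtr = features[[feat_pos[i] for i in tr]]
            ytr = yc.loc[tr].to_numpy(dtype=float)
            if cfg.tune == "once":
                _spec, _ = grid_search(_name, Xtr, ytr, DEFAULT_GRIDS[_name], seed=cfg.seed)
            Xva = features[[feat_pos[i] for i in va]]
            return pd.Series(_fp(Xtr, ytr, Xva, _spec), index=va)

        predictors[name] = _ml
    return predictors


def run_pipeline(cfg: RunConfig, resume: bool = False) -> CVReport:
    """Execute the full pipeline and write all artifacts to the run dir."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest_path = out / "manifest.json"
    stale = True
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        stale = old.get("config_hash") != chash
        if stale:
            log.info("config hash changed; invalidating previous stages")

    input_dir = out / "inputs"
    if cfg.input_dir is not None:
        geno, ped, pheno = read_dataset(cfg.input_dir)
    elif resume and not stale and (input_dir / "pedigree.csv").exists():
        geno, ped, pheno = read_dataset(input_dir)
        log.info("resumed simulated inputs from %s", input_dir)
    else:
        ped, geno, pheno = _simulate(cfg)
        write_dataset(input_dir, geno, ped, pheno)
    log.info("inputs: %d animals, %d genotyped, %d markers",
             ped.n, geno.n_individuals, geno.n_markers)

    geno_qc, qc_report = qc_filter(geno)
    (out / "qc_report.txt").write_text(qc_report.summary() + "\n")
    log.info("QC: %s", qc_report.summary())

    if cfg.ld_threshold is not None:
        kept = ld_prune(geno_qc, r2_threshold=cfg.ld_threshold)
        geno_qc = geno_qc.subset(markers=kept)
        log.info("LD pruning at r2=%s kept %d markers", cfg.ld_threshold, len(kept))

    covariates: tuple[str, ...] = ()
    if cfg.n_pcs > 0 and cfg.n_pcs < min(geno_qc.n_individuals, geno_qc.n_markers):
        pcs, frac = compute_pcs(geno_qc, cfg.n_pcs)
        pheno = pheno.merge(pcs, on="id", how="left")
        covariates = tuple(f"pc{i + 1}" for i in range(cfg.n_pcs))
        log.info("PCs explain %s of genomic variance", np.round(frac, 4).tolist())

    yc, ablup_fit = ablup_corrected_phenotypes(
        pheno, ped, trait=cfg.trait, fixed=cfg.fixed, covariates=covariates
    )
    yc_geno = yc[yc.index.isin(geno_qc.ids)]
    yc.rename("yc").to_frame().reset_index(names="id").to_csv(
        out / "corrected_phenotypes.tsv", sep="\t", index=False
    )
    log.info(
        "ABLUP variance components: sigma_g2=%.5g sigma_e2=%.5g h2=%.3f",
        ablup_fit.vc.sigma_g2, ablup_fit.vc.sigma_e2, ablup_fit.vc.h2,
    )

    plan = make_folds(list(yc_geno.index), k=cfg.cv_k, repeats=cfg.cv_repeats, seed=cfg.seed)
    predictors = build_predictors(cfg, ped, geno_qc, pheno, yc_geno)
    report = run_cv(predictors, yc_geno, plan)

    report.rounds.assign(trait=cfg.trait).to_csv(out / "cv_rounds.tsv", sep="\t", index=False)
    report.summary.assign(trait=cfg.trait).to_csv(out / "cv_summary.tsv", sep="\t", index=False)
    if report.anova is not None:
        report.anova.to_csv(out / "tukey.tsv", sep="\t", index=False)

    gebv_rows = []
    all_ids = list(yc_geno.index)
    for name, predictor in predictors.items():
        fit_pred = predictor(all_ids, all_ids)
        for iid, val in fit_pred.items():
            gebv_rows.append({"id": iid, "gebv": val, "model": name, "trait": cfg.trait})
    pd.DataFrame(gebv_rows).to_csv(out / "gebv.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": chash,
        "seed": cfg.seed,
        "n_rounds": plan.n_rounds,
        "elapsed_s": round(time.time() - t0, 2),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return report
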