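"""End-to-end pipeline: simulate -> QC -> derive -> build -> stack -> evaluate.

A single :class:`RunConfig` (YAML round-trippable) holds every threshold and
scale parameter; one master seed drives all stochastic stages through
per-operation child seeds. :func:`run_pipeline` executes the three framework
steps plus benchmarks on fully simulated data and writes every intermediate
with a checksum manifest, so a rerun under the same config is bit-identical
and any deleted intermediate is reproduced exactly.

The bundled desk-scale demo (:func:`demo_config`) uses 2,000 variants, a
20-trait score library and a 4,000-individual cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benchmark, evaluation, library_builder, pgs_engine, plink, synthetic_data
from ._rng import child_seed
from .library_builder import LibraryConfig
from .sumstats_io import SdQcThresholds, write_sumstats

__all__ = ["RunConfig", "demo_config", "run_pipeline", "compare_report"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults give the desk-scale profile."""

    seed: int = 0
    out_dir: str = "multipgs_run"
    profile: str = "desk"                      # desk | full sampler scale

    # panel
    m_variants: int = 2000
    block_size: int = 50
    rho: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5

    # architecture: trait 0 is the prediction target
    n_traits: int = 20
    h2: float = 0.5
    rg_target_aux: float = 0.5                 # rg between target and each auxiliary
    rg_aux_aux: float = 0.3
    polygenicity: float = 0.05

    # external GWAS: the target trait's own GWAS is much smaller than the
    # auxiliary GWAS, the regime where multi-PGS stacking pays off
    n_gwas_target: int = 1_000
    n_gwas_aux: int = 80_000

    # cohort
    n_ind: int = 4_000
    prevalence: float = 0.2
    ascertainment: str | None = None
    target_case_proportion: float | None = None
    sex_beta: float = 0.1
    age_beta: float = 0.1
    sex_age_beta: float = 0.0
    n_pcs: int = 10

    # sumstats QC
    min_snps: int = 500                        # desk-scale gate (200,000 at genome scale)
    sd_t_low: float = 0.5
    sd_t_high: float = 1.1
    sd_t_abs: float = 0.05
    sd_t_ref: float = 0.05

    # sampler (desk profile; the full-scale profile is 30 / 800 / 400)
    n_chains: int = 10
    burn_in: int = 200
    n_iter: int = 100

    # stacking / evaluation
    models: tuple = ("lasso", "xgboost")
    xgb_eta: float = 0.01
    xgb_nrounds: int = 10
    k_folds: int = 5
    n_bootstrap: int = 2_000                   # 10,000 at full scale
    inner_folds: int = 10
    simplify_threshold: float = 0.01

    # benchmarks
    m_eff: float | None = None                 # None -> m_variants / mean LD score
    include_wmt: bool = True
    wmt_mode: str = "plugin"                   # plugin (estimated params) | oracle
    include_blup: bool = True
    leave_target_out: bool = True              # refit the stack without trait0's score

    def sampler_settings(self) -> dict:
        if self.profile == "full":
            return dict(pgs_engine.FULL_SCALE)
        return {"n_chains": self.n_chains, "burn_in": self.burn_in,
                "n_iter": self.n_iter}

    def rg_matrix(self) -> np.ndarray:
        T = self.n_traits
        rg = np.full((T, T), self.rg_aux_aux)
        rg[0, :] = rg[:, 0] = self.rg_target_aux
        np.fill_diagonal(rg, 1.0)
        w = np.linalg.eigvalsh(rg)
        if w.min() < 1e-8:                     # project to the PSD cone
            vals, vecs = np.linalg.eigh(rg)
            rg = vecs @ np.diag(np.clip(vals, 1e-6, None)) @ vecs.T
            d = np.sqrt(np.diag(rg))
            rg = rg / np.outer(d, d)
        return rg

    # --- YAML round-trip
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["models"] = list(d["models"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def demo_config(out_dir: str = "multipgs_demo", seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed, out_dir=out_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, skip_existing: bool = False) -> Path:
    """Execute the full framework on simulated data; returns the run directory.

    Writes: panel/ (variant TSV + LD blocks), sumstats/ (canonical TSVs),
    cohort/ (PLINK bed/bim/fam + phenotype/covariate TSV), library/
    (scores + per-score metadata + provenance log), models/ (stack weights),
    report/ (evaluation JSON + comparison TSV) and manifest.json with a
    sha256 checksum per artifact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seed = config.seed
    log: list[dict] = []

    def stage(msg, **kw):
        log.append({"stage": msg, **kw})

    # --- Step 0: simulation -------------------------------------------------
    panel = synthetic_data.simulate_panel(
        config.m_variants, config.block_size, config.rho,
        (config.maf_low, config.maf_high), seed=child_seed(seed, "panel"))
    panel.save(out / "panel")
    stage("panel", m=panel.m, blocks=len(panel.blocks))

    rg = config.rg_matrix()
    arch = synthetic_data.simulate_architecture(
        panel, config.n_traits, config.h2, rg, config.polygenicity,
        seed=child_seed(seed, "architecture"))

    sums_dir = out / "sumstats"
    sums_dir.mkdir(exist_ok=True)
    manifest_rows = []
    n_gwas_all = []
    for t in range(config.n_traits):
        n_gwas = config.n_gwas_target if t == 0 else config.n_gwas_aux
        n_gwas_all.append(n_gwas)
        ss = synthetic_data.simulate_sumstats(
            panel, arch, t, n_gwas, seed=child_seed(seed, f"sumstats:{t}"))
        path = sums_dir / f"trait{t}.tsv"
        write_sumstats(ss, path)
        manifest_rows.append({"tag": f"trait{t}", "path": str(path)})
    manifest = pd.DataFrame(manifest_rows)
    rel = manifest.assign(path=[str(Path(p).relative_to(out))
                                for p in manifest["path"]])
    rel.to_csv(out / "manifest.tsv", sep="\t", index=False)
    stage("sumstats", files=len(manifest))

    cm = synthetic_data.CovariateModel(
        sex_beta=config.sex_beta, age_beta=config.age_beta,
        sex_age_beta=config.sex_age_beta, n_pcs=config.n_pcs)
    cohort = synthetic_data.simulate_cohort(
        panel, arch, config.n_ind, prevalence=config.prevalence,
        ascertainment=config.ascertainment,
        target_case_proportion=config.target_case_proportion,
        covariate_model=cm, seed=child_seed(seed, "cohort"))
    plink.write_plink(out / "cohort" / "cohort", cohort.dosages, panel.variants)
    plink.write_pheno_covar(out / "cohort" / "pheno.tsv", cohort.phenotypes,
                            cohort.covariates)
    stage("cohort", n=cohort.n, case_fraction=cohort.case_proportion.get(0))

    # --- Step 1: build the PGS library -------------------------------------
    lib_cfg = LibraryConfig(
        min_snps=config.min_snps,
        sd_thresholds=SdQcThresholds(config.sd_t_low, config.sd_t_high,
                                     config.sd_t_abs, config.sd_t_ref),
        seed=child_seed(seed, "library"), **config.sampler_settings())
    library = library_builder.build_library(manifest, panel, cohort, lib_cfg)
    library.save(out / "library")
    stage("library", scores=library.n_scores,
          failures=int((library.provenance["status"] != "ok").sum()))

    # --- benchmarks ---------------------------------------------------------
    y = cohort.phenotypes["trait0"].to_numpy()
    cov = cohort.covariates
    extra = {}
    if "trait0" in library.tags:
        extra["single_pgs"] = library.scores["trait0"].to_numpy()
    if config.include_wmt:
        from . import sumstats_io

        ld = pgs_engine.ld_scores(panel)
        m_eff = config.m_eff or panel.m / float(ld.mean())
        T = config.n_traits
        if config.wmt_mode == "oracle":
            h2_vec = arch.h2.copy()
            rg_use = rg
            n_vec = np.array(n_gwas_all, dtype=float)
        else:
            # plug-in estimates from the summary statistics themselves
            ss_list = []
            for row in manifest.itertuples():
                s = sumstats_io.parse_sumstats(row.path, trait_label=row.tag)
                ss_list.append(sumstats_io.harmonize(s, panel))
            h2_vec = np.array([pgs_engine.ldsc_h2(s, ld)[0] for s in ss_list])
            n_vec = np.array([float(np.median(s.table["n_eff"])) for s in ss_list])
            rg_est = np.eye(T)
            for i in range(T):
                for j in range(i + 1, T):
                    rg_est[i, j] = rg_est[j, i] = benchmark.estimate_rg(
                        ss_list[i], ss_list[j], ld, h2_vec[i], h2_vec[j])
            rg_use = benchmark.nearest_correlation(rg_est)
        params = benchmark.GeneticParams(h2=h2_vec, n_gwas=n_vec, rg=rg_use,
                                         m_eff=m_eff)
        w, audit = benchmark.wmt_weights(params, target_trait=0)
        present = [t for t in range(T) if f"trait{t}" in library.tags]
        extra["wmt_index"] = benchmark.wmt_predict(
            library.scores[[f"trait{t}" for t in present]].to_numpy(), w[present])
        (out / "wmt_weights.tsv").write_text(
            "trait_tag\tweight\n" + "\n".join(
                f"trait{t}\t{w[t]:.10g}" for t in range(T)) + "\n")
    fold = evaluation.make_folds(cohort.n, k=config.k_folds,
                                 seed=child_seed(seed, "folds"), y=y)
    if config.include_blup:
        Z = cohort.standardized_dosages().astype(np.float64)
        oof, _ = benchmark.blup_pgs(Z, y, fold, h2_hint=float(arch.h2[0]))
        extra["blup_pgs"] = oof
    stage("benchmarks", extra=list(extra))

    # --- Steps 2-3: stack + evaluate ----------------------------------------
    report = evaluation.cv_evaluate(
        library.raw, cov, y, model_kinds=config.models,
        K_prevalence=config.prevalence, seed=child_seed(seed, "evaluate"),
        k_folds=config.k_folds, B=config.n_bootstrap, extra_scores=extra,
        xgb_params={"eta": config.xgb_eta, "nrounds": config.xgb_nrounds})

    if config.leave_target_out and "trait0" in library.tags and \
            "lasso" in config.models:
        drop = ["trait0"]
        lib_loto = library_builder.exclude_scores(library, drop)
        rep_loto = evaluation.cv_evaluate(
            lib_loto.raw, cov, y, model_kinds=("lasso",),
            K_prevalence=config.prevalence, seed=child_seed(seed, "evaluate"),
            k_folds=config.k_folds, B=config.n_bootstrap)
        report.models["lasso_excl_target"] = rep_loto.models["lasso"]
        report.predictions["lasso_excl_target"] = rep_loto.predictions["lasso"]

    rep_dir = out / "report"
    rep_dir.mkdir(exist_ok=True)
    (rep_dir / "evaluation.json").write_text(
        json.dumps(report.to_json_dict(), indent=1, sort_keys=True))
    report.to_frame().to_csv(rep_dir / "evaluation.tsv", sep="\t", index=False,
                             float_format="%.10g")
    comparison = compare_report(report, baseline="single_pgs"
                                if "single_pgs" in report.models else
                                "covariates_only")
    comparison.to_csv(rep_dir / "comparison.tsv", sep="\t", index=False,
                      float_format="%.10g")
    stage("report", models=list(report.models))

    # lasso weight export mirroring the deposited multi-PGS weight format
    if "lasso" in config.models:
        from .stacking import fit_lasso_stack

        m = fit_lasso_stack(library.scores, cov, y,
                            seed=child_seed(seed, "weights_export"))
        (out / "models").mkdir(exist_ok=True)
        wtab = m.score_weights(library.tags).rename("mean_weight")
        wtab.index.name = "score_tag"
        wtab.reset_index().to_csv(out / "models" / "lasso_weights.tsv",
                                  sep="\t", index=False, float_format="%.10g")

    (out / "stages.json").write_text(json.dumps(log, indent=1))

    checks = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checks[str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(checks, indent=1, sort_keys=True))
    return out


def compare_report(report: evaluation.EvalReport, baseline: str) -> pd.DataFrame:
    """Model x statistic table with fold-change of adjusted R2 vs a baseline."""
    if baseline not in report.models:
        raise KeyError(f"baseline model '{baseline}' not in report")
    base = report.models[baseline]
    rows = []
    for model, st in report.models.items():
        r2 = st.get("r2_adj", np.nan)
        b = base.get("r2_adj", np.nan)
        if b is not None and np.isfinite(b) and b > 0:
            fc, fc_flag = r2 / b, ""
        else:
            fc, fc_flag = np.nan, "undefined_baseline"
        ci_overlap = not (st.get("r2_adj_lo", np.nan) > base.get("r2_adj_hi", np.nan)
                          or st.get("r2_adj_hi", np.nan) < base.get("r2_adj_lo", np.nan))
        rows.append({
            "model": model, "r2_adj": r2,
            "r2_adj_lo": st.get("r2_adj_lo"), "r2_adj_hi": st.get("r2_adj_hi"),
            "r2_liab_adj": st.get("r2_liab_adj"), "auc": st.get("auc"),
            "top_vs_middle_log_or": st.get("top_vs_middle_log_or"),
            "fold_change_vs_baseline": fc, "fold_change_flag": fc_flag,
            "ci_overlaps_baseline": bool(ci_overlap),
        })
    return pd.DataFrame(rows)
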