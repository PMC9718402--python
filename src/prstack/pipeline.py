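"""End-to-end orchestration: QC -> harmonize -> matched design -> grid ->
maxCT/SCT -> testing-set evaluation.

`run_study` drives the whole analysis on in-memory objects; `run_files`
reads the standard file formats, runs the same stages, and writes every
stage artifact (design TSV, weight files, evaluation JSON, log) to an
output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as design_mod
from . import evaluate as eval_mod
from . import grid as grid_mod
from . import io_formats, models, qc

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


@dataclass
class RunConfig:
    """Knobs of one pipeline run; defaults follow the study design
    (5 matched controls per case, 70/30 split, 5:1 unmatched test set)."""

    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    grid_spec: grid_mod.GridSpec = field(default_factory=grid_mod.GridSpec)
    k_max: int = 5
    split: float = 0.70
    test_ratio: int = 5
    method: str = "both"          # maxct | sct | both
    folds: int = 10
    seed: int = 0
    grid_dtype: str = "float32"   # storage dtype of the 30,800-column grid
    keep_grid: bool = False       # retain the PRSGrid on the StudyResult

    def validate(self) -> None:
        if not 0 < self.split < 1:
            raise io_formats.ConfigurationError("split must be in (0, 1)")
        if self.test_ratio < 1:
            raise io_formats.ConfigurationError("test_ratio must be >= 1")
        if self.method not in ("maxct", "sct", "both"):
            raise io_formats.ConfigurationError(f"unknown method {self.method}")
        self.qc_thresholds.validate()


@dataclass
class StudyResult:
    config: RunConfig
    qc_report: dict
    harmonized_counts: dict
    design: design_mod.MatchedDesign
    maxct: models.MaxCTModel | None
    sct: models.StackedModel | None
    reports: dict[str, eval_mod.EvaluationReport]
    variants: pd.DataFrame          # harmonized variant table (aligned betas)
    log: dict
    scores: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    grid: grid_mod.PRSGrid | None = None

    def weight_records(self, which: str) -> list[io_formats.WeightRecord]:
        w = (self.maxct.weights if which == "maxct" else self.sct.weights)
        recs = []
        for j in np.nonzero(w)[0]:
            v = self.variants.iloc[j]
            recs.append(io_formats.WeightRecord(
                rsid=v.rsid, effect_allele=v.a1, weight=float(w[j]),
                chrom=int(v.chrom), pos=int(v.pos),
            ))
        return recs


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def _rows_for(genotypes: io_formats.GenotypeMatrix, ids: list[str]) -> np.ndarray:
    index = {s: i for i, s in enumerate(genotypes.samples)}
    return np.array([index[str(i)] for i in ids], dtype=np.int64)


def run_study(genotypes: io_formats.GenotypeMatrix, cohort: pd.DataFrame,
              sumstats: pd.DataFrame, config: RunConfig | None = None
              ) -> StudyResult:
    """Run QC, harmonization, matched design, the C+T grid, model fitting
    and testing-set evaluation on in-memory inputs."""
    config = config or RunConfig()
    config.validate()
    t0 = time.time()
    log: dict = {"seed": config.seed, "n_samples": genotypes.n_samples,
                 "n_variants_input": genotypes.n_variants}

    kept, qc_report = _stage("qc")(qc.variant_qc)(
        genotypes, config.qc_thresholds
    )
    geno_qc = genotypes.subset_variants(kept)
    log["n_variants_qc"] = int(kept.size)

    panel = _stage("harmonize")(qc.harmonize)(geno_qc.variants, sumstats)
    geno_h = geno_qc.subset_variants(panel.kept_idx)
    betas, pvalues = panel.beta, panel.pvalue
    log["n_variants_harmonized"] = panel.n_matched
    harmonized_counts = panel.counts()

    @_stage("design")
    def _make_design():
        cases, _ = design_mod._eligible(cohort)
        strata = design_mod.age_strata(cases["age"].to_numpy())
        d = design_mod.sample_matched_training(
            cohort, strata, k_max=config.k_max, split=config.split,
            seed=config.seed,
        )
        return design_mod.build_test_set(
            cohort, d, ratio=config.test_ratio, seed=config.seed
        )

    study_design = _make_design()
    log.update(
        k=study_design.k,
        n_train_cases=len(study_design.train_sets),
        n_train=len(study_design.train_ids),
        n_test_cases=len(study_design.test_cases),
        n_test=len(study_design.test_ids),
    )

    # prevalent cases must never reach either split
    prevalent = set(
        cohort.loc[(cohort["status"] == "case")
                   & (cohort["incident"].astype("Int64").fillna(1) == 0), "id"]
        .astype(str)
    )
    touched = set(study_design.train_ids) | set(study_design.test_ids)
    assert not (prevalent & touched), "prevalent case leaked into the design"

    status = cohort.set_index(cohort["id"].astype(str))["status"]
    train_rows = _rows_for(geno_h, study_design.train_ids)
    test_rows = _rows_for(geno_h, study_design.test_ids)
    y_train = (status.loc[study_design.train_ids] == "case").to_numpy()
    y_test = (status.loc[study_design.test_ids] == "case").to_numpy()

    geno_train = geno_h.subset_samples(train_rows)
    prs_grid = _stage("grid")(grid_mod.build_grid)(
        geno_train, betas, pvalues, config.grid_spec,
        dtype=np.dtype(config.grid_dtype),
    )
    log["n_grid_columns"] = prs_grid.n_columns

    dos_train = geno_train.dosages_float()
    dos_test = geno_h.subset_samples(test_rows).dosages_float()

    maxct = sct = None
    reports: dict[str, eval_mod.EvaluationReport] = {}
    scores: dict[str, dict[str, np.ndarray]] = {}

    def _score_and_eval(name: str, weights: np.ndarray, n_snps: int):
        subset = np.nonzero(weights)[0]
        s_train = grid_mod.prs_score(dos_train, weights, subset,
                                     prs_grid.impute_means)
        s_test = grid_mod.prs_score(dos_test, weights, subset,
                                    prs_grid.impute_means)
        scores[name] = {"train": s_train, "test": s_test}
        reports[name] = eval_mod.evaluate_prs(
            s_train, y_train, s_test, y_test, n_snps=n_snps
        )

    if config.method in ("maxct", "both"):
        maxct = _stage("maxct")(models.max_ct)(prs_grid, y_train, betas)
        log["maxct_n_snps"] = maxct.n_snps
        _stage("evaluate")(_score_and_eval)("maxct", maxct.weights,
                                            maxct.n_snps)
    if config.method in ("sct", "both"):
        sct = _stage("sct")(models.sct_stack)(
            prs_grid, y_train, betas, folds=config.folds, seed=config.seed
        )
        log["sct_n_snps"] = sct.n_nonzero_snps
        log["sct_n_columns"] = sct.n_nonzero_columns
        _stage("evaluate")(_score_and_eval)("sct", sct.weights,
                                            sct.n_nonzero_snps)

    log["runtime_s"] = round(time.time() - t0, 2)
    variants = geno_h.variants.copy()
    variants["beta"] = betas
    variants["pvalue"] = pvalues
    return StudyResult(
        config=config, qc_report=qc_report,
        harmonized_counts=harmonized_counts, design=study_design,
        maxct=maxct, sct=sct, reports=reports, variants=variants,
        log=log, scores=scores,
        grid=prs_grid if config.keep_grid else None,
    )


def write_outputs(result: StudyResult, outdir: str | Path) -> None:
    """Write design TSV, per-stratum summary, weight files, evaluation
    JSON and the stage log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.design.to_frame().to_csv(outdir / "design.tsv", sep="\t",
                                    index=False)
    result.design.summary().to_csv(outdir / "design_summary.tsv", sep="\t",
                                   index=False)
    report = {name: r.to_dict() for name, r in result.reports.items()}
    io_formats.write_report(report, outdir / "evaluation.json")
    for name, model in (("maxct", result.maxct), ("sct", result.sct)):
        if model is None:
            continue
        io_formats.write_weights(result.weight_records(name),
                                 outdir / f"weights_{name}.tsv")
    sidecar = {
        "qc": result.qc_report,
        "harmonized": result.harmonized_counts,
        "log": result.log,
    }
    if result.maxct is not None:
        sidecar["maxct"] = {
            "r2": result.maxct.r2, "base_kb": result.maxct.base_kb,
            "p_threshold": result.maxct.p_threshold,
            "training_auc": result.maxct.training_auc,
            "n_snps": result.maxct.n_snps,
        }
    if result.sct is not None:
        sidecar["sct"] = {
            "lambda": result.sct.lambda_,
            "n_nonzero_columns": result.sct.n_nonzero_columns,
            "n_nonzero_snps": result.sct.n_nonzero_snps,
            "cv_trace": result.sct.cv_trace.to_dict(orient="list"),
        }
    io_formats.write_report(sidecar, outdir / "run_log.json")


def run_files(genotype_prefix: str | Path, phenotype_path: str | Path,
              sumstats_path: str | Path, outdir: str | Path,
              config: RunConfig | None = None,
              column_map: dict | None = None) -> StudyResult:
    """File-based front end: read PLINK + phenotype TSV + sumstats TSV,
    run the study, write all artifacts. On stage failure a FAILED marker
    naming the stage is left in the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        genotypes = io_formats.read_plink(genotype_prefix)
        cohort = pd.read_csv(phenotype_path, sep="\t",
                             dtype={"id": str, "incident": "Int64"})
        sumstats, skip_log = io_formats.read_sumstats(sumstats_path,
                                                      column_map)
        logger.info("sumstats skip log: %s", skip_log)
        result = run_study(genotypes, cohort, sumstats, config)
    except Exception as exc:
        stage = exc.stage if isinstance(exc, PipelineError) else "input"
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise
    write_outputs(result, outdir)
    return result
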