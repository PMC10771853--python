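"""End-to-end analysis pipeline: configuration, stages, run report.

Stages run in a fixed order on shared intermediate artifacts written under
the configured output directory:

    simulate -> validate -> preprocess -> deconvolve -> label -> dm
             -> genescan -> classify

Each stage records elapsed time, input/output row counts and a SHA-256
checksum for every file it writes; the whole run is reproducible
byte-for-byte from the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import deconvolution, diffmeth, geneagg, io, labels, preprocess, stability, synthetic
from .errors import PipelineStageError, ValidationError

STAGE_ORDER = (
    "simulate",
    "validate",
    "preprocess",
    "deconvolve",
    "label",
    "dm",
    "genescan",
    "classify",
)


@dataclass
class PipelineConfig:
    """Declarative configuration of a pipeline run.

    Either point the four input paths at existing files or enable the
    ``simulate`` stage to generate a synthetic cohort in place.  The global
    seed propagates deterministically to every stochastic stage.
    """

    outdir: str = "epiresponse_run"
    beta_matrix: str | None = None
    sample_sheet: str | None = None
    manifest: str | None = None
    references: str | None = None
    gene_table: str | None = None
    stages: tuple = STAGE_ORDER
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    boost: stability.BoostConfig = field(default_factory=stability.BoostConfig)
    n_reference_probes: int = 60
    n_discriminating_per_type: int = 10
    gap_threshold: float = preprocess.DEFAULT_GAP_THRESHOLD
    min_group_fraction: float = preprocess.DEFAULT_MIN_GROUP_FRACTION
    drop_gapped_probes: bool = False
    m_offset: float = 1e-6
    covariates: tuple = diffmeth.DEFAULT_COVARIATES
    scan_genes: tuple | None = None
    loess_span: float = 0.75
    seed: int = 0

    def __post_init__(self):
        self.generator.seed = synthetic_seed = stability._child_seed(self.seed, 10)
        self.boost.seed = stability._child_seed(self.seed, 11)
        del synthetic_seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = synthetic.GeneratorConfig(**raw.pop("generator", {}))
        boost = stability.BoostConfig(**raw.pop("boost", {}))
        cfg = cls(**raw)
        cfg.generator = gen
        cfg.boost = boost
        cfg.__post_init__()
        return cfg

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        raw = plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(
    beta: pd.DataFrame, sheet: pd.DataFrame, manifest: pd.DataFrame
) -> list[str]:
    """Cross-check matrix/sheet/manifest alignment; returns every violation."""
    violations: list[str] = []
    try:
        io.validate_beta_matrix(beta)
    except Exception as exc:  # collect instead of raising
        violations.append(str(exc))
    missing_sheet = beta.columns.difference(sheet.index)
    if len(missing_sheet):
        violations.append(f"samples in matrix but not in sheet: {missing_sheet.tolist()[:10]}")
    extra_sheet = sheet.index.difference(beta.columns)
    if len(extra_sheet):
        violations.append(f"samples in sheet but not in matrix: {extra_sheet.tolist()[:10]}")
    missing_manifest = beta.index.difference(manifest.index)
    if len(missing_manifest):
        violations.append(
            f"probes in matrix but not in manifest: {missing_manifest.tolist()[:10]}"
        )
    if "response" not in sheet.columns:
        violations.append("sample sheet has no 'response' column")
    else:
        unlabeled = sheet.index[sheet["response"].isna()]
        if len(unlabeled):
            violations.append(f"unlabeled samples: {unlabeled.tolist()[:10]}")
    for col in ("das28_baseline", "das28_followup"):
        if col not in sheet.columns:
            violations.append(f"sample sheet missing column {col!r}")
    return violations


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.beta: pd.DataFrame | None = None
        self.sheet: pd.DataFrame | None = None
        self.manifest: pd.DataFrame | None = None
        self.references: pd.DataFrame | None = None
        self.gene_table: pd.DataFrame | None = None
        self.m_values: pd.DataFrame | None = None
        self.dm: pd.DataFrame | None = None
        self.report: dict = {"seed": config.seed, "stages": [], "checksums": {}}

    def path(self, name: str) -> str:
        return os.path.join(self.config.outdir, name)

    def record(self, stage: str, elapsed: float, n_in: int, n_out: int, outputs: dict):
        self.report["stages"].append(
            {
                "stage": stage,
                "elapsed_s": round(elapsed, 3),
                "rows_in": n_in,
                "rows_out": n_out,
                "outputs": outputs,
            }
        )
        self.report["checksums"].update(outputs)


def _load_inputs(run: PipelineRun) -> None:
    cfg = run.config
    if run.beta is None:
        if cfg.beta_matrix is None:
            raise ValidationError("no beta matrix: provide a path or enable the simulate stage")
        run.beta = io.read_beta_matrix(cfg.beta_matrix)
        run.sheet = io.read_sample_sheet(cfg.sample_sheet)
        run.manifest = io.read_manifest(cfg.manifest)
        if cfg.references:
            run.references = io.read_reference_profiles(cfg.references)
        if cfg.gene_table:
            run.gene_table = io.read_gene_table(cfg.gene_table)


def _stage_simulate(run: PipelineRun) -> tuple[int, int, dict]:
    cfg = run.config
    refs = synthetic.generate_reference_profiles(
        cfg.n_reference_probes,
        cfg.n_discriminating_per_type,
        seed=stability._child_seed(cfg.seed, 12),
    )
    beta, sheet, manifest, truth = synthetic.generate_cohort(cfg.generator, refs)
    run.beta, run.sheet, run.manifest, run.references = beta, sheet, manifest, refs
    run.gene_table = synthetic.gene_table_from_manifest(manifest)
    paths = synthetic.write_cohort(cfg.outdir, beta, sheet, manifest, truth)
    refs_path = run.path("references.tsv")
    io.write_reference_profiles(refs, refs_path)
    genes_path = run.path("gene_table.tsv")
    io.write_gene_table(run.gene_table, genes_path)
    outputs = {p: _sha256(p) for p in [*paths.values(), refs_path, genes_path]}
    return 0, beta.shape[0], outputs


def _stage_validate(run: PipelineRun) -> tuple[int, int, dict]:
    _load_inputs(run)
    violations = validate_inputs(run.beta, run.sheet, run.manifest)
    path = run.path("validation_report.json")
    with open(path, "w") as fh:
        json.dump({"violations": violations}, fh, indent=1)
    if violations:
        raise ValidationError("input validation failed: " + "; ".join(violations))
    return run.beta.shape[0], run.beta.shape[0], {path: _sha256(path)}


def _stage_preprocess(run: PipelineRun) -> tuple[int, int, dict]:
    cfg = run.config
    _load_inputs(run)
    n_in = run.beta.shape[0]
    run.beta = preprocess.filter_allosomes(run.beta, run.manifest)
    gaps = preprocess.gap_hunt_matrix(run.beta, cfg.gap_threshold, cfg.min_group_fraction)
    if cfg.drop_gapped_probes:
        run.beta = run.beta.loc[~gaps.loc[run.beta.index, "flagged"]]
    run.m_values = preprocess.beta_to_m(run.beta, offset=cfg.m_offset)
    gap_path = run.path("gap_report.tsv")
    gaps.to_csv(gap_path, sep="\t")
    m_path = run.path("m_values.tsv")
    io.write_matrix(run.m_values, m_path)
    return n_in, run.beta.shape[0], {gap_path: _sha256(gap_path), m_path: _sha256(m_path)}


def _stage_deconvolve(run: PipelineRun) -> tuple[int, int, dict]:
    if run.references is None:
        raise ValidationError("deconvolution needs reference profiles")
    shared = run.beta.index.intersection(run.references.index)
    props = deconvolution.estimate_proportions(
        run.beta.loc[shared], run.references.loc[shared]
    )
    anova = deconvolution.compare_proportions(props, run.sheet["response"])
    props_path = run.path("cell_proportions.csv")
    combined = pd.concat(
        {"raw": props.raw, "normalized": props.normalized}, axis=1
    )
    combined.to_csv(props_path, index_label="sample_id")
    anova_path = run.path("anova_cell_proportions.csv")
    anova.table.to_csv(anova_path)
    return len(shared), props.normalized.shape[0], {
        props_path: _sha256(props_path),
        anova_path: _sha256(anova_path),
    }


def _stage_label(run: PipelineRun) -> tuple[int, int, dict]:
    calls = labels.label_samples(run.sheet)
    run.sheet = run.sheet.copy()
    if "response" not in run.sheet.columns:
        run.sheet["response"] = calls
    run.sheet["response_recomputed"] = calls
    spec = {
        "age": labels.CONTINUOUS_NORMAL,
        "sex": labels.CATEGORICAL,
        "smoking": labels.CATEGORICAL,
        "mtx": labels.CATEGORICAL,
        "das28_baseline": labels.CONTINUOUS_NORMAL,
    }
    spec = {k: v for k, v in spec.items() if k in run.sheet.columns}
    table = labels.cohort_table(run.sheet, spec)
    calls_path = run.path("response_calls.csv")
    run.sheet[["das28_baseline", "das28_followup", "response", "response_recomputed"]].to_csv(
        calls_path, index_label="sample_id"
    )
    table_path = run.path("cohort_characteristics.csv")
    table.to_csv(table_path, index=False)
    return len(run.sheet), len(run.sheet), {
        calls_path: _sha256(calls_path),
        table_path: _sha256(table_path),
    }


def _stage_dm(run: PipelineRun) -> tuple[int, int, dict]:
    cfg = run.config
    if run.m_values is None:
        raise ValidationError("run the preprocess stage before dm")
    design = diffmeth.build_design(run.sheet.loc[run.m_values.columns], cfg.covariates)
    run.dm = diffmeth.fit_dm(run.m_values, design, run.beta)
    unadj = diffmeth.fit_dm(run.m_values, diffmeth.build_design(run.sheet.loc[run.m_values.columns]))
    path = run.path("differential_methylation.tsv")
    diffmeth.export_results(run.dm, run.manifest, path, adjusted=None)
    full = run.dm.copy()
    full["p_value_unadjusted"] = unadj["p_value"]
    full_path = run.path("dm_full.tsv")
    full.to_csv(full_path, sep="\t", index_label="probe_id")
    return run.m_values.shape[0], len(run.dm), {
        path: _sha256(path),
        full_path: _sha256(full_path),
    }


def _stage_genescan(run: PipelineRun) -> tuple[int, int, dict]:
    cfg = run.config
    if run.dm is None:
        raise ValidationError("run the dm stage before genescan")
    manifest = run.manifest
    if run.gene_table is not None:
        manifest = geneagg.annotate_probes(manifest, run.gene_table)
    genes = cfg.scan_genes
    if genes is None:
        genes = [g for g in pd.unique(manifest["gene"].dropna())][:20]
    scan = geneagg.gene_level_scan(run.dm, manifest, run.m_values, genes)
    scan_path = run.path("gene_scan.tsv")
    scan.to_csv(scan_path, sep="\t")
    outputs = {scan_path: _sha256(scan_path)}
    profiles = []
    for gene in genes[:5]:
        probes = manifest.index[manifest["gene"] == gene].intersection(run.dm.index)
        if len(probes) < 3:
            continue
        prof = geneagg.regional_profile(gene, run.dm, manifest, span=cfg.loess_span)
        profiles.append(
            pd.DataFrame(
                {"gene": gene, "pos": prof.grid, "fit": prof.fit, "se": prof.se}
            )
        )
    if profiles:
        prof_path = run.path("regional_profiles.tsv")
        pd.concat(profiles).to_csv(prof_path, sep="\t", index=False)
        outputs[prof_path] = _sha256(prof_path)
    return len(genes), len(scan), outputs


def _stage_classify(run: PipelineRun) -> tuple[int, int, dict]:
    cfg = run.config
    if run.m_values is None:
        raise ValidationError("run the preprocess stage before classify")
    X = run.m_values.T  # samples x probes
    y = run.sheet.loc[X.index, "response"]
    X_tr, y_tr, X_te, y_te = stability.split_train_test(
        X, y, cfg.boost.train_fraction, seed=stability._child_seed(cfg.seed, 13)
    )
    result = stability.run_stability_selection(X_tr, y_tr, cfg.boost)
    panel = stability.aggregate_pairwise(result, cfg.boost)
    model = stability.train_final(X_tr, y_tr, panel, cfg.boost)
    perf = stability.evaluate(model, X_te, y_te, result, cfg.boost.cv_folds)
    panel_path = run.path("panel.tsv")
    panel.table.sort_values(
        ["member", "copeland", "mean_importance"], ascending=[False, False, False]
    ).to_csv(panel_path, sep="\t")
    perf_path = run.path("performance.json")
    with open(perf_path, "w") as fh:
        json.dump(
            {
                "test_auroc": None if np.isnan(perf.test_auroc) else perf.test_auroc,
                "mean_cv_auroc": None if np.isnan(perf.mean_cv_auroc) else perf.mean_cv_auroc,
                "cv_auc_per_repetition": [
                    float(v)
                    for v in (
                        perf.cv_auc_per_repetition
                        if perf.cv_auc_per_repetition is not None
                        else []
                    )
                ],
                "panel_size": len(panel),
                "n_train": len(y_tr),
                "n_test": len(y_te),
                "note": perf.note,
                "roc": perf.roc.to_dict(orient="list") if perf.roc is not None else None,
            },
            fh,
            indent=1,
        )
    return X_tr.shape[0] + X_te.shape[0], len(panel), {
        panel_path: _sha256(panel_path),
        perf_path: _sha256(perf_path),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "validate": _stage_validate,
    "preprocess": _stage_preprocess,
    "deconvolve": _stage_deconvolve,
    "label": _stage_label,
    "dm": _stage_dm,
    "genescan": _stage_genescan,
    "classify": _stage_classify,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the machine-readable report."""
    os.makedirs(config.outdir, exist_ok=True)
    run = PipelineRun(config)
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    for stage in enabled:
        t0 = time.perf_counter()
        try:
            n_in, n_out, outputs = _STAGE_FUNCS[stage](run)
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc
        run.record(stage, time.perf_counter() - t0, n_in, n_out, outputs)
    report_path = run.path("run_report.json")
    with open(report_path, "w") as fh:
        json.dump(run.report, fh, indent=1)
    return run.report


def verify_report(outdir: str) -> list[str]:
    """Re-hash every artifact in the run report; returns mismatching paths."""
    report_path = os.path.join(outdir, "run_report.json")
    with open(report_path) as fh:
        report = json.load(fh)
    mismatches = []
    for path, digest in report["checksums"].items():
        if not os.path.exists(path) or _sha256(path) != digest:
            mismatches.append(path)
    return mismatches
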