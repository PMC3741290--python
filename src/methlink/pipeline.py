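"""Configuration-driven orchestration of the full analysis.

Stages: QC -> within-array loess -> between-array quantile normalization ->
per-probe moderated-t inference -> unmethylated calls and DMR filtering ->
probe-to-feature mapping -> expression preprocessing and DE -> integration and
report.  In synthetic mode the inputs are generated with planted truth and the
report includes a planted-vs-recovered evaluation.  Every run writes a
manifest (config, seed, versions, output checksums) so a run can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import ProbeAnnotation, map_probes, read_annotation
from .expression import (
    combine_de,
    differential_expression,
    median_polish_summarize,
    pca_outlier_detect,
)
from .integrate import (
    IntegratedTranscript,
    SummaryReport,
    detect_dual_direction,
    join_platforms,
    summarize,
)
from .io import (
    read_arrays,
    write_annotation,
    write_arrays,
    write_dmr_bed,
    write_expression,
    write_json,
    write_truth,
)
from .methylation import (
    DmrSet,
    MaValues,
    QcReport,
    TwoColorArray,
    call_unmethylated,
    compute_ma,
    filter_dmrs,
    fit_probe_models,
    moderate_statistics,
    normalize_within_control_loess,
    quantile_normalize,
)
from .simulate import (
    ConfigError,
    ExpressionSets,
    SyntheticConfig,
    TruthTable,
    generate_annotation,
    generate_expression,
    generate_methylation_arrays,
)

log = logging.getLogger("methlink")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_methylation_stage",
           "run_expression_stage", "evaluate_dmr_recovery"]


@dataclass
class PipelineConfig:
    """All thresholds, options and input locations for one run."""

    # inputs: either synthetic study conditions, or file paths
    synthetic: SyntheticConfig | None = None
    meth_sample_sheet: str | None = None
    transcripts_path: str | None = None
    cpg_path: str | None = None
    expression_dir: str | None = None
    # thresholds (the printed cutoffs of the analysis)
    fdr: float = 0.05
    meth_min_lfc: float = 0.5
    meth_max_lfc: float = 0.5
    group_diff: float = 0.3
    expr_min_fc: float = 1.25
    # normalization / QC options
    loess_span: float = 0.3
    min_controls: int = 50
    min_iqr_ratio: float = 0.5
    quantile_on: str = "M"  # "M" or "channels"
    pca_k_mad: float = 3.0
    pca_exclude: bool = False  # opt-in: drop the top flagged sample per set
    combine_mode: str = "intersection"
    seed: int = 1
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr < 1.0):
            raise ConfigError("fdr must lie in (0, 1)")
        for name in ("meth_min_lfc", "meth_max_lfc", "group_diff", "expr_min_fc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.quantile_on not in ("M", "channels"):
            raise ConfigError("quantile_on must be 'M' or 'channels'")
        if self.synthetic is None:
            missing = [
                n for n in ("meth_sample_sheet", "transcripts_path", "cpg_path")
                if getattr(self, n) is None
            ]
            if missing:
                raise ConfigError(f"real-data mode requires paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            if "master_seed" not in syn and "seed" in raw:
                syn["master_seed"] = raw["seed"]
            if "n_expr_replicates_per_group" in syn:
                syn["n_expr_replicates_per_group"] = tuple(
                    syn["n_expr_replicates_per_group"]
                )
            if "qc_fail_arrays" in syn:
                syn["qc_fail_arrays"] = tuple(syn["qc_fail_arrays"])
            syn = SyntheticConfig(**syn)
        return cls(synthetic=syn, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    qc_report: QcReport
    probe_results: pd.DataFrame
    calls: dict[str, set[str]]
    dmr_hyper: DmrSet
    dmr_hypo: DmrSet
    probe_annotation: ProbeAnnotation
    de: pd.DataFrame
    de_per_set: dict[str, pd.DataFrame]
    pca_outliers: dict[str, list[str]]
    records: list[IntegratedTranscript]
    report: SummaryReport
    truth: TruthTable | None = None
    evaluation: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _quantile_on_channels(arrays: list[TwoColorArray], floor: float = 1.0) -> MaValues:
    """Alternative between-array normalization on the individual log2 channels."""
    ma = compute_ma(arrays, floor=floor)
    lt = {a.array_id: np.log2(np.maximum(a.treated, floor)) for a in arrays}
    lu = {a.array_id: np.log2(np.maximum(a.untreated, floor)) for a in arrays}
    both = pd.concat(
        [pd.DataFrame(lt, index=ma.M.index), pd.DataFrame(lu, index=ma.M.index)],
        axis=1, keys=["t", "u"],
    )
    qt = quantile_normalize(pd.DataFrame(lt, index=ma.M.index))
    qu = quantile_normalize(pd.DataFrame(lu, index=ma.M.index))
    del both
    return MaValues(M=qu - qt, A=(qu + qt) / 2.0, groups=ma.groups,
                    is_control=ma.is_control)


def run_methylation_stage(
    arrays: list[TwoColorArray], cfg: PipelineConfig
) -> tuple[pd.DataFrame, dict[str, set[str]], DmrSet, DmrSet, QcReport]:
    """Arrays -> probe results, unmethylated calls, DMR pair, QC report."""
    ma = compute_ma(arrays)
    ma, qc = qc_exclude_low_iqr_logged(ma, cfg.min_iqr_ratio)
    ma = normalize_within_control_loess(
        ma, span=cfg.loess_span, min_controls=cfg.min_controls
    )
    if cfg.quantile_on == "M":
        M = quantile_normalize(ma.M)
    else:
        kept = list(ma.M.columns)
        ma2 = _quantile_on_channels([a for a in arrays if a.array_id in kept])
        ma2 = normalize_within_control_loess(
            ma2, span=cfg.loess_span, min_controls=cfg.min_controls
        )
        M = ma2.M
    # control probes anchor normalization but are excluded from inference
    M_exp = M.loc[~ma.is_control]
    fit = fit_probe_models(M_exp, ma.groups)
    results, prior = moderate_statistics(fit)
    log.info("methylation: %d probes, prior d0=%.3g s0_sq=%.3g",
             len(M_exp), prior.d0, prior.s0_sq)
    calls = call_unmethylated(results, fdr=cfg.fdr, min_lfc=cfg.meth_min_lfc)
    dmr_hyper, dmr_hypo = filter_dmrs(
        calls, results, max_meth_lfc=cfg.meth_max_lfc, min_group_diff=cfg.group_diff
    )
    return results, calls, dmr_hyper, dmr_hypo, qc


def qc_exclude_low_iqr_logged(ma: MaValues, min_iqr_ratio: float):
    from .methylation import qc_exclude_low_iqr

    kept, qc = qc_exclude_low_iqr(ma, min_iqr_ratio)
    for row in qc.table.itertuples(index=False):
        if row.excluded:
            log.info("QC: excluding array %s (IQR %.3f < %.3f)", row.array_id,
                     row.iqr, qc.threshold)
    return kept, qc


def run_expression_stage(
    sets: ExpressionSets, cfg: PipelineConfig
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, list[str]]]:
    """Probe-level matrices -> combined DE table (stimulated comparison)."""
    de_per_set = {}
    outliers = {}
    for ds, mat in (("set1", sets.set1), ("set2", sets.set2)):
        sub_samples = sets.samples[sets.samples["dataset"] == ds]
        logm = np.log2(np.maximum(mat, 1.0))
        groups_all = sub_samples.set_index("sample_id")["group"]
        flagged = pca_outlier_detect(logm, groups_all, k_mad=cfg.pca_k_mad)
        outliers[ds] = flagged
        drop = set(flagged[:1]) if (cfg.pca_exclude and flagged) else set()
        if drop:
            log.info("expression %s: excluding PCA outlier %s", ds, sorted(drop))
        keep_cols = [c for c in logm.columns if c not in drop]
        logm = logm[keep_cols]
        qn = quantile_normalize(logm)
        expr = median_polish_summarize(qn, sets.probeset_map)
        stim = sub_samples[
            (sub_samples["condition"] == "stim")
            & (sub_samples["sample_id"].isin(keep_cols))
        ]
        de = differential_expression(
            expr[list(stim["sample_id"])],
            stim.set_index("sample_id")["group"],
            fdr=cfg.fdr,
            min_fc=cfg.expr_min_fc,
        )
        de_per_set[ds] = de
        log.info("expression %s: %d transcripts, %d pass", ds, len(de),
                 int(de["passes"].sum()))
    de = combine_de(de_per_set["set1"], de_per_set["set2"], mode=cfg.combine_mode)
    return de, de_per_set, outliers


def evaluate_dmr_recovery(
    dmr_hyper: DmrSet, dmr_hypo: DmrSet, truth: TruthTable
) -> dict[str, float]:
    """Sensitivity and observed false-discovery proportion against planted truth."""
    t = truth.probes
    true_hyper = set(t.loc[t["dmr_direction"] == dmr_hyper.direction, "probe_id"])
    true_hypo = set(t.loc[t["dmr_direction"] == dmr_hypo.direction, "probe_id"])
    called_hyper = set(dmr_hyper.probe_ids)
    called_hypo = set(dmr_hypo.probe_ids)
    tp = len(called_hyper & true_hyper) + len(called_hypo & true_hypo)
    n_called = len(called_hyper) + len(called_hypo)
    n_true = len(true_hyper) + len(true_hypo)
    return {
        "n_true_dmr_probes": n_true,
        "n_called_dmr_probes": n_called,
        "sensitivity": tp / n_true if n_true else float("nan"),
        "fdp": (n_called - tp) / n_called if n_called else 0.0,
    }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage; write tables, report and manifest when outdir is set."""
    outdir = config.outdir
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    truth = None
    if config.synthetic is not None:
        syn = config.synthetic
        annotation = generate_annotation(syn)
        arrays, truth = generate_methylation_arrays(syn, annotation)
        expr_sets, truth = generate_expression(syn, annotation, truth)
        probe_coords = truth.probe_intervals
        if outdir:
            write_annotation(annotation, os.path.join(outdir, "transcripts.gtf"),
                             os.path.join(outdir, "cpg_islands.bed"))
            write_truth(truth, outdir)
    else:
        annotation = read_annotation(config.transcripts_path, config.cpg_path)
        arrays, probe_coords = read_arrays(config.meth_sample_sheet)
        if probe_coords is None:
            raise ConfigError("array files carry no probe coordinates "
                              "(chrom/start/end columns required for mapping)")
        if config.expression_dir is None:
            raise ConfigError("real-data mode requires expression_dir")
        from .io import read_expression

        expr_sets = read_expression(config.expression_dir)

    results, calls, dmr_hyper, dmr_hypo, qc = run_methylation_stage(arrays, config)
    log.info("methylation calls: normal_only=%d asthma_only=%d both=%d; "
             "DMRs hyper=%d hypo=%d",
             len(calls["normal_only"]), len(calls["asthma_only"]), len(calls["both"]),
             len(dmr_hyper.table), len(dmr_hypo.table))

    exp_coords = probe_coords[
        probe_coords["probe_id"].isin(results["probe_id"].unique())
    ]
    probe_annotation = map_probes(exp_coords, annotation)

    de, de_per_set, outliers = run_expression_stage(expr_sets, config)

    records = join_platforms(
        (dmr_hyper, dmr_hypo), probe_annotation.table, probe_coords, de
    )
    n_exp_probes = results["probe_id"].nunique()
    report = summarize(
        records,
        n_meth_platform=probe_annotation.table["transcript_id"].nunique(),
        n_expr_platform=len(de),
        probe_counts={
            "unmeth_normal_only": len(calls["normal_only"]),
            "unmeth_asthma_only": len(calls["asthma_only"]),
            "unmeth_both": len(calls["both"]),
        },
        total_probes=n_exp_probes,
    )
    evaluation = {}
    if truth is not None:
        evaluation = evaluate_dmr_recovery(dmr_hyper, dmr_hypo, truth)

    result = PipelineResult(
        qc_report=qc,
        probe_results=results,
        calls=calls,
        dmr_hyper=dmr_hyper,
        dmr_hypo=dmr_hypo,
        probe_annotation=probe_annotation,
        de=de,
        de_per_set=de_per_set,
        pca_outliers=outliers,
        records=records,
        report=report,
        truth=truth,
        evaluation=evaluation,
    )
    if outdir:
        _write_outputs(result, probe_coords, config, outdir)
    return result


def _integrated_table(records: list[IntegratedTranscript]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "de_passes": r.de_passes,
                "de_log2fc": r.de["log2fc"] if r.de is not None else np.nan,
                "de_direction": r.de["direction"] if r.de is not None else "n/a",
                "n_dmr_probes": len(r.dmrs),
                "dual_direction": r.dual_direction,
                "concordance": r.concordance,
                "influential_probe": r.influential or "",
                "context_class": r.context_class or "",
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, probe_coords: pd.DataFrame,
                   config: PipelineConfig, outdir: str) -> None:
    paths = {}

    def save(name, writer):
        path = os.path.join(outdir, name)
        writer(path)
        paths[name] = path

    save("qc_report.tsv",
         lambda p: result.qc_report.table.to_csv(p, sep="\t", index=False,
                                                 float_format="%.6f"))
    save("probe_results.tsv",
         lambda p: result.probe_results.to_csv(p, sep="\t", index=False,
                                               float_format="%.6g"))
    for dmr, tag in ((result.dmr_hyper, "hyper_in_asthma"),
                     (result.dmr_hypo, "hypo_in_asthma")):
        save(f"dmr_{tag}.bed",
             lambda p, d=dmr: write_dmr_bed(
                 d, probe_coords, p, p.replace(".bed", ".tsv")))
        paths[f"dmr_{tag}.tsv"] = os.path.join(outdir, f"dmr_{tag}.tsv")
    save("probe_annotation.tsv",
         lambda p: result.probe_annotation.table.to_csv(p, sep="\t", index=False))
    save("de.tsv", lambda p: result.de.to_csv(p, sep="\t", float_format="%.6g"))
    save("integrated.tsv",
         lambda p: _integrated_table(result.records).to_csv(p, sep="\t", index=False,
                                                            float_format="%.6g"))
    save("dual_direction.tsv",
         lambda p: detect_dual_direction(result.records).to_csv(
             p, sep="\t", index=False, float_format="%.6g"))
    save("summary.json", lambda p: write_json(result.report.to_dict(), p))
    save("summary.txt",
         lambda p: open(p, "w").write(result.report.to_text() + "\n"))
    if result.evaluation:
        save("evaluation.json", lambda p: write_json(result.evaluation, p))

    cfg_dict = config.to_dict()
    cfg_dict.pop("outdir", None)  # content-identical runs share a manifest
    manifest = {
        "package": "methlink",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "outputs": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    result.manifest = manifest
    write_json(manifest, os.path.join(outdir, "manifest.json"))


def write_synthetic_inputs(syn: SyntheticConfig, outdir: str) -> None:
    """Materialize a synthetic study as on-disk inputs (simulate subcommand)."""
    os.makedirs(outdir, exist_ok=True)
    annotation = generate_annotation(syn)
    arrays, truth = generate_methylation_arrays(syn, annotation)
    expr_sets, truth = generate_expression(syn, annotation, truth)
    write_annotation(annotation, os.path.join(outdir, "transcripts.gtf"),
                     os.path.join(outdir, "cpg_islands.bed"))
    write_arrays(arrays, truth.probe_intervals, os.path.join(outdir, "arrays"))
    write_expression(expr_sets, os.path.join(outdir, "expression"))
    write_truth(truth, outdir)
    with open(os.path.join(outdir, "synthetic_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(syn), fh, indent=2, sort_keys=True)
        fh.write("\n")
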