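"""End-to-end pipeline orchestration.

Stages communicate only through files under the configured output
directory, so each stage is independently runnable and resumable; every
stage writes a JSON provenance record (input hashes, parameters, package
version) and the run ends with a manifest of all outputs.  Reruns with the
same config and seed are bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigError, get
from .containers import Scale
from .dea import CONTRAST_GROUPS, run_dea
from .io import (
    read_dsp_bundle,
    read_gmt,
    read_macrosig,
    write_dsp_bundle,
    write_expression_table,
    write_frame,
    write_gmt,
    write_macrosig,
)
from .mask_validation import validate_masks
from .preprocess import QCThresholds, run_preprocess
from .scoring import signature_score, tertile_stratify
from .signatures import derive_all_macrosigs, percentile_ranks
from .simulate import SimParams, make_pathway_sets, simulate_cohort, simulate_dsp_experiment
from .survival import compare_extreme_tertiles
from .association import associate, geneset_enrichment

logger = logging.getLogger("dspsig")

STAGE_ORDER = [
    "simulate",
    "preprocess",
    "validate-masks",
    "dea",
    "derive-sig",
    "score",
    "survive",
    "associate",
    "enrich",
]

SIG_PAIRS = {
    "GC_vs_IF": ("MacroSig1_GC", "MacroSig2_IF"),
    "LZ_vs_DZ": ("MacroSig3_LZ", "MacroSig4_DZ"),
    "RLT_vs_DLBCL": ("MacroSig5_RLT", "MacroSig6_DLBCL"),
}


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _rel(path, outdir: Path) -> str:
    path = Path(path)
    try:
        return str(path.relative_to(outdir))
    except ValueError:
        return str(path)


def _provenance(outdir: Path, stage: str, inputs: list, params: dict) -> None:
    record = {
        "stage": stage,
        "version": __version__,
        "inputs": {_rel(p, outdir): _hash_file(p) for p in inputs if Path(p).exists()},
        "params": params,
    }
    (outdir / f"provenance_{stage.replace('-', '_')}.json").write_text(
        json.dumps(record, indent=1, sort_keys=True, default=str)
    )


def sim_params_from_config(config: dict, seed: int | None = None) -> SimParams:
    sim = get(config, "simulate")
    from .simulate import default_aoi_design

    return SimParams(
        n_genes=sim["n_genes"],
        n_neg_probes=sim["n_neg_probes"],
        aoi_design=default_aoi_design(sim["aois_per_stratum"]),
        n_patients=sim["n_patients"],
        frac_planted=sim["frac_planted"],
        frac_contaminant=sim["frac_contaminant"],
        lfc_magnitude=sim["lfc_magnitude"],
        nb_dispersion=sim["nb_dispersion"],
        size_factor_sd=sim["size_factor_sd"],
        batch_sd=sim["batch_sd"],
        n_batches=sim["n_batches"],
        censor_frac=sim["censor_frac"],
        hazard_coef=sim["hazard_coef"],
        duplicate_core_frac=sim["duplicate_core_frac"],
        label_assoc=sim["label_assoc"],
        seed=get(config, "seed") if seed is None else seed,
    )


def run_pipeline(config: dict, dry_run: bool = False) -> dict:
    """Execute the enabled stages in fixed order; returns the manifest.

    Any failure aborts with an error naming the stage.  ``dry_run``
    validates configuration and stage inputs without computing.
    """
    outdir = Path(get(config, "pipeline.outdir"))
    stages = list(get(config, "pipeline.stages"))
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ConfigError(f"unknown pipeline stages {unknown}")
    stages = [s for s in STAGE_ORDER if s in stages]
    seed = int(get(config, "seed"))
    manifest: dict = {"outdir": outdir.name, "seed": seed, "stages": {}}
    if dry_run:
        # touch every config key each stage will need
        sim_params_from_config(config)
        QCThresholds(
            min_raw_reads=get(config, "qc.min_raw_reads"),
            min_saturation=get(config, "qc.min_saturation"),
            min_gene_frac=get(config, "qc.min_gene_frac"),
            loq_detect_frac=get(config, "qc.loq_detect_frac"),
            loq_epsilon=get(config, "qc.loq_epsilon"),
        )
        get(config, "dea.alpha"), get(config, "dea.lfc_min")
        get(config, "scoring.standardize")
        return manifest
    outdir.mkdir(parents=True, exist_ok=True)

    for stage in stages:
        logger.info("pipeline: stage %s", stage)
        try:
            outputs = _run_stage(stage, config, outdir, seed)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = outputs
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _require(path: Path, producer: str) -> Path:
    if not Path(path).exists():
        raise FileNotFoundError(
            f"missing input {path}; run the {producer!r} stage first"
        )
    return Path(path)


def _run_stage(stage: str, config: dict, outdir: Path, seed: int) -> dict:
    if stage == "simulate":
        params = sim_params_from_config(config, seed=seed)
        exp = simulate_dsp_experiment(params)
        bundle_dir = outdir / "fixture"
        manifest = write_dsp_bundle(exp, bundle_dir)
        pathways = make_pathway_sets(exp.truth, seed, exp.counts.gene_ids)
        write_gmt(pathways, bundle_dir / "pathways.gmt")
        manifest["pathways"] = str(bundle_dir / "pathways.gmt")
        manifest = {k: _rel(v, outdir) for k, v in manifest.items()}
        _provenance(outdir, stage, [], {"seed": seed, "n_genes": params.n_genes})
        return manifest

    if stage == "preprocess":
        bundle = outdir / "fixture"
        _require(bundle / "counts.tsv", "simulate")
        exp = read_dsp_bundle(bundle)
        thr = QCThresholds(
            min_raw_reads=get(config, "qc.min_raw_reads"),
            min_saturation=get(config, "qc.min_saturation"),
            min_gene_frac=get(config, "qc.min_gene_frac"),
            loq_detect_frac=get(config, "qc.loq_detect_frac"),
            loq_epsilon=get(config, "qc.loq_epsilon"),
        )
        exp_f, normalized, harmonized, flags = run_preprocess(
            exp, thr, log_pseudocount=get(config, "dea.log_pseudocount")
        )
        write_expression_table(normalized, outdir / "normalized.tsv")
        write_expression_table(harmonized, outdir / "log2_harmonized.tsv")
        exp_f.annotation_frame.drop(columns="aoi_id").to_csv(
            outdir / "annotations_qc.tsv", sep="\t"
        )
        qc_report = pd.DataFrame(
            {"aoi_id": flags.index, "criterion": "pca_outlier", "flag": flags.to_numpy()}
        )
        qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        _provenance(outdir, stage, [bundle / "counts.tsv"], vars(thr))
        return {
            "normalized": _rel(outdir / "normalized.tsv", outdir),
            "log2": _rel(outdir / "log2_harmonized.tsv", outdir),
            "qc_report": _rel(outdir / "qc_report.tsv", outdir),
        }

    # later stages share the preprocessed matrices
    from .io import read_expression_table

    if stage in ("validate-masks", "dea", "derive-sig"):
        _require(outdir / "log2_harmonized.tsv", "preprocess")
        ann = pd.read_csv(outdir / "annotations_qc.tsv", sep="\t", index_col=0)

    if stage == "validate-masks":
        logged = read_expression_table(outdir / "log2_harmonized.tsv", scale=Scale.LOG2)
        res = validate_masks(logged, ann["mask"])
        res.to_csv(outdir / "mask_validation.tsv", sep="\t", index=False)
        _provenance(outdir, stage, [outdir / "log2_harmonized.tsv"], {})
        return {"mask_validation": _rel(outdir / "mask_validation.tsv", outdir)}

    if stage == "dea":
        logged = read_expression_table(outdir / "log2_harmonized.tsv", scale=Scale.LOG2)
        from .io import read_aoi_annotations

        annotations = read_aoi_annotations(outdir / "annotations_qc.tsv")
        outputs = {}
        for contrast in CONTRAST_GROUPS:
            table = run_dea(logged, annotations, contrast, mask="CD68")
            path = outdir / f"dea_{contrast}.tsv"
            write_frame(table, path)
            outputs[contrast] = str(path)
        _provenance(
            outdir, stage, [outdir / "log2_harmonized.tsv"],
            {"alpha": get(config, "dea.alpha"), "lfc_min": get(config, "dea.lfc_min")},
        )
        return outputs

    if stage == "derive-sig":
        normalized = read_expression_table(
            _require(outdir / "normalized.tsv", "preprocess"), scale=Scale.Q3_NORMALIZED
        )
        dea_tables = {}
        for contrast in CONTRAST_GROUPS:
            path = _require(outdir / f"dea_{contrast}.tsv", "dea")
            dea_tables[contrast] = pd.read_csv(path, sep="\t", index_col=0)
        ranks = percentile_ranks(normalized, ann["mask"], which_masks=["CD68", "CD20"])
        sigs = derive_all_macrosigs(
            dea_tables,
            ranks,
            alpha=get(config, "dea.alpha"),
            lfc_min=get(config, "dea.lfc_min"),
        )
        outputs = {}
        for name, sig in sigs.items():
            write_macrosig(sig, outdir / f"{name}.gmt")
            outputs[name] = _rel(outdir / f"{name}.gmt", outdir)
        _provenance(outdir, stage, [outdir / "normalized.tsv"], {})
        return outputs

    if stage == "score":
        pair_names = SIG_PAIRS["LZ_vs_DZ"]
        lz = read_macrosig(_require(outdir / f"{pair_names[0]}.gmt", "derive-sig"))
        dz = read_macrosig(_require(outdir / f"{pair_names[1]}.gmt", "derive-sig"))
        params = sim_params_from_config(config, seed=seed)
        from .signatures import merge_pair

        # positive score pole = the contrast's up side (LZ); the cohort is
        # simulated around the merged signed signature
        sig = merge_pair(lz, dz)
        cohort = simulate_cohort(params, sig)
        scores, info = signature_score(
            cohort, sig, standardize=get(config, "scoring.standardize")
        )
        strat = tertile_stratify(scores, signature_pair=pair_names, info=info)
        strat.table.to_csv(outdir / "scores.tsv", sep="\t")
        cohort.survival.to_csv(outdir / "cohort_survival.tsv", sep="\t")
        cohort.labels.to_csv(outdir / "cohort_labels.tsv", sep="\t")
        _provenance(outdir, stage, [outdir / f"{pair_names[0]}.gmt"], {"seed": seed})
        return {"scores": _rel(outdir / "scores.tsv", outdir)}

    if stage == "survive":
        scores = pd.read_csv(_require(outdir / "scores.tsv", "score"), sep="\t", index_col=0)
        surv = pd.read_csv(_require(outdir / "cohort_survival.tsv", "score"), sep="\t", index_col=0)
        from .containers import StratificationResult

        strat = StratificationResult(
            table=scores, signature_pair=("up", "down"), n_genes_used=0
        )
        res = compare_extreme_tertiles(strat, surv)
        fit = res["cox"]
        forest = pd.DataFrame(
            [
                {
                    "comparison": "high_vs_low",
                    "hr": fit.hr,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "log_hr": fit.log_hr,
                    "wald_p": fit.p,
                    "logrank_p": res["logrank_p"],
                    "n": fit.n,
                    "n_events": fit.n_events,
                }
            ]
        )
        forest.to_csv(outdir / "survival_summary.tsv", sep="\t", index=False)
        km_rows = []
        for g, curve in res["km"].items():
            for t, s in zip(curve.times, curve.survival):
                km_rows.append({"group": g, "time": t, "survival": s})
        pd.DataFrame(km_rows).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
        from .plots import plot_forest, plot_km_curves

        plot_km_curves(res["km"], outdir / "km_curves.svg", title="score tertiles")
        plot_forest({"high_vs_low": fit}, outdir / "forest.svg")
        _provenance(outdir, stage, [outdir / "scores.tsv"], {})
        return {
            "survival_summary": _rel(outdir / "survival_summary.tsv", outdir),
            "km_curves": _rel(outdir / "km_curves.tsv", outdir),
            "km_plot": _rel(outdir / "km_curves.svg", outdir),
            "forest_plot": _rel(outdir / "forest.svg", outdir),
        }

    if stage == "associate":
        scores = pd.read_csv(_require(outdir / "scores.tsv", "score"), sep="\t", index_col=0)
        labels = pd.read_csv(_require(outdir / "cohort_labels.tsv", "score"), sep="\t", index_col=0)
        universe = set(scores.index)
        groups = {
            g: set(scores.index[scores["group"] == g]) for g in ("low", "high")
        }
        categories = {
            c: set(labels.index[labels["COO"] == c]) for c in sorted(labels["COO"].unique())
        }
        table = associate(
            groups, categories, universe, alternative=get(config, "association.alternative")
        )
        table.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        _provenance(outdir, stage, [outdir / "scores.tsv"], {})
        return {"associations": _rel(outdir / "associations.tsv", outdir)}

    if stage == "enrich":
        gmt_path = _require(outdir / "fixture" / "pathways.gmt", "simulate")
        genesets = read_gmt(gmt_path)
        sig_path = _require(outdir / "MacroSig4_DZ.gmt", "derive-sig")
        sig = read_macrosig(sig_path)
        dea_table = pd.read_csv(
            _require(outdir / "dea_LZ_vs_DZ.tsv", "dea"), sep="\t", index_col=0
        )
        table = geneset_enrichment(set(sig.genes), genesets, set(dea_table.index))
        table.to_csv(outdir / "enrichment.tsv", sep="\t")
        _provenance(outdir, stage, [gmt_path], {})
        return {"enrichment": _rel(outdir / "enrichment.tsv", outdir)}

    raise ConfigError(f"unknown stage {stage!r}")
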