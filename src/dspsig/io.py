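"""Readers and writers for the on-disk formats used by the pipeline.

All tabular formats are plain TSV (UTF-8, header row).  Expression tables
are genes-as-rows / samples-as-columns; MatrixMarket input is supported via
two sidecar index files.  Gene sets travel as GMT.  Floats are written with
17 significant digits so write→read round trips are bit-stable.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    AOIAnnotation,
    CohortDataset,
    DataFormatError,
    ExpressionMatrix,
    GeneSignature,
    MacroSig,
    Scale,
)

logger = logging.getLogger("dspsig")

FLOAT_FMT = "%.17g"


def _check_unique(ids: Iterable[str], what: str, path) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dup = set(), []
        for x in ids:
            if x in seen:
                dup.append(x)
            seen.add(x)
        raise DataFormatError(f"{path}: duplicate {what} ids: {dup[:5]}")


def read_expression_table(
    path, format: str = "tsv", scale: Scale | str = Scale.COUNTS
) -> ExpressionMatrix:
    """Read a gene-by-sample expression table.

    ``tsv``: header row of sample ids, first column gene ids.
    ``mtx``: MatrixMarket coordinate file plus ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` sidecars (one id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        if path.stat().st_size == 0:
            raise DataFormatError(f"{path}: empty file")
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
        if df.shape[1] == 0:
            raise DataFormatError(f"{path}: no sample columns")
        _check_unique(df.index, "gene", path)
        _check_unique(df.columns, "sample", path)
        bad = df.apply(pd.to_numeric, errors="coerce")
        if bad.isna().any().any():
            r, c = np.argwhere(bad.isna().to_numpy())[0]
            raise DataFormatError(
                f"{path}: non-numeric value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        df = bad
    elif format == "mtx":
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        if mat.shape != (len(genes), len(samples)):
            raise DataFormatError(
                f"{path}: matrix shape {mat.shape} does not match index files"
            )
        _check_unique(genes, "gene", path)
        _check_unique(samples, "sample", path)
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r} (expected tsv or mtx)")
    return ExpressionMatrix(df, Scale(scale))


def write_expression_table(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df = matrix.data
        if np.issubdtype(df.to_numpy().dtype, np.integer):
            df.to_csv(path, sep="\t")
        else:
            df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    elif format == "mtx":
        stem = path.with_suffix("")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
        Path(f"{stem}.genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(matrix.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


ANNOTATION_COLUMNS = (
    "aoi_id",
    "roi_id",
    "patient_id",
    "tissue",
    "mask",
    "region",
    "batch",
    "raw_reads",
    "saturation",
)


def read_aoi_annotations(path) -> list[AOIAnnotation]:
    """Read the AOI annotation TSV into validated records."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                AOIAnnotation(
                    aoi_id=row["aoi_id"],
                    roi_id=row["roi_id"],
                    patient_id=row["patient_id"],
                    tissue=row["tissue"],
                    mask=row["mask"],
                    region=row["region"],
                    batch=row["batch"],
                    raw_reads=int(row["raw_reads"]),
                    saturation=float(row["saturation"]),
                    area=float(row["area"]) if "area" in df.columns and pd.notna(row.get("area")) else None,
                    nuclei=int(float(row["nuclei"])) if "nuclei" in df.columns and pd.notna(row.get("nuclei")) else None,
                )
            )
        except (DataFormatError, ValueError) as exc:
            raise DataFormatError(f"{path}: row {i}: {exc}") from exc
    _check_unique([a.aoi_id for a in out], "aoi", path)
    return out


def write_aoi_annotations(annotations: list[AOIAnnotation], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for a in annotations:
        row = {c: getattr(a, c) for c in ANNOTATION_COLUMNS}
        row["area"] = a.area
        row["nuclei"] = a.nuclei
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gmt(path) -> list[GeneSignature]:
    """Read gene sets from GMT (name, description, then >=1 gene per line)."""
    path = Path(path)
    sigs = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(
                    f"{path}: line {i + 1}: GMT lines need name, description and >=1 gene"
                )
            sigs.append(GeneSignature(name=parts[0], description=parts[1], genes=parts[2:]))
    return sigs


def write_gmt(signatures: list[GeneSignature], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for s in signatures:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_cohort(expr_path, survival_path, labels_path=None) -> CohortDataset:
    """Assemble a cohort from expression, survival and label TSVs.

    Patients missing from the survival table are dropped with a warning;
    the intersection must be non-empty.
    """
    expr = read_expression_table(expr_path, scale=Scale.LOG2)
    surv = pd.read_csv(survival_path, sep="\t")
    for col in ("patient_id", "time", "event"):
        if col not in surv.columns:
            raise DataFormatError(f"{survival_path}: missing column {col!r}")
    surv = surv.set_index("patient_id")
    if not surv["event"].isin([0, 1]).all():
        bad = surv.loc[~surv["event"].isin([0, 1])].index.tolist()
        raise DataFormatError(f"{survival_path}: event must be 0/1 (patients {bad[:5]})")
    if not (surv["time"] > 0).all():
        raise DataFormatError(f"{survival_path}: times must be > 0")
    common = [p for p in expr.sample_ids if p in surv.index]
    if not common:
        raise DataFormatError("no overlapping patients between expression and survival")
    dropped = sorted(set(expr.sample_ids) - set(common))
    if dropped:
        logger.warning(
            "read_cohort: dropping %d patients without survival data: %s",
            len(dropped),
            dropped[:5],
        )
    if labels_path is not None:
        labels = pd.read_csv(labels_path, sep="\t")
        if "patient_id" not in labels.columns:
            raise DataFormatError(f"{labels_path}: missing column 'patient_id'")
        labels = labels.set_index("patient_id").reindex(common)
    else:
        labels = pd.DataFrame(index=pd.Index(common, name="patient_id"))
    return CohortDataset(
        expression=expr.subset(samples=common),
        survival=surv.loc[common, ["time", "event"]],
        labels=labels,
    )


def write_macrosig(sig: MacroSig, gmt_path, weights_path=None) -> None:
    """Serialise a MacroSig as GMT plus a weights sidecar TSV.

    GMT cannot carry per-gene weights, so (weight, sign, log2fc, p, adj_p)
    go to ``<name>.weights.tsv``.
    """
    gmt_path = Path(gmt_path)
    if weights_path is None:
        weights_path = gmt_path.with_suffix("").with_suffix(".weights.tsv")
    write_gmt(
        [GeneSignature(sig.name, sig.genes, description=sig.contrast)], gmt_path
    )
    df = sig.entries.copy()
    df.index.name = "gene_id"
    df.to_csv(weights_path, sep="\t", float_format=FLOAT_FMT)


def read_macrosig(gmt_path, weights_path=None) -> MacroSig:
    gmt_path = Path(gmt_path)
    if weights_path is None:
        weights_path = gmt_path.with_suffix("").with_suffix(".weights.tsv")
    sigs = read_gmt(gmt_path)
    if len(sigs) != 1:
        raise DataFormatError(f"{gmt_path}: expected exactly one signature")
    entries = pd.read_csv(weights_path, sep="\t", index_col="gene_id", float_precision="round_trip")
    entries.index.name = None
    sig = MacroSig(name=sigs[0].name, contrast=sigs[0].description, entries=entries)
    if set(sig.genes) != set(sigs[0].genes):
        raise DataFormatError(f"{gmt_path}: gene list disagrees with weights sidecar")
    return sig


def write_dsp_bundle(exp, outdir, format: str = "tsv") -> dict:
    """Write a DSP experiment as a fixture bundle: counts, annotations,
    negative probes, and (if present) planted truth as JSON."""
    import json

    from .containers import DSPExperiment  # noqa: F401  (type only)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path = outdir / ("counts.tsv" if format == "tsv" else "counts.mtx")
    write_expression_table(exp.counts, counts_path, format=format)
    write_aoi_annotations(exp.annotations, outdir / "annotations.tsv")
    exp.neg_probes.to_csv(outdir / "neg_probes.tsv", sep="\t")
    manifest = {
        "counts": str(counts_path),
        "annotations": str(outdir / "annotations.tsv"),
        "neg_probes": str(outdir / "neg_probes.tsv"),
    }
    if exp.truth is not None:
        t = exp.truth
        payload = {
            "planted_up": t.planted_up,
            "planted_down": t.planted_down,
            "planted_lfc": t.planted_lfc,
            "planted_contaminants": t.planted_contaminants,
            "hazard_coef": t.hazard_coef,
            "seeds": t.seeds,
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        if t.batch_factors is not None:
            t.batch_factors.to_csv(outdir / "batch_factors.tsv", sep="\t", float_format=FLOAT_FMT)
        manifest["truth"] = str(outdir / "truth.json")
    return manifest


def read_dsp_bundle(outdir, format: str = "tsv"):
    """Read a fixture bundle written by :func:`write_dsp_bundle`."""
    import json

    from .containers import DSPExperiment, SyntheticTruth

    outdir = Path(outdir)
    counts = read_expression_table(
        outdir / ("counts.tsv" if format == "tsv" else "counts.mtx"), format=format
    )
    annotations = read_aoi_annotations(outdir / "annotations.tsv")
    neg = pd.read_csv(outdir / "neg_probes.tsv", sep="\t", index_col=0, float_precision="round_trip")
    truth = None
    truth_path = outdir / "truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        bf_path = outdir / "batch_factors.tsv"
        truth = SyntheticTruth(
            planted_up=payload.get("planted_up", {}),
            planted_down=payload.get("planted_down", {}),
            planted_lfc=payload.get("planted_lfc", {}),
            planted_contaminants=payload.get("planted_contaminants", []),
            batch_factors=pd.read_csv(bf_path, sep="\t", index_col=0) if bf_path.exists() else None,
            hazard_coef=payload.get("hazard_coef"),
            seeds=payload.get("seeds", {}),
        )
    return DSPExperiment(counts=counts, annotations=annotations, neg_probes=neg, truth=truth)


def read_frame(path) -> pd.DataFrame:
    """Generic TSV-with-index reader (e.g. negative-probe tables)."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_frame(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
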