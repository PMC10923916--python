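"""Core in-memory containers shared by every pipeline stage.

Expression tables are stored genes-as-rows, samples-as-columns throughout,
matching DSP export conventions.  Missing values are disallowed: the
pipeline has no imputation step, so a NaN anywhere is treated as a data
error at construction time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

MASKS = ("CD68", "CD3", "CD20")
REGIONS = ("GC", "IF", "LZ", "DZ", "NONE")
TISSUES = ("RLT", "DLBCL")


class Scale(str, Enum):
    """Scale of an expression matrix as it moves through preprocessing."""

    COUNTS = "counts"
    Q3_NORMALIZED = "q3_normalized"
    LOG2 = "log2"


class DataFormatError(ValueError):
    """Malformed on-disk or in-memory data (duplicates, bad enums, NaNs)."""


@dataclass
class ExpressionMatrix:
    """A dense gene-by-sample expression grid with a declared scale.

    Parameters
    ----------
    data
        DataFrame with unique gene ids as index and unique sample ids as
        columns.  Values must be finite; non-negative when ``scale`` is
        ``counts``.
    scale
        One of :class:`Scale`.
    """

    data: pd.DataFrame
    scale: Scale = Scale.COUNTS

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate gene ids: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate sample ids: {dup[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise DataFormatError("expression values must be finite (no NA/inf)")
        if self.scale is Scale.COUNTS and values.size and (values < 0).any():
            raise DataFormatError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            df = df.loc[list(genes)]
        if samples is not None:
            df = df[list(samples)]
        return ExpressionMatrix(df.copy(), self.scale)


@dataclass
class AOIAnnotation:
    """Annotation of one area of interest (AOI).

    An AOI is the mask-defined cell-type compartment (CD68 macrophage,
    CD3 T cell or CD20 B cell) within a region of interest on the tissue.
    Regions (GC/IF/LZ/DZ) apply to reactive lymphoid tissue only; tumor
    (DLBCL) AOIs carry region ``NONE``.
    """

    aoi_id: str
    roi_id: str
    patient_id: str
    tissue: str
    mask: str
    region: str
    batch: str
    raw_reads: int
    saturation: float
    area: Optional[float] = None
    nuclei: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise DataFormatError(
                f"AOI {self.aoi_id!r}: unknown tissue {self.tissue!r} (expected {TISSUES})"
            )
        if self.mask not in MASKS:
            raise DataFormatError(
                f"AOI {self.aoi_id!r}: unknown mask {self.mask!r} (expected {MASKS})"
            )
        if self.region not in REGIONS:
            raise DataFormatError(
                f"AOI {self.aoi_id!r}: unknown region {self.region!r} (expected {REGIONS})"
            )
        if self.tissue == "RLT" and self.region == "NONE":
            raise DataFormatError(
                f"AOI {self.aoi_id!r}: RLT AOIs require a region (GC/IF/LZ/DZ)"
            )
        if self.tissue == "DLBCL" and self.region != "NONE":
            raise DataFormatError(
                f"AOI {self.aoi_id!r}: regions apply to RLT only; DLBCL AOIs use NONE"
            )
        self.raw_reads = int(self.raw_reads)
        self.saturation = float(self.saturation)
        if self.raw_reads < 0:
            raise DataFormatError(f"AOI {self.aoi_id!r}: raw_reads must be >= 0")
        if not 0.0 <= self.saturation <= 1.0:
            raise DataFormatError(
                f"AOI {self.aoi_id!r}: saturation {self.saturation} outside [0, 1]"
            )


def annotations_to_frame(annotations: list[AOIAnnotation]) -> pd.DataFrame:
    """Tabulate annotations (index: aoi_id) for vectorised selection."""
    rows = [vars(a).copy() for a in annotations]
    df = pd.DataFrame(rows)
    return df.set_index("aoi_id", drop=False)


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the synthetic-data generators."""

    planted_up: dict[str, list[str]] = field(default_factory=dict)
    planted_down: dict[str, list[str]] = field(default_factory=dict)
    planted_lfc: dict[str, float] = field(default_factory=dict)
    planted_contaminants: list[str] = field(default_factory=list)
    batch_factors: Optional[pd.DataFrame] = None
    size_factors: Optional[pd.Series] = None
    hazard_coef: Optional[float] = None
    latent_activity: Optional[pd.Series] = None
    cluster_labels: Optional[pd.Series] = None
    seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contrast in self.planted_up:
            overlap = set(self.planted_up[contrast]) & set(
                self.planted_down.get(contrast, [])
            )
            if overlap:
                raise ValueError(
                    f"contrast {contrast}: genes planted both up and down: {sorted(overlap)[:5]}"
                )
        if self.hazard_coef is not None and not np.isfinite(self.hazard_coef):
            raise ValueError("hazard_coef must be finite")


@dataclass
class DSPExperiment:
    """A DSP dataset: counts, AOI annotations, negative probes, optional truth."""

    counts: ExpressionMatrix
    annotations: list[AOIAnnotation]
    neg_probes: pd.DataFrame
    truth: Optional[SyntheticTruth] = None

    def __post_init__(self) -> None:
        ann_ids = [a.aoi_id for a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            raise DataFormatError("duplicate aoi_id in annotations")
        missing = set(self.counts.sample_ids) - set(ann_ids)
        if missing:
            raise DataFormatError(f"AOIs without annotation: {sorted(missing)[:5]}")
        # keep annotations aligned and restricted to the count columns
        order = {s: i for i, s in enumerate(self.counts.sample_ids)}
        self.annotations = sorted(
            (a for a in self.annotations if a.aoi_id in order),
            key=lambda a: order[a.aoi_id],
        )
        if self.neg_probes is not None:
            if list(self.neg_probes.columns) != self.counts.sample_ids:
                if set(self.neg_probes.columns) >= set(self.counts.sample_ids):
                    self.neg_probes = self.neg_probes[self.counts.sample_ids]
                else:
                    raise DataFormatError("neg_probes columns do not cover count AOIs")

    @property
    def annotation_frame(self) -> pd.DataFrame:
        return annotations_to_frame(self.annotations)

    def subset_aois(self, aoi_ids: list[str]) -> "DSPExperiment":
        keep = [a for a in self.annotations if a.aoi_id in set(aoi_ids)]
        return DSPExperiment(
            counts=self.counts.subset(samples=[a.aoi_id for a in keep]),
            annotations=keep,
            neg_probes=self.neg_probes[[a.aoi_id for a in keep]].copy(),
            truth=self.truth,
        )

    def subset_genes(self, gene_ids: list[str]) -> "DSPExperiment":
        return DSPExperiment(
            counts=self.counts.subset(genes=gene_ids),
            annotations=list(self.annotations),
            neg_probes=self.neg_probes.copy(),
            truth=self.truth,
        )


@dataclass
class GeneSignature:
    """A plain (unweighted) gene set, e.g. a cell-type marker list."""

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r}: gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r}: duplicate genes")


@dataclass
class MacroSig:
    """A signed, significance-weighted gene signature from one DE contrast.

    ``entries`` is a DataFrame indexed by gene id with columns
    ``weight`` (= -log10 of the moderated-t p-value), ``sign`` (+1 for
    genes upregulated in the contrast's first group, -1 for
    downregulated), ``log2fc``, ``p`` and ``adj_p``.
    """

    name: str
    contrast: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"weight", "sign", "log2fc", "p", "adj_p"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"MacroSig {self.name!r}: missing columns {sorted(missing)}")
        if self.entries.index.has_duplicates:
            raise ValueError(f"MacroSig {self.name!r}: duplicate genes")
        e = self.entries
        if len(e):
            if not ((e["weight"] > 0).all()):
                raise ValueError(f"MacroSig {self.name!r}: weights must be > 0")
            if not e["sign"].isin([-1, 1]).all():
                raise ValueError(f"MacroSig {self.name!r}: signs must be +/-1")
            if not (np.sign(e["log2fc"]) == e["sign"]).all():
                raise ValueError(f"MacroSig {self.name!r}: sign must match log2FC sign")

    @property
    def genes(self) -> list[str]:
        return list(self.entries.index)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CohortDataset:
    """A bulk expression cohort with survival follow-up and category labels."""

    expression: ExpressionMatrix  # genes x patients, log2 scale
    survival: pd.DataFrame  # index patient_id; columns time, event
    labels: pd.DataFrame  # index patient_id; one column per category type
    truth: Optional[SyntheticTruth] = None

    def __post_init__(self) -> None:
        patients = list(self.expression.sample_ids)
        if list(self.survival.index) != patients:
            if not set(self.survival.index) >= set(patients):
                raise DataFormatError("survival table does not cover all patients")
            self.survival = self.survival.loc[patients]
        if not (self.survival["time"] > 0).all():
            raise DataFormatError("survival times must be > 0")
        if not self.survival["event"].isin([0, 1]).all():
            raise DataFormatError("event indicator must be 0 or 1")
        if self.labels is not None and len(self.labels):
            self.labels = self.labels.reindex(patients)

    @property
    def patients(self) -> list[str]:
        return list(self.expression.sample_ids)

    @property
    def n_patients(self) -> int:
        return len(self.expression.sample_ids)


@dataclass
class StratificationResult:
    """Per-patient signature score and tertile group assignment.

    ``table`` is indexed by patient with columns ``score`` and ``group``
    (low / mid / high).
    """

    table: pd.DataFrame
    signature_pair: tuple[str, str]
    n_genes_used: int
    genes_dropped: list[str] = field(default_factory=list)
    cutpoints: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if not {"score", "group"} <= set(self.table.columns):
            raise ValueError("stratification table needs score and group columns")
        if not np.isfinite(self.table["score"]).all():
            raise ValueError("scores must be finite")

    def members(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])
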