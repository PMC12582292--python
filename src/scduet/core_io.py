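"""Data containers, file readers/writers, configuration and logging.

All per-cell joins across the pipeline use ``well_id`` strings — one plate well
is one cell (or doublet, or empty control). Matrices are oriented feature x cell
throughout (genes x cells, analytes x cells).

File dialects
-------------
* Tables: TSV or CSV, missing numeric values serialized as ``NA`` (readers also
  accept ``NaN`` and empty cells).
* Count matrices: dense TSV (genes x cells with header) or MatrixMarket
  coordinate (1-based indices) plus plain-text ``.rownames.txt`` /
  ``.colnames.txt`` sidecars, one label per line.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

log = logging.getLogger("scduet")

NA_VALUES = ["NA", "NaN", ""]


def configure_logging(level: str = "INFO") -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    logger = logging.getLogger("scduet")
    logger.setLevel(level.upper())
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)


class FormatError(ValueError):
    """A file or matrix does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Contents violate a container invariant (e.g. duplicate well IDs)."""


class ConfigError(ValueError):
    """Invalid pipeline or simulation configuration."""


class WellStatus(str, Enum):
    SINGLE = "single"
    DOUBLET = "doublet"
    EMPTY = "empty"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellRecord:
    """One plate well: identity, batch (collection day), picked status and the
    protoplast diameter measured from the picking-robot image (µm).

    ``diameter_um`` is absent exactly when the well is empty; the diameter of a
    doublet well is the robot's single measurement and is never used for
    quantification (doublets are excluded upstream of concentration estimates).
    """

    well_id: str
    plate: str
    batch: str
    status: WellStatus
    diameter_um: float | None = None

    def __post_init__(self) -> None:
        status = WellStatus(self.status)
        object.__setattr__(self, "status", status)
        if status is WellStatus.EMPTY:
            if self.diameter_um is not None and not np.isnan(self.diameter_um):
                raise ValidationError(f"empty well {self.well_id} must not carry a diameter")
            object.__setattr__(self, "diameter_um", None)
        else:
            d = self.diameter_um
            if d is None or np.isnan(d):
                raise ValidationError(f"non-empty well {self.well_id} requires a diameter")
            if d <= 0:
                raise ValidationError(f"well {self.well_id}: diameter must be positive, got {d}")
            object.__setattr__(self, "diameter_um", float(d))


@dataclass
class ExpressionSet:
    """Gene x cell raw counts with per-gene transcript lengths.

    ``layers`` holds derived same-shape matrices ("tpm", "lognorm") or the
    variable-gene scaled matrix keyed by name; they are not validated beyond
    what the producing operation guarantees.
    """

    genes: list[str]
    cells: list[str]
    counts: np.ndarray
    gene_length_bp: np.ndarray
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = list(map(str, self.genes))
        self.cells = list(map(str, self.cells))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if counts.size and (np.any(counts < 0) or np.any(counts != np.floor(counts))):
            raise FormatError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64)
        lengths = np.asarray(self.gene_length_bp)
        if lengths.shape != (len(self.genes),):
            raise ValidationError("gene_length_bp must align with the gene list")
        if lengths.size and np.any(lengths < 1):
            raise ValidationError("gene lengths must be >= 1 bp")
        self.gene_length_bp = lengths.astype(np.int64)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene IDs")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell (well) IDs")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.cells)

    def subset_cells(self, cells: list[str]) -> "ExpressionSet":
        idx = [self.cells.index(c) for c in cells]
        layers = {k: v.iloc[:, idx].copy() for k, v in self.layers.items()}
        return ExpressionSet(
            genes=list(self.genes),
            cells=list(cells),
            counts=self.counts[:, idx].copy(),
            gene_length_bp=self.gene_length_bp.copy(),
            layers=layers,
        )


@dataclass
class MetaboliteMatrix:
    """Analyte x cell intracellular concentrations (µM) with below-LOQ mask.

    Entries flagged below LOQ are recorded as 0 µM; ``batch_of_cell`` carries
    the collection-day label needed for within-batch standardization.
    """

    analytes: list[str]
    cells: list[str]
    conc_uM: np.ndarray
    below_loq: np.ndarray
    batch_of_cell: list[str]

    def __post_init__(self) -> None:
        self.analytes = list(map(str, self.analytes))
        self.cells = list(map(str, self.cells))
        if len(set(self.analytes)) != len(self.analytes):
            raise ValidationError("analyte names must be unique")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("cell (well) IDs must be unique")
        conc = np.asarray(self.conc_uM, dtype=float)
        mask = np.asarray(self.below_loq, dtype=bool)
        shape = (len(self.analytes), len(self.cells))
        if conc.shape != shape or mask.shape != shape:
            raise ValidationError(f"matrix shapes must be {shape}")
        if conc.size and np.any(conc < 0):
            raise ValidationError("concentrations must be non-negative")
        if conc.size and np.any(conc[mask] != 0):
            raise ValidationError("below-LOQ entries must be recorded as 0")
        if len(self.batch_of_cell) != len(self.cells):
            raise ValidationError("batch_of_cell must align with the cell list")
        self.conc_uM = conc
        self.below_loq = mask
        self.batch_of_cell = list(map(str, self.batch_of_cell))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.conc_uM, index=self.analytes, columns=self.cells)

    def subset_cells(self, cells: list[str]) -> "MetaboliteMatrix":
        idx = [self.cells.index(c) for c in cells]
        return MetaboliteMatrix(
            analytes=list(self.analytes),
            cells=list(cells),
            conc_uM=self.conc_uM[:, idx].copy(),
            below_loq=self.below_loq[:, idx].copy(),
            batch_of_cell=[self.batch_of_cell[i] for i in idx],
        )


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis stages.

    Defaults mirror the experimental design this pipeline targets: QC keeps single cells with strictly more
    than 1,000 and strictly fewer than 10,000 detected genes; 500 variable
    genes; lysate split factor 2 (half to MS, half to RNA-seq); 4 µL analysis
    aliquot; top/bottom 15 transporter edges per analyte.
    """

    min_genes: int = 1000
    max_genes: int = 10000
    n_variable_genes: int = 500
    lognorm_scale_factor: float = 10000.0
    aliquot_volume_uL: float = 4.0
    split_factor: float = 2.0
    loq_accuracy_tol: float = 0.2
    loq_cv_tol: float = 0.2
    embed_method: str = "pca"
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    top_k: int = 15
    bottom_k: int = 15
    loess_span: float = 0.75
    spearman_detected_only: bool = False
    seed: int = 0
    # ordered (label, [genes]) RNA marker rules; detection = raw count >= 1
    rna_marker_rules: list = field(
        default_factory=lambda: [
            ("idioblast", ["D4H", "DAT"]),
            ("ipap", ["G8H", "ISY"]),
            ("epidermis", ["NLTP2"]),
        ]
    )
    # ordered (label, required analytes, forbidden analytes) metabolite rules
    met_marker_rules: list = field(
        default_factory=lambda: [
            ("idioblast", ["serpentine"], []),
            ("loganic_acid_cell", ["loganic_acid"], []),
            ("epidermis_mauritianin", ["secologanin", "mauritianin"], []),
            ("epidermis", ["secologanin"], ["mauritianin"]),
        ]
    )

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ConfigError("require 0 < min_genes < max_genes")
        for name in ("loq_accuracy_tol", "loq_cv_tol"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be a proportion in [0, 1]")
        if self.split_factor <= 0 or self.aliquot_volume_uL <= 0:
            raise ConfigError("volume constants must be positive")
        if self.embed_method not in ("pca", "umap"):
            raise ConfigError("embed_method must be 'pca' or 'umap'")
        if int(self.seed) != self.seed:
            raise ConfigError("seed must be an integer")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        payload = {
            k: ([tuple(r) for r in v] if k.endswith("_rules") else v)
            for k, v in payload.items()
        }
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            k: ([list(r) for r in v] if k.endswith("_rules") else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_any_table(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, na_values=NA_VALUES, keep_default_na=False, **kwargs)


def read_well_metadata(path: str | Path) -> list[WellRecord]:
    """Read the per-well picking metadata table.

    Required columns: well_id, plate, batch, status, diameter_um. Duplicate
    well IDs are rejected; a diameter on an empty well is a validation error.
    """
    df = _read_any_table(path)
    required = ["well_id", "plate", "batch", "status", "diameter_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"well metadata is missing columns: {missing}")
    if df["well_id"].duplicated().any():
        dupes = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
        raise ValidationError(f"duplicate well_id(s): {dupes}")
    records = []
    for row in df.itertuples(index=False):
        d = row.diameter_um
        records.append(
            WellRecord(
                well_id=str(row.well_id),
                plate=str(row.plate),
                batch=str(row.batch),
                status=WellStatus(str(row.status)),
                diameter_um=None if pd.isna(d) else float(d),
            )
        )
    log.info("read %d well records from %s", len(records), path)
    return records


def _mtx_sidecar_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return base.with_suffix(".rownames.txt"), base.with_suffix(".colnames.txt")


def _read_names(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_expression(path_counts: str | Path, path_lengths: str | Path) -> ExpressionSet:
    """Read a raw count matrix (dense TSV or MTX + name sidecars) and the
    gene-length table (columns gene_id, length_bp) into an ExpressionSet."""
    path_counts = Path(path_counts)
    if path_counts.suffix == ".mtx":
        rows_path, cols_path = _mtx_sidecar_paths(path_counts)
        mat = scipy.io.mmread(path_counts)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        genes = _read_names(rows_path)
        cells = _read_names(cols_path)
    else:
        df = _read_any_table(path_counts, index_col=0)
        dense = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    if dense.size and (np.any(dense < 0) or np.any(dense != np.floor(dense))):
        raise FormatError("count matrix contains negative or non-integer entries")

    ldf = _read_any_table(path_lengths)
    if not {"gene_id", "length_bp"}.issubset(ldf.columns):
        raise FormatError("length table requires columns gene_id, length_bp")
    lengths = dict(zip(ldf["gene_id"].astype(str), ldf["length_bp"]))
    missing = [g for g in genes if g not in lengths]
    if missing:
        raise ValidationError(f"gene(s) missing from length table: {missing[:10]}")
    length_arr = np.array([lengths[g] for g in genes])
    es = ExpressionSet(genes=genes, cells=cells, counts=dense, gene_length_bp=length_arr)
    log.info("read expression matrix %d genes x %d cells from %s", es.n_genes, es.n_cells, path_counts)
    return es


def read_metabolite_matrix(path: str | Path, path_wells: str | Path | None = None) -> MetaboliteMatrix:
    """Read an analyte x cell concentration table written by write_table.

    Below-LOQ flags are stored alongside as a parallel ``<stem>.below_loq``
    table when present; otherwise zeros are treated as below LOQ.
    """
    df = _read_any_table(path, index_col=0)
    mask_path = Path(path).with_suffix(".below_loq" + Path(path).suffix)
    if mask_path.exists():
        mask = _read_any_table(mask_path, index_col=0).astype(bool).to_numpy()
    else:
        mask = df.to_numpy(dtype=float) == 0
    if path_wells is not None:
        wells = {w.well_id: w for w in read_well_metadata(path_wells)}
        batches = [wells[c].batch for c in df.columns]
    else:
        batches = [""] * df.shape[1]
    return MetaboliteMatrix(
        analytes=[str(a) for a in df.index],
        cells=[str(c) for c in df.columns],
        conc_uM=df.to_numpy(dtype=float),
        below_loq=mask,
        batch_of_cell=batches,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def wells_to_frame(wells: list[WellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "well_id": [w.well_id for w in wells],
            "plate": [w.plate for w in wells],
            "batch": [w.batch for w in wells],
            "status": [w.status.value for w in wells],
            "diameter_um": [w.diameter_um for w in wells],
        }
    )


def write_table(obj: Any, path: str | Path, format: str | None = None) -> None:
    """Write a tabular pipeline result (DataFrame, container, or list of
    WellRecord) as TSV/CSV. NaN is serialized as ``NA``; round-trip reads
    reproduce numeric values to 1e-9 relative tolerance."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix in (".tsv", ".txt") else "csv"
    if format not in ("tsv", "csv"):
        raise FormatError(f"unsupported table format: {format}")
    sep = "\t" if format == "tsv" else ","
    if isinstance(obj, list) and obj and isinstance(obj[0], WellRecord):
        df, index = wells_to_frame(obj), False
    elif isinstance(obj, (ExpressionSet, MetaboliteMatrix)):
        df, index = obj.to_frame(), True
        if isinstance(obj, MetaboliteMatrix):
            mask_path = path.with_suffix(".below_loq" + path.suffix)
            pd.DataFrame(obj.below_loq.astype(int), index=obj.analytes, columns=obj.cells).to_csv(
                mask_path, sep=sep
            )
    elif isinstance(obj, pd.DataFrame):
        df, index = obj, not isinstance(obj.index, pd.RangeIndex)
    else:
        raise FormatError(f"cannot serialize object of type {type(obj).__name__}")
    df.to_csv(path, sep=sep, na_rep="NA", index=index, float_format="%.12g")


def write_expression(es: ExpressionSet, path_counts: str | Path, path_lengths: str | Path) -> None:
    """Write counts as MatrixMarket + sidecars (``.mtx``) or dense TSV, plus
    the gene-length table."""
    path_counts = Path(path_counts)
    if path_counts.suffix == ".mtx":
        scipy.io.mmwrite(path_counts, scipy.sparse.coo_matrix(es.counts))
        rows_path, cols_path = _mtx_sidecar_paths(path_counts)
        rows_path.write_text("".join(g + "\n" for g in es.genes))
        cols_path.write_text("".join(c + "\n" for c in es.cells))
    else:
        write_table(es.to_frame(), path_counts)
    write_table(
        pd.DataFrame({"gene_id": es.genes, "length_bp": es.gene_length_bp}),
        path_lengths,
    )
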