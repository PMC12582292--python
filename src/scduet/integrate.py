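"""Well-identity integration of transcriptome and metabolome, dual marker
annotation, embeddings, and annotation cross-tabulation.

The two modalities are measured from the same lysate, so the well ID is the
cell identity: integration is a strict intersection join on well IDs, never a
computational alignment. Metabolite features are log10(1 + µM) transformed and
z-scored within each collection batch before embedding. Annotation is
rule-based in a fixed priority order — on the RNA side detection (count >= 1)
of validated marker genes (idioblast: D4H/DAT, IPAP: G8H/ISY, epidermis:
NLTP2), on the metabolite side presence above LOQ of marker analytes
(serpentine -> idioblast, loganic acid -> loganic-acid cell, secologanin with
mauritianin -> mauritianin epidermal subtype, secologanin alone -> epidermis).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    ConfigError,
    ExpressionSet,
    MetaboliteMatrix,
    ValidationError,
    log,
)


@dataclass
class MarkerRules:
    """Ordered annotation rules; first match wins.

    ``rna``: (label, genes, min_count) — label if any gene has count >= min_count.
    ``met``: (label, required analytes, forbidden analytes) — label if all
    required are present above LOQ and no forbidden one is.
    """

    rna: list[tuple[str, list[str], int]]
    met: list[tuple[str, list[str], list[str]]]

    @classmethod
    def from_config(cls, rna_rules: list, met_rules: list) -> "MarkerRules":
        rna = [(r[0], list(r[1]), int(r[2]) if len(r) > 2 else 1) for r in rna_rules]
        met = [(m[0], list(m[1]), list(m[2]) if len(m) > 2 else []) for m in met_rules]
        return cls(rna=rna, met=met)


@dataclass
class MultiOmicDataset:
    """Cells jointly profiled in both modalities, with per-cell batch."""

    cells: list[str]
    expr: ExpressionSet
    met: MetaboliteMatrix
    batch: list[str]
    dropped: dict[str, list[str]] = field(default_factory=dict)
    met_log10: pd.DataFrame | None = None
    met_batch_z: pd.DataFrame | None = None


@dataclass
class AnnotationTable:
    """Per-cell RNA-derived and metabolite-derived labels with embeddings."""

    table: pd.DataFrame  # index well_id: rna_label, met_label, [embeddings]


def join_by_well(
    expr: ExpressionSet, met: MetaboliteMatrix, wells=None
) -> MultiOmicDataset:
    """Strict intersection join on well identity; one-modality cells land in
    the drop report."""
    expr_cells = set(expr.cells)
    met_cells = set(met.cells)
    shared = [c for c in expr.cells if c in met_cells]
    if not shared:
        raise ValidationError("no cells shared between expression and metabolite matrices")
    dropped = {
        "expression_only": sorted(expr_cells - met_cells),
        "metabolite_only": sorted(met_cells - expr_cells),
    }
    met_sub = met.subset_cells(shared)
    ds = MultiOmicDataset(
        cells=shared,
        expr=expr.subset_cells(shared),
        met=met_sub,
        batch=list(met_sub.batch_of_cell),
        dropped=dropped,
    )
    log.info(
        "joined %d cells (%d expression-only, %d metabolite-only dropped)",
        len(shared), len(dropped["expression_only"]), len(dropped["metabolite_only"]),
    )
    return ds


def normalize_metabolites(met: MetaboliteMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log10(1 + conc µM), then per-analyte z-score within each batch
    (sample sd, n-1; constant-within-batch analytes get 0)."""
    logm = pd.DataFrame(
        np.log10(1.0 + met.conc_uM), index=met.analytes, columns=met.cells
    )
    z = pd.DataFrame(0.0, index=met.analytes, columns=met.cells)
    batches = pd.Series(met.batch_of_cell, index=met.cells)
    for batch, cells in batches.groupby(batches).groups.items():
        sub = logm.loc[:, list(cells)]
        if sub.shape[1] < 2:
            warnings.warn(f"batch {batch} has a single cell; z-scores set to 0")
            continue
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        zb = sub.sub(mu, axis=0).div(sd.replace(0.0, np.inf), axis=0)
        z.loc[:, list(cells)] = zb
    return logm, z


def embed(
    features: pd.DataFrame,
    method: str = "pca",
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """2-D embedding of a feature x cell matrix.

    ``pca`` is exact and fully deterministic; ``umap`` is deterministic for a
    fixed seed and library version but its coordinates are not portable
    across versions, so PCA is the strict-reproducibility route.
    """
    x = features.to_numpy(dtype=float).T  # cells x features
    cells = list(features.columns)
    if method == "umap":
        if len(cells) <= n_neighbors:
            raise ValidationError(
                f"{len(cells)} cells <= n_neighbors={n_neighbors}; reduce n_neighbors"
            )
        import umap  # deferred: numba compilation is slow

        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
        )
        coords = reducer.fit_transform(x)
    elif method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(x)
        # sign convention: orient each axis by its largest-magnitude loading
        for k in range(coords.shape[1]):
            j = np.argmax(np.abs(coords[:, k]))
            if coords[j, k] < 0:
                coords[:, k] = -coords[:, k]
    else:
        raise ConfigError(f"unknown embedding method: {method}")
    if not np.all(np.isfinite(coords)):
        raise ValidationError("embedding produced non-finite coordinates")
    return pd.DataFrame(coords, index=cells, columns=["dim1", "dim2"])


def _check_rna_rules(rules: MarkerRules, genes: list[str]) -> None:
    known = set(genes)
    for label, gset, _ in rules.rna:
        unknown = [g for g in gset if g not in known]
        if unknown:
            raise ConfigError(f"rule {label}: unknown gene(s) {unknown}")


def annotate_rna(dataset: MultiOmicDataset | ExpressionSet, rules: MarkerRules) -> pd.Series:
    """First matching RNA rule (detection = raw count >= min_count) assigns
    the label; conflicts with lower-priority rules are logged."""
    expr = dataset.expr if isinstance(dataset, MultiOmicDataset) else dataset
    _check_rna_rules(rules, expr.genes)
    counts = expr.to_frame()
    labels = pd.Series("unassigned", index=expr.cells, name="rna_label")
    matched = pd.DataFrame(
        {
            label: (counts.loc[gset] >= min_count).any(axis=0)
            for label, gset, min_count in rules.rna
        }
    )
    n_conflicts = int((matched.sum(axis=1) > 1).sum())
    if n_conflicts:
        log.info("RNA annotation: %d cell(s) matched multiple rules; priority order applied", n_conflicts)
    for label, gset, min_count in rules.rna:  # priority order
        hit = matched[label] & (labels == "unassigned")
        labels[hit[hit].index] = label
    return labels


def annotate_met(dataset: MultiOmicDataset | MetaboliteMatrix, rules: MarkerRules) -> pd.Series:
    """First matching metabolite rule assigns the label; presence = above
    LOQ (mask false and concentration > 0)."""
    met = dataset.met if isinstance(dataset, MultiOmicDataset) else dataset
    known = set(met.analytes)
    for label, req, forb in rules.met:
        unknown = [a for a in req + forb if a not in known]
        if unknown:
            raise ConfigError(f"rule {label}: unknown analyte(s) {unknown}")
    present = pd.DataFrame(
        (met.conc_uM > 0) & ~met.below_loq, index=met.analytes, columns=met.cells
    )
    labels = pd.Series("unassigned", index=met.cells, name="met_label")
    for label, req, forb in rules.met:
        ok = present.loc[req].all(axis=0)
        if forb:
            ok &= ~present.loc[forb].any(axis=0)
        hit = ok & (labels == "unassigned")
        labels[hit[hit].index] = label
    return labels


def build_annotation_table(
    dataset: MultiOmicDataset,
    rules: MarkerRules,
    rna_embedding: pd.DataFrame | None = None,
    met_embedding: pd.DataFrame | None = None,
) -> AnnotationTable:
    table = pd.DataFrame(
        {
            "rna_label": annotate_rna(dataset, rules),
            "met_label": annotate_met(dataset, rules),
        }
    )
    if rna_embedding is not None:
        table[["rna_umap_x", "rna_umap_y"]] = rna_embedding.loc[table.index].to_numpy()
    if met_embedding is not None:
        table[["met_umap_x", "met_umap_y"]] = met_embedding.loc[table.index].to_numpy()
    table.index.name = "well_id"
    return AnnotationTable(table=table)


def round_half_up_pct(numerator: int, denominator: int) -> int:
    """Integer percentage, .5 rounding up (reporting convention)."""
    return int(np.floor(100.0 * numerator / denominator + 0.5))


def cross_tabulate(ann: AnnotationTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency table of (rna_label, met_label) counts and the nonzero
    entries as Sankey flow edges."""
    table = pd.crosstab(ann.table["rna_label"], ann.table["met_label"])
    edges = (
        table.stack()
        .rename("n_cells")
        .reset_index()
        .query("n_cells > 0")
        .reset_index(drop=True)
    )
    return table, edges


def coexpression_fraction(
    dataset: MultiOmicDataset,
    analyte: str,
    genes: list[str],
    min_count: int = 1,
) -> int | None:
    """Percentage (half-up integer) of cells with the analyte present above
    LOQ that also detect any of the given genes; None when no cell has the
    analyte (undefined)."""
    if analyte not in dataset.met.analytes:
        raise ConfigError(f"unknown analyte {analyte}")
    i = dataset.met.analytes.index(analyte)
    present = (dataset.met.conc_uM[i] > 0) & ~dataset.met.below_loq[i]
    n_present = int(present.sum())
    if n_present == 0:
        return None
    counts = dataset.expr.to_frame()
    expressed = (counts.loc[genes] >= min_count).any(axis=0).to_numpy()
    n_both = int((present & expressed).sum())
    return round_half_up_pct(n_both, n_present)
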