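"""Quantitative gene-metabolite analysis: Spearman correlation matrices and
rank curves, local-regression trends of expression versus concentration,
bipartite transporter-metabolite networks, z-score heatmap preparation, and
Wilcoxon rank-sum differential expression between metabolic subclusters.

Correlations pair each gene's TPM vector with each analyte's intracellular
concentration vector over the jointly profiled cells; below-LOQ entries stay
at 0 µM by default, so presence/absence of a cell-type-restricted metabolite
carries most of the signal — exactly the contrast that separates metabolites
stored where they are made from those relocated by intercellular transport.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ._loess import loess_fit
from .core_io import ConfigError, ValidationError, log


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationTable:
    """Gene x analyte Spearman rho with per-analyte gene ranks
    (1 = most positive; NA rhos excluded from ranking)."""

    rho: pd.DataFrame     # genes x analytes
    rank: pd.DataFrame    # genes x analytes, rank within analyte
    n_cells: int | pd.DataFrame
    detected_only: bool = False


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(scipy.stats.rankdata, 1, mat)


def spearman_matrix(
    tpm: pd.DataFrame,
    conc: pd.DataFrame,
    detected_only: bool = False,
) -> CorrelationTable:
    """Spearman rho between every gene (rows of ``tpm``) and every analyte
    (rows of ``conc``) over their shared cells.

    Ties get average ranks; constant vectors give NA. With
    ``detected_only`` the correlation for each analyte is restricted to the
    cells in which that analyte is nonzero.
    """
    shared = [c for c in tpm.columns if c in set(conc.columns)]
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared cells; need >= 3")
    x = tpm.loc[:, shared].to_numpy(dtype=float)
    y = conc.loc[:, shared].to_numpy(dtype=float)

    def corr_block(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
        n = xb.shape[1]
        rx = _rank_rows(xb)
        ry = _rank_rows(yb)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean(axis=1, keepdims=True)
        sx = np.sqrt((rx**2).sum(axis=1))
        sy = np.sqrt((ry**2).sum(axis=1))
        num = rx @ ry.T
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = num / np.outer(sx, sy)
        rho[sx == 0, :] = np.nan
        rho[:, sy == 0] = np.nan
        return rho

    if not detected_only:
        rho = corr_block(x, y)
        n_cells: int | pd.DataFrame = len(shared)
    else:
        cols = []
        ns = []
        for i in range(y.shape[0]):
            keep = y[i] > 0
            if keep.sum() < 3:
                cols.append(np.full(x.shape[0], np.nan))
                ns.append(int(keep.sum()))
                continue
            cols.append(corr_block(x[:, keep], y[i : i + 1, keep])[:, 0])
            ns.append(int(keep.sum()))
        rho = np.column_stack(cols)
        n_cells = pd.DataFrame({"n_cells": ns}, index=conc.index)
    rho_df = pd.DataFrame(rho, index=tpm.index, columns=conc.index)
    # rank 1 = most positive rho, per analyte, NA excluded
    rank_df = rho_df.rank(axis=0, ascending=False, method="first")
    log.info(
        "Spearman matrix %d genes x %d analytes over %s cells (detected_only=%s)",
        *rho_df.shape, n_cells if isinstance(n_cells, int) else "per-analyte", detected_only,
    )
    return CorrelationTable(rho=rho_df, rank=rank_df, n_cells=n_cells, detected_only=detected_only)


def rank_curve(
    table: CorrelationTable, analyte: str, highlight_genes: list[str] | None = None
) -> pd.DataFrame:
    """Genes ordered by descending rho for one analyte, with highlight flags."""
    if analyte not in table.rho.columns:
        raise ConfigError(f"unknown analyte {analyte}")
    series = table.rho[analyte].dropna().sort_values(ascending=False)
    out = pd.DataFrame(
        {"gene": series.index, "rho": series.to_numpy(), "rank": np.arange(1, len(series) + 1)}
    )
    highlight_genes = highlight_genes or []
    unknown = [g for g in highlight_genes if g not in set(out["gene"])]
    if unknown:
        warnings.warn(f"highlight gene(s) without a defined rho skipped: {unknown}")
    out["highlight"] = out["gene"].isin(set(highlight_genes) - set(unknown))
    return out


# ---------------------------------------------------------------------------
# Local-regression trend
# ---------------------------------------------------------------------------

@dataclass
class TrendCurve:
    """Fitted expression along a concentration grid with 95 % CI."""

    grid_conc_uM: np.ndarray
    fitted: np.ndarray
    ci_half_width: np.ndarray
    span: float
    log_axis: bool

    @property
    def peak_conc_uM(self) -> float:
        return float(self.grid_conc_uM[int(np.argmax(self.fitted))])


def loess_trend(
    conc: np.ndarray,
    tpm: np.ndarray,
    span: float = 0.75,
    grid_size: int = 100,
    log_axis: bool = True,
) -> TrendCurve:
    """Local linear regression (tricube weights) of expression on
    concentration, evaluated on an even grid over the observed range with
    pointwise 95 % CI (fit ± 1.96 SE).

    Concentrations spanning decades are fitted on the log10(1 + c) axis
    (default); the returned grid is always in µM.
    """
    conc = np.asarray(conc, dtype=float)
    tpm = np.asarray(tpm, dtype=float)
    if len(conc) != len(tpm):
        raise ValidationError("conc and tpm must align")
    if len(conc) < 10:
        raise ValidationError(
            f"only {len(conc)} cells; need >= 10 (consider relaxing presence filtering)"
        )
    x = np.log10(1.0 + conc) if log_axis else conc
    grid_x = np.linspace(x.min(), x.max(), grid_size)
    fitted, se = loess_fit(x, tpm, grid_x, span=span)
    grid_conc = 10.0**grid_x - 1.0 if log_axis else grid_x
    return TrendCurve(
        grid_conc_uM=grid_conc,
        fitted=fitted,
        ci_half_width=1.96 * se,
        span=span,
        log_axis=log_axis,
    )


# ---------------------------------------------------------------------------
# Transporter network
# ---------------------------------------------------------------------------

@dataclass
class TransporterNetwork:
    """Bipartite transporter-analyte edges selected per analyte as the
    ``top_k`` most positive and ``bottom_k`` most negative correlations."""

    edges: pd.DataFrame  # transporter, analyte, rho, sign
    degree: pd.Series    # per transporter


def build_transporter_network(
    table: CorrelationTable,
    transporters: list[str],
    top_k: int = 15,
    bottom_k: int = 15,
) -> TransporterNetwork:
    """Per analyte, connect the top_k transporters by rho ("pos" edges) and
    the bottom_k ("neg" edges); NA rhos are excluded and ties at the cutoff
    break by gene ID lexical order (logged)."""
    if not transporters:
        raise ConfigError("transporter list is empty")
    present = [t for t in transporters if t in table.rho.index]
    if not present:
        raise ConfigError("no transporter has a defined correlation")
    rows = []
    for analyte in table.rho.columns:
        sub = table.rho.loc[present, analyte].dropna()
        if sub.empty:
            continue
        ordered = sub.rename("rho").rename_axis("gene").reset_index()
        top = ordered.sort_values(["rho", "gene"], ascending=[False, True]).head(top_k)
        bottom = ordered.sort_values(["rho", "gene"], ascending=[True, True]).head(bottom_k)
        chosen: set[str] = set()
        for _, r in top.iterrows():
            rows.append((r["gene"], analyte, float(r["rho"]), "pos"))
            chosen.add(r["gene"])
        for _, r in bottom.iterrows():
            if r["gene"] in chosen:  # pool smaller than top_k + bottom_k
                continue
            rows.append((r["gene"], analyte, float(r["rho"]), "neg"))
    edges = pd.DataFrame(rows, columns=["transporter", "analyte", "rho", "sign"])
    degree = edges.groupby("transporter").size().rename("degree")
    log.info("transporter network: %d edges, %d transporters", len(edges), degree.size)
    return TransporterNetwork(edges=edges, degree=degree)


def export_network(net: TransporterNetwork, path, format: str = "sif") -> None:
    """Write the network as SIF lines (``transporter <sign> analyte``) or
    GraphML with rho edge attributes and transporter degrees."""
    if net.edges.empty:
        raise ValidationError("cannot export an empty network")
    if format == "sif":
        with open(path, "w") as fh:
            for r in net.edges.itertuples(index=False):
                fh.write(f"{r.transporter}\t{r.sign}\t{r.analyte}\n")
    elif format == "graphml":
        g = nx.Graph()
        for t, d in net.degree.items():
            g.add_node(t, kind="transporter", degree=int(d))
        for a in net.edges["analyte"].unique():
            g.add_node(a, kind="analyte")
        for r in net.edges.itertuples(index=False):
            g.add_edge(r.transporter, r.analyte, rho=float(r.rho), sign=r.sign)
        nx.write_graphml(g, path)
    else:
        raise ConfigError(f"unknown network format: {format}")


def read_network_sif(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            t, sign, a = line.rstrip("\n").split("\t")
            rows.append((t, a, sign))
    return pd.DataFrame(rows, columns=["transporter", "analyte", "sign"])


# ---------------------------------------------------------------------------
# Z-score heatmap preparation
# ---------------------------------------------------------------------------

@dataclass
class HeatmapMatrix:
    matrix: pd.DataFrame     # stacked feature x cell z-scores
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def zscore_heatmap_matrix(dataset, genes: list[str], analytes: list[str]) -> HeatmapMatrix:
    """Stack per-gene z-scores (from the lognorm layer) and per-analyte
    z-scores (from the log10 concentration layer) and hierarchically cluster
    rows and columns (average linkage, Euclidean distance)."""
    lognorm = dataset.expr.layers.get("lognorm")
    if lognorm is None:
        raise ValidationError("dataset lacks a lognorm layer; run log_normalize first")
    log10m = dataset.met_log10
    if log10m is None:
        log10m = pd.DataFrame(
            np.log10(1.0 + dataset.met.conc_uM),
            index=dataset.met.analytes,
            columns=dataset.met.cells,
        )
    missing = [g for g in genes if g not in lognorm.index] + [
        a for a in analytes if a not in log10m.index
    ]
    if missing:
        raise ConfigError(f"unknown feature(s): {missing}")
    block = pd.concat([lognorm.loc[genes], log10m.loc[analytes, lognorm.columns]])

    def zscore(df: pd.DataFrame) -> pd.DataFrame:
        mu = df.mean(axis=1)
        sd = df.std(axis=1, ddof=1)
        const = sd == 0
        if const.any():
            warnings.warn(f"constant feature(s) get all-zero z rows: {list(df.index[const])}")
        return df.sub(mu, axis=0).div(sd.replace(0.0, np.inf), axis=0)

    z = zscore(block)
    row_link = scipy.cluster.hierarchy.average(
        scipy.spatial.distance.pdist(z.to_numpy())
    )
    col_link = scipy.cluster.hierarchy.average(
        scipy.spatial.distance.pdist(z.to_numpy().T)
    )
    row_order = [z.index[i] for i in scipy.cluster.hierarchy.leaves_list(row_link)]
    col_order = [z.columns[i] for i in scipy.cluster.hierarchy.leaves_list(col_link)]
    return HeatmapMatrix(
        matrix=z, row_order=row_order, col_order=col_order,
        row_linkage=row_link, col_linkage=col_link,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    table: pd.DataFrame  # per gene: mean_a, mean_b, log2fc, statistic, p, padj


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of group assignments
    (midranks, so ties are handled); feasible for small groups."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = ranks.sum() * n_a / len(pooled)
    d_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= d_obs - 1e-9:
            count += 1
    return count / total


def wilcoxon_de(
    lognorm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    exact_max_n: int = 10,
) -> DEResult:
    """Per-gene two-sided Wilcoxon rank-sum between two disjoint cell
    groups, BH-adjusted across genes.

    Exact enumeration when both groups have <= ``exact_max_n`` cells,
    tie-corrected normal approximation otherwise. log2 fold change uses the
    de-logged group means with pseudocount 1.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValidationError(f"groups overlap: {sorted(set_a & set_b)[:5]}")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("each group needs >= 3 cells")
    xa = lognorm.loc[:, group_a].to_numpy(dtype=float)
    xb = lognorm.loc[:, group_b].to_numpy(dtype=float)
    exact = len(group_a) <= exact_max_n and len(group_b) <= exact_max_n
    stats = np.empty(lognorm.shape[0])
    pvals = np.empty(lognorm.shape[0])
    for i in range(lognorm.shape[0]):
        a, b = xa[i], xb[i]
        ranks = scipy.stats.rankdata(np.concatenate([a, b]))
        stats[i] = ranks[: len(a)].sum()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[i] = 1.0
        elif exact:
            pvals[i] = _exact_ranksum_p(a, b)
        else:
            pvals[i] = scipy.stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    mean_a = np.expm1(xa).mean(axis=1)
    mean_b = np.expm1(xb).mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "statistic": stats,
            "p": pvals,
            "padj": padj,
        },
        index=lognorm.index,
    )
    log.info(
        "Wilcoxon DE: %d genes, groups %d vs %d (%s)",
        len(table), len(group_a), len(group_b), "exact" if exact else "asymptotic",
    )
    return DEResult(table=table)
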