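"""Single-cell expression QC, TPM, log-normalization, variable genes and
pseudobulk concordance.

QC keeps picked single cells detecting strictly more than ``min_genes`` and
strictly fewer than ``max_genes`` genes (detection = raw count > 0).
Log-normalization is ln(1 + scale_factor * count / total) with scale factor
10,000; variable genes are chosen by a variance-stabilizing-transform style
criterion: a local regression of log10 variance on log10 mean predicts each
gene's expected sd, counts are standardized by it (clipped at sqrt(n_cells)),
and genes are ranked by the variance of the standardized values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._loess import loess_fit
from .core_io import ExpressionSet, ValidationError, WellRecord, WellStatus, log


@dataclass
class QCReport:
    """Per-cell detection counts and keep flags, plus summary counts."""

    per_cell: pd.DataFrame  # index well_id: genes_detected, status, kept
    min_genes: int
    max_genes: int
    n_input: int
    n_kept: int

    @property
    def retention_pct(self) -> int:
        """Percentage of input cells kept, truncated to an integer."""
        return int(100 * self.n_kept / self.n_input) if self.n_input else 0


def qc_filter(
    expr: ExpressionSet,
    wells: list[WellRecord],
    min_genes: int = 1000,
    max_genes: int = 10000,
) -> tuple[ExpressionSet, QCReport]:
    """Keep single cells with min_genes < detected genes < max_genes."""
    by_id = {w.well_id: w for w in wells}
    missing = [c for c in expr.cells if c not in by_id]
    if missing:
        raise ValidationError(f"cells lacking well metadata: {missing[:10]}")
    detected = (expr.counts > 0).sum(axis=0)
    statuses = [by_id[c].status for c in expr.cells]
    kept_mask = np.array(
        [
            s is WellStatus.SINGLE and min_genes < d < max_genes
            for s, d in zip(statuses, detected)
        ]
    )
    per_cell = pd.DataFrame(
        {
            "genes_detected": detected,
            "status": [s.value for s in statuses],
            "kept": kept_mask,
        },
        index=pd.Index(expr.cells, name="well_id"),
    )
    kept_cells = [c for c, k in zip(expr.cells, kept_mask) if k]
    report = QCReport(
        per_cell=per_cell,
        min_genes=min_genes,
        max_genes=max_genes,
        n_input=expr.n_cells,
        n_kept=len(kept_cells),
    )
    log.info(
        "QC: kept %d / %d cells (%d%%) with %d < detected genes < %d",
        report.n_kept, report.n_input, report.retention_pct, min_genes, max_genes,
    )
    return expr.subset_cells(kept_cells), report


def compute_tpm(expr: ExpressionSet) -> pd.DataFrame:
    """Transcripts per million from counts and transcript lengths.

    tpm[g, c] = 1e6 * (count/len_kb) / sum_g(count/len_kb); all-zero cells
    yield an all-zero column with a warning.
    """
    len_kb = expr.gene_length_bp / 1000.0
    rate = expr.counts / len_kb[:, None]
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) have zero counts; TPM column set to 0")
    totals = np.where(zero, 1.0, totals)
    tpm = rate / totals * 1e6
    tpm[:, zero] = 0.0
    df = pd.DataFrame(tpm, index=expr.genes, columns=expr.cells)
    expr.layers["tpm"] = df
    return df


def log_normalize(expr: ExpressionSet, scale_factor: float = 10000.0) -> pd.DataFrame:
    """ln(1 + scale_factor * count / total counts of the cell)."""
    totals = expr.counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) have zero total counts; lognorm column set to 0")
    totals = np.where(zero, 1.0, totals)
    mat = np.log1p(scale_factor * expr.counts / totals)
    mat[:, zero] = 0.0
    df = pd.DataFrame(mat, index=expr.genes, columns=expr.cells)
    expr.layers["lognorm"] = df
    return df


def select_variable_genes(
    expr: ExpressionSet, n: int = 500, span: float = 0.3
) -> list[str]:
    """Rank genes by variance standardized against a fitted mean-variance
    trend (local regression of log10 variance on log10 mean, span 0.3;
    standardized counts clipped at sqrt(n_cells)); return the top ``n``.

    Ties in standardized variance break by gene ID lexical order. Scaled
    z-scores of the selected genes are stored as layer "scaled".
    """
    counts = expr.counts.astype(float)
    n_cells = expr.n_cells
    means = counts.mean(axis=1)
    variances = counts.var(axis=1, ddof=1)
    nonconstant = variances > 0
    if nonconstant.sum() < n:
        warnings.warn(
            f"only {int(nonconstant.sum())} non-constant genes available; returning all"
        )
    fit_sd = np.zeros(expr.n_genes)
    idx = np.where(nonconstant)[0]
    if len(idx) >= 3:
        lx = np.log10(means[idx])
        ly = np.log10(variances[idx])
        fitted, _ = loess_fit(lx, ly, lx, span=span)
        fit_sd[idx] = np.sqrt(10.0 ** fitted)
    else:
        fit_sd[idx] = np.sqrt(variances[idx])

    std_var = np.zeros(expr.n_genes)
    clip = np.sqrt(n_cells)
    for i in idx:
        z = (counts[i] - means[i]) / fit_sd[i]
        z = np.clip(z, -clip, clip)
        std_var[i] = z.var(ddof=1)

    order = sorted(idx, key=lambda i: (-std_var[i], expr.genes[i]))
    selected = [expr.genes[i] for i in order[:n]]

    sel_idx = [expr.genes.index(g) for g in selected]
    sub = expr.layers["lognorm"].to_numpy()[sel_idx] if "lognorm" in expr.layers else counts[sel_idx]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    expr.layers["scaled"] = pd.DataFrame(
        (sub - mu) / sd, index=selected, columns=expr.cells
    )
    log.info("selected %d variable genes (of %d)", len(selected), expr.n_genes)
    return selected


def pseudobulk_compare(expr: ExpressionSet, bulk_profile: pd.Series) -> float:
    """Spearman rho between the TPM-normalized pseudobulk (per-gene sum of
    counts over kept cells) and a bulk expression profile, over genes
    detected in either profile."""
    shared = [g for g in expr.genes if g in bulk_profile.index]
    if len(shared) < 10:
        raise ValidationError(f"only {len(shared)} shared genes; need >= 10")
    gidx = [expr.genes.index(g) for g in shared]
    pseudo_counts = expr.counts[gidx].sum(axis=1).astype(float)
    len_kb = expr.gene_length_bp[gidx] / 1000.0
    rate = pseudo_counts / len_kb
    pseudo_tpm = rate / rate.sum() * 1e6 if rate.sum() > 0 else rate
    bulk = bulk_profile.loc[shared].to_numpy(dtype=float)
    detected = (pseudo_tpm > 0) | (bulk > 0)
    rho = scipy.stats.spearmanr(pseudo_tpm[detected], bulk[detected]).statistic
    log.info("pseudobulk vs bulk Spearman rho = %.3f over %d genes", rho, int(detected.sum()))
    return float(rho)
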