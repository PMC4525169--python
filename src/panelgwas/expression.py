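"""Expression preprocessing, variance-based gene selection, PCA and a
simplified differential-expression stage.

Transcript counts are converted to RPKM (reads per kilobase of transcript
per million mapped reads) and aggregated to gene level as the unweighted
mean over a gene's transcripts.  Sample-level structure is summarized by PCA
on the ``k`` most variable genes.  Differential expression between two
sample groups uses library-size-normalized log2 values with a (paired)
t-test and Benjamini-Hochberg adjustment; this is a deliberately simple
stage whose contrast and thresholding logic (adjusted p and minimum fold
change) mirrors standard moderated pipelines without their empirical-Bayes
variance shrinkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .tables import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


def rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    transcript_to_gene: pd.Series,
) -> ExpressionMatrix:
    """Transcript counts -> gene-level RPKM.

    ``RPKM_t = count * 1e9 / (length_t * library_size)`` per transcript and
    sample; a gene's value is the unweighted mean over its transcripts.
    ``lengths`` are transcript lengths in bp; ``transcript_to_gene`` maps
    transcript id -> gene id (every transcript must be mapped).
    """
    missing = [t for t in counts.index if t not in lengths.index]
    if missing:
        raise ValidationError(f"transcripts without length: {missing[:5]}")
    unmapped = [t for t in counts.index if t not in transcript_to_gene.index]
    if unmapped:
        raise ValidationError(f"transcripts without gene mapping: {unmapped[:5]}")
    lens = np.asarray(lengths.loc[counts.index], dtype=float)
    if (lens <= 0).any():
        raise ValidationError("transcript lengths must be positive")
    lib = np.asarray(counts.sum(axis=0), dtype=float)
    if (lib == 0).any():
        zero = [s for s, v in zip(counts.columns, lib) if v == 0]
        raise ValidationError(f"zero library size for sample(s) {zero}")
    vals = np.asarray(counts, dtype=float) * 1e9 / (lens[:, None] * lib[None, :])
    tx_rpkm = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    gene_rpkm = tx_rpkm.groupby(transcript_to_gene.loc[counts.index].values).mean()
    return ExpressionMatrix(values=gene_rpkm, unit="rpkm")


def _analysis_matrix(expr: ExpressionMatrix, scale: str, pseudocount: float = 1.0):
    vals = np.asarray(expr.values, dtype=float)
    if scale == "log2":
        return np.log2(vals + pseudocount)
    if scale == "raw":
        return vals
    raise ValueError(f"unknown scale {scale!r}")


def top_variance_genes(
    expr: ExpressionMatrix, k: int = 2000, scale: str = "log2"
) -> ExpressionMatrix:
    """Retain the ``k`` genes with the largest across-sample variance.

    Variance is computed on the analysis scale (default log2(x+1)); original
    gene order is preserved within the subset; boundary ties are broken by
    lexicographic gene id (logged).
    """
    if k > len(expr.values):
        raise ValidationError(f"k={k} exceeds number of genes ({len(expr.values)})")
    mat = _analysis_matrix(expr, scale)
    var = pd.Series(mat.var(axis=1, ddof=1), index=expr.values.index)
    order = var.to_frame("var")
    order["gene"] = order.index
    ranked = order.sort_values(["var", "gene"], ascending=[False, True],
                               kind="mergesort")
    boundary = ranked["var"].iloc[k - 1] if k >= 1 else np.nan
    if k < len(ranked) and ranked["var"].iloc[k] == boundary:
        logger.info("variance tie at the top-%d boundary broken by gene id", k)
    chosen = set(ranked.index[:k])
    sub = expr.values.loc[[g for g in expr.values.index if g in chosen]]
    return ExpressionMatrix(values=sub, unit=expr.unit, meta=expr.meta)


def pca_samples(
    expr: ExpressionMatrix,
    scale: str = "log2",
    center: bool = True,
    scale_unit_variance: bool = False,
    n_components: int | None = None,
):
    """PCA with samples as observations and genes as variables.

    Returns ``(scores, explained_fraction)``: a samples x components
    DataFrame and the fraction of variance per component (summing to <= 1,
    exactly 1 when all non-degenerate components are kept).  Genes are
    centred by default; unit-variance scaling is off by default.
    """
    mat = _analysis_matrix(expr, scale).T  # samples x genes
    n_samples, n_genes = mat.shape
    if n_samples < 2 or n_genes < 2:
        raise ValidationError("PCA needs >= 2 samples and >= 2 genes")
    if center:
        mat = mat - mat.mean(axis=0)
    if scale_unit_variance:
        sd = mat.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        mat = mat / sd
    max_comp = min(n_samples - 1 if center else n_samples, n_genes)
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(mat)
    total_var = mat.var(axis=0, ddof=1).sum()
    frac = (pca.explained_variance_ / total_var if total_var > 0
            else np.zeros(k))
    scores_df = pd.DataFrame(
        scores,
        index=expr.values.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return scores_df, frac


def differential_expression(
    expr: ExpressionMatrix,
    group_labels: pd.Series,
    paired_by: pd.Series | None = None,
    adj_p_max: float = 0.05,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Two-group differential expression on log2 values.

    ``group_labels`` maps sample id -> one of exactly two group labels (the
    second sorted label is the "treatment"; log2 fold change is treatment
    minus reference).  When ``paired_by`` maps samples to a pairing unit
    (e.g. the line measured under both treatments) a paired t-test is used.
    Values are library-size normalized (counts-per-mean-library) before the
    log transform unless ``normalize=False``.

    Returns a per-gene DataFrame with ``log2_fc, p, adj_p, passes`` where
    ``passes = (adj_p <= adj_p_max) & (|log2_fc| >= log2(min_fold))``.
    Genes with zero within-group variance in both groups get p = 1 and are
    flagged in ``zero_variance``.
    """
    labels = group_labels.loc[expr.values.columns]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {uniq}")
    ref, trt = uniq
    vals = np.asarray(expr.values, dtype=float)
    if normalize:
        lib = vals.sum(axis=0)
        if (lib == 0).any():
            raise ValidationError("zero library size during normalization")
        vals = vals / lib[None, :] * lib.mean()
    logv = np.log2(vals + pseudocount)
    a = logv[:, np.asarray(labels == trt)]
    b = logv[:, np.asarray(labels == ref)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("need >= 2 samples per group")

    if paired_by is not None:
        pa = paired_by.loc[expr.values.columns]
        units_a = pa[np.asarray(labels == trt)]
        units_b = pa[np.asarray(labels == ref)]
        if sorted(units_a) != sorted(units_b):
            raise ValidationError("pairing units differ between groups")
        order = np.argsort(np.asarray(units_a))
        a = a[:, order]
        b = b[:, np.argsort(np.asarray(units_b))]
        with np.errstate(all="ignore"):
            tstat, p = stats.ttest_rel(a, b, axis=1)
    else:
        with np.errstate(all="ignore"):
            tstat, p = stats.ttest_ind(a, b, axis=1)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    zero_var = ~np.isfinite(p)
    p = np.where(zero_var, 1.0, p)
    if zero_var.any():
        logger.warning("%d gene(s) with undefined t statistic set to p=1",
                       int(zero_var.sum()))
    adj_p = multipletests(p, method="fdr_bh")[1]
    passes = (adj_p <= adj_p_max) & (np.abs(log2_fc) >= np.log2(min_fold))
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p": p,
            "adj_p": adj_p,
            "passes": passes,
            "zero_variance": zero_var,
        },
        index=expr.values.index,
    )
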