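"""Co-expression module discovery and module evaluation.

Modules are found by maximizing Newman weighted-graph modularity over a
*sharpened* absolute Spearman correlation matrix: for each exponent ``s`` in
a grid, the edge weights are ``W = |r_s| ** s`` (self-edges removed),
modularity is maximized by recursive spectral bisection with a
Kernighan-Lin-style single-node refinement, and the partition from the
modularity-maximizing exponent is returned.  Sharpening suppresses the
background of small sample correlations (with 16 samples the null mean of
``|r_s|`` is around 0.2) while preserving genuinely co-expressed blocks, in
the spirit of modulated modularity clustering.

Two evaluation layers mirror how such modules are interrogated downstream:

* :func:`module_separation_test` -- does PCA on the module's genes separate
  the class x treatment sample groups on PC1 more than expected by chance?
  Calibrated by shuffling sample labels.
* :func:`module_variance_explained` -- how much line-level phenotypic
  variance does the module eigengene (PC1 score) explain?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.linalg import eigsh
from scipy.stats import rankdata

from .errors import InsufficientDataError, ValidationError
from .expression import _analysis_matrix, pca_samples
from .tables import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


def spearman_abs_matrix(expr_or_values) -> pd.DataFrame:
    """Gene x gene matrix of absolute Spearman correlations.

    Ties receive average ranks.  Genes constant across samples get zero
    correlation with everything (flagged in the log); the diagonal is 1.
    """
    values = (
        expr_or_values.values
        if isinstance(expr_or_values, ExpressionMatrix)
        else expr_or_values
    )
    mat = np.asarray(values, dtype=float)
    if mat.shape[1] < 3:
        raise ValidationError("need >= 3 samples for Spearman correlations")
    ranks = np.apply_along_axis(rankdata, 1, mat)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant gene(s); correlations set to 0",
                       int(constant.sum()))
        ranks[constant] += np.arange(mat.shape[1])  # placeholder, zeroed below
    with np.errstate(all="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.abs(corr)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.nan_to_num(corr, nan=0.0)
    genes = list(values.index)
    return pd.DataFrame(corr, index=genes, columns=genes)


# ---------------------------------------------------------------------------
# Newman spectral modularity

def modularity(W: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a partition (diagonal of W ignored)."""
    W = np.asarray(W, dtype=float)
    W = W - np.diag(np.diag(W))
    k = W.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += W[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _leading_eigvec(Bsub: np.ndarray, rng: np.random.Generator):
    n = Bsub.shape[0]
    if n <= 2:
        w, v = np.linalg.eigh(Bsub)
        return w[-1], v[:, -1]
    if n <= 400:
        w, v = np.linalg.eigh(Bsub)
        return w[-1], v[:, -1]
    v0 = rng.standard_normal(n)
    try:
        w, v = eigsh(Bsub, k=1, which="LA", v0=v0, maxiter=2000)
        return w[0], v[:, 0]
    except Exception:  # pragma: no cover - ARPACK fallback
        w, v = np.linalg.eigh(Bsub)
        return w[-1], v[:, -1]


def _refine(Bsub: np.ndarray, s: np.ndarray, max_passes: int = 10):
    """Greedy single-node Kernighan-Lin refinement of a bisection vector."""
    for _ in range(max_passes):
        Bs = Bsub @ s
        # gain of flipping node i: -4 s_i (Bs)_i + 4 B_ii  (x 1/4m, constant)
        gains = -4.0 * s * Bs + 4.0 * np.diag(Bsub)
        i = int(np.argmax(gains))
        if gains[i] <= 1e-12:
            break
        s[i] = -s[i]
    return s


def _split(W, k, two_m, idx, rng):
    """One spectral bisection step on the node subset ``idx``.

    Returns (idx_a, idx_b) or None if the subset is indivisible.
    """
    Wg = W[np.ix_(idx, idx)]
    kg = k[idx]
    Bsub = Wg - np.outer(kg, kg) / two_m
    # generalized modularity matrix: remove each node's total within-subset B
    Bsub = Bsub - np.diag(Bsub.sum(axis=1))
    lam, vec = _leading_eigvec(Bsub, rng)
    if lam <= 1e-10:
        return None
    s = np.where(vec >= 0, 1.0, -1.0)
    if np.all(s == s[0]):
        return None
    s = _refine(Bsub, s)
    if np.all(s == s[0]):
        return None
    dq = float(s @ Bsub @ s) / (2.0 * two_m)
    if dq <= 1e-12:
        return None
    return idx[s > 0], idx[s < 0]


def spectral_modularity_partition(W: np.ndarray, seed: int = 0) -> np.ndarray:
    """Partition nodes by recursive spectral bisection with KL refinement."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    k = W.sum(axis=1)
    two_m = k.sum()
    labels = np.zeros(n, dtype=int)
    if two_m == 0:
        return labels
    rng = np.random.default_rng(seed)
    next_label = 1
    stack = [np.arange(n)]
    final: list[np.ndarray] = []
    while stack:
        idx = stack.pop()
        if len(idx) < 2:
            final.append(idx)
            continue
        split = _split(W, k, two_m, idx, rng)
        if split is None:
            final.append(idx)
        else:
            stack.extend(split)
    for part in final:
        labels[part] = next_label
        next_label += 1
    return labels


def _leiden_partition(W: np.ndarray, seed: int) -> np.ndarray:
    """Maximize modularity with the Leiden algorithm (weighted graph)."""
    try:
        import igraph as ig
        import leidenalg as la
    except ImportError:  # pragma: no cover - fallback for minimal installs
        logger.warning("leidenalg/igraph unavailable; using spectral bisection")
        return spectral_modularity_partition(W, seed=seed)
    src, dst = np.nonzero(np.triu(W, 1) > 1e-15)
    g = ig.Graph(n=W.shape[0], edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = W[src, dst]
    part = la.find_partition(
        g, la.ModularityVertexPartition, weights="weight", seed=seed
    )
    return np.asarray(part.membership)


def null_abs_spearman_moments(n_samples: int) -> tuple[float, float]:
    """Mean and s.d. of |Spearman r| between independent genes.

    Uses the large-sample normal approximation r ~ N(0, 1/(n-1)), under
    which |r| is half-normal: mean sqrt(2/pi)/sqrt(n-1), s.d.
    sqrt((1-2/pi)/(n-1)).  At n = 16 the mean is ~0.207, matching
    simulation.
    """
    if n_samples < 4:
        raise ValidationError("need >= 4 samples for the null approximation")
    var = 1.0 / (n_samples - 1)
    mean = np.sqrt(2.0 / np.pi * var)
    sd = np.sqrt((1.0 - 2.0 / np.pi) * var)
    return float(mean), float(sd)


def _trim_to_coherent_core(C: np.ndarray, idx, threshold: float, min_size: int):
    """Iteratively drop the member least correlated with the rest.

    Stops when every remaining gene's mean |r| to the others reaches
    ``threshold``; returns [] if fewer than ``min_size`` genes survive.
    """
    idx = list(idx)
    while len(idx) >= min_size:
        block = C[np.ix_(idx, idx)]
        mean_r = (block.sum(axis=1) - 1.0) / (len(idx) - 1)
        worst = int(np.argmin(mean_r))
        if mean_r[worst] >= threshold:
            return idx
        idx.pop(worst)
    return []


@dataclass
class ModuleSet:
    """Discovered co-expression modules.

    ``modules`` maps module id -> list of gene ids (size >= ``min_size``);
    ``unassigned`` collects all remaining genes.
    """

    modules: dict[str, list[str]]
    unassigned: list[str]
    sharpness: float
    modularity: float
    min_size: int
    mean_within_abs_r: dict[str, float] = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def labels(self) -> pd.Series:
        """Gene -> module id (unassigned genes map to 'unassigned')."""
        out = {}
        for mid, genes in self.modules.items():
            for g in genes:
                out[g] = mid
        for g in self.unassigned:
            out[g] = "unassigned"
        return pd.Series(out)


def mmc_cluster(
    corr: pd.DataFrame,
    min_size: int = 15,
    sharpness_grid=tuple(range(1, 11)),
    seed: int = 0,
    n_samples: int | None = None,
    optimizer: str = "leiden",
    coherence_z: float = 2.0,
) -> ModuleSet:
    """Modularity clustering of a |Spearman| matrix over a sharpness grid.

    For each exponent ``s`` in ``sharpness_grid`` the weighted graph
    ``W = max(corr - r0, 0) ** s`` (diagonal removed) is partitioned by a
    modularity maximizer (Leiden by default, ``optimizer='spectral'`` for
    recursive spectral bisection with KL refinement); the partition with
    maximal modularity on its own graph wins.

    When ``n_samples`` is given, ``r0`` is the null mean of |Spearman r| for
    that sample size, so only correlation in excess of chance carries edge
    weight, and each community of size >= ``min_size`` is trimmed to a
    coherent core: genes are removed until every member's mean |r| to the
    rest reaches ``r0 + coherence_z * sd_null``.  Without ``n_samples`` the
    raw matrix is used and communities are reported untrimmed (useful for
    exact block-structured inputs).  Communities below ``min_size`` (or
    trimmed away) are pooled into ``unassigned``.
    """
    grid = list(sharpness_grid)
    if not grid:
        raise ValidationError("sharpness grid is empty")
    C = np.asarray(corr, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise ValidationError("correlation matrix must be square symmetric")
    if C.min() < -1e-9 or C.max() > 1 + 1e-9:
        raise ValidationError("correlation entries must lie in [0, 1]")
    if optimizer not in ("leiden", "spectral"):
        raise ValueError(f"unknown optimizer {optimizer!r}")
    genes = list(corr.index)
    if n_samples is not None:
        r0, sd_null = null_abs_spearman_moments(n_samples)
        threshold = r0 + coherence_z * sd_null
    else:
        r0, threshold = 0.0, None
    E = np.maximum(C - r0, 0.0)
    best = None
    for s in grid:
        W = E ** s
        np.fill_diagonal(W, 0.0)
        if W.sum() == 0:
            labels = np.zeros(len(genes), dtype=int)
            q = 0.0
        elif optimizer == "leiden":
            labels = _leiden_partition(W, seed=seed)
            q = modularity(W, labels)
        else:
            labels = spectral_modularity_partition(W, seed=seed)
            q = modularity(W, labels)
        logger.debug("sharpness %s -> modularity %.4f, %d communities",
                     s, q, len(np.unique(labels)))
        if best is None or q > best[0]:
            best = (q, s, labels)
    q, s, labels = best
    modules: dict[str, list[str]] = {}
    mean_r: dict[str, float] = {}
    mid = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < min_size:
            continue
        if threshold is not None:
            idx = _trim_to_coherent_core(C, idx, threshold, min_size)
            if not len(idx):
                continue
        mid += 1
        name = f"M{mid}"
        modules[name] = [genes[i] for i in idx]
        block = C[np.ix_(idx, idx)]
        off = block[~np.eye(len(idx), dtype=bool)]
        mean_r[name] = float(off.mean()) if off.size else np.nan
    assigned = {g for gs in modules.values() for g in gs}
    unassigned = [g for g in genes if g not in assigned]
    return ModuleSet(
        modules=modules,
        unassigned=unassigned,
        sharpness=float(s),
        modularity=float(q),
        min_size=min_size,
        mean_within_abs_r=mean_r,
    )


# ---------------------------------------------------------------------------
# module evaluation

@dataclass
class ModuleSeparation:
    module_genes: list[str]
    pc1_scores: pd.Series
    f_statistic: float
    p_permutation: float
    n_perm: int


def _anova_f_vectorized(z: np.ndarray, group_codes: np.ndarray, perms: np.ndarray):
    """One-way F of permuted group labels on fixed scores ``z``.

    ``perms`` is (B, n) of sample indices; row b assigns ``group_codes`` to
    ``z[perms[b]]`` -- equivalently shuffles the labels.
    """
    n = len(z)
    G = group_codes.max() + 1
    Z = z[perms]  # (B, n)
    tot = Z.sum(axis=1)
    sst = (Z ** 2).sum(axis=1) - tot ** 2 / n
    ssb = np.zeros(len(perms))
    for g in range(G):
        idx = np.flatnonzero(group_codes == g)
        sg = Z[:, idx].sum(axis=1)
        ssb += sg ** 2 / len(idx)
    ssb -= tot ** 2 / n
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (G - 1)) / (ssw / (n - G))
    return np.nan_to_num(f, nan=0.0, posinf=np.inf)


def module_separation_test(
    expr: ExpressionMatrix,
    module_genes: list[str],
    meta: SampleMetadata,
    n_perm: int = 10000,
    seed: int = 0,
    scale: str = "log2",
) -> ModuleSeparation:
    """Permutation test for class x treatment separation on a module's PC1.

    The observed statistic is the one-way F of the four class x treatment
    groups on PC1 scores of the module's genes; the null distribution is
    built by shuffling the sample labels ``n_perm`` times.  PCA scores do
    not depend on the labels, so only the F statistic is recomputed per
    shuffle.  p uses the +1 Monte-Carlo correction.
    """
    if len(module_genes) < 2:
        raise ValidationError("module must contain >= 2 genes")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p will be coarse", n_perm)
    sub = ExpressionMatrix(
        values=expr.values.loc[module_genes], unit=expr.unit, meta=meta
    )
    scores, _ = pca_samples(sub, scale=scale, n_components=1)
    z = np.asarray(scores["PC1"], dtype=float)
    groups = meta.group_labels().loc[scores.index]
    codes, uniques = pd.factorize(groups)
    sizes = pd.Series(codes).value_counts()
    if len(uniques) < 2 or (sizes < 2).any():
        raise ValidationError("each class x treatment group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    n = len(z)
    perms = np.vstack(
        [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)]
    )
    f = _anova_f_vectorized(z, codes, perms)
    f_obs = float(f[0])
    p = (1.0 + np.count_nonzero(f[1:] >= f_obs)) / (n_perm + 1.0)
    return ModuleSeparation(
        module_genes=list(module_genes),
        pc1_scores=pd.Series(z, index=scores.index),
        f_statistic=f_obs,
        p_permutation=float(p),
        n_perm=n_perm,
    )


def module_eigengene(
    expr: ExpressionMatrix,
    module_genes: list[str],
    scale: str = "log2",
) -> pd.Series:
    """PC1 score per sample over a module's genes, sign-anchored.

    The sign is fixed so the eigengene correlates positively with the
    module's mean expression, removing PCA sign ambiguity.
    """
    sub = ExpressionMatrix(values=expr.values.loc[module_genes], unit=expr.unit)
    scores, _ = pca_samples(sub, scale=scale, n_components=1)
    z = np.asarray(scores["PC1"], dtype=float)
    mean_expr = _analysis_matrix(sub, scale).mean(axis=0)
    c = np.corrcoef(z, mean_expr)[0, 1]
    if np.isfinite(c) and c < 0:
        z = -z
    return pd.Series(z, index=scores.index)


def module_variance_explained(
    expr: ExpressionMatrix,
    module_genes: list[str],
    line_means: pd.DataFrame,
    meta: SampleMetadata,
    treatment: str = "unchallenged",
    scale: str = "log2",
):
    """Phenotypic variance explained by a module eigengene across lines.

    The eigengene is computed per sample, restricted to samples of the given
    ``treatment``, averaged per line, and regressed (OLS) against angular
    line-mean phenotypes.  Returns ``(r2, n_lines)``.  With few lines the
    null expectation of R-squared is 1/(n-1); interpret small-n values
    accordingly.
    """
    eig = module_eigengene(expr, module_genes, scale=scale)
    mt = meta.table.set_index("sample_id")
    samples = [s for s in eig.index if mt.loc[s, "treatment"] == treatment]
    if not samples:
        raise InsufficientDataError(f"no samples with treatment {treatment!r}")
    per_line = (
        pd.DataFrame({"line": mt.loc[samples, "line_id"], "eig": eig.loc[samples]})
        .groupby("line")["eig"].mean()
    )
    shared = [l for l in per_line.index if l in line_means.index]
    if len(shared) < 3:
        raise InsufficientDataError(f"only {len(shared)} lines shared with phenotype")
    x = np.asarray(per_line.loc[shared], dtype=float)
    y = np.asarray(line_means.loc[shared, "mean"], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0, len(shared)
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2), len(shared)
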