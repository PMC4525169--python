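"""Non-parametric association scan over grouped multi-allelic loci.

The scan follows the rank-based arm of a panel GWAS on near-homozygous
lines: variants whose coordinates overlap (share at least one base pair on
the same chromosome, transitively) are grouped into composite loci; each
line's composite allele is the concatenation of its member alleles; loci must
retain at least two alleles each carried by at least ``min_allele_count``
lines.  Per locus, replicate phenotype measurements are pooled by allele and
compared with a tie-corrected Kruskal-Wallis test.  Significance is
calibrated by permuting the line-to-phenotype assignment as whole replicate
sets, which yields both a per-locus permutation p-value (with the +1
correction) and a permutation-based false-discovery-rate table,
FDR(t) = mean permuted hits at threshold t / observed hits, capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .errors import InsufficientDataError, ValidationError
from .tables import MISSING, GenotypeTable, PhenotypeTable

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLDS = (1e-6, 1e-5, 2e-5, 1e-4, 1e-3, 1e-2, 0.05)


@dataclass
class LocusGroup:
    """A cluster of overlapping variants treated as one multi-allelic locus."""

    locus_id: str
    chrom: str
    start: int
    end: int
    member_ids: list[str]
    labels: pd.Series  # composite allele per line; None/NaN = excluded
    allele_counts: dict = field(default_factory=dict)

    @property
    def alleles(self) -> list[str]:
        return sorted(self.allele_counts)

    @property
    def df(self) -> int:
        return len(self.allele_counts) - 1


def group_variants(
    geno: GenotypeTable, min_allele_count: int = 10
) -> list[LocusGroup]:
    """Cluster overlapping variants and apply the minor-allele-count filter.

    Lines with a missing call at any member variant are excluded from the
    group, as are lines carrying a composite allele seen fewer than
    ``min_allele_count`` times.  Groups retaining fewer than two alleles are
    dropped (tally logged).  The output partitions the retained input loci.
    """
    loci = geno.loci
    groups: list[LocusGroup] = []
    n_dropped = 0
    for chrom, sub in loci.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        cluster: list[pd.Series] = []
        cur_end = None
        for _, row in sub.iterrows():
            if cluster and row["start"] <= cur_end:
                cluster.append(row)
                cur_end = max(cur_end, row["end"])
            else:
                if cluster:
                    g = _build_group(geno, chrom, cluster, min_allele_count)
                    if g is None:
                        n_dropped += 1
                    else:
                        groups.append(g)
                cluster = [row]
                cur_end = row["end"]
        if cluster:
            g = _build_group(geno, chrom, cluster, min_allele_count)
            if g is None:
                n_dropped += 1
            else:
                groups.append(g)
    if n_dropped:
        logger.info(
            "dropped %d locus group(s) failing the >=2 alleles with "
            "count >= %d rule", n_dropped, min_allele_count
        )
    return groups


def _build_group(geno, chrom, cluster, min_allele_count) -> LocusGroup | None:
    member_ids = [row["locus_id"] for row in cluster]
    start = int(min(row["start"] for row in cluster))
    end = int(max(row["end"] for row in cluster))
    if len(member_ids) == 1:
        col = geno.alleles[member_ids[0]]
        labels = col.where(col != MISSING, other=None)
    else:
        cols = geno.alleles[member_ids]
        any_missing = (cols == MISSING).any(axis=1)
        labels = cols.apply(lambda r: "|".join(r), axis=1)
        labels = labels.where(~any_missing, other=None)
    counts = labels.value_counts(dropna=True)
    rare = counts[counts < min_allele_count].index
    if len(rare):
        labels = labels.where(~labels.isin(rare), other=None)
        counts = labels.value_counts(dropna=True)
    if len(counts) < 2:
        return None
    locus_id = member_ids[0] if len(member_ids) == 1 else f"grp:{chrom}:{start}:{end}"
    return LocusGroup(
        locus_id=locus_id,
        chrom=str(chrom),
        start=start,
        end=end,
        member_ids=member_ids,
        labels=labels,
        allele_counts=counts.to_dict(),
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis machinery

def _kw_from_samples(samples: list[np.ndarray]):
    """Tie-corrected Kruskal-Wallis H, df and asymptotic chi-square p."""
    k = len(samples)
    all_vals = np.concatenate(samples)
    n = len(all_vals)
    ranks = rankdata(all_vals)
    _, t = np.unique(all_vals, return_counts=True)
    tie = 1.0 - ((t ** 3 - t).sum()) / (n ** 3 - n) if n > 1 else 0.0
    dfree = k - 1
    if tie == 0.0:  # all values identical
        return 0.0, dfree, 1.0
    offset = 0
    h = 0.0
    for s in samples:
        r = ranks[offset: offset + len(s)]
        h += r.sum() ** 2 / len(s)
        offset += len(s)
    h = (12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)) / tie
    p = float(stats.chi2.sf(h, dfree))
    return float(h), dfree, p


@dataclass
class AssociationResult:
    locus_id: str
    H: float
    df: int
    p_asymptotic: float
    p_permutation: float | None
    n_lines: int
    group_sizes: dict


def kw_test(
    group: LocusGroup, pheno: PhenotypeTable, unit: str = "replicate"
) -> AssociationResult:
    """Kruskal-Wallis test of phenotype by composite allele at one locus.

    ``unit='replicate'`` pools every replicate measurement of each line into
    its allele group (default); ``unit='line_mean'`` uses one mean value per
    line.  Measurements are taken on the proportion scale; the test is
    rank-based and thus invariant to any strictly monotone rescaling.
    """
    samples, sizes = _allele_samples(group, pheno, unit)
    if len(samples) < 2:
        raise InsufficientDataError(
            f"locus {group.locus_id}: fewer than 2 allele groups with data"
        )
    h, dfree, p = _kw_from_samples(samples)
    return AssociationResult(
        locus_id=group.locus_id,
        H=h,
        df=dfree,
        p_asymptotic=p,
        p_permutation=None,
        n_lines=int(sum(sizes.values())),
        group_sizes=sizes,
    )


def _allele_samples(group, pheno, unit):
    if unit not in ("replicate", "line_mean"):
        raise ValueError(f"unknown unit {unit!r}")
    by_line = pheno.values_by_line("proportion")
    samples, sizes = [], {}
    for allele in group.alleles:
        lines = [
            l for l in group.labels.index
            if group.labels[l] == allele and l in by_line
        ]
        if not lines:
            continue
        if unit == "replicate":
            vals = np.concatenate([by_line[l] for l in lines])
        else:
            vals = np.array([by_line[l].mean() for l in lines])
        samples.append(vals)
        sizes[allele] = len(lines)
    return samples, sizes


# ---------------------------------------------------------------------------
# permutation GWAS

def _vectorized_kw_full(S, Msz, allele_line_idx, N, tie):
    """H for each permutation row when a group includes every shared line.

    S : (B+1, L) permuted per-line rank sums (row 0 = observed)
    Msz : (B+1, L) permuted per-line measurement counts
    allele_line_idx : list of integer index arrays, one per allele
    """
    B1 = S.shape[0]
    acc = np.zeros(B1)
    for idx in allele_line_idx:
        R = S[:, idx].sum(axis=1)
        n_g = Msz[:, idx].sum(axis=1)
        acc += R ** 2 / n_g
    h = (12.0 / (N * (N + 1)) * acc - 3.0 * (N + 1))
    if tie > 0:
        h = h / tie
    else:
        h = np.zeros_like(h)
    return h


def run_gwas(
    geno: GenotypeTable,
    pheno: PhenotypeTable,
    min_allele_count: int = 10,
    B: int = 1000,
    seed: int | None = None,
    unit: str = "replicate",
    thresholds=DEFAULT_FDR_THRESHOLDS,
):
    """Permutation-calibrated Kruskal-Wallis scan over all locus groups.

    Returns ``(assoc, fdr)``: a per-locus association table (Manhattan-ready,
    with ``-log10`` asymptotic p) and an FDR table over ``thresholds``.
    Phenotypes are permuted at the line level -- whole replicate sets move
    together -- so the within-line correlation structure is preserved under
    the null.  Deterministic given ``seed`` (required).
    """
    if seed is None:
        raise ValidationError("run_gwas requires an explicit seed")
    if B < 100:
        logger.warning("B=%d permutations; FDR estimates will be unstable", B)
    shared = [l for l in geno.line_ids if l in set(pheno.line_ids)]
    if len(shared) < 10:
        raise InsufficientDataError(
            f"only {len(shared)} lines shared between genotypes and phenotypes"
        )
    groups = group_variants(geno, min_allele_count=min_allele_count)
    if not groups:
        raise InsufficientDataError("no locus groups pass the allele-count filter")
    logger.info("testing %d locus groups on %d lines (B=%d, seed=%d)",
                len(groups), len(shared), B, seed)

    by_line = pheno.values_by_line("proportion")
    if unit == "line_mean":
        by_line = {l: np.array([v.mean()]) for l, v in by_line.items()}
    elif unit != "replicate":
        raise ValueError(f"unknown unit {unit!r}")
    line_pos = {l: i for i, l in enumerate(shared)}
    vals = np.concatenate([by_line[l] for l in shared])
    counts = np.array([len(by_line[l]) for l in shared])
    starts = np.concatenate([[0], np.cumsum(counts)])
    N_all = len(vals)

    rng = np.random.default_rng(seed)
    perms = np.vstack(
        [np.arange(len(shared))]
        + [rng.permutation(len(shared)) for _ in range(B)]
    )  # (B+1, L); row 0 = identity

    ranks_all = rankdata(vals)
    s_line = np.array(
        [ranks_all[starts[i]: starts[i + 1]].sum() for i in range(len(shared))]
    )
    _, t = np.unique(vals, return_counts=True)
    tie_all = 1.0 - ((t ** 3 - t).sum()) / (N_all ** 3 - N_all)
    S = s_line[perms]
    Msz = counts[perms].astype(float)

    p_matrix = np.empty((B + 1, len(groups)))
    rows = []
    for gi, group in enumerate(groups):
        allele_lines = {
            a: [l for l in shared if group.labels.get(l) == a]
            for a in group.alleles
        }
        allele_lines = {a: ls for a, ls in allele_lines.items() if ls}
        k = len(allele_lines)
        included = sum(len(ls) for ls in allele_lines.values())
        if k < 2:
            p_matrix[:, gi] = 1.0
            rows.append((group.locus_id, group.chrom, group.start, 0.0, 0,
                         1.0, 1.0, included, "{}"))
            continue
        dfree = k - 1
        if included == len(shared):
            idx_lists = [
                np.array([line_pos[l] for l in ls])
                for ls in allele_lines.values()
            ]
            h = _vectorized_kw_full(S, Msz, idx_lists, N_all, tie_all)
            p = stats.chi2.sf(h, dfree)
            p[h <= 0] = 1.0
        else:
            h = np.empty(B + 1)
            p = np.empty(B + 1)
            idx_lists = [
                np.array([line_pos[l] for l in ls])
                for ls in allele_lines.values()
            ]
            for b in range(B + 1):
                samples = [
                    np.concatenate([
                        vals[starts[perms[b, i]]: starts[perms[b, i] + 1]]
                        for i in idx
                    ])
                    for idx in idx_lists
                ]
                h[b], _, p[b] = _kw_from_samples(samples)
        p_obs = float(p[0])
        p_perm = (1.0 + np.count_nonzero(p[1:] <= p_obs)) / (B + 1.0)
        p_matrix[:, gi] = p
        sizes = {a: len(ls) for a, ls in allele_lines.items()}
        rows.append((group.locus_id, group.chrom, group.start, float(h[0]),
                     dfree, p_obs, p_perm, included, str(sizes)))

    assoc = pd.DataFrame(
        rows,
        columns=["locus_id", "chrom", "pos", "H", "df", "p_asymptotic",
                 "p_permutation", "n_lines", "group_sizes"],
    )
    with np.errstate(divide="ignore"):
        assoc["neglog10_p"] = -np.log10(assoc["p_asymptotic"].clip(lower=1e-300))

    fdr = fdr_table(
        np.asarray(assoc["p_asymptotic"]), p_matrix[1:], thresholds
    )
    return assoc, fdr


def fdr_table(p_obs: np.ndarray, p_perm: np.ndarray, thresholds) -> pd.DataFrame:
    """Permutation FDR over a grid of p-value thresholds.

    ``p_perm`` has one row per permutation and one column per locus.
    FDR(t) = mean over permutations of #{p_perm <= t} / #{p_obs <= t},
    capped at 1; NaN where no observed hit exists.
    """
    rows = []
    for t in sorted(thresholds):
        obs = int(np.count_nonzero(p_obs <= t))
        mean_perm = float((p_perm <= t).sum(axis=1).mean())
        fdr = min(mean_perm / obs, 1.0) if obs > 0 else np.nan
        rows.append((t, obs, mean_perm, fdr))
    return pd.DataFrame(
        rows, columns=["threshold", "observed_hits", "mean_permuted_hits", "fdr"]
    )


# ---------------------------------------------------------------------------
# parametric per-locus variance explained

@dataclass
class R2Result:
    """Variance explained by one locus as a categorical factor."""

    locus_id: str
    r2: float
    k: int
    n: int
    f_p: float
    saturated: bool = False


def single_locus_r2(group: LocusGroup, line_means: pd.DataFrame) -> R2Result:
    """R-squared of OLS of angular line means on the composite allele factor.

    ``line_means`` is a table as returned by
    :func:`panelgwas.quantgen.line_means` on the angular scale.  Returns the
    factor-regression ``SS_model / SS_total`` together with its F-test
    p-value; a design with one line per allele is flagged as saturated
    (R-squared = 1 by construction).
    """
    labels = group.labels.dropna()
    shared = [l for l in labels.index if l in line_means.index]
    y = np.asarray(line_means.loc[shared, "mean"], dtype=float)
    lab = labels.loc[shared]
    uniq = lab.unique()
    if len(uniq) < 2:
        raise InsufficientDataError(
            f"locus {group.locus_id}: fewer than 2 allele groups among lines"
        )
    n, k = len(y), len(uniq)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    ssw = 0.0
    for a in uniq:
        sub = y[np.asarray(lab == a)]
        ssw += float(((sub - sub.mean()) ** 2).sum())
    if sst == 0:
        return R2Result(group.locus_id, 0.0, k, n, 1.0, saturated=False)
    r2 = 1.0 - ssw / sst
    saturated = n <= k
    if saturated:
        logger.warning("locus %s: saturated design (n=%d, k=%d)",
                       group.locus_id, n, k)
        return R2Result(group.locus_id, 1.0, k, n, np.nan, saturated=True)
    f = (r2 / (k - 1)) / ((1 - r2) / (n - k)) if r2 < 1 else np.inf
    f_p = float(stats.f.sf(f, k - 1, n - k))
    return R2Result(group.locus_id, float(r2), k, n, f_p, saturated=False)
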