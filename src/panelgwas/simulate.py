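"""Synthetic panels with the statistical structure the analyses assume.

Every generator is deterministic given its spec's seed and returns, next to
the data table, a *truth record* sufficient to score downstream recovery
without re-simulation.

Design choices
--------------
* Phenotype liabilities live on the angular (arcsin-sqrt) scale, so the
  analysis model is exactly correct on simulated data: per line,
  ``liability = mu + sum(QTL effects) + N(0, V_line_extra)``; each replicate
  adds ``N(0, V_rep) + N(0, V_res)``; the replicate's death count is then
  Binomial(n_flies, sin^2(liability)).  On the angular scale binomial
  sampling contributes an extra ~``1/(4 n_flies)`` of replicate variance
  (the transform is variance-stabilizing), which the truth record includes
  in its expected environmental variance.
* Linkage is block-copy, not coalescent: loci within a block copy the block
  anchor's allele indicator with probability ``ld_decay``, else redraw.
* The diallel generator places effects directly in the identifiable
  parameter space (GCA sum to zero; SCA symmetric with zero row sums;
  reciprocal antisymmetric).
* Expression modules are one-factor models: module gene = sqrt(rho) * latent
  + sqrt(1-rho) * noise in log space, with class/treatment mean shifts on
  the latent factor (in within-group s.d. units); values are exponentiated
  so the matrix is positive (log-normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimSpecError
from .tables import (
    DiallelTable,
    ExpressionMatrix,
    GenotypeTable,
    PhenotypeTable,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

CHROMS = ("2L", "2R", "3L", "3R", "X")
ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))
THIRD_ALLELE = "TAA"  # non-SNP third allele label for multi-allelic loci


# ---------------------------------------------------------------------------
# panel genotypes

@dataclass
class PanelSimSpec:
    n_lines: int = 140
    n_loci: int = 100
    maf_range: tuple[float, float] = (0.15, 0.5)
    ld_block_size: int = 1
    ld_decay: float = 0.0
    frac_multiallelic: float = 0.0
    multiallelic_freq: float = 0.1
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if self.n_lines < 2:
            raise SimSpecError("n_lines must be >= 2")
        if not (0 < lo <= hi <= 0.5):
            raise SimSpecError("maf_range must lie in (0, 0.5]")
        if self.ld_block_size < 1:
            raise SimSpecError("ld_block_size must be >= 1")
        if self.n_loci < self.ld_block_size:
            raise SimSpecError("n_loci < ld_block_size")
        if not (0 <= self.ld_decay <= 1):
            raise SimSpecError("ld_decay must be in [0, 1]")
        if not (0 <= self.frac_multiallelic <= 1):
            raise SimSpecError("frac_multiallelic must be in [0, 1]")


def simulate_panel(spec: PanelSimSpec) -> GenotypeTable:
    """Generate homozygous line genotypes with block-structured LD.

    Loci are laid out 100 bp apart (non-overlapping single-base SNPs except
    multi-allelic loci, which span 3 bp), cycling across chromosome arms
    block by block.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_lines, spec.n_loci
    line_ids = [f"L{i + 1:03d}" for i in range(n)]

    n_multi = int(round(spec.frac_multiallelic * L))
    multi_set = set(rng.choice(L, size=n_multi, replace=False)) if n_multi else set()

    loci_rows = []
    allele_cols = {}
    block_id = -1
    anchor_ind = None
    for j in range(L):
        if j % spec.ld_block_size == 0:
            block_id += 1
        maf = rng.uniform(*spec.maf_range)
        ind = rng.random(n) < maf
        if j % spec.ld_block_size != 0 and anchor_ind is not None:
            copy = rng.random(n) < spec.ld_decay
            ind = np.where(copy, anchor_ind, ind)
        if j % spec.ld_block_size == 0:
            anchor_ind = ind
        major, minor = ALLELE_PAIRS[int(rng.integers(len(ALLELE_PAIRS)))]
        labels = np.where(ind, minor, major).astype(object)
        width = 1
        if j in multi_set:
            third = rng.random(n) < spec.multiallelic_freq
            labels[third] = THIRD_ALLELE
            width = 3
        chrom = CHROMS[block_id % len(CHROMS)]
        start = 1000 + (block_id // len(CHROMS)) * 1_000_000 \
            + (j % spec.ld_block_size) * 100
        locus_id = f"{chrom}:{start}"
        loci_rows.append((chrom, start, start + width - 1, locus_id))
        allele_cols[locus_id] = labels
    loci = pd.DataFrame(loci_rows, columns=["chrom", "start", "end", "locus_id"])
    alleles = pd.DataFrame(allele_cols, index=line_ids)

    # drop loci that came out monomorphic in this finite sample
    poly = [c for c in alleles.columns if alleles[c].nunique() >= 2]
    if len(poly) < len(alleles.columns):
        logger.info("panel simulation: %d monomorphic locus/loci redrawn as "
                    "dropped", len(alleles.columns) - len(poly))
    loci = loci[loci["locus_id"].isin(poly)].reset_index(drop=True)
    return GenotypeTable(line_ids=line_ids, loci=loci, alleles=alleles[poly])


# ---------------------------------------------------------------------------
# survival phenotypes

@dataclass
class PhenoSimSpec:
    """Spec for replicate-level binomial survival phenotypes.

    ``qtl_loci`` maps locus_id -> {allele label -> additive liability effect
    on the angular scale}.  ``mu`` is the grand mean liability (angular).
    """

    qtl_loci: dict = field(default_factory=dict)
    mu: float = float(np.arcsin(np.sqrt(0.5)))
    V_line_extra: float = 0.0
    V_rep: float = 0.0
    V_res: float = 0.0
    n_reps: int = 3
    n_flies_per_rep: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("V_line_extra", "V_rep", "V_res"):
            if getattr(self, name) < 0:
                raise SimSpecError(f"{name} must be >= 0")
        if self.n_reps < 1 or self.n_flies_per_rep < 1:
            raise SimSpecError("n_reps and n_flies_per_rep must be >= 1")


@dataclass
class PhenoTruth:
    """Ground truth accompanying a simulated phenotype table."""

    line_liability: pd.Series
    qtl_effects: dict
    qtl_variance: dict  # locus_id -> realized liability variance contribution
    V_line_expected: float
    V_env_expected: float  # V_rep + V_res + binomial term on angular scale
    H_expected: float
    n_clamped: int = 0


def simulate_phenotypes(
    geno: GenotypeTable, spec: PhenoSimSpec
) -> tuple[PhenotypeTable, PhenoTruth]:
    """Binomial death counts per line x replicate from additive liabilities."""
    for locus_id in spec.qtl_loci:
        if locus_id not in geno.alleles.columns:
            raise SimSpecError(f"QTL locus {locus_id} not in genotype table")
    rng = np.random.default_rng(spec.seed)
    n = geno.n_lines
    lines = geno.line_ids

    liab = np.full(n, spec.mu)
    qtl_var = {}
    for locus_id, effects in spec.qtl_loci.items():
        col = geno.alleles[locus_id]
        eff = np.array([effects.get(a, 0.0) for a in col], dtype=float)
        liab += eff
        qtl_var[locus_id] = float(eff.var())
    liab += rng.normal(0.0, np.sqrt(spec.V_line_extra), size=n)

    rep_sd = np.sqrt(spec.V_rep + spec.V_res)
    rows = []
    n_clamped = 0
    for i, line in enumerate(lines):
        for r in range(spec.n_reps):
            theta = liab[i] + rng.normal(0.0, rep_sd)
            clamped = np.clip(theta, 0.0, np.pi / 2)
            if clamped != theta:
                n_clamped += 1
            p = np.sin(clamped) ** 2
            dead = rng.binomial(spec.n_flies_per_rep, p)
            rows.append((line, f"r{r + 1}", spec.n_flies_per_rep, int(dead)))
    if n_clamped:
        logger.info("%d replicate liability value(s) clamped to [0, pi/2]",
                    n_clamped)
    pheno = PhenotypeTable(
        records=pd.DataFrame(
            rows, columns=["line_id", "replicate_id", "n_flies", "n_dead"]
        )
    )
    v_line_exp = sum(
        _expected_qtl_variance(geno.alleles[lid], eff)
        for lid, eff in spec.qtl_loci.items()
    ) + spec.V_line_extra
    binom_var = 1.0 / (4.0 * spec.n_flies_per_rep)
    v_env_exp = spec.V_rep + spec.V_res + binom_var
    v_a = v_line_exp / 2.0
    truth = PhenoTruth(
        line_liability=pd.Series(liab, index=lines),
        qtl_effects=dict(spec.qtl_loci),
        qtl_variance=qtl_var,
        V_line_expected=float(v_line_exp),
        V_env_expected=float(v_env_exp),
        H_expected=float(v_a / (v_a + v_env_exp)) if v_a + v_env_exp > 0 else 0.0,
        n_clamped=n_clamped,
    )
    return pheno, truth


def _expected_qtl_variance(col: pd.Series, effects: dict) -> float:
    freqs = col.value_counts(normalize=True)
    mean = sum(freqs.get(a, 0.0) * e for a, e in effects.items())
    return float(sum(
        freqs.get(a, 0.0) * (e - mean) ** 2 for a, e in effects.items()
    ))


# ---------------------------------------------------------------------------
# diallel crosses

def project_diallel_effects(gca, sca, rec, parents):
    """Project raw effect inputs onto the identifiable parameter space.

    Returns centred ``gca``, symmetric zero-row-sum ``sca`` and antisymmetric
    ``rec`` as pandas objects indexed by ``parents``.  Raises if ``sca`` is
    not symmetric or ``rec`` not antisymmetric.
    """
    p = len(parents)
    if isinstance(gca, (np.ndarray, list, tuple)):
        g = np.asarray(gca, dtype=float)
    else:  # dict or Series keyed by parent
        g = np.asarray([gca[parent] for parent in parents], dtype=float)
    S = np.asarray(sca, dtype=float)
    R = np.asarray(rec, dtype=float)
    if S.shape != (p, p) or R.shape != (p, p):
        raise SimSpecError("sca/rec must be p x p matrices")
    if not np.allclose(S, S.T, atol=1e-10):
        raise SimSpecError("sca matrix must be symmetric")
    if not np.allclose(R, -R.T, atol=1e-10):
        raise SimSpecError("rec matrix must be antisymmetric")
    M = g[:, None] + g[None, :] + S
    mu_shift = M.mean()
    row = M.mean(axis=1) - mu_shift
    S_id = M - mu_shift - row[:, None] - row[None, :]
    return (
        float(mu_shift),
        pd.Series(row, index=parents),
        pd.DataFrame(S_id, index=parents, columns=parents),
        pd.DataFrame(R, index=parents, columns=parents),
    )


@dataclass
class DiallelTruth:
    mu: float
    gca: pd.Series
    sca: pd.DataFrame
    rec: pd.DataFrame


def simulate_diallel(
    parents: list[str],
    gca,
    sca,
    rec,
    V_res: float = 0.0,
    n_reps: int = 3,
    mu: float = float(np.arcsin(np.sqrt(0.5))),
    seed: int = 0,
) -> tuple[DiallelTable, DiallelTruth]:
    """Full p x p diallel (selfs and reciprocals) with additive noise.

    The angular-scale phenotype of cross (dam i x sire j) is
    ``mu + gca_i + gca_j + sca_ij + rec_ij + N(0, V_res)``, back-transformed
    to a proportion.  Effects are projected onto the identifiable space;
    the projected truth is returned.
    """
    if V_res < 0:
        raise SimSpecError("V_res must be >= 0")
    p = len(parents)
    mu_shift, g, S, R = project_diallel_effects(gca, sca, rec, parents)
    mu_eff = mu + mu_shift
    rng = np.random.default_rng(seed)
    rows = []
    for i, dam in enumerate(parents):
        for j, sire in enumerate(parents):
            base = (mu_eff + g.iloc[i] + g.iloc[j]
                    + S.iloc[i, j] + R.iloc[i, j])
            for r in range(n_reps):
                y = base + rng.normal(0.0, np.sqrt(V_res))
                prop = float(np.sin(np.clip(y, 0.0, np.pi / 2)) ** 2)
                rows.append((dam, sire, f"r{r + 1}", prop))
    table = DiallelTable(
        records=pd.DataFrame(rows, columns=["dam", "sire", "replicate",
                                            "proportion"]),
        parents=list(parents),
    )
    return table, DiallelTruth(mu=mu_eff, gca=g, sca=S, rec=R)


# ---------------------------------------------------------------------------
# expression matrices

@dataclass
class ModuleSpec:
    size: int
    within_correlation: float = 0.8
    class_shift: float = 0.0
    treatment_shift: float = 0.0

    def __post_init__(self):
        if self.size < 2:
            raise SimSpecError("module size must be >= 2")
        if not (0 < self.within_correlation < 1):
            raise SimSpecError("within_correlation must lie in (0, 1)")


@dataclass
class ExprSimSpec:
    n_genes: int = 2000
    modules: list[ModuleSpec] = field(default_factory=list)
    n_lines_per_class: int = 4
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if sum(m.size for m in self.modules) > self.n_genes:
            raise SimSpecError("sum of module sizes exceeds n_genes")
        if self.n_lines_per_class < 1:
            raise SimSpecError("n_lines_per_class must be >= 1")
        if self.noise_sd <= 0:
            raise SimSpecError("noise_sd must be > 0")


def simulate_expression(
    spec: ExprSimSpec,
) -> tuple[ExpressionMatrix, SampleMetadata, pd.Series]:
    """Log-normal expression with planted correlated modules.

    Design: 2 susceptibility classes x ``n_lines_per_class`` lines x 2
    treatments, one sample per line x treatment.  Module genes load on a
    shared latent factor whose mean is shifted by +/- class_shift/2 and
    +/- treatment_shift/2 (in latent s.d. units); backgrounds are i.i.d.
    noise.  Returns the matrix, metadata and true module label per gene
    ("background" for unplanted genes).
    """
    rng = np.random.default_rng(spec.seed)
    classes = ["resistant", "susceptible"]
    treatments = ["unchallenged", "challenged"]
    meta_rows = []
    for ci, cls in enumerate(classes):
        for li in range(spec.n_lines_per_class):
            line = f"{'R' if cls == 'resistant' else 'S'}{li + 1}"
            for tr in treatments:
                meta_rows.append((f"{line}_{'uc' if tr == 'unchallenged' else 'ch'}",
                                  line, cls, tr))
    meta = SampleMetadata(
        table=pd.DataFrame(
            meta_rows,
            columns=["sample_id", "line_id", "susceptibility_class", "treatment"],
        )
    )
    n_samples = len(meta_rows)
    class_sign = np.array(
        [+0.5 if row[2] == "resistant" else -0.5 for row in meta_rows]
    )
    treat_sign = np.array(
        [+0.5 if row[3] == "challenged" else -0.5 for row in meta_rows]
    )

    gene_ids = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    log_expr = np.empty((spec.n_genes, n_samples))
    truth = np.array(["background"] * spec.n_genes, dtype=object)
    gi = 0
    for mi, mod in enumerate(spec.modules, start=1):
        shift = (mod.class_shift * class_sign
                 + mod.treatment_shift * treat_sign)
        latent = shift + rng.standard_normal(n_samples)
        rho = mod.within_correlation
        for _ in range(mod.size):
            eps = rng.standard_normal(n_samples)
            log_expr[gi] = np.sqrt(rho) * latent + np.sqrt(1 - rho) * eps
            truth[gi] = f"module{mi}"
            gi += 1
    n_bg = spec.n_genes - gi
    if n_bg:
        log_expr[gi:] = rng.standard_normal((n_bg, n_samples))
    log_expr *= spec.noise_sd
    base = rng.normal(2.0, 1.0, size=spec.n_genes)
    values = np.exp(log_expr + base[:, None])
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids,
                            columns=[r[0] for r in meta_rows]),
        unit="rpkm",
        meta=meta,
    )
    return expr, meta, pd.Series(truth, index=gene_ids)
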