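"""Core in-memory containers for panel genotypes, phenotypes and expression.

Conventions
-----------
* Genomic coordinates are 1-based closed intervals (VCF-style); ``end >= start``.
* Inbred lines are treated as (near-)homozygous, so a genotype call is a single
  allele label per line and locus.  Missing calls use the empty string
  (:data:`MISSING`) in memory and in TSV, and ``./.`` in VCF.
* Survival phenotypes are replicate-level binomial records
  ``(line, replicate, n_flies, n_dead)`` from which the proportion dead and
  its variance-stabilizing angular transform ``arcsin(sqrt(p))`` are derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyInputError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele call.
MISSING = ""

LOCUS_COLUMNS = ["chrom", "start", "end", "locus_id"]


@dataclass
class GenotypeTable:
    """Allele labels for a panel of homozygous lines at a set of loci.

    Parameters
    ----------
    line_ids:
        Ordered line identifiers (rows of :attr:`alleles`).
    loci:
        DataFrame with columns ``chrom, start, end, locus_id`` (1-based closed
        coordinates), one row per locus, in column order of :attr:`alleles`.
    alleles:
        DataFrame of allele labels (strings), indexed by line id with one
        column per ``locus_id``.  :data:`MISSING` marks a missing call.
    """

    line_ids: list[str]
    loci: pd.DataFrame
    alleles: pd.DataFrame

    def __post_init__(self):
        self.loci = self.loci.reset_index(drop=True)
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise ValidationError(f"loci table lacks columns {missing_cols}")
        if len(self.loci) == 0:
            raise EmptyInputError("genotype table contains zero loci")
        if (self.loci["end"] < self.loci["start"]).any():
            bad = self.loci.loc[self.loci["end"] < self.loci["start"], "locus_id"]
            raise ValidationError(f"locus end < start for {list(bad)}")
        if (self.loci["start"] < 1).any():
            raise ValidationError("coordinates are 1-based; start < 1 found")
        if list(self.alleles.index) != list(self.line_ids):
            raise ValidationError("alleles index does not match line_ids")
        if list(self.alleles.columns) != list(self.loci["locus_id"]):
            raise ValidationError("alleles columns do not match loci locus_ids")
        if self.loci["locus_id"].duplicated().any():
            raise ValidationError("duplicate locus_id in loci table")
        for locus_id in self.alleles.columns:
            col = self.alleles[locus_id]
            labels = set(col[col != MISSING])
            if len(labels) < 2:
                raise ValidationError(
                    f"locus {locus_id} has fewer than 2 distinct non-missing alleles"
                )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_lines(self, lines: list[str]) -> "GenotypeTable":
        """Restrict the table to ``lines`` (order preserved as given)."""
        unknown = [l for l in lines if l not in set(self.line_ids)]
        if unknown:
            raise KeyError(f"unknown lines {unknown}")
        return GenotypeTable(
            line_ids=list(lines),
            loci=self.loci.copy(),
            alleles=self.alleles.loc[lines].copy(),
        )


@dataclass
class PhenotypeTable:
    """Replicate-level survival records with derived proportions.

    :attr:`records` has columns ``line_id, replicate_id, n_flies, n_dead``
    plus derived ``proportion`` and ``angular`` (radians).
    """

    records: pd.DataFrame

    MIN_REPLICATES_EXPECTED = 3
    MIN_FLIES_EXPECTED = 20

    def __post_init__(self):
        df = self.records.copy()
        required = ["line_id", "replicate_id", "n_flies", "n_dead"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype records lack columns {missing}")
        for c in ("n_flies", "n_dead"):
            vals = np.asarray(df[c], dtype=float)
            if not np.all(np.isfinite(vals)) or not np.array_equal(
                vals, np.trunc(vals)
            ):
                raise ValidationError(f"non-integer counts in column {c}")
            df[c] = vals.astype(np.int64)
        if (df["n_flies"] <= 0).any():
            bad = df.loc[df["n_flies"] <= 0]
            raise ValidationError(f"n_flies must be positive; offending records:\n{bad}")
        if (df["n_dead"] < 0).any() or (df["n_dead"] > df["n_flies"]).any():
            bad = df.loc[(df["n_dead"] < 0) | (df["n_dead"] > df["n_flies"])]
            raise ValidationError(
                f"n_dead outside [0, n_flies]; offending records:\n{bad}"
            )
        dup = df.duplicated(subset=["line_id", "replicate_id"])
        if dup.any():
            keys = df.loc[dup, ["line_id", "replicate_id"]].to_records(index=False)
            raise ValidationError(f"duplicate (line, replicate) keys: {list(keys)}")
        df["proportion"] = df["n_dead"] / df["n_flies"]
        df["angular"] = np.arcsin(np.sqrt(df["proportion"]))
        self.records = df.reset_index(drop=True)

        reps = df.groupby("line_id").size()
        if (reps < self.MIN_REPLICATES_EXPECTED).any():
            logger.warning(
                "%d line(s) have fewer than %d replicates",
                int((reps < self.MIN_REPLICATES_EXPECTED).sum()),
                self.MIN_REPLICATES_EXPECTED,
            )
        if (df["n_flies"] < self.MIN_FLIES_EXPECTED).any():
            logger.warning(
                "%d replicate(s) have fewer than %d flies",
                int((df["n_flies"] < self.MIN_FLIES_EXPECTED).sum()),
                self.MIN_FLIES_EXPECTED,
            )

    @property
    def line_ids(self) -> list[str]:
        return list(pd.unique(self.records["line_id"]))

    def values_by_line(self, scale: str = "proportion") -> dict[str, np.ndarray]:
        """Replicate measurements grouped by line, on ``proportion`` or
        ``angular`` scale."""
        if scale not in ("proportion", "angular"):
            raise ValueError(f"unknown scale {scale!r}")
        return {
            line: np.asarray(sub[scale], dtype=float)
            for line, sub in self.records.groupby("line_id", sort=False)
        }


@dataclass
class SampleMetadata:
    """Sample annotations for an expression matrix.

    Columns: ``sample_id, line_id, susceptibility_class, treatment`` with
    ``susceptibility_class in {resistant, susceptible}`` and
    ``treatment in {unchallenged, challenged}``.
    """

    table: pd.DataFrame

    CLASSES = ("resistant", "susceptible")
    TREATMENTS = ("unchallenged", "challenged")

    def __post_init__(self):
        df = self.table.copy()
        required = ["sample_id", "line_id", "susceptibility_class", "treatment"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"sample metadata lacks columns {missing}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_ids in metadata")
        bad_class = ~df["susceptibility_class"].isin(self.CLASSES)
        if bad_class.any():
            raise ValidationError(
                f"unknown susceptibility_class values: "
                f"{sorted(df.loc[bad_class, 'susceptibility_class'].unique())}"
            )
        bad_tr = ~df["treatment"].isin(self.TREATMENTS)
        if bad_tr.any():
            raise ValidationError(
                f"unknown treatment values: "
                f"{sorted(df.loc[bad_tr, 'treatment'].unique())}"
            )
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_labels(self) -> pd.Series:
        """Class x treatment group label per sample (indexed by sample_id)."""
        df = self.table
        lab = df["susceptibility_class"] + ":" + df["treatment"]
        return pd.Series(lab.values, index=df["sample_id"].values)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with optional sample metadata.

    ``values`` is a genes x samples DataFrame of non-negative reals.  ``unit``
    tags the measurement scale (``"counts"`` or ``"rpkm"``).  When metadata is
    attached, sample columns are aligned to metadata order.
    """

    values: pd.DataFrame
    unit: str = "rpkm"
    meta: SampleMetadata | None = None
    gene_lengths: pd.Series | None = None

    def __post_init__(self):
        vals = self.values
        if (np.asarray(vals, dtype=float) < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.unit not in ("counts", "rpkm"):
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        if self.meta is not None:
            meta_samples = self.meta.sample_ids
            extra = [s for s in vals.columns if s not in set(meta_samples)]
            if extra:
                raise AlignmentError(f"samples missing from metadata: {extra}")
            absent = [s for s in meta_samples if s not in set(vals.columns)]
            if absent:
                raise AlignmentError(f"metadata samples missing from matrix: {absent}")
            self.values = vals[meta_samples]
        zero = (np.asarray(self.values, dtype=float).sum(axis=1) == 0)
        self.all_zero_genes = list(self.values.index[zero])
        if self.all_zero_genes:
            logger.warning("%d gene(s) have all-zero expression", len(self.all_zero_genes))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DiallelTable:
    """Replicate phenotypes of a full diallel cross (including selfs).

    Columns: ``dam, sire, replicate, proportion`` with proportions in [0, 1].
    """

    records: pd.DataFrame
    parents: list[str] = field(default_factory=list)

    def __post_init__(self):
        df = self.records.copy()
        required = ["dam", "sire", "replicate", "proportion"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"diallel records lack columns {missing}")
        p = np.asarray(df["proportion"], dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("diallel proportions outside [0, 1]")
        if not self.parents:
            self.parents = sorted(set(df["dam"]) | set(df["sire"]))
        seen = {(d, s) for d, s in zip(df["dam"], df["sire"])}
        absent = [
            (d, s) for d in self.parents for s in self.parents if (d, s) not in seen
        ]
        if absent:
            logger.warning("diallel grid has %d empty cell(s): %s", len(absent), absent)
        self.records = df.reset_index(drop=True)

    @property
    def n_parents(self) -> int:
        return len(self.parents)
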