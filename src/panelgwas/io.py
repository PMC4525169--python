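"""Readers and writers for the pipeline's file formats.

Formats
-------
Genotypes
    Either a minimal VCF subset (``CHROM POS ID REF ALT QUAL FILTER INFO
    FORMAT`` + sample columns, ``GT`` field only, haploid or
    homozygous-diploid calls) or a "sites" TSV with columns
    ``chrom, start, end, locus_id`` followed by one allele column per line.
    Heterozygous diploid calls are downgraded to missing with a warning,
    because panel lines are expected to be almost entirely homozygous.
Phenotypes
    TSV with columns ``line_id, replicate_id, n_flies, n_dead``.
Expression
    Genes x samples TSV (first column gene id) plus a sample metadata TSV
    with columns ``sample_id, line_id, susceptibility_class, treatment``.
Diallel
    TSV with columns ``dam, sire, replicate, proportion``.

All writers prepend ``#``-prefixed provenance comment lines (tool version and
optional parameters); all readers skip such lines.  CRLF and LF line endings
are accepted identically.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables
from .errors import EmptyInputError, ParseError, ValidationError
from .tables import (
    MISSING,
    DiallelTable,
    ExpressionMatrix,
    GenotypeTable,
    PhenotypeTable,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

VCF_MISSING = "./."
FLOAT_FORMAT = "%.15g"  # round-trips doubles to >= 12 significant digits


# ---------------------------------------------------------------------------
# helpers

def _read_text_lines(path) -> list[str]:
    text = Path(path).read_text()
    # normalize CRLF/CR to LF
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    return text.split("\n")


def _provenance_header(params: dict | None) -> str:
    from . import __version__

    lines = [f"# panelgwas {__version__}"]
    if params:
        lines.append("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items())))
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path, params: dict | None = None, index=False):
    buf = _io.StringIO()
    buf.write(_provenance_header(params))
    df.to_csv(buf, sep="\t", index=index, float_format=FLOAT_FORMAT)
    Path(path).write_text(buf.getvalue())


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path, format: str = "tsv") -> GenotypeTable:
    """Read a genotype matrix from a sites TSV or a minimal VCF.

    Monomorphic loci (fewer than two distinct non-missing alleles) are
    dropped with a warning; an :class:`EmptyInputError` is raised if no locus
    remains.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _finalize_genotypes(loci: pd.DataFrame, alleles: pd.DataFrame,
                        line_ids: list[str]) -> GenotypeTable:
    keep, dropped = [], []
    for locus_id in alleles.columns:
        col = alleles[locus_id]
        labels = set(col[col != MISSING])
        (keep if len(labels) >= 2 else dropped).append(locus_id)
    if dropped:
        logger.warning("dropping %d monomorphic locus/loci: %s",
                       len(dropped), dropped[:10])
    if not keep:
        raise EmptyInputError("no polymorphic loci remain after parsing")
    loci = loci[loci["locus_id"].isin(keep)].reset_index(drop=True)
    return GenotypeTable(line_ids=line_ids, loci=loci, alleles=alleles[keep])


def _read_genotypes_tsv(path) -> GenotypeTable:
    try:
        df = _read_tsv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse genotype TSV: {exc}") from exc
    required = ["chrom", "start", "end", "locus_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"genotype TSV header lacks columns {missing}", line_number=1)
    if len(df) == 0:
        raise EmptyInputError("genotype TSV contains zero loci")
    line_ids = [c for c in df.columns if c not in required]
    if not line_ids:
        raise ParseError("genotype TSV has no line columns", line_number=1)
    try:
        loci = pd.DataFrame({
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "locus_id": df["locus_id"],
        })
    except ValueError as exc:
        raise ParseError(f"non-integer coordinate in genotype TSV: {exc}") from exc
    blank = loci["locus_id"] == ""
    loci.loc[blank, "locus_id"] = (
        loci.loc[blank, "chrom"] + ":" + loci.loc[blank, "start"].astype(str)
        + ":" + loci.loc[blank, "end"].astype(str)
    )
    alleles = df[line_ids].T
    alleles.columns = list(loci["locus_id"])
    alleles.index = line_ids
    return _finalize_genotypes(loci, alleles, line_ids)


def _parse_gt(gt: str, alleles: list[str], line_no: int) -> str:
    """Resolve one GT call to an allele label, MISSING, or raise."""
    gt = gt.split(":")[0]
    if gt in (".", "./.", ".|."):
        return MISSING
    parts = gt.replace("|", "/").split("/")
    try:
        idx = [int(p) for p in parts if p != "."]
    except ValueError:
        raise ParseError(f"malformed GT field {gt!r}", line_number=line_no)
    if not idx:
        return MISSING
    if any(i >= len(alleles) or i < 0 for i in idx):
        raise ParseError(f"GT allele index out of range in {gt!r}", line_number=line_no)
    if len(set(idx)) > 1:
        logger.warning("line %d: heterozygous call %s recorded as missing", line_no, gt)
        return MISSING
    return alleles[idx[0]]


def _read_genotypes_vcf(path) -> GenotypeTable:
    lines = _read_text_lines(path)
    samples: list[str] | None = None
    loci_rows = []
    allele_rows = []
    n_fixed = 9
    for i, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        if raw.startswith("##"):
            continue
        if raw.startswith("#CHROM"):
            cols = raw.lstrip("#").split("\t")
            if cols[:9] != ["CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                            "FILTER", "INFO", "FORMAT"]:
                raise ParseError("malformed #CHROM header", line_number=i)
            samples = cols[9:]
            if not samples:
                raise ParseError("VCF has no sample columns", line_number=i)
            continue
        if raw.startswith("#"):
            continue
        if samples is None:
            raise ParseError("data row before #CHROM header", line_number=i)
        fields = raw.split("\t")
        if len(fields) != n_fixed + len(samples):
            raise ParseError(
                f"expected {n_fixed + len(samples)} columns, got {len(fields)}",
                line_number=i,
            )
        chrom, pos, vid, ref, alt, _qual, _filt, _info, fmt = fields[:9]
        try:
            pos = int(pos)
        except ValueError:
            raise ParseError(f"non-integer POS {pos!r}", line_number=i)
        if fmt.split(":")[0] != "GT":
            raise ParseError("FORMAT must lead with GT", line_number=i)
        allele_list = [ref] + ([] if alt in (".", "") else alt.split(","))
        start, end = pos, pos + len(ref) - 1
        locus_id = vid if vid not in (".", "") else f"{chrom}:{start}:{end}"
        loci_rows.append((chrom, start, end, locus_id))
        allele_rows.append(
            [_parse_gt(g, allele_list, i) for g in fields[9:]]
        )
    if samples is None:
        raise ParseError("no #CHROM header found", line_number=len(lines))
    if not loci_rows:
        raise EmptyInputError("VCF contains zero variant rows")
    loci = pd.DataFrame(loci_rows, columns=tables.LOCUS_COLUMNS)
    alleles = pd.DataFrame(
        np.array(allele_rows, dtype=object).T,
        index=samples,
        columns=list(loci["locus_id"]),
    )
    return _finalize_genotypes(loci, alleles, samples)


def write_genotypes(geno: GenotypeTable, path, params: dict | None = None):
    """Write a genotype table in the sites-TSV dialect."""
    df = geno.loci.copy()
    mat = geno.alleles.T
    for line in geno.line_ids:
        df[line] = mat[line].values
    _write_tsv(df, path, params=params)


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path) -> PhenotypeTable:
    df = _read_tsv(path)
    required = ["line_id", "replicate_id", "n_flies", "n_dead"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype TSV header lacks columns {missing}", line_number=1)
    for c in ("n_flies", "n_dead"):
        if not np.issubdtype(df[c].dtype, np.number):
            raise ParseError(f"non-numeric values in column {c}")
        vals = np.asarray(df[c], dtype=float)
        if not np.array_equal(vals, np.trunc(vals)):
            raise ParseError(f"non-integer counts in column {c}")
    return PhenotypeTable(records=df[required])


def write_phenotypes(pheno: PhenotypeTable, path, params: dict | None = None):
    _write_tsv(pheno.records, path, params=params)


# ---------------------------------------------------------------------------
# diallel

def read_diallel(path) -> DiallelTable:
    df = _read_tsv(path, dtype={"dam": str, "sire": str})
    required = ["dam", "sire", "replicate", "proportion"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"diallel TSV header lacks columns {missing}", line_number=1)
    return DiallelTable(records=df[required])


def write_diallel(table: DiallelTable, path, params: dict | None = None):
    _write_tsv(table.records, path, params=params)


# ---------------------------------------------------------------------------
# expression

def read_sample_metadata(path) -> SampleMetadata:
    df = _read_tsv(path, dtype=str)
    return SampleMetadata(table=df)


def read_expression(path, metadata_path, unit: str = "rpkm") -> ExpressionMatrix:
    """Read a genes x samples TSV and align columns to the metadata order."""
    meta = read_sample_metadata(metadata_path)
    df = _read_tsv(path, index_col=0)
    vals = np.asarray(df, dtype=float)
    if (vals < 0).any():
        bad = df.index[(vals < 0).any(axis=1)]
        raise ValidationError(f"negative expression values for genes {list(bad)[:5]}")
    return ExpressionMatrix(values=df, unit=unit, meta=meta)


def write_expression(expr: ExpressionMatrix, path, params: dict | None = None):
    _write_tsv(expr.values, path, params=params, index=True)


def write_sample_metadata(meta: SampleMetadata, path, params: dict | None = None):
    _write_tsv(meta.table, path, params=params)


# ---------------------------------------------------------------------------
# JSON summaries

def write_json(obj: dict, path):
    """Write a fitted-model summary as JSON (numpy scalars coerced)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
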