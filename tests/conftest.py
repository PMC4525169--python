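import numpy as np
import pandas as pd
import pytest

from panelgwas.tables import GenotypeTable, PhenotypeTable


def make_genotypes(allele_rows, loci=None, line_ids=None):
    """Build a GenotypeTable from a list of per-line allele lists.

    ``allele_rows[i][j]`` is line i's allele at locus j.  Loci default to
    non-overlapping SNPs 1 kb apart on chromosome 2L.
    """
    n_lines = len(allele_rows)
    n_loci = len(allele_rows[0])
    if line_ids is None:
        line_ids = [f"L{i + 1}" for i in range(n_lines)]
    if loci is None:
        loci = pd.DataFrame(
            [("2L", 1000 * (j + 1), 1000 * (j + 1), f"v{j + 1}")
             for j in range(n_loci)],
            columns=["chrom", "start", "end", "locus_id"],
        )
    alleles = pd.DataFrame(
        np.array(allele_rows, dtype=object),
        index=line_ids,
        columns=list(loci["locus_id"]),
    )
    return GenotypeTable(line_ids=line_ids, loci=loci, alleles=alleles)


def make_phenotypes(records):
    """PhenotypeTable from (line, replicate, n_flies, n_dead) tuples."""
    return PhenotypeTable(
        records=pd.DataFrame(
            records, columns=["line_id", "replicate_id", "n_flies", "n_dead"]
        )
    )


@pytest.fixture
def tiny_genotypes():
    # 4 lines x 2 loci; second locus tri-allelic
    return make_genotypes(
        [
            ["A", "A"],
            ["A", "C"],
            ["G", "T"],
            ["G", "C"],
        ]
    )


@pytest.fixture
def tiny_phenotypes():
    return make_phenotypes(
        [
            ("L1", "r1", 20, 5), ("L1", "r2", 20, 6), ("L1", "r3", 20, 4),
            ("L2", "r1", 20, 8), ("L2", "r2", 20, 9), ("L2", "r3", 20, 7),
            ("L3", "r1", 20, 14), ("L3", "r2", 20, 15), ("L3", "r3", 20, 13),
            ("L4", "r1", 20, 18), ("L4", "r2", 20, 17), ("L4", "r3", 20, 19),
        ]
    )
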