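"""Built-in study tables: phenotype distributions, the 351-cat three-marker
diplotype table, and the four-variant genotyping scheme table.

The count tables are transcribed as printed.  Note one internal
inconsistency of the source data, preserved deliberately: the type-A
diplotype counts sum to 243 (grand total 353) while the accompanying text
counts 241 type-A cats (total 351).  Consumers that need percentages
should report both denominators (see :mod:`cmahtype.concordance`).
"""

from __future__ import annotations

import pandas as pd

from .catalog import Catalog, load_default_catalog
from .genotypes import CohortTable, CountRow, expand_counts_table

__all__ = [
    "table1_phenotype_distribution",
    "table1_totals",
    "table3_count_rows",
    "table3_cohort",
    "table4_rows",
    "table4_cohort",
]

# --------------------------------------------------------------- Table 1
# breed, (sequenced A, B, C), (SNV-genotyped A, B, C)
_TABLE1 = [
    ("Abyssinian", 1, 1, 0, 0, 0, 0),
    ("Bengal", 0, 0, 0, 2, 0, 0),
    ("Birman", 1, 4, 0, 27, 14, 0),
    ("British Longhair", 0, 1, 0, 0, 4, 0),
    ("British Shorthair", 1, 4, 1, 5, 55, 0),
    ("Devon Rex", 0, 0, 0, 0, 1, 0),
    ("Domestic Shorthair", 0, 1, 6, 58, 16, 0),
    ("Highlander", 0, 0, 0, 0, 1, 0),
    ("Maine Coon", 2, 2, 0, 47, 2, 0),
    ("Neva Masquerade", 1, 3, 0, 6, 0, 0),
    ("Norwegian Forest", 0, 0, 0, 6, 0, 0),
    ("Oriental Shorthair", 0, 0, 0, 2, 0, 0),
    ("Persian", 1, 0, 0, 25, 3, 0),
    ("Ragdoll", 1, 14, 12, 33, 12, 0),
    ("Scottish Fold", 1, 2, 0, 4, 2, 0),
    ("Siberian", 1, 0, 1, 25, 0, 0),
    ("Turkish Angora", 4, 4, 0, 1, 0, 0),
]

_T1_COLS = ["breed", "seq_A", "seq_B", "seq_C", "geno_A", "geno_B", "geno_C"]


def table1_phenotype_distribution() -> pd.DataFrame:
    """Per-breed phenotype counts, split by sequenced vs SNV-genotyped cats."""
    return pd.DataFrame(_TABLE1, columns=_T1_COLS)


def table1_totals() -> dict[str, int]:
    """Overall phenotype counts (sequenced + genotyped) and the grand total."""
    df = table1_phenotype_distribution()
    n_a = int(df.seq_A.sum() + df.geno_A.sum())
    n_b = int(df.seq_B.sum() + df.geno_B.sum())
    n_c = int(df.seq_C.sum() + df.geno_C.sum())
    return {"A": n_a, "B": n_b, "C": n_c, "total": n_a + n_b + n_c}


# --------------------------------------------------------------- Table 3
# (row label, count, c.142G>A, c.268T>A, Δ-53, comment-column variants, breed)
_TABLE3 = [
    ("A1", 145, "GG", "TT", "NN", {}, ""),
    ("A2", 60, "GA", "TT", "NP", {}, ""),
    ("A3", 11, "GG", "TT", "NP", {}, ""),
    ("A4", 5, "GA", "TT", "NN", {}, ""),
    ("A5", 5, "GG", "TT", "PP", {}, ""),
    ("A6", 5, "GA", "TA", "NN", {}, ""),
    ("A7", 3, "GG", "TA", "NN", {}, ""),
    ("A8", 3, "GA", "TA", "PP", {}, ""),
    ("A9", 2, "AA", "TA", "NN", {}, ""),
    ("A10", 2, "AA", "TT", "NN", {}, ""),
    ("A11", 2, "GG", "TA", "NP", {}, ""),
    ("b1", 90, "AA", "AA", "PP", {}, ""),
    ("b2", 2, "GA", "AA", "PP", {}, ""),
    ("b3", 1, "GG", "AA", "PP", {}, ""),
    ("b4", 1, "AA", "AA", "NN", {}, ""),
    ("b5", 1, "AA", "AA", "NP", {}, ""),
    # the b6/b7 comment column resolves most of the c.268-wildtype B cats
    ("b6", 6, "GG", "TT", "NN", {"c.1322delT": "**"}, "Ragdoll"),
    ("b6", 2, "GG", "TT", "NN", {"c.179G>T": "TT"}, "Turkish Angora"),
    ("b6", 1, "GG", "TT", "NN", {"c.1193G>A": "AA"}, "Domestic Shorthair"),
    # one DSH type-B cat with no CMAH variant found: documented false A call
    ("b6", 1, "GG", "TT", "NN", {}, "Domestic Shorthair"),
    ("b7", 4, "GA", "TA", "NP", {"c.1322delT": "T*"}, "Ragdoll"),
    ("b7", 1, "GA", "TA", "NP", {"c.179G>T": "GT"}, "Turkish Angora"),
]

SNV3_LOCI = ("c.142G>A", "c.268T>A", "Δ-53")
#: loci filled with explicit homozygous-reference calls in the full-panel
#: cohort view (the screened cats carried no other known causal variant
#: unless the comment column says so)
FULL_PANEL_LOCI = SNV3_LOCI + (
    "c.179G>T", "c.364C>T", "c.1322delT", "c.933delA", "c.1193G>A"
)


def table3_count_rows(
    include_comment_variants: bool = True, catalog: Catalog | None = None
) -> list[CountRow]:
    """The 351-cat diplotype table as count rows (sum of counts = 353)."""
    catalog = catalog or load_default_catalog()
    loci = FULL_PANEL_LOCI if include_comment_variants else SNV3_LOCI
    rows = []
    for label, count, g142, g268, g53, extra, breed in _TABLE3:
        pattern = {}
        for vid in loci:
            v = catalog.lookup(vid)
            pattern[vid] = v.ref_allele * 2
        pattern["c.142G>A"] = g142
        pattern["c.268T>A"] = g268
        pattern["Δ-53"] = g53
        if include_comment_variants:
            pattern.update(extra)
        rows.append(
            CountRow(pattern=tuple(pattern.items()), count=count, breed=breed,
                     phenotype="B" if label.startswith("b") else "A", label=label)
        )
    return rows


def table3_cohort(
    include_comment_variants: bool = True, catalog: Catalog | None = None
) -> CohortTable:
    """Per-cat expansion of the diplotype table.

    With ``include_comment_variants`` the records carry explicit calls at
    the full causal panel (reference-homozygous unless the comment column
    states a variant), which is what the four- and six-variant schemes
    expect; without it only the three assayed markers are present.
    """
    catalog = catalog or load_default_catalog()
    cohort = expand_counts_table(
        table3_count_rows(include_comment_variants, catalog), catalog, id_prefix="t3_"
    )
    cohort.provenance = "351-cat genotyped A/B cohort (table as printed sums to 353)"
    return cohort


# --------------------------------------------------------------- Table 4
# (blood type, c.179G>T, c.268T>A, c.364C>T, c.1322delT,
#  n sequenced A, n B, n C, genotype label, breeds, theoretical-only)
_TABLE4 = [
    ("A", "GG", "TT", "CC", "TT", 9, 0, 0, "A/A", "Multiple", False),
    ("A", "GT", "TT", "CC", "TT", 1, 0, 7, "A/b", "Turkish Angora", False),
    ("A", "GG", "TA", "CC", "TT", 3, 0, 1, "A/b", "All breeds", False),
    ("A", "GG", "TT", "CC", "T*", 1, 0, 0, "A/b", "Ragdoll", False),
    ("B", "TT", "TT", "CC", "TT", 0, 4, 0, "b/b", "Turkish Angora", False),
    ("B", "GG", "AA", "CC", "TT", 0, 20, 0, "b/b", "Multiple", False),
    ("B", "GG", "TT", "CC", "**", 0, 6, 0, "b/b", "Ragdoll", False),
    ("B", "GT", "TA", "CC", "TT", 0, 1, 0, "b/b", "Neva Masquerade", False),
    ("B", "GT", "TT", "CC", "T*", 0, 0, 0, "b/b", "(theoretical)", True),
    ("B", "GG", "TA", "CC", "T*", 0, 3, 0, "b/b", "Ragdoll", False),
    ("B", "GG", "AA", "CC", "T*", 0, 1, 0, "b/b", "Scottish Fold", False),
    ("C", "GG", "TT", "TT", "TT", 0, 0, 3, "a^c/a^c", "Ragdoll", False),
    ("C", "GG", "TA", "CT", "TT", 0, 0, 5, "a^c/b", "Ragdoll", False),
    ("C", "GG", "TT", "CT", "T*", 0, 0, 4, "a^c/b", "Ragdoll", False),
]

_T4_COLS = ["blood_type", "c.179G>T", "c.268T>A", "c.364C>T", "c.1322delT",
            "n_A", "n_B", "n_C", "genotype_label", "breeds", "theoretical"]


def table4_rows() -> pd.DataFrame:
    """The four-variant genotyping scheme: 14 genotype rows."""
    return pd.DataFrame(_TABLE4, columns=_T4_COLS)


def table4_cohort(catalog: Catalog | None = None) -> CohortTable:
    """Expand the scheme table's sequenced-cat counts into per-cat records.

    Each row contributes one record per counted cat of each observed
    phenotype (so a genotype printed under type A but observed in type-C
    cats yields records of both phenotypes).
    """
    catalog = catalog or load_default_catalog()
    rows = []
    loci = ("c.179G>T", "c.268T>A", "c.364C>T", "c.1322delT")
    for i, r in enumerate(_TABLE4):
        pattern = tuple(zip(loci, r[1:5]))
        for pheno, count in zip(("A", "B", "C"), r[5:8]):
            if count:
                rows.append(CountRow(pattern=pattern, count=count, breed=r[9],
                                     phenotype=pheno, label=f"r{i + 1}"))
    cohort = expand_counts_table(rows, catalog, id_prefix="t4_")
    cohort.provenance = "sequenced cats arranged by four-variant scheme genotype"
    return cohort
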