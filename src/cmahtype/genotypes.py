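"""Per-sample multi-locus genotype containers and table I/O.

The on-disk dialect mirrors the notation used in published feline blood
typing tables: tab-separated with header
``sample_id  breed  phenotype  <variant_id> ...`` and two-character genotype
cells such as ``GA``, ``T*`` or ``NP``; ``--`` or an empty cell means a
missing call.  VCF input is matched to the catalog by the ID column only,
since the catalog carries cDNA rather than genomic coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import Catalog, VariantDef, load_default_catalog

__all__ = [
    "MultiLocusGenotype",
    "CohortTable",
    "CountRow",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "expand_counts_table",
    "read_vcf_by_id",
    "normalize_call",
]

logger = logging.getLogger(__name__)

PHENOTYPES = ("A", "B", "C", "unknown")
MISSING_TOKENS = {"", "--", ".", "./.", "NA"}

Call = tuple[str, str]


def normalize_call(pair: Iterable[str], variant: VariantDef) -> Call:
    """Order-normalize an unphased allele pair (reference allele first)."""
    a, b = tuple(pair)
    for allele in (a, b):
        if allele not in variant.alleles:
            raise ValueError(
                f"invalid allele {allele!r} for {variant.variant_id} "
                f"(expected {variant.ref_allele!r} or {variant.alt_allele!r})"
            )
    if a == variant.alt_allele and b == variant.ref_allele:
        return (b, a)
    return (a, b)


@dataclass
class MultiLocusGenotype:
    """One cat's unphased genotype calls across catalog variants."""

    sample_id: str
    breed: str = ""
    observed_phenotype: str = "unknown"
    calls: dict[str, Call | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observed_phenotype not in PHENOTYPES:
            raise ValueError(f"bad phenotype {self.observed_phenotype!r}")

    def call(self, variant_id: str) -> Call | None:
        return self.calls.get(variant_id)

    def alt_dosage(self, variant: VariantDef) -> int | None:
        """Count of alternate alleles at ``variant`` (None if missing)."""
        pair = self.calls.get(variant.variant_id)
        if pair is None:
            return None
        return sum(1 for a in pair if a == variant.alt_allele)


@dataclass
class CohortTable:
    records: list[MultiLocusGenotype]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def variant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            for vid in r.calls:
                seen.setdefault(vid)
        return list(seen)

    def subset(self, phenotype: str) -> "CohortTable":
        return CohortTable(
            [r for r in self.records if r.observed_phenotype == phenotype],
            provenance=f"{self.provenance} [phenotype={phenotype}]",
        )

    def to_dataframe(self) -> pd.DataFrame:
        vids = self.variant_ids()
        rows = []
        for r in self.records:
            row = {"sample_id": r.sample_id, "breed": r.breed,
                   "phenotype": r.observed_phenotype}
            for vid in vids:
                pair = r.calls.get(vid)
                row[vid] = "--" if pair is None else "".join(pair)
            rows.append(row)
        return pd.DataFrame(rows, columns=["sample_id", "breed", "phenotype"] + vids)

    def validate(self, catalog: Catalog) -> list[str]:
        problems = []
        for r in self.records:
            for vid, pair in r.calls.items():
                if vid not in catalog:
                    problems.append(f"{r.sample_id}: unknown variant {vid}")
                    continue
                if pair is None:
                    continue
                v = catalog.lookup(vid)
                for allele in pair:
                    if allele not in v.alleles:
                        problems.append(f"{r.sample_id}: invalid allele {allele!r} at {vid}")
        return problems


def read_genotype_tsv(path: str | Path, catalog: Catalog | None = None) -> CohortTable:
    """Parse a genotype TSV into a cohort, validating against the catalog.

    Unknown variant columns and out-of-catalog alleles are hard errors;
    unparseable cells (wrong length) become missing calls with a warning.
    """
    catalog = catalog or load_default_catalog()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "breed"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    has_pheno = "phenotype" in df.columns
    meta_cols = set(required) | {"phenotype"}
    variant_cols = [c for c in df.columns if c not in meta_cols]
    for col in variant_cols:
        if col not in catalog:
            raise ValueError(f"unknown variant column {col!r}")

    records = []
    for i, row in df.iterrows():
        calls: dict[str, Call | None] = {}
        for col in variant_cols:
            cell = str(row[col]).strip()
            if cell in MISSING_TOKENS:
                calls[col] = None
                continue
            if len(cell) != 2:
                logger.warning("line %d: unparseable cell %r at %s -> missing",
                               i + 2, cell, col)
                calls[col] = None
                continue
            try:
                calls[col] = normalize_call(cell, catalog.lookup(col))
            except ValueError as exc:
                raise ValueError(f"line {i + 2}: {exc}") from None
        pheno = str(row["phenotype"]).strip() if has_pheno else "unknown"
        if pheno in ("", "-", "--"):
            pheno = "unknown"
        records.append(
            MultiLocusGenotype(sample_id=str(row["sample_id"]), breed=str(row["breed"]),
                               observed_phenotype=pheno, calls=calls)
        )
    return CohortTable(records, provenance=str(path))


def write_genotype_tsv(cohort: CohortTable, path: str | Path) -> None:
    cohort.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CountRow:
    """A count-style table row: a genotype pattern shared by ``count`` cats."""

    pattern: dict[str, str] | tuple  # variant_id -> two-character genotype
    count: int
    breed: str = ""
    phenotype: str = "unknown"
    label: str = ""  # e.g. the printed diplotype row name

    def pattern_dict(self) -> dict[str, str]:
        return dict(self.pattern)


def expand_counts_table(
    rows: Sequence[CountRow],
    catalog: Catalog | None = None,
    id_prefix: str = "cat",
) -> CohortTable:
    """Expand count-style rows into one record per cat.

    Sample ids are synthesized as ``<prefix><serial>`` (optionally suffixed
    with the row label), so the total equals the sum of counts.
    """
    catalog = catalog or load_default_catalog()
    records = []
    serial = 0
    for row in rows:
        if row.count < 0:
            raise ValueError(f"negative count in row {row.label or row.pattern}")
        for _ in range(row.count):
            serial += 1
            calls: dict[str, Call | None] = {}
            for vid, cell in row.pattern_dict().items():
                if cell in MISSING_TOKENS:
                    calls[vid] = None
                else:
                    calls[vid] = normalize_call(cell, catalog.lookup(vid))
            tag = f"_{row.label}" if row.label else ""
            records.append(
                MultiLocusGenotype(sample_id=f"{id_prefix}{serial:04d}{tag}",
                                   breed=row.breed, observed_phenotype=row.phenotype,
                                   calls=calls)
            )
    return CohortTable(records, provenance="expanded counts table")


def read_vcf_by_id(path: str | Path, catalog: Catalog | None = None) -> CohortTable:
    """Build a cohort from a VCF whose ID fields name catalog variants.

    Sites whose ID matches no catalog entry are skipped with a warning;
    REF/ALT strings are cross-checked against the catalog where both are
    single bases.  Genotypes use allele indices (0=ref, 1=alt); half-missing
    or fully missing genotypes become missing calls.
    """
    from cyvcf2 import VCF  # heavy import kept local

    catalog = catalog or load_default_catalog()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls_by_sample: dict[str, dict[str, Call | None]] = {s: {} for s in samples}
    n_used = 0
    for rec in vcf:
        vid = rec.ID
        if vid is None or vid not in catalog:
            logger.warning("skipping VCF site with unmatched ID %r", vid)
            continue
        v = catalog.lookup(vid)
        if (len(rec.REF) == 1 and rec.ALT and len(rec.ALT[0]) == 1
                and (rec.REF, rec.ALT[0]) != (v.ref_allele, v.alt_allele)):
            logger.warning("VCF REF/ALT %s>%s disagree with catalog for %s; "
                           "using catalog alleles by index", rec.REF, rec.ALT[0], vid)
        n_used += 1
        for sample, gt in zip(samples, rec.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                calls_by_sample[sample][vid] = None
            else:
                pair = tuple(v.alt_allele if i else v.ref_allele for i in (a1, a2))
                calls_by_sample[sample][vid] = normalize_call(pair, v)
    if n_used == 0:
        logger.warning("no usable sites: no VCF ID matched the catalog")
    records = [
        MultiLocusGenotype(sample_id=s, calls=calls_by_sample[s]) for s in samples
    ]
    return CohortTable(records, provenance=str(path))
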