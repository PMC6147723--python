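"""CMAH variant and haplotype catalog.

The feline AB blood group system (phenotypes A, B and C) is controlled by
*CMAH*, the enzyme converting NeuAc (the B antigen) into NeuGc (the A
antigen).  Loss-of-function variants on both chromosomes abolish NeuGc
synthesis and give type B; the partial-activity variant c.364C>T (the
``a_c`` allele) gives type C when paired with another non-functional allele.

This module holds the built-in catalog of observed *CMAH* coding/regulatory
variants together with the named haplotype backgrounds on which the causal
variants segregate, plus validation and flat-file round-tripping.  All
coordinates are cDNA positions counted from the ATG in exon 1a
(GenBank EF127684.1); the alternate exon-1b numbering (shift of -3) is
recorded as metadata only and never used for matching.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "VariantDef",
    "HaplotypeDef",
    "Catalog",
    "load_default_catalog",
    "validate_catalog",
    "CAUSAL_B_VARIANTS",
    "CAUSAL_AC_VARIANTS",
]

#: variant ids whose alternate allele defines a non-functional b allele
CAUSAL_B_VARIANTS = frozenset(
    {"c.179G>T", "c.268T>A", "c.933delA", "c.1193G>A", "c.1322delT"}
)
#: variant ids whose alternate allele defines the partial-activity a^c allele
CAUSAL_AC_VARIANTS = frozenset({"c.364C>T"})

EFFECT_CLASSES = ("neutral", "deleterious", "frameshift", "not_applicable")
ALLELE_ASSOCIATIONS = ("b", "a_c", "none")


@dataclass(frozen=True)
class VariantDef:
    """One catalog entry: a single *CMAH* nsSNV or indel.

    ``alt_allele`` uses ``*`` for a deleted base (so the genotype of a cat
    heterozygous for c.1322delT is the two-character string ``T*``) and the
    18-bp upstream indel is modeled as a biallelic presence/absence marker
    with alleles ``N`` (absent) / ``P`` (present).
    """

    variant_id: str
    region: str
    ref_allele: str
    alt_allele: str
    protein_effect: str = "unknown"
    effect_class: str = "neutral"
    allele_association: str = "none"
    first_reported: str = "previously_described"

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"{self.variant_id}: alleles must be single characters")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"{self.variant_id}: bad effect_class {self.effect_class!r}")
        if self.allele_association not in ALLELE_ASSOCIATIONS:
            raise ValueError(
                f"{self.variant_id}: bad allele_association {self.allele_association!r}"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class HaplotypeDef:
    """A named chromosome background labeled with a blood-group allele.

    ``allele_map`` pins the allele carried at each *causal* variant; loci
    not listed are wildcards (their phase on published backgrounds is not
    fully determined, so only causal loci constrain matching).
    """

    name: str
    allele_label: str  # "A", "b" or "a_c"
    allele_map: dict[str, str] = field(default_factory=dict)
    breeds: str = ""

    def allele_at(self, variant: VariantDef) -> str | None:
        """Pinned allele at ``variant``, or None if unconstrained."""
        return self.allele_map.get(variant.variant_id)


@dataclass
class Catalog:
    variants: list[VariantDef]
    haplotypes: list[HaplotypeDef]
    numbering_note: str = (
        "cDNA positions from the ATG in exon 1a (EF127684.1); alternate "
        "exon-1b transcript numbering is shifted by -3 and is not used."
    )

    def __post_init__(self) -> None:
        self._by_id = {v.variant_id: v for v in self.variants}

    def lookup(self, variant_id: str) -> VariantDef:
        try:
            return self._by_id[variant_id]
        except KeyError:
            raise KeyError(f"unknown variant {variant_id!r}") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._by_id

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def causal_variants(self) -> list[VariantDef]:
        return [v for v in self.variants if v.allele_association != "none"]

    def haplotype(self, name: str) -> HaplotypeDef:
        for h in self.haplotypes:
            if h.name == name:
                return h
        raise KeyError(f"unknown haplotype {name!r}")

    # ---------------------------------------------------------------- I/O
    def to_tsv(self, variants_path: str | Path, haplotypes_path: str | Path) -> None:
        """Export the catalog as two flat TSV files."""
        with open(variants_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["variant_id", "region", "ref", "alt", "protein_effect",
                 "effect_class", "allele_association", "first_reported"]
            )
            for v in self.variants:
                w.writerow(
                    [v.variant_id, v.region, v.ref_allele, v.alt_allele,
                     v.protein_effect, v.effect_class, v.allele_association,
                     v.first_reported]
                )
        with open(haplotypes_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["name", "allele_label", "allele_map", "breeds"])
            for h in self.haplotypes:
                amap = ";".join(f"{k}={v}" for k, v in sorted(h.allele_map.items()))
                w.writerow([h.name, h.allele_label, amap, h.breeds])

    @classmethod
    def from_tsv(cls, variants_path: str | Path, haplotypes_path: str | Path) -> "Catalog":
        variants = []
        with open(variants_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                variants.append(
                    VariantDef(
                        variant_id=row["variant_id"], region=row["region"],
                        ref_allele=row["ref"], alt_allele=row["alt"],
                        protein_effect=row["protein_effect"],
                        effect_class=row["effect_class"],
                        allele_association=row["allele_association"],
                        first_reported=row["first_reported"],
                    )
                )
        haplotypes = []
        with open(haplotypes_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                amap = {}
                if row["allele_map"]:
                    for item in row["allele_map"].split(";"):
                        k, _, v = item.partition("=")
                        amap[k] = v
                haplotypes.append(
                    HaplotypeDef(name=row["name"], allele_label=row["allele_label"],
                                 allele_map=amap, breeds=row["breeds"])
                )
        return cls(variants=variants, haplotypes=haplotypes)


def validate_catalog(catalog: Catalog) -> list[str]:
    """Return a list of invariant-violation messages (empty iff valid)."""
    problems: list[str] = []
    seen: set[str] = set()
    for v in catalog.variants:
        if v.variant_id in seen:
            problems.append(f"duplicate id: {v.variant_id}")
        seen.add(v.variant_id)
        expected = (
            "b" if v.variant_id in CAUSAL_B_VARIANTS
            else "a_c" if v.variant_id in CAUSAL_AC_VARIANTS
            else "none"
        )
        if v.allele_association != expected:
            problems.append(
                f"{v.variant_id}: allele_association {v.allele_association!r}, "
                f"expected {expected!r}"
            )
        if v.allele_association != "none" and v.effect_class == "neutral":
            problems.append(
                f"{v.variant_id}: causal variant cannot be effect_class 'neutral'"
            )
    causal_ids = {v.variant_id for v in catalog.variants if v.allele_association != "none"}
    for h in catalog.haplotypes:
        for vid in h.allele_map:
            if vid not in seen:
                problems.append(f"haplotype {h.name}: unknown variant {vid}")
        if h.allele_label not in ("A", "b", "a_c"):
            problems.append(f"haplotype {h.name}: bad allele_label {h.allele_label!r}")
            continue
        # count causal alt alleles pinned on this background
        n_alt = 0
        for vid, allele in h.allele_map.items():
            if vid in causal_ids and vid in catalog:
                if allele == catalog.lookup(vid).alt_allele:
                    n_alt += 1
        if h.allele_label == "A" and n_alt != 0:
            problems.append(f"haplotype {h.name}: A background carries a causal alt allele")
        if h.allele_label in ("b", "a_c") and n_alt != 1:
            problems.append(
                f"haplotype {h.name}: expected exactly one causal alt allele, found {n_alt}"
            )
    return problems


def _default_variants() -> list[VariantDef]:
    new = "this_study"
    prev = "previously_described"
    rows: list[tuple] = [
        # (id, region, ref, alt, protein, effect_class, association, reported)
        ("Δ-53", "5'UTR", "N", "P", "unknown", "not_applicable", "none", prev),
        ("c.139C>T", "exon 2", "C", "T", "p.Arg47Cys", "neutral", "none", prev),
        ("c.142G>A", "exon 2", "G", "A", "p.Val48Met", "neutral", "none", prev),
        ("c.179G>T", "exon 2", "G", "T", "p.Gly60Val", "deleterious", "b", prev),
        ("c.187A>G", "exon 2", "A", "G", "p.Ile63Val", "neutral", "none", prev),
        ("c.268T>A", "exon 3", "T", "A", "p.Tyr90Asn", "deleterious", "b", prev),
        ("c.327A>C", "exon 4", "A", "C", "p.Glu109Asp", "neutral", "none", prev),
        ("c.364C>T", "exon 4", "C", "T", "p.Pro122Ser", "deleterious", "a_c", prev),
        ("c.374C>T", "exon 4", "C", "T", "p.Ser125Leu", "neutral", "none", new),
        ("c.376G>A", "exon 4", "G", "A", "p.Glu126Lys", "neutral", "none", new),
        ("c.593A>C", "exon 5", "A", "C", "p.His198Pro", "deleterious", "none", new),
        ("c.868A>C", "exon 8", "A", "C", "p.Thr290Pro", "neutral", "none", new),
        ("c.898A>G", "exon 8", "A", "G", "p.Lys300Glu", "neutral", "none", new),
        ("c.933delA", "exon 8", "A", "*", "p.Ala312Hisfs*6", "frameshift", "b", new),
        ("c.1193G>A", "unknown", "G", "A", "p.Trp398*", "deleterious", "b", new),
        ("c.1322delT", "exon 11", "T", "*", "p.Leu441*", "frameshift", "b", new),
        ("c.1342G>A", "exon 11", "G", "A", "p.Val448Ile", "neutral", "none", new),
        ("c.1603G>A", "exon 12", "G", "A", "p.Asp535Asn", "deleterious", "none", prev),
    ]
    return [
        VariantDef(variant_id=r[0], region=r[1], ref_allele=r[2], alt_allele=r[3],
                   protein_effect=r[4], effect_class=r[5], allele_association=r[6],
                   first_reported=r[7])
        for r in rows
    ]


def _wildtype_causal_map() -> dict[str, str]:
    return {
        "c.179G>T": "G", "c.268T>A": "T", "c.364C>T": "C",
        "c.933delA": "A", "c.1193G>A": "G", "c.1322delT": "T",
    }


def _default_haplotypes() -> list[HaplotypeDef]:
    def background(label: str, causal_alt: str | None, alt_allele: str | None,
                   name: str, breeds: str) -> HaplotypeDef:
        amap = _wildtype_causal_map()
        if causal_alt is not None:
            amap[causal_alt] = alt_allele  # type: ignore[assignment]
        return HaplotypeDef(name=name, allele_label=label, allele_map=amap, breeds=breeds)

    return [
        background("A", None, None, "A", "all breeds (wildtype background)"),
        background("b", "c.268T>A", "A", "b_common",
                   "all breeds except Turkish Angora and Ragdoll"),
        background("b", "c.179G>T", "T", "b_turkish",
                   "Turkish Angora (and related breeds); some DSH"),
        background("b", "c.1322delT", "*", "b_ragdoll", "Ragdoll"),
        background("b", "c.933delA", "*", "b_dsh_933", "one DSH"),
        background("b", "c.1193G>A", "A", "b_dsh_1193", "one DSH"),
        background("a_c", "c.364C>T", "T", "ac_ragdoll", "Ragdoll"),
    ]


_DEFAULT: Catalog | None = None


def load_default_catalog() -> Catalog:
    """Return the validated built-in catalog (18 variants, 7 haplotypes)."""
    global _DEFAULT
    if _DEFAULT is None:
        cat = Catalog(variants=_default_variants(), haplotypes=_default_haplotypes())
        problems = validate_catalog(cat)
        if problems:  # pragma: no cover - corrupted build guard
            raise RuntimeError("built-in catalog failed validation:\n" + "\n".join(problems))
        _DEFAULT = cat
    return _DEFAULT
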