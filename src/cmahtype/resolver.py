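"""Diplotype resolution: enumerate haplotype pairs consistent with an
unphased multi-locus genotype.

Strict mode pairs only the published haplotype backgrounds, each carrying
exactly one causal variant (co-occurring heterozygous causal variants are
assumed in trans — compound heterozygosity).  Relaxed (allow-cis) mode
additionally admits synthetic haplotypes carrying several causal variants,
which is needed for rare genotypes with three causal alleles (e.g. a cat
homozygous alternate at c.268T>A that also carries one c.1322delT allele).
Enumeration is exhaustive over unordered pairs and serves as the
independent oracle for the rule engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement, product

from .catalog import Catalog, HaplotypeDef, load_default_catalog
from .genotypes import MultiLocusGenotype

__all__ = ["Diplotype", "enumerate_compatible_diplotypes", "phenotype_of_allele_pair"]


@dataclass(frozen=True)
class Diplotype:
    """An unordered pair of named haplotypes with its allele-pair label."""

    pair: tuple[str, str]  # haplotype names, sorted
    allele_pair: tuple[str, str]  # from {"A", "b", "a_c"}, sorted

    @property
    def phenotype(self) -> str:
        return phenotype_of_allele_pair(self.allele_pair)


def phenotype_of_allele_pair(pair: tuple[str, str]) -> str:
    """Dominance map A > a_c >= b: A/- is A, b/b is B, a_c/- otherwise C."""
    if "A" in pair:
        return "A"
    if "a_c" in pair:
        return "C"
    return "B"


def _compatible(
    g: MultiLocusGenotype, h1: HaplotypeDef, h2: HaplotypeDef, catalog: Catalog
) -> bool:
    """True iff the pair reproduces g's called genotypes at all causal loci.

    Loci without a call in ``g`` and loci unconstrained on either haplotype
    are wildcards.
    """
    for v in catalog.causal_variants():
        pair = g.call(v.variant_id)
        if pair is None:
            continue
        a1 = h1.allele_at(v)
        a2 = h2.allele_at(v)
        if a1 is None or a2 is None:
            continue
        if tuple(sorted((a1, a2))) != tuple(sorted(pair)):
            return False
    return True


def _synthetic_haplotypes(catalog: Catalog) -> list[HaplotypeDef]:
    """All 2^k allele assignments over the k causal loci, labeled by content.

    A background carrying any fully non-functional (b-class) variant is
    labeled ``b`` even if it also carries c.364C>T; one carrying only
    c.364C>T is ``a_c``; one carrying none is ``A``.
    """
    causal = catalog.causal_variants()
    haps = []
    for bits in product((0, 1), repeat=len(causal)):
        amap = {}
        label = "A"
        has_b = has_ac = False
        for bit, v in zip(bits, causal):
            amap[v.variant_id] = v.alt_allele if bit else v.ref_allele
            if bit:
                if v.allele_association == "b":
                    has_b = True
                else:
                    has_ac = True
        if has_b:
            label = "b"
        elif has_ac:
            label = "a_c"
        name = "syn_" + "".join(str(b) for b in bits)
        haps.append(HaplotypeDef(name=name, allele_label=label, allele_map=amap,
                                 breeds="synthetic (allow-cis enumeration)"))
    return haps


def enumerate_compatible_diplotypes(
    g: MultiLocusGenotype,
    catalog: Catalog | None = None,
    *,
    allow_cis: bool = False,
) -> list[Diplotype]:
    """Every unordered haplotype pair consistent with ``g``.

    An empty list means no pair of (published, or with ``allow_cis``
    synthetic) haplotypes explains the genotype.  Ambiguity is returned as
    multiple candidates, never collapsed.
    """
    catalog = catalog or load_default_catalog()
    haps = _synthetic_haplotypes(catalog) if allow_cis else catalog.haplotypes
    out = []
    for h1, h2 in combinations_with_replacement(haps, 2):
        if _compatible(g, h1, h2, catalog):
            out.append(
                Diplotype(
                    pair=tuple(sorted((h1.name, h2.name))),
                    allele_pair=tuple(sorted((h1.allele_label, h2.allele_label))),
                )
            )
    return out
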