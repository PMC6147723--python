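"""Offspring prediction and incompatibility risk from parental blood-group
genotypes.

Each parent transmits either of its two alleles with probability 1/2,
independently.  Phenotypes follow the dominance hierarchy A > a_c >= b.
Neonatal isoerythrolysis (NI) risk is flagged for type-B dams only: type-B
cats carry strong naturally occurring anti-A alloantibodies, so nursing
type-A or type-C kittens are at risk of hemolysis.  Anti-B alloantibodies
in type-A dams are rare and weak and are reported as a note, not a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product

from .resolver import phenotype_of_allele_pair

__all__ = ["ParentGenotype", "OffspringDistribution", "offspring_distribution", "ni_risk"]

ALLELES = ("A", "b", "a_c")

_PARSE = {"a": "A", "A": "A", "b": "b", "ac": "a_c", "a^c": "a_c", "a_c": "a_c", "c": "a_c"}


@dataclass(frozen=True)
class ParentGenotype:
    """An unordered allele pair from {A, b, a_c}."""

    allele_pair: tuple[str, str]

    def __post_init__(self) -> None:
        for a in self.allele_pair:
            if a not in ALLELES:
                raise ValueError(f"invalid allele symbol {a!r}")
        object.__setattr__(self, "allele_pair", tuple(sorted(self.allele_pair)))

    @classmethod
    def parse(cls, text: str) -> "ParentGenotype":
        """Parse notations like ``A/b``, ``b/b``, ``a^c/b`` or ``ac/ac``."""
        parts = text.replace(" ", "").split("/")
        if len(parts) != 2:
            raise ValueError(f"cannot parse genotype {text!r} (expected e.g. 'A/b')")
        try:
            pair = tuple(_PARSE[p] for p in parts)
        except KeyError as exc:
            raise ValueError(f"invalid allele symbol {exc.args[0]!r} in {text!r}") from None
        return cls(pair)  # type: ignore[arg-type]

    @property
    def phenotype(self) -> str:
        return phenotype_of_allele_pair(self.allele_pair)

    def __str__(self) -> str:
        return "/".join("a^c" if a == "a_c" else a for a in self.allele_pair)


@dataclass
class OffspringDistribution:
    genotype_probs: dict[tuple[str, str], Fraction]
    phenotype_probs: dict[str, Fraction]


def offspring_distribution(
    dam: ParentGenotype, sire: ParentGenotype
) -> OffspringDistribution:
    """Exact offspring genotype and phenotype distribution (Punnett square)."""
    geno: dict[tuple[str, str], Fraction] = {}
    for a1, a2 in product(dam.allele_pair, sire.allele_pair):
        pair = tuple(sorted((a1, a2)))
        geno[pair] = geno.get(pair, Fraction(0)) + Fraction(1, 4)
    pheno: dict[str, Fraction] = {"A": Fraction(0), "B": Fraction(0), "C": Fraction(0)}
    for pair, p in geno.items():
        pheno[phenotype_of_allele_pair(pair)] += p
    return OffspringDistribution(genotype_probs=geno, phenotype_probs=pheno)


def ni_risk(dam: ParentGenotype, sire: ParentGenotype) -> tuple[bool, float, str]:
    """Neonatal isoerythrolysis risk for a mating.

    Returns ``(risk_flag, p_incompatible, note)``: the flag is raised iff
    the dam is type B and some offspring can be type A or C (those kittens
    would ingest colostral anti-A); ``p_incompatible`` is that probability.
    """
    dist = offspring_distribution(dam, sire)
    p_ac_offspring = float(dist.phenotype_probs["A"] + dist.phenotype_probs["C"])
    if dam.phenotype == "B":
        flag = p_ac_offspring > 0
        note = ("type-B dam: strong anti-A alloantibodies expected"
                if flag else "type-B dam but no type-A/C offspring possible")
        return flag, p_ac_offspring if flag else 0.0, note
    note = ""
    if dam.phenotype == "A" and float(dist.phenotype_probs["B"]) > 0:
        note = ("low severity: type-A dams rarely carry weak anti-B "
                "alloantibodies; type-B offspring possible")
    return False, 0.0, note
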