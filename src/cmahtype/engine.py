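"""Rule-based blood-type calling from unphased *CMAH* genotypes.

Four deterministic genotyping schemes are provided:

``LEGACY2``
    The historical two-marker screen (c.142G>A and the upstream indel
    Δ-53): predict B iff c.142 is homozygous alternate or Δ-53 is
    homozygous present.  Neither marker is causal; this rule is the
    reconstruction of the legacy screening practice and exists to quantify
    its error rate.
``SNV3``
    The three-marker assay panel (c.142G>A, c.268T>A, Δ-53): predict B iff
    c.268 is homozygous alternate; c.142/Δ-53 are carried as annotations.
``SCHEME4``
    The proposed causal panel: c.179G>T, c.268T>A, c.364C>T, c.1322delT.
``EXTENDED6``
    SCHEME4 plus the rare b variants c.933delA and c.1193G>A.

For the causal schemes the decision rule is the allele dosage form of the
dominance hierarchy A > a_c >= b: with ``b`` the total alternate dosage
over b-associated loci and ``ac`` the dosage at c.364C>T,

* type A  if b + ac <= 1 (at least one fully functional A allele remains),
* type C  if ac >= 1 and b + ac >= 2 (an a_c allele paired with any other
  non-functional allele),
* type B  otherwise (b >= 2).

Missing genotypes: a call is emitted only when every possible completion
of the missing loci yields the same phenotype; otherwise the sample is
``unresolved``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .catalog import Catalog, load_default_catalog
from .genotypes import CohortTable, MultiLocusGenotype

__all__ = [
    "Scheme",
    "SCHEMES",
    "BloodTypeCall",
    "count_causal_alleles",
    "call_blood_type",
    "apply_scheme",
]


@dataclass(frozen=True)
class Scheme:
    name: str
    loci: tuple[str, ...]


SCHEMES: dict[str, Scheme] = {
    "LEGACY2": Scheme("LEGACY2", ("c.142G>A", "Δ-53")),
    "SNV3": Scheme("SNV3", ("c.142G>A", "c.268T>A", "Δ-53")),
    "SCHEME4": Scheme("SCHEME4", ("c.179G>T", "c.268T>A", "c.364C>T", "c.1322delT")),
    "EXTENDED6": Scheme(
        "EXTENDED6",
        ("c.179G>T", "c.268T>A", "c.364C>T", "c.1322delT", "c.933delA", "c.1193G>A"),
    ),
}

AC_LOCUS = "c.364C>T"


def get_scheme(name: str) -> Scheme:
    key = name.upper()
    if key not in SCHEMES:
        raise KeyError(f"unknown scheme {name!r} (choose from {sorted(SCHEMES)})")
    return SCHEMES[key]


@dataclass
class BloodTypeCall:
    phenotype: str  # "A", "B", "C" or "unresolved"
    allele_pair_label: str  # "A/A", "A/b", "A/a^c", "b/b", "a^c/b", "a^c/a^c", "?"
    warnings: list[str] = field(default_factory=list)


def count_causal_alleles(
    g: MultiLocusGenotype, scheme: Scheme, catalog: Catalog | None = None
) -> tuple[int, int, int]:
    """Alternate-allele dosages over the scheme's causal loci.

    Returns ``(b_count, ac_count, n_missing)`` where ``b_count`` sums alt
    dosage over b-associated scheme loci, ``ac_count`` is the alt dosage at
    c.364C>T (0 if not in the scheme) and ``n_missing`` counts scheme loci
    without a genotype call.
    """
    catalog = catalog or load_default_catalog()
    b = ac = missing = 0
    for vid in scheme.loci:
        v = catalog.lookup(vid)
        dose = g.alt_dosage(v)
        if dose is None:
            missing += 1
            continue
        if v.allele_association == "b":
            b += dose
        elif v.allele_association == "a_c":
            ac += dose
    return b, ac, missing


def _phenotype_of(b: int, ac: int) -> str:
    if b + ac <= 1:
        return "A"
    if ac >= 1:
        return "C"
    return "B"


def _label_of(b: int, ac: int) -> str:
    # cap combined dosage at the two available haplotypes
    if b + ac <= 1:
        return "A/A" if b + ac == 0 else ("A/b" if b == 1 else "A/a^c")
    if ac >= 2:
        return "a^c/a^c"
    if ac == 1:
        return "a^c/b"
    return "b/b"


def call_blood_type(
    b_count: int,
    ac_count: int,
    n_missing: int,
    *,
    ac_locus_missing: bool = False,
) -> BloodTypeCall:
    """Turn causal-allele dosages into a blood-type call.

    With missing loci the phenotype is called only when it is forced, i.e.
    identical under every completion of the missing genotypes (each missing
    locus may contribute 0-2 further b alleles; a missing c.364C>T may
    contribute a_c alleles).
    """
    warnings: list[str] = []
    if b_count + ac_count > 2:
        warnings.append(
            "more causal alleles than haplotypes — possible cis configuration "
            f"(raw b={b_count}, a^c={ac_count})"
        )
    if n_missing > 0:
        phenos = set()
        extra_b_max = 2 * n_missing
        extra_ac_max = 2 if ac_locus_missing else 0
        for eb, eac in product(range(extra_b_max + 1), range(extra_ac_max + 1)):
            phenos.add(_phenotype_of(b_count + eb, ac_count + eac))
        if len(phenos) > 1:
            return BloodTypeCall("unresolved", "?",
                                 warnings + [f"{n_missing} scheme locus/loci missing"])
        warnings.append(f"call forced despite {n_missing} missing locus/loci")
    pheno = _phenotype_of(b_count, ac_count)
    return BloodTypeCall(pheno, _label_of(b_count, ac_count), warnings)


def _call_legacy2(g: MultiLocusGenotype, catalog: Catalog) -> BloodTypeCall:
    d142 = g.alt_dosage(catalog.lookup("c.142G>A"))
    d53 = g.alt_dosage(catalog.lookup("Δ-53"))
    observed = [d for d in (d142, d53) if d is not None]
    n_missing = 2 - len(observed)
    if any(d == 2 for d in observed):
        call = BloodTypeCall("B", "b/b", [])
        if n_missing:
            call.warnings.append(f"call forced despite {n_missing} missing locus/loci")
        return call
    if n_missing:
        return BloodTypeCall("unresolved", "?", [f"{n_missing} scheme locus/loci missing"])
    label = "A/b" if any(d == 1 for d in observed) else "A/A"
    return BloodTypeCall("A", label, [])


def _call_single(g: MultiLocusGenotype, scheme: Scheme, catalog: Catalog) -> BloodTypeCall:
    if scheme.name == "LEGACY2":
        return _call_legacy2(g, catalog)
    b, ac, missing = count_causal_alleles(g, scheme, catalog)
    ac_missing = AC_LOCUS in scheme.loci and g.call(AC_LOCUS) is None
    call = call_blood_type(b, ac, missing, ac_locus_missing=ac_missing)

    if scheme.name == "SNV3":
        # c.142 / Δ-53 are assay companions, annotated when divergent
        d142 = g.alt_dosage(catalog.lookup("c.142G>A"))
        d53 = g.alt_dosage(catalog.lookup("Δ-53"))
        if call.phenotype == "A" and (d142 == 2 or d53 == 2):
            call.warnings.append("legacy markers (c.142G>A/Δ-53) divergent from call")
    if scheme.name in ("SCHEME4", "EXTENDED6") and call.phenotype == "A":
        v179 = catalog.lookup("c.179G>T")
        if g.alt_dosage(v179) == 1 and call.allele_pair_label == "A/b":
            call.warnings.append("possible type C (heterozygous c.179G>T)")
    return call


def apply_scheme(
    cohort: CohortTable | MultiLocusGenotype,
    scheme: Scheme | str,
    catalog: Catalog | None = None,
) -> list[BloodTypeCall]:
    """Call blood types for every record, order-preserving."""
    catalog = catalog or load_default_catalog()
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if isinstance(cohort, MultiLocusGenotype):
        return [_call_single(cohort, scheme, catalog)]
    return [_call_single(g, scheme, catalog) for g in cohort]
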