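import pytest

from cmahtype import load_default_catalog
from cmahtype.tables import table3_cohort


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def t3_cohort(catalog):
    """Full-panel per-cat expansion of the 351-cat diplotype table."""
    return table3_cohort(include_comment_variants=True, catalog=catalog)


@pytest.fixture(scope="session")
def t3_cohort_raw(catalog):
    """Three-marker-only view of the same cohort."""
    return table3_cohort(include_comment_variants=False, catalog=catalog)


def make_genotype(catalog, sample_id="x", breed="", phenotype="unknown",
                  fill_causal_ref=True, **genotype_cells):
    """Build a MultiLocusGenotype from cells like ``{'c.268T>A': 'TA'}``.

    With ``fill_causal_ref`` every causal locus not mentioned gets an
    explicit homozygous-reference call (so diplotype enumeration is fully
    constrained).
    """
    from cmahtype import MultiLocusGenotype
    from cmahtype.genotypes import normalize_call

    calls = {}
    if fill_causal_ref:
        for v in catalog.causal_variants():
            calls[v.variant_id] = (v.ref_allele, v.ref_allele)
    for vid, cell in genotype_cells.items():
        if cell is None:
            calls[vid] = None
        else:
            calls[vid] = normalize_call(cell, catalog.lookup(vid))
    return MultiLocusGenotype(sample_id=sample_id, breed=breed,
                              observed_phenotype=phenotype, calls=calls)
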