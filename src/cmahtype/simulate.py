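"""Synthetic cohort simulation under Hardy-Weinberg haplotype sampling.

Each simulated cat belongs to a breed drawn from ``breed_mix``, receives
two haplotypes i.i.d. from its breed's haplotype frequencies, and its
genotype at every catalog locus is the union of the two haplotype alleles
(loci a background leaves unconstrained are taken as reference).  The true
phenotype follows the dominance map of the two blood-group allele labels.
Genotyping error, when enabled, replaces each locus's genotype with one of
the other two possible genotypes uniformly at random — a deliberately
simple symmetric model providing a robustness knob.

The bundled default breed profile is illustrative only: it qualitatively
mirrors a European diagnostic-lab case mix (b-rich British Shorthair, the
partial-activity a_c background confined to Ragdolls, Turkish backgrounds
confined to Turkish Angora) and makes no biological frequency claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import Catalog, load_default_catalog
from .genotypes import Call, CohortTable, MultiLocusGenotype, normalize_call
from .resolver import phenotype_of_allele_pair

__all__ = ["SimulationConfig", "simulate_cohort", "DEFAULT_BREED_PROFILE"]

#: Illustrative, non-biological breed-stratified haplotype frequencies.
DEFAULT_BREED_PROFILE: dict[str, dict[str, float]] = {
    "Domestic Shorthair": {"A": 0.82, "b_common": 0.14, "b_turkish": 0.02,
                           "b_dsh_933": 0.01, "b_dsh_1193": 0.01},
    "British Shorthair": {"A": 0.40, "b_common": 0.60},
    "Ragdoll": {"A": 0.55, "b_common": 0.15, "b_ragdoll": 0.18, "ac_ragdoll": 0.12},
    "Maine Coon": {"A": 0.90, "b_common": 0.10},
    "Birman": {"A": 0.70, "b_common": 0.30},
    "Turkish Angora": {"A": 0.35, "b_turkish": 0.65},
}

DEFAULT_BREED_MIX: dict[str, float] = {
    "Domestic Shorthair": 0.30, "British Shorthair": 0.18, "Ragdoll": 0.18,
    "Maine Coon": 0.14, "Birman": 0.12, "Turkish Angora": 0.08,
}


@dataclass
class SimulationConfig:
    """Cohort simulation parameters.

    ``haplotype_freqs`` is either a flat mapping (one stratum) or a
    per-breed mapping used together with ``breed_mix``.  The seed is
    mandatory: simulated cohorts are reproducible by construction.
    """

    n: int
    haplotype_freqs: dict = field(
        default_factory=lambda: {b: dict(f) for b, f in DEFAULT_BREED_PROFILE.items()}
    )
    genotyping_error_rate: float = 0.0
    seed: int | None = None
    breed_mix: dict[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_BREED_MIX)
    )

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 <= self.genotyping_error_rate < 1.0:
            raise ValueError("genotyping_error_rate must be in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self._stratified():
            if self.breed_mix is None:
                raise ValueError("per-breed haplotype_freqs require breed_mix")
            _check_simplex(self.breed_mix, "breed_mix")
            for breed, freqs in self.haplotype_freqs.items():
                _check_simplex(freqs, f"haplotype_freqs[{breed}]")
            missing = set(self.breed_mix) - set(self.haplotype_freqs)
            if missing:
                raise ValueError(f"breeds without haplotype frequencies: {sorted(missing)}")
        else:
            _check_simplex(self.haplotype_freqs, "haplotype_freqs")

    def _stratified(self) -> bool:
        return any(isinstance(v, dict) for v in self.haplotype_freqs.values())


def _check_simplex(freqs: dict[str, float], name: str) -> None:
    vals = np.array(list(freqs.values()), dtype=float)
    if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name}: frequencies must be non-negative and sum to 1")


def _genotype_from_haplotypes(h1, h2, catalog: Catalog) -> dict[str, Call]:
    calls: dict[str, Call] = {}
    for v in catalog.variants:
        a1 = h1.allele_at(v) or v.ref_allele
        a2 = h2.allele_at(v) or v.ref_allele
        calls[v.variant_id] = normalize_call((a1, a2), v)
    return calls


def simulate_cohort(cfg: SimulationConfig, catalog: Catalog | None = None) -> CohortTable:
    """Draw a genotyped, phenotyped cohort; deterministic given the seed."""
    catalog = catalog or load_default_catalog()
    rng = np.random.default_rng(cfg.seed)

    if cfg._stratified():
        breeds = sorted(cfg.breed_mix)  # type: ignore[arg-type]
        mix = np.array([cfg.breed_mix[b] for b in breeds])  # type: ignore[index]
        breed_draw = rng.choice(len(breeds), size=cfg.n, p=mix)
        strata = {b: cfg.haplotype_freqs[b] for b in breeds}
    else:
        breeds = [""]
        breed_draw = np.zeros(cfg.n, dtype=int)
        strata = {"": cfg.haplotype_freqs}

    # pre-resolve haplotype objects and per-stratum probability vectors
    hap_tables = {}
    for breed, freqs in strata.items():
        names = sorted(freqs)
        hap_tables[breed] = (
            [catalog.haplotype(nm) for nm in names],
            np.array([freqs[nm] for nm in names], dtype=float),
        )

    # genotype substitution alternatives per variant: the three genotypes
    geno_space = {
        v.variant_id: [
            (v.ref_allele, v.ref_allele),
            (v.ref_allele, v.alt_allele),
            (v.alt_allele, v.alt_allele),
        ]
        for v in catalog.variants
    }

    records = []
    for i in range(cfg.n):
        breed = breeds[breed_draw[i]]
        haps, probs = hap_tables[breed]
        i1, i2 = rng.choice(len(haps), size=2, p=probs)
        h1, h2 = haps[i1], haps[i2]
        calls = _genotype_from_haplotypes(h1, h2, catalog)
        pheno = phenotype_of_allele_pair(
            tuple(sorted((h1.allele_label, h2.allele_label)))
        )
        if cfg.genotyping_error_rate > 0:
            for vid in calls:
                if rng.random() < cfg.genotyping_error_rate:
                    options = [gt for gt in geno_space[vid] if gt != calls[vid]]
                    calls[vid] = options[rng.integers(len(options))]
        records.append(
            MultiLocusGenotype(sample_id=f"sim{i:05d}", breed=breed,
                               observed_phenotype=pheno, calls=dict(calls))
        )
    return CohortTable(records, provenance=f"simulated (seed={cfg.seed}, n={cfg.n})")
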