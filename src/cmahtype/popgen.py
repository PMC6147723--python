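"""Allele-frequency estimation under Hardy-Weinberg with dominance.

With allele frequencies (p_A, p_b, p_ac) on the 3-simplex and random
mating, the phenotype frequencies follow from the dominance hierarchy
A > a_c >= b:

    f_B = p_b**2
    f_C = p_ac**2 + 2 p_ac p_b          # a_c/a_c and a_c/b
    f_A = 1 - f_B - f_C                 # any genotype carrying an A allele

Because f_B and f_B + f_C are monotone one-to-one functions of p_b and
p_b + p_ac, the maximum-likelihood estimator from a multinomial phenotype
count triple has the closed form

    p_b  = sqrt(n_B / N)
    p_ac = sqrt((n_B + n_C) / N) - p_b
    p_A  = 1 - p_b - p_ac.

An EM estimator over the latent genotype counts is provided as an
independent numerical check of the closed form, together with direct
allele counting from genotype-called cohorts and a percentile bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import Catalog, load_default_catalog
from .engine import Scheme, apply_scheme
from .genotypes import CohortTable

__all__ = [
    "AlleleFreqs",
    "PhenotypeCounts",
    "expected_phenotype_freqs",
    "freqs_from_phenotypes",
    "em_freqs_from_phenotypes",
    "freqs_from_genotypes",
    "bootstrap_freqs",
]

_TOL = 1e-9


@dataclass(frozen=True)
class AlleleFreqs:
    """A point on the (p_A, p_b, p_ac) simplex."""

    p_A: float
    p_b: float
    p_ac: float

    def __post_init__(self) -> None:
        for name, p in (("p_A", self.p_A), ("p_b", self.p_b), ("p_ac", self.p_ac)):
            if not -_TOL <= p <= 1 + _TOL:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if abs(self.p_A + self.p_b + self.p_ac - 1.0) > 1e-6:
            raise ValueError("allele frequencies must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_A, self.p_b, self.p_ac)


@dataclass(frozen=True)
class PhenotypeCounts:
    n_A: int
    n_B: int
    n_C: int

    def __post_init__(self) -> None:
        if min(self.n_A, self.n_B, self.n_C) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_A + self.n_B + self.n_C


def expected_phenotype_freqs(p: AlleleFreqs) -> tuple[float, float, float]:
    """Hardy-Weinberg phenotype frequencies (f_A, f_B, f_C)."""
    f_B = p.p_b**2
    f_C = p.p_ac**2 + 2.0 * p.p_ac * p.p_b
    return (1.0 - f_B - f_C, f_B, f_C)


def freqs_from_phenotypes(c: PhenotypeCounts) -> AlleleFreqs:
    """Closed-form maximum-likelihood allele frequencies from a count triple."""
    n = c.total
    if n == 0:
        raise ValueError("cannot estimate from zero counts")
    p_b = math.sqrt(c.n_B / n)
    p_ac = math.sqrt((c.n_B + c.n_C) / n) - p_b
    p_A = 1.0 - p_b - p_ac
    # clamp rounding dust at the simplex boundary
    return AlleleFreqs(p_A=max(p_A, 0.0), p_b=p_b, p_ac=max(p_ac, 0.0))


def _loglik(c: PhenotypeCounts, p: AlleleFreqs) -> float:
    ll = 0.0
    for n_k, f_k in zip((c.n_A, c.n_B, c.n_C), expected_phenotype_freqs(p)):
        if n_k:
            ll += n_k * math.log(max(f_k, 1e-300))
    return ll


def em_freqs_from_phenotypes(
    c: PhenotypeCounts, tol: float = 1e-12, max_iter: int = 1000
) -> tuple[AlleleFreqs, int, list[float], bool]:
    """EM over latent genotype counts; converges to the closed-form MLE.

    E-step: apportion n_A among A/A, A/b, A/a_c and n_C among a_c/a_c,
    a_c/b by current Hardy-Weinberg posteriors (n_B is purely b/b).
    M-step: gene counting.  Returns (estimate, iterations, log-likelihood
    trace, converged).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = c.total
    if n == 0:
        raise ValueError("cannot estimate from zero counts")
    pA, pb, pac = 1 / 3, 1 / 3, 1 / 3
    trace = [_loglik(c, AlleleFreqs(pA, pb, pac))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected genotype counts
        wA = np.array([pA * pA, 2 * pA * pb, 2 * pA * pac])
        sA = wA.sum()
        gAA, gAb, gAac = (c.n_A * wA / sA) if sA > 0 else (c.n_A, 0.0, 0.0)
        wC = np.array([pac * pac, 2 * pac * pb])
        sC = wC.sum()
        gacac, gacb = (c.n_C * wC / sC) if sC > 0 else (c.n_C, 0.0)
        gbb = float(c.n_B)
        # M-step: allele counting over 2n genes
        pA_new = (2 * gAA + gAb + gAac) / (2 * n)
        pb_new = (gAb + 2 * gbb + gacb) / (2 * n)
        pac_new = (gAac + 2 * gacac + gacb) / (2 * n)
        delta = max(abs(pA_new - pA), abs(pb_new - pb), abs(pac_new - pac))
        pA, pb, pac = pA_new, pb_new, pac_new
        trace.append(_loglik(c, AlleleFreqs(pA, pb, pac)))
        if delta < tol:
            converged = True
            break
    return AlleleFreqs(pA, pb, pac), it, trace, converged


_LABEL_ALLELES = {
    "A/A": ("A", "A"), "A/b": ("A", "b"), "A/a^c": ("A", "a_c"),
    "b/b": ("b", "b"), "a^c/b": ("a_c", "b"), "a^c/a^c": ("a_c", "a_c"),
}


def freqs_from_genotypes(
    cohort: CohortTable, scheme: Scheme | str, catalog: Catalog | None = None
) -> tuple[AlleleFreqs, dict[str, int], int]:
    """Direct allele counting from rule-engine calls on a genotyped cohort.

    Returns (frequencies, per-allele counts, number of unresolved samples
    excluded from counting).
    """
    catalog = catalog or load_default_catalog()
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    calls = apply_scheme(cohort, scheme, catalog)
    counts = {"A": 0, "b": 0, "a_c": 0}
    n_unresolved = 0
    for call in calls:
        alleles = _LABEL_ALLELES.get(call.allele_pair_label)
        if alleles is None:
            n_unresolved += 1
            continue
        for a in alleles:
            counts[a] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no resolved samples to count")
    return (
        AlleleFreqs(counts["A"] / total, counts["b"] / total, counts["a_c"] / total),
        counts,
        n_unresolved,
    )


def bootstrap_freqs(
    c: PhenotypeCounts,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for the closed-form estimator."""
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap intervals")
    rng = np.random.default_rng(seed)
    n = c.total
    probs = np.array([c.n_A, c.n_B, c.n_C], dtype=float) / n
    draws = rng.multinomial(n, probs, size=n_boot)
    ests = np.array(
        [freqs_from_phenotypes(PhenotypeCounts(*map(int, d))).as_tuple() for d in draws]
    )
    lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    out = {}
    for i, name in enumerate(("p_A", "p_b", "p_ac")):
        out[name] = (float(np.percentile(ests[:, i], lo)),
                     float(np.percentile(ests[:, i], hi)))
    return out
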