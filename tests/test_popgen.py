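"""Hardy-Weinberg estimators: closed form, EM cross-check, genotype-based
counting and bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmahtype import (
    AlleleFreqs,
    PhenotypeCounts,
    SimulationConfig,
    bootstrap_freqs,
    em_freqs_from_phenotypes,
    expected_phenotype_freqs,
    freqs_from_genotypes,
    freqs_from_phenotypes,
    simulate_cohort,
)


class TestClosedForm:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((100, 0, 0), (1.0, 0.0, 0.0)),
            ((0, 100, 0), (0.0, 1.0, 0.0)),
        ],
    )
    def test_boundaries(self, counts, expected):
        f = freqs_from_phenotypes(PhenotypeCounts(*counts))
        assert f.as_tuple() == pytest.approx(expected, abs=1e-12)

    def test_study_totals(self):
        f = freqs_from_phenotypes(PhenotypeCounts(255, 146, 20))
        assert f.p_b == pytest.approx(math.sqrt(146 / 421))
        assert f.p_ac == pytest.approx(math.sqrt(166 / 421) - math.sqrt(146 / 421))
        assert f.as_tuple() == pytest.approx((0.372, 0.589, 0.039), abs=5e-4)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            freqs_from_phenotypes(PhenotypeCounts(0, 0, 0))

    def test_scaling_invariance(self):
        f1 = freqs_from_phenotypes(PhenotypeCounts(12, 7, 3))
        f2 = freqs_from_phenotypes(PhenotypeCounts(12 * 17, 7 * 17, 3 * 17))
        assert f1.as_tuple() == pytest.approx(f2.as_tuple(), abs=1e-12)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    p_b=st.floats(0.01, 0.95),
    p_ac_frac=st.floats(0.01, 0.95),
)
def test_round_trip_identity_on_simplex_interior(p_b, p_ac_frac):
    """freqs_from_phenotypes inverts expected_phenotype_freqs exactly."""
    p_ac = (1.0 - p_b) * p_ac_frac * 0.9
    p = AlleleFreqs(1.0 - p_b - p_ac, p_b, p_ac)
    f_a, f_b, f_c = expected_phenotype_freqs(p)
    # feed the exact expected fractions back as (scaled) counts
    scale = 10**9
    est = freqs_from_phenotypes(
        PhenotypeCounts(round(f_a * scale), round(f_b * scale), round(f_c * scale))
    )
    assert est.as_tuple() == pytest.approx(p.as_tuple(), abs=1e-4)


def test_round_trip_identity_analytic():
    p = AlleleFreqs(0.3675, 0.5916, 0.0409)
    f_a, f_b, f_c = expected_phenotype_freqs(p)
    assert (f_a, f_b, f_c) == pytest.approx((0.60, 0.35, 0.05), abs=5e-3)
    # analytic inversion without discretization
    p_b = math.sqrt(f_b)
    p_ac = math.sqrt(f_b + f_c) - p_b
    assert (1 - p_b - p_ac, p_b, p_ac) == pytest.approx(p.as_tuple(), abs=1e-9)


class TestEM:
    def test_pure_b_converges_immediately(self):
        f, it, trace, conv = em_freqs_from_phenotypes(PhenotypeCounts(0, 50, 0))
        assert conv
        assert f.as_tuple() == pytest.approx((0.0, 1.0, 0.0), abs=1e-9)

    def test_matches_closed_form_on_study_totals(self):
        c = PhenotypeCounts(255, 146, 20)
        f_em, _, _, conv = em_freqs_from_phenotypes(c)
        assert conv
        assert f_em.as_tuple() == pytest.approx(
            freqs_from_phenotypes(c).as_tuple(), abs=1e-6)

    def test_agreement_and_monotone_loglik_on_random_triples(self):
        rng = np.random.default_rng(20180920)
        for _ in range(100):
            c = PhenotypeCounts(*(int(x) for x in rng.integers(0, 500, size=3)))
            if c.total == 0:
                continue
            f_em, _, trace, conv = em_freqs_from_phenotypes(c)
            assert conv
            assert f_em.as_tuple() == pytest.approx(
                freqs_from_phenotypes(c).as_tuple(), abs=1e-6)
            assert all(b - a > -1e-9 for a, b in zip(trace, trace[1:]))

    def test_bad_tol_rejected(self):
        with pytest.raises(ValueError):
            em_freqs_from_phenotypes(PhenotypeCounts(1, 1, 1), tol=0)


class TestFromGenotypes:
    def test_single_bb_cat(self, catalog):
        from conftest import make_genotype
        from cmahtype import CohortTable

        g = make_genotype(catalog, **{"c.268T>A": "AA"})
        f, counts, n_unres = freqs_from_genotypes(CohortTable([g]), "SCHEME4", catalog)
        assert f.p_b == 1.0
        assert counts == {"A": 0, "b": 2, "a_c": 0}
        assert n_unres == 0

    def test_empty_cohort_errors(self, catalog):
        from cmahtype import CohortTable

        with pytest.raises(ValueError):
            freqs_from_genotypes(CohortTable([]), "SCHEME4", catalog)

    def test_parameter_recovery_from_simulation(self, catalog):
        haplotype_freqs = {"A": 0.3675, "b_common": 0.50, "b_ragdoll": 0.0916,
                          "ac_ragdoll": 0.0409}
        n = 10_000
        cohort = simulate_cohort(
            SimulationConfig(n=n, seed=20180920, haplotype_freqs=haplotype_freqs,
                             breed_mix=None),
            catalog,
        )
        f, _, n_unres = freqs_from_genotypes(cohort, "EXTENDED6", catalog)
        assert n_unres == 0
        for est, true in zip(f.as_tuple(), (0.3675, 0.5916, 0.0409)):
            se = math.sqrt(true * (1 - true) / (2 * n))
            assert abs(est - true) <= 3 * se


class TestBootstrap:
    def test_requires_seed_and_is_deterministic(self):
        c = PhenotypeCounts(255, 146, 20)
        with pytest.raises(ValueError):
            bootstrap_freqs(c, n_boot=10)
        a = bootstrap_freqs(c, n_boot=200, seed=5)
        b = bootstrap_freqs(c, n_boot=200, seed=5)
        assert a == b
        lo, hi = a["p_b"]
        assert lo < math.sqrt(146 / 421) < hi
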