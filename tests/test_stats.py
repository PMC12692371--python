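"""Association statistics: HWE exact test, inheritance models, haplotype
EM/LD, diagnostic performance, allele burden, chi-square power."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ctg18 import (
    GenotypeCounts,
    InheritanceModel,
    PowerSpec,
    allele_burden,
    allele_frequency,
    chisq_power,
    diagnostic_performance,
    fit_all_models,
    fit_inheritance_model,
    haplotype_em,
    haplotype_loglik,
    hwe_exact,
    select_model,
)
from ctg18.reference import EXPANSION_COUNTS, SNP_COUNTS
from ctg18.stats import AssocResult, OddsRatio


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_oracle(counts):
    """Exact-rational enumeration of the conditional HWE test."""
    hom_ref, het, hom_alt = counts
    n = sum(counts)
    n_rare = het + 2 * min(hom_ref, hom_alt)
    if n == 0 or n_rare == 0:
        return Fraction(1)

    def prob(n_het):
        n_hom_rare = (n_rare - n_het) // 2
        n_hom_common = n - n_het - n_hom_rare
        ways = (
            Fraction(math.factorial(n))
            / (math.factorial(n_het) * math.factorial(n_hom_rare) * math.factorial(n_hom_common))
            * 2**n_het
        )
        return ways / math.comb(2 * n, n_rare)

    p_obs = prob(het)
    total = Fraction(0)
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        p = prob(h)
        if p <= p_obs:
            total += p
    return total


def test_perfect_hwe_proportions_give_p_one():
    assert hwe_exact((25, 50, 25)) == pytest.approx(1.0)


def test_published_control_counts_conform_to_hwe():
    assert hwe_exact(EXPANSION_COUNTS.controls) > 0.05
    assert hwe_exact(EXPANSION_COUNTS.cases) > 0.05
    assert hwe_exact(SNP_COUNTS.controls) > 0.05


def test_monomorphic_locus_is_trivially_in_equilibrium():
    assert hwe_exact((42, 0, 0)) == 1.0


@settings(max_examples=150, deadline=None)
@given(
    st.tuples(
        st.integers(0, 70), st.integers(0, 60), st.integers(0, 70)
    ).filter(lambda c: 0 < sum(c) <= 100)
)
def test_hwe_matches_exact_enumeration_oracle(counts):
    """Tables up to 200 alleles agree with the rational-arithmetic
    enumeration to floating-point accuracy."""
    assert hwe_exact(counts) == pytest.approx(float(hwe_exact_oracle(counts)), abs=1e-9)


# ---------------------------------------------------------------------------
# allele frequencies and table percentages

@pytest.mark.parametrize(
    "counts,expected",
    [
        (EXPANSION_COUNTS.cases, 23 / 72),
        (EXPANSION_COUNTS.controls, 3 / 116),
        (SNP_COUNTS.cases, 29 / 72),
        (SNP_COUNTS.controls, 20 / 116),
        ((50, 0, 0), 0.0),
    ],
)
def test_allele_frequency(counts, expected):
    assert allele_frequency(counts) == pytest.approx(expected)


def test_published_percentage_columns_regenerate_from_counts():
    assert EXPANSION_COUNTS.percentages("control") == (94.8, 5.2, 0.0)
    assert EXPANSION_COUNTS.percentages("case") == (44.4, 47.2, 8.3)
    assert SNP_COUNTS.percentages("control") == (65.5, 34.5, 0.0)
    assert SNP_COUNTS.percentages("case") == (38.9, 41.7, 19.4)


# ---------------------------------------------------------------------------
# inheritance models

class TestInheritanceModels:
    def test_dominant_or_equals_cross_product_ratio(self):
        r = fit_inheritance_model(EXPANSION_COUNTS, InheritanceModel.DOMINANT)
        assert r.odds_ratios[0].estimate == pytest.approx((20 * 55) / (3 * 16), rel=1e-6)
        assert r.odds_ratios[0].ci_low < r.odds_ratios[0].estimate < r.odds_ratios[0].ci_high

    def test_codominant_het_contrast_or(self):
        r = fit_inheritance_model(EXPANSION_COUNTS, InheritanceModel.CODOMINANT)
        assert r.odds_ratios[0].estimate == pytest.approx((17 * 55) / (3 * 16), rel=1e-6)

    def test_zero_cell_reported_na_with_one_sided_ci(self):
        r = fit_inheritance_model(EXPANSION_COUNTS, InheritanceModel.CODOMINANT)
        xx = r.odds_ratios[1]
        assert xx.is_na and xx.one_sided
        rec = fit_inheritance_model(EXPANSION_COUNTS, InheritanceModel.RECESSIVE)
        assert rec.odds_ratios[0].is_na

    def test_recessive_or_equals_cross_product_on_nondegenerate_table(self):
        counts = GenotypeCounts(controls=(40, 30, 10), cases=(20, 30, 30))
        r = fit_inheritance_model(counts, InheritanceModel.RECESSIVE)
        assert r.odds_ratios[0].estimate == pytest.approx(
            (30 * 70) / (10 * 50), rel=1e-6
        )

    def test_lrt_p_and_aic_ordering_on_published_expansion_table(self):
        results = fit_all_models(EXPANSION_COUNTS)
        by_model = {r.model: r for r in results}
        assert by_model[InheritanceModel.DOMINANT].p_value < 1e-4
        # the per-allele model fits these counts best, as in the published table
        assert select_model(results).model is InheritanceModel.LOG_ADDITIVE

    def test_covariate_adjusted_fit_runs_and_brackets_estimate(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 400
        g = rng.integers(0, 3, size=n)
        age = rng.normal(70, 8, size=n)
        logit = -2 + 1.2 * g + 0.01 * (age - 70)
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({"status": y.astype(int), "genotype": g, "age": age})
        r = fit_inheritance_model(df, InheritanceModel.LOG_ADDITIVE, covariates=["age"])
        assert r.adjusted
        o = r.odds_ratios[0]
        assert o.ci_low < o.estimate < o.ci_high
        assert o.ci_low < math.exp(1.2) < o.ci_high

    def test_degenerate_identical_genotypes_flagged(self):
        counts = GenotypeCounts(controls=(50, 0, 0), cases=(50, 0, 0))
        r = fit_inheritance_model(counts, InheritanceModel.DOMINANT)
        assert r.odds_ratios[0].is_na


def _stub(model, aic, k):
    return AssocResult(
        model=model, odds_ratios=[OddsRatio("x", 1.0, 0.5, 2.0)],
        p_value=0.05, aic=aic, n_params=k, loglik=0.0,
    )


class TestModelSelection:
    def test_minimum_aic_wins(self):
        results = [
            _stub(InheritanceModel.LOG_ADDITIVE, 101, 2),
            _stub(InheritanceModel.DOMINANT, 102, 2),
            _stub(InheritanceModel.CODOMINANT, 103, 3),
            _stub(InheritanceModel.RECESSIVE, 127, 2),
        ]
        assert select_model(results).model is InheritanceModel.LOG_ADDITIVE

    def test_aic_tie_breaks_toward_fewer_parameters(self):
        results = [
            _stub(InheritanceModel.CODOMINANT, 118, 3),
            _stub(InheritanceModel.DOMINANT, 118, 2),
        ]
        assert select_model(results).model is InheritanceModel.DOMINANT

    def test_dominant_truth_recovered_across_replicates(self):
        """Cohorts generated under a dominant carrier effect (OR 3) mostly
        select the dominant coding; AIC concedes to the codominant model
        (which nests the truth at the cost of one parameter) at the
        chi-square(1) > 2 rate, so the asymptotic selection rate is ~84%."""
        p = 0.3
        ctrl_probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        w = ctrl_probs * np.array([1.0, 3.0, 3.0])
        case_probs = w / w.sum()
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            counts = GenotypeCounts(
                controls=tuple(rng.multinomial(1000, ctrl_probs)),
                cases=tuple(rng.multinomial(1000, case_probs)),
            )
            if select_model(fit_all_models(counts)).model is InheritanceModel.DOMINANT:
                hits += 1
        assert hits >= 34  # 36/40 with these seeds; theory predicts ~84%


# ---------------------------------------------------------------------------
# haplotype EM and LD

def _grid_loglik_max(table, step=0.01):
    """Brute-force maximum of the observed-data log-likelihood over the
    step-gridded haplotype-frequency simplex."""
    m = int(round(1 / step))
    grid = []
    for a in range(m + 1):
        for b in range(m + 1 - a):
            for c in range(m + 1 - a - b):
                grid.append((a, b, c, m - a - b - c))
    H = np.asarray(grid, float) / m
    # genotype-cell probabilities as quadratic forms in the haplotype freqs
    hap_alleles = [(1, 1), (1, 0), (0, 1), (0, 0)]
    P = np.zeros((len(H), 3, 3))
    for p, (a1, b1) in enumerate(hap_alleles):
        for q, (a2, b2) in enumerate(hap_alleles):
            P[:, a1 + a2, b1 + b2] += H[:, p] * H[:, q]
    mask = table > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (table[mask] * np.log(P[:, mask])).sum(axis=1)
    return float(np.nanmax(ll))


class TestHaplotypeEm:
    def test_phase_known_complete_ld(self):
        # only AB/AB and ab/ab subjects: D' must be 1
        ld = haplotype_em(np.array([2] * 8 + [0] * 24), np.array([2] * 8 + [0] * 24))
        assert ld.d_prime == pytest.approx(1.0)
        assert ld.r == pytest.approx(1.0)

    def test_independent_loci_give_near_zero_d_prime(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.3, size=20_000)
        b = rng.binomial(2, 0.4, size=20_000)
        ld = haplotype_em(a, b)
        assert abs(ld.d_prime) < 0.05

    def test_monomorphic_locus_flagged(self):
        ld = haplotype_em(np.zeros(30, int), np.array([0, 1, 2] * 10))
        assert math.isnan(ld.d_prime) and "monomorphic" in ld.note

    def test_em_loglik_is_monotone(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.integers(0, 3, size=25)
            b = rng.integers(0, 3, size=25)
            if a.std() == 0 or b.std() == 0:
                continue
            ld = haplotype_em(a, b)
            diffs = np.diff(ld.loglik_path)
            assert (diffs >= -1e-9).all()

    def test_em_beats_grid_search_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(3):
            a = rng.integers(0, 3, size=30)
            b = rng.integers(0, 3, size=30)
            if a.std() == 0 or b.std() == 0:
                continue
            table = np.zeros((3, 3))
            for i, j in zip(a, b):
                table[i, j] += 1
            ld = haplotype_em(a, b)
            assert ld.loglik >= _grid_loglik_max(table) - 1e-9

    def test_haplotype_frequencies_consistent_with_d(self):
        rng = np.random.default_rng(23)
        a = rng.binomial(2, 0.4, size=500)
        b = np.where(rng.random(500) < 0.7, a, rng.binomial(2, 0.3, size=500))
        ld = haplotype_em(a, b)
        f = ld.haplotype_freqs
        assert f.sum() == pytest.approx(1.0)
        pA, pB = f[0] + f[1], f[0] + f[2]
        assert ld.d == pytest.approx(f[0] - pA * pB, abs=1e-9)
        assert abs(ld.d_prime) <= 1 + 1e-9
        assert ld.r**2 <= 1 + 1e-9


# ---------------------------------------------------------------------------
# diagnostic performance, burden, power

def test_diagnostic_performance_on_published_margins():
    carrier = np.array([1] * 20 + [0] * 16 + [1] * 3 + [0] * 55, bool)
    disease = np.array([1] * 36 + [0] * 58, bool)
    sens, spec = diagnostic_performance(carrier, disease)
    assert sens == pytest.approx(20 / 36)
    assert spec == pytest.approx(55 / 58)
    assert round(100 * spec) == 95


def test_perfect_classifier():
    d = np.array([1, 1, 0, 0], bool)
    assert diagnostic_performance(d, d) == (1.0, 1.0)


def test_specificity_under_independence_matches_noncarrier_rate():
    rng = np.random.default_rng(29)
    carrier = rng.random(40_000) < 0.2
    disease = rng.random(40_000) < 0.5
    _, spec = diagnostic_performance(carrier, disease)
    assert spec == pytest.approx(0.8, abs=0.01)


@pytest.mark.parametrize(
    "x,g,burden,category",
    [(2, 2, 4, "3-4"), (1, 1, 2, "2"), (0, 0, 0, "0-1"), (1, 0, 1, "0-1"), (2, 1, 3, "3-4")],
)
def test_allele_burden_categories(x, g, burden, category):
    assert allele_burden(x, g) == (burden, category)


def test_allele_burden_propagates_missing():
    assert allele_burden(None, 2) is None


class TestChisqPower:
    def test_null_effect_power_equals_alpha(self):
        assert chisq_power(PowerSpec(0.0, 2, 94, 0.05)) == pytest.approx(0.05)

    def test_power_increases_with_n(self):
        powers = [chisq_power(PowerSpec(0.3, 2, n)) for n in (50, 100, 200, 400)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_matches_monte_carlo_oracle_in_local_regime(self):
        """Simulated multinomial rejection rate at the noncentrality of the
        published design (lambda = 94 * 0.3^2) matches the noncentral
        chi-square formula within 1%."""
        rng = np.random.default_rng(1)
        n, lam = 10_000, 94 * 0.09
        w = math.sqrt(lam / n)
        p0 = np.ones(3) / 3
        v = np.array([2.0, -1.0, -1.0]) / 3
        eps = w / math.sqrt(float((v**2 / p0).sum()))
        p1 = p0 + eps * v
        X = rng.multinomial(n, p1, size=200_000)
        stat = (((X - n * p0) ** 2) / (n * p0)).sum(axis=1)
        mc = float((stat > sps.chi2.ppf(0.95, 2)).mean())
        assert chisq_power(PowerSpec(w, 2, n)) == pytest.approx(mc, abs=0.01)
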