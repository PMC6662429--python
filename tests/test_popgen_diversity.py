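import itertools
import math

import numpy as np
import pytest

from nestkin.data_model import GenotypePanel, Locus
from nestkin.popgen_diversity import (
    allele_frequencies,
    filter_loci,
    fis_weir_cockerham,
    heterozygosity,
    holm_correction,
    hwe_exact,
    null_allele_estimate,
)

from conftest import hwe_panel


def panel_from_pairs(pairs, locus="L1"):
    calls = np.asarray(pairs, dtype=np.int64).reshape(len(pairs), 1, 2)
    return GenotypePanel([f"i{k}" for k in range(len(pairs))], [Locus(locus)], calls)


# ---------------------------------------------------------------------------
# allele frequencies and heterozygosity
# ---------------------------------------------------------------------------

def test_allele_frequencies_examples():
    het = panel_from_pairs([(101, 102)] * 10)
    f = allele_frequencies(het)["L1"]
    assert f.loc[101] == 0.5 and f.loc[102] == 0.5
    homo = panel_from_pairs([(101, 101)])
    assert allele_frequencies(homo)["L1"].loc[101] == 1.0
    mixed = panel_from_pairs([(101, 102), (101, 101), (0, 0)])
    f = allele_frequencies(mixed)["L1"]
    assert f.attrs["n_alleles_sampled"] == 4
    assert f.loc[101] == 0.75


def test_allele_frequencies_sum_to_one(rng):
    panel = hwe_panel(40, rng.dirichlet(np.ones(6), size=5), rng)
    for s in allele_frequencies(panel).values():
        assert abs(s.sum() - 1.0) < 1e-12


def test_heterozygosity_closed_forms():
    # p = (0.5, 0.5), n = 10: h_exp = (20/19) * 0.5
    pairs = [(101, 102)] * 5 + [(101, 101), (101, 101), (102, 102), (102, 102), (101, 102)]
    d = heterozygosity(panel_from_pairs(pairs))[0]
    assert d.h_exp == pytest.approx(20 / 19 * 0.5, abs=1e-12)
    # all homozygous, one allele
    d = heterozygosity(panel_from_pairs([(101, 101)] * 4))[0]
    assert d.h_obs == 0.0 and d.h_exp == 0.0
    # 5 individuals all heterozygous: h_exp = (10/9) * 0.5
    d = heterozygosity(panel_from_pairs([(101, 102)] * 5))[0]
    assert d.h_obs == 1.0
    assert d.h_exp == pytest.approx(10 / 9 * 0.5, abs=1e-12)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def enumeration_hwe_p(n11, n12, n22):
    """Complete-enumeration exact p for a biallelic genotype table (Levene)."""
    n = n11 + n12 + n22
    na = 2 * n11 + n12

    def log_prob(h):
        a11 = (na - h) // 2
        a22 = n - a11 - h
        if (na - h) % 2 or a11 < 0 or a22 < 0:
            return None
        return (
            math.lgamma(n + 1) + h * math.log(2)
            + math.lgamma(na + 1) + math.lgamma(2 * n - na + 1)
            - math.lgamma(2 * n + 1)
            - math.lgamma(a11 + 1) - math.lgamma(h + 1) - math.lgamma(a22 + 1)
        )

    lp_obs = log_prob(n12)
    total = 0.0
    for h in range(min(na, 2 * n - na) + 1):
        lp = log_prob(h)
        if lp is not None and lp <= lp_obs + 1e-12:
            total += math.exp(lp)
    return total


def test_hwe_monomorphic_locus_p_one():
    p, se = hwe_exact(panel_from_pairs([(101, 101)] * 6), None, "L1", mc_reps=10)
    assert p == 1.0 and se == 0.0


@pytest.mark.parametrize(
    "table", [(0, 5, 0), (2, 1, 2), (3, 4, 3), (1, 2, 5)]
)
def test_hwe_monte_carlo_matches_enumeration(table):
    n11, n12, n22 = table
    pairs = [(1, 1)] * n11 + [(1, 2)] * n12 + [(2, 2)] * n22
    panel = panel_from_pairs(pairs)
    p_mc, se = hwe_exact(panel, None, "L1", mc_reps=40_000, seed=5)
    p_exact = enumeration_hwe_p(n11, n12, n22)
    assert p_mc == pytest.approx(p_exact, abs=max(4 * se, 0.01))


def test_hwe_p_roughly_uniform_under_null(rng):
    # large sample at HWE proportions: p should not pile up near 0
    pvals = []
    for _ in range(40):
        panel = hwe_panel(300, np.array([[0.6, 0.4]]), rng)
        p, _ = hwe_exact(panel, None, "L01", mc_reps=500, seed=int(rng.integers(2**31)))
        pvals.append(p)
    assert 0.25 < np.mean(pvals) < 0.75
    assert np.mean(np.array(pvals) < 0.05) < 0.2


# ---------------------------------------------------------------------------
# Weir-Cockerham F_IS
# ---------------------------------------------------------------------------

def test_fis_zero_at_hwe(rng):
    freqs = rng.dirichlet(np.ones(5) * 2, size=8)
    panel = hwe_panel(1000, freqs, rng)
    _, f, _ = fis_weir_cockerham(panel)
    assert abs(f) < 0.02


def test_fis_one_when_all_homozygous():
    pairs = [(101, 101)] * 4 + [(102, 102)] * 4
    _, f, _ = fis_weir_cockerham(panel_from_pairs(pairs))
    assert f == pytest.approx(1.0)


def test_fis_matches_hand_computed_component_sums():
    # 6 individuals, one biallelic locus
    pairs = [(1, 1), (1, 2), (1, 2), (2, 2), (1, 1), (1, 2)]
    n, hbar = 6, 3 / 6
    b_sum = c_sum = 0.0
    for p in (7 / 12, 5 / 12):  # both alleles
        b_sum += (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
        c_sum += hbar / 2
    expected = 1 - c_sum / (b_sum + c_sum)
    per_locus, f, _ = fis_weir_cockerham(panel_from_pairs(pairs))
    assert f == pytest.approx(expected, abs=1e-12)
    assert per_locus["L1"] == pytest.approx(expected, abs=1e-12)


def test_fis_permutation_detects_homozygote_excess(rng):
    # strong homozygote excess: one-sided p should be small
    pairs = [(1, 1)] * 15 + [(2, 2)] * 15 + [(1, 2)] * 2
    _, f, p = fis_weir_cockerham(panel_from_pairs(pairs), permutations=199, seed=3)
    assert f > 0.5 and p < 0.05


def test_fis_permutation_p_mean_near_half_under_null(rng):
    pvals = []
    for _ in range(60):
        panel = hwe_panel(40, rng.dirichlet(np.ones(4), size=3), rng)
        _, _, p = fis_weir_cockerham(
            panel, permutations=199, seed=int(rng.integers(2**31))
        )
        pvals.append(p)
    assert abs(np.mean(pvals) - 0.5) < 0.08


# ---------------------------------------------------------------------------
# Holm correction
# ---------------------------------------------------------------------------

def test_holm_stepwise_example():
    reject, adj = holm_correction([0.01, 0.04, 0.03], alpha=0.05)
    assert list(reject) == [True, False, False]
    assert adj[0] == pytest.approx(0.03)
    assert (np.diff(np.sort(adj)) >= -1e-15).all()


def test_holm_edge_cases():
    reject, _ = holm_correction([1.0, 1.0, 1.0])
    assert not reject.any()
    reject, adj = holm_correction([0.03])
    assert reject[0] and adj[0] == pytest.approx(0.03)


# ---------------------------------------------------------------------------
# null alleles and locus filtering
# ---------------------------------------------------------------------------

def simulate_null_locus(n, p_null, rng, k_visible=6):
    """Genotypes with a non-amplifying allele: null homozygotes appear blank,
    null heterozygotes appear as visible homozygotes."""
    p = np.array([(1 - p_null) / k_visible] * k_visible + [p_null])
    draws = rng.choice(k_visible + 1, size=(n, 2), p=p)
    calls = np.zeros((n, 1, 2), dtype=np.int64)
    for i, (a, b) in enumerate(draws):
        if a == k_visible and b == k_visible:
            continue  # blank
        elif a == k_visible:
            calls[i] = [b + 1, b + 1]
        elif b == k_visible:
            calls[i] = [a + 1, a + 1]
        else:
            calls[i] = [a + 1, b + 1]
    return GenotypePanel([f"i{k}" for k in range(n)], [Locus("L1")], calls)


def test_null_allele_recovery_and_null_case(rng):
    est = null_allele_estimate(simulate_null_locus(1000, 0.3, rng), None, "L1")
    assert est.freq == pytest.approx(0.3, abs=0.05)
    est0 = null_allele_estimate(simulate_null_locus(500, 0.0, rng), None, "L1")
    assert est0.freq < 0.05


def test_filter_loci_strict_threshold():
    calls = np.ones((4, 2, 2), dtype=np.int64)
    panel = GenotypePanel(["a", "b", "c", "d"], [Locus("A"), Locus("B")], calls)
    kept = filter_loci(panel, {"A": 0.48, "B": 0.06}, threshold=0.20)
    assert kept.locus_names == ["B"]
    assert filter_loci(panel, {"A": 0.10, "B": 0.06}).locus_names == ["A", "B"]
    assert filter_loci(panel, {"A": 0.20, "B": 0.06}).locus_names == ["A", "B"]
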