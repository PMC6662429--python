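import numpy as np
import pandas as pd
import pytest

from nestkin.data_model import GenotypePanel, Locus, StudyDesign
from nestkin.structure_amova import (
    amova_report,
    hierarchical_amova,
    pairwise_fst,
)
from nestkin.synthetic_data import SimulationConfig, simulate_allele_frequencies

from conftest import hwe_panel


# ---------------------------------------------------------------------------
# brute-force AMOVA oracle: sums of squares from pairwise identity distances
# ---------------------------------------------------------------------------

def brute_force_sigmas(calls, nests, clusters):
    """Variance components from first principles, one locus at a time.

    SS within any grouping G = sum over groups of (1/N_g) sum_{copies a<b in g}
    delta_ab with delta the allele identity distance; the nested SS ladder is
    solved against independently derived expected-SS coefficients.
    """
    total = np.zeros(4)
    seen = np.zeros(4, dtype=bool)
    n_ind, n_loci, _ = calls.shape
    for j in range(n_loci):
        copies, owner = [], []
        for i in range(n_ind):
            a, b = calls[i, j]
            if a == 0 or b == 0:
                continue
            copies += [a, b]
            owner += [i, i]
        copies = np.array(copies)
        owner = np.array(owner)
        if len(copies) < 4 or len(set(copies)) < 2:
            continue

        def ss_within(groups):
            ss = 0.0
            for g in set(groups):
                idx = np.where(np.array(groups) == g)[0]
                if len(idx) < 2:
                    continue
                d = 0.0
                for x in range(len(idx)):
                    for y in range(x + 1, len(idx)):
                        d += copies[idx[x]] != copies[idx[y]]
                ss += d / len(idx)
            return ss

        ind_of = owner
        nest_of = np.array([nests[i] for i in owner])
        clus_of = np.array([clusters[i] for i in owner])
        all_of = np.zeros(len(copies), dtype=int)
        ss_tot = ss_within(all_of)
        ss_in_clus = ss_within(clus_of)
        ss_in_nest = ss_within(nest_of)
        ss_in_ind = ss_within(ind_of)
        ss_ac = ss_tot - ss_in_clus
        ss_an = ss_in_clus - ss_in_nest
        ss_ai = ss_in_nest - ss_in_ind
        ss_wi = ss_in_ind
        # sizes in copies
        N = len(copies)
        nc_sizes = pd.Series(clus_of).value_counts()
        nn = pd.Series(nest_of).value_counts()
        I = N / 2
        C, Nn = len(nc_sizes), len(nn)
        df = np.array([C - 1, Nn - C, I - Nn, I])
        nest_to_clus = {}
        for nid, cid in zip(nest_of, clus_of):
            nest_to_clus[nid] = cid
        sum_nn2_by_c = {}
        for nid, size in nn.items():
            cid = nest_to_clus[nid]
            sum_nn2_by_c[cid] = sum_nn2_by_c.get(cid, 0.0) + size**2
        ratio = sum(sum_nn2_by_c[c] / nc_sizes[c] for c in nc_sizes.index)
        n2 = N - ratio
        c_s2_ac = ratio - (nn**2).sum() / N
        n1 = N - (nc_sizes**2).sum() / N
        s = np.full(4, np.nan)
        if df[3] > 0:
            s[3] = ss_wi / df[3]
        if df[2] > 0:
            s[2] = (ss_ai - s[3] * df[2]) / (2 * df[2])
        if df[1] > 0 and n2 > 0:
            s[1] = (ss_an - 2 * s[2] * df[1] - s[3] * df[1]) / n2
        if df[0] > 0 and n1 > 0:
            s[0] = (ss_ac - c_s2_ac * s[1] - 2 * s[2] * df[0] - s[3] * df[0]) / n1
        for k in range(4):
            if not np.isnan(s[k]):
                total[k] += s[k]
                seen[k] = True
    return np.where(seen, total, np.nan)


def make_design(individuals, nests, clusters, site="S", pop="P"):
    return StudyDesign(
        pd.DataFrame(
            {
                "individual": individuals,
                "nest": nests,
                "cluster": clusters,
                "site": [site] * len(individuals),
                "population": [pop] * len(individuals),
            }
        )
    )


def random_instance(rng, n_ind=12, n_loci=2, k=4, missing=0.1):
    calls = rng.integers(1, k + 1, size=(n_ind, n_loci, 2)).astype(np.int64)
    mask = rng.random((n_ind, n_loci)) < missing
    calls[mask] = 0
    nests = [f"n{v}" for v in rng.integers(0, 4, n_ind)]
    clus_of_nest = {f"n{i}": f"c{i % 2}" for i in range(4)}
    clusters = [clus_of_nest[n] for n in nests]
    inds = [f"i{k}" for k in range(n_ind)]
    panel = GenotypePanel(inds, [Locus(f"L{j}") for j in range(n_loci)], calls)
    return panel, make_design(inds, nests, clusters), nests, clusters


@pytest.mark.parametrize("seed", range(8))
def test_hierarchical_components_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    panel, design, nests, clusters = random_instance(rng, n_ind=16)
    res = hierarchical_amova(panel, design)
    oracle = brute_force_sigmas(panel.calls, nests, clusters)
    got = np.array(list(res.variance_components.values()))
    assert np.allclose(got, oracle, atol=1e-10, equal_nan=True)


def test_toy_two_by_two_instance_matches_oracle():
    # 2 clusters x 2 nests x 2 diploids, 1 biallelic locus
    rng = np.random.default_rng(99)
    calls = rng.integers(1, 3, size=(8, 1, 2)).astype(np.int64)
    inds = [f"i{k}" for k in range(8)]
    nests = ["n1", "n1", "n2", "n2", "n3", "n3", "n4", "n4"]
    clusters = ["c1", "c1", "c1", "c1", "c2", "c2", "c2", "c2"]
    panel = GenotypePanel(inds, [Locus("L1")], calls)
    res = hierarchical_amova(panel, make_design(inds, nests, clusters))
    oracle = brute_force_sigmas(calls, nests, clusters)
    got = np.array(list(res.variance_components.values()))
    assert np.allclose(got, oracle, atol=1e-10, equal_nan=True)


def test_f_statistic_identity(rng):
    panel, design, _, _ = random_instance(rng, n_ind=20, n_loci=4, missing=0.0)
    res = hierarchical_amova(panel, design)
    phi = res.phi
    lhs = 1 - phi["F_IT"]
    rhs = (1 - phi["F_IS"]) * (1 - phi["F_SC"]) * (1 - phi["F_CT"])
    assert lhs == pytest.approx(rhs, abs=1e-10)


def test_identical_individuals_are_degenerate():
    calls = np.full((8, 2, 2), 5, dtype=np.int64)
    inds = [f"i{k}" for k in range(8)]
    nests = ["n1"] * 4 + ["n2"] * 4
    clusters = ["c1"] * 4 + ["c2"] * 4
    panel = GenotypePanel(inds, [Locus("A"), Locus("B")], calls)
    res = hierarchical_amova(panel, make_design(inds, nests, clusters))
    assert res.degenerate
    assert all(np.isnan(v) for v in res.phi.values())


def test_duplicating_individuals_leaves_estimates_nearly_unchanged(rng):
    """Doubling the data must not move the between-group estimators.

    F_CT and F_IT depend on individuals only through within/between sums and
    are exactly invariant; theta carries explicit 1/n corrections and may
    drift by a small-sample amount. (The within-nest statistics F_IS/F_SC are
    excluded: a duplicated individual is a genuine genetic twin inside its
    nest, which legitimately changes the within-nest decomposition.)
    """
    from nestkin.synthetic_data import simulate_allele_frequencies

    cfg = SimulationConfig(n_loci=10, alleles_per_locus=6, divergence_f=0.15)
    _, demes = simulate_allele_frequencies(cfg, seed=4)
    pa = hwe_panel(90, demes["popA"], rng)
    pb = hwe_panel(110, demes["popB"], rng)
    inds = [f"a{i}" for i in range(90)] + [f"b{i}" for i in range(110)]
    panel = GenotypePanel(inds, pa.loci, np.concatenate([pa.calls, pb.calls]))

    # unbalanced nests inside two genuinely divergent clusters
    nests, sizes = [], [5, 7, 9, 12, 15, 20, 22]
    for tot, pref in ((90, "A"), (110, "B")):
        rem, j = tot, 0
        while rem > 0:
            s = min(sizes[j % len(sizes)], rem)
            nests += [f"{pref}n{j}"] * s
            rem -= s
            j += 1
    clusters = ["cA"] * 90 + ["cB"] * 110
    res1 = hierarchical_amova(panel, make_design(inds, nests, clusters))
    inds2 = inds + [f"{i}_dup" for i in inds]
    panel2 = GenotypePanel(inds2, panel.loci, np.concatenate([panel.calls, panel.calls]))
    res2 = hierarchical_amova(panel2, make_design(inds2, nests * 2, clusters * 2))
    for k in ("F_CT", "F_IT"):
        assert res2.phi[k] == pytest.approx(res1.phi[k], abs=0.005)

    panel.labels["population"] = ["A"] * 90 + ["B"] * 110
    doubled = GenotypePanel(
        inds2, pa.loci, np.concatenate([panel.calls, panel.calls])
    )
    doubled.labels["population"] = (["A"] * 90 + ["B"] * 110) * 2
    t1 = pairwise_fst(panel)["theta"].iloc[0]
    t2 = pairwise_fst(doubled)["theta"].iloc[0]
    assert abs(t1 - t2) <= 0.005


def test_pairwise_fst_fixation_and_null_split(rng):
    # two groups fixed for different alleles -> theta = 1
    calls = np.concatenate(
        [np.full((8, 3, 2), 1, dtype=np.int64), np.full((8, 3, 2), 2, dtype=np.int64)]
    )
    labels = pd.DataFrame(
        {"population": ["A"] * 8 + ["B"] * 8},
        index=pd.Index([f"i{k}" for k in range(16)], name="id"),
    )
    panel = GenotypePanel(
        [f"i{k}" for k in range(16)], [Locus(f"L{j}") for j in range(3)], calls, labels
    )
    out = pairwise_fst(panel)
    assert out["theta"].iloc[0] == pytest.approx(1.0)

    # one panmictic population split at random -> theta near 0
    panel = hwe_panel(200, rng.dirichlet(np.ones(6), size=10), rng)
    panel.labels["population"] = ["X"] * 100 + ["Y"] * 100
    out = pairwise_fst(panel)
    assert abs(out["theta"].iloc[0]) < 0.02


def test_pairwise_fst_recovers_divergence(rng):
    cfg = SimulationConfig(n_loci=20, alleles_per_locus=8, divergence_f=0.15)
    thetas = []
    for rep in range(10):
        _, demes = simulate_allele_frequencies(cfg, seed=300 + rep)
        pa = hwe_panel(100, demes["popA"], rng)
        pb = hwe_panel(100, demes["popB"], rng)
        inds = [f"a{i}" for i in range(100)] + [f"b{i}" for i in range(100)]
        panel = GenotypePanel(
            inds, pa.loci, np.concatenate([pa.calls, pb.calls])
        )
        panel.labels["population"] = ["A"] * 100 + ["B"] * 100
        thetas.append(pairwise_fst(panel)["theta"].iloc[0])
    assert np.mean(thetas) == pytest.approx(0.15, abs=0.03)


def test_fct_null_when_clusters_are_arbitrary(rng):
    # full-sib nests but cluster labels assigned independently of genetics
    from conftest import full_sib_panel

    panel = full_sib_panel(12, rng, per_family=6)
    fams = np.repeat(np.arange(6), 6)
    nests = [f"n{f}" for f in fams]
    clus_of_nest = {f"n{f}": f"c{rng.integers(3)}" for f in range(6)}
    clusters = [clus_of_nest[n] for n in nests]
    design = make_design(panel.individuals, nests, clusters)
    res = hierarchical_amova(panel, design, permutations=99, seed=11)
    assert res.phi["F_SC"] > 0.1  # full-sib nests strongly differentiated
    assert res.pvals["F_SC"] < 0.05
    assert abs(res.phi["F_CT"]) < 0.1


def test_amova_report_shapes(rng):
    panel, design, _, _ = random_instance(rng, n_ind=12, missing=0.0)
    res = hierarchical_amova(panel, design, permutations=19, seed=0)
    tab = amova_report(res)
    assert list(tab["statistic"]) == ["F_CT", "F_SC", "F_IS", "F_IT"]
    panel2 = hwe_panel(20, rng.dirichlet(np.ones(3), size=2), rng)
    panel2.labels["population"] = ["A"] * 10 + ["B"] * 10
    tab2 = amova_report(pairwise_fst(panel2))
    assert len(tab2) == 1 and tab2["statistic"].iloc[0] == "F_ST"
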