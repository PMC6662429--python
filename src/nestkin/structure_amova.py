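"""AMOVA F-statistics over nested sampling designs.

Two estimators are provided:

* :func:`pairwise_fst` — Weir & Cockerham's (1984) theta between pairs of
  groups, variance components summed over alleles and loci, significance by
  permuting individuals between the two groups.
* :func:`hierarchical_amova` — a four-level analysis of molecular variance
  on allele-identity distances: among clusters (F_CT), among nests within
  clusters (F_SC), among individuals within nests (F_IS), and within
  individuals (F_IT). Variance components are solved from the exact
  unbalanced nested-ANOVA expected sums of squares; permutation nulls follow
  the Arlequin conventions per level (whole nests among clusters for F_CT,
  individuals among nests within clusters for F_SC, alleles within/among
  individuals for F_IS/F_IT).

Negative variance components are retained, so slightly negative F values are
representable. Multilocus estimates sum variance components over loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import GenotypePanel, StudyDesign

__all__ = ["AmovaResult", "pairwise_fst", "hierarchical_amova", "amova_report"]


@dataclass
class AmovaResult:
    levels: list
    variance_components: dict
    phi: dict
    pvals: dict
    permutations: int
    se: dict = field(default_factory=dict)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (two or more groups)
# ---------------------------------------------------------------------------

def _wc_components(groups_calls, locus_j: int):
    """Weir-Cockerham (1984) a, b, c sums over alleles at one locus.

    ``groups_calls`` is a list of call arrays (one per group). Returns
    (a_sum, b_sum, c_sum) or None when fewer than 2 groups are typed or the
    locus is monomorphic overall.
    """
    typed = []
    for calls in groups_calls:
        g = calls[:, locus_j, :]
        t = g[(g > 0).all(axis=1)]
        if len(t) >= 1:
            typed.append(t)
    if len(typed) < 2:
        return None
    r = len(typed)
    n_i = np.array([len(t) for t in typed], dtype=float)
    alleles = np.unique(np.concatenate([t.ravel() for t in typed]))
    if len(alleles) < 2:
        return None
    nbar = n_i.mean()
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([(t == al).mean() for t in typed])
        h_i = np.array(
            [((t[:, 0] != t[:, 1]) & (t == al).any(axis=1)).mean() for t in typed]
        )
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0
        a = (nbar / n_c) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _theta_multilocus(groups_calls, n_loci: int) -> float:
    A = B = C = 0.0
    any_locus = False
    for j in range(n_loci):
        comp = _wc_components(groups_calls, j)
        if comp is None:
            continue
        any_locus = True
        A += comp[0]
        B += comp[1]
        C += comp[2]
    if not any_locus or (A + B + C) == 0:
        return np.nan
    return A / (A + B + C)


def pairwise_fst(
    panel: GenotypePanel,
    group_by: str = "population",
    permutations: int = 0,
    seed=None,
) -> pd.DataFrame:
    """Weir-Cockerham theta between every pair of groups, with permutation p.

    Significance: individuals permuted between the two groups; one-sided
    p = P(theta_perm >= theta_obs), computed as (count + 1)/(perms + 1).
    Returns a tidy DataFrame (group_1, group_2, theta, p_val).
    """
    labels = panel.labels[group_by]
    groups = [g for g in pd.unique(labels) if not pd.isna(g)]
    if len(groups) < 2:
        raise ValueError("pairwise_fst needs >= 2 groups")
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            mask_i = (labels == groups[gi]).to_numpy()
            mask_j = (labels == groups[gj]).to_numpy()
            calls_i, calls_j = panel.calls[mask_i], panel.calls[mask_j]
            theta = _theta_multilocus([calls_i, calls_j], panel.n_loci)
            p = np.nan
            if permutations > 0 and not np.isnan(theta):
                pooled = np.concatenate([calls_i, calls_j], axis=0)
                n_i = len(calls_i)
                exceed = 0
                for _ in range(permutations):
                    perm = rng.permutation(len(pooled))
                    t = _theta_multilocus(
                        [pooled[perm[:n_i]], pooled[perm[n_i:]]], panel.n_loci
                    )
                    if not np.isnan(t) and t >= theta - 1e-12:
                        exceed += 1
                p = (exceed + 1) / (permutations + 1)
            rows.append(
                {"group_1": groups[gi], "group_2": groups[gj], "theta": theta, "p_val": p}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Four-level hierarchical AMOVA
# ---------------------------------------------------------------------------

def _locus_sums(codes: np.ndarray, k: int, ind_nest: np.ndarray, nest_cluster: np.ndarray):
    """Sums of squared group-total norms for the nested one-hot decomposition.

    codes: (m, 2) allele indices for the m typed individuals at this locus;
    ind_nest: (m,) compact nest index; nest_cluster: cluster index per nest.
    Returns the pieces needed for the SS ladder, on the identity-distance
    scale (half the squared Euclidean one-hot scale).
    """
    m = len(codes)
    n_nest_all = len(nest_cluster)
    # individual sums (m, k)
    s_ind = np.zeros((m, k))
    rows = np.arange(m)
    np.add.at(s_ind, (rows, codes[:, 0]), 1.0)
    np.add.at(s_ind, (rows, codes[:, 1]), 1.0)
    s_nest = np.zeros((n_nest_all, k))
    np.add.at(s_nest, ind_nest, s_ind)
    clus_of_nest = nest_cluster
    s_clus = np.zeros((int(clus_of_nest.max()) + 1, k))
    np.add.at(s_clus, clus_of_nest, s_nest)
    total = s_ind.sum(axis=0)
    N = 2.0 * m
    n_copies_nest = 2.0 * np.bincount(ind_nest, minlength=n_nest_all).astype(float)
    n_copies_clus = np.bincount(clus_of_nest, weights=n_copies_nest, minlength=len(s_clus))
    present_nest = n_copies_nest > 0
    present_clus = n_copies_clus > 0

    def qsum(s, n):
        with np.errstate(invalid="ignore", divide="ignore"):
            q = (s**2).sum(axis=1) / n
        return float(q[n > 0].sum())

    q_ind = float((s_ind**2).sum() / 2.0)
    q_nest = qsum(s_nest, n_copies_nest)
    q_clus = qsum(s_clus, n_copies_clus)
    q_tot = float((total**2).sum() / N)
    # identity-distance scale: halve the one-hot SS
    ss_wi = (N - q_ind) / 2.0
    ss_ai = (q_ind - q_nest) / 2.0
    ss_an = (q_nest - q_clus) / 2.0
    ss_ac = (q_clus - q_tot) / 2.0
    I = float(m)
    Nn = float(present_nest.sum())
    Cc = float(present_clus.sum())
    # unbalanced-design coefficients
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_nn2_by_c = np.bincount(
            clus_of_nest, weights=n_copies_nest**2, minlength=len(s_clus)
        )
        ratio = np.where(n_copies_clus > 0, sum_nn2_by_c / np.where(n_copies_clus > 0, n_copies_clus, 1), 0.0)
    n2 = N - float(ratio.sum())  # coeff of sigma2 in SS_AN
    c_s2_ac = float(ratio.sum()) - float((n_copies_nest**2).sum()) / N
    n1 = N - float((n_copies_clus**2).sum()) / N
    return {
        "ss": (ss_ac, ss_an, ss_ai, ss_wi),
        "df": (Cc - 1, Nn - Cc, I - Nn, I),
        "n2": n2,
        "c_s2_ac": c_s2_ac,
        "n1": n1,
        "C": Cc,
        "Nn": Nn,
        "I": I,
    }


def _components_from_sums(d: dict):
    """Solve the expected-SS ladder for (sigma1..sigma4) at one locus."""
    ss_ac, ss_an, ss_ai, ss_wi = d["ss"]
    df_ac, df_an, df_ai, df_wi = d["df"]
    s4 = ss_wi / df_wi if df_wi > 0 else np.nan
    s3 = (ss_ai - s4 * df_ai) / (2.0 * df_ai) if df_ai > 0 else np.nan
    s2 = (
        (ss_an - 2.0 * s3 * df_an - s4 * df_an) / d["n2"]
        if df_an > 0 and d["n2"] > 0
        else np.nan
    )
    s1 = (
        (ss_ac - d["c_s2_ac"] * s2 - 2.0 * s3 * df_ac - s4 * df_ac) / d["n1"]
        if df_ac > 0 and d["n1"] > 0
        else np.nan
    )
    return s1, s2, s3, s4


def _amova_sigmas(calls: np.ndarray, ind_nest: np.ndarray, nest_cluster: np.ndarray):
    """Summed variance components (s1, s2, s3, s4) across loci.

    calls: (n, L, 2); ind_nest: per-individual compact nest index;
    nest_cluster: per-nest compact cluster index. Missing genotypes excluded
    per locus.
    """
    sums = np.zeros(4)
    seen = np.zeros(4, dtype=bool)
    for j in range(calls.shape[1]):
        g = calls[:, j, :]
        mask = (g > 0).all(axis=1)
        typed = g[mask]
        if len(typed) < 2:
            continue
        alleles, codes_flat = np.unique(typed.ravel(), return_inverse=True)
        if len(alleles) < 2:
            continue
        codes = codes_flat.reshape(-1, 2)
        d = _locus_sums(codes, len(alleles), ind_nest[mask], nest_cluster)
        comps = _components_from_sums(d)
        for i, c in enumerate(comps):
            if not np.isnan(c):
                sums[i] += c
                seen[i] = True
    return np.where(seen, sums, np.nan)


def _phi_from_sigmas(s):
    s1, s2, s3, s4 = s
    tot = np.nansum([s1, s2, s3, s4])
    phi = {}
    phi["F_CT"] = s1 / tot if not np.isnan(s1) and tot != 0 else np.nan
    denom_sc = np.nansum([s2, s3, s4])
    phi["F_SC"] = s2 / denom_sc if not np.isnan(s2) and denom_sc != 0 else np.nan
    denom_is = np.nansum([s3, s4])
    phi["F_IS"] = s3 / denom_is if not np.isnan(s3) and denom_is != 0 else np.nan
    phi["F_IT"] = (
        np.nansum([s1, s2, s3]) / tot
        if tot != 0 and not (np.isnan(s1) and np.isnan(s2) and np.isnan(s3))
        else np.nan
    )
    return phi


def hierarchical_amova(
    panel: GenotypePanel,
    design: StudyDesign,
    permutations: int = 0,
    seed=None,
    test_levels=("F_CT", "F_SC", "F_IS", "F_IT"),
) -> AmovaResult:
    """Four-level AMOVA (clusters / nests / individuals / within individuals).

    Uses the ``nest`` and ``cluster`` columns of the design for the panel's
    individuals. Statistics whose level has a single unit are reported as NaN
    with ``degenerate=True``; the remaining levels are still computed.
    ``test_levels`` restricts which statistics get a permutation test.
    """
    table = design.table.set_index("individual")
    inds = [i for i in panel.individuals if i in table.index]
    sub = panel.subset_individuals(inds)
    nests = table.loc[inds, "nest"].to_numpy()
    clusters = table.loc[inds, "cluster"].to_numpy()
    if pd.isna(nests).any() or pd.isna(clusters).any():
        raise ValueError("all individuals need nest and cluster assignments")
    nest_codes, ind_nest = np.unique(nests, return_inverse=True)
    nest_cluster = np.empty(len(nest_codes), dtype=int)
    clus_of_nest = pd.DataFrame({"nest": nests, "cluster": clusters}).drop_duplicates()
    if clus_of_nest["nest"].duplicated().any():
        raise ValueError("a nest maps to multiple clusters")
    cmap = {n: c for n, c in zip(clus_of_nest["nest"], clus_of_nest["cluster"])}
    clus_codes, _ = np.unique(list(cmap.values()), return_inverse=True)
    clus_index = {c: i for i, c in enumerate(clus_codes)}
    for i, n in enumerate(nest_codes):
        nest_cluster[i] = clus_index[cmap[n]]

    sig_obs = _amova_sigmas(sub.calls, ind_nest, nest_cluster)
    phi_obs = _phi_from_sigmas(sig_obs)
    degenerate = np.isnan(list(phi_obs.values())).any()
    pvals = {k: np.nan for k in phi_obs}
    if permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = {k: 0 for k in ("F_CT", "F_SC", "F_IS", "F_IT")}
        valid = {k: 0 for k in exceed}
        n_ind = sub.n_individuals
        for _ in range(permutations):
            if "F_CT" in test_levels and not np.isnan(phi_obs["F_CT"]):
                # permute whole nests among clusters
                perm_nc = rng.permutation(nest_cluster)
                phi = _phi_from_sigmas(_amova_sigmas(sub.calls, ind_nest, perm_nc))
                if not np.isnan(phi["F_CT"]):
                    valid["F_CT"] += 1
                    if phi["F_CT"] >= phi_obs["F_CT"] - 1e-12:
                        exceed["F_CT"] += 1
            if "F_SC" in test_levels and not np.isnan(phi_obs["F_SC"]):
                # permute individuals among nests within clusters
                perm_in = ind_nest.copy()
                clus_of_ind = nest_cluster[ind_nest]
                for c in range(len(clus_codes)):
                    idx = np.where(clus_of_ind == c)[0]
                    perm_in[idx] = ind_nest[rng.permutation(idx)]
                phi = _phi_from_sigmas(_amova_sigmas(sub.calls, perm_in, nest_cluster))
                if not np.isnan(phi["F_SC"]):
                    valid["F_SC"] += 1
                    if phi["F_SC"] >= phi_obs["F_SC"] - 1e-12:
                        exceed["F_SC"] += 1
            if "F_IS" in test_levels and not np.isnan(phi_obs["F_IS"]):
                # permute alleles among individuals within nests
                calls_is = sub.calls.copy()
                for j in range(sub.n_loci):
                    g = calls_is[:, j, :]
                    typed_mask = (g > 0).all(axis=1)
                    for nnest in range(len(nest_codes)):
                        sel = np.where(typed_mask & (ind_nest == nnest))[0]
                        if len(sel) < 2:
                            continue
                        pool = g[sel].ravel()
                        rng.shuffle(pool)
                        calls_is[sel, j, :] = pool.reshape(-1, 2)
                phi = _phi_from_sigmas(_amova_sigmas(calls_is, ind_nest, nest_cluster))
                if not np.isnan(phi["F_IS"]):
                    valid["F_IS"] += 1
                    if phi["F_IS"] >= phi_obs["F_IS"] - 1e-12:
                        exceed["F_IS"] += 1
            if "F_IT" in test_levels and not np.isnan(phi_obs["F_IT"]):
                # permute alleles among all individuals
                calls_it = sub.calls.copy()
                for j in range(sub.n_loci):
                    g = calls_it[:, j, :]
                    typed_mask = (g > 0).all(axis=1)
                    sel = np.where(typed_mask)[0]
                    if len(sel) < 2:
                        continue
                    pool = g[sel].ravel()
                    rng.shuffle(pool)
                    calls_it[sel, j, :] = pool.reshape(-1, 2)
                phi = _phi_from_sigmas(_amova_sigmas(calls_it, ind_nest, nest_cluster))
                if not np.isnan(phi["F_IT"]):
                    valid["F_IT"] += 1
                    if phi["F_IT"] >= phi_obs["F_IT"] - 1e-12:
                        exceed["F_IT"] += 1
        for k in pvals:
            if valid[k] > 0:
                pvals[k] = (exceed[k] + 1) / (valid[k] + 1)
    se = {
        k: (np.sqrt(p * (1 - p) / permutations) if permutations > 0 and not np.isnan(p) else np.nan)
        for k, p in pvals.items()
    }
    comps = {
        "among_clusters": sig_obs[0],
        "among_nests_within_clusters": sig_obs[1],
        "among_individuals_within_nests": sig_obs[2],
        "within_individuals": sig_obs[3],
    }
    return AmovaResult(
        levels=["cluster", "nest", "individual", "within"],
        variance_components=comps,
        phi=phi_obs,
        pvals=pvals,
        permutations=permutations,
        se=se,
        degenerate=bool(degenerate),
    )


def amova_report(result) -> pd.DataFrame:
    """Render an AMOVA result (or a pairwise-theta DataFrame) as a tidy table."""
    if isinstance(result, pd.DataFrame):
        out = result.rename(columns={"theta": "estimate"}).copy()
        out.insert(0, "statistic", "F_ST")
        return out
    rows = []
    for stat, est in result.phi.items():
        rows.append(
            {
                "statistic": stat,
                "estimate": est,
                "p_val": result.pvals.get(stat, np.nan),
                "se": result.se.get(stat, np.nan),
                "degenerate": result.degenerate and np.isnan(est),
            }
        )
    return pd.DataFrame(rows)
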