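"""Per-locus descriptive population genetics for microsatellite panels.

Covers allele frequencies, observed and Nei-unbiased expected heterozygosity,
a Monte Carlo exact test of Hardy-Weinberg proportions, the Weir-Cockerham
(1984) within-population inbreeding coefficient f (F_IS) with a permutation
test, Holm's step-down multiple-testing correction, EM estimation of null
allele frequency from the heterozygote deficit, and the >threshold locus
filter used for marker quality control.

Conventions: missing genotypes are excluded pairwise per locus; permutation
and Monte Carlo p-values use (exceedances + 1) / (replicates + 1), so p is
never exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import GenotypePanel

__all__ = [
    "LocusDiversity",
    "NullAlleleEstimate",
    "allele_frequencies",
    "heterozygosity",
    "hwe_exact",
    "fis_weir_cockerham",
    "holm_correction",
    "null_allele_estimate",
    "filter_loci",
    "diversity_table",
]


@dataclass
class LocusDiversity:
    locus: str
    n: int
    n_alleles: int
    h_obs: float
    h_exp: float
    hwe_p: float = np.nan
    hwe_se: float = np.nan
    f_is: float = np.nan


@dataclass
class NullAlleleEstimate:
    locus: str
    freq: float
    method: str = "em"
    converged: bool = True


def _group_calls(panel: GenotypePanel, group) -> np.ndarray:
    """Calls restricted to a group. ``group`` is None (whole panel), a label
    value matched against the population column, or an explicit id list."""
    if group is None:
        return panel.calls
    if isinstance(group, (list, tuple, np.ndarray, pd.Index)):
        sub = panel.subset_individuals(list(group))
    else:
        sub = panel.subset_by_label("population", group)
    if sub.n_individuals == 0:
        raise ValueError(f"group '{group}' is empty")
    return sub.calls


def allele_frequencies(panel: GenotypePanel, group=None) -> dict:
    """Per-locus allele frequency tables from non-missing genotypes.

    Returns {locus name: pandas.Series indexed by allele code} with the sample
    allele count stored as ``series.attrs['n_alleles_sampled']``. Loci with no
    typed individuals in the group map to an empty Series (flagged for
    downstream exclusion).
    """
    calls = _group_calls(panel, group)
    out = {}
    for j, loc in enumerate(panel.loci):
        alleles = calls[:, j, :].ravel()
        alleles = alleles[alleles > 0]
        if len(alleles) == 0:
            s = pd.Series(dtype=float)
        else:
            counts = pd.Series(alleles).value_counts().sort_index()
            s = counts / counts.sum()
        s.attrs["n_alleles_sampled"] = int(len(alleles))
        out[loc.name] = s
    return out


def heterozygosity(panel: GenotypePanel, group=None) -> list:
    """Observed and Nei-unbiased expected heterozygosity per locus.

    h_exp = (2n / (2n - 1)) * (1 - sum p_k^2), with n the number of typed
    individuals at the locus.
    """
    calls = _group_calls(panel, group)
    results = []
    for j, loc in enumerate(panel.loci):
        g = calls[:, j, :]
        typed = g[(g > 0).all(axis=1)]
        n = len(typed)
        if n < 2:
            raise ValueError(f"locus {loc.name}: need >= 2 genotyped individuals")
        h_obs = float(np.mean(typed[:, 0] != typed[:, 1]))
        freqs = pd.Series(typed.ravel()).value_counts(normalize=True)
        h_exp = (2 * n / (2 * n - 1)) * (1.0 - float((freqs**2).sum()))
        results.append(
            LocusDiversity(loc.name, n, int(freqs.size), h_obs, h_exp)
        )
    return results


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene/Guo-Thompson null, Monte Carlo)
# ---------------------------------------------------------------------------

def _log_table_prob(het_count: int, genotype_counts: np.ndarray, allele_counts: np.ndarray) -> float:
    """Log conditional probability of a genotype table given allele counts
    (Levene 1949): P = n! 2^h prod(a_k!) / ((2n)! prod(g_ij!))."""
    n = genotype_counts.sum()
    lp = (
        math.lgamma(n + 1)
        + het_count * math.log(2.0)
        + sum(math.lgamma(a + 1) for a in allele_counts)
        - math.lgamma(2 * n + 1)
        - sum(math.lgamma(g + 1) for g in genotype_counts)
    )
    return lp


def _table_stats(pairs: np.ndarray, k: int):
    """Genotype counts (upper-triangle order) and het count from allele pairs."""
    a = np.minimum(pairs[:, 0], pairs[:, 1])
    b = np.maximum(pairs[:, 0], pairs[:, 1])
    idx = a * k + b
    counts = np.bincount(idx, minlength=k * k)
    het = int((a != b).sum())
    return counts[counts > 0], het


def hwe_exact(panel: GenotypePanel, group, locus: str, mc_reps: int = 100_000, seed=None):
    """Monte Carlo exact test of Hardy-Weinberg proportions at one locus.

    Estimates the probability, under the Levene null (random pairing of the
    observed allele counts), of genotype tables at most as probable as the
    observed one. Returns (p, Monte Carlo standard error). Monomorphic loci
    return p = 1 by convention.
    """
    j = panel.locus_names.index(locus)
    calls = _group_calls(panel, group)
    g = calls[:, j, :]
    typed = g[(g > 0).all(axis=1)]
    alleles = np.unique(typed.ravel())
    if len(alleles) < 2:
        return 1.0, 0.0
    if len(typed) < 3:
        raise ValueError("need >= 3 genotyped individuals")
    code = {a: i for i, a in enumerate(alleles)}
    pairs = np.vectorize(code.get)(typed)
    k = len(alleles)
    flat = pairs.ravel()
    allele_counts = np.bincount(flat, minlength=k)
    gc, het = _table_stats(pairs, k)
    lp_obs = _log_table_prob(het, gc, allele_counts)
    rng = np.random.default_rng(seed)
    exceed = 0
    pool = flat.copy()
    for _ in range(mc_reps):
        rng.shuffle(pool)
        sim_pairs = pool.reshape(-1, 2)
        gc_s, het_s = _table_stats(sim_pairs, k)
        if _log_table_prob(het_s, gc_s, allele_counts) <= lp_obs + 1e-12:
            exceed += 1
    p = (exceed + 1) / (mc_reps + 1)
    se = math.sqrt(p * (1 - p) / mc_reps)
    return p, se


# ---------------------------------------------------------------------------
# Weir-Cockerham F_IS
# ---------------------------------------------------------------------------

def _fis_components(typed: np.ndarray):
    """Per-locus Weir-Cockerham (1984) single-population b and c sums.

    For each allele: b = (n/(n-1)) [p(1-p) - (2n-1)/(4n) hbar], c = hbar/2,
    where hbar is the observed frequency of heterozygotes carrying the allele.
    Returns (sum_b, sum_c) over alleles; f = 1 - c/(b+c).
    """
    n = len(typed)
    alleles = np.unique(typed.ravel())
    het = typed[:, 0] != typed[:, 1]
    b_sum = c_sum = 0.0
    for a in alleles:
        carries = typed == a
        p = carries.mean()
        hbar = float((het & carries.any(axis=1)).mean())
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
        c = hbar / 2.0
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def fis_weir_cockerham(
    panel: GenotypePanel, group=None, permutations: int = 0, seed=None
):
    """Weir-Cockerham f (F_IS) per locus and multilocus, with an optional
    one-sided permutation test (alleles shuffled among individuals within the
    group; p = P(rand f >= obs f)).

    Returns (per_locus: dict, multilocus: float, pvalue: float or nan).
    Monomorphic loci contribute nothing; an entirely monomorphic panel yields
    nan with no p-value.
    """
    calls = _group_calls(panel, group)
    rng = np.random.default_rng(seed)

    def _multilocus(cs: np.ndarray):
        per_locus, B, C = {}, 0.0, 0.0
        for j, loc in enumerate(panel.loci):
            g = cs[:, j, :]
            typed = g[(g > 0).all(axis=1)]
            if len(typed) < 2 or len(np.unique(typed.ravel())) < 2:
                per_locus[loc.name] = np.nan
                continue
            b, c = _fis_components(typed)
            per_locus[loc.name] = 1.0 - c / (b + c) if (b + c) != 0 else np.nan
            B += b
            C += c
        multi = 1.0 - C / (B + C) if (B + C) != 0 else np.nan
        return per_locus, multi

    per_locus, f_obs = _multilocus(calls)
    if permutations <= 0 or np.isnan(f_obs):
        return per_locus, f_obs, np.nan
    exceed = 0
    for _ in range(permutations):
        perm = calls.copy()
        for j in range(panel.n_loci):
            g = perm[:, j, :]
            typed_mask = (g > 0).all(axis=1)
            pool = g[typed_mask].ravel()
            rng.shuffle(pool)
            perm[typed_mask, j, :] = pool.reshape(-1, 2)
        _, f_perm = _multilocus(perm)
        if not np.isnan(f_perm) and f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return per_locus, f_obs, p


def holm_correction(pvals, alpha: float = 0.05):
    """Holm step-down correction. Returns (reject: bool array, adjusted p)."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (pvals < 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject, adj


# ---------------------------------------------------------------------------
# Null alleles
# ---------------------------------------------------------------------------

def null_allele_estimate(
    panel: GenotypePanel,
    group=None,
    locus: str = None,
    method: str = "em",
    use_blanks: bool = False,
    max_iter: int = 10_000,
    tol: float = 1e-9,
) -> NullAlleleEstimate:
    """Dempster EM estimate of a single null allele's frequency at a locus.

    Model: one non-amplifying allele of frequency p_0 segregates with the
    visible alleles under Hardy-Weinberg proportions. Apparent homozygotes
    k/k are a mixture of true k/k and k/null genotypes; null/null homozygotes
    are indistinguishable from failed amplifications. By default the null/null
    class is treated as unobserved and imputed from the truncated-multinomial
    likelihood over typed genotypes (robust to technical missingness); with
    ``use_blanks=True`` every blank genotype is instead counted as a putative
    null homozygote.
    """
    if method != "em":
        raise ValueError("only the EM method is implemented")
    j = panel.locus_names.index(locus)
    calls = _group_calls(panel, group)
    g = calls[:, j, :]
    typed = g[(g > 0).all(axis=1)]
    n_blank = int(len(g) - len(typed))
    alleles = np.unique(typed.ravel())
    if len(alleles) < 2:
        raise ValueError(f"locus {locus}: need >= 2 visible alleles")
    k = len(alleles)
    code = {a: i for i, a in enumerate(alleles)}
    pairs = np.vectorize(code.get)(typed)
    het_mask = pairs[:, 0] != pairs[:, 1]
    het_counts = np.zeros(k)
    for a, b in pairs[het_mask]:
        het_counts[a] += 1
        het_counts[b] += 1
    homo_counts = np.bincount(pairs[~het_mask][:, 0], minlength=k).astype(float)
    n_typed = len(typed)
    # init: uniform visible freqs, small null freq
    p = np.full(k, 0.99 / k)
    p0 = 0.01
    converged = False
    for _ in range(max_iter):
        # E step: P(k/null | apparent k/k) = 2 p_k p0 / (p_k^2 + 2 p_k p0)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_null_in_homo = np.where(p > 0, 2 * p0 / (p + 2 * p0), 0.0)
        exp_null_homo = homo_counts * frac_null_in_homo
        if use_blanks:
            m_nullhomo = float(n_blank)
        else:
            # expected unobserved null/null individuals, truncated multinomial
            m_nullhomo = n_typed * p0**2 / (1.0 - p0**2) if p0 > 0 else 0.0
        # M step: allele counting over 2 (n_typed + m) gene copies
        counts = het_counts + 2 * homo_counts - exp_null_homo
        null_count = exp_null_homo.sum() + 2.0 * m_nullhomo
        total = counts.sum() + null_count
        new_p = counts / total
        new_p0 = null_count / total
        if abs(new_p0 - p0) < tol and np.abs(new_p - p).max() < tol:
            p, p0 = new_p, new_p0
            converged = True
            break
        p, p0 = new_p, new_p0
    return NullAlleleEstimate(locus, float(p0), "em", converged)


def filter_loci(panel: GenotypePanel, estimates, threshold: float = 0.20) -> GenotypePanel:
    """Drop loci whose null-allele frequency estimate is strictly above the
    threshold (estimates: dict name->freq or list of NullAlleleEstimate)."""
    if not isinstance(estimates, dict):
        estimates = {e.locus: e.freq for e in estimates}
    keep = [nm for nm in panel.locus_names if estimates.get(nm, 0.0) <= threshold]
    return panel.subset_loci(keep)


def diversity_table(
    panel: GenotypePanel, group=None, mc_reps: int = 20_000, permutations: int = 1_000, seed=None
) -> pd.DataFrame:
    """Per-locus summary mirroring a descriptive genetic-variation table:
    N_a, H_E, H_O, HWE exact p with Monte Carlo s.e., and per-locus f."""
    rng = np.random.default_rng(seed)
    divs = heterozygosity(panel, group)
    per_locus_f, _, _ = fis_weir_cockerham(panel, group)
    rows = []
    for d in divs:
        p, se = hwe_exact(
            panel, group, d.locus, mc_reps=mc_reps, seed=int(rng.integers(2**31))
        )
        rows.append(
            {
                "locus": d.locus,
                "n": d.n,
                "N_a": d.n_alleles,
                "H_E": d.h_exp,
                "H_O": d.h_obs,
                "p_val": p,
                "SD": se,
                "F_IS": per_locus_f.get(d.locus, np.nan),
            }
        )
    return pd.DataFrame(rows)
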