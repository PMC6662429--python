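"""Gene flow (Nm) and effective population size (Ne) estimators.

* :func:`private_allele_nm` — Barton & Slatkin's (1986) private-allele
  method: the mean frequency of alleles restricted to a single group, p(1),
  is regressed against the number of migrants per generation via their
  published log-log coefficients, with a GENEPOP-style correction for the
  harmonic-mean per-group sample size.
* :func:`ne_ld` — the linkage-disequilibrium method: Burrows' composite
  disequilibrium gives a mean squared correlation r^2 among unlinked locus
  pairs; after Waples' (2006) sample-size bias correction, the residual drift
  signal is inverted for Ne (random-mating constants of NeEstimator v2).
* :func:`ne_het_excess` — heterozygote-excess method (Zhdanova & Pudovkin
  2008): with few breeders, binomial sampling of parental allele frequencies
  makes offspring slightly too heterozygous; Nb = 1/(2 D) + 1/(2 (D + 1)).
* :func:`ne_coancestry` — molecular-coancestry method (Nomura 2008): the mean
  pairwise kinship estimated from allele-sharing equals 1/(2 Nb) in the
  parental generation.

All estimators return ∞ rather than a negative estimate when the signal is
at or below its sampling expectation, matching field convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import GenotypePanel
from .popgen_diversity import allele_frequencies

__all__ = ["NmEstimate", "NeEstimate", "private_allele_nm", "ne_ld", "ne_het_excess", "ne_coancestry"]


@dataclass
class NmEstimate:
    nm: float
    mean_private_freq: float
    mean_sample_size: float
    n_private_alleles: int


@dataclass
class NeEstimate:
    method: str
    ne: float
    ci_lo: float
    ci_hi: float
    pcrit: float
    n: float
    detail: dict = None


# ---------------------------------------------------------------------------
# Private-allele Nm
# ---------------------------------------------------------------------------

# Barton & Slatkin (1986) regression ln p(1) = a ln(Nm) + b at reference
# per-deme sample sizes 10, 25, 50.
_BS_COEFFS = {10: (-0.505, -2.440), 25: (-0.577, -2.609), 50: (-0.611, -2.585)}


def _bs_solve(p1: float, ref_n: int) -> float:
    a, b = _BS_COEFFS[ref_n]
    return (math.log(p1) - b) / a  # ln(Nm)


def private_allele_nm(panel: GenotypePanel, group_by: str = "population") -> NmEstimate:
    """Nm from the mean frequency of private alleles across groups.

    p(1) is the mean, over private alleles, of the allele's frequency in the
    group holding it. ln(Nm) is solved from the Barton-Slatkin regression at
    the two reference sample sizes bracketing the harmonic-mean per-group
    sample size and linearly interpolated (clamped at 10 and 50).
    Raises ValueError when no private alleles exist (gene flow unbounded).
    """
    labels = panel.labels[group_by]
    groups = [g for g in pd.unique(labels) if not pd.isna(g)]
    if len(groups) < 2:
        raise ValueError("private_allele_nm needs >= 2 groups")
    freqs = {g: allele_frequencies(panel, g if group_by == "population" else list(
        np.asarray(panel.individuals)[(labels == g).to_numpy()])) for g in groups}
    private, sizes = [], []
    for loc in panel.locus_names:
        present = {g: set(freqs[g][loc].index) for g in groups}
        for g in groups:
            others = set().union(*(present[h] for h in groups if h != g))
            for allele in present[g] - others:
                private.append(freqs[g][loc].loc[allele])
        for g in groups:
            sizes.append(freqs[g][loc].attrs["n_alleles_sampled"] / 2.0)
    if not private:
        raise ValueError("no private alleles: gene flow effectively unbounded")
    p1 = float(np.mean(private))
    sizes = [s for s in sizes if s > 0]
    harm_n = len(sizes) / sum(1.0 / s for s in sizes)
    refs = sorted(_BS_COEFFS)
    n_eff = min(max(harm_n, refs[0]), refs[-1])
    lo = max(r for r in refs if r <= n_eff)
    hi = min(r for r in refs if r >= n_eff)
    if lo == hi:
        ln_nm = _bs_solve(p1, lo)
    else:
        w = (n_eff - lo) / (hi - lo)
        ln_nm = (1 - w) * _bs_solve(p1, lo) + w * _bs_solve(p1, hi)
    return NmEstimate(math.exp(ln_nm), p1, harm_n, len(private))


# ---------------------------------------------------------------------------
# LD method (Burrows' delta, Waples 2006 correction)
# ---------------------------------------------------------------------------

def _screened_loci(calls: np.ndarray, pcrit: float):
    """Per locus: typed genotype rows and alleles passing the pcrit screen."""
    out = []
    for j in range(calls.shape[1]):
        g = calls[:, j, :]
        mask = (g > 0).all(axis=1)
        typed = g[mask]
        if len(typed) == 0:
            out.append((mask, np.array([])))
            continue
        freqs = pd.Series(typed.ravel()).value_counts(normalize=True)
        keep = freqs[freqs > pcrit].index.to_numpy()
        if len(keep) < 2:
            keep = np.array([])
        out.append((mask, keep))
    return out


def ne_ld(
    panel: GenotypePanel,
    group=None,
    pcrit: float = 0.05,
    mating: str = "random",
    jackknife: bool = True,
    seed=None,
) -> NeEstimate:
    """LD effective size from mean Burrows r^2 across locus pairs.

    For every pair of loci and every retained allele pair, the composite
    (Burrows) disequilibrium over individuals typed at both loci gives
    r^2 = Delta^2 / (p(1-p) q(1-q)); the weighted mean (weights = comparisons
    per locus pair) is bias-corrected for sample size (Waples 2006, random
    mating) and inverted for Ne. r^2 at or below its sampling expectation
    yields Ne = inf. CI by delete-one-locus jackknife (95%).
    """
    if mating != "random":
        raise ValueError("only random mating is implemented")
    from .popgen_diversity import _group_calls

    calls = _group_calls(panel, group)
    screened = _screened_loci(calls, pcrit)
    usable = [j for j, (_, keep) in enumerate(screened) if len(keep) >= 2]
    if len(usable) < 2:
        raise ValueError("ne_ld needs >= 2 polymorphic loci after screening")
    pair_r2, pair_w, pair_s, pair_loci = [], [], [], []
    for a_idx in range(len(usable)):
        for b_idx in range(a_idx + 1, len(usable)):
            ja, jb = usable[a_idx], usable[b_idx]
            mask = screened[ja][0] & screened[jb][0]
            S = int(mask.sum())
            if S < 3:
                continue
            ga, gb = calls[mask, ja, :], calls[mask, jb, :]
            r2s = []
            for al in screened[ja][1]:
                x = (ga == al).sum(axis=1).astype(float)  # 0,1,2 copies
                p = x.mean() / 2.0
                if not (pcrit < p < 1 - pcrit):
                    continue
                for bl in screened[jb][1]:
                    y = (gb == bl).sum(axis=1).astype(float)
                    q = y.mean() / 2.0
                    if not (pcrit < q < 1 - pcrit):
                        continue
                    delta = (x * y).mean() / 2.0 - 2.0 * p * q
                    delta *= S / (S - 1.0)
                    r2s.append(delta**2 / (p * (1 - p) * q * (1 - q)))
            if r2s:
                pair_r2.append(float(np.mean(r2s)))
                pair_w.append(len(r2s))
                pair_s.append(S)
                pair_loci.append((ja, jb))
    if not pair_r2:
        raise ValueError("no usable locus pairs")
    pair_r2 = np.asarray(pair_r2)
    pair_w = np.asarray(pair_w, dtype=float)
    pair_s = np.asarray(pair_s, dtype=float)
    S_harm = pair_w.sum() / (pair_w / pair_s).sum()

    def _invert(r2bar: float, S: float) -> float:
        if S >= 30:
            exp_r2 = 1.0 / S + 3.19 / S**2
            r2p = r2bar - exp_r2
            disc = 1.0 / 9.0 - 2.76 * r2p
            if r2p <= 0 or disc < 0:
                return math.inf
            return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)
        exp_r2 = 0.0018 + 0.907 / S + 4.44 / S**2
        r2p = r2bar - exp_r2
        disc = 0.308**2 - 2.08 * r2p
        if r2p <= 0 or disc < 0:
            return math.inf
        return (0.308 + math.sqrt(disc)) / (2.0 * r2p)

    r2bar = float((pair_w * pair_r2).sum() / pair_w.sum())
    ne = _invert(r2bar, S_harm)
    ci_lo = ci_hi = math.inf
    if jackknife and len(usable) >= 3:
        # delete-one-locus jackknife: locus pairs sharing a locus are
        # correlated, so pairs are grouped by locus rather than dropped singly
        jack = []
        for drop in usable:
            keep = np.array([drop not in pl for pl in pair_loci])
            if keep.sum() == 0 or pair_w[keep].sum() == 0:
                continue
            jack.append((pair_w[keep] * pair_r2[keep]).sum() / pair_w[keep].sum())
        jack = np.asarray(jack)
        g = len(jack)
        var_r2 = (g - 1) / g * ((jack - jack.mean()) ** 2).sum()
        half = 1.96 * math.sqrt(var_r2)
        # Ne is monotone decreasing in r2: upper r2 -> lower Ne bound
        ci_lo = _invert(r2bar + half, S_harm)
        ci_hi = _invert(r2bar - half, S_harm)
        if ci_lo > ci_hi:
            ci_lo, ci_hi = ci_hi, ci_lo
    return NeEstimate(
        "ld", ne, ci_lo, ci_hi, pcrit, S_harm,
        {"r2_mean": r2bar, "n_locus_pairs": len(pair_r2)},
    )


# ---------------------------------------------------------------------------
# Heterozygote-excess method
# ---------------------------------------------------------------------------

def ne_het_excess(panel: GenotypePanel, group=None, pcrit: float = 0.05) -> NeEstimate:
    """Effective number of breeders from per-allele heterozygote excess.

    D = (H_obs - H_exp) / H_exp per allele (H_exp with the small-sample
    correction), averaged over alleles and loci with weights proportional to
    the number of typed individuals; Nb = 1/(2 D) + 1/(2 (D + 1)).
    Non-positive mean excess yields infinity.
    """
    from .popgen_diversity import _group_calls

    calls = _group_calls(panel, group)
    ds, ws = [], []
    for j in range(calls.shape[1]):
        g = calls[:, j, :]
        typed = g[(g > 0).all(axis=1)]
        n = len(typed)
        if n < 2:
            continue
        freqs = pd.Series(typed.ravel()).value_counts(normalize=True)
        het = typed[:, 0] != typed[:, 1]
        for al, p in freqs.items():
            if not (pcrit < p < 1 - pcrit):
                continue
            h_exp = 2 * p * (1 - p) * (2 * n / (2 * n - 1))
            h_obs = float((het & (typed == al).any(axis=1)).mean())
            if h_exp > 0:
                ds.append((h_obs - h_exp) / h_exp)
                ws.append(n)
    if not ds:
        return NeEstimate("het_excess", math.inf, math.inf, math.inf, pcrit, np.nan)
    dbar = float(np.average(ds, weights=ws))
    n_mean = float(np.mean(ws))
    if dbar <= 0:
        ne = math.inf
    else:
        ne = 1.0 / (2.0 * dbar) + 1.0 / (2.0 * (dbar + 1.0))
    return NeEstimate("het_excess", ne, math.inf, math.inf, pcrit, n_mean, {"D_mean": dbar})


# ---------------------------------------------------------------------------
# Molecular-coancestry method
# ---------------------------------------------------------------------------

def _pairwise_kinship(calls: np.ndarray):
    """Allele-sharing (lookalike) kinship for every individual pair.

    Per locus, the similarity s of genotypes (a,b),(c,d) is the mean of the
    four allele-identity indicators; the correction subtracts the expected
    similarity of random gametes from the sample, s0 = sum p_k^2, and loci
    combine as a ratio of sums: f_ij = sum_l (s_ijl - s0_l) / sum_l (1 - s0_l).
    With the sample itself as the frequency reference, unrelated pairs have
    (slightly negative) kinship near zero while full sibs sit near +0.25
    scaled down by the sample's internal relatedness.
    Returns the condensed upper-triangle vector (NaN entries dropped).
    """
    n, L, _ = calls.shape
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(L):
        g = calls[:, j, :]
        mask = (g > 0).all(axis=1)
        m = int(mask.sum())
        if m < 3:
            continue
        typed = g[mask]
        alleles, codes = np.unique(typed.ravel(), return_inverse=True)
        K = len(alleles)
        X = np.zeros((m, K))
        codes = codes.reshape(-1, 2)
        rows = np.arange(m)
        np.add.at(X, (rows, codes[:, 0]), 1.0)
        np.add.at(X, (rows, codes[:, 1]), 1.0)
        p = X.sum(axis=0) / (2.0 * m)
        s0 = float((p**2).sum())
        s = (X @ X.T) / 4.0  # mean of the 4 allele-identity indicators
        idx = np.where(mask)[0]
        num[np.ix_(idx, idx)] += s - s0
        den[np.ix_(idx, idx)] += 1.0 - s0
    iu = np.triu_indices(n, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = num[iu] / den[iu]
    return f[np.isfinite(f)]


def ne_coancestry(panel: GenotypePanel, group=None) -> NeEstimate:
    """Nomura's (2008) molecular-coancestry effective number of breeders.

    Nb = 1 / (2 f_bar) with f_bar the mean pairwise kinship after setting
    negative pair values to zero (Nomura's convention: negative molecular
    coancestries are estimation noise around unrelatedness). Family-structured
    samples give small Nb; samples of unrelated individuals give Nb well above
    any plausible breeder count (the positive part of pure noise).
    CI by jackknife over individuals (95%).
    """
    from .popgen_diversity import _group_calls

    calls = _group_calls(panel, group)
    n = calls.shape[0]
    if n < 2:
        raise ValueError("ne_coancestry needs >= 2 individuals")
    f = np.maximum(_pairwise_kinship(calls), 0.0)
    if len(f) == 0:
        return NeEstimate("coancestry", math.inf, math.inf, math.inf, 0.0, n)
    fbar = float(f.mean())
    ne = 1.0 / (2.0 * fbar) if fbar > 0 else math.inf
    # jackknife over individuals
    ci_lo = ci_hi = math.inf
    pair_i, pair_j = np.triu_indices(n, 1)
    if n >= 3 and len(f) == len(pair_i):
        jack = []
        for drop in range(n):
            keep = (pair_i != drop) & (pair_j != drop)
            jack.append(float(f[keep].mean()))
        jack = np.asarray(jack)
        var_f = (n - 1) / n * ((jack - jack.mean()) ** 2).sum()
        half = 1.96 * math.sqrt(var_f)
        hi_f, lo_f = fbar + half, fbar - half
        ci_lo = 1.0 / (2.0 * hi_f) if hi_f > 0 else math.inf
        ci_hi = 1.0 / (2.0 * lo_f) if lo_f > 0 else math.inf
        if ci_lo > ci_hi:
            ci_lo, ci_hi = ci_hi, ci_lo
    return NeEstimate("coancestry", ne, ci_lo, ci_hi, 0.0, n, {"f_mean": fbar})
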