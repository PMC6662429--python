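"""Shared fixtures and simulation oracles for the test suite."""

import numpy as np
import pytest

from nestkin.data_model import GenotypePanel, Locus, PointPattern


def hwe_panel(n, freqs, rng, locus_names=None):
    """Panel of n diploids drawn at Hardy-Weinberg proportions.

    ``freqs``: (L, K) per-locus allele frequencies; codes are 1..K.
    """
    L, K = freqs.shape
    calls = np.zeros((n, L, 2), dtype=np.int64)
    for j in range(L):
        calls[:, j, :] = rng.choice(K, size=(n, 2), p=freqs[j]) + 1
    names = locus_names or [f"L{j + 1:02d}" for j in range(L)]
    return GenotypePanel(
        [f"i{i + 1:04d}" for i in range(n)], [Locus(nm) for nm in names], calls
    )


def wright_fisher_sample(Ne, S, rng, gens=8, L=20, K=8):
    """Sample S offspring from an ideal Wright-Fisher population of size Ne.

    The population runs ``gens`` generations so that linkage disequilibrium
    among unlinked loci reaches its drift-recombination equilibrium before
    sampling (fresh from linkage equilibrium the r^2 signal is attenuated).
    """
    freqs = rng.dirichlet(np.ones(K) * 2, size=L)
    pop = np.zeros((Ne, L, 2), dtype=np.int64)
    for j in range(L):
        pop[:, j, :] = rng.choice(K, size=(Ne, 2), p=freqs[j]) + 1
    ar = np.arange(L)

    def offspring(parents, n_out):
        out = np.zeros((n_out, L, 2), dtype=np.int64)
        m = rng.integers(0, len(parents), n_out)
        f = rng.integers(0, len(parents), n_out)
        mi = rng.integers(0, 2, (n_out, L))
        fi = rng.integers(0, 2, (n_out, L))
        for i in range(n_out):
            out[i, :, 0] = parents[m[i], ar, mi[i]]
            out[i, :, 1] = parents[f[i], ar, fi[i]]
        return out

    for _ in range(gens):
        pop = offspring(pop, Ne)
    return offspring(pop, S)


def full_sib_panel(n_parents, rng, per_family=10, L=15, K=8):
    """Full-sib families: n_parents/2 monogamous pairs, per_family offspring."""
    freqs = rng.dirichlet(np.ones(K) * 2, size=L)
    parents = np.zeros((n_parents, L, 2), dtype=np.int64)
    for j in range(L):
        parents[:, j, :] = rng.choice(K, size=(n_parents, 2), p=freqs[j]) + 1
    ar = np.arange(L)
    off = []
    for fam in range(n_parents // 2):
        mo, fa = parents[2 * fam], parents[2 * fam + 1]
        for _ in range(per_family):
            off.append(
                np.column_stack(
                    [mo[ar, rng.integers(0, 2, L)], fa[ar, rng.integers(0, 2, L)]]
                )
            )
    off = np.stack(off)
    return GenotypePanel(
        [f"i{i + 1:04d}" for i in range(len(off))],
        [Locus(f"L{j + 1:02d}") for j in range(L)],
        off,
    )


def random_pattern(n, window, rng):
    xy = np.column_stack(
        [
            rng.uniform(window[0], window[1], n),
            rng.uniform(window[2], window[3], n),
        ]
    )
    return PointPattern([f"p{i}" for i in range(n)], xy, window)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
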