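"""Independent brute-force oracles used by the test suite.

The PI oracles enumerate genotype space directly and know nothing about
the closed forms under test.
"""

import numpy as np


def enumerate_pi_hwe(freqs):
    """Sum of squared HWE genotype probabilities over unordered pairs."""
    p = np.asarray(freqs, dtype=float)
    k = len(p)
    total = 0.0
    for i in range(k):
        for j in range(i, k):
            p_g = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            total += p_g**2
    return total


def enumerate_pi_sibs(freqs):
    """P(two full sibs share an unordered genotype).

    Enumerates all parental allele draws (m1, m2, f1, f2); each sib
    inherits one maternal and one paternal allele uniformly, so the two
    sibs' genotypes range over the 4 x 4 grid of inheritance choices.
    """
    p = np.asarray(freqs, dtype=float)
    k = len(p)
    idx = np.arange(k)
    m1, m2, f1, f2 = np.meshgrid(idx, idx, idx, idx, indexing="ij")
    w = p[m1] * p[m2] * p[f1] * p[f2]
    genos = [
        np.minimum(m, f) * k + np.maximum(m, f)
        for m in (m1, m2)
        for f in (f1, f2)
    ]
    match = sum(
        (genos[a] == genos[b]).astype(float) for a in range(4) for b in range(4)
    ) / 16.0
    return float(np.sum(w * match))
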