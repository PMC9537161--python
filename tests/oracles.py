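"""Independent reference computations used to check the ML engine.

These maximise the site log likelihood by brute force (dense or refined
grid search) and never share code with the Fisher-scoring path they
verify.
"""

import numpy as np


def loglik_at(f, counts, errors):
    p = np.outer(f, 1.0 - 2.0 * errors) + errors
    return float((counts * np.log(p)).sum())


def grid_argmax(counts, errors, step=1e-5):
    """Brute-force maximiser of L(f) over the frequency simplex.

    Two alleles: dense 1-D grid at ``step``.  Three alleles: a coarse
    2-D pass over the simplex followed by a fine pass at ``step`` around
    the coarse optimum.
    """
    m = counts.shape[0]
    if m == 2:
        f1 = np.arange(0.0, 1.0 + step / 2, step)
        ll = np.zeros_like(f1)
        for j, e in enumerate(errors):
            w = 1.0 - 2.0 * e
            ll += counts[1, j] * np.log(f1 * w + e)
            ll += counts[0, j] * np.log((1.0 - f1) * w + e)
        best = float(f1[int(ll.argmax())])
        return np.array([1.0 - best, best])
    if m == 3:

        def scan(lo1, hi1, lo2, hi2, s):
            f1 = np.arange(lo1, hi1 + s / 2, s)
            f2 = np.arange(lo2, hi2 + s / 2, s)
            F1, F2 = np.meshgrid(f1, f2, indexing="ij")
            ok = F1 + F2 <= 1.0 + 1e-12
            ll = np.full(F1.shape, -np.inf)
            ll[ok] = 0.0
            for j, e in enumerate(errors):
                w = 1.0 - 2.0 * e
                ll[ok] += counts[1, j] * np.log(F1[ok] * w + e)
                ll[ok] += counts[2, j] * np.log(F2[ok] * w + e)
                ll[ok] += counts[0, j] * np.log((1.0 - F1[ok] - F2[ok]) * w + e)
            i, k = np.unravel_index(int(ll.argmax()), ll.shape)
            return float(F1[i, k]), float(F2[i, k])

        c1, c2 = scan(0.0, 1.0, 0.0, 1.0, 2e-3)
        r = 4e-3
        b1, b2 = scan(
            max(c1 - r, 0.0), min(c1 + r, 1.0), max(c2 - r, 0.0), min(c2 + r, 1.0), step
        )
        return np.array([1.0 - b1 - b2, b1, b2])
    raise NotImplementedError("grid oracle supports 2 or 3 alleles")


def random_site(rng, m=None, max_obs=200, levels=(10, 20, 30)):
    """A random stratified count matrix with Dirichlet-drawn frequencies."""
    m = m or int(rng.integers(2, 4))
    J = len(levels)
    counts = np.zeros((m, J))
    n = int(rng.integers(10, max_obs + 1))
    f_true = rng.dirichlet(np.ones(m) * 0.5)
    for _ in range(n):
        i = rng.choice(m, p=f_true)
        j = int(rng.integers(0, J))
        counts[i, j] += 1
    errors = np.array([10.0 ** (-q / 10) for q in levels])
    return counts, errors
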