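import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


def brute_force_sampen_counts(x, m, r):
    """Loop-level template-pair counting oracle for sample entropy.

    Counts unordered pairs i < j of templates of length m (B) and m+1
    (A) under the Chebyshev tolerance r, with both template sets
    indexed 0 .. N-m-1.  Deliberately written with explicit loops.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_templ = n - m
    a = b = 0
    for i in range(n_templ - 1):
        for j in range(i + 1, n_templ):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def brute_force_fluctuation(Y, s, q_list, poly_order):
    """Loop-level MFDFA fluctuation-function oracle.

    Segments taken from the start and from the end, each detrended with
    a polynomial fit of the given order; moments averaged per the
    standard definition with the log-average at q = 0.
    """
    Y = np.asarray(Y, dtype=float)
    n = len(Y)
    n_s = n // s
    f2 = []
    t = np.arange(s, dtype=float)
    for nu in range(n_s):
        seg = Y[nu * s:(nu + 1) * s]
        coef = np.polyfit(t, seg, poly_order)
        resid = seg - np.polyval(coef, t)
        f2.append(np.mean(resid ** 2))
    for nu in range(n_s):
        seg = Y[n - (nu + 1) * s: n - nu * s]
        coef = np.polyfit(t, seg, poly_order)
        resid = seg - np.polyval(coef, t)
        f2.append(np.mean(resid ** 2))
    # reorder tail segments to match start-and-end ordering
    f2 = f2[:n_s] + f2[n_s:][::-1]
    f2 = np.asarray(f2)
    out = []
    for q in q_list:
        if q == 0:
            out.append(np.exp(np.mean(np.log(f2)) / 2.0))
        else:
            out.append(np.mean(f2 ** (q / 2.0)) ** (1.0 / q))
    return np.asarray(out)
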