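"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written as a plain scalar loop from the definition of the
quantity, sharing no code with the package internals.
"""

import math

import numpy as np


def hc_brute(pvalues, variant="hc2004", alpha0=0.5):
    """Scalar-loop Higher Criticism from the definition."""
    p = sorted(float(v) for v in pvalues)
    n = len(p)
    bound = min(1.0 / (10.0 * n), 1e-8)
    limit = max(1, math.floor(alpha0 * n))
    best = None
    fallback = None
    for i, pi in enumerate(p[:limit], start=1):
        pi = min(max(pi, bound), 1.0 - bound)
        term = math.sqrt(n) * (i / n - pi) / math.sqrt(pi * (1.0 - pi))
        fallback = term if fallback is None else max(fallback, term)
        if variant == "hc_plus" and not pi > 1.0 / n:
            continue
        best = term if best is None else max(best, term)
    return best if best is not None else fallback


def bh_brute(pvalues, q=0.05):
    """Step-up Benjamini-Hochberg from the definition.

    adjusted_(i) = min_{k >= i} min(1, n * p_(k) / k), via the sorted order;
    discovery iff adjusted <= q.
    """
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, min(1.0, n * p[idx] / rank))
        adjusted[idx] = running
    return adjusted, adjusted <= q


def run_length_metrics(sequence, n_states):
    """NT/MDT/FRC by explicit run-length encoding."""
    seq = list(sequence)
    nt = sum(1 for a, b in zip(seq, seq[1:]) if a != b)
    runs = []
    for s in seq:
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([s, 1])
    mdt = {}
    frc = {}
    for state in range(n_states):
        lengths = [r[1] for r in runs if r[0] == state]
        mdt[state] = sum(lengths) / len(lengths) if lengths else float("nan")
        frc[state] = seq.count(state) / len(seq)
    return nt, mdt, frc
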