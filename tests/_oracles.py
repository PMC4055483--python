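"""Independent brute-force reference implementations used as test oracles.

Everything here is written straight from the defining formulas with
plain Python loops and dict lookups — no numpy vectorization, no reuse
of the package's computation paths — so that agreement with the
package is a meaningful check rather than a tautology.
"""

import itertools
import math

BASES = "ACGT"
DINUCLEOTIDES = [a + b for a in BASES for b in BASES]

# Standardized property rows (twist, tilt, roll, shift, slide, rise),
# transcribed independently for the oracle.
PROPS = {
    "AA": (0.06, 0.5, 0.27, 1.59, 0.11, -0.11),
    "AC": (1.50, 0.50, 0.80, 0.13, 1.29, 1.04),
    "AG": (0.78, 0.36, 0.09, 0.68, -0.24, -0.62),
    "AT": (1.07, 0.22, 0.62, -1.02, 2.51, 1.17),
    "CA": (-1.38, -1.36, -0.27, -0.86, -0.62, -1.25),
    "CC": (0.06, 1.08, 0.09, 0.56, -0.82, 0.24),
    "CG": (-1.66, -1.22, -0.44, -0.82, -0.29, -1.39),
    "CT": (0.78, 0.36, 0.09, 0.68, -0.24, -0.62),
    "GA": (-0.08, 0.5, 0.27, 0.13, -0.39, 0.71),
    "GC": (-0.08, 0.22, 1.33, -0.35, 0.65, 1.59),
    "GG": (0.06, 1.08, 0.09, 0.56, -0.82, 0.24),
    "GT": (1.50, 0.50, 0.80, 0.13, 1.29, 1.04),
    "TA": (-1.23, -2.37, -0.44, -2.24, -1.51, -1.39),
    "TC": (-0.08, 0.5, 0.27, 0.13, -0.39, 0.71),
    "TG": (-1.38, -1.36, -0.27, -0.86, -0.62, -1.25),
    "TT": (0.06, 0.5, 0.27, 1.59, 0.11, -0.11),
}


def bf_theta(d1, d2):
    """Mean over the 6 properties of the squared value difference."""
    total = 0.0
    for p1, p2 in zip(PROPS[d1], PROPS[d2]):
        total += (p1 - p2) ** 2
    return total / 6.0


def bf_tier_factors(seq, lam):
    """theta_j = (1/(L-j-1)) * sum_i Theta(pair_i, pair_{i+j})."""
    L = len(seq)
    thetas = []
    for j in range(1, lam + 1):
        acc = 0.0
        for i in range(1, L - j):  # 1-based i from 1 to L-j-1
            d1 = seq[i - 1 : i + 1]
            d2 = seq[i + j - 1 : i + j + 1]
            acc += bf_theta(d1, d2)
        thetas.append(acc / (L - j - 1))
    return thetas


def bf_dnc(seq):
    counts = {d: 0 for d in DINUCLEOTIDES}
    for i in range(len(seq) - 1):
        counts[seq[i : i + 2]] += 1
    n = len(seq) - 1
    return [counts[d] / n for d in DINUCLEOTIDES]


def bf_psednc(seq, lam, w):
    """Straight from the definition, including the explicit sum of f_i
    in the denominator (not simplified to 1)."""
    f = bf_dnc(seq)
    thetas = bf_tier_factors(seq, lam)
    denom = sum(f) + w * sum(thetas)
    return [fu / denom for fu in f] + [w * t / denom for t in thetas]


def standard_mcc(tp, tn, fp, fn):
    """Confusion-matrix MCC; None when undefined."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / math.sqrt(denom)


def bf_windowed_means(track, window, step):
    out = []
    start = 0
    while start + window <= len(track):
        out.append(sum(track[start : start + window]) / window)
        start += step
    return out
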