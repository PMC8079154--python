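"""Independent brute-force oracles shared by the unit and acceptance suites.

These deliberately re-derive results from first principles (full node
scans, exact integer combinatorics) and never call the implementation
paths they check.
"""

import math
from fractions import Fraction

from kleptoscreen.core_io import UNASSIGNED


def exhaustive_lca_oracle(tree, taxa, lca_percent):
    """Scan *every* tree node for subtree support over the hit taxa.

    Support of a node = fraction of distinct hit taxa whose root path
    contains the node; the answer is the deepest node with support >=
    lca_percent/100, ties resolved to their LCA.
    """
    taxa = set(taxa)
    n = len(taxa)
    qualifying = []
    for node in tree.parents:
        support = sum(1 for t in taxa if node in tree.path_to_root(t)) / n
        if support >= lca_percent / 100.0:
            qualifying.append(node)
    if not qualifying:
        return UNASSIGNED
    best = max(tree.depth(q) for q in qualifying)
    deepest = [q for q in qualifying if tree.depth(q) == best]
    return deepest[0] if len(deepest) == 1 else tree.lca(deepest)


def fisher_enumeration_oracle(a, b, c, d, sided="two-sided"):
    """Exact-arithmetic Fisher p: enumerate every table with the fixed margins.

    Hypergeometric probabilities are exact Fractions; the two-sided p sums
    tables whose point probability does not exceed the observed one (with
    the customary 1+1e-7 relative slack for floating-point ties).
    """
    K, N = a + b, a + b + c + d
    n = a + c
    lo, hi = max(0, n - (N - K)), min(K, n)
    denom = math.comb(N, n)
    probs = {x: Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
             for x in range(lo, hi + 1)}
    obs = probs[a]
    if sided == "greater":
        return float(sum(p for x, p in probs.items() if x >= a))
    cut = obs * Fraction(10_000_001, 10_000_000)
    return float(sum(p for p in probs.values() if p <= cut))
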