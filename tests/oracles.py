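"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: motif matching enumerates
every gap choice and substring window; the Fisher p-value sums hypergeometric
outcomes explicitly; BH is the literal step-up definition.
"""

from itertools import product
from math import comb

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(seq: str, i: int, pattern: str) -> bool:
    if i + len(pattern) > len(seq):
        return False
    return all(seq[i + j] in IUPAC[c] for j, c in enumerate(pattern))


def brute_force_scan(seq: str, parts, gaps):
    """All (start, minimal_end) matches by exhaustive gap enumeration."""
    seq = seq.upper().replace("U", "T")
    best_end = {}
    for gap_choice in product(*[range(lo, hi + 1) for lo, hi in gaps]):
        full = parts[0]
        for g, part in zip(gap_choice, parts[1:]):
            full += "N" * g + part
        for i in range(len(seq) - len(full) + 1):
            if iupac_match(seq, i, full):
                end = i + len(full)
                if i not in best_end or end < best_end[i]:
                    best_end[i] = end
    return sorted(best_end.items())


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by explicit hypergeometric enumeration
    (minimum-likelihood rule) with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def bh_stepup(p_values):
    """Literal Benjamini-Hochberg step-up definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, m * p_values[i] / rank_from_top)
        running_min = min(running_min, val)
        q[i] = running_min
    return q


def binomial_tail_enumeration(k: int, n: int, p0: float, direction: str) -> float:
    """Exact binomial tail by summing the pmf term by term."""
    def pmf(x):
        return comb(n, x) * p0**x * (1 - p0) ** (n - x)

    if direction == "greater":
        return sum(pmf(x) for x in range(k, n + 1))
    if direction == "less":
        return sum(pmf(x) for x in range(0, k + 1))
    obs = pmf(k)
    return sum(pmf(x) for x in range(n + 1) if pmf(x) <= obs * (1 + 1e-12))


def fisher_family_pvalues(r1: int, r2: int, c1: int):
    """Two-sided Fisher p for every table in the margin family
    (row sums r1, r2; first column sum c1), keyed by cell a."""
    n = r1 + r2
    denom = comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in support}
    out = {}
    for a in support:
        pa = pmf[a]
        out[a] = min(1.0, sum(px for px in pmf.values() if px <= pa * (1 + 1e-9)))
    return out
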