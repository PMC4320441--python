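"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written without importing spliceimpact
internals: a literal standard-code codon table, a per-residue set-based
domain-status call, and exhaustive hypergeometric enumeration with exact
integer arithmetic.
"""

from math import comb

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def brute_translate(nt: str) -> str:
    """Codon-by-codon table lookup, stopping at the first stop codon."""
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        residue = CODON_TABLE.get(codon, "X")
        if residue == "*":
            break
        aa.append(residue)
    return "".join(aa)


def prefix_suffix_scan(a: str, b: str):
    """Character-scan longest common prefix and capped common suffix."""
    p = 0
    while p < min(len(a), len(b)) and a[p] == b[p]:
        p += 1
    s = 0
    while s < min(len(a), len(b)) - p and a[len(a) - 1 - s] == b[len(b) - 1 - s]:
        s += 1
    return p, s


def domain_status_by_sets(incl: str, excl: str, dom_start: int, dom_end: int) -> str:
    """Materialize the absent-residue set and call the domain status from it."""
    p, s = prefix_suffix_scan(incl, excl)
    absent = set(range(p, len(incl) - s))
    dres = set(range(dom_start, dom_end))
    hit = dres & absent
    if not hit:
        return "intact"
    if hit == dres:
        return "lost"
    if s == 0 and dom_start < p < dom_end:
        return "truncated"
    return "internally_altered"


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k), X ~ Hypergeom(N, K, n), by exact integer enumeration."""
    total = comb(N, n)
    acc = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return acc / total
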