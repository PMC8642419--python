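"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (loops, literal formulas) and shares
no code with the implementation under test.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def poisson_tail(n: int, lam: float) -> float:
    """Upper-tail P(X >= n) for X ~ Poisson(lam), by direct summation."""
    if n <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    acc = 0.0
    term = math.exp(-lam)
    for i in range(n):
        if i > 0:
            term *= lam / i
        acc += term
    return 1.0 - acc


def bh_qvalues(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = pvals[i] * m / rank_from_top
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return q


def local_lambda(
    positions_by_umi: dict[str, int],
    genome_length: int,
    apex: int,
    cluster_start: int,
    cluster_end: int,
    window: int,
    flanks=(1000, 10000),
) -> float:
    """Sliding-window Poisson expectation, recomputed by brute force."""
    total = len(positions_by_umi)
    rate = total / genome_length
    for flank in flanks:
        lo = max(0, apex - flank)
        hi = min(genome_length, apex + flank)
        n_bg = 0
        for _, pos in positions_by_umi.items():
            if lo <= pos < hi and not (cluster_start <= pos < cluster_end):
                n_bg += 1
        span = (hi - lo) - (min(hi, cluster_end) - max(lo, cluster_start))
        if span > 0:
            rate = max(rate, n_bg / span)
    return rate * window


def brute_force_offtargets(spacer: str, pam: str, genome: str, max_mm: int):
    """Position-by-position scan on both strands; returns a set of
    (start, end, strand, mismatches) tuples."""
    hits = set()
    L = len(spacer) + len(pam)
    for strand in ("+", "-"):
        for i in range(len(genome) - L + 1):
            site = genome[i : i + L]
            if strand == "-":
                site = revcomp(site)
            if any(site[len(spacer) + j] not in IUPAC[c] for j, c in enumerate(pam)):
                continue
            mm = sum(1 for a, b in zip(site, spacer) if a != b)
            if mm <= max_mm:
                hits.add((i, i + L, strand, mm))
    return hits
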