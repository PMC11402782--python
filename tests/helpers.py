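"""Independent oracles used by the test suite.

Exact-arithmetic reimplementations of the statistics (integer/Fraction
combinatorics, no scipy) and per-base brute-force gene membership, kept
deliberately naive and separate from the package code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full hypergeometric enumeration, exact."""
    total = a + b + c + d
    n_row1 = a + b
    n_col1 = a + c
    k_min = max(0, n_row1 - (total - n_col1))
    k_max = min(n_row1, n_col1)
    # pmf(k) shares the denominator comb(total, n_row1): compare numerators.
    weights = {
        k: comb(n_col1, k) * comb(total - n_col1, n_row1 - k)
        for k in range(k_min, k_max + 1)
    }
    obs = weights[a]
    tail = sum(w for w in weights.values() if w <= obs)
    return Fraction(tail, comb(total, n_row1))


def binom_two_sided_oracle(k: int, n: int, p0: Fraction) -> Fraction:
    """Two-sided exact binomial p by full enumeration in rational arithmetic."""
    p0 = Fraction(p0)
    a, d = p0.numerator, p0.denominator
    b = d - a
    # pmf(j) = comb(n, j) a^j b^(n-j) / d^n: integer numerators, common denom.
    weights = [comb(n, j) * a**j * b ** (n - j) for j in range(n + 1)]
    obs = weights[k]
    tail = sum(w for w in weights if w <= obs)
    return Fraction(tail, d**n)


def bh_stepup_oracle(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted values: q(i) = min_{j>=i} p(j) * m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


def per_base_membership(genes, chrom: str, pos: int, same_strand: bool = False):
    """Brute-force assignment of one base: the unique covering gene or None.

    ``genes`` are GeneModel-like objects. Under the default policy a base
    covered by more than one gene maps to no gene; under ``same_strand`` the
    multiplicity is counted per strand and a base is ambiguous only when a
    single strand holds several covering genes (a base covered once on each
    strand is still unassignable without a strand hint).
    """
    covering = [
        g
        for g in genes
        if g.chrom == chrom and any(s <= pos < e for s, e in g.intervals)
    ]
    if not same_strand:
        return covering[0].gene_id if len(covering) == 1 else None
    by_strand = {}
    for g in covering:
        by_strand.setdefault(g.strand, []).append(g)
    singles = [gs[0] for gs in by_strand.values() if len(gs) == 1]
    return singles[0].gene_id if len(singles) == 1 else None


def brute_force_counts(insertions, genes):
    """Per-(gene, sample) sense/antisense counts by per-insertion scan."""
    unique = sorted(set(insertions))
    counts: dict[tuple[str, str], dict[str, int]] = {}
    unassigned: dict[str, int] = {}
    for ins in unique:
        unassigned.setdefault(ins.sample, 0)
        gene = None
        covering = [
            g
            for g in genes
            if g.chrom == ins.chrom
            and any(s <= ins.pos < e for s, e in g.intervals)
        ]
        if len(covering) == 1:
            gene = covering[0]
        if gene is None:
            unassigned[ins.sample] += 1
            continue
        key = (gene.gene_id, ins.sample)
        entry = counts.setdefault(key, {"sense": 0, "antisense": 0})
        entry["sense" if ins.strand == gene.strand else "antisense"] += 1
    return counts, unassigned
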