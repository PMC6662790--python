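"""Independent brute-force oracles.

Everything here is written as plain Python loops, deliberately avoiding the
package's vectorized implementations, so the two routes can be compared on
small inputs.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

MISSING = -1


# ---------------------------------------------------------------- haplotypes
def match_string(hap, consensus) -> bool:
    """Wildcard equality of two allele strings (missing matches anything)."""
    for a, c in zip(hap, consensus):
        if a == MISSING or c == MISSING:
            continue
        if a != c:
            return False
    return True


def brute_define(carrier_hap_pairs, scan_order):
    """Exhaustive consensus search.

    ``carrier_hap_pairs``: per carrier, an (n_markers, 2) list-like of
    alleles.  ``scan_order``: marker indices in order of distance from the
    focal position.  Returns (status, set of consensus tuples).
    """
    k = len(carrier_hap_pairs)
    n_markers = len(carrier_hap_pairs[0])
    candidates = set()
    for assignment in itertools.product((0, 1), repeat=k):
        consensus = [MISSING] * n_markers
        ok = True
        for rank in scan_order:
            for pair, hap in zip(carrier_hap_pairs, assignment):
                allele = pair[rank][hap]
                if allele == MISSING:
                    continue
                if consensus[rank] == MISSING:
                    consensus[rank] = allele
                elif consensus[rank] != allele:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            candidates.add(tuple(consensus))
    if not candidates:
        return "no_consensus", candidates
    return ("ok" if len(candidates) == 1 else "ambiguous"), candidates


def brute_scan(all_hap_pairs, ids, candidates, exclude):
    """String-comparison scan: ids with >= 1 haplotype matching any
    candidate consensus."""
    hits = []
    for ind, pair in zip(ids, all_hap_pairs):
        if ind in exclude:
            continue
        for hap in (0, 1):
            hap_string = [row[hap] for row in pair]
            if any(match_string(hap_string, c) for c in candidates):
                hits.append(ind)
                break
    return set(hits)


def brute_fine(hap_a, hap_b, positions, focal_pos):
    """Per-side longest-run scan (independent of the interleaved walk).

    Returns None when the four closest markers do not all match, else
    (start, end, n_matching).
    """
    order = sorted(
        range(len(positions)), key=lambda j: (abs(positions[j] - focal_pos), positions[j])
    )

    def ok(j):
        a, b = hap_a[j], hap_b[j]
        return a == MISSING or b == MISSING or a == b

    if not all(ok(j) for j in order[:4]):
        return None
    left = sorted((j for j in range(len(positions)) if positions[j] < focal_pos),
                  key=lambda j: -positions[j])
    right = sorted((j for j in range(len(positions)) if positions[j] >= focal_pos),
                   key=lambda j: positions[j])
    matched = []
    for side in (left, right):
        for j in side:
            if ok(j):
                matched.append(positions[j])
            else:
                break
    return min(matched), max(matched), len(matched)


# ----------------------------------------------------------------------- HWE
def hwe_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p-value by full enumeration with rational
    arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    rare = min(n_alt, 2 * n - n_alt)

    def weight(h: int) -> Fraction:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(h) * math.factorial(hom_rare) * math.factorial(hom_common),
        )

    hets = list(range(rare % 2, rare + 1, 2))
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    w_obs = weights[n_het]
    p = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(p, total))


# -------------------------------------------------------------------- Mendel
def mendel_possible_children(gf: int, gm: int) -> set[int]:
    """Child genotypes producible from two parent genotypes (no missing)."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    out = set()
    for fa in alleles[gf]:
        for ma in alleles[gm]:
            out.add(fa + ma)
    return out


def mendel_trio_inconsistent(gf: int, gm: int, gc: int) -> bool:
    """Rule-by-rule trio check over the 27 genotype combinations; missing
    parents degrade to duo rules."""
    if gc == MISSING:
        return False
    if gf != MISSING and gm != MISSING:
        return gc not in mendel_possible_children(gf, gm)
    for parent in (gf, gm):
        if parent == MISSING:
            continue
        if parent == 0 and gc == 2:
            return True
        if parent == 2 and gc == 0:
            return True
    return False


# -------------------------------------------------------------- IBD summary
def recount_sharing(lengths_mb, hi=5.0, lo=2.5):
    over = [x for x in lengths_mb if x > hi]
    band = [x for x in lengths_mb if lo < x <= hi]
    return {
        "total_over": sum(over),
        "n_over": len(over),
        "longest": max(lengths_mb, default=0.0),
        "total_band": sum(band),
        "n_band": len(band),
    }


# ----------------------------------------------------------------- pedigree
def replay_kindred_count(generations, mean_sibship, n_founder_couples, rng):
    """Replay of the kindred generator's documented sampling rules, counting
    members only."""
    count = 2 * n_founder_couples
    n_couples = n_founder_couples
    for gen in range(1, generations):
        terminal = gen == generations - 1
        next_couples = 0
        total = 0
        for _ in range(n_couples):
            n_children = int(rng.poisson(mean_sibship))
            total += n_children
            for _ in range(n_children):
                rng.integers(0, 2)  # sex draw
                count += 1
                if not terminal:
                    count += 1  # founder spouse
                    next_couples += 1
        n_couples = next_couples
        if total == 0:
            break
    return count
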