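"""Brute-force reference implementations, written independently of the
library code paths they check.  Everything here favours clarity over
speed: explicit loops, naive recomputation, set arithmetic."""

from __future__ import annotations

import itertools
import math

import numpy as np


def r2_naive(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation on pairwise-complete entries; 0 if undefined."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    if np.isnan(r):
        return 0.0
    # same 12-decimal rounding as the library so exact-boundary pairs
    # (r^2 a small rational equal to the threshold) decide identically
    return round(float(r**2), 12)


def ld_prune_naive(
    dosage: np.ndarray, maf: np.ndarray,
    window_snps: int, step_snps: int, r2_threshold: float,
) -> list[int]:
    """Windowed greedy pruning, recomputing r^2 from scratch every time.

    Same rule as the library: windows advance by step; within a window,
    scanning index pairs (a, b) in order, an offending pair loses its
    lower-MAF member (tie: the later variant).
    """
    V = dosage.shape[1]
    keep = [True] * V
    X = dosage.astype(float)
    X[dosage < 0] = np.nan
    start = 0
    while True:
        stop = min(start + window_snps, V)
        idx = list(range(start, stop))
        for ai in range(len(idx)):
            a = idx[ai]
            if not keep[a]:
                continue
            for bi in range(ai + 1, len(idx)):
                b = idx[bi]
                if not keep[a]:
                    break
                if not keep[b]:
                    continue
                if r2_naive(X[:, a], X[:, b]) > r2_threshold:
                    if maf[a] < maf[b]:
                        keep[a] = False
                    elif maf[b] < maf[a]:
                        keep[b] = False
                    else:
                        keep[b] = False
        if stop >= V:
            break
        start += step_snps
        if start >= V - 1:
            break
    return [i for i in range(V) if keep[i]]


def pi_pairwise_counting(dosages: np.ndarray) -> float:
    """Per-site nucleotide diversity by enumerating all gene-copy pairs.

    Expands each diploid dosage into two allele copies and returns the
    fraction of differing pairs among all C(c, 2) pairs.  Missing (-1)
    genotypes contribute no copies.
    """
    copies: list[int] = []
    for d in dosages:
        if d < 0:
            continue
        copies.extend([1] * int(d) + [0] * (2 - int(d)))
    n = len(copies)
    if n < 2:
        return math.nan
    diff = sum(
        1 for i in range(n) for j in range(i + 1, n) if copies[i] != copies[j]
    )
    return diff / (n * (n - 1) / 2)


def coancestry_matching(alleles_i: list[str], alleles_j: list[str]) -> float:
    """Probability two alleles, one drawn from each explicit allele list,
    match in state (enumeration over all ordered pairs)."""
    matches = sum(a == b for a in alleles_i for b in alleles_j)
    return matches / (len(alleles_i) * len(alleles_j))


def allelic_partition_sets(pop_alleles: list[list[set[str]]]):
    """(A_S, D_A, A_T) from explicit per-population per-locus allele sets,
    by direct set arithmetic over all ordered pairs including i = j."""
    s = len(pop_alleles)
    V = len(pop_alleles[0])
    a_s = d_a = a_t = 0.0
    for v in range(V):
        sets = [pop_alleles[i][v] for i in range(s)]
        a_s += sum(len(S) - 1 for S in sets) / s
        for i in range(s):
            for j in range(s):
                u_ij = len(sets[i] - sets[j])
                u_ji = len(sets[j] - sets[i])
                d_a += (u_ij + u_ji) / 2 / s**2
                a_t += (len(sets[i] | sets[j]) - 1) / s**2
    return a_s / V, d_a / V, a_t / V


def interval_overlaps_allpairs(windows, genes):
    """All (window, gene) half-open overlaps by quadratic scan."""
    out = []
    for (wc, ws, we) in windows:
        for (gc, gs, ge, name) in genes:
            if wc == gc and gs < we and ge > ws:
                out.append((wc, ws, we, name))
    return out


def simplex_grid(s: int, resolution: float):
    """All weight vectors on the simplex grid with the given step."""
    n = int(round(1.0 / resolution))
    for comp in itertools.combinations(range(n + s - 1), s - 1):
        parts = []
        prev = -1
        for c in comp:
            parts.append(c - prev - 1)
            prev = c
        parts.append(n + s - 2 - prev)
        yield np.array(parts, dtype=float) / n


def best_pool_on_grid(f: np.ndarray, resolution: float = 0.01):
    """Exhaustive grid maximisation of 1 - c'fc over the simplex."""
    best_c, best_val = None, -np.inf
    for c in simplex_grid(f.shape[0], resolution):
        val = 1.0 - c @ f @ c
        if val > best_val:
            best_c, best_val = c, val
    return best_c, best_val


def exact_subset_counts(presence: dict[str, set[int]]):
    """Power-set enumeration of exactly-this-subset variant counts."""
    pops = list(presence)
    universe = set().union(*presence.values()) if presence else set()
    counts = {}
    for r in range(1, len(pops) + 1):
        for subset in itertools.combinations(pops, r):
            inside = set(universe)
            for p in subset:
                inside &= presence[p]
            for p in pops:
                if p not in subset:
                    inside -= presence[p]
            if inside:
                counts[frozenset(subset)] = len(inside)
    return counts
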