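"""Brute-force reference implementations used to cross-check the package.

Each oracle is deliberately naive (per-base loops, explicit ECDF scans,
full combinatorial enumeration) and shares no code with the implementation
it checks; they are only usable at small problem sizes.
"""

from itertools import combinations
from math import comb


def per_base_overlap_resolution(annotations):
    """Map each covered (scaffold, base) to the winning hit's (family, score).

    The winner at a base is the covering annotation with the highest score,
    ties broken by earlier start, then lexicographic family name.
    """
    owner = {}
    for a in annotations:
        key_priority = (-a.score, a.start, a.family)
        for base in range(a.start, a.end):
            k = (a.scaffold_id, base)
            if k not in owner or key_priority < owner[k][0]:
                owner[k] = (key_priority, (a.family, a.score))
    return {k: v[1] for k, v in owner.items()}


def per_base_window_te_bp(windows, lifted_intervals):
    """TE bp per window by per-base counting.

    ``lifted_intervals`` are (chromosome, start, end) already in chromosome
    coordinates; ``windows`` are (chromosome, start, end) triples.
    """
    counts = [0] * len(windows)
    for chrom, s, e in lifted_intervals:
        for base in range(s, e):
            for i, (wc, ws, we) in enumerate(windows):
                if wc == chrom and ws <= base < we:
                    counts[i] += 1
                    break
    return counts


def lift_interval(scaffold_length, offset, orientation, start, end):
    """Scaffold → chromosome coordinates, independent arithmetic."""
    if orientation == "reverse":
        start, end = scaffold_length - end, scaffold_length - start
    return offset + start, offset + end


def ks_statistic(sample_a, sample_b):
    """Maximum ECDF gap over the pooled support, by explicit counting."""
    support = sorted(set(sample_a) | set(sample_b))
    na, nb = len(sample_a), len(sample_b)
    best = 0.0
    for x in support:
        fa = sum(1 for v in sample_a if v <= x) / na
        fb = sum(1 for v in sample_b if v <= x) / nb
        best = max(best, abs(fa - fb))
    return best


def mann_whitney_exact_p(sample_a, sample_b):
    """Exact two-sided p by enumerating all group assignments (tie-free input).

    Counts assignments whose U statistic is at least as extreme (in the
    two-sided sense min(U, n_a n_b − U)) as the observed one.
    """
    pooled = sorted(sample_a) + sorted(sample_b)
    values = sorted(pooled)
    assert len(set(values)) == len(values), "oracle requires tie-free input"
    rank = {v: i + 1 for i, v in enumerate(values)}
    na, nb = len(sample_a), len(sample_b)
    nanb = na * nb

    def u_of(group):
        r = sum(rank[v] for v in group)
        return r - na * (na + 1) / 2

    u_obs = u_of(sample_a)
    extreme = min(u_obs, nanb - u_obs)
    hits = 0
    all_values = sorted(sample_a) + sorted(sample_b)
    for idx in combinations(range(na + nb), na):
        group = [all_values[i] for i in idx]
        u = u_of(group)
        if min(u, nanb - u) <= extreme + 1e-9:
            hits += 1
    return hits / comb(na + nb, na)
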