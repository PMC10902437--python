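"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own code paths: plain-Python loops
and direct textbook formulas only.
"""

from __future__ import annotations

import itertools

MISS = -1


def brute_r2_genotype(a, b):
    """Direct Pearson r² over pairwise-complete genotype codes; None when
    undefined (fewer than 2 complete pairs or a monomorphic site)."""
    xs, ys = [], []
    for x, y in zip(a, b):
        if x != MISS and y != MISS:
            xs.append(float(x))
            ys.append(float(y))
    n = len(xs)
    if n < 2:
        return None
    mx = sum(xs) / n
    my = sum(ys) / n
    vx = sum((x - mx) ** 2 for x in xs) / n
    vy = sum((y - my) ** 2 for y in ys) / n
    if vx == 0 or vy == 0:
        return None
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    return (cov * cov) / (vx * vy)


def brute_r2_haplotype(ha, hb):
    """Classical D²/(p(1-p)q(1-q)) by direct haplotype counting."""
    n = len(ha)
    pa = sum(ha) / n
    pb = sum(hb) / n
    if pa in (0, 1) or pb in (0, 1):
        return None
    pab = sum(1 for x, y in zip(ha, hb) if x == 1 and y == 1) / n
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def brute_nx(lengths, fraction):
    """Cumulative-sum N50/N90 oracle."""
    ordered = sorted(lengths, reverse=True)
    target = fraction * sum(ordered)
    acc = 0
    for ln in ordered:
        acc += ln
        if acc >= target:
            return ln
    raise AssertionError("unreachable")


def best_layout_score(scaffolds, candidate_edges):
    """Optimal total junction score by exhaustive search over all signed
    orderings of the scaffolds (junctions between consecutive elements are
    included whenever a candidate edge exists; chains split where none does).
    """

    def trailing(s, plus):
        return (s, "tail" if plus else "head")

    def leading(s, plus):
        return (s, "head" if plus else "tail")

    best = 0.0
    n = len(scaffolds)
    for perm in itertools.permutations(scaffolds):
        for signs in itertools.product((True, False), repeat=n):
            w = 0.0
            for i in range(n - 1):
                e = frozenset(
                    {trailing(perm[i], signs[i]), leading(perm[i + 1], signs[i + 1])}
                )
                w += candidate_edges.get(e, 0.0)
            if w > best:
                best = w
    return best


def maximal_reversed_runs(entries):
    """All maximal intervals of (id, sign, chrom) entries that are entirely
    negative, on one chromosome, with strictly decreasing ids — found by
    checking every interval (quadratic, independent of the scanning caller).
    """

    def qualifies(i, j):
        seg = entries[i:j]
        if any(s >= 0 for _, s, _ in seg):
            return False
        if len({c for _, _, c in seg}) != 1:
            return False
        ids = [b for b, _, _ in seg]
        return all(x > y for x, y in zip(ids, ids[1:]))

    runs = []
    n = len(entries)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not qualifies(i, j):
                continue
            if i > 0 and qualifies(i - 1, j):
                continue
            if j < n and qualifies(i, j + 1):
                continue
            runs.append((i, j))
    return runs


def fitch_ancestral(adj_presence):
    """Small-parsimony (Fitch) state at the (A,B) ancestor of (((A,B),C))
    for one adjacency given its presence at the three leaves; root ambiguity
    resolves to absent (absence is the unmarked state)."""
    a, b, c = ({1} if p else {0} for p in adj_presence)
    ab = (a & b) or (a | b)
    root_set = (ab & c) or (ab | c)
    root = 1 if root_set == {1} else 0
    anc = root if root in ab else next(iter(ab))
    return anc == 1
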