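"""Inversion/translocation calls from signed block permutations, and a
majority-rule ancestral-adjacency reconstruction for three genomes.

Blocks are numbered by their rank in one genome (the anchor); each other
genome is then a signed permutation of those serial numbers, listed in
anchor coordinate order per anchor chromosome.  Calls are read off runs of
the permutation; ancestral adjacencies follow a presence-in->=2-genomes
rule with matching-style conflict resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConsistencyError, ValidationError
from .synteny import ANCHOR, SyntenyBlock
from .variants import HEAD, TAIL

BlockEnd = tuple[int, str]  # (block_id, HEAD|TAIL)
Adjacency = frozenset  # frozenset of two BlockEnds


@dataclass(frozen=True)
class PermEntry:
    block_id: int  # other-genome serial index
    sign: int  # +1 / -1 relative to the anchor
    chrom: str  # other-genome chromosome

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValidationError("sign must be +1 or -1")


@dataclass
class SignedPermutation:
    genome: str
    chromosomes: dict  # anchor chromosome -> list[PermEntry] in anchor order

    def __post_init__(self):
        ids = [e.block_id for ents in self.chromosomes.values() for e in ents]
        if len(ids) != len(set(ids)):
            raise ValidationError("block ids must be unique across chromosomes")


@dataclass(frozen=True)
class RearrangementCall:
    type: str  # "inversion" | "translocation"
    anchor_chrom: str
    block_ids: tuple[int, ...]  # other-genome ids, contiguous in anchor order
    evidence: str  # "reversed run" | "chromosome switch" | "displacement"
    anchor_positions: tuple[int, ...] = ()  # 0-based positions in anchor order


def signed_permutation(
    blocks: list[SyntenyBlock], anchor: str = ANCHOR, other: str = "other"
) -> SignedPermutation:
    """The `other` genome as a signed permutation in anchor order."""
    for b in blocks:
        if anchor not in b.intervals or other not in b.intervals:
            raise ConsistencyError(
                f"block {b.block_id} missing genome {anchor!r} or {other!r}"
            )
    chroms: dict[str, list] = {}
    for b in sorted(blocks, key=lambda b: b.intervals[anchor][:3]):
        a_chrom = b.intervals[anchor][0]
        rel_sign = b.sign(other) * b.sign(anchor)
        chroms.setdefault(a_chrom, []).append(
            PermEntry(b.index[other], rel_sign, b.intervals[other][0])
        )
    return SignedPermutation(other, chroms)


def _as_perm(perm) -> SignedPermutation:
    if isinstance(perm, SignedPermutation):
        return perm
    # plain {chrom: [(id, sign), ...]} or [(id, sign), ...] accepted for tests
    if isinstance(perm, dict):
        chroms = {
            c: [PermEntry(i, s, "chr") for i, s in ents] for c, ents in perm.items()
        }
    else:
        chroms = {"chr": [PermEntry(i, s, "chr") for i, s in perm]}
    return SignedPermutation("other", chroms)


def call_inversions(perm) -> list[RearrangementCall]:
    """One call per maximal run of negative blocks on one other-chromosome
    with strictly decreasing indices; single negatives qualify."""
    perm = _as_perm(perm)
    calls = []
    for a_chrom, entries in perm.chromosomes.items():
        i = 0
        while i < len(entries):
            if entries[i].sign >= 0:
                i += 1
                continue
            j = i + 1
            while (
                j < len(entries)
                and entries[j].sign < 0
                and entries[j].chrom == entries[i].chrom
                and entries[j].block_id < entries[j - 1].block_id
            ):
                j += 1
            calls.append(
                RearrangementCall(
                    "inversion",
                    a_chrom,
                    tuple(e.block_id for e in entries[i:j]),
                    "reversed run",
                    tuple(range(i, j)),
                )
            )
            i = j
    return calls


def _chrom_runs(entries: list[PermEntry]) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of identical other-chromosome."""
    runs = []
    i = 0
    while i < len(entries):
        j = i + 1
        while j < len(entries) and entries[j].chrom == entries[i].chrom:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def _collinear_runs(entries: list[PermEntry]) -> list[tuple[int, int]]:
    """Maximal [start, end) runs advancing by +1 (positive) or -1 (negative)
    on one other-chromosome."""
    runs = []
    i = 0
    while i < len(entries):
        j = i + 1
        while (
            j < len(entries)
            and entries[j].chrom == entries[i].chrom
            and entries[j].sign == entries[i].sign
            and entries[j].block_id - entries[j - 1].block_id == entries[i].sign
        ):
            j += 1
        runs.append((i, j))
        i = j
    return runs


def call_translocations(perm) -> list[RearrangementCall]:
    """Interchromosomal runs plus intrachromosomal displacements.

    (a) a maximal same-chromosome run is a translocation when it maps away
    from the anchor chromosome's plurality (home) chromosome and both
    flanking runs exist and map to different chromosomes (anchor-chromosome
    ends count as agreeing flanks, so end runs and whole-chromosome runs are
    not called); (b) a collinear run not qualifying as an inversion is a
    displacement when its other-index interval is adjacent to neither of the
    nearest same-chromosome flanking runs at the facing boundary (chromosome
    ends again count as adjacent).
    """
    perm = _as_perm(perm)
    calls = []
    for a_chrom, entries in perm.chromosomes.items():
        counts: dict[str, int] = {}
        for e in entries:
            counts[e.chrom] = counts.get(e.chrom, 0) + 1
        home = min(counts, key=lambda c: (-counts[c], c))
        interchrom: set[tuple[int, int]] = set()
        runs = _chrom_runs(entries)
        for k, (i, j) in enumerate(runs):
            left = entries[runs[k - 1][0]].chrom if k > 0 else None
            right = entries[runs[k + 1][0]].chrom if k + 1 < len(runs) else None
            if left is None or right is None:
                continue  # end flanks agree with anything
            if (
                entries[i].chrom != home
                and left != entries[i].chrom
                and right != entries[i].chrom
            ):
                interchrom.add((i, j))
                calls.append(
                    RearrangementCall(
                        "translocation",
                        a_chrom,
                        tuple(e.block_id for e in entries[i:j]),
                        "chromosome switch",
                        tuple(range(i, j)),
                    )
                )
        inter_positions = {p for i, j in interchrom for p in range(i, j)}
        cruns = _collinear_runs(entries)
        for k, (i, j) in enumerate(cruns):
            if entries[i].sign < 0:
                continue  # inversion territory
            if any(p in inter_positions for p in range(i, j)):
                continue  # already called interchromosomal
            # flanks: nearest collinear runs on the same other-chromosome;
            # boundary ids are taken with any flank inversion undone (a
            # negative run faces with its max id on the left, min on the
            # right), so runs bordering an inversion are not displaced
            left_adj = True
            for li, lj in reversed(cruns[:k]):
                if entries[li].chrom != entries[i].chrom:
                    continue
                boundary = max(entries[li].block_id, entries[lj - 1].block_id)
                left_adj = abs(entries[i].block_id - boundary) == 1
                break
            right_adj = True
            for ri, rj in cruns[k + 1 :]:
                if entries[ri].chrom != entries[j - 1].chrom:
                    continue
                boundary = min(entries[ri].block_id, entries[rj - 1].block_id)
                right_adj = abs(boundary - entries[j - 1].block_id) == 1
                break
            if not left_adj and not right_adj:
                calls.append(
                    RearrangementCall(
                        "translocation",
                        a_chrom,
                        tuple(e.block_id for e in entries[i:j]),
                        "displacement",
                        tuple(range(i, j)),
                    )
                )
    return calls


def call_rearrangements(perm) -> list[RearrangementCall]:
    """Combined calls; interchromosomal runs are never double-reported as
    inversions (each anchor block belongs to at most one call)."""
    perm = _as_perm(perm)
    trans = call_translocations(perm)
    trans_ids = {bid for c in trans for bid in c.block_ids}
    inv = [
        c
        for c in call_inversions(perm)
        if not any(bid in trans_ids for bid in c.block_ids)
    ]
    return inv + trans


# --------------------------------------------------------------------------
# adjacencies and the three-genome ancestor


def adjacency(a: BlockEnd, b: BlockEnd) -> Adjacency:
    if a == b:
        raise ValidationError("adjacency ends must differ")
    return frozenset({a, b})


def adjacencies(order) -> set[Adjacency]:
    """Adjacency set of a signed block order.

    Accepts a SignedPermutation, a {chrom: [(id, sign), ...]} dict, or a
    single [(id, sign), ...] chromosome.  For consecutive signed blocks a, b
    the adjacency joins a's trailing end with b's leading end (+a trails with
    its tail, -a with its head).
    """
    perm = _as_perm(order)
    out: set[Adjacency] = set()
    for entries in perm.chromosomes.values():
        for a, b in zip(entries, entries[1:]):
            trailing = (a.block_id, TAIL if a.sign > 0 else HEAD)
            leading = (b.block_id, HEAD if b.sign > 0 else TAIL)
            out.add(adjacency(trailing, leading))
    return out


def _adj_key(adj: Adjacency) -> tuple:
    return tuple(sorted(adj))


def _block_ids(order) -> set[int]:
    perm = _as_perm(order)
    return {e.block_id for ents in perm.chromosomes.values() for e in ents}


def ancestral_adjacencies(genome_a, genome_b, genome_c) -> dict:
    """Majority-rule ancestor of the ((A,B),C) topology.

    An adjacency is ancestral iff present in >= 2 of the 3 genomes; end-use
    conflicts drop the adjacency with lower support, then the
    lexicographically larger one; any cycle in the chained result is broken
    at its lexicographically largest adjacency.  Returns the ancestral set,
    its chains (contiguous ancestral regions as signed block orders) and the
    adjacencies derived in / lost from genome A.
    """
    ids = _block_ids(genome_a)
    if _block_ids(genome_b) != ids or _block_ids(genome_c) != ids:
        raise ConsistencyError("the three genomes must share one block set")
    sets = [adjacencies(g) for g in (genome_a, genome_b, genome_c)]
    support: dict[Adjacency, int] = {}
    for s in sets:
        for adj in s:
            support[adj] = support.get(adj, 0) + 1
    candidates = sorted(
        (a for a, n in support.items() if n >= 2),
        key=lambda a: (-support[a], _adj_key(a)),
    )
    used: set[BlockEnd] = set()
    chosen: list[Adjacency] = []
    dropped: list[Adjacency] = []
    for adj in candidates:
        if any(end in used for end in adj):
            dropped.append(adj)
            continue
        chosen.append(adj)
        used.update(adj)
    ancestral, cycles_broken = _break_cycles(set(chosen), ids)
    chains = _chains(ancestral, ids)
    set_a = sets[0]
    return {
        "ancestral": ancestral,
        "chains": chains,
        "derived_in_a": sorted(set_a - ancestral, key=_adj_key),
        "lost_in_a": sorted(ancestral - set_a, key=_adj_key),
        "conflicts_dropped": dropped,
        "cycles_broken": cycles_broken,
    }


def _partner_map(adjs: set[Adjacency]) -> dict[BlockEnd, BlockEnd]:
    partner: dict[BlockEnd, BlockEnd] = {}
    for adj in adjs:
        a, b = sorted(adj)
        if a in partner or b in partner:
            raise ValidationError("adjacency set uses an end twice")
        partner[a] = b
        partner[b] = a
    return partner


def _break_cycles(
    adjs: set[Adjacency], ids: set[int]
) -> tuple[set[Adjacency], list[Adjacency]]:
    """Remove the lexicographically largest adjacency of every cycle."""
    removed: list[Adjacency] = []
    while True:
        partner = _partner_map(adjs)
        cycle = _find_cycle(partner, ids)
        if cycle is None:
            return adjs, removed
        worst = max(cycle, key=_adj_key)
        removed.append(worst)
        adjs = adjs - {worst}


def _find_cycle(partner, ids) -> list[Adjacency] | None:
    seen: set[int] = set()
    for start in sorted(ids):
        if start in seen:
            continue
        cur = (start, HEAD)
        edges: list[Adjacency] = []
        is_cycle = False
        for _ in range(2 * len(ids) + 1):
            seen.add(cur[0])
            exit_end = (cur[0], TAIL if cur[1] == HEAD else HEAD)
            nxt = partner.get(exit_end)
            if nxt is None:
                # walk the other direction to mark the rest of the path
                back = partner.get((start, HEAD))
                while back is not None:
                    seen.add(back[0])
                    back = partner.get((back[0], TAIL if back[1] == HEAD else HEAD))
                break
            edges.append(frozenset({exit_end, nxt}))
            cur = nxt
            if cur[0] == start:
                is_cycle = True
                break
        if is_cycle:
            return edges
    return None


def _chains(adjs: set[Adjacency], ids: set[int]) -> list[list[tuple[int, int]]]:
    """Linear contiguous runs (signed block orders) implied by an acyclic
    adjacency set; singleton blocks become length-1 chains."""
    partner = _partner_map(adjs)
    chains: list[list[tuple[int, int]]] = []
    seen: set[int] = set()
    for start in sorted(ids):
        if start in seen:
            continue
        # rewind to a free end
        entry = (start, HEAD)
        for _ in range(2 * len(ids) + 1):
            exit_end = (entry[0], TAIL if entry[1] == HEAD else HEAD)
            # moving backwards: the previous block connects into `entry`
            prev = partner.get(entry)
            if prev is None:
                break
            entry = (prev[0], TAIL if prev[1] == HEAD else HEAD)
        chain: list[tuple[int, int]] = []
        cur = entry
        while True:
            seen.add(cur[0])
            chain.append((cur[0], 1 if cur[1] == HEAD else -1))
            exit_end = (cur[0], TAIL if cur[1] == HEAD else HEAD)
            nxt = partner.get(exit_end)
            if nxt is None:
                break
            cur = nxt
        # canonical direction: smaller (id, sign-order) sequence first
        rev = [(i, -s) for i, s in reversed(chain)]
        if [(i, 0 if s > 0 else 1) for i, s in rev] < [
            (i, 0 if s > 0 else 1) for i, s in chain
        ]:
            chain = rev
        chains.append(chain)
    chains.sort(key=lambda c: c[0][0])
    return chains
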