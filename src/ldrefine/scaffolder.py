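"""Super-scaffolding: terminal matching, cycle linearization, emission.

Scaffold terminals (head/tail of every scaffold) form a graph whose
obligatory internal edges pair each scaffold's two ends and whose candidate
edges are the inter-scaffold linkage scores above the cutoff.  A maximum
weight matching on candidate edges, unioned with the internal edges,
decomposes into simple paths and cycles; cycles are linearized by deleting
their weakest matching edge.  Because deleting a cycle edge can free
terminals for better partners, the acyclic optimum is recomputed after any
cycle is found — exactly at small scale, by iterative re-matching at large
scale (see :func:`solve_layout`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx

from ._util import revcomp, write_fasta
from .errors import ConsistencyError, ValidationError
from .ldscore import LinkageScoreMatrix
from .variants import HEAD, TAIL

Terminal = tuple[str, str]
Edge = frozenset  # frozenset of two Terminals


@dataclass
class ScaffoldGraph:
    scaffolds: list[str]
    candidate_edges: dict  # Edge -> score, all > threshold
    threshold: float

    def __post_init__(self):
        for e, s in self.candidate_edges.items():
            (s1, _), (s2, _) = sorted(e)
            if s1 == s2:
                raise ValidationError(f"candidate edge within scaffold {s1}")
            if not s > self.threshold:
                raise ValidationError("candidate edge at or below threshold")


@dataclass
class ScaffoldLayout:
    """Ordered, signed super-scaffolds plus the edges cut to linearize them."""

    super_scaffolds: list[list[tuple[str, str]]]  # [(scaffold_id, '+'|'-'), ...]
    junction_scores: list[list[float]]  # per super-scaffold, len-1 scores
    removed_edges: list[tuple[tuple[Terminal, Terminal], float]]
    singletons: list[str]

    def all_scaffolds(self) -> list[str]:
        out = [s for ss in self.super_scaffolds for s, _ in ss]
        out.extend(self.singletons)
        return out

    def junctions(self) -> set[Edge]:
        """Terminal pairs joined by this layout (orientation-aware)."""
        out: set[Edge] = set()
        for ss in self.super_scaffolds:
            for (a, sa), (b, sb) in zip(ss, ss[1:]):
                out.add(frozenset({_trailing(a, sa), _leading(b, sb)}))
        return out

    @property
    def total_score(self) -> float:
        return float(sum(sum(js) for js in self.junction_scores))


def _trailing(scaffold: str, strand: str) -> Terminal:
    return (scaffold, TAIL if strand == "+" else HEAD)


def _leading(scaffold: str, strand: str) -> Terminal:
    return (scaffold, HEAD if strand == "+" else TAIL)


def build_graph(matrix: LinkageScoreMatrix, threshold: float) -> ScaffoldGraph:
    """Candidate edges are exactly the inter-scaffold cells with score
    strictly above the threshold."""
    candidates = {
        frozenset({a, b}): s for a, b, s in matrix.iter_defined() if s > threshold
    }
    scaffolds = sorted({s for s, _ in matrix.terminals})
    return ScaffoldGraph(scaffolds, candidates, threshold)


# --------------------------------------------------------------------------
# layout solving


def _edge_key(e: Edge) -> tuple:
    return tuple(sorted(e))


def _max_matching(candidates: dict, forbidden: set) -> tuple[set[Edge], float]:
    g = nx.Graph()
    for e, s in sorted(candidates.items(), key=lambda kv: _edge_key(kv[0])):
        if e not in forbidden:
            a, b = sorted(e)
            g.add_edge(a, b, weight=s)
    matching = {frozenset(pair) for pair in nx.max_weight_matching(g)}
    weight = sum(candidates[e] for e in matching)
    return matching, weight


def _find_cycles(matching: set[Edge], scaffolds: list[str]) -> list[list[Edge]]:
    """Cycles of the union graph (matching + internal edges), each returned
    as its list of matching edges."""
    partner: dict[Terminal, Terminal] = {}
    for e in matching:
        a, b = sorted(e)
        partner[a] = b
        partner[b] = a
    cycles = []
    seen: set[str] = set()
    for start in sorted(scaffolds):
        if start in seen:
            continue
        # walk the chain of scaffolds starting here
        chain = []
        terminal = (start, HEAD)
        # rewind to a free terminal if this component is a path
        is_cycle = True
        probe = terminal
        for _ in range(2 * len(scaffolds) + 1):
            if probe not in partner:
                is_cycle = False
                terminal = probe
                break
            probe = partner[probe]
            probe = (probe[0], TAIL if probe[1] == HEAD else HEAD)
            if probe == terminal:
                break
        # traverse forward collecting scaffolds and matching edges
        edges: list[Edge] = []
        cur = terminal
        while True:
            scaffold = cur[0]
            if scaffold in seen:
                break
            seen.add(scaffold)
            chain.append(scaffold)
            exit_t = (scaffold, TAIL if cur[1] == HEAD else HEAD)
            nxt = partner.get(exit_t)
            if nxt is None:
                break
            edges.append(frozenset({exit_t, nxt}))
            cur = nxt
        if is_cycle and edges:
            cycles.append(edges)
    return cycles


_EXACT_MAX_SCAFFOLDS = 12


def _exact_acyclic(candidates: dict, scaffolds: list[str]) -> tuple[set[Edge], float]:
    """Maximum-weight acyclic matching by exhaustive search with union-find
    cycle rejection (feasible for small scaffold counts only).

    A junction set is acyclic iff, merging scaffolds as junctions are added,
    no junction ever joins two scaffolds already in one chain component.
    """
    terminals = sorted({t for e in candidates for t in e})
    edges_at: dict[Terminal, list[tuple[Terminal, Edge, float]]] = {t: [] for t in terminals}
    for e, s in candidates.items():
        a, b = sorted(e)
        edges_at[a].append((b, e, s))
        edges_at[b].append((a, e, s))
    for t in terminals:
        edges_at[t].sort(key=lambda x: (-x[2], x[0]))
    best_at = {t: (edges_at[t][0][2] if edges_at[t] else 0.0) for t in terminals}
    # suffix upper bound: half the sum of each later terminal's best edge
    suffix = [0.0] * (len(terminals) + 1)
    for i in range(len(terminals) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + 0.5 * best_at[terminals[i]]

    best = {"w": -1.0, "m": set()}

    def find(parent, s):
        while parent[s] != s:
            s = parent[s]
        return s

    def rec(i, used, parent, w, m):
        if w + suffix[i] <= best["w"] + 1e-15:
            return
        if i == len(terminals):
            if w > best["w"]:
                best["w"], best["m"] = w, set(m)
            return
        t = terminals[i]
        if t in used:
            rec(i + 1, used, parent, w, m)
            return
        for u, e, s in edges_at[t]:
            if u in used or u < t:
                continue
            ra, rb = find(parent, t[0]), find(parent, u[0])
            if ra == rb:
                continue  # would close a cycle through internal edges
            p2 = dict(parent)
            p2[ra] = rb
            rec(i + 1, used | {t, u}, p2, w + s, m + [e])
        rec(i + 1, used, parent, w, m)  # leave t unmatched

    rec(0, set(), {s: s for s in scaffolds}, 0.0, [])
    return best["m"], best["w"]


def _linearize_iterative(
    candidates: dict, scaffolds: list[str]
) -> tuple[set[Edge], list[Edge]]:
    """Match, delete every cycle's minimum-score edge, re-match; repeat.

    Polynomial fallback for large graphs; not guaranteed optimal."""
    forbidden: set[Edge] = set()
    removed: list[Edge] = []
    while True:
        matching, _ = _max_matching(candidates, forbidden)
        cycles = _find_cycles(matching, scaffolds)
        if not cycles:
            return matching, removed
        for cyc in cycles:
            e = min(cyc, key=lambda e: (candidates[e], _edge_key(e)))
            forbidden.add(e)
            removed.append(e)


def solve_layout(graph: ScaffoldGraph) -> ScaffoldLayout:
    """Order and orient scaffolds by maximum-weight terminal matching.

    Cycles are linearized by deleting their minimum-score matching edge.
    Deleting a cycle edge frees terminals for better partners, so after a
    cycle is found the acyclic optimum is recomputed — exactly (exhaustive
    search) up to 12 scaffolds, else by iterative delete-and-rematch.  When
    the initial matching is already acyclic it is the provable optimum (its
    weight upper-bounds every acyclic matching).  ``removed_edges`` records
    initial-matching cycle edges absent from the final layout.
    """
    matching, _ = _max_matching(graph.candidate_edges, set())
    cycles = _find_cycles(matching, graph.scaffolds)
    if cycles:
        cycle_edges = {e for cyc in cycles for e in cyc}
        if len(graph.scaffolds) <= _EXACT_MAX_SCAFFOLDS:
            final, _ = _exact_acyclic(graph.candidate_edges, graph.scaffolds)
        else:
            final, _ = _linearize_iterative(graph.candidate_edges, graph.scaffolds)
        removed = sorted(cycle_edges - final, key=_edge_key)
        matching = final
    else:
        removed = []
    removed_edges = [(_edge_key(e), graph.candidate_edges[e]) for e in removed]

    partner: dict[Terminal, Terminal] = {}
    for e in matching:
        a, b = sorted(e)
        partner[a] = b
        partner[b] = a

    supers: list[list[tuple[str, str]]] = []
    scores: list[list[float]] = []
    singletons: list[str] = []
    seen: set[str] = set()
    for scaffold in sorted(graph.scaffolds):
        if scaffold in seen:
            continue
        if (scaffold, HEAD) not in partner and (scaffold, TAIL) not in partner:
            seen.add(scaffold)
            singletons.append(scaffold)
            continue
        # find the free terminal of this path component
        start = None
        probe = (scaffold, HEAD)
        for _ in range(2 * len(graph.scaffolds) + 1):
            if probe not in partner:
                start = probe
                break
            probe = partner[probe]
            probe = (probe[0], TAIL if probe[1] == HEAD else HEAD)
        assert start is not None, "cycle survived linearization"
        chain: list[tuple[str, str]] = []
        junc: list[float] = []
        cur = start
        while True:
            s = cur[0]
            seen.add(s)
            chain.append((s, "+" if cur[1] == HEAD else "-"))
            exit_t = (s, TAIL if cur[1] == HEAD else HEAD)
            nxt = partner.get(exit_t)
            if nxt is None:
                break
            junc.append(graph.candidate_edges[frozenset({exit_t, nxt})])
            cur = nxt
        chain, junc = _canonical(chain, junc)
        supers.append(chain)
        scores.append(junc)
    order = sorted(range(len(supers)), key=lambda i: supers[i][0][0])
    return ScaffoldLayout(
        [supers[i] for i in order],
        [scores[i] for i in order],
        removed_edges,
        singletons,
    )


def _canonical(chain, junc):
    """Pick the traversal direction whose first (id, strand) is smaller;
    '+' sorts before '-' so a single scaffold canonicalizes to '+'."""
    rev = [(s, "-" if st == "+" else "+") for s, st in reversed(chain)]

    def key(c):
        return [(s, 0 if st == "+" else 1) for s, st in c]

    if key(rev) < key(chain):
        return rev, list(reversed(junc))
    return chain, junc


# --------------------------------------------------------------------------
# emission


def emit_super_scaffolds(
    layout: ScaffoldLayout,
    scaffold_sequences: dict[str, str],
    gap_length: int = 100,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Materialize the layout: (name, sequence) records plus AGP rows.

    Components are joined with N-runs of ``gap_length``; strand '-'
    components are reverse-complemented.  Singletons pass through unchanged
    (single-component AGP objects named after themselves).
    """
    for s in layout.all_scaffolds():
        if s not in scaffold_sequences:
            raise ConsistencyError(f"no sequence for scaffold {s}")
    records: list[tuple[str, str]] = []
    objects: dict[str, list[tuple[str, str]]] = {}
    for i, ss in enumerate(layout.super_scaffolds, start=1):
        name = f"super_{i}"
        parts = []
        for s, strand in ss:
            seq = scaffold_sequences[s]
            parts.append(revcomp(seq) if strand == "-" else seq)
        records.append((name, ("N" * gap_length).join(parts)))
        objects[name] = list(ss)
    for s in layout.singletons:
        records.append((s, scaffold_sequences[s]))
        objects[s] = [(s, "+")]
    lengths = {s: len(scaffold_sequences[s]) for s in layout.all_scaffolds()}
    agp_rows = agp_lines(objects, lengths, gap_length)
    return records, agp_rows


def agp_lines(
    objects: dict[str, list[tuple[str, str]]],
    component_lengths: dict[str, int],
    gap_length: int = 100,
) -> list[str]:
    """AGP v2.1 rows: W component lines alternating with U gap lines."""
    rows = ["##agp-version 2.1"]
    for name, comps in objects.items():
        pos = 0
        part = 0
        for k, (comp, strand) in enumerate(comps):
            if k > 0:
                part += 1
                rows.append(
                    f"{name}\t{pos + 1}\t{pos + gap_length}\t{part}\tU\t"
                    f"{gap_length}\tscaffold\tyes\talign_genus"
                )
                pos += gap_length
            clen = component_lengths[comp]
            part += 1
            rows.append(
                f"{name}\t{pos + 1}\t{pos + clen}\t{part}\tW\t{comp}\t1\t{clen}\t{strand}"
            )
            pos += clen
    return rows


def write_agp(
    path: str | os.PathLike,
    objects: dict[str, list[tuple[str, str]]],
    component_lengths: dict[str, int],
    gap_length: int = 100,
) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(agp_lines(objects, component_lengths, gap_length)) + "\n")


def agp_to_fasta(
    agp_rows: list[str], component_sequences: dict[str, str]
) -> dict[str, str]:
    """Rebuild object sequences from AGP rows + component FASTA (round-trip
    check for :func:`emit_super_scaffolds`)."""
    out: dict[str, list[str]] = {}
    for row in agp_rows:
        if row.startswith("#") or not row.strip():
            continue
        f = row.split("\t")
        name, ctype = f[0], f[4]
        parts = out.setdefault(name, [])
        if ctype == "U" or ctype == "N":
            parts.append("N" * int(f[5]))
        elif ctype == "W":
            comp, beg, end, strand = f[5], int(f[6]), int(f[7]), f[8]
            seq = component_sequences[comp][beg - 1 : end]
            parts.append(revcomp(seq) if strand == "-" else seq)
        else:
            raise ValidationError(f"unsupported AGP component type {ctype!r}")
    return {name: "".join(parts) for name, parts in out.items()}


def read_agp(path: str | os.PathLike) -> dict[str, list[tuple[str, str]]]:
    """Read AGP back into {object: [(component, strand), ...]} (gaps implied)."""
    objects: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for row in fh:
            if row.startswith("#") or not row.strip():
                continue
            f = row.rstrip("\n").split("\t")
            if f[4] == "W":
                objects.setdefault(f[0], []).append((f[5], f[8]))
    return objects


# --------------------------------------------------------------------------
# truth comparison


def compare_to_truth(
    layout: ScaffoldLayout,
    truth_adjacencies: list[tuple[str, str, str, str]],
) -> dict:
    """Adjacency precision/recall and orientation accuracy against truth.

    A called junction is correct iff it joins the same two terminals as a
    true junction (direction-independent).  Orientation accuracy is scored
    over junctions joining a correct scaffold pair: the fraction whose
    terminal pair (hence relative strand) also matches.
    """
    known = set(layout.all_scaffolds())
    for sa, ea, sb, eb in truth_adjacencies:
        for s in (sa, sb):
            if s not in known:
                raise ConsistencyError(f"truth references unknown scaffold {s}")
    truth = {frozenset({(sa, ea), (sb, eb)}) for sa, ea, sb, eb in truth_adjacencies}
    called = layout.junctions()
    correct = called & truth

    def pair(j):
        return frozenset(s for s, _ in j)

    truth_pairs = {pair(j) for j in truth}
    pair_correct = [j for j in called if pair(j) in truth_pairs]
    n_called, n_true = len(called), len(truth)
    return {
        "n_called": n_called,
        "n_true": n_true,
        "n_correct": len(correct),
        "precision": len(correct) / n_called if n_called else None,
        "recall": len(correct) / n_true if n_true else None,
        "orientation_accuracy": (
            sum(1 for j in pair_correct if j in truth) / len(pair_correct)
            if pair_correct
            else None
        ),
    }
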