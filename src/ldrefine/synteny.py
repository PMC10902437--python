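"""Alignment-coordinate parsing, block filters and multi-genome intersection.

The coords dialect is tab-separated with optional ``#`` comment lines and
columns ref_start, ref_end, qry_start, qry_end, ref_alnlen, qry_alnlen,
pct_identity, ref_id, qry_id (1-based inclusive).  A query interval written
start > end encodes the '-' strand; intervals are normalized to (min, max)
with an explicit strand on input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .errors import FormatError, ValidationError

Interval = tuple[str, int, int]  # (chrom, start, end), 1-based closed


@dataclass(frozen=True)
class AlignmentBlock:
    ref_id: str
    ref_start: int
    ref_end: int
    qry_id: str
    qry_start: int
    qry_end: int
    strand: str  # '+' | '-'
    identity: float  # percent

    def __post_init__(self):
        if self.ref_start > self.ref_end or self.qry_start > self.qry_end:
            raise ValidationError("intervals must be normalized (start <= end)")
        if not 0.0 <= self.identity <= 100.0:
            raise ValidationError("identity must be in [0, 100]")
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def ref_interval(self) -> Interval:
        return (self.ref_id, self.ref_start, self.ref_end)

    @property
    def qry_interval(self) -> Interval:
        return (self.qry_id, self.qry_start, self.qry_end)


def read_coords(path: str | os.PathLike) -> list[AlignmentBlock]:
    """Parse a coords-dialect table; '#' lines are comments."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(f)}")
            try:
                rs, re_, qs, qe = (int(v) for v in f[:4])
                idy = float(f[6])
                ref_id, qry_id = f[7], f[8]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            strand = "-" if qs > qe else "+"
            try:
                blocks.append(
                    AlignmentBlock(
                        ref_id, rs, re_, qry_id, min(qs, qe), max(qs, qe), strand, idy
                    )
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return blocks


def filter_blocks(
    blocks: list[AlignmentBlock], min_len: int = 2_000, min_idy: float = 90.0
) -> list[AlignmentBlock]:
    """Keep blocks with reference length >= min_len and identity >= min_idy."""
    return [b for b in blocks if b.ref_len >= min_len and b.identity >= min_idy]


def overlap_fraction(a: Interval, b: Interval) -> float:
    """|a intersect b| / min(|a|, |b|) on closed 1-based intervals."""
    if a[0] != b[0]:
        raise ValidationError(
            f"overlap_fraction on different chromosomes {a[0]!r} vs {b[0]!r}"
        )
    inter = min(a[2], b[2]) - max(a[1], b[1]) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a[2] - a[1] + 1, b[2] - b[1] + 1)


@dataclass(frozen=True)
class SharedRegion:
    """An anchor interval with its matched interval per comparison genome."""

    anchor: Interval
    matches: dict  # genome -> (Interval, strand)
    overlaps: dict  # genome -> overlap fraction recorded at intersection time

    def genomes(self) -> list[str]:
        return sorted(self.matches)


def intersect_homologs(
    comparisons: list[tuple[str, list[AlignmentBlock]]],
    overlap_min: float = 0.8,
) -> list[SharedRegion]:
    """Successively intersect per-comparison blocks on the shared anchor.

    Starts from the first comparison's anchor intervals; at each later
    comparison an anchor region survives only if some block's reference
    interval overlaps it by strictly more than ``overlap_min`` (of the
    shorter interval), and is replaced by the intersection.  Each surviving
    region carries every genome's matched query interval and strand.
    """
    if not comparisons:
        raise ValidationError("need at least one comparison")
    genome0, blocks0 = comparisons[0]
    regions = [
        SharedRegion(
            b.ref_interval,
            {genome0: (b.qry_interval, b.strand)},
            {genome0: 1.0},
        )
        for b in sorted(blocks0, key=lambda b: b.ref_interval)
    ]
    for genome, blocks in comparisons[1:]:
        by_chrom: dict[str, list[AlignmentBlock]] = {}
        for b in blocks:
            by_chrom.setdefault(b.ref_id, []).append(b)
        nxt: list[SharedRegion] = []
        for region in regions:
            chrom, start, end = region.anchor
            best, best_frac = None, overlap_min
            for b in by_chrom.get(chrom, ()):
                frac = overlap_fraction(region.anchor, b.ref_interval)
                if frac > best_frac or (
                    best is not None
                    and frac == best_frac
                    and b.ref_interval < best.ref_interval
                ):
                    best, best_frac = b, frac
            if best is None:
                continue
            anchor = (chrom, max(start, best.ref_start), min(end, best.ref_end))
            nxt.append(
                SharedRegion(
                    anchor,
                    {**region.matches, genome: (best.qry_interval, best.strand)},
                    {**region.overlaps, genome: best_frac},
                )
            )
        regions = nxt
    return regions


@dataclass(frozen=True)
class SyntenyBlock:
    """A homologous interval present in every genome of the block set, with a
    per-genome rank along that genome's coordinate order."""

    block_id: int
    intervals: dict  # genome -> (chrom, start, end, strand)
    index: dict  # genome -> 1-based rank by (chrom, start)

    def chrom(self, genome: str) -> str:
        return self.intervals[genome][0]

    def sign(self, genome: str) -> int:
        return -1 if self.intervals[genome][3] == "-" else 1


ANCHOR = "anchor"


def threeway_blocks(
    regions: list[SharedRegion],
    min_len: int = 10_000,
    overlap_min: float = 0.8,
) -> list[SyntenyBlock]:
    """Synteny blocks for the anchor plus its comparator genomes.

    Keeps shared regions whose anchor interval is strictly longer than
    ``min_len`` and whose recorded overlap exceeds ``overlap_min`` in every
    genome; indices are assigned per genome by (chrom, start) sort; signs are
    relative to the anchor (defined '+')."""
    kept = [
        r
        for r in regions
        if (r.anchor[2] - r.anchor[1] + 1) > min_len
        and all(f > overlap_min for f in r.overlaps.values())
    ]
    kept.sort(key=lambda r: r.anchor)
    if not kept:
        return []
    genomes = kept[0].genomes()
    blocks = []
    for i, r in enumerate(kept, start=1):
        intervals = {ANCHOR: (*r.anchor, "+")}
        for g in genomes:
            (chrom, s, e), strand = r.matches[g]
            intervals[g] = (chrom, s, e, strand)
        blocks.append(SyntenyBlock(i, intervals, {}))
    _assign_indices(blocks, [ANCHOR, *genomes])
    return blocks


def pairwise_synteny(
    blocks: list[AlignmentBlock], anchor: str = ANCHOR, other: str = "other"
) -> list[SyntenyBlock]:
    """Synteny blocks from a single filtered comparison (one block per
    alignment block); block ids follow the anchor coordinate order."""
    ordered = sorted(blocks, key=lambda b: b.ref_interval)
    out = []
    for i, b in enumerate(ordered, start=1):
        out.append(
            SyntenyBlock(
                i,
                {
                    anchor: (b.ref_id, b.ref_start, b.ref_end, "+"),
                    other: (b.qry_id, b.qry_start, b.qry_end, b.strand),
                },
                {},
            )
        )
    _assign_indices(out, [anchor, other])
    return out


def _assign_indices(blocks: list[SyntenyBlock], genomes: list[str]) -> None:
    for g in genomes:
        order = sorted(
            range(len(blocks)), key=lambda i: blocks[i].intervals[g][:3]
        )
        for rank, i in enumerate(order, start=1):
            blocks[i].index[g] = rank
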