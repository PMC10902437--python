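"""Assembly length statistics (contig counts, N50/N90, N content)."""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

from ._util import read_fasta
from .errors import ValidationError

LENGTH_THRESHOLDS = (0, 1_000, 5_000, 10_000, 25_000, 50_000)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: dict[int, int]  # threshold -> count of sequences >= threshold
    total_lengths: dict[int, int]  # threshold -> summed length
    largest: int
    total: int
    n50: int
    n90: int
    ns_per_100kbp: float
    min_length: int = 0  # sequences below this were ignored entirely

    def __post_init__(self):
        counts = [self.n_contigs[t] for t in sorted(self.n_contigs)]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValidationError("contig counts must be non-increasing in threshold")
        if not (self.n90 <= self.n50 <= self.largest <= self.total):
            raise ValidationError("expected n90 <= n50 <= largest <= total")


def nx_length(lengths: list[int], fraction: float) -> int:
    """Length of the sequence at which the descending cumulative length first
    reaches ``fraction`` of the total."""
    if not lengths:
        raise ValidationError("no sequences")
    ordered = sorted(lengths, reverse=True)
    target = fraction * sum(ordered)
    acc = 0
    for ln in ordered:
        acc += ln
        if acc >= target:
            return ln
    return ordered[-1]  # unreachable for fraction <= 1


def assembly_stats(
    sequences: dict[str, str] | list[str] | str | os.PathLike,
    min_length: int = 0,
) -> AssemblyStats:
    """Compute length statistics for a FASTA path, a name->sequence dict, or
    a plain list of sequences.  Ns are counted case-insensitively."""
    if isinstance(sequences, (str, os.PathLike)):
        sequences = read_fasta(sequences)
    seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    seqs = [s for s in seqs if len(s) >= min_length]
    if not seqs:
        raise ValidationError("no sequences (after min_length filter)")
    lengths = [len(s) for s in seqs]
    total = sum(lengths)
    n_count = sum(s.upper().count("N") for s in seqs)
    return AssemblyStats(
        n_contigs={t: sum(1 for ln in lengths if ln >= t) for t in LENGTH_THRESHOLDS},
        total_lengths={
            t: sum(ln for ln in lengths if ln >= t) for t in LENGTH_THRESHOLDS
        },
        largest=max(lengths),
        total=total,
        n50=nx_length(lengths, 0.5),
        n90=nx_length(lengths, 0.9),
        ns_per_100kbp=100_000.0 * n_count / total,
        min_length=min_length,
    )


def compare_stats(before: AssemblyStats, after: AssemblyStats) -> dict[str, float]:
    """Fold changes (after / before); values < 1 indicate regressions but no
    judgment is applied."""

    def fold(a, b):
        if b == 0:
            return 1.0 if a == 0 else math.inf
        return a / b

    report = {
        "n50_fold": fold(after.n50, before.n50),
        "n90_fold": fold(after.n90, before.n90),
        "largest_fold": fold(after.largest, before.largest),
        "total_fold": fold(after.total, before.total),
    }
    for t in LENGTH_THRESHOLDS:
        report[f"n_contigs_ge_{t}_fold"] = fold(
            after.n_contigs[t], before.n_contigs[t]
        )
    return report
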