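"""Synthetic genomes, populations and alignment fixtures with known truth.

A single chromosome is fragmented into shuffled, randomly oriented scaffolds;
diploid genotypes are produced by a founder-mosaic copying model so that LD
decays with physical distance and persists across true scaffold junctions.
All randomness flows from one seeded ``numpy.random.Generator`` in a fixed
draw order, so every artifact is a pure function of the configuration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._util import revcomp, write_fasta
from .errors import ValidationError
from .variants import HEAD, TAIL, GenotypeMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    chromosome_length: int = 1_000_000
    n_scaffolds: int = 10
    n_samples: int = 30
    n_founders: int = 6
    n_sites: int = 2_000
    recomb_rate: float = 1e-6  # per-bp founder switch probability
    min_maf: float = 0.125  # among founders
    gap_free: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValidationError("n_founders must be >= 2")
        if self.n_sites < self.n_scaffolds * 2:
            raise ValidationError("n_sites must be >= 2 * n_scaffolds")
        if not 0.0 <= self.recomb_rate <= 1.0:
            raise ValidationError("recomb_rate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValidationError("min_maf must be in [0, 0.5]")
        for name in ("chromosome_length", "n_scaffolds", "n_samples", "n_sites"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_sites > self.chromosome_length:
            raise ValidationError("n_sites cannot exceed chromosome_length")
        if self.n_scaffolds > self.chromosome_length:
            raise ValidationError("n_scaffolds cannot exceed chromosome_length")


@dataclass
class TruthAssembly:
    """The simulated chromosome and how it was cut into scaffolds."""

    chromosome_sequence: str
    breakpoints: np.ndarray  # sorted, strictly inside (0, L); 0-based cut points
    scaffold_order: np.ndarray  # emission order of scaffold ids 0..S-1
    scaffold_strand: np.ndarray  # '+'/'-' per scaffold id
    site_positions: np.ndarray  # 0-based positions on the chromosome
    site_scaffold: np.ndarray  # scaffold id per site
    site_offset: np.ndarray  # 0-based offset within the emitted scaffold
    ref_bases: np.ndarray  # chromosome-frame allele-0 base per site (uint8)
    alt_bases: np.ndarray  # chromosome-frame allele-1 base per site (uint8)

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffold_order)

    def scaffold_name(self, sid: int) -> str:
        width = len(str(self.n_scaffolds - 1))
        return f"scaffold_{sid:0{width}d}"

    @property
    def scaffold_bounds(self) -> list[tuple[int, int]]:
        """0-based half-open chromosome interval per scaffold id."""
        edges = [0, *map(int, self.breakpoints), len(self.chromosome_sequence)]
        return list(zip(edges[:-1], edges[1:]))

    def scaffold_sequences(self) -> dict[str, str]:
        """Emitted (strand-applied) scaffold sequences keyed by name, in truth
        chromosome order."""
        out = {}
        for sid, (lo, hi) in enumerate(self.scaffold_bounds):
            seq = self.chromosome_sequence[lo:hi]
            if self.scaffold_strand[sid] == "-":
                seq = revcomp(seq)
            out[self.scaffold_name(sid)] = seq
        return out


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes for the simulated diploid samples."""

    haplotypes: np.ndarray  # (2*n_samples, n_sites) uint8 in {0,1}
    founder_ids: np.ndarray  # (2*n_samples, n_sites) int16
    site_positions: np.ndarray  # 0-based chromosome positions

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def sample_names(self) -> list[str]:
        return [f"sample_{i:03d}" for i in range(self.n_samples)]

    def genotype_codes(self) -> np.ndarray:
        """(n_sites, n_samples) alt-allele dosage matrix (no missing data)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).T.astype(np.int8)


def simulate_truth(config: SimulationConfig) -> tuple[TruthAssembly, HaplotypePanel]:
    """Simulate chromosome, scaffold fragmentation and population haplotypes.

    Draw order (single generator seeded from ``config.seed``): chromosome
    bases, SNP positions, alt bases, founder alleles, haplotype founder
    mosaics, breakpoints, scaffold order, scaffold strands.
    """
    rng = np.random.default_rng(config.seed)
    L, S = config.chromosome_length, config.n_scaffolds

    chrom_codes = rng.integers(0, 4, size=L, dtype=np.uint8)
    chromosome = _BASES[chrom_codes].tobytes().decode("ascii")

    site_positions = np.sort(rng.choice(L, size=config.n_sites, replace=False))
    ref_bases = _BASES[chrom_codes[site_positions]]
    # alt base: uniform over the three non-reference bases
    alt_shift = rng.integers(1, 4, size=config.n_sites, dtype=np.uint8)
    alt_bases = _BASES[(chrom_codes[site_positions] + alt_shift) % 4]

    founders = _draw_founder_alleles(rng, config)

    n_hap = 2 * config.n_samples
    founder_ids = _founder_mosaic(rng, config, site_positions, n_hap)
    haplotypes = founders[founder_ids, np.arange(config.n_sites)]

    breakpoints = np.sort(rng.choice(np.arange(1, L), size=S - 1, replace=False))
    scaffold_order = rng.permutation(S)
    scaffold_strand = np.where(rng.integers(0, 2, size=S) == 0, "+", "-")

    bounds = [0, *map(int, breakpoints), L]
    site_scaffold = np.searchsorted(breakpoints, site_positions, side="right")
    starts = np.asarray(bounds[:-1])[site_scaffold]
    ends = np.asarray(bounds[1:])[site_scaffold]
    fwd_offset = site_positions - starts
    minus = scaffold_strand[site_scaffold] == "-"
    site_offset = np.where(minus, (ends - starts) - 1 - fwd_offset, fwd_offset)

    truth = TruthAssembly(
        chromosome_sequence=chromosome,
        breakpoints=breakpoints,
        scaffold_order=scaffold_order,
        scaffold_strand=scaffold_strand,
        site_positions=site_positions,
        site_scaffold=site_scaffold,
        site_offset=site_offset,
        ref_bases=ref_bases,
        alt_bases=alt_bases,
    )
    panel = HaplotypePanel(
        haplotypes=haplotypes.astype(np.uint8),
        founder_ids=founder_ids,
        site_positions=site_positions,
    )
    return truth, panel


def _draw_founder_alleles(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """(n_founders, n_sites) binary founder alleles, each site polymorphic
    with founder MAF >= min_maf."""
    F, n = config.n_founders, config.n_sites
    min_count = max(1, int(np.ceil(config.min_maf * F)))
    founders = rng.integers(0, 2, size=(F, n), dtype=np.uint8)
    for _ in range(1000):
        counts = founders.sum(axis=0)
        bad = np.flatnonzero(np.minimum(counts, F - counts) < min_count)
        if bad.size == 0:
            return founders
        founders[:, bad] = rng.integers(0, 2, size=(F, bad.size), dtype=np.uint8)
    raise ValidationError("could not satisfy founder min_maf; lower min_maf")


def _founder_mosaic(
    rng: np.random.Generator,
    config: SimulationConfig,
    site_positions: np.ndarray,
    n_hap: int,
) -> np.ndarray:
    """Founder index per (haplotype, site) under per-base uniform switching.

    Equivalent in distribution to switching to a uniform founder at each base
    with probability ``recomb_rate``: between consecutive SNPs the founder is
    redrawn uniformly with probability 1 - (1 - r)^gap, because the founder
    after any switch is uniform.
    """
    n = len(site_positions)
    # gap from "position 0 before any base" to the first site, then site gaps
    gaps = np.diff(site_positions, prepend=-1)
    p_switch = 1.0 - (1.0 - config.recomb_rate) ** gaps
    p_switch[0] = 1.0  # the starting founder is uniform anyway
    switched = rng.random(size=(n_hap, n)) < p_switch
    choices = rng.integers(0, config.n_founders, size=(n_hap, n), dtype=np.int16)
    ids = np.empty((n_hap, n), dtype=np.int16)
    ids[:, 0] = choices[:, 0]
    for j in range(1, n):
        ids[:, j] = np.where(switched[:, j], choices[:, j], ids[:, j - 1])
    return ids


def truth_adjacencies(
    truth: TruthAssembly, scaffolds: set[str] | None = None
) -> list[tuple[str, str, str, str]]:
    """True junctions (scaffold_a, end_a, scaffold_b, end_b) in chromosome order.

    The end facing the junction depends on each scaffold's emitted strand: a
    '+' scaffold meets its right neighbour with its tail, a '-' scaffold with
    its head.  When ``scaffolds`` restricts to a subset (e.g. the survivors of
    scaffold filtering), adjacency means consecutive among the survivors in
    true chromosome order.
    """
    ids = [
        sid
        for sid in range(truth.n_scaffolds)
        if scaffolds is None or truth.scaffold_name(sid) in scaffolds
    ]
    out = []
    for a, b in zip(ids, ids[1:]):
        end_a = TAIL if truth.scaffold_strand[a] == "+" else HEAD
        end_b = HEAD if truth.scaffold_strand[b] == "+" else TAIL
        out.append((truth.scaffold_name(a), end_a, truth.scaffold_name(b), end_b))
    return out


def truth_layout(truth: TruthAssembly) -> list[list[tuple[str, str]]]:
    """The true super-scaffold as one ordered, signed scaffold list."""
    return [
        [
            (truth.scaffold_name(sid), str(truth.scaffold_strand[sid]))
            for sid in range(truth.n_scaffolds)
        ]
    ]


def genotype_matrices(
    truth: TruthAssembly, panel: HaplotypePanel
) -> dict[str, GenotypeMatrix]:
    """In-memory per-scaffold genotype matrices (scaffold-relative 1-based
    positions, emitted-strand alleles), bypassing VCF round-tripping."""
    codes = panel.genotype_codes()
    samples = panel.sample_names()
    out: dict[str, GenotypeMatrix] = {}
    for sid in range(truth.n_scaffolds):
        idx = np.flatnonzero(truth.site_scaffold == sid)
        idx = idx[np.argsort(truth.site_offset[idx], kind="stable")]
        name = truth.scaffold_name(sid)
        refs, alts = _emitted_alleles(truth, idx)
        out[name] = GenotypeMatrix(
            name,
            samples,
            truth.site_offset[idx] + 1,
            refs,
            alts,
            codes[idx],
        )
    return out


def _emitted_alleles(truth: TruthAssembly, idx: np.ndarray) -> tuple[list[str], list[str]]:
    """REF/ALT bases in the emitted scaffold orientation for the given sites."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    refs, alts = [], []
    for i in idx:
        r = chr(truth.ref_bases[i])
        a = chr(truth.alt_bases[i])
        if truth.scaffold_strand[truth.site_scaffold[i]] == "-":
            r, a = comp[r], comp[a]
        refs.append(r)
        alts.append(a)
    return refs, alts


def scaffold_lengths(truth: TruthAssembly) -> dict[str, int]:
    return {
        truth.scaffold_name(sid): hi - lo
        for sid, (lo, hi) in enumerate(truth.scaffold_bounds)
    }


def emit_dataset(
    truth: TruthAssembly,
    panel: HaplotypePanel,
    outdir: str | os.PathLike,
    seed: int = 0,
) -> dict[str, Path]:
    """Write the scaffold FASTA, unphased VCF, phased haplotype table, truth
    AGP and truth adjacency TSV.  ``seed`` controls the within-individual
    allele-order randomization of unphased GT fields only."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    seqs = truth.scaffold_sequences()
    emitted_order = [truth.scaffold_name(sid) for sid in truth.scaffold_order]
    fasta = outdir / "scaffolds.fasta"
    write_fasta(fasta, [(name, seqs[name]) for name in emitted_order])

    vcf = outdir / "variants.vcf"
    _write_vcf(vcf, truth, panel, emitted_order, {n: len(seqs[n]) for n in seqs}, rng)

    hap_table = outdir / "haplotypes.tsv"
    _write_haplotype_table(hap_table, truth, panel)

    agp = outdir / "truth.agp"
    from .scaffolder import write_agp  # deferred: avoids import cycle

    write_agp(agp, {"truth_super_1": truth_layout(truth)[0]}, scaffold_lengths(truth))

    adj = outdir / "truth_adjacencies.tsv"
    with open(adj, "w") as fh:
        fh.write("scaffold_a\tend_a\tscaffold_b\tend_b\n")
        for row in truth_adjacencies(truth):
            fh.write("\t".join(row) + "\n")

    return {
        "fasta": fasta,
        "vcf": vcf,
        "haplotypes": hap_table,
        "agp": agp,
        "adjacencies": adj,
    }


def _write_vcf(path, truth, panel, emitted_order, lengths, rng):
    matrices = genotype_matrices(truth, panel)
    samples = panel.sample_names()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldrefine-simpop\n")
        for name in emitted_order:
            fh.write(f"##contig=<ID={name},length={lengths[name]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for name in emitted_order:
            m = matrices[name]
            swap = rng.integers(0, 2, size=(m.n_sites, m.n_samples)).astype(bool)
            for i in range(m.n_sites):
                gts = []
                for j, code in enumerate(m.codes[i]):
                    a, b = (0, 1) if code == 1 else (code // 2, code // 2)
                    if code == 1 and swap[i, j]:
                        a, b = b, a
                    gts.append(f"{a}/{b}")
                fh.write(
                    f"{name}\t{m.positions[i]}\t.\t{m.refs[i]}\t{m.alts[i]}"
                    f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
                )


def _write_haplotype_table(path, truth, panel):
    with open(path, "w") as fh:
        names = [
            f"{s}_h{h}" for s in panel.sample_names() for h in (1, 2)
        ]
        fh.write("chrom_pos\tscaffold\tscaffold_pos\t" + "\t".join(names) + "\n")
        for i in range(panel.n_sites):
            fh.write(
                f"{truth.site_positions[i] + 1}\t"
                f"{truth.scaffold_name(int(truth.site_scaffold[i]))}\t"
                f"{truth.site_offset[i] + 1}\t"
                + "\t".join(str(int(a)) for a in panel.haplotypes[:, i])
                + "\n"
            )


# ---------------------------------------------------------------------------
# alignment-block fixtures with planted rearrangements


@dataclass(frozen=True)
class PlantedEvent:
    type: str  # "inversion" | "translocation"
    anchor_positions: tuple[int, ...]  # 0-based anchor-order positions
    block_ids: tuple[int, ...]  # 1-based serial ids of the moved blocks


def simulate_coords(
    n_blocks: int,
    inversions: int,
    translocations: int,
    seed: int = 0,
    path: str | os.PathLike | None = None,
) -> tuple[list[str], list[PlantedEvent]]:
    """Emit a coords-dialect table with planted inversions/translocations.

    Blocks are collinear between anchor chromosome ``ref_1`` and query
    ``qry_1``; inversions flip a run's strand and reverse its query order;
    translocations move an interior run to ``qry_2``.  Returns the table rows
    (including header) and the truth event list; optionally writes ``path``.
    """
    if inversions < 0 or translocations < 0 or n_blocks <= 0:
        raise ValidationError("counts must be non-negative, n_blocks positive")
    # events are planted on disjoint interior runs of up to 3 blocks,
    # separated by >= 2 untouched blocks so calls can never merge or create
    # spurious single-block islands between two translocated runs
    max_run = 3
    need = 2 + (inversions + translocations) * (max_run + 2)
    if inversions + translocations > 0 and n_blocks < need:
        raise ValidationError(
            f"n_blocks={n_blocks} too small for {inversions} inversions + "
            f"{translocations} translocations (need >= {need})"
        )
    rng = np.random.default_rng(seed)

    lengths = rng.integers(12_000, 30_000, size=n_blocks)
    gaps = rng.integers(500, 3_000, size=n_blocks + 1)
    ref_starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]])) + 1
    idents = np.round(rng.uniform(92.0, 99.9, size=n_blocks), 2)

    # choose disjoint interior runs (never touching the first/last block)
    runs: list[tuple[int, ...]] = []
    free = set(range(1, n_blocks - 1))
    events: list[PlantedEvent] = []
    for etype, count in (("inversion", inversions), ("translocation", translocations)):
        for _ in range(count):
            run = _pick_run(rng, free, max_run, n_blocks)
            runs.append(run)
            events.append(
                PlantedEvent(etype, run, tuple(p + 1 for p in run))
            )

    # query layout: per anchor position, (qry_chrom, qry_order_key, strand)
    qry_chrom = ["qry_1"] * n_blocks
    strand = ["+"] * n_blocks
    qry_rank = list(range(n_blocks))
    for ev in events:
        if ev.type == "inversion":
            pos = list(ev.anchor_positions)
            for p, r in zip(pos, reversed([qry_rank[p] for p in pos])):
                qry_rank[p] = r
                strand[p] = "-"
        else:
            for p in ev.anchor_positions:
                qry_chrom[p] = "qry_2"

    rows = ["#ref_start\tref_end\tqry_start\tqry_end\tref_alnlen\tqry_alnlen\tpct_idy\tref_id\tqry_id"]
    # assign query coordinates chromosome by chromosome in rank order
    cursor = {"qry_1": 1, "qry_2": 1}
    qry_start = [0] * n_blocks
    for p in sorted(range(n_blocks), key=lambda p: (qry_chrom[p], qry_rank[p])):
        qry_start[p] = cursor[qry_chrom[p]]
        cursor[qry_chrom[p]] += int(lengths[p]) + int(rng.integers(500, 3_000))
    for p in range(n_blocks):
        rs, re = int(ref_starts[p]), int(ref_starts[p] + lengths[p] - 1)
        qs, qe = qry_start[p], qry_start[p] + int(lengths[p]) - 1
        if strand[p] == "-":
            qs, qe = qe, qs
        rows.append(
            f"{rs}\t{re}\t{qs}\t{qe}\t{int(lengths[p])}\t{int(lengths[p])}\t"
            f"{idents[p]}\tref_1\t{qry_chrom[p]}"
        )
    if path is not None:
        Path(path).write_text("\n".join(rows) + "\n")
    return rows, events


def _pick_run(rng, free: set[int], max_run: int, n_blocks: int) -> tuple[int, ...]:
    """Pick a run of 1..max_run consecutive free interior positions; reserve
    the run plus two blocks of padding on each side."""
    run_len = int(rng.integers(1, max_run + 1))
    starts = [
        s
        for s in sorted(free)
        if all(s + i in free for i in range(run_len)) and s + run_len - 1 < n_blocks - 1
    ]
    if not starts:
        raise ValidationError("could not place planted event; increase n_blocks")
    s = int(rng.choice(starts))
    run = tuple(range(s, s + run_len))
    for p in range(s - 2, s + run_len + 2):
        free.discard(p)
    return run
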