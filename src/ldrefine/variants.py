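"""VCF input, site- and scaffold-level filters, and edge SNP windows.

Genotypes are coded as the count of the alternate allele per diploid sample
(0, 1, 2) with :data:`MISSING` (= -1) for missing or half-missing calls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF

from .errors import ConsistencyError, FormatError, ValidationError

MISSING = -1

HEAD = "head"
TAIL = "tail"


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP: alleles plus per-sample dosage codes."""

    scaffold_id: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray  # int8, values in {0,1,2,MISSING}

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValidationError("SiteRecord alleles must be single nucleotides")


@dataclass
class GenotypeMatrix:
    """Per-scaffold table of biallelic SNP sites (rows) x samples (columns)."""

    scaffold_id: str
    samples: list[str]
    positions: np.ndarray  # int64, 1-based, strictly increasing
    refs: list[str]
    alts: list[str]
    codes: np.ndarray  # (n_sites, n_samples) int8

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n = len(self.positions)
        if self.codes.shape != (n, len(self.samples)):
            raise ValidationError(
                f"codes shape {self.codes.shape} does not match "
                f"{n} sites x {len(self.samples)} samples"
            )
        if len(self.refs) != n or len(self.alts) != n:
            raise ValidationError("refs/alts length must equal site count")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise FormatError(
                f"positions not strictly increasing on scaffold {self.scaffold_id}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site(self, i: int) -> SiteRecord:
        return SiteRecord(
            self.scaffold_id,
            int(self.positions[i]),
            self.refs[i],
            self.alts[i],
            self.codes[i],
        )

    @property
    def sites(self) -> list[SiteRecord]:
        return [self.site(i) for i in range(self.n_sites)]

    def take(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.scaffold_id,
            self.samples,
            self.positions[index],
            [self.refs[i] for i in index],
            [self.alts[i] for i in index],
            self.codes[index],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.scaffold_id == other.scaffold_id
            and self.samples == other.samples
            and np.array_equal(self.positions, other.positions)
            and self.refs == other.refs
            and self.alts == other.alts
            and np.array_equal(self.codes, other.codes)
        )


@dataclass(frozen=True)
class EdgeBlock:
    """Up to k SNP sites from one end (head or tail) of one scaffold."""

    scaffold_id: str
    end: str  # HEAD or TAIL
    positions: np.ndarray
    codes: np.ndarray  # (n_sites, n_samples) int8

    def __post_init__(self):
        if self.end not in (HEAD, TAIL):
            raise ValidationError(f"end must be '{HEAD}' or '{TAIL}', got {self.end!r}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def terminal(self) -> tuple[str, str]:
        return (self.scaffold_id, self.end)


@dataclass(frozen=True)
class FilterThresholds:
    """Site/scaffold filter settings; defaults follow the pipeline defaults."""

    max_missing_rate: float = 0.15
    min_minor_allele_count: int = 4  # "greater than three"
    min_scaffold_length: int = 20_000
    min_scaffold_snps: int = 100
    edge_snps: int = 500

    def __post_init__(self):
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValidationError("max_missing_rate must be in [0, 1]")
        for name in (
            "min_minor_allele_count",
            "min_scaffold_length",
            "min_scaffold_snps",
            "edge_snps",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def read_vcf(
    path: str | os.PathLike, sample_subset: list[str] | None = None
) -> dict[str, GenotypeMatrix]:
    """Read a VCF into per-scaffold genotype matrices.

    Only biallelic SNP records (single-nucleotide REF and exactly one
    single-nucleotide ALT) are retained.  Genotype codes are computed from GT
    regardless of the phasing separator; half-missing calls count as missing.
    """
    vcf = VCF(str(path), samples=sample_subset)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise FormatError(f"{path}: VCF has no GT FORMAT definition")
    samples = list(vcf.samples)
    per_scaffold: dict[str, dict[str, list]] = {}
    for v in vcf:
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            continue
        bucket = per_scaffold.setdefault(
            v.CHROM, {"pos": [], "ref": [], "alt": [], "codes": []}
        )
        gt = np.asarray(v.genotypes, dtype=np.int64)[:, :2]
        codes = np.where((gt >= 0).all(axis=1), gt.sum(axis=1), MISSING)
        bucket["pos"].append(v.POS)
        bucket["ref"].append(v.REF)
        bucket["alt"].append(v.ALT[0])
        bucket["codes"].append(codes.astype(np.int8))
    out: dict[str, GenotypeMatrix] = {}
    for scaffold, b in per_scaffold.items():
        pos = np.asarray(b["pos"], dtype=np.int64)
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise FormatError(f"VCF positions not sorted on scaffold {scaffold}")
        out[scaffold] = GenotypeMatrix(
            scaffold, samples, pos, b["ref"], b["alt"], np.vstack(b["codes"])
        )
    return out


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path: str | os.PathLike,
    matrices: dict[str, GenotypeMatrix],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write genotype matrices as a minimal unphased VCF v4.2."""
    names = list(matrices)
    samples = matrices[names[0]].samples if names else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=ldrefine\n")
        for name in names:
            if contig_lengths and name in contig_lengths:
                fh.write(f"##contig=<ID={name},length={contig_lengths[name]}>\n")
            else:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for name in names:
            m = matrices[name]
            for i in range(m.n_sites):
                gts = "\t".join(_GT[int(c)] for c in m.codes[i])
                fh.write(
                    f"{name}\t{m.positions[i]}\t.\t{m.refs[i]}\t{m.alts[i]}"
                    f"\t.\tPASS\t.\tGT\t{gts}\n"
                )


def site_missing_rate(codes: np.ndarray) -> np.ndarray:
    """Per-site fraction of missing genotypes."""
    codes = np.atleast_2d(codes)
    return (codes == MISSING).mean(axis=1)


def site_minor_allele_count(codes: np.ndarray) -> np.ndarray:
    """Per-site minor allele count over non-missing diploid genotypes."""
    codes = np.atleast_2d(codes)
    present = codes != MISSING
    alt = np.where(present, codes, 0).sum(axis=1)
    total = 2 * present.sum(axis=1)
    return np.minimum(alt, total - alt)


def filter_sites(
    matrix: GenotypeMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> GenotypeMatrix:
    """Keep sites with missing rate < max and minor allele count >= min."""
    keep = (site_missing_rate(matrix.codes) < thresholds.max_missing_rate) & (
        site_minor_allele_count(matrix.codes) >= thresholds.min_minor_allele_count
    )
    return matrix.take(keep)


def filter_scaffolds(
    matrices: dict[str, GenotypeMatrix],
    scaffold_lengths: dict[str, int],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[dict[str, GenotypeMatrix], list[tuple[str, str]]]:
    """Drop short scaffolds and scaffolds with too few SNPs.

    Returns the kept matrices plus an exclusion report of
    ``(scaffold_id, reason)`` with reason in {"length", "snp_count"}.
    """
    kept: dict[str, GenotypeMatrix] = {}
    excluded: list[tuple[str, str]] = []
    for scaffold, matrix in matrices.items():
        if scaffold not in scaffold_lengths:
            raise ConsistencyError(f"scaffold {scaffold} missing from FASTA lengths")
        if scaffold_lengths[scaffold] < thresholds.min_scaffold_length:
            excluded.append((scaffold, "length"))
        elif matrix.n_sites < thresholds.min_scaffold_snps:
            excluded.append((scaffold, "snp_count"))
        else:
            kept[scaffold] = matrix
    return kept, excluded


def extract_edge_blocks(
    matrix: GenotypeMatrix, k: int = 500
) -> tuple[EdgeBlock, EdgeBlock]:
    """Take up to k sites from each end of the scaffold, never overlapping.

    With m < 2k sites the scaffold is split half/half, the odd site going to
    the tail window.
    """
    m = matrix.n_sites
    if m == 0:
        raise ValidationError(f"scaffold {matrix.scaffold_id} has no sites")
    n_head = k if m >= 2 * k else m // 2
    head = EdgeBlock(
        matrix.scaffold_id, HEAD, matrix.positions[:n_head], matrix.codes[:n_head]
    )
    n_tail = k if m >= 2 * k else m - n_head
    tail = EdgeBlock(
        matrix.scaffold_id, TAIL, matrix.positions[m - n_tail :], matrix.codes[m - n_tail :]
    )
    return head, tail
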