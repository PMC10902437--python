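"""LD statistics between sites and linkage scores between scaffold terminals.

The per-pair statistic is the composite (phase-free) genotype r²: the squared
Pearson correlation of alt-allele dosages over pairwise-complete samples.
The classical haplotype r² (D² normalized by allele-frequency products) is
provided for phased data and used as an independent oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedLDError, ValidationError
from .variants import HEAD, MISSING, TAIL, EdgeBlock, SiteRecord

__all__ = [
    "EdgeBlock",
    "LinkageScoreMatrix",
    "NullModel",
    "r2_genotype",
    "r2_haplotype",
    "edge_score",
    "score_matrix",
    "fit_null",
]


def r2_genotype(a: SiteRecord | np.ndarray, b: SiteRecord | np.ndarray) -> float:
    """Squared Pearson correlation of genotype codes over complete pairs.

    Raises :class:`UndefinedLDError` with fewer than two complete sample
    pairs or when either site is monomorphic among them.
    """
    ga = a.genotypes if isinstance(a, SiteRecord) else np.asarray(a)
    gb = b.genotypes if isinstance(b, SiteRecord) else np.asarray(b)
    if ga.shape != gb.shape:
        raise ValidationError("sites do not share a sample list")
    ok = (ga != MISSING) & (gb != MISSING)
    x = ga[ok].astype(np.float64)
    y = gb[ok].astype(np.float64)
    if x.size < 2:
        raise UndefinedLDError("fewer than 2 complete sample pairs")
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        raise UndefinedLDError("monomorphic site among complete pairs")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return min(1.0, cov * cov / (vx * vy))


def r2_haplotype(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Classical haplotype r² = D² / (p_a (1-p_a) p_b (1-p_b))."""
    a = np.asarray(hap_a, dtype=np.float64)
    b = np.asarray(hap_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("haplotype vectors must be equal-length, size >= 2")
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise UndefinedLDError("monomorphic haplotype vector")
    d = (a * b).mean() - pa * pb
    return min(1.0, d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _pairwise_r2(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """All-pairs composite r² between the site rows of two code matrices.

    Returns an (n_a, n_b) array with NaN where LD is undefined.  Matches
    :func:`r2_genotype` pair by pair (same pairwise-complete rule).
    """
    ma = (ca != MISSING).astype(np.float64)
    mb = (cb != MISSING).astype(np.float64)
    xa = np.where(ca == MISSING, 0, ca).astype(np.float64)
    xb = np.where(cb == MISSING, 0, cb).astype(np.float64)
    n = ma @ mb.T
    sx = xa @ mb.T
    sy = ma @ xb.T
    sxx = (xa * xa) @ mb.T
    syy = ma @ (xb * xb).T
    sxy = xa @ xb.T
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx * sx) * (n * syy - sy * sy)
        r2 = (num * num) / den
    r2[(n < 2) | (den <= 0)] = np.nan
    return np.minimum(r2, 1.0)


def edge_score(
    x: EdgeBlock,
    y: EdgeBlock,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> tuple[float, int]:
    """Mean composite r² over all cross site pairs of two edge blocks.

    Undefined pairs are skipped.  If ``max_pairs`` is set and the number of
    cross pairs exceeds it, a seeded uniform subsample of pairs is scored.
    Returns ``(score, n_pairs_used)``.
    """
    if x.n_sites == 0 or y.n_sites == 0:
        raise UndefinedLDError("empty edge block")
    total = x.n_sites * y.n_sites
    if max_pairs is not None and total > max_pairs:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total, size=max_pairs, replace=False)
        ia, ib = np.unravel_index(flat, (x.n_sites, y.n_sites))
        vals = np.array(
            [
                _pairwise_r2(x.codes[i : i + 1], y.codes[j : j + 1])[0, 0]
                for i, j in zip(ia, ib)
            ]
        )
    else:
        vals = _pairwise_r2(x.codes, y.codes).ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise UndefinedLDError(
            f"all pairs undefined between {x.terminal} and {y.terminal}"
        )
    return float(vals.mean()), int(vals.size)


@dataclass
class LinkageScoreMatrix:
    """Symmetric scores over all scaffold terminals.

    ``scores`` is NaN where undefined; ``internal`` flags same-scaffold cells
    (including the diagonal), which are never scored.
    """

    terminals: list[tuple[str, str]]  # (scaffold_id, end), sorted
    scores: np.ndarray  # (2S, 2S) float, NaN = undefined/internal
    n_pairs_used: np.ndarray  # (2S, 2S) int
    internal: np.ndarray  # (2S, 2S) bool

    def index(self, scaffold_id: str, end: str) -> int:
        return self.terminals.index((scaffold_id, end))

    def get(self, s1: str, e1: str, s2: str, e2: str) -> float:
        return float(self.scores[self.index(s1, e1), self.index(s2, e2)])

    def defined_scores(self) -> np.ndarray:
        """Defined inter-scaffold scores from the upper triangle."""
        iu = np.triu_indices(len(self.terminals), k=1)
        vals = self.scores[iu]
        keep = ~self.internal[iu] & ~np.isnan(vals)
        return vals[keep]

    def iter_defined(self):
        """Yield (terminal_a, terminal_b, score) for defined cells, a < b."""
        t = self.terminals
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                if not self.internal[i, j] and not np.isnan(self.scores[i, j]):
                    yield t[i], t[j], float(self.scores[i, j])


def score_matrix(
    edge_blocks: list[EdgeBlock],
    max_pairs: int | None = None,
    seed: int | None = None,
) -> LinkageScoreMatrix:
    """Fill the terminal x terminal linkage-score matrix.

    Terminals are ordered lexicographically by (scaffold_id, end); head sorts
    before tail.  Same-scaffold cells are flagged internal and left NaN.
    """
    blocks = {b.terminal: b for b in edge_blocks}
    scaffolds = sorted({b.scaffold_id for b in edge_blocks})
    if len(scaffolds) < 2:
        raise ValidationError("score_matrix needs >= 2 scaffolds")
    terminals = [(s, e) for s in scaffolds for e in (HEAD, TAIL)]
    missing = [t for t in terminals if t not in blocks]
    if missing:
        raise ValidationError(f"missing edge blocks for terminals: {missing}")
    m = len(terminals)
    scores = np.full((m, m), np.nan)
    n_used = np.zeros((m, m), dtype=np.int64)
    internal = np.zeros((m, m), dtype=bool)
    for i, (si, _) in enumerate(terminals):
        for j in range(i, m):
            if terminals[j][0] == si:
                internal[i, j] = internal[j, i] = True
                continue
            try:
                s, n = edge_score(blocks[terminals[i]], blocks[terminals[j]], max_pairs, seed)
            except UndefinedLDError:
                continue
            scores[i, j] = scores[j, i] = s
            n_used[i, j] = n_used[j, i] = n
    return LinkageScoreMatrix(terminals, scores, n_used, internal)


@dataclass(frozen=True)
class NullModel:
    """Robust Gaussian null for inter-scaffold linkage scores."""

    mean: float
    sd: float
    threshold: float
    ci_level: float = 0.97

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.threshold < self.mean:
            raise ValidationError("threshold must be >= mean")


def fit_null(matrix: LinkageScoreMatrix, ci_level: float = 0.97) -> NullModel:
    """Fit the noise bulk of the score distribution and derive the cutoff.

    Location = median, scale = 1.4826 x MAD over all defined inter-scaffold
    scores (true adjacencies are a vanishing, robustly-ignored fraction);
    threshold = location + z * scale with z the upper bound of the central
    two-sided ``ci_level`` interval.
    """
    vals = matrix.defined_scores()
    if vals.size < 20:
        raise ValidationError(
            f"only {vals.size} defined scores (< 20); set the threshold manually"
        )
    loc = float(np.median(vals))
    scale = 1.4826 * float(np.median(np.abs(vals - loc)))
    z = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    return NullModel(mean=loc, sd=scale, threshold=loc + z * scale, ci_level=ci_level)
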