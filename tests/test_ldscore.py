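import numpy as np
import pytest

from oracles import brute_r2_genotype, brute_r2_haplotype

from ldrefine import ldscore, simpop, variants
from ldrefine.errors import UndefinedLDError, ValidationError
from ldrefine.ldscore import (
    LinkageScoreMatrix,
    edge_score,
    fit_null,
    r2_genotype,
    r2_haplotype,
    score_matrix,
)
from ldrefine.variants import HEAD, MISSING, TAIL, EdgeBlock


def block(codes, scaffold="s", end=HEAD):
    codes = np.asarray(codes, dtype=np.int8)
    return EdgeBlock(scaffold, end, np.arange(1, len(codes) + 1), codes)


class TestR2Genotype:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        assert r2_genotype(g, g) == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        with pytest.raises(UndefinedLDError):
            r2_genotype(np.array([0, 0, 1, 1]), np.array([1, 1, 1, 1]))

    def test_zero_by_symmetry(self):
        a = np.array([0, 0, 2, 2, 1, 1], dtype=np.int8)
        b = np.array([0, 2, 0, 2, 1, 1], dtype=np.int8)
        assert r2_genotype(a, b) == pytest.approx(0.0, abs=1e-15)

    def test_too_few_complete_pairs(self):
        a = np.array([0, MISSING, MISSING], dtype=np.int8)
        b = np.array([1, 1, MISSING], dtype=np.int8)
        with pytest.raises(UndefinedLDError):
            r2_genotype(a, b)

    def test_brute_force_equivalence(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            a = rng.integers(0, 3, n).astype(np.int8)
            b = rng.integers(0, 3, n).astype(np.int8)
            a[rng.random(n) < 0.1] = MISSING
            b[rng.random(n) < 0.1] = MISSING
            expect = brute_r2_genotype(a, b)
            if expect is None:
                with pytest.raises(UndefinedLDError):
                    r2_genotype(a, b)
            else:
                assert r2_genotype(a, b) == pytest.approx(expect, abs=1e-12)

    def test_range(self, rng):
        for _ in range(200):
            a = rng.integers(0, 3, 20).astype(np.int8)
            b = rng.integers(0, 3, 20).astype(np.int8)
            try:
                v = r2_genotype(a, b)
            except UndefinedLDError:
                continue
            assert 0.0 <= v <= 1.0


class TestR2Haplotype:
    def test_worked_example(self):
        # 8 haplotypes: AB x4, ab x2, Ab x1, aB x1
        ha = np.array([1, 1, 1, 1, 0, 0, 1, 0])
        hb = np.array([1, 1, 1, 1, 0, 0, 0, 1])
        expect = 0.011962890625 / 0.054931640625
        assert r2_haplotype(ha, hb) == pytest.approx(expect, abs=1e-15)
        assert expect == pytest.approx(0.217777, abs=1e-6)

    def test_perfect_coupling(self):
        ha = np.array([1, 1, 0, 0])
        assert r2_haplotype(ha, ha) == pytest.approx(1.0)

    def test_independence(self):
        # p_AB = p_A * p_B exactly -> D = 0
        ha = np.array([1, 1, 0, 0])
        hb = np.array([1, 0, 1, 0])
        assert r2_haplotype(ha, hb) == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic(self):
        with pytest.raises(UndefinedLDError):
            r2_haplotype(np.array([1, 1, 1]), np.array([0, 1, 0]))

    def test_brute_force_equivalence(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 60)) * 2
            ha = rng.integers(0, 2, n)
            hb = rng.integers(0, 2, n)
            expect = brute_r2_haplotype(ha, hb)
            if expect is None:
                with pytest.raises(UndefinedLDError):
                    r2_haplotype(ha, hb)
            else:
                assert r2_haplotype(ha, hb) == pytest.approx(expect, abs=1e-12)


def test_genotype_equals_haplotype_on_homozygous_panels(rng):
    """Doubling each haplotype into a homozygous diploid makes the composite
    genotype r² and the classical haplotype r² coincide exactly."""
    for _ in range(200):
        n = int(rng.integers(4, 30))
        ha = rng.integers(0, 2, n)
        hb = rng.integers(0, 2, n)
        if brute_r2_haplotype(ha, hb) is None:
            continue
        ga = (2 * ha).astype(np.int8)
        gb = (2 * hb).astype(np.int8)
        assert r2_genotype(ga, gb) == pytest.approx(r2_haplotype(ha, hb), abs=1e-12)


def test_genotype_correlates_with_haplotype_r2():
    cfg = simpop.SimulationConfig(
        chromosome_length=1_000_000,
        n_scaffolds=2,
        n_samples=120,
        n_founders=6,
        n_sites=800,
        recomb_rate=1e-5,
        seed=42,
    )
    _, panel = simpop.simulate_truth(cfg)
    hap = panel.haplotypes
    codes = panel.genotype_codes()
    rng = np.random.default_rng(5)
    gvals, hvals = [], []
    for _ in range(400):
        i, j = rng.integers(0, panel.n_sites, 2)
        if i == j:
            continue
        hv = brute_r2_haplotype(hap[:, i], hap[:, j])
        if hv is None:
            continue
        try:
            gv = r2_genotype(codes[i], codes[j])
        except UndefinedLDError:
            continue
        gvals.append(gv)
        hvals.append(hv)
    assert len(gvals) > 100
    assert np.corrcoef(gvals, hvals)[0, 1] > 0.9


class TestEdgeScore:
    def test_mean_of_cross_pairs(self):
        # construct 2x2 cross pairs with r^2 {1, 0, 0, 1} -> mean 0.5
        x = block([[0, 0, 1, 1, 2, 2], [0, 2, 2, 0, 1, 1]], "a", TAIL)
        y = block([[0, 0, 1, 1, 2, 2], [0, 2, 2, 0, 1, 1]], "b", HEAD)
        expect = np.mean(
            [
                brute_r2_genotype(x.codes[i], y.codes[j])
                for i in range(2)
                for j in range(2)
            ]
        )
        s, n = edge_score(x, y)
        assert n == 4
        assert s == pytest.approx(expect)
        assert expect == pytest.approx(0.5, abs=1e-12)

    def test_all_r2_one(self):
        g = [0, 1, 2, 1, 0, 2]
        x = block([g, g], "a")
        y = block([g, g], "b")
        s, n = edge_score(x, y)
        assert s == pytest.approx(1.0) and n == 4

    def test_skips_undefined(self):
        poly = [0, 1, 2, 1]
        mono = [1, 1, 1, 1]
        x = block([poly, mono], "a")
        y = block([poly, mono], "b")
        s, n = edge_score(x, y)
        assert n == 1  # only the poly-poly pair is defined
        assert s == pytest.approx(1.0)

    def test_all_undefined(self):
        mono = [1, 1, 1, 1]
        with pytest.raises(UndefinedLDError):
            edge_score(block([mono], "a"), block([mono], "b"))

    def test_symmetry(self, small_sim):
        _, truth, panel = small_sim
        mats = simpop.genotype_matrices(truth, panel)
        names = sorted(mats)
        h0, _ = variants.extract_edge_blocks(mats[names[0]], 50)
        _, t1 = variants.extract_edge_blocks(mats[names[1]], 50)
        assert edge_score(h0, t1)[0] == edge_score(t1, h0)[0]

    def test_subsample_converges(self, small_sim):
        _, truth, panel = small_sim
        mats = simpop.genotype_matrices(truth, panel)
        big = sorted(mats.values(), key=lambda m: -m.n_sites)[:2]
        x, _ = variants.extract_edge_blocks(big[0], 150)
        _, y = variants.extract_edge_blocks(big[1], 150)
        assert x.n_sites * y.n_sites > 10_000
        full, _ = edge_score(x, y)
        sub, n = edge_score(x, y, max_pairs=10_000, seed=1)
        assert n == 10_000
        assert abs(sub - full) < 0.05


class TestScoreMatrix:
    def test_combinatorics_and_symmetry(self, small_sim):
        _, truth, panel = small_sim
        mats = simpop.genotype_matrices(truth, panel)
        names = sorted(mats)[:3]
        blocks = []
        for n in names:
            blocks.extend(variants.extract_edge_blocks(mats[n], 50))
        m = score_matrix(blocks)
        assert len(m.terminals) == 6
        defined = list(m.iter_defined())
        assert len(defined) == 12  # C(6,2)=15 minus 3 internal pairs
        assert np.array_equal(m.scores, m.scores.T, equal_nan=True)
        assert m.internal[0, 1] and not m.internal[0, 2]

    def test_true_adjacency_beats_median(self):
        cfg = simpop.SimulationConfig(
            chromosome_length=2_000_000,
            n_scaffolds=8,
            n_samples=40,
            n_founders=6,
            n_sites=1_600,
            recomb_rate=5e-6,
            seed=17,
        )
        truth, panel = simpop.simulate_truth(cfg)
        mats = simpop.genotype_matrices(truth, panel)
        blocks = []
        for mat in mats.values():
            blocks.extend(variants.extract_edge_blocks(mat, 100))
        m = score_matrix(blocks)
        median = np.median(m.defined_scores())
        for sa, ea, sb, eb in simpop.truth_adjacencies(truth):
            assert m.get(sa, ea, sb, eb) > median

    def test_needs_two_scaffolds(self):
        b = block([[0, 1, 2, 0]], "only", HEAD)
        t = block([[0, 1, 2, 0]], "only", TAIL)
        with pytest.raises(ValidationError):
            score_matrix([b, t])


def _fake_matrix(values):
    """A LinkageScoreMatrix whose defined inter-scaffold cells take the given
    values, packed into the smallest sufficient terminal set."""
    n_scaffolds = 2
    while 2 * n_scaffolds * (n_scaffolds - 1) < len(values):
        n_scaffolds += 1
    terminals = [(f"s{i:04d}", e) for i in range(n_scaffolds) for e in (HEAD, TAIL)]
    m = len(terminals)
    scores = np.full((m, m), np.nan)
    internal = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(m):
            if terminals[i][0] == terminals[j][0]:
                internal[i, j] = True
    it = iter(values)
    for i in range(m):
        for j in range(i + 1, m):
            if internal[i, j]:
                continue
            v = next(it, None)
            if v is None:
                break
            scores[i, j] = scores[j, i] = v
    return LinkageScoreMatrix(terminals, scores, np.zeros((m, m), int), internal)


class TestFitNull:
    def test_degenerate_identical_scores(self):
        m = _fake_matrix([0.3] * 25)
        null = fit_null(m)
        assert null.threshold == pytest.approx(0.3)
        from ldrefine import scaffolder

        graph = scaffolder.build_graph(m, null.threshold)
        assert graph.candidate_edges == {}

    def test_gaussian_quantile_geometry(self):
        rng = np.random.default_rng(77)
        vals = rng.normal(0.12, 0.0138, 10_000)
        null = fit_null(_fake_matrix(list(vals)))
        assert 0.14 <= null.threshold <= 0.16
        assert null.mean == pytest.approx(0.12, abs=0.002)

    def test_planted_signal_above_threshold(self):
        rng = np.random.default_rng(8)
        noise = list(rng.normal(0.1, 0.01, 500))
        signal = [0.9] * 10
        null = fit_null(_fake_matrix(noise + signal))
        assert all(s > null.threshold for s in signal)

    def test_too_few_scores(self):
        with pytest.raises(ValidationError):
            fit_null(_fake_matrix([0.1] * 10))
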