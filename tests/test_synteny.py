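import numpy as np
import pytest
from hypothesis import given, strategies as st

import synclock as sc
from conftest import random_gene_order


# --- independent brute-force oracle (no shared code with the implementation) ---

def oracle_neighborhood(genes, pos, k, circular):
    n = len(genes)
    labels = set()
    for d in list(range(-k, 0)) + list(range(1, k + 1)):
        i = pos + d
        if circular:
            labels.add(genes[i % n])
        elif 0 <= i < n:
            labels.add(genes[i])
    return labels


def oracle_si_distance(A, B, k):
    """Naive per-gene average over the label union; first occurrence positions."""
    pos_a = {}
    for i, g in enumerate(A.genes):
        pos_a.setdefault(g, i)
    pos_b = {}
    for i, g in enumerate(B.genes):
        pos_b.setdefault(g, i)
    union = set(pos_a) | set(pos_b)
    total = 0.0
    for g in union:
        if g in pos_a and g in pos_b:
            na = oracle_neighborhood(A.genes, pos_a[g], k, A.is_circular)
            nb = oracle_neighborhood(B.genes, pos_b[g], k, B.is_circular)
            total += len(na & nb) / (2 * k)
    return 1.0 - total / len(union)


class TestNeighborhood:
    def test_circular_wraps(self, circular8):
        assert sc.neighborhood(circular8, 0, 2) == {"g7", "g8", "g2", "g3"}

    def test_linear_truncates_at_end(self, circular8):
        linear = sc.GeneOrder("A", circular8.genes, "linear")
        assert sc.neighborhood(linear, 0, 2) == {"g2", "g3"}

    def test_overlapping_windows_cover_all_other_labels(self, circular8):
        # k=4 on an 8-gene circle: upstream and downstream windows overlap
        got = sc.neighborhood(circular8, 0, 4)
        brute = oracle_neighborhood(circular8.genes, 0, 4, True)
        assert got == brute == set(circular8.genes) - {"g1"}

    def test_si_analysis_rejects_window_covering_genome(self, circular8):
        with pytest.raises(ValueError, match="cover"):
            sc.pairwise_si_distance(circular8, circular8, sc.SyntenyParams(k=4))

    def test_position_out_of_range(self, circular8):
        with pytest.raises(IndexError):
            sc.neighborhood(circular8, 8, 2)


class TestGeneSI:
    def test_swap_example(self, circular8, circular8_swapped):
        rec = sc.gene_si("g1", circular8, circular8_swapped, sc.SyntenyParams(k=2))
        assert rec.si_similarity == pytest.approx(0.75)

    def test_identical_genomes_similarity_one(self, circular8):
        for g in circular8.genes:
            rec = sc.gene_si(g, circular8, circular8, sc.SyntenyParams(k=2))
            assert rec.si_similarity == 1.0

    def test_gene_absent_from_one_genome_scores_zero(self, circular8):
        other = sc.GeneOrder("B", ("h1", "h2", "h3", "h4", "h5", "g1", "h7", "h8"))
        assert sc.gene_si("g2", circular8, other, sc.SyntenyParams(k=2)).si_similarity == 0.0


class TestPairwiseDistance:
    def test_identical_genomes_distance_zero(self, circular8):
        assert sc.pairwise_si_distance(circular8, circular8, sc.SyntenyParams(k=2)) == 0.0

    def test_disjoint_gene_sets_distance_one(self, circular8):
        other = sc.GeneOrder("B", tuple(f"h{i}" for i in range(8)))
        assert sc.pairwise_si_distance(circular8, other, sc.SyntenyParams(k=2)) == 1.0

    def test_swap_example_matches_per_gene_average(self, circular8, circular8_swapped):
        params = sc.SyntenyParams(k=2)
        per_gene = [sc.gene_si(g, circular8, circular8_swapped, params).si_similarity
                    for g in circular8.genes]
        expected = 1.0 - sum(per_gene) / 8
        got = sc.pairwise_si_distance(circular8, circular8_swapped, params)
        assert got == pytest.approx(expected)
        assert got == oracle_si_distance(circular8, circular8_swapped, 2)

    @pytest.mark.parametrize("case", range(50))
    def test_agrees_with_brute_force_oracle(self, case):
        """Exact equality with an independent naive implementation."""
        rng = np.random.default_rng(case)
        n = int(rng.integers(12, 41))
        k = int(rng.integers(1, min(5, (n - 1) // 2) + 1))
        topo = "circular" if rng.random() < 0.5 else "linear"
        a = random_gene_order(rng, n, "A", topo)
        # second genome: permuted and with some labels replaced (content difference)
        genes = list(rng.permutation(a.genes))
        for i in rng.choice(n, size=n // 5, replace=False):
            genes[i] = f"x{i}"
        b = sc.GeneOrder("B", tuple(genes), topo)
        params = sc.SyntenyParams(k=k)
        oracle = oracle_si_distance(a, b, k)
        # equal up to summation order (last-ulp float differences)
        assert sc.pairwise_si_distance(a, b, params) == pytest.approx(oracle, abs=1e-12)
        assert sc.pairwise_si_distance(b, a, params) == pytest.approx(oracle, abs=1e-12)

    def test_duplicate_labels_collapse_to_first_occurrence(self):
        a = sc.GeneOrder("A", ("g1", "g2", "g3", "g4", "g5", "g2"))
        b = sc.GeneOrder("B", ("g1", "g2", "g3", "g4", "g5", "g6"))
        params = sc.SyntenyParams(k=1)
        # the duplicated g2 counts once, at its first position: the oracle
        # implements exactly that collapse rule
        assert sc.pairwise_si_distance(a, b, params) == \
            pytest.approx(oracle_si_distance(a, b, 1), abs=1e-12)
        # g2's neighbourhood is taken at its first occurrence (g1, g3)
        assert sc.gene_si("g2", a, b, params).si_similarity == 1.0


class TestDistanceMatrix:
    def test_identical_genomes_zero_matrix(self, circular8):
        coll = sc.GenomeCollection([
            sc.GeneOrder(f"G{i}", circular8.genes) for i in range(3)])
        m = sc.si_distance_matrix(coll, sc.SyntenyParams(k=2))
        np.testing.assert_array_equal(m.values, np.zeros((3, 3)))

    def test_matrix_reproduces_pairwise_values(self, circular8, circular8_swapped):
        copy = sc.GeneOrder("C", circular8.genes)
        coll = sc.GenomeCollection([circular8, circular8_swapped, copy])
        params = sc.SyntenyParams(k=2)
        m = sc.si_distance_matrix(coll, params)
        for a, b, d in m.iter_pairs():
            assert d == pytest.approx(
                sc.pairwise_si_distance(coll[a], coll[b], params))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        genomes = [random_gene_order(rng, 20, f"G{i}") for i in range(4)]
        params = sc.SyntenyParams(k=3)
        m1 = sc.si_distance_matrix(sc.GenomeCollection(genomes), params)
        m2 = sc.si_distance_matrix(sc.GenomeCollection(genomes[::-1]), params)
        for a, b, d in m1.iter_pairs():
            assert m2.get(a, b) == d

    def test_undersized_genome_named_in_error(self, circular8):
        tiny = sc.GeneOrder("tiny", ("c1", "c2", "c3"))
        coll = sc.GenomeCollection([circular8, tiny])
        with pytest.raises(ValueError, match="tiny"):
            sc.si_distance_matrix(coll, sc.SyntenyParams(k=2))


class TestProperties:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounds_symmetry_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 30))
        a = random_gene_order(rng, n, "A")
        b = random_gene_order(rng, n, "B")
        params = sc.SyntenyParams(k=2)
        d = sc.pairwise_si_distance(a, b, params)
        assert 0.0 <= d <= 1.0
        assert sc.pairwise_si_distance(b, a, params) == d
        assert sc.pairwise_si_distance(a, a, params) == 0.0

    def test_more_translocations_increase_expected_distance(self):
        """Mean SI distance grows with the number of applied events."""
        rng = np.random.default_rng(11)
        base = sc.GeneOrder("anc", tuple(f"g{i}" for i in range(60)))
        params = sc.SyntenyParams(k=3)
        means = []
        for p in (5, 25):
            dists = [
                sc.pairwise_si_distance(
                    base,
                    sc.simulate_translocations(base, sc.TranslocationScenario(p), rng),
                    params)
                for _ in range(200)
            ]
            means.append(np.mean(dists))
        assert means[1] > means[0]
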