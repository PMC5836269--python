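"""Domain count matrices, Poisson expansion tests, log2 ratios, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musselkit import synthetic
from musselkit.domainx import (
    DomainCountMatrix,
    DomainError,
    average_dot_similarity,
    cluster,
    expected_lambda,
    expected_lambdas,
    log2_ratio_matrix,
    poisson_tails,
    read_counts,
    read_domtblout_counts,
    results_frame,
)
from musselkit.domainx import test_domains as run_domain_tests


def matrix_from(rows, genomes, domains):
    return DomainCountMatrix(pd.DataFrame(rows, index=genomes, columns=domains))


# ---------------------------------------------------------------------------
# input handling


class TestReadCounts:
    def test_long_tsv_with_zero_fill(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "genome\tdomain\tcount\n"
            "A\tPF1\t10\nA\tPF2\t5\nB\tPF1\t7\nC\tPF2\t3\n"
        )
        m = read_counts(path)
        assert m.genomes == ["A", "B", "C"]
        assert m.counts.loc["B", "PF2"] == 0
        assert m.totals.to_dict() == {"A": 15, "B": 7, "C": 3}

    def test_duplicate_cells_rejected(self):
        df = pd.DataFrame({"genome": ["A", "A"], "domain": ["PF1", "PF1"], "count": [1, 2]})
        with pytest.raises(DomainError, match="duplicate"):
            read_counts(df)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"genome": ["A", "B"], "domain": ["PF1", "PF1"], "count": [1, -2]})
        with pytest.raises(DomainError, match="negative"):
            read_counts(df)

    def test_round_trip_preserves_counts(self, tmp_path):
        m, _ = synthetic.sim_domain_matrix(4, 30, seed=1, total_counts=500)
        path = tmp_path / "rt.tsv"
        m.to_long_tsv(path)
        back = read_counts(path)
        # read_counts orders labels lexicographically; counts are unchanged
        pd.testing.assert_frame_equal(
            back.counts, m.counts.sort_index(axis=0).sort_index(axis=1))

    def test_domtblout_evalue_threshold(self, tmp_path):
        path = tmp_path / "lf.domtblout"
        path.write_text(
            "# comment line\n"
            "geneA PF00001.1 100 q1 - 300 1e-06 50 1.1 ...\n"
            "geneB PF00001.1 100 q2 - 300 1e-04 40 1.2 ...\n"
        )
        m = read_domtblout_counts({"Lf": path, "Cg": path}, max_evalue=1e-5)
        assert m.counts.loc["Lf", "PF00001.1"] == 1


class TestMatrixInvariants:
    def test_frequencies_sum_to_one_exactly(self):
        m, _ = synthetic.sim_domain_matrix(5, 50, seed=3, total_counts=1000)
        sums = m.frequencies().sum(axis=1)
        assert np.allclose(sums, 1.0, rtol=0, atol=1e-12)

    def test_needs_two_genomes(self):
        with pytest.raises(DomainError):
            matrix_from([[1, 2]], ["only"], ["PF1", "PF2"])


# ---------------------------------------------------------------------------
# expectations


class TestExpectedLambda:
    def test_frequency_average_rescaled_to_focal_total(self):
        # A: 10/100, B: 30/300 -> both 0.1; focal total 200 -> lambda 20
        m = matrix_from(
            [[10, 90], [30, 270], [40, 160]],
            ["A", "B", "F"],
            ["d", "other"],
        )
        assert expected_lambda(m, "F", "d") == pytest.approx(20.0)

    def test_zero_everywhere_else_gives_zero(self):
        m = matrix_from([[0, 10], [0, 20], [5, 15]], ["A", "B", "F"], ["d", "o"])
        assert expected_lambda(m, "F", "d") == 0.0

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 50, size=(5, 20))
        counts[:, 0] += 1  # keep totals positive
        genomes = [f"g{i}" for i in range(5)]
        domains = [f"d{j}" for j in range(20)]
        m = matrix_from(counts, genomes, domains)
        lams = expected_lambdas(m, "g2")
        n_focal = counts[2].sum()
        for j, d in enumerate(domains):
            freqs = [counts[i, j] / counts[i].sum() for i in range(5) if i != 2]
            assert lams[d] == pytest.approx(np.mean(freqs) * n_focal)

    def test_zero_total_genome_rejected(self):
        with pytest.raises(DomainError, match="zero total"):
            matrix_from([[0, 0], [1, 2]], ["A", "B"], ["d", "o"]).frequencies()


# ---------------------------------------------------------------------------
# Poisson tails


def brute_pmf(i, lam):
    # log-space to stay finite for large i and lam
    if lam == 0:
        return 1.0 if i == 0 else 0.0
    return math.exp(-lam + i * math.log(lam) - math.lgamma(i + 1))


class TestPoissonTails:
    def test_matches_brute_force_summation(self):
        p_up, p_down = poisson_tails(7, 2.0)
        assert p_up == pytest.approx(1 - sum(brute_pmf(i, 2.0) for i in range(7)), abs=1e-12)
        assert p_up == pytest.approx(0.00453, abs=5e-6)
        assert p_down == pytest.approx(sum(brute_pmf(i, 2.0) for i in range(8)), abs=1e-12)

    @given(lam=st.floats(min_value=0.01, max_value=60.0))
    def test_x_zero_closed_form(self, lam):
        p_up, p_down = poisson_tails(0, lam)
        assert p_up == 1.0
        assert p_down == pytest.approx(math.exp(-lam), rel=1e-12)

    @given(
        x=st.integers(min_value=0, max_value=200),
        lam=st.floats(min_value=0.0, max_value=100.0),
    )
    def test_tail_identity(self, x, lam):
        p_up, p_down = poisson_tails(x, lam)
        assert p_up + p_down == pytest.approx(1.0 + brute_pmf(x, lam), abs=1e-9)

    def test_degenerate_lambda_zero(self):
        assert poisson_tails(0, 0.0) == (1.0, 1.0)
        p_up, p_down = poisson_tails(3, 0.0)
        assert (p_up, p_down) == (0.0, 1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            poisson_tails(-1, 2.0)
        with pytest.raises(DomainError):
            poisson_tails(1, -2.0)

    def test_brute_force_agreement_sweep(self):
        """Tails agree with direct pmf summation to 1e-12 for lambda <= 50."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            lam = float(rng.uniform(0.1, 50.0))
            x = int(rng.integers(0, 120))
            p_up, p_down = poisson_tails(x, lam)
            assert p_down == pytest.approx(sum(brute_pmf(i, lam) for i in range(x + 1)), abs=1e-12)


# ---------------------------------------------------------------------------
# expansion testing


class TestTestDomains:
    def test_bonferroni_adjustment_example(self):
        # raw p_up 0.0004 with 100 domains (family 'domains') -> adjusted 0.04
        rng = np.random.default_rng(4)
        base = rng.integers(20, 60, size=100)
        counts = np.vstack([base, base, base])
        counts[2, 0] = int(3.2 * base[0])  # clearly expanded
        m = matrix_from(counts, ["A", "B", "F"], [f"d{j}" for j in range(100)])
        res = {r.domain: r for r in run_domain_tests(m, "F", family_size="domains")}
        r0 = res["d0"]
        assert r0.call == "expanded"
        assert r0.p_adjusted == pytest.approx(min(1.0, r0.p_up * 100))

    def test_observation_at_expectation_is_neutral(self):
        counts = np.full((3, 10), 30)
        m = matrix_from(counts, ["A", "B", "F"], [f"d{j}" for j in range(10)])
        assert all(r.call == "neutral" for r in run_domain_tests(m, "F"))

    def test_invariant_to_scaling_one_reference_genome(self):
        m, _ = synthetic.sim_domain_matrix(6, 100, planted=[(0, 4.0)], seed=8,
                                           total_counts=5000)
        calls = {r.domain: r.call for r in run_domain_tests(m, "Lf")}
        scaled = m.counts.copy()
        scaled.loc["G03"] *= 7  # totals scale along with counts
        m2 = DomainCountMatrix(scaled)
        calls2 = {r.domain: r.call for r in run_domain_tests(m2, "Lf")}
        assert calls == calls2

    def test_bonferroni_never_calls_more_than_unadjusted(self):
        m, _ = synthetic.sim_domain_matrix(10, 300, planted=[(0, 4.0), (1, 0.25)], seed=12,
                                           total_counts=8000)
        res = run_domain_tests(m, "Lf")
        called = {r.domain for r in res if r.call != "neutral"}
        raw_called = {
            r.domain for r in res
            if (r.p_up <= 0.05 and r.observed > r.expected)
            or (r.p_down <= 0.05 and r.observed < r.expected)
        }
        assert called <= raw_called

    def test_unfloored_rule_flags_focal_only_singletons(self):
        # with min_expected=0 a single focal count with zero references is
        # "infinitely significant" under Poisson(0); the default floor is not
        counts = np.zeros((10, 3), dtype=int)
        counts[:, 2] = 100
        counts[0, 0] = 1
        m = matrix_from(counts, [f"g{i}" for i in range(10)], ["rare", "absent", "common"])
        literal = {r.domain: r.call for r in run_domain_tests(m, "g0", min_expected=0.0)}
        floored = {r.domain: r.call for r in run_domain_tests(m, "g0")}
        assert literal["rare"] == "expanded"
        assert floored["rare"] == "neutral"

    def test_alpha_bounds_checked(self):
        m, _ = synthetic.sim_domain_matrix(3, 10, seed=0, total_counts=100)
        with pytest.raises(DomainError):
            run_domain_tests(m, "Lf", alpha=1.5)

    def test_results_frame_columns(self):
        m, _ = synthetic.sim_domain_matrix(3, 10, seed=0, total_counts=100)
        frame = results_frame(run_domain_tests(m, "Lf"))
        assert list(frame.columns) == [
            "domain", "observed", "expected", "p_up", "p_down", "p_adjusted", "call"]


# ---------------------------------------------------------------------------
# log2 ratio matrix


class TestLog2Ratio:
    def test_identical_rows_give_zero(self):
        counts = np.tile(np.array([10, 20, 30]), (4, 1))
        m = matrix_from(counts, list("ABCD"), ["d1", "d2", "d3"])
        lrm = log2_ratio_matrix(m)
        assert np.allclose(lrm.values.to_numpy(), 0.0)

    def test_doubled_domain_approaches_plus_one(self):
        # one genome doubled on one domain; with a vanishing pseudocount the
        # entry tends to log2(2 / mean-ratio) ~ +1 against many references
        n_ref = 40
        counts = np.tile(np.array([100, 900]), (n_ref + 1, 1))
        counts[0, 0] = 200
        counts[0, 1] = 800  # keep total fixed so normalization is untouched
        m = matrix_from(counts, [f"g{i}" for i in range(n_ref + 1)], ["d", "rest"])
        lrm = log2_ratio_matrix(m, pseudocount=1e-9)
        assert lrm.values.iloc[0, 0] == pytest.approx(1.0, abs=0.05)

    def test_reconstruction_inverts_transform(self):
        m, _ = synthetic.sim_domain_matrix(6, 40, seed=21, total_counts=2000)
        lrm = log2_ratio_matrix(m, pseudocount=0.5)
        norm = m.frequencies() * lrm.scale_total
        pd.testing.assert_frame_equal(
            lrm.reconstructed_counts(), norm, check_exact=False, atol=1e-9)

    def test_negative_pseudocount_rejected(self):
        m, _ = synthetic.sim_domain_matrix(3, 10, seed=0, total_counts=100)
        with pytest.raises(DomainError):
            log2_ratio_matrix(m, pseudocount=-1)


# ---------------------------------------------------------------------------
# clustering


def brute_force_complete_linkage(dist, labels):
    """O(n^3) agglomeration oracle with the same tie-break convention."""
    clusters = {label: (label,) for label in labels}
    merges = []
    while len(clusters) > 1:
        best = None
        reps = sorted(clusters)
        for i, ra in enumerate(reps):
            for rb in reps[i + 1:]:
                d = max(
                    dist[labels.index(x), labels.index(y)]
                    for x in clusters[ra]
                    for y in clusters[rb]
                )
                key = (d, ra, rb)
                if best is None or key < best:
                    best = key
        d, ra, rb = best
        merges.append((tuple(sorted(clusters[ra])), tuple(sorted(clusters[rb])), d))
        clusters[ra] = clusters[ra] + clusters.pop(rb)
    return merges


class TestCluster:
    def test_identical_rows_merge_first_at_distance_zero(self):
        # under dot-product similarity the identical pair merges at zero
        # when it carries the largest profile norm (its self-similarity is
        # then the global maximum); cosine similarity guarantees it always
        df = pd.DataFrame(
            [[2.0, 4.0, 6.0], [2.0, 4.0, 6.0], [0.9, 0.1, 0.4]],
            index=["a", "b", "c"],
        )
        for similarity in ("avg_dot", "cosine"):
            result = cluster(df, similarity=similarity)
            first = result.merges[0]
            assert set(first.left + first.right) == {"a", "b"}
            assert first.distance == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_merge_sequence_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"g{i}" for i in range(5)])
        result = cluster(df)
        sim = average_dot_similarity(df.to_numpy())
        dist = sim.max() - sim
        np.fill_diagonal(dist, 0.0)
        expected = brute_force_complete_linkage(dist, list(df.index))
        got = [(m.left, m.right, m.distance) for m in result.merges]
        for (gl, gr, gd), (el, er, ed) in zip(got, expected):
            assert {gl, gr} == {el, er}
            assert gd == pytest.approx(ed)

    def test_heights_match_scipy_cophenetic(self):
        """Independent check against scipy's complete-linkage heights."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(99)
        df = pd.DataFrame(rng.normal(size=(7, 9)), index=[f"g{i}" for i in range(7)])
        sim = average_dot_similarity(df.to_numpy())
        dist = sim.max() - sim
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        z = linkage(squareform(dist, checks=False), method="complete")
        coph = squareform(cophenet(z))
        result = cluster(df)
        # cophenetic distance between two labels = height of the merge
        # that first united them
        labels = list(df.index)
        mine = np.zeros_like(coph)
        for merge in result.merges:
            for a in merge.left:
                for b in merge.right:
                    i, j = labels.index(a), labels.index(b)
                    mine[i, j] = mine[j, i] = merge.distance
        assert np.allclose(mine, coph, atol=1e-9)

    def test_newick_reparses_to_same_topology(self):
        import dendropy

        m, _ = synthetic.sim_domain_matrix(6, 25, seed=31, total_counts=800)
        result = cluster(log2_ratio_matrix(m))
        tree = dendropy.Tree.get(data=result.newick, schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(result.labels)
        # every merge corresponds to a clade in the parsed tree
        clades = {
            frozenset(lf.taxon.label for lf in node.leaf_iter())
            for node in tree.preorder_node_iter()
        }
        for merge in result.merges:
            assert frozenset(merge.members) in clades

    def test_single_item_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["only"])
        with pytest.raises(DomainError):
            cluster(df)

    def test_domain_axis_clusters_columns(self):
        m, _ = synthetic.sim_domain_matrix(5, 12, seed=2, total_counts=600)
        result = cluster(log2_ratio_matrix(m), axis="domains")
        assert set(result.labels) == set(m.domains)
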