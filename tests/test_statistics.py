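import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from correlognet.network import CorrelogGroupSet, build_mrs, correlog_groups
from correlognet.statistics import (
    AnnotationMap,
    PairSet,
    category_overlap,
    category_overlap_p,
    clustering_bounds,
    clustering_expectation,
    clustering_z,
    coherence_null_z,
    dispersion_slope,
    functional_coherence,
    pairset_w_comparison,
    phylum_dispersion_z,
    shortest_path_strata,
)


def make_groups(sizes):
    genes = [f"g{i:03d}" for i in range(sum(sizes))]
    group_of, members, pos = {}, {}, 0
    for gid, s in enumerate(sizes, 1):
        members[gid] = genes[pos : pos + s]
        for g in members[gid]:
            group_of[g] = gid
        pos += s
    return CorrelogGroupSet(group_of, members), genes


def enumerate_expectation(sizes, n_mapped):
    """Exhaustive enumeration oracle for the clustering mean and sd."""
    labels = [gid for gid, s in enumerate(sizes) for _ in range(s)]
    m = len(labels)
    total = total_sq = 0
    count = 0
    for subset in itertools.combinations(range(m), n_mapped):
        n = len({labels[i] for i in subset})
        total += n
        total_sq += n * n
        count += 1
    mean = Fraction(total, count)
    var = Fraction(total_sq, count) - mean * mean
    return float(mean), math.sqrt(max(float(var), 0.0))


# ---------------------------------------------------------------------------
# clustering statistics


class TestClusteringExpectation:
    def test_two_singletons_one_draw(self):
        assert clustering_expectation([1, 1], 1) == (1.0, 0.0)

    def test_derived_two_pairs_two_draws(self):
        eta, sigma = clustering_expectation([2, 2], 2)
        assert eta == pytest.approx(5 / 3)
        assert sigma == pytest.approx(math.sqrt(2 / 9))

    def test_saturation(self):
        eta, sigma = clustering_expectation([3, 2, 4], 9)
        assert eta == 3.0
        assert sigma == 0.0

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            clustering_expectation([2, 2], 5)

    @given(
        sizes=st.lists(st.integers(1, 4), min_size=1, max_size=4),
        data=st.data(),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_enumeration(self, sizes, data):
        n = data.draw(st.integers(1, sum(sizes)))
        eta, sigma = clustering_expectation(sizes, n)
        eta_o, sigma_o = enumerate_expectation(sizes, n)
        assert eta == pytest.approx(eta_o, abs=1e-13)
        assert sigma == pytest.approx(sigma_o, abs=1e-13)

    def test_with_replacement_variant(self):
        # single group: always hit -> eta=1, sigma=0 under both models
        assert clustering_expectation([5], 3, with_replacement=True) == (1.0, 0.0)
        # two equal groups, 2 draws with replacement: p_g = 3/4,
        # q = 1/2, var = 2*(3/16) + 2*(1/2 - 9/16) = 1/4
        eta, sigma = clustering_expectation([2, 2], 2, with_replacement=True)
        assert eta == pytest.approx(1.5)
        assert sigma == pytest.approx(0.5)


class TestClusteringZ:
    def test_single_group_set_is_clustered(self):
        groups, _ = make_groups([4, 4, 4])
        st_ = clustering_z(groups, groups.members[1])
        assert st_.n == 1
        assert st_.z is not None and st_.z < 0

    def test_one_gene_per_group_is_anticlustered(self):
        groups, _ = make_groups([4, 4, 4])
        gene_set = [groups.members[g][0] for g in groups.members]
        st_ = clustering_z(groups, gene_set)
        assert st_.n == groups.n_groups
        assert st_.z is not None and st_.z > 0

    def test_unmapped_genes_reported(self):
        groups, _ = make_groups([2, 2])
        st_ = clustering_z(groups, ["g000", "unknown"])
        assert st_.n_mapped == 1
        assert st_.unmapped_genes == ["unknown"]

    def test_no_mappable_genes_errors(self):
        groups, _ = make_groups([2])
        with pytest.raises(ValueError, match="maps"):
            clustering_z(groups, ["nope"])

    def test_saturation_flags_z_none(self):
        groups, genes = make_groups([2, 3])
        st_ = clustering_z(groups, genes)
        assert st_.sigma == 0.0
        assert st_.z is None

    def test_organism_from_few_modules_clusters(self, planted_run):
        from correlognet.synthetic import generate_organism_sets

        sets = generate_organism_sets(
            planted_run["model"], n_organisms=5, modules_per_organism=3, seed=2
        )
        groups = planted_run["groups"]
        zs = [clustering_z(groups, s).z for s in sets]
        assert all(z is not None and z < -2 for z in zs)

    def test_n_within_bounds(self):
        rng = np.random.default_rng(8)
        groups, genes = make_groups([5, 3, 3, 2, 1])
        sizes = list(groups.sizes.values())
        for _ in range(20):
            k = int(rng.integers(1, len(genes)))
            subset = rng.choice(genes, size=k, replace=False)
            st_ = clustering_z(groups, subset)
            n_min, n_max = clustering_bounds(sizes, st_.n_mapped)
            assert n_min <= st_.n <= n_max


class TestClusteringBounds:
    def test_derived_pack_and_spread(self):
        assert clustering_bounds([3, 2], 4) == (2, 2)

    def test_fits_one_group(self):
        n_min, _ = clustering_bounds([5, 5], 5)
        assert n_min == 1

    def test_single_gene(self):
        assert clustering_bounds([2, 2], 1) == (1, 1)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            clustering_bounds([2], 3)


# ---------------------------------------------------------------------------
# coherence and overlap


class TestFunctionalCoherence:
    def test_fraction_arithmetic(self):
        groups, genes = make_groups([3])
        ann = AnnotationMap(
            {genes[0]: {"c1"}, genes[1]: {"c1"}, genes[2]: {"c2"}}
        )
        table, summary = functional_coherence(groups, ann)
        assert table[1]["c1"] == pytest.approx(2 / 3)
        assert table[1]["c2"] == pytest.approx(1 / 3)
        assert summary == 0.0  # no category covers all three genes

    def test_unannotated_group_excluded(self):
        groups, genes = make_groups([2, 2])
        ann = AnnotationMap({genes[0]: {"c"}, genes[1]: {"c"}})
        table, summary = functional_coherence(groups, ann)
        assert 2 not in table
        assert summary == 1.0

    def test_multilabel_singleton(self):
        groups, genes = make_groups([1])
        ann = AnnotationMap({genes[0]: {"c1", "c2"}})
        table, summary = functional_coherence(groups, ann)
        assert table[1] == {"c1": 1.0, "c2": 1.0}
        assert summary is None  # no group with >1 annotated gene


class TestCoherenceNullZ:
    def test_identical_annotations_give_zero(self):
        groups, genes = make_groups([3, 3])
        ann = AnnotationMap({g: {"c"} for g in genes})
        z, observed, mean, sd = coherence_null_z(groups, ann, n_perm=100, seed=0)
        assert observed == 1.0
        assert mean == 1.0
        assert z is None  # degenerate null flagged

    def test_pure_modules_strongly_coherent(self, planted_run):
        from correlognet.synthetic import generate_annotations

        ann = generate_annotations(planted_run["model"], purity=1.0)
        groups = planted_run["groups"]
        _, observed = functional_coherence(groups, ann)
        assert observed == 1.0
        z, *_ = coherence_null_z(groups, ann, n_perm=200, seed=0)
        assert z is not None and z > 2

    def test_permutation_preserves_cardinality(self):
        # genes with 2 labels must keep 2 labels under the null; verify the
        # null never produces an impossible coherence when cardinalities are
        # the invariant that forces it
        groups, genes = make_groups([2])
        ann = AnnotationMap({genes[0]: {"a", "b"}, genes[1]: {"a", "b"}})
        z, observed, mean, sd = coherence_null_z(groups, ann, n_perm=50, seed=1)
        assert observed == 1.0 and mean == 1.0


class TestCategoryOverlap:
    def test_one_third(self):
        groups, genes = make_groups([2, 1, 1])
        ann = AnnotationMap(
            {
                genes[0]: {"c1"},
                genes[1]: {"c2"},  # group 1 has both
                genes[2]: {"c1"},  # group 2 only c1
                genes[3]: {"c2"},  # group 3 only c2
            }
        )
        assert category_overlap(groups, ann, "c1", "c2") == pytest.approx(1 / 3)

    def test_never_shared_is_zero(self):
        groups, genes = make_groups([1, 1])
        ann = AnnotationMap({genes[0]: {"c1"}, genes[1]: {"c2"}})
        assert category_overlap(groups, ann, "c1", "c2") == 0.0

    def test_self_overlap_is_one(self):
        groups, genes = make_groups([2, 1])
        ann = AnnotationMap({genes[0]: {"c1"}})
        assert category_overlap(groups, ann, "c1", "c1") == 1.0

    def test_unknown_category_rejected(self):
        groups, genes = make_groups([1])
        ann = AnnotationMap({genes[0]: {"c1"}})
        with pytest.raises(ValueError, match="unknown"):
            category_overlap(groups, ann, "c1", "zz")

    def test_absent_categories_flagged_null(self):
        groups, genes = make_groups([1])
        ann = AnnotationMap({genes[0]: {"c1"}}, categories={"c1", "c2", "c3"})
        # c2/c3 exist in the universe but occur in no group
        assert category_overlap(groups, ann, "c2", "c3") is None


class TestCategoryOverlapP:
    def test_minimum_statistic_gives_p_near_one(self):
        groups, genes = make_groups([1, 1])
        ann = AnnotationMap({genes[0]: {"c1"}, genes[1]: {"c2"}})
        p, y = category_overlap_p(groups, ann, "c1", "c2", n_perm=99, seed=0)
        assert y == 0.0
        assert p == 1.0  # every permutation has Y >= 0

    def test_cosegregating_categories_minimal_p(self):
        # c1 and c2 always share a group; permutations break that
        sizes = [2] * 10 + [1] * 10
        groups, genes = make_groups(sizes)
        labels = {}
        pos = 0
        for s in sizes:
            if s == 2:
                labels[genes[pos]] = {"c1"}
                labels[genes[pos + 1]] = {"c2"}
            else:
                labels[genes[pos]] = {"c3"}
            pos += s
        ann = AnnotationMap(labels)
        p, y = category_overlap_p(groups, ann, "c1", "c2", n_perm=199, seed=0)
        assert y == 1.0
        assert p < 0.05

    def test_p_in_unit_interval_add_one(self):
        groups, genes = make_groups([2, 2])
        ann = AnnotationMap({g: {"c1"} if i % 2 else {"c2"} for i, g in enumerate(genes)})
        p, _ = category_overlap_p(groups, ann, "c1", "c2", n_perm=49, seed=3)
        assert 1 / 50 <= p <= 1.0


# ---------------------------------------------------------------------------
# pair-set comparison


class TestShortestPathStrata:
    def test_path_graph(self):
        ps = shortest_path_strata([("a", "b"), ("b", "c")], ["a", "b", "c"])
        d = dict(zip(ps.pairs, ps.strata))
        assert d[("a", "c")] == 2
        assert d[("a", "b")] == 1

    def test_cross_component_pairs_excluded(self):
        ps = shortest_path_strata([("a", "b"), ("c", "d")], ["a", "b", "c", "d"])
        assert ("a", "c") not in ps.pairs
        assert set(ps.pairs) == {("a", "b"), ("c", "d")}

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="interaction graph"):
            shortest_path_strata([("x", "y")], ["a", "b"])

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(17)
        n = 30
        nodes = [f"n{i:02d}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.1
        ]
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0)
        for a, b in edges:
            i, j = nodes.index(a), nodes.index(b)
            dist[i, j] = dist[j, i] = 1
        for k in range(n):
            dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
        ps = shortest_path_strata(edges, nodes)
        got = dict(zip(ps.pairs, ps.strata))
        for i in range(n):
            for j in range(i + 1, n):
                key = (nodes[i], nodes[j])
                if np.isfinite(dist[i, j]):
                    assert got[key] == int(dist[i, j])
                else:
                    assert key not in got


class TestPairSetComparison:
    def _matrix(self, rng, genes):
        a = rng.standard_normal((len(genes), len(genes)))
        w = (a + a.T) / 2
        np.fill_diagonal(w, 0.0)
        return w

    def test_pair_set_equals_population_gives_zero_z(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(6)]
        w = self._matrix(rng, genes)
        all_pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        ps = PairSet(list(all_pairs))
        cmp_ = pairset_w_comparison(w, genes, ps, PairSet(list(all_pairs)),
                                    n_draws=50, seed=1)
        assert cmp_.z == 0.0

    def test_constant_matrix_flags_null(self):
        genes = ["a", "b", "c", "d"]
        w = np.full((4, 4), 0.3)
        np.fill_diagonal(w, 0.0)
        all_pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        ps = PairSet(all_pairs[:2])
        cmp_ = pairset_w_comparison(w, genes, ps, PairSet(all_pairs),
                                    n_draws=50, seed=1)
        assert cmp_.z is None

    def test_within_module_pairs_enriched(self, planted_run):
        res = planted_run["result"]
        labels = planted_run["labels"]
        genes = res.gene_ids
        within = [
            (a, b)
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
            if labels[a] == labels[b]
        ]
        all_pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        cmp_ = pairset_w_comparison(
            res.w, genes, PairSet(within), PairSet(all_pairs), n_draws=300, seed=4
        )
        assert cmp_.z is not None and cmp_.z > 3
        assert cmp_.p_gaussian < 1e-3

    def test_small_stratum_resampled_with_warning(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(5)]
        w = self._matrix(rng, genes)
        obs = PairSet([("g0", "g1"), ("g0", "g2")], strata=[1, 1])
        pop = PairSet([("g3", "g4")], strata=[1])
        with pytest.warns(UserWarning, match="replacement"):
            pairset_w_comparison(w, genes, obs, pop, n_draws=20, seed=0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(8)]
        w = self._matrix(rng, genes)
        all_pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        obs = PairSet(all_pairs[:5])
        c1 = pairset_w_comparison(w, genes, obs, PairSet(all_pairs),
                                  n_draws=200, seed=7)
        # relabel genes by a permutation applied consistently everywhere
        perm = {g: f"x{i}" for i, g in enumerate(genes)}
        genes2 = [perm[g] for g in genes]
        obs2 = PairSet([(perm[a], perm[b]) for a, b in obs.pairs])
        pop2 = PairSet([(perm[a], perm[b]) for a, b in all_pairs])
        c2 = pairset_w_comparison(w, genes2, obs2, pop2, n_draws=200, seed=7)
        assert c1.observed_mean == pytest.approx(c2.observed_mean)
        assert c1.z == pytest.approx(c2.z)

    def test_unknown_gene_rejected(self):
        w = np.zeros((2, 2))
        with pytest.raises(ValueError, match="unknown gene"):
            pairset_w_comparison(
                w, ["a", "b"], PairSet([("a", "zz")]), PairSet([("a", "b")])
            )


# ---------------------------------------------------------------------------
# phylum dispersion


def phylum_fixture(seed):
    """Narrow low-coupling genes confined to one phylum vs broad modules."""
    from correlognet.profile_io import ProfileMatrix

    rng = np.random.default_rng(seed)
    phyla_sizes = [150, 30, 20, 12, 10, 8, 6, 4]
    phylum_of = np.concatenate([[p] * s for p, s in enumerate(phyla_sizes)])
    n_sp = len(phylum_of)
    species = [f"s{k:03d}" for k in range(n_sp)]
    tax = {s: f"P{p}" for s, p in zip(species, phylum_of)}
    genes, rows = [], []
    for m in range(10):  # singletons restricted to the dominant phylum
        act = (rng.random(n_sp) < 0.15) & (phylum_of == 0)
        u = rng.random(n_sp)
        rows.append(np.where(act, u >= 0.05, u < 0.01))
        genes.append(f"n{m}")
    for m in range(6):  # 6-gene modules spanning five phyla
        act = (rng.random(n_sp) < 0.10) & (phylum_of <= 4)
        for g in range(6):
            u = rng.random(n_sp)
            rows.append(np.where(act, u >= 0.05, u < 0.01))
            genes.append(f"b{m}_{g}")
    pm = ProfileMatrix(genes, species, np.array(rows, dtype=np.int8))
    return pm, tax


class TestDispersionSlope:
    def test_exact_ols_line(self):
        slope, _, n = dispersion_slope([1, 2, 3], [1.0, 2.0, 3.0], n_phyla_max=7)
        assert slope == pytest.approx(1.0)
        assert n == 3

    def test_constant_response_zero_slope(self):
        slope, norm, _ = dispersion_slope([1, 2, 3, 4], [5.0] * 4, n_phyla_max=7)
        assert slope == pytest.approx(0.0)
        assert norm == 0.0

    def test_too_few_distinct_counts(self):
        with pytest.raises(ValueError, match="distinct"):
            dispersion_slope([1, 1, 2, 2], [1.0, 2.0, 3.0, 4.0], n_phyla_max=7)

    def test_max_filter_applies(self):
        slope, _, n = dispersion_slope([1, 2, 3, 50], [1.0, 2.0, 3.0, 99.0],
                                       n_phyla_max=7)
        assert n == 3
        assert slope == pytest.approx(1.0)


class TestPhylumDispersionZ:
    def test_broad_modules_drive_positive_z(self):
        pm, tax = phylum_fixture(5)
        res = phylum_dispersion_z(pm, tax, x_th=10, n_phyla_max=7, n_perm=100, seed=5)
        assert res.z > 2
        assert res.slope > 0

    def test_missing_taxonomy_errors(self):
        pm, tax = phylum_fixture(5)
        tax = dict(tax)
        tax.pop(pm.species_ids[0])
        with pytest.raises(ValueError, match="missing"):
            phylum_dispersion_z(pm, tax, x_th=10, n_perm=1, seed=0)
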