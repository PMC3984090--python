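"""Identity distance, UPGMA (vs. independent oracles) and haplogroups."""

import itertools

import numpy as np
import pytest

from haploclust.clustering import (
    ZeroOverlapWarning,
    distance_matrix,
    pairwise_distance,
    partition_haplogroups,
    upgma,
)
from haploclust.core import DataError, DistanceMatrix, Region, SNPMatrix
from haploclust.simulate import FixtureSpec, generate_matrix
from .conftest import make_matrix


# ------------------------------------------------------------------ distance

@pytest.mark.parametrize(
    "a,b,d,compared",
    [
        (list("ACGT"), list("ACTT"), 0.25, 4),
        (list("ANG"), list("AC-"), 0.0, 1),   # missing excluded either side
        (list("ACGT"), list("ACGT"), 0.0, 4),
        (list("RYSW"), list("RYSW"), 0.0, 4),  # ambiguity codes first-class
        (list("RG"), list("AG"), 0.5, 2),      # R is not expanded to A/G
    ],
)
def test_pairwise_distance(a, b, d, compared):
    got_d, got_c = pairwise_distance(a, b)
    assert got_d == pytest.approx(d)
    assert got_c == compared
    # symmetry
    assert pairwise_distance(b, a) == (got_d, got_c)


def test_pairwise_zero_overlap_warns_and_maxes():
    with pytest.warns(ZeroOverlapWarning):
        d, c = pairwise_distance(list("NN"), list("AC"))
    assert (d, c) == (1.0, 0)


def test_pairwise_length_mismatch():
    with pytest.raises(DataError):
        pairwise_distance(list("AC"), list("A"))


def test_distance_matrix_identical_samples():
    m = make_matrix("c", range(1, 11), ["R", "S"], ["AA"] * 10)
    dm = distance_matrix(m)
    assert dm.d[0, 1] == 0.0
    assert dm.compared[0, 1] == 10
    assert dm.compared[0, 0] == 10  # diagonal: non-missing cell count


def test_distance_matrix_requires_two_samples():
    m = make_matrix("c", [1], ["R"], ["A"])
    with pytest.raises(DataError):
        distance_matrix(m)


def test_distance_matrix_counts_missing_on_diagonal():
    m = make_matrix("c", [1, 2, 3], ["R", "S"], ["AN", "C-", "GT"])
    dm = distance_matrix(m)
    assert dm.compared[0, 0] == 3 and dm.compared[1, 1] == 1
    assert dm.compared[0, 1] == 1


def test_distance_matrix_planted_clusters(clean_two_cluster):
    m, truth = clean_two_cluster
    dm = distance_matrix(m)
    founder_of = {s: truth[s] for s in m.samples}
    # realized divergence: reference column vs any founder-2 column
    any2 = next(s for s in m.samples if founder_of[s] == 2)
    planted = float(np.mean(m.column("Ref") != m.column(any2)))
    assert planted >= 0.05
    for i, a in enumerate(m.samples):
        for j, b in enumerate(m.samples):
            if i >= j:
                continue
            if founder_of[a] == founder_of[b]:
                assert dm.d[i, j] == 0.0
            else:
                assert dm.d[i, j] == pytest.approx(planted)


def test_distance_matrix_permutation_equivariance(clean_two_cluster):
    m, _ = clean_two_cluster
    rng = np.random.default_rng(0)
    perm = rng.permutation(m.n_samples)
    shuffled = SNPMatrix(
        chromosome=m.chromosome,
        positions=m.positions,
        samples=tuple(m.samples[i] for i in perm),
        calls=m.calls[:, perm],
    )
    dm = distance_matrix(m)
    dm2 = distance_matrix(shuffled)
    assert np.allclose(dm2.d, dm.d[np.ix_(perm, perm)])


def test_distance_matrix_properties_across_fixtures():
    for seed in range(5):
        m, _ = generate_matrix(FixtureSpec(
            n_samples=10, n_sites=80, region=Region("c", 1, 4000),
            noise=0.05, missing=0.2, seed=seed,
        ))
        dm = distance_matrix(m)
        assert np.allclose(dm.d, dm.d.T)
        assert (np.diag(dm.d) == 0).all()
        assert ((dm.d >= 0) & (dm.d <= 1)).all()


# ----------------------------------------------------------------- UPGMA

def brute_force_upgma(d):
    """Average-linkage oracle recomputing all means from scratch each merge.

    Returns a set of (frozenset(leaf indices), height) merge records and
    the nested-cluster topology, using the same deterministic tie rule
    as the implementation under test.
    """
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    records = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            avg = float(np.mean([d[i, j] for i in a for j in b]))
            key = (avg, (min(min(a), min(b)), max(min(a), min(b))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (avg, _), a, b = best
        merged = a | b
        records.append((merged, avg / 2.0))
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
    return records


def tree_merge_records(tree, samples):
    index = {name: i for i, name in enumerate(samples)}
    records = []

    def walk(node):
        if node.is_leaf:
            return frozenset([index[node.name]])
        members = frozenset()
        for child in node.children:
            members |= walk(child)
        records.append((members, node.height))
        return members

    walk(tree.root)
    return records


def test_upgma_two_samples():
    dm = DistanceMatrix(
        samples=("A", "B"),
        d=np.array([[0, 0.2], [0.2, 0]], dtype=float),
        compared=np.ones((2, 2), dtype=int),
    )
    t = upgma(dm)
    assert t.root.height == pytest.approx(0.1)
    assert t.leaf_order() == ["A", "B"]


def test_upgma_three_samples_hand_example():
    d = np.array([
        [0.0, 0.1, 0.4],
        [0.1, 0.0, 0.4],
        [0.4, 0.4, 0.0],
    ])
    dm = DistanceMatrix(samples=("A", "B", "C"), d=d,
                        compared=np.ones((3, 3), dtype=int))
    t = upgma(dm)
    assert t.root.height == pytest.approx(0.2)
    inner = next(c for c in t.root.children if not c.is_leaf)
    assert inner.height == pytest.approx(0.05)
    assert sorted(inner.leaf_names()) == ["A", "B"]


def test_upgma_rejects_nan():
    bad = DistanceMatrix(samples=("A", "B"), d=np.zeros((2, 2)),
                         compared=np.ones((2, 2), dtype=int))
    # NaN cannot pass DistanceMatrix validation, so smuggle it in
    object.__setattr__(bad, "d", np.array([[0.0, np.nan], [np.nan, 0.0]]))
    with pytest.raises(DataError):
        upgma(bad)


def test_upgma_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(2, 9))
        x = rng.random((n, n))
        d = (x + x.T) / 2.0
        np.fill_diagonal(d, 0.0)
        samples = tuple(f"s{i}" for i in range(n))
        dm = DistanceMatrix(samples=samples, d=d,
                            compared=np.ones((n, n), dtype=int))
        t = upgma(dm)
        got = {frozenset(m): h for m, h in tree_merge_records(t, samples)}
        expected = {frozenset(m): h for m, h in brute_force_upgma(d)}
        assert set(got) == set(expected)
        for members, h in expected.items():
            assert got[members] == pytest.approx(h, abs=1e-9)


def test_upgma_heights_match_scipy_average_linkage():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(3, 10))
        x = rng.random((n, n))
        d = (x + x.T) / 2.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(
            samples=tuple(f"s{i}" for i in range(n)), d=d,
            compared=np.ones((n, n), dtype=int),
        )
        t = upgma(dm)
        mine = sorted(h for _, h in tree_merge_records(t, dm.samples))
        Z = linkage(squareform(d), method="average")
        theirs = sorted(Z[:, 2] / 2.0)
        assert np.allclose(mine, theirs, atol=1e-9)


def test_upgma_trees_are_ultrametric_and_monotone():
    for seed in range(5):
        m, _ = generate_matrix(FixtureSpec(
            n_samples=15, n_sites=120, region=Region("c", 1, 4000),
            noise=0.05, missing=0.1, seed=seed,
        ))
        t = upgma(distance_matrix(m))

        def check_monotone(node):
            for child in node.children:
                assert child.height <= node.height + 1e-12
                check_monotone(child)

        check_monotone(t.root)

        # ultrametricity: root-to-leaf branch-length sums all equal
        def depth(node, acc):
            if node.is_leaf:
                yield acc
            else:
                for c in node.children:
                    yield from depth(c, acc + (node.height - c.height))

        total = list(depth(t.root, 0.0))
        assert max(total) - min(total) < 1e-9


def test_upgma_is_deterministic_under_ties():
    d = np.array([
        [0.0, 0.5, 0.5, 0.5],
        [0.5, 0.0, 0.5, 0.5],
        [0.5, 0.5, 0.0, 0.5],
        [0.5, 0.5, 0.5, 0.0],
    ])
    dm = DistanceMatrix(samples=("a", "b", "c", "d"), d=d,
                        compared=np.ones((4, 4), dtype=int))
    t1 = upgma(dm)
    t2 = upgma(dm)
    assert t1.leaf_order() == t2.leaf_order() == ["a", "b", "c", "d"]


# -------------------------------------------------------------- haplogroups

def test_tier1_partition_is_root_children(clean_two_cluster):
    m, truth = clean_two_cluster
    t = upgma(distance_matrix(m))
    part = partition_haplogroups(t, "Ref", tier=1)
    assert len(part.groups) == 2
    root_sets = {frozenset(c.leaf_names()) for c in t.root.children}
    assert set(part.groups) == root_sets
    assert "Ref" in part.reference_group


def test_planted_labels_recovered_at_tier1(clean_two_cluster):
    m, truth = clean_two_cluster
    t = upgma(distance_matrix(m))
    part = partition_haplogroups(t, "Ref", tier=1)
    cluster1 = {s for s in m.samples if truth[s] == 1}
    assert part.reference_group == frozenset(cluster1)


def test_tier2_on_three_leaf_tree():
    d = np.array([
        [0.0, 0.1, 0.4],
        [0.1, 0.0, 0.4],
        [0.4, 0.4, 0.0],
    ])
    dm = DistanceMatrix(samples=("A", "B", "C"), d=d,
                        compared=np.ones((3, 3), dtype=int))
    t = upgma(dm)
    part = partition_haplogroups(t, "A", tier=2)
    # depth-2 subtrees {A},{B}; leaf C sits at depth 1 and forms its own group
    assert set(part.groups) == {frozenset("A"), frozenset("B"),
                                frozenset("C")}


def test_tiers_refine_monotonically(clean_two_cluster):
    m, _ = clean_two_cluster
    t = upgma(distance_matrix(m))
    previous = partition_haplogroups(t, "Ref", tier=1)
    for tier in (2, 3, 4):
        current = partition_haplogroups(t, "Ref", tier=tier)
        union = set().union(*current.groups)
        assert union == set(m.samples)
        for g in current.groups:
            assert any(g <= big for big in previous.groups)
        previous = current


def test_partition_unknown_reference(clean_two_cluster):
    m, _ = clean_two_cluster
    t = upgma(distance_matrix(m))
    with pytest.raises(DataError):
        partition_haplogroups(t, "nobody", tier=1)
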