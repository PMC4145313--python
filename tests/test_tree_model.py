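import dendropy
import numpy as np
import pytest

from commrer import tree_model as tm
from tests.conftest import random_newick


# -- independent oracles ---------------------------------------------------


def brute_force_midpoint_minimax(tree: tm.ReferenceTree) -> float:
    """Minimum over all points on all edges of the max point-to-tip distance.

    For a point at distance x from the proximal end of an edge, the distance
    to tip t is min(d_prox(t) + x, d_dist(t) + L - x); candidate optima are
    the edge endpoints and every pairwise line crossing.
    """
    adj = {v: [] for v in tree.parent}
    for v, p in tree.parent.items():
        if p is not None:
            adj[v].append((p, tree.lengths[v]))
            adj[p].append((v, tree.lengths[v]))
    tips = [v for v in tree.parent if tree.is_tip(v)]

    def dists_from(start):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for w, l in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + l
                    stack.append(w)
        return dist

    best = np.inf
    for child, parent in tree.parent.items():
        if parent is None:
            continue
        L = tree.lengths[child]
        du = dists_from(parent)
        dv = dists_from(child)
        candidates = {0.0, L}
        for t1 in tips:
            for t2 in tips:
                candidates.add((dv[t2] - du[t1] + L) / 2.0)
        for x in candidates:
            x = min(max(x, 0.0), L)
            val = max(min(du[t] + x, dv[t] + L - x) for t in tips)
            best = min(best, val)
    return best


def path_sum_root_to_tip(tree: tm.ReferenceTree) -> dict:
    """Per-tip path sums by explicit parent walking (independent traversal)."""
    out = {}
    for v, label in tree.labels.items():
        total = 0.0
        node = v
        while tree.parent[node] is not None:
            total += tree.lengths[node]
            node = tree.parent[node]
        out[label] = total
    return out


# -- read/write ------------------------------------------------------------


def test_read_newick_trivial():
    t = tm.read_newick("((A:1,B:2):1,C:3);")
    assert t.n_tips == 3
    assert len(t.parent) - 1 == 4  # 4 edges
    assert sorted(t.lengths[v] for v in t.parent if v != t.root) == [1, 1, 2, 3]


def test_read_newick_single_tip():
    t = tm.read_newick("(A:1);")
    assert t.n_tips == 1
    assert len(t.parent) - 1 == 1


def test_read_newick_rejects_malformed():
    with pytest.raises(tm.TreeError, match="malformed"):
        tm.read_newick("((A:1,B:2;")


def test_read_newick_rejects_missing_length():
    with pytest.raises(tm.TreeError, match="branch length"):
        tm.read_newick("((A:1,B):1,C:3);")


def test_edge_numbers_from_jplace_annotations():
    t = tm.read_newick("((A:1{0},B:2{1}):1{2},C:3{3});")
    nums = t.edge_by_number()
    assert set(nums) == {0, 1, 2, 3}
    assert t.labels[nums[0]] == "A"
    assert t.labels[nums[3]] == "C"


def test_partial_edge_numbers_rejected():
    with pytest.raises(tm.TreeError, match="partial edge numbering"):
        tm.read_newick("((A:1{0},B:2):1,C:3);")


def test_roundtrip_against_independent_parser(rng):
    """write(read(t)) preserves topology and lengths; checked with dendropy
    as the second parser via weighted Robinson-Foulds distance."""
    for _ in range(100):
        n = int(rng.integers(3, 15))
        original = random_newick(rng, n)
        ours = tm.write_newick(tm.read_newick(original))
        taxa = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=original, schema="newick", taxon_namespace=taxa)
        t2 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=taxa)
        assert dendropy.calculate.treecompare.weighted_robinson_foulds_distance(
            t1, t2
        ) < 1e-12


# -- midpoint rooting ------------------------------------------------------


def test_midpoint_example_root_at_existing_node():
    t = tm.midpoint_root(tm.read_newick("((A:1,B:2):1,C:3);"))
    lengths = tm.root_to_tip_lengths(t)
    assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 3.0})


def test_midpoint_idempotent():
    t = tm.midpoint_root(tm.read_newick("((A:1,B:2):1,C:3);"))
    again = tm.midpoint_root(t)
    assert tm.root_to_tip_lengths(again) == pytest.approx(tm.root_to_tip_lengths(t))
    assert again.total_length() == pytest.approx(t.total_length())


@pytest.mark.parametrize("seed", range(25))
def test_midpoint_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    t = tm.read_newick(random_newick(rng, int(rng.integers(3, 13))))
    rooted = tm.midpoint_root(t)
    depths = tm.root_to_tip_lengths(rooted)
    achieved = max(depths.values())
    assert achieved == pytest.approx(brute_force_midpoint_minimax(t), abs=1e-9)
    # the two deepest tips are equidistant from the root
    top_two = sorted(depths.values())[-2:]
    assert top_two[0] == pytest.approx(top_two[1], abs=1e-9)
    assert rooted.total_length() == pytest.approx(t.total_length(), abs=1e-9)


def test_midpoint_zero_length_tree_warns():
    with pytest.warns(UserWarning, match="zero"):
        t = tm.midpoint_root(tm.read_newick("((A:0,B:0):0,C:0);"))
    assert t.rooted


def test_midpoint_requires_two_tips():
    with pytest.raises(tm.TreeError):
        tm.midpoint_root(tm.read_newick("(A:1);"))


# -- root-to-tip and medians -----------------------------------------------


def test_root_to_tip_star_tree():
    t = tm.read_newick("(A:1,B:1,C:1,D:1);")
    t.rooted = True  # treat the hub as an explicit root
    assert all(v == 1.0 for v in tm.root_to_tip_lengths(t).values())


def test_root_to_tip_requires_rooted():
    t = tm.read_newick("(A:1,B:1,C:1,D:1);")
    assert not t.rooted
    with pytest.raises(tm.TreeError, match="root"):
        tm.root_to_tip_lengths(t)


def test_root_to_tip_matches_path_oracle(rng):
    for _ in range(20):
        t = tm.midpoint_root(
            tm.read_newick(random_newick(rng, int(rng.integers(3, 12))))
        )
        assert tm.root_to_tip_lengths(t) == pytest.approx(path_sum_root_to_tip(t))


def test_phylum_medians_odd_and_even():
    t = tm.read_newick("(((A:1.0,B:1.2):0,C:1.4):0,(D:1.0,E:2.0):0);")
    t.rooted = True
    taxonomy = {"A": "X", "B": "X", "C": "X", "D": "Y", "E": "Y"}
    med = tm.phylum_reference_medians(t, taxonomy)
    assert med == pytest.approx({"X": 1.2, "Y": 1.5})


def test_phylum_medians_sort_oracle(rng):
    lengths = rng.uniform(0.1, 3.0, size=9)
    newick = "(" + ",".join(f"t{i}:{l:.10g}" for i, l in enumerate(lengths)) + ");"
    t = tm.read_newick(newick)
    t.rooted = True
    med = tm.phylum_reference_medians(t, {f"t{i}": "P" for i in range(9)})
    s = sorted(lengths)
    assert med["P"] == pytest.approx(s[len(s) // 2])


def test_phylum_medians_require_complete_taxonomy(small_tree):
    with pytest.raises(tm.TreeError, match="missing"):
        tm.phylum_reference_medians(tm.midpoint_root(small_tree), {"A": "X"})


def test_unplaced_phylum_warns(small_tree):
    rooted = tm.midpoint_root(small_tree)
    taxonomy = {"A": "X", "B": "X", "C": "X", "ghost": "Z"}
    with pytest.warns(UserWarning, match="no tips"):
        med = tm.phylum_reference_medians(rooted, taxonomy)
    assert "Z" not in med


# -- invariants ------------------------------------------------------------


def test_uniform_scaling_property(rng):
    base = random_newick(rng, 8)
    t = tm.midpoint_root(tm.read_newick(base))
    c = 3.7
    scaled = tm.read_newick(base)
    for v in scaled.lengths:
        scaled.lengths[v] *= c
    ts = tm.midpoint_root(scaled)
    taxonomy = {f"t{i}": "P" for i in range(8)}
    assert tm.phylum_reference_medians(ts, taxonomy)["P"] == pytest.approx(
        c * tm.phylum_reference_medians(t, taxonomy)["P"]
    )
    a, b = tm.root_to_tip_lengths(t), tm.root_to_tip_lengths(ts)
    for tip in a:
        assert b[tip] == pytest.approx(c * a[tip])


def test_taxonomy_tsv_parsing(tmp_path):
    p = tmp_path / "tax.tsv"
    p.write_text("taxon_id\tphylum\nA\tX\nB\tY\n")
    assert tm.read_taxonomy(str(p)) == {"A": "X", "B": "Y"}
    assert tm.read_taxonomy("taxon_id\tphylum\nA\tX\n") == {"A": "X"}
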