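import dendropy
import numpy as np
import pytest

from mitocomp.phylo import concatenate, jc_distance_matrix, make_model, nj_tree
from mitocomp.simulate import clock_tree, sim_alignment_on_tree
from mitocomp.timetree import Calibration, relative_heights, reltime_scale


def test_linear_scaling_of_ultrametric_input():
    # ultrametric tree with root height 1.0; calibrating the root at 48.5 Ma
    # dates the node at relative height 0.5 to 24.25 Ma
    tree = dendropy.Tree.get(
        data="((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5);", schema="newick")
    tt = reltime_scale(tree, Calibration(taxa=("a", "b", "c", "d"),
                                         lo=44.0, hi=80.0, point=48.5))
    assert tt.tree.seed_node.age == pytest.approx(48.5)
    assert tt.age_of(["a", "b"]) == pytest.approx(24.25)
    assert tt.age_of(["c", "d"]) == pytest.approx(24.25)


def test_calibration_midpoint_default():
    cal = Calibration(taxa=("a", "b"), lo=44.0, hi=80.0)
    assert cal.age == pytest.approx(62.0)


def test_calibration_point_outside_interval_rejected():
    with pytest.raises(ValueError):
        Calibration(taxa=("a", "b"), lo=44.0, hi=80.0, point=100.0).age


def test_calibration_on_leaf_rejected():
    tree = dendropy.Tree.get(data="((a:1,b:1):1,c:2);", schema="newick")
    with pytest.raises(ValueError, match="internal"):
        reltime_scale(tree, Calibration(taxa=("a",), lo=1, hi=2))


@pytest.mark.parametrize("seed", range(6))
def test_strict_clock_age_recovery_within_5_percent(seed):
    tree, truth = clock_tree(7, seed=seed, join_scale=15.0)
    names = [f"t{i}" for i in range(7)]
    tt = reltime_scale(tree, Calibration(
        taxa=tuple(names), lo=truth["root_age"] * 0.5,
        hi=truth["root_age"] * 1.5, point=truth["root_age"]))
    for clade, true_age in truth["ages"].items():
        assert tt.age_of(list(clade)) == pytest.approx(true_age, rel=0.05)
    assert tt.max_ultrametric_deviation() < 1e-9 * max(1.0, truth["root_age"])


def test_output_ultrametric_even_on_nonclock_input():
    tree = dendropy.Tree.get(
        data="((a:0.9,b:0.1):0.3,(c:0.4,d:0.35):0.2);", schema="newick")
    tt = reltime_scale(tree, Calibration(taxa=("a", "b", "c", "d"),
                                         lo=10, hi=20))
    assert tt.max_ultrametric_deviation() < 1e-9 * tt.tree.seed_node.age
    assert 10 <= tt.tree.seed_node.age <= 20
    for leaf, age in tt.leaf_ages().items():
        assert age == pytest.approx(0.0, abs=1e-12)


def test_two_rate_tree_beats_naive_scaling():
    """With one subtree evolving 2x faster, relative-rate reconciliation
    recovers ages better than treating branch lengths as clock-like."""

    def naive_ages(tree, cal_taxa, cal_age):
        # node age = arithmetic mean root-to-tip path below it, scaled
        heights = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                heights[node] = 0.0
            else:
                vals = [heights[c] + (c.edge.length or 0) for c in node.child_nodes()]
                heights[node] = sum(vals) / len(vals)
        root_h = heights[tree.seed_node]
        out = {}
        for node in tree.postorder_node_iter():
            if not node.is_leaf():
                clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
                out[clade] = heights[node] * cal_age / root_h
        return out

    rng_err = {"reltime": [], "naive": []}
    for seed in range(20):
        tree, truth = clock_tree(8, seed=seed, join_scale=10.0)
        # double the rate in the subtree under the root's first child
        first = tree.seed_node.child_nodes()[0]
        for node in first.preorder_iter():
            if node.edge.length is not None:
                node.edge.length *= 2.0
        names = tuple(f"t{i}" for i in range(8))
        cal = Calibration(taxa=names, lo=truth["root_age"] * 0.5,
                          hi=truth["root_age"] * 2.0, point=truth["root_age"])
        tt = reltime_scale(tree, cal)
        naive = naive_ages(tree, names, truth["root_age"])
        for clade, true_age in truth["ages"].items():
            if len(clade) == 8:
                continue
            rng_err["reltime"].append((tt.age_of(list(clade)) - true_age) ** 2)
            rng_err["naive"].append((naive[clade] - true_age) ** 2)
    rmse = {k: np.sqrt(np.mean(v)) for k, v in rng_err.items()}
    assert rmse["reltime"] < rmse["naive"]


def test_relative_heights_of_clock_tree_are_exact():
    tree, truth = clock_tree(6, seed=4)
    H = relative_heights(tree)
    assert H[tree.seed_node] == pytest.approx(truth["root_age"])


def test_sequence_pipeline_yields_calibrated_ultrametric_tree():
    # full pipeline: clock simulation (500 sites) -> JC distances -> NJ ->
    # outgroup rooting -> dating; the output must be ultrametric with the
    # calibrated node fixed at its calibration age
    tree, truth = clock_tree(6, seed=13, join_scale=0.06)
    root = tree.seed_node
    og = dendropy.Node(taxon=tree.taxon_namespace.new_taxon("outgroup"))
    og.edge.length = truth["root_age"] * 2
    newroot = dendropy.Node()
    newroot.add_child(root)
    root.edge.length = truth["root_age"]
    newroot.add_child(og)
    tree.seed_node = newroot
    aln = sim_alignment_on_tree(tree, make_model("JC69"), 500, seed=14)
    sm = concatenate({"g": aln})
    nj = nj_tree(jc_distance_matrix(sm), sm.taxa)
    og_leaf = next(lf for lf in nj.leaf_node_iter()
                   if lf.taxon.label == "outgroup")
    nj.reroot_at_edge(og_leaf.edge, update_bipartitions=False)
    nj.prune_taxa_with_labels(["outgroup"])
    ingroup = tuple(f"t{i}" for i in range(6))
    tt = reltime_scale(nj, Calibration(taxa=ingroup, lo=44, hi=80, point=48.5))
    assert tt.age_of(list(ingroup)) == pytest.approx(48.5)
    assert tt.max_ultrametric_deviation() < 1e-9 * 48.5
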