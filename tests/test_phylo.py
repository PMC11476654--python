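import itertools
import math

import dendropy
import numpy as np
import pytest

from mitocomp.phylo import (Supermatrix, bootstrap_support, concatenate,
                            fit_model, is_monophyletic, jc_distance_matrix,
                            log_likelihood, make_model, nj_tree, select_model,
                            tree_splits)
from mitocomp.simulate import random_tree, sim_alignment_on_tree


def _sm(seqs: dict[str, str]) -> Supermatrix:
    return Supermatrix(taxa=list(seqs), sequences=seqs,
                       partitions={"g": (1, len(next(iter(seqs.values()))))})


# ------------------------------ concatenation ------------------------------

def test_concatenate_partitions():
    sm = concatenate({"g1": {"a": "ACGTAC", "b": "ACGTAC"},
                      "g2": {"a": "ACGTACGTA", "b": "ACGTACGTA"}})
    assert sm.n_sites == 15
    assert sm.partitions == {"g1": (1, 6), "g2": (7, 15)}


def test_concatenate_union_gap_fills_with_warning():
    with pytest.warns(UserWarning, match="gap-filled"):
        sm = concatenate({"g1": {"a": "ACG", "b": "ACG"},
                          "g2": {"a": "TTTT"}}, policy="union")
    assert sm.sequences["b"] == "ACG" + "----"


def test_concatenate_thirteen_genes_round_trip():
    rng = np.random.default_rng(0)
    genes = {}
    widths = {}
    for i in range(13):
        w = int(rng.integers(30, 90)) * 3
        widths[f"gene{i:02d}"] = w
        genes[f"gene{i:02d}"] = {
            t: "".join(rng.choice(list("ACGT"), size=w)) for t in ("a", "b", "c")}
    sm = concatenate(genes)
    pos = 1
    for g, w in widths.items():
        assert sm.partitions[g] == (pos, pos + w - 1)
        pos += w


def test_unequal_gene_widths_rejected():
    with pytest.raises(ValueError, match="unequal"):
        concatenate({"g": {"a": "ACG", "b": "ACGT"}})


# --------------------------------- NJ ---------------------------------------

def test_nj_three_taxa_closed_form():
    D = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
    tree = nj_tree(D, ["a", "b", "c"])
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx(0.1)
    assert lengths["b"] == pytest.approx(0.2)
    assert lengths["c"] == pytest.approx(0.3)


def test_nj_recovers_additive_four_taxon_tree():
    # ((a:1,b:2):1,(c:3,d:4)) with internal branch 1
    D = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0]], dtype=float)
    tree = nj_tree(D, ["a", "b", "c", "d"])
    assert frozenset(["c", "d"]) in tree_splits(tree, ["a", "b", "c", "d"])
    # patristic distances reproduce the additive matrix exactly
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    for (i, a), (j, b) in itertools.combinations(enumerate("abcd"), 2):
        assert pdm.patristic_distance(tx[a], tx[b]) == pytest.approx(D[i, j])


@pytest.mark.parametrize("seed", range(10))
def test_nj_recovers_topology_from_additive_matrices(seed):
    n = 4 + seed % 5  # 4..8 taxa
    true = random_tree(n, seed=seed)
    names = [f"t{i}" for i in range(n)]
    pdm = true.phylogenetic_distance_matrix()
    tx = {t.label: t for t in true.taxon_namespace}
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(tx[names[i]], tx[names[j]])
        D[i, j] = D[j, i] = d
    est = nj_tree(D, names)
    assert tree_splits(est, names) == tree_splits(true, names)


def test_nj_too_few_taxa():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])


# ------------------------------ likelihood ----------------------------------

def test_two_sequence_jc_closed_form():
    # per-site likelihood of a match under JC69 at distance d:
    # (1/16) (1 + 3 e^{-4d/3}); of a mismatch: (1/16)(1 - e^{-4d/3})
    seqs = {"a": "ACGTACGTAC", "b": "ACGTACGTTC"}  # 9 matches, 1 mismatch
    sm = _sm(seqs)
    tree = dendropy.Tree.get(data="(a:0.07,b:0.03);", schema="newick")
    model = make_model("JC69")
    d = 0.1
    e = math.exp(-4 * d / 3)
    expected = 9 * math.log((1 + 3 * e) / 16) + math.log((1 - e) / 16)
    assert log_likelihood(tree, sm, model) == pytest.approx(expected, abs=1e-10)


def test_zero_distance_identical_sequences():
    seqs = {"a": "ACGT" * 5, "b": "ACGT" * 5}
    sm = _sm(seqs)
    tree = dendropy.Tree.get(data="(a:0.0,b:0.0);", schema="newick")
    assert log_likelihood(tree, sm, make_model("JC69")) == \
        pytest.approx(20 * math.log(0.25))


def _bruteforce_loglik(tree, sm, model):
    """Exhaustive sum over internal-state assignments (<= 4 taxa, few sites)."""
    pi = model.freqs
    eigen = model.eigen()
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    n_sites = sm.n_sites
    for site in range(n_sites):
        site_lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            states = {n: s for n, s in zip(internals, assign)}
            for n in nodes:
                if n.is_leaf():
                    states[n] = enc[sm.sequences[n.taxon.label][site]]
            prob = pi[states[tree.seed_node]]
            for n in nodes:
                if n is tree.seed_node:
                    continue
                P = model.transition_matrix(n.edge.length or 0.0, eigen)
                prob *= P[states[n.parent_node], states[n]]
            site_lik += prob
        total += math.log(site_lik)
    return total


@pytest.mark.parametrize("spec", ["JC69", "K2P", "GTR"])
def test_pruning_matches_bruteforce_state_sum(spec):
    rng = np.random.default_rng(3)
    tree = dendropy.Tree.get(
        data="((a:0.1,b:0.25):0.12,(c:0.3,d:0.05):0.2);", schema="newick")
    seqs = {t: "".join(rng.choice(list("ACGT"), size=8)) for t in "abcd"}
    sm = _sm(seqs)
    model = make_model(spec, freqs=np.array([0.3, 0.2, 0.15, 0.35]),
                       exch=np.array([1.2, 3.0, 0.8, 1.1, 4.0, 1.0]))
    assert log_likelihood(tree, sm, model) == \
        pytest.approx(_bruteforce_loglik(tree, sm, model), abs=1e-9)


def test_gamma_limit_recovers_no_gamma():
    rng = np.random.default_rng(4)
    tree = dendropy.Tree.get(data="((a:0.1,b:0.2):0.1,(c:0.15,d:0.1):0.1);",
                             schema="newick")
    seqs = {t: "".join(rng.choice(list("ACGT"), size=200)) for t in "abcd"}
    sm = _sm(seqs)
    plain = log_likelihood(tree, sm, make_model("JC69"))
    big_alpha = make_model("JC69+G", alpha=1e6)
    assert abs(log_likelihood(tree, sm, big_alpha) - plain) < 1e-4


def test_gamma_category_rates_mean_one():
    m = make_model("GTR+G", alpha=0.7)
    rates = m.category_rates()
    assert len(rates) == 4
    assert rates.mean() == pytest.approx(1.0)
    assert (np.diff(rates) > 0).all()


# --------------------------- model selection --------------------------------

@pytest.fixture(scope="module")
def jc_data():
    tree = random_tree(5, seed=11)
    aln = sim_alignment_on_tree(tree, make_model("JC69"), 600, seed=12)
    return concatenate({"g": aln})


def test_gtr_nests_jc(jc_data):
    tree = nj_tree(jc_distance_matrix(jc_data), jc_data.taxa)
    jc = fit_model(tree, jc_data, "JC69")
    gtr = fit_model(tree, jc_data, "GTR")
    assert gtr.lnL >= jc.lnL - 1e-6


def test_parameter_count_audit(jc_data):
    tree = nj_tree(jc_distance_matrix(jc_data), jc_data.taxa)
    fit = fit_model(tree, jc_data, "GTR+G+I", rounds=1)
    n_taxa = len(jc_data.taxa)
    assert fit.k == (2 * n_taxa - 3) + 8 + 1 + 1
    assert fit.bic == pytest.approx(-2 * fit.lnL + fit.k * math.log(fit.n))


def test_jc_data_selects_simple_model(jc_data):
    fits = select_model(jc_data, candidates=("JC69", "K2P", "HKY85", "GTR"))
    assert fits[0].model == "JC69"
    assert fits[0].bic <= fits[-1].bic


# ------------------------------ bootstrap -----------------------------------

def test_bootstrap_single_replicate_supports_binary():
    tree = random_tree(5, seed=2)
    aln = sim_alignment_on_tree(tree, make_model("JC69"), 300, seed=3)
    sm = concatenate({"g": aln})
    _, supports = bootstrap_support(sm, B=1, seed=9)
    assert set(supports.values()) <= {0.0, 100.0}


def test_bootstrap_strong_signal_high_support():
    tree = random_tree(6, seed=8, bl_low=0.2, bl_high=0.5)
    aln = sim_alignment_on_tree(tree, make_model("JC69"), 2000, seed=9)
    sm = concatenate({"g": aln})
    _, supports = bootstrap_support(sm, B=100, seed=10)
    true_splits = tree_splits(tree, sm.taxa)
    for split, support in supports.items():
        if split in true_splits:
            assert support >= 95.0


def test_bootstrap_deterministic_given_seed():
    tree = random_tree(5, seed=5)
    aln = sim_alignment_on_tree(tree, make_model("JC69"), 200, seed=6)
    sm = concatenate({"g": aln})
    _, s1 = bootstrap_support(sm, B=20, seed=42)
    _, s2 = bootstrap_support(sm, B=20, seed=42)
    assert s1 == s2


# ------------------------------ monophyly -----------------------------------

def test_monophyly_queries_on_planted_topology():
    # mirrors the family/subfamily clade structure of a Spariformes-style tree
    newick = ("((((Latl,Llat,Lobs)lethrininae,(Mgra,Gaur)monotaxinae)lethrinidae,"
              "(Nem1,Nem2)nemipteridae),((Spar1,Spar2,Smae)sparidae,Outg));")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    assert is_monophyletic(tree, {"Latl", "Llat", "Lobs"}, rooted=True)
    assert is_monophyletic(tree, {"Mgra", "Gaur"}, rooted=True)
    assert is_monophyletic(tree, {"Spar1", "Spar2", "Smae"}, rooted=True)
    assert not is_monophyletic(tree, {"Latl", "Mgra"}, rooted=True)
    # unrooted split query: Lethrinidae + Nemipteridae vs the rest
    assert is_monophyletic(
        tree, {"Latl", "Llat", "Lobs", "Mgra", "Gaur", "Nem1", "Nem2"})
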