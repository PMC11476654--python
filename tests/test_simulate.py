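import math

import pytest

from mitocomp.annotation import scan_spacers_overlaps
from mitocomp.composition import base_composition
from mitocomp.genome import extract_feature_sequence
from mitocomp.kaks import kaks_pair
from mitocomp.phylo import make_model, p_distance_matrix, concatenate
from mitocomp.simulate import (EvolveSpec, MitoSpec, default_mitospec,
                               evolve_codon_pair, gen_mitogenome, random_tree,
                               sim_alignment_on_tree)
from mitocomp.trna import fold_cloverleaf


def test_default_spec_round_trips_gap_accounting(synthetic_genome):
    _, table = synthetic_genome
    _, summary = scan_spacers_overlaps(table)
    assert (summary.n_spacers, summary.spacer_bp) == (11, 76)
    assert (summary.n_overlaps, summary.overlap_bp) == (5, 14)


def test_planted_nd4l_nd4_overlap_shares_sequence(synthetic_genome):
    genome, table = synthetic_genome
    nd4l = extract_feature_sequence(genome, table.get("ND4L"))
    nd4 = extract_feature_sequence(genome, table.get("ND4"))
    assert nd4l[-7:] == nd4[:7]  # both on the heavy strand


def test_symmetric_composition_gives_small_skews():
    spec = default_mitospec(
        seed=3, composition={"A": 26.5, "T": 26.5, "G": 23.5, "C": 23.5})
    genome, _ = gen_mitogenome(spec)
    st = base_composition(genome.sequence)
    assert abs(st.at_skew) < 0.02
    assert abs(st.gc_skew) < 0.02


def test_composition_within_one_percent_of_target(synthetic_genome):
    genome, _ = synthetic_genome
    st = base_composition(genome.sequence)
    targets = {"A": 27.20, "T": 25.90, "G": 17.02, "C": 29.88}
    for b, want in targets.items():
        assert st.pct(b) == pytest.approx(want, abs=1.0)


def test_generator_deterministic():
    a, _ = gen_mitogenome(default_mitospec(seed=7))
    b, _ = gen_mitogenome(default_mitospec(seed=7))
    c, _ = gen_mitogenome(default_mitospec(seed=8))
    assert a.sequence == b.sequence
    assert a.sequence != c.sequence


def test_closure_violation_rejected():
    spec = default_mitospec(seed=0)
    with pytest.raises(ValueError, match="closure"):
        MitoSpec(genome_length=spec.genome_length + 5, genes=spec.genes)


def test_planted_anticodons_recovered_by_unconstrained_folding(synthetic_genome):
    genome, table = synthetic_genome
    for f in table.by_class("tRNA"):
        st = fold_cloverleaf(extract_feature_sequence(genome, f))
        assert st.anticodon == f.anticodon, f.name


def test_evolve_zero_time_identical():
    pair = evolve_codon_pair(EvolveSpec(n_codons=50, omega=1.0, t=0.0, seed=1))
    assert pair.ancestor == pair.derived
    assert pair.n_syn == pair.n_nonsyn == 0


def test_evolve_never_creates_stops():
    from mitocomp.genetic_code import is_stop
    pair = evolve_codon_pair(EvolveSpec(n_codons=200, omega=2.0, t=2.0, seed=3))
    for seq in (pair.ancestor, pair.derived):
        assert not any(is_stop(seq[i:i + 3]) for i in range(0, len(seq), 3))


def test_omega_extremes_shift_substitution_mix():
    lo = evolve_codon_pair(EvolveSpec(n_codons=500, omega=0.05, t=1.0, seed=5))
    hi = evolve_codon_pair(EvolveSpec(n_codons=500, omega=5.0, t=1.0, seed=5))
    assert lo.n_nonsyn / max(lo.n_syn, 1) < hi.n_nonsyn / max(hi.n_syn, 1)


def test_purifying_selection_estimates_below_one():
    below = 0
    for seed in range(30):
        pair = evolve_codon_pair(EvolveSpec(n_codons=300, omega=0.1, t=1.0,
                                            seed=seed))
        r = kaks_pair(pair.ancestor, pair.derived)
        below += (not math.isnan(r.ratio)) and r.ratio < 1.0
    assert below >= 29  # >= 95% of replicates


def test_zero_length_star_tree_identical_sequences():
    import dendropy
    tree = dendropy.Tree.get(data="(a:0,b:0,c:0);", schema="newick")
    aln = sim_alignment_on_tree(tree, make_model("JC69"), 100, seed=4)
    assert len(set(aln.values())) == 1


def test_jc_p_distance_matches_expectation():
    # E[p] = 3/4 (1 - e^{-4d/3}); check within 3 sigma at 20 kb
    import dendropy
    d = 0.2
    tree = dendropy.Tree.get(data=f"(a:{d / 2},b:{d / 2});", schema="newick")
    sites = 20000
    aln = sim_alignment_on_tree(tree, make_model("JC69"), sites, seed=6)
    sm = concatenate({"g": aln})
    p = p_distance_matrix(sm)[0, 1]
    expect = 0.75 * (1 - math.exp(-4 * d / 3))
    sigma = math.sqrt(expect * (1 - expect) / sites)
    assert abs(p - expect) < 3 * sigma


def test_simulation_deterministic_given_seed():
    tree = random_tree(5, seed=1)
    a = sim_alignment_on_tree(tree, make_model("GTR+G"), 200, seed=9)
    b = sim_alignment_on_tree(tree, make_model("GTR+G"), 200, seed=9)
    assert a == b


def test_gamma_rate_variation_increases_pattern_dispersion():
    # +G with small alpha concentrates changes on few sites: more invariant
    # columns than the equal-rates simulation at the same depth
    tree = random_tree(6, seed=2, bl_low=0.1, bl_high=0.3)
    plain = sim_alignment_on_tree(tree, make_model("JC69"), 2000, seed=11)
    gamma = sim_alignment_on_tree(tree, make_model("JC69+G", alpha=0.2), 2000,
                                  seed=11)

    def n_constant(aln):
        rows = list(aln.values())
        return sum(1 for j in range(len(rows[0]))
                   if len({r[j] for r in rows}) == 1)

    assert n_constant(gamma) > n_constant(plain)
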