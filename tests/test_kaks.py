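"""Nei-Gojobori Ka/Ks against an independent brute-force oracle.

The oracle below enumerates every mutational pathway explicitly and uses
Biopython's translation of the vertebrate mito code directly, sharing no code
with the implementation under test.
"""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from mitocomp.genetic_code import sense_codons
from mitocomp.kaks import (KaKsResult, jukes_cantor, kaks_pair, ng86_sites,
                           rank_genes)
from mitocomp.simulate import EvolveSpec, evolve_codon_pair

# --------------------------- brute-force oracle ----------------------------

def _aa(codon):
    return str(Seq(codon).translate(table=2))  # '*' for stops


def oracle_sites(codon):
    s = 0.0
    for pos in range(3):
        neighbors = [codon[:pos] + b + codon[pos + 1:]
                     for b in "ACGT" if b != codon[pos]]
        non_stop = [n for n in neighbors if _aa(n) != "*"]
        if non_stop:
            s += sum(1 for n in non_stop if _aa(n) == _aa(codon)) / len(non_stop)
    return s, 3.0 - s


def oracle_differences(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths, blocked = [], []
    for order in itertools.permutations(diff):
        sd = nd = 0.0
        cur, ok = c1, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == "*":
                ok = False
            if _aa(nxt) == _aa(cur) and _aa(nxt) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        (paths if ok else blocked).append((sd, nd))
    use = paths or blocked
    return (sum(p[0] for p in use) / len(use), sum(p[1] for p in use) / len(use))


def oracle_pair(seq1, seq2):
    S1 = S2 = N1 = N2 = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if _aa(c1) == "*" or _aa(c2) == "*":
            continue
        a, b = oracle_sites(c1)
        c, d = oracle_sites(c2)
        S1 += a; N1 += b; S2 += c; N2 += d
        sd, nd = oracle_differences(c1, c2)
        Sd += sd; Nd += nd
    S, N = (S1 + S2) / 2, (N1 + N2) / 2
    pS, pN = Sd / S, Nd / N
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else math.nan
    return S, N, Sd, Nd, jc(pS), jc(pN)


# ------------------------------- unit tests --------------------------------

def test_phe_codon_site_decomposition():
    # TTT: only TTC among the nine neighbors is synonymous
    s, n = ng86_sites("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


@pytest.mark.parametrize("codon", sense_codons())
def test_sites_sum_to_three_and_match_oracle(codon):
    s, n = ng86_sites(codon)
    assert s + n == pytest.approx(3.0)
    es, en = oracle_sites(codon)
    assert s == pytest.approx(es)


def test_fourfold_family_synonymous_sites():
    s, _ = ng86_sites("GGA")  # Gly: fourfold-degenerate third position
    assert s >= 1.0


def test_stop_codon_sites_rejected():
    with pytest.raises(ValueError):
        ng86_sites("TAA")


def test_identical_sequences_ratio_undefined():
    r = kaks_pair("ATGGCT" * 10, "ATGGCT" * 10)
    assert r.Ka == r.Ks == 0.0
    assert math.isnan(r.ratio)


def test_single_synonymous_difference():
    seq1 = "TTT" * 100
    seq2 = "TTT" * 99 + "TTC"
    r = kaks_pair(seq1, seq2)
    assert r.Sd == pytest.approx(1.0)
    assert r.Nd == pytest.approx(0.0)
    assert r.Ka == 0.0
    assert r.Ks == pytest.approx(jukes_cantor(1.0 / r.S))


def test_pairwise_symmetry():
    rng = np.random.default_rng(7)
    codons = sense_codons()
    a = "".join(rng.choice(codons, size=40))
    b = "".join(rng.choice(codons, size=40))
    ra, rb = kaks_pair(a, b), kaks_pair(b, a)
    assert ra.S == pytest.approx(rb.S)
    assert ra.Sd == pytest.approx(rb.Sd)
    assert ra.Nd == pytest.approx(rb.Nd)


def test_gapped_codons_skipped_pairwise():
    r = kaks_pair("ATG---GCT", "ATGAAAGCT")
    assert r.codons_compared == 2


@pytest.mark.parametrize("seed", range(8))
def test_matches_bruteforce_oracle_on_random_alignments(seed):
    rng = np.random.default_rng(seed)
    codons = sense_codons()
    n = int(rng.integers(5, 30))
    anc = rng.choice(codons, size=n)
    der = anc.copy()
    # mutate a few codons, multi-nucleotide changes included
    for i in rng.choice(n, size=max(1, n // 3), replace=False):
        der[i] = rng.choice(codons)
    s1, s2 = "".join(anc), "".join(der)
    got = kaks_pair(s1, s2)
    S, N, Sd, Nd, Ks, Ka = oracle_pair(s1, s2)
    assert got.S == pytest.approx(S, abs=1e-9)
    assert got.N == pytest.approx(N, abs=1e-9)
    assert got.Sd == pytest.approx(Sd, abs=1e-9)
    assert got.Nd == pytest.approx(Nd, abs=1e-9)
    if not math.isnan(Ks):
        assert got.Ks == pytest.approx(Ks, abs=1e-9)


def test_saturated_proportion_is_nan():
    with pytest.warns(UserWarning, match="undefined"):
        assert math.isnan(jukes_cantor(0.8))


def test_rank_genes_ascending_with_alphabetical_ties():
    mk = lambda g, r: KaKsResult(g, 1, 2, 0, 0, 0, 0, 1, r, r)
    assert rank_genes([mk("A", 0.2), mk("B", 0.1)]) == ["B", "A"]
    assert rank_genes([mk("z", 0.3), mk("m", 0.3), mk("a", 0.3)]) == ["a", "m", "z"]


def test_rank_recovers_planted_ordering():
    # genes evolved at increasing omega rank in that order
    omegas = {"g1": 0.05, "g2": 0.3, "g3": 0.9}
    results = []
    for i, (gene, w) in enumerate(omegas.items()):
        pair = evolve_codon_pair(EvolveSpec(n_codons=400, omega=w, t=1.0, seed=i))
        results.append(kaks_pair(pair.ancestor, pair.derived, gene=gene))
    assert rank_genes(results) == ["g1", "g2", "g3"]
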