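"""Pairwise Ka/Ks under the Nei-Gojobori (1986) counting method.

Synonymous (S) and nonsynonymous (N) *sites* are counted per codon by
enumerating all nine single-nucleotide neighbours: at each position the
synonymous fraction is taken over the non-stop neighbours, so every codon
contributes exactly 3 sites. *Differences* between a codon pair with k
mismatches are averaged over all k! orderings of the single steps, excluding
pathways that pass through a stop codon (all pathways are used if every one
is blocked). Proportions pS = Sd/S and pN = Nd/N are corrected for multiple
hits with the Jukes-Cantor formula d = -3/4 ln(1 - 4p/3).

Ka/Ks < 1 indicates purifying (negative) selection; the ratio is undefined
(NaN) when Ks == 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

from .genetic_code import BASES, is_stop, translate

_AMBIGUOUS = set("RYSWKMBDHVN-")


@dataclass(frozen=True)
class KaKsResult:
    gene: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float  # NaN when Ks == 0 or either distance undefined

    @property
    def codons_compared(self) -> int:
        return round((self.S + self.N) / 3)


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon; sums to 3."""
    codon = codon.upper().replace("U", "T")
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = translate(codon)
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if is_stop(mut):
                continue
            valid += 1
            if translate(mut) == aa:
                syn += 1
        if valid:
            s_sites += syn / valid
    return s_sites, 3.0 - s_sites


def ng86_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences of a codon pair."""
    codon1 = codon1.upper().replace("U", "T")
    codon2 = codon2.upper().replace("U", "T")
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = codon1
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
            if is_stop(nxt):
                return None
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [walk(order) for order in permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:  # every pathway blocked by a stop; fall back to all pathways
        valid = []
        for order in permutations(diff_pos):
            sd = nd = 0.0
            cur = codon1
            for pos in order:
                nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
                if is_stop(nxt) or translate(nxt) != translate(cur):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            valid.append((sd, nd))
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN (with warning) when p >= 3/4."""
    if p >= 0.75:
        warnings.warn(f"proportion {p:.3f} >= 3/4: JC distance undefined",
                      stacklevel=2)
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _usable(codon1: str, codon2: str) -> bool:
    if len(codon1) < 3 or len(codon2) < 3:
        return False
    if _AMBIGUOUS & (set(codon1) | set(codon2)):
        return False
    return not (is_stop(codon1) or is_stop(codon2))


def kaks_pair(seq1: str, seq2: str, gene: str = "") -> KaKsResult:
    """NG86 Ka, Ks and Ka/Ks for a gap-free codon alignment of two sequences.

    Codons containing gaps/ambiguity in either sequence, and stop codons, are
    skipped pairwise. Site totals are averaged over the two sequences.
    """
    seq1 = seq1.upper().replace("U", "T")
    seq2 = seq2.upper().replace("U", "T")
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("alignment length is not a multiple of 3")
    S1 = N1 = S2 = N2 = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if not _usable(c1, c2):
            continue
        s1, n1 = ng86_sites(c1)
        s2, n2 = ng86_sites(c2)
        S1 += s1; N1 += n1; S2 += s2; N2 += n2
        sd, nd = ng86_differences(c1, c2)
        Sd += sd; Nd += nd
    S = (S1 + S2) / 2.0
    N = (N1 + N2) / 2.0
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    Ks = jukes_cantor(pS) if pS == pS else math.nan
    Ka = jukes_cantor(pN) if pN == pN else math.nan
    ratio = Ka / Ks if (Ks == Ks and Ka == Ka and Ks > 0) else math.nan
    return KaKsResult(gene=gene, S=S, N=N, Sd=Sd, Nd=Nd,
                      pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio)


def rank_genes(results: list[KaKsResult]) -> list[str]:
    """Gene names in ascending Ka/Ks order; ties (and NaN) break alphabetically."""
    if len(results) < 2:
        raise ValueError("need at least two genes to rank")
    def key(r: KaKsResult):
        undefined = r.ratio != r.ratio
        return (undefined, r.ratio if not undefined else 0.0, r.gene)
    return [r.gene for r in sorted(results, key=key)]
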