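"""Base composition, A+T content and strand-asymmetry skews.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), the standard
strand-asymmetry statistics for mitogenomes. Counts are exact integers;
percentages and skews are kept at full precision and rounded only when a
report is serialized (skews to 3 dp, percentages to 2 dp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .genome import FeatureTable, MitoGenome, extract_feature_sequence


@dataclass(frozen=True)
class CompositionStats:
    a: int
    t: int
    g: int
    c: int
    length: int  # includes N bases

    @property
    def n_other(self) -> int:
        return self.length - (self.a + self.t + self.g + self.c)

    def pct(self, base: str, acgt_denominator: bool = False) -> float:
        denom = (self.a + self.t + self.g + self.c) if acgt_denominator else self.length
        return 100.0 * getattr(self, base.lower()) / denom

    def pct_at(self, acgt_denominator: bool = False) -> float:
        return self.pct("a", acgt_denominator) + self.pct("t", acgt_denominator)

    @property
    def at_skew(self) -> float:
        """(A-T)/(A+T); NaN when A+T == 0 (undefined, not zero)."""
        if self.a + self.t == 0:
            return math.nan
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float:
        if self.g + self.c == 0:
            return math.nan
        return (self.g - self.c) / (self.g + self.c)

    def __add__(self, other: "CompositionStats") -> "CompositionStats":
        return CompositionStats(self.a + other.a, self.t + other.t,
                                self.g + other.g, self.c + other.c,
                                self.length + other.length)


def base_composition(seq: str) -> CompositionStats:
    """Exact base counts of a sequence. N bases count toward length only."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return CompositionStats(a=s.count("A"), t=s.count("T"),
                            g=s.count("G"), c=s.count("C"), length=len(s))


def skew(x: float, y: float) -> float:
    """(x-y)/(x+y) from two counts or printed percentages; NaN if x+y == 0."""
    if x + y == 0:
        return math.nan
    return (x - y) / (x + y)


def class_composition(genome: MitoGenome, table: FeatureTable, cls: str,
                      dedupe: bool = False) -> CompositionStats:
    """Composition over the concatenated features of one class.

    By default, positions inside gene overlaps are counted once per feature
    (so the PCG total of the reference geometry is 11,425 bp, overlaps
    included, matching how published annotation tables total gene sizes).
    With ``dedupe=True`` the union of reference positions is used instead.
    Each feature is read on its coding strand (ND6 reverse-complemented).
    """
    feats = table.by_class(cls)
    if not feats:
        raise ValueError(f"no features of class {cls!r}")
    if not dedupe:
        total = None
        for f in feats:
            stats = base_composition(extract_feature_sequence(genome, f))
            total = stats if total is None else total + stats
        return total
    L = table.genome_length
    covered: set[int] = set()
    for f in feats:
        stop = f.stop if f.stop >= f.start else f.stop + L
        covered.update((p - 1) % L for p in range(f.start, stop + 1))
    seq = "".join(genome.sequence[i] for i in sorted(covered))
    return base_composition(seq)


def composition_report(sections: dict[str, dict[str, CompositionStats]]) -> pd.DataFrame:
    """Comparative composition table, one section per class, one row per genome.

    Columns follow the conventional layout:
    ``Size(bp) A% T% G% C% A+T% AT-skew GC-skew``.
    """
    rows = []
    for section, per_genome in sections.items():
        for genome_id, st in per_genome.items():
            rows.append({
                "Section": section, "Genome": genome_id, "Size(bp)": st.length,
                "A%": round(st.pct("a"), 2), "T%": round(st.pct("t"), 2),
                "G%": round(st.pct("g"), 2), "C%": round(st.pct("c"), 2),
                "A+T%": round(st.pct_at(), 2),
                "AT-skew": round(st.at_skew, 3), "GC-skew": round(st.gc_skew, 3),
            })
    return pd.DataFrame(rows)
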