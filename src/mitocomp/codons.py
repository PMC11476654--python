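"""Codon usage statistics over protein-coding genes.

Counts in-frame sense codons across a set of CDSs and derives:

* RSCU (relative synonymous codon usage): observed count of a codon divided
  by the mean count of its synonymous family; 1 means no bias within the
  family, and the family-wise RSCU values sum to the family size.
* CDspT (codon distribution per thousand codons): 1000 * n_c / total, also
  aggregated per amino acid.

Terminal complete stop codons and trailing incomplete codons (1-2 nt left
by the incomplete T--/TA- stops) are excluded: they are not translated
codons. The initiator is counted as written (a GTG start stays GTG).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import is_stop, sense_codons, synonymous_families, translate


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    total_codons: int = field(init=False)

    def __post_init__(self):
        self.total_codons = sum(self.counts.values())

    @property
    def rscu(self) -> dict[str, float]:
        return rscu(self.counts)

    @property
    def per_thousand(self) -> dict[str, float]:
        return cdspt(self.counts)

    @property
    def aa_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for codon, n in self.counts.items():
            aa = translate(codon)
            totals[aa] = totals.get(aa, 0) + n
        return totals

    def aa_per_thousand(self) -> dict[str, float]:
        return {aa: 1000.0 * n / self.total_codons
                for aa, n in self.aa_totals.items()}

    def to_frame(self) -> pd.DataFrame:
        rs, pt = self.rscu, self.per_thousand
        rows = [{"codon": c, "aa": translate(c), "count": self.counts[c],
                 "rscu": rs[c], "per_thousand": pt[c]}
                for c in sense_codons()]
        return pd.DataFrame(rows)


def count_codons(cds_list: list[str]) -> CodonUsageTable:
    """Count sense codons over CDSs read in frame from position 1.

    Trailing incomplete codons are dropped; a terminal complete stop codon is
    excluded. Internal in-frame stop codons trigger a warning (they suggest a
    frame or annotation problem) and are not counted.
    """
    counts: Counter[str] = Counter({c: 0 for c in sense_codons()})
    for idx, cds in enumerate(cds_list):
        s = cds.upper().replace("U", "T")
        n_full = len(s) // 3
        codons = [s[3 * i:3 * i + 3] for i in range(n_full)]
        if codons and is_stop(codons[-1]):
            codons = codons[:-1]
        for pos, codon in enumerate(codons):
            if any(b not in "ACGT" for b in codon):
                continue
            if is_stop(codon):
                warnings.warn(
                    f"internal stop codon {codon} at codon {pos + 1} of CDS "
                    f"#{idx + 1}", stacklevel=2)
                continue
            counts[codon] += 1
    return CodonUsageTable(counts=dict(counts))


def rscu(counts: dict[str, int]) -> dict[str, float]:
    """RSCU(c) = n_c * k / sum over the synonymous family (k = family size).

    Families with zero total usage get NaN for every member (undefined, not 0).
    """
    out: dict[str, float] = {}
    for _aa, family in synonymous_families().items():
        total = sum(counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            out[c] = (counts.get(c, 0) * k / total) if total > 0 else float("nan")
    return out


def cdspt(counts: dict[str, int]) -> dict[str, float]:
    """Per-mille usage of each codon: 1000 * n_c / total_codons."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no codons counted")
    return {c: 1000.0 * counts.get(c, 0) / total for c in sense_codons()}


def flag_low_usage(rscu_map: dict[str, float], threshold: float = 0.5) -> list[str]:
    """Codons with measured RSCU <= threshold (NaN families excluded)."""
    return sorted(c for c, v in rscu_map.items() if v == v and v <= threshold)
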