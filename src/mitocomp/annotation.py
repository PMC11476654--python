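"""Annotation arithmetic on the circular gene map.

Covers intergenic-nucleotide (IN) accounting — positive values are spacers,
negative values overlaps — start/stop codon classification of protein-coding
genes (including the incomplete T-- / TA- stops completed to TAA by
polyadenylation), and circular gene-order comparison by adjacency
breakpoints. The closure identity

    sum(feature sizes) + sum(signed IN) == genome length

holds for any consistent circular annotation and is the main integrity check
on a feature table.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genetic_code import stop_codons
from .genome import AnnotationError, FeatureTable

#: Complete stop codons of the vertebrate mitochondrial code. AGA/AGG are
#: accepted as complete stops even though Lethrinus PCGs use only TAA/TAG.
COMPLETE_STOPS = tuple(sorted(stop_codons()))


@dataclass(frozen=True)
class GapRecord:
    """Signed gap between two adjacent features on the circle."""

    upstream: str
    downstream: str
    in_value: int  # > 0 spacer, < 0 overlap, 0 contiguous


@dataclass(frozen=True)
class GapSummary:
    n_spacers: int
    spacer_bp: int
    n_overlaps: int
    overlap_bp: int  # absolute total
    signed_total: int


@dataclass(frozen=True)
class CodonClassification:
    gene: str
    start_codon: str
    stop_class: str  # e.g. "complete:TAA", "incomplete:TA-", "irregular"
    remainder: int  # size mod 3

    @property
    def is_complete(self) -> bool:
        return self.stop_class.startswith("complete")


def scan_spacers_overlaps(table: FeatureTable) -> tuple[list[GapRecord], GapSummary]:
    """One GapRecord per adjacency, including the circular wrap at the origin.

    IN(up, down) = start(down) - stop(up) - 1 in linear coordinates; the
    last -> first adjacency wraps: IN = (L - stop(last)) + start(first) - 1.
    """
    if not table.is_sorted():
        raise AnnotationError("feature table must be sorted by start coordinate")
    feats = table.features
    L = table.genome_length
    records = []
    n = len(feats)
    for i, up in enumerate(feats):
        if i < n - 1:
            down = feats[i + 1]
            in_value = down.start - up.stop - 1
        else:
            if not table.circular:
                break
            down = feats[0]
            # if the last feature itself wraps the origin, its stop already
            # lives on the next turn of the circle
            eff_stop = up.stop if up.wraps else up.stop - L
            in_value = down.start - eff_stop - 1
        records.append(GapRecord(up.name, down.name, in_value))
    spacers = [r for r in records if r.in_value > 0]
    overlaps = [r for r in records if r.in_value < 0]
    summary = GapSummary(
        n_spacers=len(spacers),
        spacer_bp=sum(r.in_value for r in spacers),
        n_overlaps=len(overlaps),
        overlap_bp=-sum(r.in_value for r in overlaps),
        signed_total=sum(r.in_value for r in records),
    )
    return records, summary


def closure_identity(table: FeatureTable) -> int:
    """sum(sizes) + sum(signed IN); equals the genome length when consistent."""
    _, summary = scan_spacers_overlaps(table)
    sizes = sum(f.size(table.genome_length) for f in table)
    return sizes + summary.signed_total


def classify_codons(cds: str, gene: str = "") -> CodonClassification:
    """Start codon and stop class of a coding-strand CDS.

    size % 3 == 0 with a final codon in the mito stop set -> complete;
    size % 3 == 2 ending in "TA" -> incomplete:TA- (completed by polyA);
    size % 3 == 1 ending in "T"  -> incomplete:T--;
    anything else is flagged "irregular", never coerced.
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError(f"{gene or 'CDS'}: sequence shorter than 6 nt")
    remainder = len(cds) % 3
    if remainder == 0:
        last = cds[-3:]
        stop_class = f"complete:{last}" if last in COMPLETE_STOPS else "irregular"
    elif remainder == 2:
        stop_class = "incomplete:TA-" if cds.endswith("TA") else "irregular"
    else:
        stop_class = "incomplete:T--" if cds.endswith("T") else "irregular"
    return CodonClassification(gene=gene, start_codon=cds[:3],
                               stop_class=stop_class, remainder=remainder)


def _circular_adjacencies(order: list[str]) -> set[frozenset[str]]:
    n = len(order)
    return {frozenset((order[i], order[(i + 1) % n])) for i in range(n)}


def compare_gene_order(table: FeatureTable | list[str],
                       reference: list[str] | tuple[str, ...]) -> tuple[bool, int]:
    """Compare two circular gene orders by unordered adjacency sets.

    Returns (identical, breakpoint_count) where a breakpoint is an adjacency
    present in the query order but absent from the reference order.
    """
    if isinstance(table, FeatureTable):
        order = [f.name for f in table]
    else:
        order = list(table)
    ref = list(reference)
    if set(order) != set(ref):
        only_q = sorted(set(order) - set(ref))
        only_r = sorted(set(ref) - set(order))
        raise AnnotationError(
            f"gene-name sets differ: only in query {only_q}, only in reference {only_r}")
    breakpoints = len(_circular_adjacencies(order) - _circular_adjacencies(ref))
    return breakpoints == 0, breakpoints
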