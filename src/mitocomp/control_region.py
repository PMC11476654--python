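"""Conserved-sequence-block (CSB) scanning of aligned control regions.

Teleost control regions carry a variable ETAS domain followed by the
conserved blocks CSB-D, CSB-I, CSB-II and CSB-III, in that canonical 5'->3'
order. Each block is located by sliding its consensus motif across the
alignment and taking the window with the highest mean identity over all rows
(leftmost on ties); blocks are forced to be non-overlapping and in canonical
order. A block whose best identity falls below 60% is reported "not found".

Within a located window, a column is *conserved* iff every row carries the
same non-gap base; columns containing a gap count as variable. Percentages
are computed from the integer counts and rounded last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

BLOCK_ORDER = ("ETAS", "CSB-D", "CSB-I", "CSB-II", "CSB-III")
MIN_IDENTITY = 0.60


def default_motifs() -> dict[str, str]:
    """Shipped consensus motifs for the teleost CR blocks (ETAS + 4 CSBs)."""
    with resources.files("mitocomp.data").joinpath("csb_motifs.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class BlockWindow:
    block: str
    start: int  # 0-based alignment column
    end: int    # inclusive
    identity: float
    found: bool


@dataclass(frozen=True)
class CSBReport:
    block: str
    start: int
    end: int
    length: int
    conserved: int
    variable: int
    per_column: tuple[bool, ...]  # True = conserved

    @property
    def pct_conserved(self) -> float:
        return 100.0 * self.conserved / self.length

    @property
    def pct_variable(self) -> float:
        return 100.0 * self.variable / self.length


def _window_identity(rows: list[str], motif: str, start: int) -> float:
    hits = 0
    total = len(rows) * len(motif)
    for row in rows:
        seg = row[start:start + len(motif)]
        hits += sum(1 for a, b in zip(seg, motif) if a == b)
    return hits / total


def locate_blocks(rows: list[str], motifs: dict[str, str] | None = None,
                  min_identity: float = MIN_IDENTITY) -> list[BlockWindow]:
    """Place each block motif at its best-identity window, in canonical order.

    `rows` is an aligned multi-FASTA as uppercase strings of equal length.
    Blocks are searched left to right: each search starts after the previous
    *found* block's window, which enforces the canonical ETAS < CSB-D <
    CSB-I < CSB-II < CSB-III ordering without overlap.
    """
    if len(rows) < 2:
        raise ValueError("need at least two aligned sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows differ in length")
    rows = [r.upper() for r in rows]
    if motifs is None:
        motifs = default_motifs()

    out = []
    floor = 0
    for block in BLOCK_ORDER:
        if block not in motifs:
            continue
        motif = motifs[block].upper()
        best_start, best_ident = -1, -1.0
        for start in range(floor, width - len(motif) + 1):
            ident = _window_identity(rows, motif, start)
            if ident > best_ident:  # strict: leftmost wins ties
                best_start, best_ident = start, ident
        found = best_start >= 0 and best_ident >= min_identity
        if found:
            out.append(BlockWindow(block, best_start,
                                   best_start + len(motif) - 1, best_ident, True))
            floor = best_start + len(motif)
        else:
            out.append(BlockWindow(block, -1, -1, max(best_ident, 0.0), False))
    return out


def score_block(rows: list[str], window: BlockWindow | None = None,
                block: str = "") -> CSBReport:
    """Conserved/variable column counts of one alignment window."""
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    rows = [r.upper() for r in rows]
    if window is not None:
        block = block or window.block
        rows = [r[window.start:window.end + 1] for r in rows]
        start, end = window.start, window.end
    else:
        start, end = 0, len(rows[0]) - 1
    length = len(rows[0])
    per_col = []
    for j in range(length):
        column = {r[j] for r in rows}
        per_col.append(len(column) == 1 and "-" not in column)
    conserved = sum(per_col)
    return CSBReport(block=block, start=start, end=end, length=length,
                     conserved=conserved, variable=length - conserved,
                     per_column=tuple(per_col))


def csb_report_frame(reports: list[CSBReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "block": r.block, "start": r.start + 1, "end": r.end + 1,
        "length": r.length, "conserved": r.conserved, "variable": r.variable,
        "pct_conserved": round(r.pct_conserved, 2),
        "pct_variable": round(r.pct_variable, 2),
    } for r in reports])
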