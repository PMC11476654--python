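"""Template-constrained cloverleaf folding of mitochondrial tRNAs.

The folder searches a bounded grid of canonical cloverleaf layouts —
acceptor stem 6-7 bp, DHU stem 0-4 bp, anticodon stem 4-5 bp with a 7-nt
anticodon loop, T(psi)C stem 4-5 bp, with canonical connector-length ranges —
and returns the layout maximizing the number of paired stem positions.
Watson-Crick (A-T/U, G-C) and wobble (G-U) pairings both count as pairs;
wobble pairs are tallied separately per stem. No thermodynamic energies are
used: this is a deliberate structural-template simplification adequate for
counting stems, anticodons and wobble pairs in mito tRNAs (55-95 nt).

A tRNA whose best DHU stem holds fewer than 2 pairs is reported as lacking
the DHU arm, the situation seen in mitochondrial tRNA-Ser(AGN).
"""

from __future__ import annotations

from dataclasses import dataclass

STEM_NAMES = ("acceptor", "DHU", "anticodon", "TpsiC")

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}

MIN_LENGTH, MAX_LENGTH = 55, 95
MIN_FOLD_SCORE = 12  # fewer total pairs -> reported unfoldable

# layout grid (see module docstring)
_LEAD = (0, 1)
_ACCEPTOR = (7, 6)          # descending: prefer the longer stem on ties
_CONN1 = (1, 2, 3)          # acceptor -> DHU connector (canonical 2)
_DHU = (0, 2, 3, 4)
_DLOOP_WITH_STEM = range(3, 10)
_DLOOP_NO_STEM = range(2, 13)  # unpaired replacement region when DHU absent
_CONN2 = (0, 1, 2)
_AC_STEM = (4, 5)
_AC_LOOP = 7                # anticodon at loop positions 3-5 (center)
_VAR = range(2, 13)         # variable region
_T_STEM = (4, 5)
_T_LOOP = range(4, 9)
_TAIL = (1, 2, 3, 4)        # discriminator (+ partial NCCA)


def pair_type(x: str, y: str) -> str | None:
    """'WC', 'wobble' or None for a putative stem pair."""
    p = (x, y)
    if p in _WC:
        return "WC"
    if p in _WOBBLE:
        return "wobble"
    return None


@dataclass(frozen=True)
class TRNAStructure:
    sequence: str
    stems: dict[str, list[tuple[int, int]]]  # paired (0-based) positions only
    stem_spans: dict[str, tuple[int, int, int]]  # (start5, start3, length)
    loops: dict[str, tuple[int, int]]  # inclusive 0-based ranges
    anticodon: str
    anticodon_position: int  # 0-based index of the first anticodon base
    wobble_per_stem: dict[str, int]
    dhu_present: bool
    score: int
    foldable: bool

    @property
    def has_wobble(self) -> bool:
        return any(self.wobble_per_stem.values())

    def dot_bracket(self) -> str:
        chars = ["." for _ in self.sequence]
        for pairs in self.stems.values():
            for i, j in pairs:
                chars[i], chars[j] = "(", ")"
        return "".join(chars)

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "dot_bracket": self.dot_bracket(),
            "anticodon": self.anticodon,
            "anticodon_position": self.anticodon_position,
            "stems": {k: [list(p) for p in v] for k, v in self.stems.items()},
            "wobble_per_stem": self.wobble_per_stem,
            "dhu_present": self.dhu_present,
            "score": self.score,
            "foldable": self.foldable,
        }


def _pair_matrix(seq: str) -> list[list[int]]:
    """L x L lookup: 0 unpaired, 1 Watson-Crick, 2 wobble."""
    code = {}
    for p in _WC:
        code[p] = 1
    for p in _WOBBLE:
        code[p] = 2
    return [[code.get((x, y), 0) for y in seq] for x in seq]


def _score_layout(pt: list[list[int]], layout: dict) -> tuple[int, dict, dict]:
    """Paired positions and wobble counts per stem for one concrete layout."""
    stems: dict[str, list[tuple[int, int]]] = {}
    wob: dict[str, int] = {}
    total = 0
    for name in STEM_NAMES:
        s5, s3, n = layout[name]
        paired = []
        w = 0
        for k in range(n):
            i, j = s5 + k, s3 + (n - 1 - k)
            p = pt[i][j]
            if p:
                paired.append((i, j))
                if p == 2:
                    w += 1
        stems[name] = paired
        wob[name] = w
        total += len(paired)
    return total, stems, wob


def fold_cloverleaf(seq: str, anticodon: str = "") -> TRNAStructure:
    """Fold one tRNA sequence onto the best-scoring cloverleaf layout.

    If ``anticodon`` is given, only layouts whose anticodon-loop center
    equals it are considered (falling back to the unconstrained search if no
    layout matches). Deterministic: ties are broken by earliest acceptor
    start, then by the longer acceptor stem, then by grid order.
    """
    s = seq.upper().replace("U", "T")
    L = len(s)
    if not (MIN_LENGTH <= L <= MAX_LENGTH):
        raise ValueError(f"tRNA length {L} outside [{MIN_LENGTH}, {MAX_LENGTH}]")
    want = anticodon.upper().replace("U", "T") if anticodon else ""
    pt = _pair_matrix(s)

    def _make_layout(params) -> dict:
        lead, a, c1, d, dl, c2, b, v, t, tl = params
        p = lead
        acc5 = p; p += a
        p += c1
        dhu5 = p; p += d
        dloop = p; p += dl
        dhu3 = p; p += d
        p += c2
        ac5 = p; p += b
        acloop = p; p += _AC_LOOP
        ac3 = p; p += b
        p += v
        t5 = p; p += t
        tloop = p; p += tl
        t3 = p; p += t
        acc3 = p
        return {
            "acceptor": (acc5, acc3, a),
            "DHU": (dhu5, dhu3, d),
            "anticodon": (ac5, ac3, b),
            "TpsiC": (t5, t3, t),
            "_loops": {
                "DHU": (dloop, dloop + dl - 1),
                "anticodon": (acloop, acloop + _AC_LOOP - 1),
                "TpsiC": (tloop, tloop + tl - 1),
            },
            "_ac_pos": acloop + 2,
        }

    def _fast_score(params) -> int:
        layout = _make_layout(params)
        total = 0
        for name in STEM_NAMES:
            s5, s3, n = layout[name]
            row = pt
            for k in range(n):
                if row[s5 + k][s3 + (n - 1 - k)]:
                    total += 1
        return total

    best = None  # (score, params)
    for constrained in ((True, False) if want else (False,)):
        for lead in _LEAD:
            for a in _ACCEPTOR:
                for c1 in _CONN1:
                    for d in _DHU:
                        dloops = _DLOOP_WITH_STEM if d else _DLOOP_NO_STEM
                        for dl in dloops:
                            head = lead + 2 * a + c1 + 2 * d + dl
                            ac_pos = lead + a + c1 + 2 * d + dl  # + c2 + b + 2
                            for c2 in _CONN2:
                                for b in _AC_STEM:
                                    if constrained and \
                                            s[ac_pos + c2 + b + 2:ac_pos + c2 + b + 5] != want:
                                        continue
                                    for t in _T_STEM:
                                        for tl in _T_LOOP:
                                            for tail in _TAIL:
                                                v = L - (head + c2 + 2 * b + _AC_LOOP
                                                         + 2 * t + tl + tail)
                                                if v not in _VAR:
                                                    continue
                                                params = (lead, a, c1, d, dl,
                                                          c2, b, v, t, tl)
                                                score = _fast_score(params)
                                                if best is None or score > best[0]:
                                                    best = (score, params)
        if best is not None:
            break  # constrained search succeeded; don't relax

    layout = _make_layout(best[1])
    score, stems, wob = _score_layout(pt, layout)
    ac_pos = layout["_ac_pos"]
    return TRNAStructure(
        sequence=s,
        stems=stems,
        stem_spans={k: layout[k] for k in STEM_NAMES},
        loops=layout["_loops"],
        anticodon=s[ac_pos:ac_pos + 3],
        anticodon_position=ac_pos,
        wobble_per_stem=wob,
        dhu_present=len(stems["DHU"]) >= 2,
        score=score,
        foldable=score >= MIN_FOLD_SCORE,
    )


@dataclass(frozen=True)
class WobbleSummary:
    n_trnas: int
    n_trnas_with_wobble: int
    per_stem: dict[str, int]
    n_without_dhu: int


def wobble_summary(structures: list[TRNAStructure]) -> WobbleSummary:
    """Tally wobble pairs per stem; each tRNA counts once in the headline
    number regardless of how many wobble pairs it carries."""
    if not structures:
        raise ValueError("need at least one structure")
    per_stem = {name: sum(st.wobble_per_stem.get(name, 0) for st in structures)
                for name in STEM_NAMES}
    return WobbleSummary(
        n_trnas=len(structures),
        n_trnas_with_wobble=sum(1 for st in structures if st.has_wobble),
        per_stem=per_stem,
        n_without_dhu=sum(1 for st in structures if not st.dhu_present),
    )
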