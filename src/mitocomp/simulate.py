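"""Synthetic mitogenome and sequence-evolution generators.

Every analysis stage in this package can be exercised offline against data
with known ground truth:

* :func:`gen_mitogenome` realizes a full 37-gene circular mitogenome in the
  ancestral vertebrate gene order, with configurable base composition,
  planted spacers/overlaps (including the 7 bp ND4L/ND4 overlap), planted
  start/stop codon classes (complete and incomplete), and cloverleaf-foldable
  tRNA loci carrying planted anticodons and wobble pairs. The default spec
  reuses the exact gene sizes, intergenic values, codon classes and
  anticodon triplets of the bundled *L. atlanticus* annotation, so the
  synthetic genome has the real geometry without the real sequence.
* :func:`evolve_codon_pair` evolves codon sequences at a chosen dN/dS
  (synonymous rate 1, nonsynonymous rate omega, stops rejected) for Ka/Ks
  recovery tests.
* :func:`sim_alignment_on_tree` simulates site-independent alignments under
  the package's substitution models (+G/+I honored) on arbitrary trees.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .genetic_code import is_stop, sense_codons, translate
from .genome import (FeatureRecord, FeatureTable, MitoGenome,
                     extract_feature_sequence, load_reference_table,
                     reverse_complement)
from .phylo import SubstitutionModel
from .trna import MAX_LENGTH, MIN_LENGTH

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# Whole-genome generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    name: str
    cls: str
    strand: str
    size: int
    in_after: int  # signed intergenic value after this gene
    start_codon: str = ""
    stop_codon: str = ""  # "TAA", "TAG", "TA-", "T--"
    anticodon: str = ""


@dataclass
class MitoSpec:
    genome_length: int
    genes: list[GeneSpec]
    composition: dict[str, float] = field(
        default_factory=lambda: {"A": 27.20, "T": 25.90, "G": 17.02, "C": 29.88})
    wobble_plan: dict[str, dict[str, int]] = field(default_factory=dict)
    cr_motifs: dict[str, int] = field(default_factory=dict)  # motif -> CR offset
    seed: int = 0

    def __post_init__(self):
        total = sum(g.size for g in self.genes) + sum(g.in_after for g in self.genes)
        if total != self.genome_length:
            raise ValueError(
                f"closure violated: sizes + signed INs = {total} != genome "
                f"length {self.genome_length}")


def default_mitospec(seed: int = 0, **overrides) -> MitoSpec:
    """Spec mirroring the bundled reference geometry (sizes, INs, codons)."""
    import csv
    from importlib import resources

    table = load_reference_table()
    genes = []
    with resources.files("mitocomp.data").joinpath(
            "lethrinus_atlanticus_features.tsv").open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    for row in rows:
        genes.append(GeneSpec(
            name=row["name"], cls=row["cls"], strand=row["strand"],
            size=int(row["size"]), in_after=int(row["in"]),
            start_codon=row["start_codon"], stop_codon=row["stop_codon"],
            anticodon=row["anticodon"]))
    spec = MitoSpec(genome_length=table.genome_length, genes=genes, seed=seed)
    return replace(spec, **overrides) if overrides else spec


def _base_probs(composition: dict[str, float]) -> np.ndarray:
    p = np.array([composition[b] for b in "ACGT"], dtype=float)
    return p / p.sum()


def _sample_sense_codon(rng: np.random.Generator, probs: np.ndarray) -> str:
    while True:
        codon = "".join(np.array(list("ACGT"))[rng.choice(4, size=3, p=probs)])
        if not is_stop(codon):
            return codon


def build_trna(length: int, anticodon: str, wobble: dict[str, int] | None = None,
               rng: np.random.Generator | None = None) -> str:
    """A designed cloverleaf tRNA: perfect stems (7/4/5/5 bp at length >= 68,
    fewer DHU loop nt below), planted anticodon at the loop center, and the
    requested number of G-U wobble pairs per stem.

    Loop/connector bases are drawn from {A, C} so the planted layout is the
    unique maximal-pairing cloverleaf — the ground truth is unambiguous.
    Pass ``wobble={'DHU': 0, ...}`` stems you want wobble-free.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    wobble = wobble or {}
    if not (MIN_LENGTH <= length <= MAX_LENGTH):
        raise ValueError(f"length {length} outside [{MIN_LENGTH}, {MAX_LENGTH}]")
    a, c1, d, c2, b, al, t, tl, tail = 7, 2, 4, 1, 5, 7, 5, 7, 1
    fixed = 2 * a + c1 + 2 * d + c2 + 2 * b + al + 2 * t + tl + tail
    rest = length - fixed
    dl = int(np.clip(rest - 2, 3, 9))
    v = rest - dl
    if not (3 <= dl <= 9 and 2 <= v <= 12):
        raise ValueError(f"cannot allocate cloverleaf segments for length {length}")

    def loop_bases(n):
        return "".join(rng.choice(["A", "C"], size=n))

    def stem(n, n_wobble):
        five = [rng.choice(list("ACGT")) for _ in range(n)]
        three = [_COMP[x] for x in five][::-1]
        pos = rng.choice(n, size=n_wobble, replace=False)
        for k in pos:
            if rng.random() < 0.5:
                five[k], three[n - 1 - k] = "G", "T"
            else:
                five[k], three[n - 1 - k] = "T", "G"
        return "".join(five), "".join(three)

    acc5, acc3 = stem(a, wobble.get("acceptor", 0))
    dhu5, dhu3 = stem(d, wobble.get("DHU", 0))
    ac5, ac3 = stem(b, wobble.get("anticodon", 0))
    t5, t3 = stem(t, wobble.get("TpsiC", 0))
    anticodon = anticodon.upper().replace("U", "T")
    acloop = loop_bases(2) + anticodon + loop_bases(2)
    seq = (acc5 + loop_bases(c1) + dhu5 + loop_bases(dl) + dhu3 + loop_bases(c2)
           + ac5 + acloop + ac3 + loop_bases(v) + t5 + loop_bases(tl) + t3
           + acc3 + loop_bases(tail))
    assert len(seq) == length
    return seq


def _build_cds(size: int, start_codon: str, stop_codon: str,
               rng: np.random.Generator, probs: np.ndarray) -> str:
    """Coding-strand CDS with the requested start codon and stop class."""
    n_full = size // 3
    remainder = size % 3
    if stop_codon in ("TAA", "TAG", "AGA", "AGG"):
        if remainder:
            raise ValueError("complete stop requires size % 3 == 0")
        middle = n_full - 2
        tail = stop_codon
    elif stop_codon == "TA-":
        if remainder != 2:
            raise ValueError("TA- stop requires size % 3 == 2")
        middle = n_full - 1
        tail = "TA"
    elif stop_codon == "T--":
        if remainder != 1:
            raise ValueError("T-- stop requires size % 3 == 1")
        middle = n_full - 1
        tail = "T"
    else:
        raise ValueError(f"unknown stop codon class {stop_codon!r}")
    body = "".join(_sample_sense_codon(rng, probs) for _ in range(middle))
    return start_codon + body + tail


def gen_mitogenome(spec: MitoSpec) -> tuple[MitoGenome, FeatureTable]:
    """Realize a synthetic circular mitogenome from a spec (see module doc)."""
    rng = np.random.default_rng(spec.seed)
    probs = _base_probs(spec.composition)
    L = spec.genome_length
    seq = list("".join(np.array(list("ACGT"))[rng.choice(4, size=L, p=probs)]))

    # coordinates from sizes + signed INs
    feats: list[FeatureRecord] = []
    pos = 1
    for g in spec.genes:
        start, stop = pos, pos + g.size - 1
        feats.append(FeatureRecord(
            name=g.name, cls=g.cls, strand=g.strand, start=start, stop=stop,
            anticodon=g.anticodon, start_codon=g.start_codon,
            stop_codon=g.stop_codon))
        pos = stop + g.in_after + 1
    table = FeatureTable(genome_id=f"synthetic_{spec.seed}", genome_length=L,
                         circular=True, features=feats)

    def write(start: int, strand: str, payload: str) -> None:
        if strand == "-":
            payload = reverse_complement(payload)
        for k, base in enumerate(payload):
            seq[(start - 1 + k) % L] = base

    locked: set[int] = set()
    for g, f in zip(spec.genes, feats):
        if g.cls == "tRNA":
            write(f.start, f.strand, build_trna(g.size, g.anticodon,
                                                spec.wobble_plan.get(g.name), rng))
            locked.update((f.start - 1 + k) % L for k in range(g.size))
    for g, f in zip(spec.genes, feats):
        if g.cls == "PCG":
            write(f.start, f.strand, _build_cds(g.size, g.start_codon,
                                                g.stop_codon, rng, probs))
    # re-assert start/stop codons in table order so overlapping CDSs keep
    # their planted classes (the default geometry is mutually consistent)
    for g, f in zip(spec.genes, feats):
        if g.cls != "PCG":
            continue
        tail = g.stop_codon.rstrip("-")
        if f.strand == "+":
            write(f.start, "+", g.start_codon)
            write(f.stop - len(tail) + 1, "+", tail)
            _lock_range(locked, f.start, 3, L)
            _lock_range(locked, f.stop - len(tail) + 1, len(tail), L)
        else:  # coding 5' end sits at the reference `stop` coordinate
            write(f.stop - 2, "-", g.start_codon)
            write(f.start, "-", tail)
            _lock_range(locked, f.stop - 2, 3, L)
            _lock_range(locked, f.start, len(tail), L)
    # plant CR motifs
    for g, f in zip(spec.genes, feats):
        if g.cls == "CR":
            for motif, offset in spec.cr_motifs.items():
                write(f.start + offset, "+", motif)
                _lock_range(locked, f.start + offset, len(motif), L)

    _rebalance_composition(seq, table, locked, spec.composition, rng)
    genome = MitoGenome(id=table.genome_id, sequence="".join(seq), circular=True)
    genome = _repair_internal_stops(genome, table, locked, rng)
    _verify_planted(genome, table)
    return genome, table


def _lock_range(locked: set[int], start: int, n: int, L: int) -> None:
    locked.update((start - 1 + k) % L for k in range(n))


def _rebalance_composition(seq: list[str], table: FeatureTable,
                           locked: set[int], composition: dict[str, float],
                           rng: np.random.Generator) -> None:
    """Nudge unlocked positions so whole-genome base counts approach the spec
    composition despite the fixed content of planted features.  Mutations that
    would create an in-frame stop in any covering PCG are skipped."""
    L = len(seq)
    total = sum(composition.values())
    target = {b: composition[b] / total * L for b in "ACGT"}
    cover: dict[int, list[tuple[FeatureRecord, int]]] = {}
    for f in table.by_class("PCG"):
        for ci in range(f.size(L)):
            cover.setdefault(_coding_to_genome(f, ci, L), []).append((f, ci))

    def would_create_stop(pos: int, base: str) -> bool:
        for f, ci in cover.get(pos, ()):
            i0 = ci - ci % 3
            if i0 + 3 > f.size(L):
                continue  # trailing partial codon cannot be a full stop
            codon = []
            for k in range(i0, i0 + 3):
                if k == ci:
                    ch = base if f.strand == "+" else _COMP[base]
                else:
                    g = _coding_to_genome(f, k, L)
                    ch = seq[g] if f.strand == "+" else _COMP[seq[g]]
                codon.append(ch)
            if is_stop("".join(codon)):
                return True
        return False

    counts = {b: 0 for b in "ACGT"}
    for ch in seq:
        counts[ch] += 1
    surplus = {b: counts[b] - target[b] for b in "ACGT"}
    for pos in rng.permutation(L):
        pos = int(pos)
        if pos in locked:
            continue
        b = seq[pos]
        if surplus[b] <= 0.5:
            continue
        want = min("ACGT", key=lambda x: surplus[x])
        if surplus[want] >= -0.5 or want == b:
            continue
        if would_create_stop(pos, want):
            continue
        seq[pos] = want
        surplus[b] -= 1
        surplus[want] += 1


def _repair_internal_stops(genome: MitoGenome, table: FeatureTable,
                           locked: set[int], rng: np.random.Generator) -> MitoGenome:
    seq = list(genome.sequence)
    L = len(seq)
    for _ in range(4):  # a few passes settle overlapping regions
        dirty = False
        for f in table.by_class("PCG"):
            cds = extract_feature_sequence(
                MitoGenome(genome.id, "".join(seq)), f)
            n_full = len(cds) // 3
            for i in range(1, n_full - 1):  # internal codons only
                codon = cds[3 * i:3 * i + 3]
                if not is_stop(codon):
                    continue
                for offset, new_base in ((2, "C"), (1, "C"), (0, "C")):
                    gpos = _coding_to_genome(f, 3 * i + offset, L)
                    if gpos not in locked:
                        seq[gpos] = new_base if f.strand == "+" else _COMP[new_base]
                        dirty = True
                        break
                else:
                    raise ValueError(
                        f"{f.name}: internal stop at codon {i} cannot be "
                        f"repaired without breaking a planted constraint")
        if not dirty:
            break
    return MitoGenome(genome.id, "".join(seq), circular=True)


def _coding_to_genome(f: FeatureRecord, coding_index: int, L: int) -> int:
    """0-based genome index of the coding-strand position `coding_index`."""
    if f.strand == "+":
        return (f.start - 1 + coding_index) % L
    return (f.stop - 1 - coding_index) % L


def _verify_planted(genome: MitoGenome, table: FeatureTable) -> None:
    from .annotation import classify_codons
    for f in table.by_class("PCG"):
        cds = extract_feature_sequence(genome, f)
        cc = classify_codons(cds, f.name)
        want_stop = ("incomplete:" + f.stop_codon if "-" in f.stop_codon
                     else "complete:" + f.stop_codon)
        if cc.start_codon != f.start_codon or cc.stop_class != want_stop:
            raise ValueError(
                f"{f.name}: planted codons clobbered "
                f"({cc.start_codon}/{cc.stop_class} vs "
                f"{f.start_codon}/{want_stop}); spec is infeasible")


# ---------------------------------------------------------------------------
# Control-region alignment generator
# ---------------------------------------------------------------------------

def gen_cr_alignment(n_rows: int, length: int, motifs: dict[str, str],
                     block_starts: dict[str, int], variable_columns: list[int],
                     seed: int = 0) -> tuple[list[str], dict[str, tuple[int, int]]]:
    """Aligned CR rows with motifs planted at known columns and a known set
    of variable columns; every other column is identical across rows.

    Returns (rows, {block: (start, end)}) with 0-based inclusive windows.
    """
    rng = np.random.default_rng(seed)
    ref = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)]))
    windows = {}
    for block, start in block_starts.items():
        motif = motifs[block].upper()
        ref[start:start + len(motif)] = list(motif)
        windows[block] = (start, start + len(motif) - 1)
    rows = [list(ref) for _ in range(n_rows)]
    for col in variable_columns:
        row = int(rng.integers(1, n_rows))  # keep row 0 as the reference
        alt = [b for b in "ACGT" if b != ref[col]]
        rows[row][col] = alt[int(rng.integers(0, 3))]
    return ["".join(r) for r in rows], windows


# ---------------------------------------------------------------------------
# Codon-pair evolution at a chosen dN/dS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolveSpec:
    n_codons: int
    omega: float  # dN/dS; relative nonsynonymous rate
    t: float      # expected substitutions per codon at omega = 1
    seed: int = 0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.t < 0:
            raise ValueError("t must be non-negative")


@dataclass(frozen=True)
class EvolvedPair:
    ancestor: str
    derived: str
    n_syn: int
    n_nonsyn: int


def evolve_codon_pair(spec: EvolveSpec) -> EvolvedPair:
    """Evolve one lineage from a random stop-free ancestor for time `t`.

    Mutation model mirrors the NG86 counting assumptions: every non-stop
    single-nucleotide neighbour is reachable, synonymous changes at rate 1
    and nonsynonymous at rate omega (per neighbour, scaled so a neutral codon
    experiences one expected substitution per unit t); mutations to stop
    codons are rejected. Realized substitution counts are the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    codons = list(sense_codons())
    anc = [codons[i] for i in rng.integers(0, len(codons), size=spec.n_codons)]
    mu = 1.0 / 9.0  # neutral total rate ~1 per codon per unit t
    derived = []
    n_syn = n_nonsyn = 0
    for codon in anc:
        cur = codon
        time = 0.0
        while True:
            neigh = []
            rates = []
            for pos in range(3):
                for b in "ACGT":
                    if b == cur[pos]:
                        continue
                    mut = cur[:pos] + b + cur[pos + 1:]
                    if is_stop(mut):
                        continue
                    syn = translate(mut) == translate(cur)
                    neigh.append((mut, syn))
                    rates.append(mu if syn else mu * spec.omega)
            total = sum(rates)
            if total <= 0:
                break
            time += rng.exponential(1.0 / total)
            if time > spec.t:
                break
            pick = rng.choice(len(neigh), p=np.array(rates) / total)
            mut, syn = neigh[pick]
            if syn:
                n_syn += 1
            else:
                n_nonsyn += 1
            cur = mut
        derived.append(cur)
    return EvolvedPair(ancestor="".join(anc), derived="".join(derived),
                       n_syn=n_syn, n_nonsyn=n_nonsyn)


# ---------------------------------------------------------------------------
# Alignment simulation on trees
# ---------------------------------------------------------------------------

def sim_alignment_on_tree(tree: dendropy.Tree, model: SubstitutionModel,
                          sites: int, seed: int = 0) -> dict[str, str]:
    """Simulate a site-independent alignment on a tree under `model`.

    Per-site rates honor +G (discrete categories) and +I (zero-rate class
    with probability p_inv).
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(model.freqs, float)
    eigen = model.eigen()
    cat_rates = model.category_rates()
    site_rates = cat_rates[rng.integers(0, len(cat_rates), size=sites)]
    if model.p_inv > 0:
        site_rates[rng.random(sites) < model.p_inv] = 0.0

    states = {}
    root = tree.seed_node
    states[root] = rng.choice(4, size=sites, p=pi)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length or 0.0
        parent = states[node.parent_node]
        child = parent.copy()
        for r in np.unique(site_rates):
            mask = site_rates == r
            if bl * r == 0:
                continue
            P = model.transition_matrix(bl * r, eigen)
            cum = P.cumsum(axis=1)
            u = rng.random(int(mask.sum()))
            child[mask] = (u[:, None] < cum[parent[mask]]).argmax(axis=1)
        states[node] = child
    bases = np.array(list("ACGT"))
    return {lf.taxon.label: "".join(bases[states[lf]])
            for lf in tree.leaf_node_iter()}


def random_tree(n_taxa: int, seed: int = 0, bl_low: float = 0.05,
                bl_high: float = 0.3) -> dendropy.Tree:
    """Random rooted binary tree with uniform branch lengths (for tests)."""
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    nodes = []
    for i in range(n_taxa):
        nd = dendropy.Node(taxon=ns.get_taxon(f"t{i}"))
        nd.edge.length = float(rng.uniform(bl_low, bl_high))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(bl_low, bl_high))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def clock_tree(n_taxa: int, seed: int = 0, rate: float = 1.0,
               join_scale: float = 0.1) -> tuple[dendropy.Tree, dict]:
    """Random ultrametric tree; returns (tree with lengths = rate * duration,
    {'ages': {taxon-frozenset: true node age}, 'root_age': age})."""
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    active = []
    for i in range(n_taxa):
        nd = dendropy.Node(taxon=ns.get_taxon(f"t{i}"))
        nd.age_true = 0.0
        active.append(nd)
    ages = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        age = max(a.age_true, b.age_true) + float(rng.exponential(join_scale))
        parent = dendropy.Node()
        parent.age_true = age
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = (age - a.age_true) * rate
        b.edge.length = (age - b.age_true) * rate
        key = frozenset(lf.taxon.label for lf in parent.leaf_iter())
        ages[key] = age
        active = [active[k] for k in range(len(active)) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = active[0]
    tree.is_rooted = True
    return tree, {"ages": ages, "root_age": active[0].age_true}
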