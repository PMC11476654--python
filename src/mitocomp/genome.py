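"""Mitogenome and annotation I/O.

Coordinates follow the convention of published mitogenome annotation tables:
1-based, inclusive on both ends, on the reference (heavy) strand. The genome
is circular by default, so a feature may wrap the origin (``stop < start``)
and the control-region -> tRNA-Phe adjacency closes the circle. All
conversions to Python slices happen inside this module only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "CR")

#: Ancestral vertebrate mitochondrial gene order (heavy-strand origin at
#: tRNA-Phe), the layout shared by the three Lethrinus mitogenomes.
ANCESTRAL_VERTEBRATE_ORDER = (
    "tRNA-Phe (F)", "12S rRNA", "tRNA-Val (V)", "16S rRNA", "tRNA-Leu (L2)",
    "ND1", "tRNA-Ile (I)", "tRNA-Gln (Q)", "tRNA-Met (M)", "ND2",
    "tRNA-Trp (W)", "tRNA-Ala (A)", "tRNA-Asn (N)", "tRNA-Cys (C)",
    "tRNA-Tyr (Y)", "COI", "tRNA-Ser (S2)", "tRNA-Asp (D)", "COII",
    "tRNA-Lys (K)", "ATP8", "ATP6", "COIII", "tRNA-Gly (G)", "ND3",
    "tRNA-Arg (R)", "ND4L", "ND4", "tRNA-His (H)", "tRNA-Ser (S1)",
    "tRNA-Leu (L1)", "ND5", "ND6", "tRNA-Glu (E)", "CYTB", "tRNA-Thr (T)",
    "tRNA-Pro (P)", "Control region",
)

#: Canonicalization map from common GenBank product/gene spellings to the
#: symbols used throughout this package. S1/S2 and L1/L2 disambiguate the
#: duplicated serine and leucine tRNA isoacceptors.
CANONICAL_NAMES = {
    "nad1": "ND1", "nad2": "ND2", "nad3": "ND3", "nad4": "ND4",
    "nad4l": "ND4L", "nad5": "ND5", "nad6": "ND6",
    "nd1": "ND1", "nd2": "ND2", "nd3": "ND3", "nd4": "ND4",
    "nd4l": "ND4L", "nd5": "ND5", "nd6": "ND6",
    "cox1": "COI", "cox2": "COII", "cox3": "COIII",
    "co1": "COI", "co2": "COII", "co3": "COIII",
    "coi": "COI", "coii": "COII", "coiii": "COIII",
    "atp6": "ATP6", "atp8": "ATP8",
    "cytb": "CYTB", "cob": "CYTB",
    "12s ribosomal rna": "12S rRNA", "rrns": "12S rRNA", "12s rrna": "12S rRNA",
    "16s ribosomal rna": "16S rRNA", "rrnl": "16S rRNA", "16s rrna": "16S rRNA",
    "d-loop": "Control region", "control region": "Control region",
}

_TRNA_AA = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "lys": "K", "met": "M",
    "phe": "F", "pro": "P", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for inconsistent or out-of-range feature coordinates."""


@dataclass(frozen=True)
class MitoGenome:
    """A (by default circular) mitochondrial genome sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated gene/region with 1-based inclusive coordinates."""

    name: str
    cls: str
    strand: str
    start: int
    stop: int
    anticodon: str = ""
    start_codon: str = ""
    stop_codon: str = ""

    def __post_init__(self):
        if self.cls not in FEATURE_CLASSES:
            raise AnnotationError(f"{self.name}: unknown feature class {self.cls!r}")
        if self.strand not in "+-":
            raise AnnotationError(f"{self.name}: strand must be '+' or '-'")
        if self.start < 1 or self.stop < 1:
            raise AnnotationError(f"{self.name}: coordinates are 1-based, got "
                                  f"{self.start}..{self.stop}")
        if bool(self.anticodon) != (self.cls == "tRNA"):
            raise AnnotationError(
                f"{self.name}: anticodon must be set iff the feature is a tRNA")

    def size(self, genome_length: int) -> int:
        """Feature length in bp, wrapping the origin when stop < start."""
        if self.stop >= self.start:
            return self.stop - self.start + 1
        return (genome_length - self.start + 1) + self.stop

    @property
    def wraps(self) -> bool:
        return self.stop < self.start


@dataclass
class FeatureTable:
    """Ordered annotation of a mitogenome (ascending start coordinate)."""

    genome_id: str
    genome_length: int
    circular: bool
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self):
        for f in self.features:
            if f.start > self.genome_length or (
                    f.stop > self.genome_length and not self.circular):
                raise AnnotationError(
                    f"{f.name}: coordinates outside [1, {self.genome_length}]")
            if f.wraps and not self.circular:
                raise AnnotationError(
                    f"{f.name}: wrapping feature on a non-circular genome")
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationError(f"duplicate feature names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_class(self, cls: str) -> list[FeatureRecord]:
        if cls not in FEATURE_CLASSES:
            raise AnnotationError(f"unknown feature class {cls!r}")
        return [f for f in self.features if f.cls == cls]

    def get(self, name: str) -> FeatureRecord:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def is_sorted(self) -> bool:
        starts = [f.start for f in self.features]
        return starts == sorted(starts)

    def validate_vertebrate(self) -> None:
        """Assert the canonical 13 PCG + 22 tRNA + 2 rRNA + 1 CR layout."""
        counts = {cls: len(self.by_class(cls)) for cls in FEATURE_CLASSES}
        expected = {"PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 1}
        if counts != expected:
            raise AnnotationError(
                f"not a full vertebrate mitogenome layout: {counts}")


def canonical_gene_name(raw: str) -> str:
    """Map a GenBank gene/product string onto the package's canonical symbol."""
    key = raw.strip().lower()
    if key in CANONICAL_NAMES:
        return CANONICAL_NAMES[key]
    if key.startswith("trna-") or key.startswith("trn"):
        rest = key.replace("trna-", "").replace("trna", "").replace("trn", "")
        aa = rest[:3]
        if aa in _TRNA_AA:
            return f"tRNA-{aa.capitalize()} ({_TRNA_AA[aa]})"
        if len(rest) >= 1:  # single-letter form like trnF
            letter = rest[0].upper()
            for name3, letter1 in _TRNA_AA.items():
                if letter1 == letter:
                    return f"tRNA-{name3.capitalize()} ({letter1})"
    return raw.strip()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["name", "cls", "strand", "start", "stop", "size", "anticodon"]
_OPTIONAL_COLUMNS = ["in", "start_codon", "stop_codon"]


def read_feature_tsv(path, genome_id: str = "", genome_length: int | None = None,
                     circular: bool = True) -> FeatureTable:
    """Read a feature TSV (header: name cls strand start stop size anticodon).

    Extra columns (`in`, `start_codon`, `stop_codon`) are kept when present.
    Declared sizes are cross-checked against the coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"feature TSV missing columns: {missing}")
    feats = []
    max_stop = int(df["stop"].astype(int).max())
    length = genome_length if genome_length is not None else max_stop
    for _, row in df.iterrows():
        rec = FeatureRecord(
            name=row["name"], cls=row["cls"], strand=row["strand"],
            start=int(row["start"]), stop=int(row["stop"]),
            anticodon=row.get("anticodon", ""),
            start_codon=row.get("start_codon", ""),
            stop_codon=row.get("stop_codon", ""),
        )
        declared = int(row["size"])
        if rec.size(length) != declared:
            raise AnnotationError(
                f"{rec.name}: declared size {declared} != coordinate span "
                f"{rec.size(length)}")
        feats.append(rec)
    return FeatureTable(genome_id=genome_id, genome_length=length,
                        circular=circular, features=feats)


def write_feature_tsv(table: FeatureTable, path) -> None:
    rows = []
    for f in table:
        rows.append({
            "name": f.name, "cls": f.cls, "strand": f.strand,
            "start": f.start, "stop": f.stop,
            "size": f.size(table.genome_length),
            "anticodon": f.anticodon,
            "start_codon": f.start_codon, "stop_codon": f.stop_codon,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotated_genome(genbank: str | Path | None = None,
                          fasta: str | Path | None = None,
                          features: str | Path | None = None,
                          circular: bool = True) -> tuple[MitoGenome, FeatureTable]:
    """Read an annotated mitogenome from GenBank, or from a FASTA + TSV pair."""
    if genbank is not None:
        return _read_genbank(genbank, circular=circular)
    if fasta is None or features is None:
        raise ValueError("provide either genbank= or both fasta= and features=")
    rec = SeqIO.read(str(fasta), "fasta")
    genome = MitoGenome(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)
    table = read_feature_tsv(features, genome_id=rec.id,
                             genome_length=genome.length, circular=circular)
    return genome, table


def _read_genbank(path, circular: bool = True) -> tuple[MitoGenome, FeatureTable]:
    rec = SeqIO.read(str(path), "genbank")
    topology = rec.annotations.get("topology", "")
    genome = MitoGenome(id=rec.id, sequence=str(rec.seq).upper(),
                        circular=circular or topology == "circular")
    key_to_cls = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}
    feats = []
    for feat in rec.features:
        if feat.type not in key_to_cls:
            continue
        cls = key_to_cls[feat.type]
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        name = canonical_gene_name(raw)
        anticodon = ""
        if cls == "tRNA":
            anticodon = (quals.get("anticodon") or [""])[0]
            if not anticodon:
                anticodon = "NNN"  # GenBank files often omit it
        feats.append(FeatureRecord(
            name=name, cls=cls,
            strand="+" if feat.location.strand != -1 else "-",
            start=int(feat.location.start) + 1, stop=int(feat.location.end),
            anticodon=anticodon,
        ))
    feats.sort(key=lambda f: f.start)
    return genome, FeatureTable(genome_id=rec.id, genome_length=genome.length,
                                circular=genome.circular, features=feats)


def extract_feature_sequence(genome: MitoGenome, f: FeatureRecord) -> str:
    """5'->3' sequence of a feature; reverse complement for '-' strand.

    Wrapping features (stop < start, or stop beyond the sequence end) are
    only legal on circular genomes.
    """
    seq = genome.sequence
    L = genome.length
    if f.wraps or f.stop > L:
        if not genome.circular:
            raise AnnotationError(
                f"{f.name}: wrap requested on a non-circular genome")
        stop = f.stop if f.stop <= L else f.stop - L
        raw = seq[f.start - 1:] + seq[:stop]
    else:
        raw = seq[f.start - 1:f.stop]
    return reverse_complement(raw) if f.strand == "-" else raw


def load_reference_table() -> FeatureTable:
    """The bundled annotation geometry of the L. atlanticus mitogenome.

    Names, coordinates, sizes, start/stop codons and anticodon triplets as
    deposited for accession OQ420716 (16,789 bp); no sequence is bundled.
    """
    with resources.files("mitocomp.data").joinpath(
            "lethrinus_atlanticus_features.tsv").open() as fh:
        return read_feature_tsv(fh, genome_id="L_atlanticus", genome_length=16789)


def table_to_json(table: FeatureTable) -> str:
    return json.dumps({
        "genome_id": table.genome_id,
        "genome_length": table.genome_length,
        "circular": table.circular,
        "features": [
            {"name": f.name, "cls": f.cls, "strand": f.strand,
             "start": f.start, "stop": f.stop,
             "size": f.size(table.genome_length), "anticodon": f.anticodon}
            for f in table
        ],
    }, indent=2)


def rotate_table(table: FeatureTable, offset: int) -> FeatureTable:
    """Shift the circular coordinate origin by `offset` bp (for invariance tests)."""
    L = table.genome_length

    def shift(pos: int) -> int:
        return (pos - 1 + offset) % L + 1

    feats = [replace(f, start=shift(f.start), stop=shift(f.stop)) for f in table]
    feats.sort(key=lambda f: f.start)
    return FeatureTable(genome_id=table.genome_id, genome_length=L,
                        circular=table.circular, features=feats)
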