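"""Data model and I/O for annotated circular mitochondrial genomes.

Coordinates are 1-based inclusive on the majority (J) strand, as in GenBank
flat files.  A feature that spans the origin of the circle is encoded with
``end < start``; its length is ``L - start + 1 + end``.  Strand is ``J``
(majority) or ``N`` (minority); N-strand features are read as the reverse
complement of the J-strand slice.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._codes import revcomp

STRAND_J = "J"
STRAND_N = "N"

PCG_NAMES = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
TRNA_NAMES = tuple(
    f"trn{x}" for x in
    ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
     "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")
)
RRNA_NAMES = ("rrnS", "rrnL")
CONTROL_REGION = "CR"
CANONICAL_GENES = frozenset(PCG_NAMES) | frozenset(TRNA_NAMES) | frozenset(RRNA_NAMES)

# Common aliases seen in GenBank records and the literature.
_ALIASES = {
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "cytb": "cob", "cob": "cob", "cytochrome b": "cob",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6", "nad4l": "nad4L",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
    "srrna": "rrnS", "lrrna": "rrnL", "12s": "rrnS", "16s": "rrnL",
    "12s rrna": "rrnS", "16s rrna": "rrnL", "rrns": "rrnS", "rrnl": "rrnL",
    "s-rrna": "rrnS", "l-rrna": "rrnL",
    "control region": CONTROL_REGION, "a+t-rich region": CONTROL_REGION,
    "at-rich region": CONTROL_REGION, "d-loop": CONTROL_REGION, "cr": CONTROL_REGION,
}

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}
# Anticodons distinguishing the two Leu/Ser isoacceptor families.
_LEU_SER_BY_ANTICODON = {
    ("L", "TAG"): "trnL1", ("L", "TAA"): "trnL2",
    ("S", "GCT"): "trnS1", ("S", "TCT"): "trnS1", ("S", "TGA"): "trnS2",
}

VALID_SEQ_CHARS = frozenset("ACGTN")


class GenomeIOError(ValueError):
    pass


@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA molecule; ``sequence`` is upper-case over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise GenomeIOError("genome sequence must be non-empty")
        bad = set(seq) - VALID_SEQ_CHARS
        if bad:
            raise GenomeIOError(f"invalid characters in sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive J-strand slice; wraps the origin when end < start."""
        if not (1 <= start <= self.length and 1 <= end <= self.length):
            raise GenomeIOError(
                f"slice {start}..{end} outside genome of length {self.length}")
        if end >= start:
            return self.sequence[start - 1:end]
        return self.sequence[start - 1:] + self.sequence[:end]


@dataclass(frozen=True)
class Feature:
    """A stranded, 1-based annotation on a circular genome."""

    name: str
    ftype: str  # PCG | tRNA | rRNA | control_region | repeat_region | other
    start: int
    end: int
    strand: str = STRAND_J
    anticodon: str | None = None
    copy_index: int = 1

    def __post_init__(self):
        if self.strand not in (STRAND_J, STRAND_N):
            raise GenomeIOError(f"{self.name}: strand must be J or N")
        if self.start < 1 or self.end < 1:
            raise GenomeIOError(f"{self.name}: coordinates must be >= 1")
        if self.copy_index < 1:
            raise GenomeIOError(f"{self.name}: copy_index must be >= 1")

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    @property
    def key(self) -> tuple[str, int]:
        return (self.name, self.copy_index)


@dataclass
class FeatureTable:
    """Ordered gene annotations for one genome, sorted by J-strand start."""

    genome_id: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen: dict[tuple[str, int], int] = {}
        for f in self.features:
            if f.key in seen:
                raise GenomeIOError(
                    f"duplicate feature {f.name} copy {f.copy_index}; "
                    "disambiguate duplicated genes with copy_index")
            seen[f.key] = 1

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def validate_against(self, genome: CircularGenome) -> None:
        for f in self.features:
            if f.start > genome.length or f.end > genome.length:
                raise GenomeIOError(
                    f"feature {f.name} ({f.start}..{f.end}) outside genome "
                    f"of length {genome.length}")

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]


def canonical_gene_name(raw: str, anticodon: str | None = None) -> str:
    """Normalize a gene symbol to the package's canonical vocabulary.

    Handles case variants (COI, ND5, CytB...), tRNA-Xxx forms, and the
    Leu/Ser isoacceptor split (by explicit 1/2 suffix or by anticodon).
    Unknown names are returned stripped but otherwise untouched.
    """
    name = raw.strip()
    low = name.lower()
    if low in _ALIASES:
        return _ALIASES[low]
    if low in {g.lower(): g for g in CANONICAL_GENES}:
        return {g.lower(): g for g in CANONICAL_GENES}[low]
    if low.startswith("trna-") or low.startswith("trn"):
        rest = low.removeprefix("trna-").removeprefix("trna").removeprefix("trn")
        rest = rest.strip("-_ ")
        suffix = ""
        if rest and rest[-1] in "12":
            rest, suffix = rest[:-1], rest[-1]
        rest = rest.strip("()")
        aa = _AA3_TO_1.get(rest, rest.upper() if len(rest) == 1 else None)
        if aa:
            if aa in ("L", "S"):
                if suffix:
                    return f"trn{aa}{suffix}"
                if anticodon:
                    hit = _LEU_SER_BY_ANTICODON.get((aa, anticodon.upper()))
                    if hit:
                        return hit
                return f"trn{aa}1"
            return f"trn{aa}"
    return name


_FTYPE_TO_GB = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                "control_region": "misc_feature", "repeat_region": "repeat_region",
                "other": "misc_feature"}
_GB_TO_FTYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "repeat_region": "repeat_region", "D-loop": "control_region"}


def read_genbank(path: str | Path) -> tuple[CircularGenome, FeatureTable]:
    """Read a single-record GenBank flat file into the circular data model."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise GenomeIOError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    genome = CircularGenome(id=rec.id, sequence=str(rec.seq).upper())
    feats: list[Feature] = []
    for sf in rec.features:
        if sf.type == "source":
            continue
        ftype = _GB_TO_FTYPE.get(sf.type)
        quals = sf.qualifiers
        label = (quals.get("gene") or quals.get("product") or quals.get("note") or [sf.type])[0]
        if ftype is None:
            if canonical_gene_name(label) == CONTROL_REGION:
                ftype = "control_region"
            else:
                ftype = "other"
        anticodon = (quals.get("anticodon_seq") or [None])[0]
        copy_index = int((quals.get("copy_index") or [1])[0])
        loc = sf.location
        strand = STRAND_N if loc.strand == -1 else STRAND_J
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # an origin-spanning join: tail of the sequence followed by the head
            if len(parts) == 2 and int(parts[1].end) == len(rec.seq) and int(parts[0].start) == 0:
                start = int(parts[1].start) + 1
                end = int(parts[0].end)
            else:
                raise GenomeIOError(f"{label}: unsupported compound location {loc}")
        else:
            start = int(loc.start) + 1
            end = int(loc.end)
        name = canonical_gene_name(label, anticodon=anticodon)
        if ftype == "control_region":
            name = CONTROL_REGION
        if start > genome.length or end > genome.length:
            raise GenomeIOError(
                f"feature {name} ({start}..{end}) outside sequence of length {genome.length}")
        feats.append(Feature(name=name, ftype=ftype, start=start, end=end,
                             strand=strand, anticodon=anticodon, copy_index=copy_index))
    return genome, FeatureTable(genome_id=genome.id, features=feats)


def write_genbank(genome: CircularGenome, table: FeatureTable, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="circular mitochondrial genome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    for f in table:
        bio_strand = -1 if f.strand == STRAND_N else 1
        if f.wraps:
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, genome.length, strand=bio_strand),
                SimpleLocation(0, f.end, strand=bio_strand),
            ])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand=bio_strand)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon_seq"] = [f.anticodon]
        if f.copy_index != 1:
            quals["copy_index"] = [str(f.copy_index)]
        rec.features.append(SeqFeature(loc, type=_FTYPE_TO_GB[f.ftype], qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path: str | Path) -> CircularGenome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GenomeIOError(f"{path}: expected exactly one FASTA record")
    return CircularGenome(id=records[0].id, sequence=str(records[0].seq).upper())


def write_fasta(genome: CircularGenome, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta")


_TSV_COLS = ("gene", "type", "start", "end", "strand", "anticodon", "copy_index")


def read_feature_tsv(path: str | Path, genome_id: str = "") -> FeatureTable:
    """Read a feature table from tab-separated text (J-strand coordinates)."""
    feats = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            feats.append(Feature(
                name=row["gene"], ftype=row["type"],
                start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"],
                anticodon=row["anticodon"] or None,
                copy_index=int(row["copy_index"] or 1)))
    return FeatureTable(genome_id=genome_id or str(path), features=feats)


def write_feature_tsv(table: FeatureTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLS)
        for f in table:
            writer.writerow([f.name, f.ftype, f.start, f.end, f.strand,
                             f.anticodon or "", f.copy_index])


def extract_feature_seq(genome: CircularGenome, feature: Feature) -> str:
    """Coding-strand sequence of a feature (reverse complement for strand N)."""
    s = genome.slice(feature.start, feature.end)
    return revcomp(s) if feature.strand == STRAND_N else s


def intergenic_report(genome: CircularGenome, table: FeatureTable
                      ) -> list[tuple[str, str, int]]:
    """Spacer lengths between adjacent features around the circle.

    Returns ``(upstream, downstream, spacer)`` triples; negative spacers are
    overlaps in bp.  Feature lengths plus signed spacers always sum to the
    genome length.
    """
    if not table.features:
        raise GenomeIOError("intergenic_report requires a non-empty feature table")
    L = genome.length
    feats = table.features

    def label(f: Feature) -> str:
        return f.name if f.copy_index == 1 else f"{f.name}.{f.copy_index}"

    def linear_end(f: Feature) -> int:
        return f.start + f.length(L) - 1  # may exceed L for wrapping features

    out = []
    for f1, f2 in zip(feats, feats[1:]):
        out.append((label(f1), label(f2), f2.start - linear_end(f1) - 1))
    last, first = feats[-1], feats[0]
    out.append((label(last), label(first), first.start + L - linear_end(last) - 1))
    return out


def rotate_table(table: FeatureTable, genome: CircularGenome, offset: int) -> tuple[CircularGenome, FeatureTable]:
    """Rotate the origin of a circular genome by ``offset`` bp (for testing symmetry)."""
    L = genome.length
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in table:
        ns = (f.start - 1 - offset) % L + 1
        ne = (f.end - 1 - offset) % L + 1
        feats.append(replace(f, start=ns, end=ne))
    return CircularGenome(id=genome.id, sequence=seq), FeatureTable(genome_id=table.genome_id, features=feats)
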