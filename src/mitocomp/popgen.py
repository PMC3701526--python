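"""Intraspecific mitochondrial variation: variable sites, haplotypes,
mutation effects, haplotype networks, diversity and two-genome divergence.

The centrepiece use case is a population survey of a short mitochondrial
fragment (nad5 portion + trnH + intergenic + nad4 portion) sequenced from
hundreds of individuals: identical sequences collapse into frequency-
weighted haplotypes, which are joined into a minimum spanning network on
Hamming distances (all edges belonging to any minimum spanning tree are
retained, so tie topologies are not broken arbitrarily).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codes import INVERTEBRATE_MITO, translate_codon
from .genome_io import CircularGenome, FeatureTable, extract_feature_seq

AMBIGUOUS = frozenset("N-")


class PopgenError(ValueError):
    pass


@dataclass
class AlignedSet:
    """Equal-length aligned sequences with unique ids."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise PopgenError("ids and seqs differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise PopgenError("sequence ids must be unique")
        if not self.seqs:
            raise PopgenError("empty alignment")
        self.seqs = [s.upper() for s in self.seqs]
        L = len(self.seqs[0])
        if any(len(s) != L for s in self.seqs):
            raise PopgenError("aligned sequences must be equal length")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.seqs)


@dataclass(frozen=True)
class Segment:
    name: str
    start: int  # 1-based inclusive, fragment coordinates
    end: int
    coding: bool = False
    frame_offset: int = 0  # bases before the first complete codon


@dataclass(frozen=True)
class FragmentMap:
    segments: tuple[Segment, ...]

    def __post_init__(self):
        segs = self.segments
        if not segs:
            raise PopgenError("fragment map needs at least one segment")
        if segs[0].start != 1:
            raise PopgenError("segments must start at position 1")
        for s1, s2 in zip(segs, segs[1:]):
            if s2.start != s1.end + 1:
                raise PopgenError(
                    f"segments {s1.name} and {s2.name} are not contiguous")

    @property
    def length(self) -> int:
        return self.segments[-1].end

    def segment_at(self, pos: int) -> Segment:
        for s in self.segments:
            if s.start <= pos <= s.end:
                return s
        raise PopgenError(f"position {pos} outside fragment of length {self.length}")


@dataclass(frozen=True)
class VariableSite:
    position: int  # 1-based
    alleles: tuple[tuple[str, int], ...]  # (base, count), descending count


def call_variable_sites(a: AlignedSet) -> list[VariableSite]:
    """Positions with two or more observed non-ambiguous alleles."""
    if len(a) < 2:
        raise PopgenError("need at least two sequences")
    mat = np.array([list(s) for s in a.seqs])
    out = []
    for j in range(a.length):
        col = mat[:, j]
        keep = ~np.isin(col, list(AMBIGUOUS))
        bases, counts = np.unique(col[keep], return_counts=True)
        if len(bases) >= 2:
            order = np.argsort(-counts, kind="stable")
            out.append(VariableSite(
                position=j + 1,
                alleles=tuple((str(bases[i]), int(counts[i])) for i in order)))
    return out


@dataclass(frozen=True)
class Haplotype:
    name: str
    signature: str  # bases at the variable sites, in position order
    count: int
    members: tuple[str, ...]


@dataclass(frozen=True)
class HaplotypeTable:
    haplotypes: tuple[Haplotype, ...]
    variable_sites: tuple[VariableSite, ...]

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(v.position for v in self.variable_sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(h.name, h.signature, h.count) for h in self.haplotypes],
            columns=["haplotype", "signature", "count"])


def collapse_haplotypes(a: AlignedSet) -> HaplotypeTable:
    """Group identical signatures over the variable sites.

    Haplotypes are numbered Haplo1, Haplo2, ... by descending count, ties
    broken by first occurrence in the input.
    """
    sites = call_variable_sites(a) if len(a) > 1 else []
    pos0 = [v.position - 1 for v in sites]
    groups: dict[str, list[str]] = {}
    first_seen: dict[str, int] = {}
    for i, (sid, s) in enumerate(zip(a.ids, a.seqs)):
        sig = "".join(s[p] for p in pos0)
        groups.setdefault(sig, []).append(sid)
        first_seen.setdefault(sig, i)
    ordered = sorted(groups, key=lambda sig: (-len(groups[sig]), first_seen[sig]))
    haps = tuple(
        Haplotype(name=f"Haplo{k + 1}", signature=sig,
                  count=len(groups[sig]), members=tuple(groups[sig]))
        for k, sig in enumerate(ordered))
    return HaplotypeTable(haplotypes=haps, variable_sites=tuple(sites))


@dataclass(frozen=True)
class MutationEffect:
    position: int
    segment: str
    kind: str  # coding | noncoding
    codon_number: int | None = None
    codon_position: int | None = None
    synonymous: bool | None = None
    aa_change: str | None = None  # e.g. "M93L"; None for synonymous/noncoding


def classify_mutation(site: int, ref: str, alt: str, fmap: FragmentMap,
                      code: int = INVERTEBRATE_MITO) -> MutationEffect:
    """Locate a substitution within the fragment and call its coding effect.

    For a coding segment whose frame starts ``frame_offset`` bases after the
    segment start, position p falls in codon ``(p - start - offset)//3 + 1``.
    """
    seg = fmap.segment_at(site)
    ref = ref.upper()
    alt = alt.upper()
    if len(alt) != 1:
        raise PopgenError("alt allele must be a single base")
    if not seg.coding:
        return MutationEffect(position=site, segment=seg.name, kind="noncoding")
    rel = site - seg.start - seg.frame_offset
    if rel < 0:
        return MutationEffect(position=site, segment=seg.name, kind="noncoding")
    codon_number = rel // 3 + 1
    codon_pos = rel % 3 + 1
    codon_start = site - (codon_pos - 1)
    codon = ref[codon_start - 1:codon_start + 2]
    if len(codon) < 3 or codon_start + 2 > seg.end:
        return MutationEffect(position=site, segment=seg.name, kind="coding",
                              codon_number=codon_number, codon_position=codon_pos)
    alt_codon = codon[:codon_pos - 1] + alt + codon[codon_pos:]
    aa_ref = translate_codon(codon, code)
    aa_alt = translate_codon(alt_codon, code)
    syn = aa_ref == aa_alt
    change = None if syn else f"{aa_ref}{codon_number}{aa_alt}"
    return MutationEffect(position=site, segment=seg.name, kind="coding",
                          codon_number=codon_number, codon_position=codon_pos,
                          synonymous=syn, aa_change=change)


@dataclass(frozen=True)
class NetworkEdge:
    h1: str
    h2: str
    positions: tuple[int, ...]  # fragment positions differing between endpoints

    @property
    def weight(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[Haplotype, ...]
    edges: tuple[NetworkEdge, ...]


def _hamming_positions(s1: str, s2: str, positions: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(p for x, y, p in zip(s1, s2, positions) if x != y)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        self.parent[self.find(x)] = self.find(y)


def build_network(t: HaplotypeTable) -> HaplotypeNetwork:
    """Minimum spanning network over haplotype Hamming distances.

    Kruskal by weight class: within each distance class, every edge joining
    two components that were separate *before the class was processed* is
    retained — i.e. the union of all minimum spanning trees, so equally
    parsimonious connections are all kept.
    """
    haps = t.haplotypes
    if not haps:
        raise PopgenError("empty haplotype table")
    n = len(haps)
    if n == 1:
        return HaplotypeNetwork(nodes=haps, edges=())
    positions = t.positions
    all_edges = []
    for i in range(n):
        for j in range(i + 1, n):
            diff = _hamming_positions(haps[i].signature, haps[j].signature, positions)
            all_edges.append((len(diff), i, j, diff))
    all_edges.sort(key=lambda e: e[0])
    uf = _UnionFind(n)
    kept: list[NetworkEdge] = []
    k = 0
    while k < len(all_edges):
        w = all_edges[k][0]
        cls = []
        while k < len(all_edges) and all_edges[k][0] == w:
            cls.append(all_edges[k])
            k += 1
        # an edge is in some MST iff its endpoints lie in different components
        # of the forest built from strictly smaller weights
        before = {i: uf.find(i) for i in range(n)}
        useful = [(i, j, diff) for _, i, j, diff in cls if before[i] != before[j]]
        for i, j, diff in useful:
            kept.append(NetworkEdge(haps[i].name, haps[j].name, diff))
            uf.union(i, j)
    if len({uf.find(i) for i in range(n)}) != 1:
        raise PopgenError("network not connected")  # cannot happen on a complete graph
    return HaplotypeNetwork(nodes=haps, edges=tuple(kept))


def nucleotide_diversity(a: AlignedSet) -> float:
    """Mean pairwise p-distance (pi); ambiguous positions excluded per pair."""
    if len(a) < 2:
        raise PopgenError("need at least two sequences")
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in a.seqs])
    amb = np.isin(mat, np.frombuffer("N-".encode(), dtype=np.uint8))
    n = len(a)
    total = 0.0
    npairs = 0
    for i in range(n - 1):
        diff = mat[i + 1:] != mat[i]
        ok = ~(amb[i + 1:] | amb[i])
        lengths = ok.sum(axis=1)
        diffs = (diff & ok).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(lengths > 0, diffs / np.maximum(lengths, 1), 0.0)
        total += float(d.sum())
        npairs += len(d)
    return total / npairs


@dataclass(frozen=True)
class GeneDivergence:
    gene: str
    length: int
    substitutions: int

    @property
    def rate(self) -> float:
        return self.substitutions / self.length


@dataclass(frozen=True)
class DivergenceReport:
    per_gene: tuple[GeneDivergence, ...]
    excluded: tuple[tuple[str, str], ...]  # (gene, reason)

    def rate_of(self, gene: str) -> float:
        for g in self.per_gene:
            if g.gene == gene:
                return g.rate
        raise KeyError(gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene, g.length, g.substitutions, g.rate) for g in self.per_gene],
            columns=["gene", "length", "substitutions", "rate"])


def pairwise_gene_divergence(genome_a: CircularGenome, table_a: FeatureTable,
                             genome_b: CircularGenome, table_b: FeatureTable,
                             ftypes: tuple[str, ...] = ("PCG", "rRNA", "tRNA")
                             ) -> DivergenceReport:
    """Per-gene substitution rates between two annotated genomes.

    Genes are matched by name and compared position-wise on the coding
    strand; genes whose lengths differ between the genomes are excluded
    with a reason rather than aligned silently.
    """
    feats_a = {f.key: f for f in table_a if f.ftype in ftypes}
    feats_b = {f.key: f for f in table_b if f.ftype in ftypes}
    shared = sorted(set(feats_a) & set(feats_b))
    if not shared:
        raise PopgenError("no shared genes between the two tables")
    per_gene = []
    excluded = []
    for key in shared:
        fa, fb = feats_a[key], feats_b[key]
        name = fa.name if fa.copy_index == 1 else f"{fa.name}.{fa.copy_index}"
        sa = extract_feature_seq(genome_a, fa)
        sb = extract_feature_seq(genome_b, fb)
        if len(sa) != len(sb):
            excluded.append((name, f"length differs ({len(sa)} vs {len(sb)} bp)"))
            continue
        subs = sum(1 for x, y in zip(sa, sb)
                   if x != y and x not in AMBIGUOUS and y not in AMBIGUOUS)
        per_gene.append(GeneDivergence(gene=name, length=len(sa), substitutions=subs))
    return DivergenceReport(per_gene=tuple(per_gene), excluded=tuple(excluded))


@dataclass(frozen=True)
class IndelEvent:
    kind: str  # "insertion" (gap in A) or "deletion" (gap in B)
    column_start: int  # 1-based alignment column
    length: int
    position_a: int  # 1-based position in A after which the event occurs


def indel_report(aligned_a: str, aligned_b: str) -> list[IndelEvent]:
    """Maximal gap runs in a pairwise alignment, as indel events of A -> B."""
    if len(aligned_a) != len(aligned_b):
        raise PopgenError("aligned sequences must have equal length")
    events = []
    i = 0
    L = len(aligned_a)
    pos_a = 0
    while i < L:
        ca, cb = aligned_a[i], aligned_b[i]
        if ca == "-" and cb == "-":
            raise PopgenError(f"column {i + 1} is gap in both sequences")
        if ca == "-" or cb == "-":
            kind = "insertion" if ca == "-" else "deletion"
            j = i
            while j < L and ((aligned_a[j] == "-") if kind == "insertion"
                             else (aligned_b[j] == "-")):
                if aligned_a[j] == "-" and aligned_b[j] == "-":
                    break
                j += 1
            events.append(IndelEvent(kind=kind, column_start=i + 1,
                                     length=j - i, position_a=pos_a))
            if kind == "deletion":
                pos_a += j - i
            i = j
        else:
            pos_a += 1
            i += 1
    return events
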