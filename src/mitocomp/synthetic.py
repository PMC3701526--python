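"""Seeded generators for every input the analysis modules consume.

The default specifications emulate a planthopper-like mitogenome: a
~17 kb circle carrying the 37 canonical genes in the delphacid gene order,
A+T-biased composition (~0.77), a control region with a 21-bp tandem-repeat
array (tens of copies, occasional degenerate copies) and a 23-bp poly-T
run, tRNAs that fold into cloverleafs (optionally with a loop-only D arm),
and a 309-individual population survey of a 642-bp fragment spanning
nad5/trnH/nad4 that collapses into 16 haplotypes.

Composition targeting samples bases from the target distribution and then
repairs any residual deviation only at freely exchangeable positions
(non-coding fill and third positions of four-fold degenerate codons), so
start/stop codons, tRNA stems and the repeat array are never corrupted.
All outputs are deterministic functions of their spec (including seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from ._codes import (INVERTEBRATE_MITO, anticodon_for, fourfold_codons,
                     revcomp, stop_codons, synonymous_families)
from .genome_io import (CONTROL_REGION, PCG_NAMES, CircularGenome, Feature,
                        FeatureTable, STRAND_J, STRAND_N)
from .gene_order import GeneOrder, load_packaged_order, parse_signed
from .popgen import AlignedSet, FragmentMap, PopgenError, Segment
from .trna_structure import (DEFAULT_PARAMS, FoldFailure, FoldParams,
                             GENE_TO_AA, classify_structure, fold_cloverleaf)


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tRNA generator
# ---------------------------------------------------------------------------

_PAIR_CHOICES = [("G", "C"), ("C", "G"), ("A", "T"), ("T", "A")]
_PAIR_WEIGHTS = [0.3, 0.3, 0.2, 0.2]


def _stem(rng: np.random.Generator, n: int) -> tuple[str, str]:
    """A perfectly pairing stem: (5' side, 3' side)."""
    idx = rng.choice(len(_PAIR_CHOICES), size=n, p=_PAIR_WEIGHTS)
    left = "".join(_PAIR_CHOICES[i][0] for i in idx)
    right = "".join(_PAIR_CHOICES[i][1] for i in reversed(idx))
    return left, right


def make_trna_seq(amino_acid: str, d_status: str = "full", t_status: str = "full",
                  seed: int = 0, target_length: int | None = None,
                  anticodon: str | None = None,
                  params: FoldParams = DEFAULT_PARAMS,
                  code: int = INVERTEBRATE_MITO) -> tuple[str, str]:
    """Build a tRNA sequence folding to the requested arm configuration.

    Returns ``(sequence, anticodon)``.  ``d_status``/``t_status`` are
    ``full`` or ``loop_only``; extra length (to ``target_length``) is
    absorbed by the variable region.  The construction is verified by
    folding; an unsatisfiable request raises SyntheticError.
    """
    if d_status not in ("full", "loop_only") or t_status not in ("full", "loop_only"):
        raise SyntheticError("arm statuses must be 'full' or 'loop_only'")
    if anticodon is None:
        anticodon = anticodon_for(amino_acid, code)
    for attempt in range(60):
        rng = np.random.default_rng((seed + attempt * 1_000_003) % 2**31)
        acc5, acc3 = _stem(rng, params.acceptor_target)
        parts = [acc5, "AA"]
        if d_status == "full":
            d5, d3 = _stem(rng, params.d_target)
            parts += [d5, "AAAA", d3]
        else:
            parts.append("A" * 8)
        parts.append("A")
        ac5, ac3 = _stem(rng, params.anticodon_target)
        parts += [ac5, "AA" + anticodon + "AA", ac3]
        var = 4
        base_len = (len("".join(parts)) + var + params.acceptor_target
                    + (2 * params.t_target + 5 if t_status == "full" else 10))
        if target_length is not None:
            extra = target_length - base_len
            if extra < 0 or var + extra > params.var_max:
                raise SyntheticError(
                    f"target length {target_length} unreachable (base {base_len})")
            var += extra
        parts.append("A" * var)
        if t_status == "full":
            t5, t3 = _stem(rng, params.t_target)
            parts += [t5, "AAAAA", t3]
        else:
            parts.append("A" * 10)
        parts.append(acc3)
        seq = "".join(parts)
        folded = fold_cloverleaf(seq, expected_anticodon=anticodon, params=params,
                                 code=code)
        if isinstance(folded, FoldFailure):
            continue
        want = {"full": "full", "loop_only": "loop_only"}
        if (folded.acceptor.status == "full"
                and folded.d_arm.status == want[d_status]
                and folded.t_arm.status == want[t_status]
                and folded.anticodon == anticodon):
            return seq, anticodon
    raise SyntheticError(
        f"could not satisfy arm config d={d_status}, t={t_status} for {amino_acid}")


# ---------------------------------------------------------------------------
# Genome generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatSpec:
    """Control-region tandem-repeat array plus poly-T specification."""

    unit: str = "GGAAAAAATGTCACGTTTTTC"
    copies: int = 55
    degenerate: tuple[int, ...] = (2,)  # 1-based copy indices rendered degenerate
    variable_last_base: tuple[str, ...] = ("C", "T")
    poly_t: int = 23


def _default_pcgs() -> dict[str, tuple[int, str, str]]:
    """gene -> (internal codon count, start, stop); total length follows."""
    return {
        "cox1": (511, "ATG", "T"), "cox2": (225, "ATG", "TAA"),
        "cox3": (261, "ATG", "T"), "cob": (377, "ATG", "TAA"),
        "nad1": (307, "ATT", "TAA"), "nad2": (324, "ATT", "TAA"),
        "nad3": (116, "ATA", "TAA"), "nad4": (445, "ATG", "TAA"),
        "nad4L": (94, "ATG", "TAA"), "nad5": (572, "ATT", "T"),
        "nad6": (172, "ATT", "TAA"), "atp6": (224, "ATA", "T"),
        "atp8": (31, "ATT", "TAA"),
    }


@dataclass(frozen=True)
class GenomeSpec:
    genome_id: str = "synthetic-mitogenome"
    order_name: str = "delphacid"  # packaged gene order realised by the genome
    comp: tuple[float, float, float, float] = (0.42, 0.35, 0.094, 0.136)  # A,T,G,C
    pcgs: dict[str, tuple[int, str, str]] = field(default_factory=_default_pcgs)
    rrna_lengths: dict[str, int] = field(
        default_factory=lambda: {"rrnS": 747, "rrnL": 1219})
    trna_arms: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {"trnS1": ("loop_only", "full")})
    trna_copies: dict[str, int] = field(default_factory=dict)  # e.g. {"trnC": 3}
    cr: RepeatSpec = field(default_factory=RepeatSpec)
    cr_flanks: tuple[int, int] = (600, 649)
    spacer: int = 2
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.comp) - 1) > 1e-9:
            raise SyntheticError("composition fractions must sum to 1")


def _random_bases(rng, n: int, comp) -> list[str]:
    return list(rng.choice(list("ATGC"), size=n, p=list(comp)))


def _random_codons(rng, n: int, comp, code: int) -> tuple[list[str], list[int]]:
    """n non-stop codons sampled base-wise; returns (codons, repairable offsets)."""
    stops = stop_codons(code)
    fourfold = fourfold_codons(code)
    codons: list[str] = []
    repairable: list[int] = []
    while len(codons) < n:
        codon = "".join(rng.choice(list("ATGC"), size=3, p=list(comp)))
        if codon in stops:
            continue
        if codon in fourfold:
            repairable.append(len(codons) * 3 + 2)
        codons.append(codon)
    return codons, repairable


def _degrade_copy(rng, unit: str, skip_last: bool) -> str:
    """Substitute enough positions to push identity below 0.8.

    The variable last column is left untouched so the planted mismatch
    count is unambiguous regardless of which base the consensus carries.
    """
    span = len(unit) - 1 if skip_last else len(unit)
    n_sub = max(5, int(len(unit) * 0.24))
    pos = rng.choice(span, size=n_sub, replace=False)
    out = list(unit)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _control_region(rng, spec: RepeatSpec, flanks: tuple[int, int], comp
                    ) -> tuple[str, list[int]]:
    """Assemble the control region; returns (sequence, repairable offsets)."""
    parts: list[str] = []
    repairable: list[int] = []
    off = 0

    def add(seg: str, free: bool):
        nonlocal off
        parts.append(seg)
        if free:
            repairable.extend(range(off, off + len(seg)))
        off += len(seg)

    add("".join(_random_bases(rng, flanks[0], comp)), free=True)
    unit = spec.unit.upper()
    for k in range(1, spec.copies + 1):
        copy = unit
        if spec.variable_last_base and len(spec.variable_last_base) > 1:
            copy = copy[:-1] + rng.choice(list(spec.variable_last_base))
        if k in spec.degenerate:
            copy = _degrade_copy(rng, copy,
                                 skip_last=len(spec.variable_last_base) > 1)
        add(copy, free=False)
    if spec.poly_t:
        add("A", free=False)  # insulate the run from neighbouring Ts
        add("T" * spec.poly_t, free=False)
        add("A", free=False)
    add("".join(_random_bases(rng, flanks[1], comp)), free=True)
    return "".join(parts), repairable


def make_mitogenome(spec: GenomeSpec) -> tuple[CircularGenome, FeatureTable]:
    """Realise a GenomeSpec as an annotated circular genome.

    The gene order is realised exactly; PCGs begin with their configured
    start codon and end with TAA/TAG or a planted incomplete stop (T/TA);
    tRNAs are built by make_trna_seq; the control region carries the
    specified repeat array and poly-T run.  Realised A+T content matches
    the target within +-0.01 for genomes of >= 10 kb (a repair pass at
    free positions enforces it); an unreachable composition raises.
    """
    rng = np.random.default_rng(spec.seed % 2**31)
    order = load_packaged_order(spec.order_name)
    segments: list[str] = []  # J-strand segments
    features: list[Feature] = []
    repairable: list[int] = []  # absolute 0-based J-strand positions
    pos = 0

    def push(seg: str, free_offsets=None, feature=None):
        nonlocal pos
        segments.append(seg)
        if free_offsets is not None:
            repairable.extend(pos + o for o in free_offsets)
        if feature is not None:
            features.append(replace(feature, start=pos + 1, end=pos + len(seg)))
        pos += len(seg)

    def push_spacer():
        if spec.spacer:
            push("".join(_random_bases(rng, spec.spacer, spec.comp)),
                 free_offsets=range(spec.spacer))

    entries: list[tuple[str, int, int]] = []  # (signed label, sign, copy_index)
    for lab in order.to_strings():
        name, sign = parse_signed(lab)
        copies = spec.trna_copies.get(name, 1)
        for ci in range(1, copies + 1):
            entries.append((name, sign, ci))

    for name, sign, copy_index in entries:
        strand = STRAND_J if sign > 0 else STRAND_N
        sub_seed = int(rng.integers(0, 2**31))
        if name in PCG_NAMES:
            ncod, start_codon, stop = spec.pcgs[name]
            codons, rep = _random_codons(rng, ncod, spec.comp, INVERTEBRATE_MITO)
            coding = start_codon + "".join(codons) + stop
            rep_abs = [3 + r for r in rep]
            if sign < 0:
                seg = revcomp(coding)
                rep_abs = [len(seg) - 1 - r for r in rep_abs]
            else:
                seg = coding
            push(seg, free_offsets=rep_abs,
                 feature=Feature(name, "PCG", 1, 1, strand, copy_index=copy_index))
        elif name in ("rrnS", "rrnL"):
            n = spec.rrna_lengths[name]
            seg = "".join(_random_bases(rng, n, spec.comp))
            push(seg, free_offsets=range(n),
                 feature=Feature(name, "rRNA", 1, 1, strand, copy_index=copy_index))
        elif name in GENE_TO_AA:
            d_st, t_st = spec.trna_arms.get(name, ("full", "full"))
            seq, anticodon = make_trna_seq(GENE_TO_AA[name], d_st, t_st,
                                           seed=sub_seed)
            seg = revcomp(seq) if sign < 0 else seq
            push(seg, feature=Feature(name, "tRNA", 1, 1, strand,
                                      anticodon=anticodon, copy_index=copy_index))
        else:
            raise SyntheticError(f"unknown gene label {name!r} in order")
        push_spacer()

    cr_seq, cr_rep = _control_region(rng, spec.cr, spec.cr_flanks, spec.comp)
    push(cr_seq, free_offsets=cr_rep,
         feature=Feature(CONTROL_REGION, "control_region", 1, 1, STRAND_J))
    push_spacer()

    seq = list("".join(segments))
    _repair_composition(rng, seq, repairable, spec.comp)
    genome = CircularGenome(id=spec.genome_id, sequence="".join(seq))
    table = FeatureTable(genome_id=spec.genome_id, features=features)
    table.validate_against(genome)
    return genome, table


def _repair_composition(rng, seq: list[str], repairable: list[int],
                        comp, tol: float = 0.002) -> None:
    target_at = comp[0] + comp[1]
    L = len(seq)
    at = sum(1 for b in seq if b in "AT")
    order = rng.permutation(len(repairable))
    p_a = comp[0] / (comp[0] + comp[1])
    p_g = comp[2] / (comp[2] + comp[3])
    for idx in order:
        frac = at / L
        if abs(frac - target_at) <= tol:
            return
        p = repairable[idx]
        b = seq[p]
        if frac < target_at and b in "GC":
            seq[p] = "A" if rng.random() < p_a else "T"
            at += 1
        elif frac > target_at and b in "AT":
            seq[p] = "G" if rng.random() < p_g else "C"
            at -= 1
    if abs(at / L - target_at) > 0.01:
        raise SyntheticError(
            f"composition target A+T={target_at:.3f} infeasible: "
            f"reached {at / L:.3f} after exhausting free positions")


# ---------------------------------------------------------------------------
# Population generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeDef:
    mutations: tuple[tuple[int, str], ...]  # (1-based fragment position, alt base)
    count: int


@dataclass(frozen=True)
class PopulationSpec:
    reference: str
    fmap: FragmentMap
    haplotypes: tuple[HaplotypeDef, ...]
    seed: int = 0

    def __post_init__(self):
        L = len(self.reference)
        if self.fmap.length != L:
            raise SyntheticError("fragment map does not cover the reference")
        for h in self.haplotypes:
            seen = {}
            for p, alt in h.mutations:
                if not 1 <= p <= L:
                    raise SyntheticError(f"mutation position {p} outside fragment")
                if p in seen and seen[p] != alt:
                    raise SyntheticError(f"conflicting alleles at position {p}")
                if alt == self.reference[p - 1]:
                    raise SyntheticError(f"alt equals reference base at {p}")
                seen[p] = alt

    @property
    def sample_size(self) -> int:
        return sum(h.count for h in self.haplotypes)


def make_population(spec: PopulationSpec) -> AlignedSet:
    """Exact planted haplotype counts, planted mutations only, seeded order."""
    rng = np.random.default_rng(spec.seed % 2**31)
    seqs = []
    for h in spec.haplotypes:
        s = list(spec.reference)
        for p, alt in h.mutations:
            s[p - 1] = alt
        seqs.extend(["".join(s)] * h.count)
    order = rng.permutation(len(seqs))
    ids = [f"ind{i + 1:04d}" for i in range(len(seqs))]
    return AlignedSet(ids=ids, seqs=[seqs[k] for k in order])


def default_fragment_map() -> FragmentMap:
    """The 642-bp survey fragment: nad5 portion (482 bp, frame from position
    1) + complete trnH (62 bp) + 2 intergenic nt + nad4 portion (96 bp)."""
    return FragmentMap(segments=(
        Segment("nad5", 1, 482, coding=True, frame_offset=0),
        Segment("trnH", 483, 544, coding=False),
        Segment("intergenic", 545, 546, coding=False),
        Segment("nad4", 547, 642, coding=True, frame_offset=0),
    ))


def default_survey_spec(seed: int = 0) -> PopulationSpec:
    """A 309-individual survey collapsing into 16 haplotypes.

    Haplo1/2/3 carry 178/93/18 individuals, separated by nonsynonymous
    mutations at fragment positions 277 (M93L) and 391 (D131N) in nad5;
    the remaining 20 individuals spread over 7 doubleton and 6 singleton
    haplotypes defined by 12 further nad5 sites (one nonsynonymous pair in
    Haplo4) and one intergenic site — 15 variable nad5 sites plus one
    intergenic site in total.
    """
    rng = np.random.default_rng((seed + 17) % 2**31)
    comp = (0.42, 0.35, 0.094, 0.136)
    n_codons = 482 // 3  # 160 full codons; 2 trailing bases
    codons, _ = _random_codons(rng, n_codons, comp, INVERTEBRATE_MITO)
    syn_codon_numbers = (15, 25, 30, 35, 40, 50, 55, 60, 70, 75, 80, 85)
    for c in syn_codon_numbers:
        codons[c - 1] = "GGA"  # four-fold Gly: third-position change is silent
    codons[20 - 1] = "ATA"   # Met, ATA -> TTA (L) at first position is nonsyn
    codons[93 - 1] = "ATA"   # position 277: M93L when A -> T
    codons[131 - 1] = "GAT"  # position 391: D131N when G -> A
    nad5 = "".join(codons) + "".join(_random_bases(rng, 2, comp))
    trnh, _ = make_trna_seq("H", seed=(seed + 31) % 2**31, target_length=62)
    nad4_codons, _ = _random_codons(rng, 96 // 3, comp, INVERTEBRATE_MITO)
    reference = nad5 + trnh + "AT" + "".join(nad4_codons)
    syn_sites = tuple(3 * c for c in syn_codon_numbers)  # third positions
    haps = [
        HaplotypeDef((), 178),
        HaplotypeDef(((277, "T"),), 93),
        HaplotypeDef(((391, "A"),), 18),
        # Haplo4: one nonsynonymous (codon 20, position 58) + one silent site
        HaplotypeDef(((58, "T"), (syn_sites[0], "G")), 2),
    ]
    for s in syn_sites[1:7]:
        haps.append(HaplotypeDef(((s, "G"),), 2))
    for s in syn_sites[7:]:
        haps.append(HaplotypeDef(((s, "G"),), 1))
    haps.append(HaplotypeDef(((545, "G"),), 1))  # the intergenic site
    return PopulationSpec(reference=reference, fmap=default_fragment_map(),
                          haplotypes=tuple(haps), seed=seed)


# ---------------------------------------------------------------------------
# Two-genome divergence generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelSpec:
    gene: str
    kind: str  # "insertion" | "deletion"
    length: int
    where: str = "start"  # "start" | "end"

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion"):
            raise SyntheticError("indel kind must be insertion or deletion")
        if self.where not in ("start", "end"):
            raise SyntheticError("indel where must be start or end")
        if self.length < 1:
            raise SyntheticError("indel length must be positive")


@dataclass(frozen=True)
class DivergedPair:
    genome: CircularGenome
    table: FeatureTable
    aligned_a: str
    aligned_b: str


def mutate_genome(genome: CircularGenome, table: FeatureTable,
                  per_gene_substitutions: dict[str, int] | None = None,
                  indels: list[IndelSpec] | None = None,
                  seed: int = 0) -> DivergedPair:
    """Derive a diverged copy with exact planted per-gene substitution
    counts (uniform positions without replacement) and the specified
    indels, plus the implied pairwise alignment.

    Features must be non-overlapping and non-wrapping (true for all
    generator genomes).  Genes receiving indels change length, so a
    subsequent divergence comparison excludes them with a reason.
    """
    per_gene_substitutions = per_gene_substitutions or {}
    indels = indels or []
    rng = np.random.default_rng(seed % 2**31)
    by_gene: dict[str, list[IndelSpec]] = {}
    for spec in indels:
        bucket = by_gene.setdefault(spec.gene, [])
        if any(b.where == spec.where for b in bucket):
            raise SyntheticError(
                f"overlapping indel spans: two '{spec.where}' indels on {spec.gene}")
        bucket.append(spec)
    feats = table.features
    for f1, f2 in zip(feats, feats[1:]):
        if f1.wraps or f1.end >= f2.start:
            raise SyntheticError("mutate_genome requires sorted, non-overlapping, "
                                 "non-wrapping features")
    # decompose the J strand into blocks of (feature | None, sequence)
    blocks: list[tuple[Feature | None, str]] = []
    cursor = 1
    for f in feats:
        if f.start > cursor:
            blocks.append((None, genome.slice(cursor, f.start - 1)))
        blocks.append((f, genome.slice(f.start, f.end)))
        cursor = f.end + 1
    if cursor <= genome.length:
        blocks.append((None, genome.slice(cursor, genome.length)))

    names = {f.name for f in feats}
    for g in set(per_gene_substitutions) | set(by_gene):
        if g not in names:
            raise SyntheticError(f"unknown gene {g!r} in mutation spec")

    al_a: list[str] = []
    al_b: list[str] = []
    new_feats: list[Feature] = []
    pos_b = 0
    for f, seg in blocks:
        b_seg = list(seg)
        if f is not None:
            nsub = per_gene_substitutions.get(f.name, 0) if f.copy_index == 1 else 0
            if nsub:
                if nsub > len(seg):
                    raise SyntheticError(f"{f.name}: more substitutions than bases")
                for off in rng.choice(len(seg), size=nsub, replace=False):
                    b_seg[off] = rng.choice([b for b in "ACGT" if b != b_seg[off]])
        a_al, b_al = seg, "".join(b_seg)
        if f is not None and f.name in by_gene and f.copy_index == 1:
            for spec in sorted(by_gene[f.name], key=lambda s: s.where):
                if spec.kind == "deletion":
                    if spec.length >= len(b_al.replace("-", "")):
                        raise SyntheticError(f"{f.name}: deletion longer than gene")
                    if spec.where == "start":
                        b_al = "-" * spec.length + b_al[spec.length:]
                    else:
                        b_al = b_al[:-spec.length] + "-" * spec.length
                else:
                    ins = "".join(rng.choice(list("ATGC"), size=spec.length,
                                             p=[0.42, 0.35, 0.094, 0.136]))
                    if spec.where == "start":
                        a_al = "-" * spec.length + a_al
                        b_al = ins + b_al
                    else:
                        a_al = a_al + "-" * spec.length
                        b_al = b_al + ins
        al_a.append(a_al)
        al_b.append(b_al)
        b_len = len(b_al) - b_al.count("-")
        if f is not None:
            new_feats.append(replace(f, start=pos_b + 1, end=pos_b + b_len))
        pos_b += b_len
    genome_b = CircularGenome(id=genome.id + "-derived",
                              sequence="".join(al_b).replace("-", ""))
    table_b = FeatureTable(genome_id=genome_b.id, features=new_feats)
    table_b.validate_against(genome_b)
    return DivergedPair(genome=genome_b, table=table_b,
                        aligned_a="".join(al_a), aligned_b="".join(al_b))


def spec_from_json(path) -> GenomeSpec:
    """Load a GenomeSpec from a JSON file (keys mirror the dataclass)."""
    raw = json.loads(open(path).read())
    if "cr" in raw:
        raw["cr"] = RepeatSpec(**{**raw["cr"],
                                  "degenerate": tuple(raw["cr"].get("degenerate", ())),
                                  "variable_last_base": tuple(
                                      raw["cr"].get("variable_last_base", ("C", "T")))})
    if "pcgs" in raw:
        raw["pcgs"] = {k: tuple(v) for k, v in raw["pcgs"].items()}
    if "trna_arms" in raw:
        raw["trna_arms"] = {k: tuple(v) for k, v in raw["trna_arms"].items()}
    for key in ("comp", "cr_flanks"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return GenomeSpec(**raw)
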