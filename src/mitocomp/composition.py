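"""Base composition, strand skews, codon usage (RSCU) and start/stop accounting.

Strand asymmetry is summarised with AT-skew = (A-T)/(A+T) and
GC-skew = (G-C)/(G+C), computed on the J-strand for whole genomes and on
the coding strand for per-gene reports.  Codon statistics use the
invertebrate mitochondrial code; relative synonymous codon usage of codon
c in a family of k synonyms is RSCU_c = k * n_c / sum(family counts).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from ._codes import (INVERTEBRATE_MITO, family_size, sense_codons,
                     stop_codons, translate_codon)


@dataclass(frozen=True)
class BaseCounts:
    a: int = 0
    t: int = 0
    g: int = 0
    c: int = 0
    n_other: int = 0

    def __post_init__(self):
        if min(self.a, self.t, self.g, self.c, self.n_other) < 0:
            raise ValueError("base counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.t + self.g + self.c + self.n_other

    @property
    def unambiguous(self) -> int:
        return self.a + self.t + self.g + self.c


@dataclass(frozen=True)
class SkewReport:
    """AT/GC content and skew; a skew is None when its denominator is zero."""

    at_content: float | None
    at_skew: float | None
    gc_skew: float | None


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    rscu: dict[str, float]
    aa_freq: dict[str, float]
    stop_counts: dict[str, int]
    total_codons: int
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, translate_codon(c), self.counts[c], self.rscu[c])
                for c in sorted(self.counts)]
        return pd.DataFrame(rows, columns=["codon", "aa", "count", "rscu"])


@dataclass(frozen=True)
class CodonReport:
    gene: str
    start_codon: str
    stop_codon: str
    stop_complete: bool


def count_bases(seq: str) -> BaseCounts:
    """Exact per-base tally; ambiguity codes are counted as ``n_other``."""
    c = Counter(seq.upper())
    acgt = c["A"] + c["C"] + c["G"] + c["T"]
    return BaseCounts(a=c["A"], t=c["T"], g=c["G"], c=c["C"],
                      n_other=len(seq) - acgt)


def skew_report(counts: BaseCounts) -> SkewReport:
    at = counts.a + counts.t
    gc = counts.g + counts.c
    at_content = at / (at + gc) if at + gc else None
    at_skew = (counts.a - counts.t) / at if at else None
    gc_skew = (counts.g - counts.c) / gc if gc else None
    return SkewReport(at_content=at_content, at_skew=at_skew, gc_skew=gc_skew)


def codon_usage(cds_list: list[str], code: int = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Tally codon usage across coding sequences and derive RSCU.

    Codons are read in frame from position 1 of every CDS; a trailing
    partial codon (an incomplete stop) is excluded, full stop codons are
    tallied separately, and codons containing ambiguity codes are skipped
    and recorded.
    """
    stops = stop_codons(code)
    counts: Counter[str] = Counter()
    stop_counts: Counter[str] = Counter()
    skipped: list[str] = []
    for cds in cds_list:
        if len(cds) < 3:
            raise ValueError("each CDS must be at least one codon long")
        seq = cds.upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if set(codon) - set("ACGT"):
                skipped.append(codon)
            elif codon in stops:
                stop_counts[codon] += 1
            else:
                counts[codon] += 1
    total = sum(counts.values())
    fam = family_size(code)
    aa_totals: Counter[str] = Counter()
    for codon, n in counts.items():
        aa_totals[translate_codon(codon, code)] += n
    rscu = {}
    full_counts = {}
    for codon in sense_codons(code):
        n = counts.get(codon, 0)
        full_counts[codon] = n
        aa = translate_codon(codon, code)
        fam_total = aa_totals.get(aa, 0)
        rscu[codon] = (n * fam[codon] / fam_total) if fam_total else 0.0
    aa_freq = {aa: n / total for aa, n in sorted(aa_totals.items())} if total else {}
    return CodonUsageTable(counts=full_counts, rscu=rscu, aa_freq=aa_freq,
                           stop_counts=dict(stop_counts), total_codons=total,
                           skipped=skipped)


def start_stop_report(cds: str, gene: str = "", code: int = INVERTEBRATE_MITO) -> CodonReport:
    """Start codon plus (possibly incomplete, T/TA) stop codon of a CDS."""
    if len(cds) < 4:
        raise ValueError("CDS too short for a start and any stop")
    seq = cds.upper()
    start = seq[:3]
    tail = len(seq) % 3
    if tail == 0:
        last = seq[-3:]
        if last in stop_codons(code):
            return CodonReport(gene, start, last, True)
        return CodonReport(gene, start, "", False)
    partial = seq[-tail:]
    return CodonReport(gene, start, partial, False)


def at_correlation(records: list[tuple[float, float]]) -> float | None:
    """Squared Pearson correlation between per-gene and genome A+T fractions.

    Returns None when either variable has zero variance.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 paired records")
    xs = [r[0] for r in records]
    ys = [r[1] for r in records]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return None
    r, _ = stats.pearsonr(xs, ys)
    if math.isnan(r):
        return None
    return r * r


def genome_skew_table(named_counts: dict[str, BaseCounts]) -> pd.DataFrame:
    """Tabulate composition and skews for a set of genomes or regions."""
    rows = []
    for name, bc in named_counts.items():
        rep = skew_report(bc)
        rows.append((name, bc.a, bc.t, bc.g, bc.c, bc.unambiguous,
                     rep.at_content, rep.at_skew, rep.gc_skew))
    return pd.DataFrame(rows, columns=["id", "A", "T", "G", "C", "total",
                                       "at_content", "at_skew", "gc_skew"])
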