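"""Tandem-repeat (VNTR) arrays, degenerate copies and homopolymer runs.

The mitochondrial control region of planthoppers carries an array of
~21-bp tandem repeats whose copy number varies among individuals, plus a
long poly-T run.  Detection here is deterministic: a periodicity scan
(self-match of the sequence against itself shifted by the candidate
period) seeds candidate arrays, which are refined copy-by-copy against a
per-column majority consensus.  A copy is *complete* when its identity to
the consensus reaches ``min_identity`` and its length is at least 80% of
the period; degenerate copies remain inside the array but are flagged.
Overlapping candidates are resolved longest-array-first (then smallest
period, so an array detectable at period p and 2p reports the primitive
unit p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

import edlib

from ._codes import revcomp


@dataclass(frozen=True)
class RepeatCopy:
    start: int  # 1-based inclusive
    end: int
    identity: float
    complete: bool


@dataclass(frozen=True)
class RepeatArray:
    start: int  # 1-based inclusive
    end: int
    unit_consensus: str
    copies: tuple[RepeatCopy, ...]

    @property
    def period(self) -> int:
        return len(self.unit_consensus)

    @property
    def copy_number(self) -> int:
        return len(self.copies)

    @property
    def n_complete(self) -> int:
        return sum(1 for c in self.copies if c.complete)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PolyRun:
    base: str
    start: int  # 1-based
    run_length: int


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    n = min(len(a), len(b))
    same = sum(1 for x, y in zip(a, b) if x == y)
    return same / max(len(a), len(b))


def _consensus(copies: list[str], period: int) -> str:
    cols = []
    for j in range(period):
        col = [c[j] for c in copies if len(c) > j]
        cols.append(max(sorted(set(col)), key=col.count) if col else "N")
    return "".join(cols)


def column_variability(seq_copies: list[str], period: int) -> list[float]:
    """Per-column fraction of copies disagreeing with the majority base."""
    out = []
    for j in range(period):
        col = [c[j] for c in seq_copies if len(c) > j]
        if not col:
            out.append(0.0)
            continue
        major = max(sorted(set(col)), key=col.count)
        out.append(1 - col.count(major) / len(col))
    return out


def _refine_array(seq: str, anchor: int, period: int, min_identity: float
                  ) -> RepeatArray | None:
    """Grow an array copy-by-copy around an anchored unit."""
    L = len(seq)
    unit = seq[anchor:anchor + period]
    floor = max(0.5, min_identity - 0.3)  # walk over degenerate copies, stop at junk

    starts = [anchor]
    pos = anchor + period
    while pos + period <= L and _identity(seq[pos:pos + period], unit) >= floor:
        starts.append(pos)
        pos += period
    pos = anchor - period
    while pos >= 0 and _identity(seq[pos:pos + period], unit) >= floor:
        starts.insert(0, pos)
        pos -= period
    copies_seq = [seq[s:s + period] for s in starts]
    consensus = _consensus(copies_seq, period)
    # re-walk identities against the consensus and trim flanking junk copies
    copies = [RepeatCopy(start=s + 1, end=s + period,
                         identity=_identity(cs, consensus),
                         complete=_identity(cs, consensus) >= min_identity)
              for s, cs in zip(starts, copies_seq)]
    # drop boundary junk picked up from the flanks, but keep genuinely
    # degenerate boundary copies (flagged incomplete) inside the array
    keep = min_identity - 0.1
    while copies and copies[0].identity < keep:
        copies = copies[1:]
    while copies and copies[-1].identity < keep:
        copies = copies[:-1]
    if not copies:
        return None
    consensus = _consensus([seq[c.start - 1:c.end] for c in copies], period)
    copies = tuple(RepeatCopy(c.start, c.end,
                              _identity(seq[c.start - 1:c.end], consensus),
                              _identity(seq[c.start - 1:c.end], consensus) >= min_identity)
                   for c in copies)
    return RepeatArray(start=copies[0].start, end=copies[-1].end,
                       unit_consensus=consensus, copies=copies)


def find_tandem_repeats(seq: str, min_period: int = 10, max_period: int = 50,
                        min_copies: int = 3, min_identity: float = 0.8
                        ) -> list[RepeatArray]:
    """Detect tandem-repeat arrays with >= ``min_copies`` complete copies.

    Deterministic periodicity-scan detector; returns non-overlapping arrays
    ordered by position.  Coordinates are 1-based inclusive.
    """
    if min_period < 2 or min_copies < 2:
        raise ValueError("min_period must be >= 2 and min_copies >= 2")
    seq = seq.upper()
    L = len(seq)
    if L < min_period * min_copies:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[RepeatArray] = []
    for p in range(min_period, min(max_period, L // 2) + 1):
        eq = (arr[:-p] == arr[p:]).astype(np.int32)
        if len(eq) < p:
            continue
        window = np.convolve(eq, np.ones(p, dtype=np.int32), mode="valid")
        need = math.ceil(p * min_identity)
        good = window >= need
        # seed refinement at each maximal run of good positions; the run
        # start may sit mid-copy, so try every phase within one period and
        # keep the best-aligned refinement
        prev = False
        for i, g in enumerate(good):
            if g and not prev:
                best = None
                for shift in range(p):
                    ra = _refine_array(seq, i + shift, p, min_identity)
                    if ra is None or ra.n_complete < min_copies:
                        continue
                    if len(set(ra.unit_consensus)) == 1:
                        continue  # a homopolymer is a poly run, not a VNTR
                    # the true copy-boundary phase maximises exact (then
                    # near-perfect) copies: a shifted phase splits every
                    # degenerate copy's damage across two windows and drags
                    # flank bases into the boundary windows
                    exact = sum(1 for c in ra.copies if c.identity == 1.0)
                    near = sum(1 for c in ra.copies
                               if c.identity >= 1 - 1.0 / p - 1e-9)
                    key = (exact, near, ra.length, -ra.start)
                    if best is None or key > best[0]:
                        best = (key, ra)
                if best is not None:
                    candidates.append(best[1])
            prev = g
    # longest-array-first, then smallest (primitive) period, then position
    candidates.sort(key=lambda r: (-r.length, r.period, r.start))
    accepted: list[RepeatArray] = []
    for cand in candidates:
        overlaps = [k for k, acc in enumerate(accepted)
                    if not (cand.end < acc.start or cand.start > acc.end)]
        if not overlaps:
            accepted.append(cand)
            continue
        # primitive-unit rule: a shorter-period candidate whose period divides
        # an accepted array's period and that covers most of its span is the
        # primitive description of the same array
        if len(overlaps) == 1:
            acc = accepted[overlaps[0]]
            shared = min(cand.end, acc.end) - max(cand.start, acc.start) + 1
            if (acc.period % cand.period == 0 and cand.period < acc.period
                    and shared >= 0.8 * acc.length):
                accepted[overlaps[0]] = cand
    accepted.sort(key=lambda r: r.start)
    return accepted


def find_poly_runs(seq: str, base: str, min_len: int = 2) -> list[PolyRun]:
    """All maximal runs of ``base`` of length >= ``min_len`` (1-based starts)."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    base = base.upper()
    seq = seq.upper()
    runs = []
    i = 0
    L = len(seq)
    while i < L:
        if seq[i] == base:
            j = i
            while j < L and seq[j] == base:
                j += 1
            if j - i >= min_len:
                runs.append(PolyRun(base=base, start=i + 1, run_length=j - i))
            i = j
        else:
            i += 1
    return runs


def compare_units(u1: str, u2: str) -> tuple[int, str, int]:
    """Best match between two repeat units over rotations and strands.

    Returns ``(rotation_offset, strand, edit_distance)`` where the rotation
    offset is applied to ``u2`` (or its reverse complement when strand is
    ``'-'``) to minimise the Levenshtein distance to ``u1``.
    """
    if not u1 or not u2:
        raise ValueError("units must be non-empty")
    u1, u2 = u1.upper(), u2.upper()
    best = None
    for strand, base in (("+", u2), ("-", revcomp(u2))):
        for off in range(len(base)):
            rot = base[off:] + base[:off]
            d = edlib.align(rot, u1, mode="NW")["editDistance"]
            key = (d, 0 if strand == "+" else 1, off)
            if best is None or key < best[0]:
                best = (key, off, strand, d)
    return best[1], best[2], best[3]


def vntr_genotype(seqs: dict[str, str], min_period: int = 10, max_period: int = 50,
                  min_copies: int = 3, min_identity: float = 0.8) -> pd.DataFrame:
    """Per-individual copy number of the dominant repeat array.

    The computational analogue of sizing a VNTR length polymorphism across
    individuals: one row per input sequence with the period, copy number
    and array length of its longest detected array (zeros when none).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    rows = []
    for sid, s in seqs.items():
        arrays = find_tandem_repeats(s, min_period, max_period, min_copies, min_identity)
        if arrays:
            top = max(arrays, key=lambda r: r.length)
            rows.append((sid, top.period, top.copy_number, top.length))
        else:
            rows.append((sid, 0, 0, 0))
    return pd.DataFrame(rows, columns=["id", "period", "copy_number", "array_length"])
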