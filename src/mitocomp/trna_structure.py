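"""Cloverleaf folding and arm classification for mitochondrial tRNAs.

Metazoan mitochondrial tRNAs are short (roughly 55-75 nt) and frequently
deviate from the canonical cloverleaf: in planthoppers some serine tRNAs
replace the dihydrouridine (DHU) arm with a simple loop.  This module folds
a candidate sequence into the cloverleaf *layout* — acceptor stem, D arm,
anticodon arm (7-nt loop with the anticodon centred), variable region and
T arm, in 5'->3' order — by deterministic search rather than free-energy
minimisation, and classifies each arm as full, loop-only or absent.

The search anchors the anticodon arm first (at the given anticodon, or the
best-scoring candidate), then maximises Watson-Crick/wobble pairs in the
acceptor, D and T stems inside the windows the anchor leaves available.
Among layouts with equal total pairs the tie-break is: longer acceptor
stem, smaller variable region, leftmost anchor, longer anticodon stem,
then leftmost/tightest D and T placements.  The result is a deterministic
function of (sequence, params).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._codes import INVERTEBRATE_MITO, anticodon_decodes
from .genome_io import CircularGenome, Feature, extract_feature_seq

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}

STATUS_FULL = "full"
STATUS_LOOP_ONLY = "loop_only"
STATUS_ABSENT = "absent"


@dataclass(frozen=True)
class FoldParams:
    """Stem-length targets/minima and layout bounds for cloverleaf search."""

    acceptor_target: int = 7
    acceptor_min: int = 5
    d_target: int = 3
    d_min: int = 2
    anticodon_target: int = 5
    anticodon_min: int = 4
    t_target: int = 4
    t_min: int = 2
    allow_gu: bool = True
    loop_min: int = 3
    d_loop_max: int = 11
    t_loop_max: int = 9
    var_max: int = 23

    def __post_init__(self):
        if (self.acceptor_min > self.acceptor_target or self.d_min > self.d_target
                or self.anticodon_min > self.anticodon_target or self.t_min > self.t_target):
            raise ValueError("stem minima must not exceed targets")


DEFAULT_PARAMS = FoldParams()


@dataclass(frozen=True)
class Arm:
    status: str
    stem_pairs: tuple[tuple[int, int], ...] = ()  # 1-based paired positions
    loop: tuple[int, int] | None = None  # 1-based inclusive span


@dataclass(frozen=True)
class CloverleafStructure:
    sequence: str
    acceptor: Arm
    d_arm: Arm
    anticodon_arm: Arm
    t_arm: Arm
    variable_region: tuple[int, int] | None
    anticodon: str
    anticodon_position: int  # 1-based start of the anticodon triplet
    score: int  # total stem pairs

    def all_pairs(self) -> tuple[tuple[int, int], ...]:
        return (self.acceptor.stem_pairs + self.d_arm.stem_pairs
                + self.anticodon_arm.stem_pairs + self.t_arm.stem_pairs)

    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.all_pairs():
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    def arm_statuses(self) -> dict[str, str]:
        return {"acceptor": self.acceptor.status, "d": self.d_arm.status,
                "anticodon": self.anticodon_arm.status, "t": self.t_arm.status}


@dataclass(frozen=True)
class FoldFailure:
    reason: str
    sequence: str


def valid_pair(x: str, y: str, allow_gu: bool = True) -> bool:
    p = (x, y)
    return p in _WC or (allow_gu and p in _GU)


def _best_arm(seq: str, lo: int, hi: int, smin: int, smax: int,
              loop_min: int, loop_max: int, allow_gu: bool,
              memo: dict, start_max: int | None = None) -> tuple[int, int, int] | None:
    """Best stem-loop inside window [lo, hi): maximise stem length, then
    leftmost start, then smallest loop.  Returns (stem, start, loop) or None."""
    key = (lo, hi, smin, smax, loop_min, loop_max, start_max)
    if key in memo:
        return memo[key]
    result = None
    for s in range(smax, smin - 1, -1):
        hi_start = hi - (2 * s + loop_min) + 1
        if start_max is not None:
            hi_start = min(hi_start, start_max + 1)
        for start in range(lo, hi_start):
            for ll in range(loop_min, loop_max + 1):
                end = start + 2 * s + ll
                if end > hi:
                    break
                if all(valid_pair(seq[start + k], seq[end - 1 - k], allow_gu)
                       for k in range(s)):
                    result = (s, start, ll)
                    break
            if result:
                break
        if result:
            break
    memo[key] = result
    return result


def _acceptor_run(seq: str, target: int, allow_gu: bool) -> int:
    L = len(seq)
    run = 0
    while (run < target and run < L // 2
           and valid_pair(seq[run], seq[L - 1 - run], allow_gu)):
        run += 1
    return run


def fold_cloverleaf(seq: str, expected_anticodon: str | None = None,
                    params: FoldParams = DEFAULT_PARAMS,
                    amino_acid: str | None = None,
                    code: int = INVERTEBRATE_MITO
                    ) -> CloverleafStructure | FoldFailure:
    """Fold a candidate tRNA into the best layout-constrained cloverleaf.

    ``expected_anticodon`` restricts the anchor to exact triplet matches;
    ``amino_acid`` (one-letter) instead restricts candidate anticodons to
    those decoding to that residue.  Returns a FoldFailure when no
    anticodon arm can be anchored.
    """
    seq = seq.upper().replace("U", "T")
    L = len(seq)
    if not 50 <= L <= 100:
        return FoldFailure(f"sequence length {L} outside [50, 100]", seq)
    if expected_anticodon:
        expected_anticodon = expected_anticodon.upper().replace("U", "T")
    gu = params.allow_gu
    run = _acceptor_run(seq, params.acceptor_target, gu)
    memo: dict = {}
    best = None
    best_key = None
    for c in range(params.anticodon_min, params.anticodon_target + 1):
        arm_len = 2 * c + 7
        for p in range(0, L - arm_len + 1):
            if not all(valid_pair(seq[p + k], seq[p + arm_len - 1 - k], gu)
                       for k in range(c)):
                continue
            triplet = seq[p + c + 2:p + c + 5]
            if expected_anticodon is not None:
                if triplet != expected_anticodon:
                    continue
            elif amino_acid is not None:
                if anticodon_decodes(triplet, code) != amino_acid:
                    continue
            for a in range(0, run + 1):
                if p < a or p + arm_len > L - a:
                    continue
                d_fit = _best_arm(seq, a, p, params.d_min, params.d_target,
                                  params.loop_min, params.d_loop_max, gu, memo)
                t_lo, t_hi = p + arm_len, L - a
                t_fit = _best_arm(seq, t_lo, t_hi,
                                  params.t_min, params.t_target,
                                  params.loop_min, params.t_loop_max, gu, memo,
                                  start_max=t_lo + params.var_max)
                d = d_fit[0] if d_fit else 0
                t = t_fit[0] if t_fit else 0
                var = (t_fit[1] - t_lo) if t_fit else 0
                dstart = d_fit[1] if d_fit else 0
                dloop = d_fit[2] if d_fit else 0
                tloop = t_fit[2] if t_fit else 0
                score = a + c + d + t
                key = (score, a, -var, -p, c, d, t, -dstart, -dloop, -tloop)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (a, c, p, d_fit, t_fit)
    if best is None:
        which = (f"no anticodon-arm candidate for anticodon "
                 f"{expected_anticodon or amino_acid or '(any)'}")
        return FoldFailure(which, seq)
    return _assemble(seq, params, *best)


def _assemble(seq: str, params: FoldParams, a: int, c: int, p: int,
              d_fit, t_fit) -> CloverleafStructure:
    L = len(seq)
    arm_len = 2 * c + 7
    acceptor = Arm(
        status=(STATUS_ABSENT if a == 0
                else STATUS_FULL if a >= params.acceptor_min else STATUS_LOOP_ONLY),
        stem_pairs=tuple((i + 1, L - i) for i in range(a)))
    d_lo, d_hi = a, p
    if d_fit:
        ds, dstart, dl = d_fit[0], d_fit[1], d_fit[2]
        d_arm = Arm(STATUS_FULL,
                    tuple((dstart + k + 1, dstart + 2 * ds + dl - k) for k in range(ds)),
                    loop=(dstart + ds + 1, dstart + ds + dl))
    elif d_hi - d_lo >= params.loop_min:
        d_arm = Arm(STATUS_LOOP_ONLY, loop=(d_lo + 1, d_hi))
    else:
        d_arm = Arm(STATUS_ABSENT)
    anticodon_arm = Arm(
        STATUS_FULL,
        tuple((p + k + 1, p + arm_len - k) for k in range(c)),
        loop=(p + c + 1, p + c + 7))
    t_lo, t_hi = p + arm_len, L - a
    if t_fit:
        ts, tstart, tl = t_fit[0], t_fit[1], t_fit[2]
        t_arm = Arm(STATUS_FULL,
                    tuple((tstart + k + 1, tstart + 2 * ts + tl - k) for k in range(ts)),
                    loop=(tstart + ts + 1, tstart + ts + tl))
        variable = (t_lo + 1, tstart) if tstart > t_lo else None
    elif t_hi - t_lo >= params.loop_min:
        t_arm = Arm(STATUS_LOOP_ONLY, loop=(t_lo + 1, t_hi))
        variable = None
    else:
        t_arm = Arm(STATUS_ABSENT)
        variable = None
    d = d_fit[0] if d_fit else 0
    t = t_fit[0] if t_fit else 0
    return CloverleafStructure(
        sequence=seq, acceptor=acceptor, d_arm=d_arm,
        anticodon_arm=anticodon_arm, t_arm=t_arm,
        variable_region=variable,
        anticodon=seq[p + c + 2:p + c + 5],
        anticodon_position=p + c + 3,
        score=a + c + d + t)


LABEL_CANONICAL = "canonical"
LABEL_DHU_LOOP_ONLY = "dhu_loop_only"
LABEL_T_LOOP_ONLY = "t_loop_only"
LABEL_DEGENERATE = "degenerate"


def classify_structure(s: CloverleafStructure) -> str:
    """Summarise arm completeness: canonical iff all four arms are full."""
    acc_ok = s.acceptor.status == STATUS_FULL
    d_ok = s.d_arm.status == STATUS_FULL
    t_ok = s.t_arm.status == STATUS_FULL
    if acc_ok and d_ok and t_ok:
        return LABEL_CANONICAL
    if acc_ok and t_ok and not d_ok:
        return LABEL_DHU_LOOP_ONLY
    if acc_ok and d_ok and not t_ok:
        return LABEL_T_LOOP_ONLY
    return LABEL_DEGENERATE


@dataclass(frozen=True)
class TrnaReport:
    gene: str
    length: int
    anticodon: str | None
    expected_anticodon: str | None
    anticodon_match: bool | None
    label: str
    structure: CloverleafStructure | None = None
    failure: str | None = None


# one-letter amino acid encoded by each canonical tRNA gene label
GENE_TO_AA = {f"trn{x}": x for x in "ACDEFGHIKMNPQRSTVWY"} | {
    "trnL1": "L", "trnL2": "L", "trnS1": "S", "trnS2": "S"}


def validate_trna_annotation(genome: CircularGenome, feature: Feature,
                             params: FoldParams = DEFAULT_PARAMS,
                             code: int = INVERTEBRATE_MITO) -> TrnaReport:
    """Extract, fold and classify an annotated tRNA gene.

    The anticodon is anchored at the annotated triplet when present,
    otherwise inferred from the amino acid implied by the gene name; a
    mismatch between the folded anticodon and the annotation is flagged.
    """
    if feature.ftype != "tRNA":
        raise ValueError(f"{feature.name}: not a tRNA feature")
    seq = extract_feature_seq(genome, feature)
    aa = GENE_TO_AA.get(feature.name)
    expected = feature.anticodon.upper().replace("U", "T") if feature.anticodon else None
    folded = fold_cloverleaf(seq, expected_anticodon=expected, params=params,
                             amino_acid=None if expected else aa, code=code)
    if isinstance(folded, FoldFailure):
        # retry unconstrained so the report can still show what folded best
        folded2 = fold_cloverleaf(seq, params=params, code=code)
        anticodon = None if isinstance(folded2, FoldFailure) else folded2.anticodon
        match = (anticodon == expected) if expected and anticodon else None
        return TrnaReport(feature.name, len(seq), anticodon, expected, match,
                          LABEL_DEGENERATE,
                          structure=None if isinstance(folded2, FoldFailure) else folded2,
                          failure=folded.reason)
    match: bool | None
    if expected:
        match = folded.anticodon == expected
    elif aa:
        match = anticodon_decodes(folded.anticodon, code) == aa
    else:
        match = None
    return TrnaReport(feature.name, len(seq), folded.anticodon, expected, match,
                      classify_structure(folded), structure=folded)


def batch_trna_report(genome: CircularGenome, table, params: FoldParams = DEFAULT_PARAMS,
                      code: int = INVERTEBRATE_MITO) -> pd.DataFrame:
    """Fold every annotated tRNA; one row per gene copy."""
    rows = []
    for f in table.of_type("tRNA"):
        rep = validate_trna_annotation(genome, f, params=params, code=code)
        rows.append((f.name, f.copy_index, rep.length, rep.anticodon or "",
                     rep.label, rep.anticodon_match))
    return pd.DataFrame(rows, columns=["gene", "copy", "length", "anticodon",
                                       "label", "anticodon_match"])
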